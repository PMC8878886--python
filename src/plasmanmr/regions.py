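"""Spectral-region table construction.

Applies the analysis window (5.5-0.5 ppm) and the water/EDTA exclusion
windows, normalizes each sample's deconvolved intensities by its total
retained integral, discovers cross-sample regions by single-linkage
clustering of fitted peak centers with an 80%-presence rule over individual
samples, and annotates regions with candidate metabolites.  Pooled controls
never vote in region discovery; they are projected onto the discovered
regions afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import MetaboliteSpec, multiplet_lines

__all__ = [
    "RegionConfig",
    "RegionDefinition",
    "RegionMatrix",
    "DegenerateSampleError",
    "EmptyRegionSetError",
    "apply_exclusions",
    "normalize_total",
    "build_regions",
    "annotate_regions",
]

DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = (
    (4.5, 5.1),    # residual water
    (3.55, 3.68),  # EDTA
    (3.04, 3.29),
    (2.67, 2.72),
    (2.52, 2.59),
)


class DegenerateSampleError(RuntimeError):
    """A sample retained no integrable intensity after exclusions."""


class EmptyRegionSetError(RuntimeError):
    """No cluster met the presence threshold."""


@dataclass(frozen=True)
class RegionConfig:
    analysis_window: tuple[float, float] = (0.5, 5.5)
    exclusion_windows: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS
    presence_threshold: float = 0.80
    cluster_tolerance_ppm: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.analysis_window
        if lo >= hi:
            raise ValueError("analysis window must satisfy lo < hi")
        if not (0.0 < self.presence_threshold <= 1.0):
            raise ValueError("presence_threshold must be in (0, 1]")
        if self.cluster_tolerance_ppm <= 0:
            raise ValueError("cluster_tolerance_ppm must be > 0")


@dataclass(frozen=True)
class RegionDefinition:
    region_id: int
    lo_ppm: float
    hi_ppm: float
    candidate_metabolites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.lo_ppm >= self.hi_ppm:
            raise ValueError("region must satisfy lo_ppm < hi_ppm")

    @property
    def label(self) -> str:
        return f"r{self.lo_ppm:.2f}-{self.hi_ppm:.2f}"


@dataclass
class RegionMatrix:
    """Samples x regions table of normalized intensities."""

    sample_ids: list[str]
    regions: list[RegionDefinition]
    values: pd.DataFrame  # index sample_id, columns region labels
    total_valid_intensity: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def region_values(self, region_id: int) -> pd.Series:
        for r in self.regions:
            if r.region_id == region_id:
                return self.values[r.label]
        raise KeyError(f"no region with id {region_id}")


def apply_exclusions(peaks: pd.DataFrame,
                     config: RegionConfig | None = None) -> pd.DataFrame:
    """Drop peaks outside the analysis window or inside any exclusion window.

    Boundaries are exclusion-inclusive: a center exactly on an exclusion (or
    analysis-window) boundary is removed.
    """
    cfg = config or RegionConfig()
    lo, hi = cfg.analysis_window
    c = peaks["center_ppm"]
    keep = (c > lo) & (c < hi)
    for (elo, ehi) in cfg.exclusion_windows:
        keep &= ~((c >= min(elo, ehi)) & (c <= max(elo, ehi)))
    out = peaks.loc[keep].reset_index(drop=True)
    out.attrs = dict(peaks.attrs)
    return out


def normalize_total(peaks: pd.DataFrame, sample_id: str = "?") -> pd.DataFrame:
    """Divide every integral by the sample's total retained integral so the
    normalized integrals sum to 1."""
    total = float(peaks["integral"].sum())
    if total <= 0:
        raise DegenerateSampleError(
            f"sample {sample_id!r}: total retained integral is zero")
    out = peaks.copy()
    out["integral"] = out["integral"] / total
    out.attrs = dict(peaks.attrs)
    out.attrs["total_valid_intensity"] = total
    return out


def _single_linkage_clusters(centers: np.ndarray, tol: float) -> list[np.ndarray]:
    """Chain-linkage clustering on a line: consecutive sorted centers closer
    than ``tol`` join the same cluster.  Deterministic; no randomness."""
    order = np.argsort(centers)
    clusters: list[list[int]] = []
    prev = None
    for i in order:
        c = centers[i]
        if prev is None or c - prev > tol:
            clusters.append([i])
        else:
            clusters[-1].append(i)
        prev = c
    return [np.array(ix) for ix in clusters]


def build_regions(all_peaks: dict[str, pd.DataFrame], individual_ids: list[str],
                  config: RegionConfig | None = None) -> RegionMatrix:
    """Discover spectral regions from individual samples and build the
    samples x regions normalized-intensity matrix.

    Peak centers of the individual samples are clustered by single linkage
    with the configured tolerance; clusters represented in at least the
    presence-threshold fraction of individual samples become regions.  Region
    bounds are the cluster center span padded by half the tolerance, trimmed
    against neighbours, exclusion windows and the analysis window.  Every
    sample in ``all_peaks`` (pooled controls included) is then projected onto
    the regions; a sample's value is the sum of its normalized integrals with
    centers inside the region (0 if absent).
    """
    cfg = config or RegionConfig()
    if len(individual_ids) < 2:
        raise ValueError("region discovery needs at least 2 individual samples")

    centers, owners = [], []
    for sid in individual_ids:
        pk = all_peaks[sid]
        centers.extend(pk["center_ppm"].tolist())
        owners.extend([sid] * len(pk))
    centers = np.asarray(centers, dtype=float)
    owners = np.asarray(owners, dtype=object)
    if centers.size == 0:
        raise EmptyRegionSetError("no peaks available for region discovery")

    clusters = _single_linkage_clusters(centers, cfg.cluster_tolerance_ppm)
    n_ind = len(individual_ids)
    half = cfg.cluster_tolerance_ppm / 2.0
    kept: list[tuple[float, float]] = []
    for ix in clusters:
        present = len(set(owners[ix]))
        if present / n_ind >= cfg.presence_threshold:
            kept.append((float(centers[ix].min()) - half,
                         float(centers[ix].max()) + half))
    if not kept:
        raise EmptyRegionSetError(
            f"no cluster reached the {cfg.presence_threshold:.0%} presence threshold")
    kept.sort()

    # trim: clip to the analysis window, truncate at exclusion windows and
    # split overlaps with neighbours at the midpoint
    alo, ahi = cfg.analysis_window
    bounds: list[tuple[float, float]] = []
    for k, (lo, hi) in enumerate(kept):
        lo, hi = max(lo, alo), min(hi, ahi)
        for (elo, ehi) in cfg.exclusion_windows:
            elo, ehi = min(elo, ehi), max(elo, ehi)
            if lo < ehi and hi > elo:  # overlap
                if lo >= elo:
                    lo = ehi
                elif hi <= ehi:
                    hi = elo
        if k > 0 and bounds and lo < bounds[-1][1]:
            mid = 0.5 * (lo + bounds[-1][1])
            bounds[-1] = (bounds[-1][0], mid)
            lo = np.nextafter(mid, np.inf)
        if lo < hi:
            bounds.append((lo, hi))

    # regions numbered down-field (high ppm) first
    bounds.sort(key=lambda b: -b[0])
    regions = [RegionDefinition(region_id=i, lo_ppm=round(lo, 6), hi_ppm=round(hi, 6))
               for i, (lo, hi) in enumerate(bounds)]

    sample_ids = list(all_peaks.keys())
    values = np.zeros((len(sample_ids), len(regions)))
    totals = {}
    for si, sid in enumerate(sample_ids):
        pk = all_peaks[sid]
        c = pk["center_ppm"].to_numpy()
        v = pk["integral"].to_numpy()
        totals[sid] = pk.attrs.get("total_valid_intensity", float("nan"))
        for ri, r in enumerate(regions):
            inside = (c >= r.lo_ppm) & (c <= r.hi_ppm)
            values[si, ri] = v[inside].sum()
    frame = pd.DataFrame(values, index=sample_ids,
                         columns=[r.label for r in regions])
    return RegionMatrix(sample_ids=sample_ids, regions=regions, values=frame,
                        total_valid_intensity=pd.Series(totals))


def annotate_regions(regions: list[RegionDefinition],
                     library: list[MetaboliteSpec],
                     freq_mhz: float = 600.0) -> list[RegionDefinition]:
    """Attach candidate metabolite names: every library metabolite with any
    multiplet line inside a region (closed interval) is a candidate there.
    The mapping is many-to-many by construction."""
    out = []
    for r in regions:
        names = []
        for m in library:
            if any(r.lo_ppm <= ppm <= r.hi_ppm
                   for (ppm, _w) in multiplet_lines(m, freq_mhz)):
                names.append(m.name)
        out.append(RegionDefinition(region_id=r.region_id, lo_ppm=r.lo_ppm,
                                    hi_ppm=r.hi_ppm,
                                    candidate_metabolites=tuple(names)))
    return out
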