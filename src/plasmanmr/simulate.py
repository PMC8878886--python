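"""Synthetic plasma-cohort generator.

Produces complex time-domain FIDs for individual AD / non-AD samples and for
pooled QA/QC controls, with the statistical structure the downstream analysis
assumes: log-normal metabolite concentrations with a group effect, multiplet
fine structure from scalar coupling, broad lipid/macromolecule background,
additive complex Gaussian noise, per-sample chemical-shift and phase errors,
and clinical scores (CDR, CDR-SoB, MMSE) correlated with group.

Pooling is modelled at the concentration level: a pooled replicate's
concentration vector is the arithmetic mean of its contributors' vectors, and
each aliquot is re-synthesised to an FID with fresh measurement noise, the way
physically mixed plasma would be re-acquired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionParams",
    "MetaboliteSpec",
    "SimConfig",
    "FID",
    "Cohort",
    "default_metabolite_library",
    "multiplet_lines",
    "simulate_cohort",
    "make_pooled_controls",
    "add_pooled_controls",
    "pooled_replicate_volumes",
]

# Binomial line-intensity patterns for first-order multiplets (n lines from
# coupling to n-1 equivalent spins): 1:1 doublet, 1:2:1 triplet, ...
def _binomial_pattern(n_lines: int) -> np.ndarray:
    row = np.array([math.comb(n_lines - 1, k) for k in range(n_lines)], dtype=float)
    return row / row.sum()


@dataclass(frozen=True)
class AcquisitionParams:
    """Spectrometer acquisition settings.

    Defaults mirror a 600 MHz HRMAS CPMG plasma experiment: 16 ppm spectral
    width, 16 K time-domain points, 100 rotor-synchronized CPMG pulses at a
    3600 Hz spinning rate, 5 s recycle time.
    """

    spectrometer_freq_mhz: float = 600.0
    spectral_width_ppm: float = 16.0
    n_points_td: int = 16384
    n_cpmg_pulses: int = 100
    spin_rate_hz: float = 3600.0
    recycle_time_s: float = 5.0
    carrier_ppm: float = 4.7  # transmitter offset, near water

    def __post_init__(self) -> None:
        for name in (
            "spectrometer_freq_mhz",
            "spectral_width_ppm",
            "n_points_td",
            "spin_rate_hz",
            "recycle_time_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"AcquisitionParams.{name} must be > 0")
        if self.n_cpmg_pulses < 0:
            raise ValueError("AcquisitionParams.n_cpmg_pulses must be >= 0")

    @property
    def spectral_width_hz(self) -> float:
        return self.spectral_width_ppm * self.spectrometer_freq_mhz

    @property
    def dwell_s(self) -> float:
        # one complex point per 1/(2 SW) seconds; the digitized band is thus
        # twice the nominal width (twofold oversampling) and the analyte
        # window sits comfortably inside it
        return 1.0 / (2.0 * self.spectral_width_hz)


@dataclass(frozen=True)
class MetaboliteSpec:
    """One simulated metabolite.

    ``multiplet`` is a list of ``(center_ppm, relative_intensity, j_split_hz,
    n_lines)`` tuples, one per resolved multiplet.  ``center_ppm`` is the
    position of the *up-field* (lowest ppm) line of the multiplet, so a
    doublet anchored at 1.32 ppm keeps a line at exactly 1.32 ppm regardless
    of field strength.  ``base_log_concentration`` and ``group_log2_effect``
    are on a log2 scale; the effect is AD minus non-AD.  ``cv`` is the
    within-group coefficient of variation of concentration.
    """

    name: str
    multiplet: tuple[tuple[float, float, float, int], ...]
    base_log_concentration: float
    group_log2_effect: float = 0.0
    cv: float = 0.2

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        total = 0.0
        for center, rel, j, n in self.multiplet:
            if rel < 0 or j < 0 or n < 1:
                raise ValueError(f"invalid multiplet entry for {self.name}")
            total += rel
        if total <= 0:
            raise ValueError(f"{self.name}: relative intensities must sum > 0")


def multiplet_lines(spec: MetaboliteSpec, freq_mhz: float) -> list[tuple[float, float]]:
    """Expand a metabolite's multiplets into individual (ppm, weight) lines.

    Lines of an n-line multiplet sit at center + k*J/freq for k = 0..n-1
    (up-field anchor), with binomial relative weights normalized so each
    multiplet's weights sum to its relative_intensity.
    """
    lines: list[tuple[float, float]] = []
    for center, rel, j, n in spec.multiplet:
        weights = _binomial_pattern(n) * rel
        j_ppm = j / freq_mhz
        for k in range(n):
            lines.append((center + k * j_ppm, weights[k]))
    return lines


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation settings; identical (config, seed) pairs reproduce
    bit-identical cohorts."""

    n_ad: int = 16
    n_non_ad: int = 19
    seed: int = 0
    noise_sd: float = 0.05
    shift_jitter_sd: float = 0.005  # ppm
    phase0_error_range: float = 20.0  # degrees, errors drawn uniform +/- range
    phase1_error_range: float = 10.0
    baseline_amplitude: float = 20.0
    lipid_background_scale: float = 1.0
    lipid_cv: float = 0.30  # per-sample biological variation of lipid amplitudes
    natural_linewidth_hz: float = 2.0
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        if self.n_ad < 0 or self.n_non_ad < 0:
            raise ValueError("sample counts must be >= 0")
        for name in ("noise_sd", "shift_jitter_sd", "phase0_error_range",
                     "phase1_error_range", "baseline_amplitude",
                     "lipid_background_scale", "lipid_cv", "natural_linewidth_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig.{name} must be >= 0")


@dataclass
class FID:
    """Complex free-induction decay with its acquisition context."""

    points: np.ndarray
    dwell_s: float
    acquisition: AcquisitionParams

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=complex)
        if self.points.size == 0:
            raise ValueError("FID must contain at least one point")
        if self.dwell_s <= 0:
            raise ValueError("dwell_s must be > 0")


@dataclass
class Cohort:
    """A simulated cohort: per-sample metadata, FIDs and the latent
    concentration vectors (metabolites and lipid components) that generated
    them."""

    metadata: pd.DataFrame  # sample_id, group, is_pooled, cdr_global, cdr_sob, mmse, age, sex
    fids: dict[str, FID]
    concentrations: pd.DataFrame  # samples x metabolites
    lipid_amplitudes: pd.DataFrame  # samples x lipid components
    library: list[MetaboliteSpec]
    config: SimConfig

    @property
    def individual_ids(self) -> list[str]:
        m = self.metadata
        return list(m.loc[~m["is_pooled"], "sample_id"])

    @property
    def pooled_ids(self) -> list[str]:
        m = self.metadata
        return list(m.loc[m["is_pooled"], "sample_id"])


# --------------------------------------------------------------------------
# metabolite library
# --------------------------------------------------------------------------

# Positions are textbook 1H plasma shifts (rounded); concentrations (log2),
# group effects and CVs are simulation choices.  Effect signs follow the
# reported AD directionality: sugars, glycine/serine, choline compounds and
# methylated amino acids up in AD; valine, glutamine and Krebs-cycle organic
# acids down.  Some lines deliberately fall inside the water/EDTA exclusion
# windows (choline, citrate) so the exclusion logic is exercised on
# realistic interferents.
_LIBRARY: tuple[MetaboliteSpec, ...] = (
    MetaboliteSpec("lactate", ((1.32, 3.0, 7.0, 2), (4.11, 1.0, 7.0, 4)), 3.0, +0.3, 0.20),
    MetaboliteSpec("alanine", ((1.48, 1.5, 7.2, 2),), 1.5, 0.0, 0.20),
    MetaboliteSpec("valine", ((0.99, 1.0, 7.0, 2), (1.04, 1.0, 7.0, 2)), 1.2, -0.4, 0.20),
    MetaboliteSpec("leucine", ((0.96, 1.5, 6.5, 2),), 1.0, 0.0, 0.20),
    MetaboliteSpec("isoleucine", ((1.01, 1.0, 7.0, 2),), 0.5, 0.0, 0.20),
    MetaboliteSpec("threonine", ((1.34, 1.5, 6.5, 2), (4.25, 0.5, 0.0, 1)), 1.0, +0.3, 0.20),
    MetaboliteSpec(
        "glucose",
        (
            (5.23, 0.5, 3.8, 2),   # alpha anomeric doublet
            (3.25, 0.6, 0.0, 1),
            (3.40, 1.0, 0.0, 1),
            (3.47, 1.0, 0.0, 1),
            (3.72, 1.0, 0.0, 1),
            (3.84, 0.8, 0.0, 1),
        ),
        3.5, +0.6, 0.20,
    ),
    MetaboliteSpec("glycine", ((3.54, 1.0, 0.0, 1),), 1.5, +0.5, 0.20),
    MetaboliteSpec("serine", ((3.95, 1.0, 0.0, 1),), 1.0, +0.4, 0.20),
    MetaboliteSpec("glutamine", ((2.13, 1.0, 0.0, 1), (2.45, 1.2, 0.0, 1)), 1.5, -0.5, 0.20),
    MetaboliteSpec("glutamate", ((2.05, 1.0, 0.0, 1), (2.34, 1.0, 0.0, 1)), 1.2, -0.2, 0.20),
    MetaboliteSpec("citrate", ((2.54, 1.0, 0.0, 1), (2.66, 1.0, 0.0, 1)), 1.0, -0.5, 0.20),
    MetaboliteSpec("choline", ((3.20, 1.2, 0.0, 1),), 1.2, +0.4, 0.20),
    MetaboliteSpec("creatinine", ((3.03, 1.0, 0.0, 1), (4.05, 0.7, 0.0, 1)), 0.8, 0.0, 0.20),
    MetaboliteSpec("acetate", ((1.92, 0.8, 0.0, 1),), 0.8, -0.2, 0.20),
    MetaboliteSpec("pyruvate", ((2.37, 0.8, 0.0, 1),), 0.6, +0.3, 0.20),
    MetaboliteSpec("succinate", ((2.41, 0.6, 0.0, 1),), 0.5, -0.3, 0.20),
    MetaboliteSpec("lysine", ((1.72, 1.0, 0.0, 1), (1.91, 0.8, 0.0, 1)), 1.0, 0.0, 0.20),
    MetaboliteSpec("sarcosine", ((2.73, 0.8, 0.0, 1),), 0.6, +0.4, 0.20),
)

# Broad lipid/macromolecule components surviving the CPMG filter:
# (center_ppm, fwhm_hz, amplitude).  These dominate the standard error of
# the regions they fall in, matching the behaviour of measurable plasma lipids.
_LIPID_COMPONENTS: tuple[tuple[float, float, float], ...] = (
    (0.90, 150.0, 8.0),
    (1.30, 250.0, 12.0),
    (2.02, 120.0, 5.0),
)


def default_metabolite_library() -> list[MetaboliteSpec]:
    """Return the built-in plasma metabolite library (a fresh list each call;
    the entries themselves are immutable)."""
    return list(_LIBRARY)


# --------------------------------------------------------------------------
# concentration and clinical-score draws
# --------------------------------------------------------------------------

def _draw_concentration(spec: MetaboliteSpec, group: str, rng: np.random.Generator) -> float:
    """Log-normal concentration around the group mean on the log2 scale."""
    half = 0.5 * spec.group_log2_effect
    mean_log2 = spec.base_log_concentration + (half if group == "AD" else -half)
    conc = 2.0 ** mean_log2
    if spec.cv > 0:
        sigma = math.sqrt(math.log1p(spec.cv ** 2))
        conc *= math.exp(sigma * rng.standard_normal() - 0.5 * sigma ** 2)
    return conc


def draw_concentrations(library: list[MetaboliteSpec], group: str,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-metabolite concentration vector for one sample of ``group``."""
    return np.array([_draw_concentration(m, group, rng) for m in library])


def _draw_clinical(group: str, rng: np.random.Generator) -> dict:
    """Clinical scores shifted by group: AD gets higher CDR / SoB, lower MMSE.

    Distributions are discretized Gaussians over the scales' valid ranges.
    """
    if group == "AD":
        cdr = float(rng.choice([0.5, 1.0, 2.0, 3.0], p=[0.25, 0.40, 0.25, 0.10]))
        sob = round(max(0.5, rng.normal(6.0, 3.0)) * 2) / 2
        mmse = int(np.clip(round(rng.normal(20.0, 4.0)), 0, 30))
        sex = "F" if rng.random() < 7 / 16 else "M"
        age = rng.normal(77.4, 3.6) if sex == "F" else rng.normal(78.6, 8.5)
    else:
        cdr = float(rng.choice([0.0, 0.5], p=[0.75, 0.25]))
        sob = round(max(0.0, rng.normal(0.5, 0.8)) * 2) / 2
        mmse = int(np.clip(round(rng.normal(28.5, 1.5)), 0, 30))
        sex = "F" if rng.random() < 10 / 19 else "M"
        age = rng.normal(60.2, 7.7) if sex == "F" else rng.normal(63.2, 12.6)
    return {"cdr_global": cdr, "cdr_sob": sob, "mmse": mmse,
            "age": round(float(age), 1), "sex": sex}


# --------------------------------------------------------------------------
# FID synthesis
# --------------------------------------------------------------------------

def draw_lipid_amplitudes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-sample lipid-component amplitudes: scaled defaults with log-normal
    biological variation of the configured CV."""
    amps = np.array([a for (_p, _w, a) in _LIPID_COMPONENTS])
    amps = amps * config.lipid_background_scale
    if config.lipid_cv > 0:
        sigma = math.sqrt(math.log1p(config.lipid_cv ** 2))
        amps = amps * np.exp(sigma * rng.standard_normal(amps.size)
                             - 0.5 * sigma ** 2)
    return amps


def _synthesize_fid(concentrations: np.ndarray, lipid_amps: np.ndarray,
                    library: list[MetaboliteSpec],
                    config: SimConfig, rng: np.random.Generator) -> FID:
    """Sum of decaying complex sinusoids + lipid background + baseline hump +
    complex Gaussian noise, with per-sample shift and phase errors."""
    acq = config.acquisition
    n = acq.n_points_td
    dwell = acq.dwell_s
    t = np.arange(n) * dwell
    fmhz = acq.spectrometer_freq_mhz

    shift = rng.normal(0.0, config.shift_jitter_sd) if config.shift_jitter_sd > 0 else 0.0
    phi0 = math.radians(rng.uniform(-config.phase0_error_range, config.phase0_error_range)) \
        if config.phase0_error_range > 0 else 0.0
    phi1 = math.radians(rng.uniform(-config.phase1_error_range, config.phase1_error_range)) \
        if config.phase1_error_range > 0 else 0.0

    signal = np.zeros(n, dtype=complex)

    def add_line(ppm: float, amplitude: float, fwhm_hz: float) -> None:
        f_hz = (ppm + shift - acq.carrier_ppm) * fmhz
        f_norm = f_hz * dwell  # normalized frequency in [-0.5, 0.5)
        phase = phi0 + phi1 * f_norm
        r2 = math.pi * fwhm_hz
        signal[:] += amplitude * np.exp(
            1j * (2.0 * math.pi * f_hz * t + phase) - r2 * t
        )

    for conc, spec in zip(concentrations, library):
        for ppm, weight in multiplet_lines(spec, fmhz):
            add_line(ppm, conc * weight, config.natural_linewidth_hz)

    if config.lipid_background_scale > 0:
        for (ppm, fwhm, _amp), a in zip(_LIPID_COMPONENTS, lipid_amps):
            add_line(ppm, a, fwhm)

    if config.baseline_amplitude > 0:
        # very fast-decaying component -> smooth spectrum-wide baseline roll
        add_line(acq.carrier_ppm - 1.0, config.baseline_amplitude, 1600.0)

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=(n, 2))
        signal += noise[:, 0] + 1j * noise[:, 1]

    return FID(points=signal, dwell_s=dwell, acquisition=acq)



def _sample_rng(seed: int, index: int, namespace: int = 0) -> np.random.Generator:
    # counter-based substream: adding samples never perturbs earlier draws
    return np.random.default_rng([seed, namespace, index])


def simulate_cohort(config: SimConfig, library: list[MetaboliteSpec] | None = None) -> Cohort:
    """Simulate an AD / non-AD cohort of individual plasma samples.

    Returns a :class:`Cohort` with one FID per sample, the latent per-sample
    concentration vectors, and clinical metadata whose CDR/SoB/MMSE scores
    correlate with group.  Bit-identical for identical (config, seed).
    """
    if library is None:
        library = default_metabolite_library()
    groups = ["AD"] * config.n_ad + ["non-AD"] * config.n_non_ad
    rows, fids, conc_rows, lipid_rows, ids = [], {}, [], [], []
    for i, group in enumerate(groups):
        rng = _sample_rng(config.seed, i, namespace=0)
        sid = f"{'AD' if group == 'AD' else 'NA'}{i + 1:03d}"
        conc = draw_concentrations(library, group, rng)
        lipids = draw_lipid_amplitudes(config, rng)
        fid = _synthesize_fid(conc, lipids, library, config, rng)
        clinical = _draw_clinical(group, rng)
        rows.append({"sample_id": sid, "group": group, "is_pooled": False, **clinical})
        fids[sid] = fid
        conc_rows.append(conc)
        lipid_rows.append(lipids)
        ids.append(sid)
    columns = ["sample_id", "group", "is_pooled", "cdr_global", "cdr_sob",
               "mmse", "age", "sex"]
    metadata = pd.DataFrame(rows, columns=columns)
    concentrations = pd.DataFrame(
        conc_rows, index=ids, columns=[m.name for m in library]
    )
    lipid_cols = [f"lipid_{p:.2f}ppm" for (p, _w, _a) in _LIPID_COMPONENTS]
    lipid_amplitudes = pd.DataFrame(lipid_rows, index=ids, columns=lipid_cols)
    return Cohort(metadata=metadata, fids=fids, concentrations=concentrations,
                  lipid_amplitudes=lipid_amplitudes, library=library,
                  config=config)


def make_pooled_controls(cohort: Cohort, contributor_ids: list[str],
                         n_replicates: int = 2, n_splits: int = 3
                         ) -> tuple[pd.DataFrame, dict[str, FID],
                                    pd.DataFrame, pd.DataFrame]:
    """Construct pooled QA/QC controls from a cohort.

    Pooling acts on concentration vectors: each replicate pool's vector is the
    arithmetic mean of the contributors' vectors (mixing equal aliquots of
    plasma).  Each replicate is split into ``n_splits`` aliquots, and every
    aliquot is re-synthesised to an FID with fresh measurement noise, shift
    and phase errors, mimicking independent acquisitions.  Returns
    ``n_replicates * n_splits`` pooled FIDs with metadata carrying no clinical
    scores.
    """
    if n_replicates < 1 or n_splits < 1:
        raise ValueError("n_replicates and n_splits must be >= 1")
    if not contributor_ids:
        raise ValueError("contributor_ids must be non-empty")
    missing = set(contributor_ids) - set(cohort.concentrations.index)
    if missing:
        raise ValueError(f"contributors not in cohort: {sorted(missing)}")

    # mean computed against the first contributor as offset: exactly the
    # contributor value when all contributors coincide (a plain column mean
    # can be off by an ulp, enough to flip knife-edge fitting decisions in
    # the noise-free limit)
    def _offset_mean(frame: pd.DataFrame) -> np.ndarray:
        base = frame.loc[contributor_ids[0]].to_numpy()
        deltas = frame.loc[contributor_ids].to_numpy() - base
        return base + deltas.mean(axis=0)

    pool_vector = _offset_mean(cohort.concentrations)
    pool_lipids = _offset_mean(cohort.lipid_amplitudes)
    rows, fids, conc_rows, lipid_rows, ids = [], {}, [], [], []
    k = 0
    for rep in range(n_replicates):
        for split in range(n_splits):
            rng = _sample_rng(cohort.config.seed, k, namespace=1)
            sid = f"POOL{rep + 1}{chr(ord('a') + split)}"
            fid = _synthesize_fid(pool_vector, pool_lipids, cohort.library,
                                  cohort.config, rng)
            rows.append({
                "sample_id": sid, "group": "pooled", "is_pooled": True,
                "cdr_global": np.nan, "cdr_sob": np.nan, "mmse": np.nan,
                "age": np.nan, "sex": "",
            })
            fids[sid] = fid
            conc_rows.append(pool_vector)
            lipid_rows.append(pool_lipids)
            ids.append(sid)
            k += 1
    metadata = pd.DataFrame(rows, columns=list(cohort.metadata.columns))
    concentrations = pd.DataFrame(conc_rows, index=ids,
                                  columns=list(cohort.concentrations.columns))
    lipid_amplitudes = pd.DataFrame(lipid_rows, index=ids,
                                    columns=list(cohort.lipid_amplitudes.columns))
    return metadata, fids, concentrations, lipid_amplitudes


def add_pooled_controls(cohort: Cohort, contributor_ids: list[str] | None = None,
                        n_replicates: int = 2, n_splits: int = 3) -> Cohort:
    """Return a new cohort extended with pooled controls (contributors default
    to every individual sample)."""
    if contributor_ids is None:
        contributor_ids = cohort.individual_ids
    meta, fids, conc, lipids = make_pooled_controls(cohort, contributor_ids,
                                                    n_replicates, n_splits)
    return Cohort(
        metadata=pd.concat([cohort.metadata, meta], ignore_index=True),
        fids={**cohort.fids, **fids},
        concentrations=pd.concat([cohort.concentrations, conc]),
        lipid_amplitudes=pd.concat([cohort.lipid_amplitudes, lipids]),
        library=cohort.library,
        config=cohort.config,
    )


def pooled_replicate_volumes(n_contributors: int = 30, aliquot_ul: float = 2.5,
                             d2o_ul: float = 7.5) -> tuple[float, float]:
    """Volumes (plasma_ul, d2o_ul) of one pooled replicate: equal plasma
    aliquots from every contributor plus the D2O lock solvent.  The default
    30 x 2.5 uL + 7.5 uL gives an H2O:D2O ratio of 10:1."""
    if n_contributors < 1 or aliquot_ul <= 0 or d2o_ul <= 0:
        raise ValueError("invalid pooling volumes")
    return n_contributors * aliquot_ul, d2o_ul


def noise_free(config: SimConfig) -> SimConfig:
    """Variant of ``config`` with every stochastic acquisition element disabled
    (noise, shift jitter, phase errors, lipid amplitude variation).
    Concentration CVs live on the library; use ``zero_cv_library`` for those."""
    return replace(config, noise_sd=0.0, shift_jitter_sd=0.0,
                   phase0_error_range=0.0, phase1_error_range=0.0, lipid_cv=0.0)


def zero_cv_library(library: list[MetaboliteSpec]) -> list[MetaboliteSpec]:
    """Copy of the library with all concentration CVs set to zero."""
    return [replace(m, cv=0.0) for m in library]
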