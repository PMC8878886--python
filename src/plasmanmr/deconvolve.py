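"""Resonance deconvolution: decompose a processed spectrum into pseudo-Voigt
lines by segmented bounded nonlinear least squares.

The spectrum is split into segments at low-intensity gaps; within each
segment a sum of pseudo-Voigt lines (Lorentzian-Gaussian mixture, pure
Lorentzian available by fixing the Gaussian fraction to 0) is fitted,
initialized at picked candidates, with lines added greedily while the
residual norm keeps improving.  The output peak table records center, height,
width, shape fraction and closed-form integral per fitted line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.signal

from .preprocess import Spectrum, estimate_noise_sd

__all__ = [
    "DeconvConfig",
    "pick_peaks",
    "fit_lineshapes",
    "reconstruct",
    "pseudo_voigt",
    "pseudo_voigt_area",
    "PEAK_COLUMNS",
]

PEAK_COLUMNS = ["center_ppm", "height", "fwhm_hz", "gauss_fraction",
                "integral", "segment_id"]

_GAUSS_AREA = 0.5 * math.sqrt(math.pi / math.log(2.0))


@dataclass(frozen=True)
class DeconvConfig:
    snr_threshold: float = 5.0
    noise_window_ppm: tuple[float, float] = (-1.5, -0.5)
    fit_window_ppm: tuple[float, float] = (0.2, 6.0)
    segment_gap_ppm: float = 0.02       # low-intensity run splitting segments
    segment_threshold_sigma: float = 2.0
    center_bound_ppm: float = 0.01      # candidate center box
    fwhm_bounds_hz: tuple[float, float] = (0.3, 400.0)
    # two-tier decomposition: components broader than sharp_fwhm_max_hz
    # (lipid / macromolecule humps) are fitted globally against the
    # morphological-opening floor, sharp resonances locally on the residual
    sharp_fwhm_max_hz: float = 30.0
    broad_fwhm_min_hz: float = 20.0
    # wider than any multiplet cluster, so inter-line saddles are flattened
    # and only genuinely broad (lipid/macromolecule) structure survives
    opening_window_ppm: float = 0.15
    broad_center_bound_ppm: float = 0.1
    far_distance_ppm: float = 0.05      # "away from any sharp line"
    greedy_improvement: float = 0.02    # stop adding lines below 2% gain
    max_added_peaks: int = 3            # per segment
    max_lines_per_segment: int = 8      # larger segments are split at minima
    lorentzian_only: bool = False
    max_nfev_per_param: int = 40
    # dynamic-range floor on the noise sigma: apodization truncation ripple
    # sits around 1e-4 of the tallest peak, so maxima below this fraction are
    # never treated as resonances even in noise-free spectra
    min_sigma_fraction: float = 1e-3


def pseudo_voigt(ppm: np.ndarray, center: float, height: float,
                 fwhm_ppm: float, gauss_fraction: float) -> np.ndarray:
    """Unit-height-normalized pseudo-Voigt line evaluated on ``ppm``."""
    x = (ppm - center) / fwhm_ppm
    lorentz = 1.0 / (1.0 + 4.0 * x * x)
    gauss = np.exp(-4.0 * math.log(2.0) * x * x)
    return height * ((1.0 - gauss_fraction) * lorentz + gauss_fraction * gauss)


def pseudo_voigt_area(height: float, fwhm_ppm: float, gauss_fraction: float) -> float:
    """Closed-form area (intensity * ppm) of a pseudo-Voigt line."""
    return height * fwhm_ppm * ((1.0 - gauss_fraction) * math.pi / 2.0
                                + gauss_fraction * _GAUSS_AREA)


def pick_peaks(spectrum: Spectrum, snr_threshold: float = 5.0,
               noise_window: tuple[float, float] = (-1.5, -0.5),
               fit_window: tuple[float, float] = (0.2, 6.0),
               min_sigma_fraction: float = 1e-3
               ) -> list[tuple[float, float]]:
    """Local maxima above ``snr_threshold`` times the robust noise sigma,
    ordered down-field (high ppm) first."""
    lo, hi = min(noise_window), max(noise_window)
    if not spectrum.window(lo, hi).any():
        raise ValueError(f"noise window {noise_window} lies outside the ppm axis")
    sigma = _effective_sigma(spectrum, noise_window, min_sigma_fraction)
    wlo, whi = min(fit_window), max(fit_window)
    mask = spectrum.window(wlo, whi)
    idx = np.flatnonzero(mask)
    y = spectrum.intensity[idx]
    # height alone would accept noise wiggles riding on elevated lipid tails,
    # so candidates must also rise above their local environment
    peaks, _ = scipy.signal.find_peaks(y, height=snr_threshold * sigma,
                                       prominence=snr_threshold * sigma)
    out = [(float(spectrum.ppm[idx[j]]), float(y[j])) for j in peaks]
    out.sort(key=lambda t: -t[0])
    return out


def _effective_sigma(spectrum: Spectrum, noise_window: tuple[float, float],
                     min_sigma_fraction: float) -> float:
    sigma = estimate_noise_sd(spectrum, noise_window)
    top = float(np.abs(spectrum.intensity).max()) if spectrum.intensity.size else 0.0
    return max(sigma, min_sigma_fraction * top)


def _segment_bounds(y: np.ndarray, sigma: float, gap_points: int,
                    threshold_sigma: float) -> list[tuple[int, int]]:
    """Split [0, n) into segments separated by runs of low intensity at least
    ``gap_points`` long."""
    above = y > threshold_sigma * sigma
    segments: list[tuple[int, int]] = []
    n = y.size
    i = 0
    start = None
    gap = 0
    for i in range(n):
        if above[i]:
            if start is None:
                start = i
            gap = 0
        elif start is not None:
            gap += 1
            if gap >= gap_points:
                segments.append((start, i - gap + 1))
                start, gap = None, 0
    if start is not None:
        segments.append((start, n))
    return segments


def _pv_model_jac(theta: np.ndarray, ppm: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pseudo-Voigt sum and its analytic Jacobian.

    theta is (m*4,) packed as (center, height, fwhm_ppm, gauss_fraction) per
    line; returns (model (n,), jacobian (n, m*4)).
    """
    m = theta.size // 4
    c = theta[0::4][None, :]
    h = theta[1::4][None, :]
    w = np.maximum(theta[2::4][None, :], 1e-12)
    e = theta[3::4][None, :]
    x = (ppm[:, None] - c) / w                      # (n, m)
    lorentz = 1.0 / (1.0 + 4.0 * x * x)
    a = 4.0 * math.log(2.0)
    gauss = np.exp(-a * x * x)
    shape = (1.0 - e) * lorentz + e * gauss
    model = (h * shape).sum(axis=1)
    dfdx = h * ((1.0 - e) * (-8.0 * x * lorentz * lorentz)
                + e * (-2.0 * a * x * gauss))
    jac = np.empty((ppm.size, 4 * m))
    jac[:, 0::4] = dfdx * (-1.0 / w)
    jac[:, 1::4] = shape
    jac[:, 2::4] = dfdx * (-x / w)
    jac[:, 3::4] = h * (gauss - lorentz)
    return model, jac


def _limit_segments(segments: list[tuple[int, int]], ppm: np.ndarray,
                    y: np.ndarray, cand: list[tuple[float, float]],
                    max_lines: int) -> list[tuple[int, int]]:
    """Recursively split segments holding more than ``max_lines`` candidates
    at the lowest-intensity point between the two central candidates, keeping
    every least-squares problem small and well-conditioned."""
    out: list[tuple[int, int]] = []

    def cand_in(a: int, b: int) -> list[float]:
        lo, hi = float(ppm[a]), float(ppm[b - 1])
        return [c for (c, _h) in cand if lo <= c <= hi]

    def rec(a: int, b: int, depth: int = 0) -> None:
        inside = cand_in(a, b)
        if len(inside) <= max_lines or depth > 8:
            out.append((a, b))
            return
        mid = len(inside) // 2
        lo_ppm, hi_ppm = inside[mid - 1], inside[mid]
        i0 = int(np.searchsorted(ppm[a:b], lo_ppm)) + a
        i1 = int(np.searchsorted(ppm[a:b], hi_ppm)) + a
        if i1 <= i0 + 1:
            out.append((a, b))
            return
        cut = i0 + 1 + int(np.argmin(y[i0 + 1:i1]))
        rec(a, cut, depth + 1)
        rec(cut, b, depth + 1)

    for (a, b) in segments:
        rec(a, b)
    return sorted(out)


def _sharp_wing_model(ppm: np.ndarray, y: np.ndarray, floor: np.ndarray,
                      candidates: list[tuple[float, float]],
                      fmhz: float, max_fwhm_hz: float) -> np.ndarray:
    """Approximate Lorentzian wing contribution of the sharp candidates.

    Heights and half-maximum crossings are measured above the local opening
    floor, so a candidate riding on a lipid pedestal is credited only with
    its own sharp mass; the summed Lorentzians estimate how much slowly
    decaying wing mass the sharp lines leave in the inter-peak floor.
    """
    if not candidates:
        return np.zeros_like(y)
    spacing = abs(float(ppm[1] - ppm[0])) if ppm.size > 1 else 1.0
    wings = np.zeros_like(y)
    n = y.size
    for (c, h) in candidates:
        j = int(np.clip(round((c - ppm[0]) / spacing), 0, n - 1))
        h_eff = max(float(y[j] - floor[j]), 0.0)
        if h_eff <= 0:
            continue
        half = floor[j] + 0.5 * h_eff
        left = j
        while left > 0 and y[left] > half and j - left < 200:
            left -= 1
        right = j
        while right < n - 1 and y[right] > half and right - j < 200:
            right += 1
        w_ppm = max((right - left) * spacing, spacing)
        w_ppm = min(w_ppm, max_fwhm_hz / fmhz)
        x = (ppm - c) / w_ppm
        wings += h_eff / (1.0 + 4.0 * x * x)
    return wings


def _fit_broad_background(ppm: np.ndarray, y: np.ndarray, sigma: float,
                          config: DeconvConfig, fmhz: float,
                          candidates: list[tuple[float, float]]
                          ) -> list[tuple[float, float, float, float]]:
    """Fit broad pseudo-Voigt components to the morphological-opening floor.

    The opening (erosion then dilation, window wider than any multiplet
    cluster) removes resonances and keeps the lipid/macromolecule humps;
    fitting those on the full window keeps each broad component's support
    intact, which a segment-wise fit would slice up.  The sharp candidates'
    own Lorentzian wings are estimated and subtracted from the floor first,
    so isolated sharp lines never masquerade as background.  Returns
    (center, height, fwhm_ppm, eta) rows; empty when the corrected floor
    never rises above noise.
    """
    spacing = abs(float(ppm[1] - ppm[0])) if ppm.size > 1 else 1.0
    w = max(3, int(round(config.opening_window_ppm / spacing)) | 1)
    floor = scipy.ndimage.maximum_filter1d(
        scipy.ndimage.minimum_filter1d(y, w), w)
    floor = scipy.ndimage.uniform_filter1d(floor, w, mode="nearest")
    floor = floor - _sharp_wing_model(ppm, y, floor, candidates, fmhz,
                                      config.sharp_fwhm_max_hz)
    np.clip(floor, 0.0, None, out=floor)
    if floor.max() <= 5.0 * sigma:
        return []
    cand_idx, _ = scipy.signal.find_peaks(floor, height=5.0 * sigma,
                                          prominence=3.0 * sigma,
                                          distance=max(1, w))
    if cand_idx.size == 0:
        return []
    lo_w = config.broad_fwhm_min_hz / fmhz
    hi_w = config.fwhm_bounds_hz[1] / fmhz
    init_w = min(max(2.5 * lo_w, lo_w * 1.01), hi_w * 0.99)
    ds = max(1, ppm.size // 2048)
    ppm_d, floor_d = ppm[::ds], floor[::ds]
    theta0, lo, hi = [], [], []
    for j in cand_idx:
        theta0 += [float(ppm[j]), float(floor[j]), init_w, 0.2]
        lo += [float(ppm[j]) - config.broad_center_bound_ppm, 0.0, lo_w, 0.0]
        hi += [float(ppm[j]) + config.broad_center_bound_ppm, np.inf, hi_w, 1.0]
    theta0, lo, hi = np.array(theta0), np.array(lo), np.array(hi)
    theta0 = np.minimum(np.maximum(theta0, lo), np.where(np.isfinite(hi), hi, theta0))
    res = scipy.optimize.least_squares(
        lambda t: _pv_model_jac(t, ppm_d)[0] - floor_d, theta0,
        jac=lambda t: _pv_model_jac(t, ppm_d)[1],
        bounds=(lo, hi), method="trf", x_scale="jac", ftol=1e-6, xtol=1e-8,
        max_nfev=50 * theta0.size)
    rows = [tuple(res.x[k:k + 4]) for k in range(0, res.x.size, 4)]
    return [r for r in rows if r[1] > 2.0 * sigma]


def _fit_segment(ppm: np.ndarray, y: np.ndarray,
                 candidates: list[tuple[float, float]],
                 config: DeconvConfig, fmhz: float, sigma: float
                 ) -> tuple[list[tuple[float, float, float, float]], bool]:
    """Fit a sum of pseudo-Voigt lines to one segment.

    Returns (rows, converged); rows are (center_ppm, height, fwhm_ppm, eta).
    Lines are added greedily at the residual maximum while the residual norm
    improves by more than ``greedy_improvement``.
    """
    lo_w = config.fwhm_bounds_hz[0] / fmhz
    hi_w = config.sharp_fwhm_max_hz / fmhz
    init_w = min(max(3.0 / fmhz, lo_w * 1.01), hi_w * 0.99)
    span = float(ppm.max() - ppm.min()) + 1e-12

    def pack(rows):
        return np.concatenate([[c, h, w, e] for (c, h, w, e) in rows])

    def model(theta):
        return _pv_model_jac(theta, ppm)[0]

    def bounds_for(rows):
        lo, hi = [], []
        for (c, h, w, e) in rows:
            lo += [c - config.center_bound_ppm, 0.0, lo_w, 0.0]
            hi += [c + config.center_bound_ppm, np.inf,
                   min(hi_w, 4 * span + lo_w * 2),
                   1e-9 if config.lorentzian_only else 1.0]
        return np.array(lo), np.array(hi)

    def run_fit(rows):
        theta0 = pack(rows)
        lo, hi = bounds_for(rows)
        theta0 = np.minimum(np.maximum(theta0, lo), np.where(np.isfinite(hi), hi, theta0))
        res = scipy.optimize.least_squares(
            lambda t: _pv_model_jac(t, ppm)[0] - y, theta0,
            jac=lambda t: _pv_model_jac(t, ppm)[1],
            bounds=(lo, hi), method="trf", x_scale="jac",
            ftol=1e-6, xtol=1e-8,
            max_nfev=config.max_nfev_per_param * max(1, theta0.size))
        rows_out = [tuple(res.x[k:k + 4]) for k in range(0, res.x.size, 4)]
        return rows_out, float(np.linalg.norm(res.fun)), res.status > 0

    rows = [(c, h, init_w, 0.0 if config.lorentzian_only else 0.2)
            for (c, h) in candidates]
    if not rows:
        return [], True
    rows, resid, ok = run_fit(rows)
    for _ in range(config.max_added_peaks):
        residual = y - model(pack(rows))
        j = int(np.argmax(residual))
        if residual[j] < max(3.0 * sigma, 0.0) or residual[j] <= 0:
            break
        trial = rows + [(float(ppm[j]), float(residual[j]), init_w,
                         0.0 if config.lorentzian_only else 0.2)]
        new_rows, new_resid, new_ok = run_fit(trial)
        if resid > 0 and (resid - new_resid) / resid > config.greedy_improvement:
            rows, resid, ok = new_rows, new_resid, new_ok
        else:
            break
    return rows, ok


def fit_lineshapes(spectrum: Spectrum,
                   candidates: list[tuple[float, float]] | None = None,
                   config: DeconvConfig | None = None) -> pd.DataFrame:
    """Deconvolve a processed spectrum into a peak table.

    Returns a DataFrame with columns ``center_ppm, height, fwhm_hz,
    gauss_fraction, integral, segment_id`` and, in ``attrs``:
    ``residual_norm``, ``input_norm`` (over the fit window) and
    ``flagged_segments`` (segments whose optimizer did not converge; their
    candidates are passed through unchanged rather than silently dropped).
    """
    cfg = config or DeconvConfig()
    if candidates is None:
        candidates = pick_peaks(spectrum, cfg.snr_threshold,
                                cfg.noise_window_ppm, cfg.fit_window_ppm,
                                cfg.min_sigma_fraction)
    fmhz = spectrum.acquisition.spectrometer_freq_mhz
    sigma = _effective_sigma(spectrum, cfg.noise_window_ppm,
                             cfg.min_sigma_fraction)
    wlo, whi = min(cfg.fit_window_ppm), max(cfg.fit_window_ppm)
    mask = spectrum.window(wlo, whi)
    idx = np.flatnonzero(mask)
    # work on an increasing-ppm axis for contiguous segmentation
    ppm_all = spectrum.ppm[idx][::-1]
    y_all = spectrum.intensity[idx][::-1]
    input_norm = float(np.linalg.norm(y_all))

    table = pd.DataFrame(columns=PEAK_COLUMNS).astype(
        {c: float for c in PEAK_COLUMNS[:5]} | {"segment_id": int})
    table.attrs["input_norm"] = input_norm
    table.attrs["flagged_segments"] = []
    if not candidates:
        table.attrs["residual_norm"] = input_norm
        return table

    # tier 1: broad lipid/macromolecule components on the full window
    broad_rows = _fit_broad_background(ppm_all, y_all, sigma, cfg, fmhz,
                                       sorted(candidates))
    recon = np.zeros_like(y_all)
    rows_all = []
    for (c, h, w, e) in broad_rows:
        rows_all.append({
            "center_ppm": float(c), "height": float(h),
            "fwhm_hz": float(w * fmhz), "gauss_fraction": float(e),
            "integral": float(pseudo_voigt_area(h, w, e)),
            "segment_id": -1,
        })
        recon += pseudo_voigt(ppm_all, c, h, w, e)
    y_sharp = y_all - recon

    # tier 2: sharp resonances, segment-wise on the broad-subtracted signal
    spacing = abs(float(ppm_all[1] - ppm_all[0])) if ppm_all.size > 1 else 1.0
    gap_points = max(1, int(round(cfg.segment_gap_ppm / spacing)))
    segments = _segment_bounds(y_sharp, sigma, gap_points, cfg.segment_threshold_sigma)
    if not segments:
        segments = [(0, y_all.size)]
    segments = _limit_segments(segments, ppm_all, y_sharp, sorted(candidates),
                               cfg.max_lines_per_segment)

    cand = sorted(candidates)  # ascending ppm
    flagged = []
    for seg_id, (a, b) in enumerate(segments):
        seg_ppm = ppm_all[a:b]
        seg_y = y_sharp[a:b]
        plo, phi = float(seg_ppm[0]), float(seg_ppm[-1])
        seg_cand = []
        for (c, h) in cand:
            if plo <= c <= phi:
                # re-measure the candidate height on the broad-subtracted signal
                j = int(np.argmin(np.abs(seg_ppm - c)))
                seg_cand.append((c, max(float(seg_y[j]), 0.0)))
        if not seg_cand:
            continue
        fitted, ok = _fit_segment(seg_ppm, seg_y, seg_cand, cfg, fmhz, sigma)
        if not ok:
            flagged.append(seg_id)
            fitted = [(c, h, 3.0 / fmhz, 0.0) for (c, h) in seg_cand]
        for (c, h, w, e) in fitted:
            rows_all.append({
                "center_ppm": float(c), "height": float(h),
                "fwhm_hz": float(w * fmhz), "gauss_fraction": float(e),
                "integral": float(pseudo_voigt_area(h, w, e)),
                "segment_id": seg_id,
            })
            recon += pseudo_voigt(ppm_all, c, h, w, e)
    table = pd.DataFrame(rows_all, columns=PEAK_COLUMNS)
    if len(table):
        table = table.sort_values("center_ppm", ascending=False,
                                  ignore_index=True)
    table.attrs["input_norm"] = input_norm
    table.attrs["residual_norm"] = float(np.linalg.norm(y_all - recon))
    table.attrs["flagged_segments"] = flagged
    return table


def reconstruct(peaks: pd.DataFrame, ppm_axis: np.ndarray,
                freq_mhz: float = 600.0) -> np.ndarray:
    """Sum of the table's pseudo-Voigt lines evaluated on ``ppm_axis``."""
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    out = np.zeros_like(ppm_axis)
    for _, row in peaks.iterrows():
        out += pseudo_voigt(ppm_axis, row["center_ppm"], row["height"],
                            row["fwhm_hz"] / freq_mhz, row["gauss_fraction"])
    return out
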