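"""End-to-end pipeline: simulate -> preprocess -> deconvolve -> regions ->
QC -> statistics, with artifact writing and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .deconvolve import DeconvConfig, fit_lineshapes
from .preprocess import PreprocConfig, preprocess
from .qc import pooled_equivalence
from .regions import (RegionConfig, apply_exclusions, build_regions,
                      annotate_regions, normalize_total)
from .simulate import (AcquisitionParams, SimConfig, add_pooled_controls,
                       default_metabolite_library, simulate_cohort)
from .stats import (overall_loading_factors, roc_analysis, run_pca,
                    select_contributors, clinical_association,
                    unidirectional_metabolites, univariate_compare)
from .io import write_peak_table, write_region_matrix, write_report

logger = logging.getLogger("plasmanmr")

__all__ = ["run_pipeline"]


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    s = cfg.simulate
    acq = AcquisitionParams(
        spectrometer_freq_mhz=s.spectrometer_freq_mhz,
        spectral_width_ppm=s.spectral_width_ppm,
        n_points_td=s.n_points_td, n_cpmg_pulses=s.n_cpmg_pulses,
        spin_rate_hz=s.spin_rate_hz, recycle_time_s=s.recycle_time_s,
        carrier_ppm=s.carrier_ppm)
    return SimConfig(
        n_ad=s.n_ad, n_non_ad=s.n_non_ad, seed=cfg.seed,
        noise_sd=s.noise_sd, shift_jitter_sd=s.shift_jitter_sd,
        phase0_error_range=s.phase0_error_range,
        phase1_error_range=s.phase1_error_range,
        baseline_amplitude=s.baseline_amplitude,
        lipid_background_scale=s.lipid_background_scale,
        lipid_cv=s.lipid_cv, natural_linewidth_hz=s.natural_linewidth_hz,
        acquisition=acq)


def _preproc_config(cfg: PipelineConfig) -> PreprocConfig:
    p = cfg.preprocess
    return PreprocConfig(
        line_broadening_hz=p.line_broadening_hz,
        zero_fill_factor=p.zero_fill_factor,
        calib_ref_ppm=p.calib_ref_ppm,
        calib_search_window_ppm=p.calib_search_window_ppm,
        auto_phase=p.auto_phase, manual_phi0_deg=p.manual_phi0_deg,
        manual_phi1_deg=p.manual_phi1_deg, baseline_lam=p.baseline_lam,
        baseline_p=p.baseline_p, baseline_iterations=p.baseline_iterations)


def _deconv_config(cfg: PipelineConfig) -> DeconvConfig:
    d = cfg.deconvolve
    return DeconvConfig(
        snr_threshold=d.snr_threshold,
        noise_window_ppm=(d.noise_window_lo_ppm, d.noise_window_hi_ppm),
        fit_window_ppm=(d.fit_window_lo_ppm, d.fit_window_hi_ppm),
        greedy_improvement=d.greedy_improvement,
        lorentzian_only=d.lorentzian_only)


def _region_config(cfg: PipelineConfig) -> RegionConfig:
    r = cfg.regions
    return RegionConfig(
        analysis_window=(r.analysis_lo_ppm, r.analysis_hi_ppm),
        presence_threshold=r.presence_threshold,
        cluster_tolerance_ppm=r.cluster_tolerance_ppm)


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None,
                 write_artifacts: bool = True) -> dict:
    """Execute the configured pipeline and return the report bundle.

    The bundle holds the cohort, region matrix, QC report and statistics;
    with ``write_artifacts`` the region matrix, peak tables, QC and stats
    reports and a run manifest land in ``output_dir``.  Deterministic for a
    fixed (config, seed).
    """
    if not config.simulate.enabled:
        raise ValueError("pipeline requires simulate.enabled "
                         "(file-based cohorts are assembled via the io module)")
    out = Path(output_dir or config.output_dir)
    timings: dict[str, float] = {}
    bundle: dict = {}

    t0 = time.perf_counter()
    library = default_metabolite_library()
    s = config.simulate
    if s.concentration_cv_scale != 1.0 or s.group_effect_scale != 1.0:
        from dataclasses import replace as _replace
        library = [_replace(m, cv=m.cv * s.concentration_cv_scale,
                            group_log2_effect=(m.group_log2_effect
                                               * s.group_effect_scale))
                   for m in library]
    cohort = simulate_cohort(_sim_config(config), library)
    if config.simulate.pooled_replicates > 0 and len(cohort.individual_ids) > 0:
        cohort = add_pooled_controls(
            cohort, n_replicates=config.simulate.pooled_replicates,
            n_splits=config.simulate.pooled_splits)
    timings["simulate"] = time.perf_counter() - t0
    bundle["cohort"] = cohort
    if not cohort.fids:
        raise ValueError("empty cohort: nothing to process")

    pre_cfg = _preproc_config(config)
    dec_cfg = _deconv_config(config)
    reg_cfg = _region_config(config)

    t0 = time.perf_counter()
    spectra = {}
    for sid, fid in cohort.fids.items():
        try:
            spectra[sid] = preprocess(fid, pre_cfg)
        except Exception as e:
            raise RuntimeError(f"preprocess failed for sample {sid}: {e}") from e
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    peaks = {}
    for sid, spec in spectra.items():
        try:
            pk = fit_lineshapes(spec, config=dec_cfg)
            pk = apply_exclusions(pk, reg_cfg)
            peaks[sid] = normalize_total(pk, sample_id=sid)
        except Exception as e:
            raise RuntimeError(f"deconvolve failed for sample {sid}: {e}") from e
    timings["deconvolve"] = time.perf_counter() - t0
    bundle["peaks"] = peaks

    t0 = time.perf_counter()
    matrix = build_regions(peaks, cohort.individual_ids, reg_cfg)
    fmhz = config.simulate.spectrometer_freq_mhz
    matrix.regions = annotate_regions(matrix.regions, library, fmhz)
    timings["regions"] = time.perf_counter() - t0
    bundle["region_matrix"] = matrix

    if cohort.pooled_ids:
        t0 = time.perf_counter()
        qc_report = pooled_equivalence(
            matrix, cohort.pooled_ids, cohort.individual_ids,
            slope_tolerance=config.qc.slope_tolerance,
            through_origin=config.qc.through_origin)
        timings["qc"] = time.perf_counter() - t0
        bundle["qc"] = qc_report
    else:
        logger.info("no pooled controls in cohort: QC stage skipped")
        bundle["qc"] = None

    t0 = time.perf_counter()
    meta = cohort.metadata.set_index("sample_id")
    labels = meta.loc[cohort.individual_ids, "group"]
    stats_bundle: dict = {}
    stats_bundle["univariate"] = univariate_compare(
        matrix, labels, alpha=config.stats.alpha, bh_adjust=config.stats.bh_adjust)
    clinical = {}
    for score in ("cdr_global", "cdr_sob", "mmse"):
        try:
            clinical[score] = clinical_association(
                matrix, cohort.metadata, score, alpha=config.stats.alpha)
        except ValueError as e:
            logger.warning("clinical association for %s skipped: %s", score, e)
    stats_bundle["clinical"] = clinical
    # PCA over individual samples; drop any zero-variance regions first
    sub = matrix.values.loc[cohort.individual_ids]
    keep = sub.std(axis=0, ddof=1) > 0
    if not keep.all():
        dropped = list(sub.columns[~keep])
        logger.warning("dropping zero-variance regions before PCA: %s", dropped)
        matrix_pca = type(matrix)(
            sample_ids=matrix.sample_ids,
            regions=[r for r in matrix.regions if r.label in set(sub.columns[keep])],
            values=matrix.values.loc[:, keep],
            total_valid_intensity=matrix.total_valid_intensity)
    else:
        matrix_pca = matrix
    pca = run_pca(matrix_pca, cohort.individual_ids)
    stats_bundle["pca"] = pca
    annotations = {r.region_id: r.candidate_metabolites for r in matrix_pca.regions}
    per_component = {}
    ad_ids = [s for s in cohort.individual_ids if labels[s] == "AD"]
    non_ad_ids = [s for s in cohort.individual_ids if labels[s] != "AD"]
    for comp in config.stats.components:
        col = f"PC{comp}"
        if col not in pca.scores.columns:
            continue
        factors = overall_loading_factors(pca, matrix_pca, comp,
                                          cohort.individual_ids)
        # map the table's positional region_id back to the region definitions
        factors = factors.copy()
        factors["region_id"] = [r.region_id for r in matrix_pca.regions]
        pos, neg = select_contributors(factors, config.stats.contributor_fraction)
        pos_names, neg_names = unidirectional_metabolites(pos, neg, annotations)
        # polarity: which score sign sits with the AD group mean
        ad_mean = float(pca.scores.loc[ad_ids, col].mean())
        non_ad_mean = float(pca.scores.loc[non_ad_ids, col].mean())
        positive_is_ad = ad_mean >= non_ad_mean
        roc = roc_analysis(pca.scores.loc[cohort.individual_ids, col].to_numpy(),
                           labels.to_numpy(), positive_label="AD")
        per_component[col] = {
            "loading_factors": factors,
            "positive_regions": pos, "negative_regions": neg,
            "positive_is_ad": positive_is_ad,
            "ad_metabolites": pos_names if positive_is_ad else neg_names,
            "non_ad_metabolites": neg_names if positive_is_ad else pos_names,
            "roc": roc,
        }
    stats_bundle["components"] = per_component
    timings["stats"] = time.perf_counter() - t0
    bundle["stats"] = stats_bundle
    bundle["timings"] = timings

    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        cohort.metadata.to_csv(out / "metadata.csv", index=False)
        write_peak_table(peaks, out / "peaks.csv")
        write_region_matrix(matrix, out / "region_matrix.csv",
                            out / "regions.json")
        if bundle["qc"] is not None:
            write_report(bundle["qc"].to_dict(), out / "qc.json")
        stats_json = {
            "univariate": stats_bundle["univariate"],
            "clinical": {k: v for k, v in clinical.items()},
            "pca": {
                "explained_variance_fraction":
                    pca.explained_variance_fraction,
                "scores": pca.scores,
                "loading_coefficients": pca.loading_coefficients,
            },
            "components": {
                col: {
                    "loading_factors": rec["loading_factors"],
                    "positive_regions": rec["positive_regions"],
                    "negative_regions": rec["negative_regions"],
                    "positive_is_ad": rec["positive_is_ad"],
                    "ad_metabolites": rec["ad_metabolites"],
                    "non_ad_metabolites": rec["non_ad_metabolites"],
                    "roc": {"auc": rec["roc"].auc,
                            "accuracy": rec["roc"].accuracy,
                            "threshold": rec["roc"].threshold,
                            "flipped": rec["roc"].flipped},
                } for col, rec in per_component.items()
            },
        }
        write_report(stats_json, out / "stats.json")
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config.model_dump(), sort_keys=True).encode()).hexdigest(),
            "config": config.model_dump(),
            "n_samples": len(cohort.fids),
            "n_regions": len(matrix.regions),
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        }
        write_report(manifest, out / "manifest.json")
    return bundle
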