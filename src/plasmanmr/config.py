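"""Pipeline configuration: TOML file with strictly validated sections
mirroring each stage's settings.  Unknown keys are rejected with a
close-match suggestion; every numeric field is range-checked at load.
An empty file yields the full default configuration.
"""

from __future__ import annotations

import difflib
import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unparseable configuration file."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    enabled: bool = True
    n_ad: int = Field(16, ge=0)
    n_non_ad: int = Field(19, ge=0)
    pooled_replicates: int = Field(2, ge=0)
    pooled_splits: int = Field(3, ge=1)
    noise_sd: float = Field(0.05, ge=0)
    shift_jitter_sd: float = Field(0.005, ge=0)
    phase0_error_range: float = Field(20.0, ge=0)
    phase1_error_range: float = Field(10.0, ge=0)
    baseline_amplitude: float = Field(20.0, ge=0)
    lipid_background_scale: float = Field(1.0, ge=0)
    lipid_cv: float = Field(0.30, ge=0)
    concentration_cv_scale: float = Field(1.0, ge=0)  # scales every library CV
    group_effect_scale: float = Field(1.0, ge=0)      # scales every group effect
    natural_linewidth_hz: float = Field(2.0, gt=0)
    spectrometer_freq_mhz: float = Field(600.0, gt=0)
    spectral_width_ppm: float = Field(16.0, gt=0)
    n_points_td: int = Field(16384, gt=0)
    n_cpmg_pulses: int = Field(100, ge=0)
    spin_rate_hz: float = Field(3600.0, gt=0)
    recycle_time_s: float = Field(5.0, gt=0)
    carrier_ppm: float = 4.7


class PreprocessSection(_Strict):
    line_broadening_hz: float = Field(0.5, ge=0)
    zero_fill_factor: int = Field(2, ge=1)
    calib_ref_ppm: float = 1.32
    calib_search_window_ppm: float = Field(0.1, gt=0)
    auto_phase: bool = True
    manual_phi0_deg: float = 0.0
    manual_phi1_deg: float = 0.0
    baseline_lam: float = Field(1e12, gt=0)
    baseline_p: float = Field(1e-3, gt=0, lt=1)
    baseline_iterations: int = Field(10, ge=1)


class DeconvolveSection(_Strict):
    snr_threshold: float = Field(5.0, gt=0)
    noise_window_lo_ppm: float = -1.5
    noise_window_hi_ppm: float = -0.5
    fit_window_lo_ppm: float = 0.2
    fit_window_hi_ppm: float = 6.0
    greedy_improvement: float = Field(0.02, ge=0)
    lorentzian_only: bool = False


class RegionsSection(_Strict):
    analysis_lo_ppm: float = 0.5
    analysis_hi_ppm: float = 5.5
    presence_threshold: float = Field(0.80, gt=0, le=1)
    cluster_tolerance_ppm: float = Field(0.01, gt=0)


class QCSection(_Strict):
    slope_tolerance: float = Field(0.1, gt=0)
    through_origin: bool = False


class StatsSection(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)
    bh_adjust: bool = False
    components: list[int] = [1, 2, 3]
    contributor_fraction: float = Field(0.5, gt=0, le=1)


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str = "plasmanmr_out"
    log_level: str = "INFO"
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    deconvolve: DeconvolveSection = Field(default_factory=DeconvolveSection)
    regions: RegionsSection = Field(default_factory=RegionsSection)
    qc: QCSection = Field(default_factory=QCSection)
    stats: StatsSection = Field(default_factory=StatsSection)


def _all_known_keys() -> list[str]:
    keys = set()
    for model in (PipelineConfig, SimulateSection, PreprocessSection,
                  DeconvolveSection, RegionsSection, QCSection, StatsSection):
        keys.update(model.model_fields.keys())
    return sorted(keys)


def _explain(exc: ValidationError, path: str) -> str:
    parts = []
    known = _all_known_keys()
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"])
        if err["type"] == "extra_forbidden":
            key = str(err["loc"][-1])
            close = difflib.get_close_matches(key, known, n=1)
            hint = f"; did you mean {close[0]!r}?" if close else ""
            parts.append(f"unknown key {loc!r}{hint}")
        else:
            parts.append(f"key {loc!r}: {err['msg']}")
    return f"invalid configuration in {path}: " + "; ".join(parts)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a TOML config; ``None`` or an empty file gives the
    defaults."""
    if path is None:
        return PipelineConfig()
    p = Path(path)
    try:
        with open(p, "rb") as fh:
            raw = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {p}") from None
    except tomllib.TOMLDecodeError as e:
        raise ConfigError(f"cannot parse {p}: {e}") from None
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as e:
        raise ConfigError(_explain(e, str(p))) from None
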