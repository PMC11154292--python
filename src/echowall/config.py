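"""Configuration for the echowall simulation and analysis pipeline.

The default :class:`CohortConfig` encodes the study conditions the package
is built around: a multicentre European cohort of 3188 high-cardiovascular-
risk subjects recruited in five countries along a north-south latitude
gradient, of whom 2138 carry at least one carotid plaque (a lesion with
IMT_max >= 1.5 mm).  Echolucency is quantified as the gray-scale median
(GSM) of the plaque (plaque-GSM, measured in plaque carriers only) and of
the plaque-free common-carotid intima-media complex (IM-GSM, measured in
everyone).  The per-predictor effect tables give, for each determinant, the
reported semi-standardized slope (GSM units per predictor SD) and the share
of outcome variance it explains (partial R^2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration object fails validation."""


class SpecificationError(ValueError):
    """Raised when an image specification is internally inconsistent."""


@dataclass(frozen=True)
class EffectTerm:
    """One determinant of a GSM outcome.

    Parameters
    ----------
    name:
        Column name of the predictor in the cohort table.
    beta:
        Reported semi-standardized slope, in outcome units per predictor SD.
        Kept for reference; the generator derives its effective slope from
        ``partial_r2`` so that variance shares are exact (see methods note).
    partial_r2:
        Fraction (0-1) of outcome variance attributed to this predictor.
    """

    name: str
    beta: float
    partial_r2: float


# Independent determinants of plaque-GSM: slope per predictor SD and the
# share of outcome variance each explains.  Whole model: 12.0%.
PLAQUE_EFFECTS: tuple[EffectTerm, ...] = (
    EffectTerm("latitude", -3.23, 0.087),
    EffectTerm("dbp", 1.36, 0.017),
    EffectTerm("imt_max_quartile", -0.96, 0.008),
    EffectTerm("pack_years_code", 0.85, 0.007),
)

# Independent determinants of IM-GSM.  Whole model: 19.7%.
IM_EFFECTS: tuple[EffectTerm, ...] = (
    EffectTerm("latitude", -4.27, 0.111),
    EffectTerm("height", 1.50, 0.020),
    EffectTerm("sbp", 1.44, 0.015),
    EffectTerm("pf_cc_imt_quartile", -1.85, 0.012),
    EffectTerm("waist_hip_ratio", -1.93, 0.010),
    EffectTerm("fibrates", -0.95, 0.006),
    EffectTerm("pack_years_code", 0.93, 0.006),
    EffectTerm("mcv", -0.79, 0.005),
    EffectTerm("sartans", -0.79, 0.005),
    EffectTerm("educational_level", -0.79, 0.004),
    EffectTerm("creatinine_log", 0.96, 0.004),
)


@dataclass(frozen=True)
class Center:
    """A recruiting centre: name, country, latitude (degrees N), subjects."""

    name: str
    country: str
    latitude: float
    n: int


# Six centres in five countries; counts sum to 3188.
CENTERS: tuple[Center, ...] = (
    Center("Kuopio", "Finland", 62.9, 533),
    Center("Stockholm", "Sweden", 59.3, 532),
    Center("Groningen", "Netherlands", 53.2, 527),
    Center("Paris", "France", 48.9, 501),
    Center("Milan", "Italy", 45.5, 553),
    Center("Perugia", "Italy", 43.1, 542),
)

# Covariates used to adjust the high-burden logistic models (the strongest
# determinants of IMT_max).  Pulse pressure = SBP - DBP.
ADJUSTMENT_COVARIATES: tuple[str, ...] = (
    "latitude",
    "sex",
    "age",
    "educational_level",
    "pulse_pressure",
    "pack_years_code",
)

# Plausible marginal distributions for covariates (means/SDs placeholders,
# config-exposed; the analysis is invariant to them because predictors enter
# standardized).
DEFAULT_COVARIATE_PARAMS: Mapping[str, tuple[float, float]] = {
    "age": (64.0, 5.5),
    "height": (168.0, 9.0),
    "waist_hip_ratio": (0.92, 0.08),
    "sbp": (142.0, 19.0),
    "dbp": (82.0, 10.0),
    "educational_level": (10.0, 4.0),
    "mcv": (90.0, 5.0),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: cohort size, plaque prevalence,
    outcome means/SDs, cross-outcome correlation, per-quartile odds ratios
    for high atherosclerotic burden, and scan-rescan reliability.
    """

    n_subjects: int = 3188
    plaque_fraction: float = 2138 / 3188
    centers: Sequence[Center] = CENTERS
    plaque_effects: Sequence[EffectTerm] = PLAQUE_EFFECTS
    im_effects: Sequence[EffectTerm] = IM_EFFECTS
    gsm_mean_plaque: float = 30.6
    gsm_sd_plaque: float = 9.9
    gsm_mean_im: float = 43.8
    gsm_sd_im: float = 11.7
    cross_gsm_rho: float = 0.51
    or_per_quartile_plaque: float = 0.79
    or_per_quartile_im: float = 1.12
    # log-OR per SD for the adjustment covariates in the high-burden model
    burden_covariate_logor: Mapping[str, float] = field(
        default_factory=lambda: {
            "latitude": 0.35,
            "sex": 0.25,
            "age": 0.30,
            "educational_level": -0.15,
            "pulse_pressure": 0.25,
            "pack_years_code": 0.15,
        }
    )
    icc_plaque: float = 0.75
    icc_im: float = 0.83
    n_repeat_scans: int = 138
    n_nuisance: int = 58
    prop_male: float = 0.46
    prop_never_smoker: float = 0.45
    prop_fibrates: float = 0.06
    prop_sartans: float = 0.14
    # linear leakage of the per-image calibration references into raw GSM
    calib_black_slope: float = 0.15
    calib_white_slope: float = -0.08
    covariate_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    seed: int = 42

    def validate(self) -> None:
        if not (0.0 < self.plaque_fraction <= 1.0):
            raise ConfigurationError(
                f"plaque_fraction must be in (0, 1], got {self.plaque_fraction}"
            )
        for label, effects in (("plaque", self.plaque_effects), ("im", self.im_effects)):
            r2s = [t.partial_r2 for t in effects]
            if any(r < 0 for r in r2s):
                raise ConfigurationError(f"negative partial R2 in {label} effect table")
            if sum(r2s) >= 1.0:
                raise ConfigurationError(
                    f"{label} effect table infeasible: sum of partial R2 "
                    f"{sum(r2s):.3f} >= 1"
                )
        if not (-1.0 < self.cross_gsm_rho < 1.0):
            raise ConfigurationError("cross_gsm_rho must lie in (-1, 1)")
        for icc in (self.icc_plaque, self.icc_im):
            if not (0.0 < icc < 1.0):
                raise ConfigurationError(f"ICC target must lie in (0, 1), got {icc}")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")

    @property
    def n_plaque(self) -> int:
        return int(round(self.n_subjects * self.plaque_fraction))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["centers"] = [dataclasses.asdict(c) for c in self.centers]
        d["plaque_effects"] = [dataclasses.asdict(t) for t in self.plaque_effects]
        d["im_effects"] = [dataclasses.asdict(t) for t in self.im_effects]
        d["burden_covariate_logor"] = dict(self.burden_covariate_logor)
        d["covariate_params"] = {k: list(v) for k, v in self.covariate_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "centers" in d:
            d["centers"] = tuple(Center(**c) for c in d["centers"])
        for key in ("plaque_effects", "im_effects"):
            if key in d:
                d[key] = tuple(EffectTerm(**t) for t in d[key])
        if "covariate_params" in d:
            d["covariate_params"] = {
                k: tuple(v) for k, v in d["covariate_params"].items()
            }
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline settings: cohort, selection, calibration, seeds."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_iterations: int = 200
    retention_threshold: float = 0.70
    entry_p: float = 0.05
    stay_p: float = 0.10
    w_target: float = 190.0
    make_figures: bool = True
    seed: int = 42

    def validate(self) -> None:
        self.cohort.validate()
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not (0.0 <= self.retention_threshold <= 1.0):
            raise ConfigurationError("retention_threshold must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        d = {
            "cohort": self.cohort.to_dict(),
            "n_iterations": self.n_iterations,
            "retention_threshold": self.retention_threshold,
            "entry_p": self.entry_p,
            "stay_p": self.stay_p,
            "w_target": self.w_target,
            "make_figures": self.make_figures,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cohort = CohortConfig.from_dict(d.pop("cohort", {}))
        return cls(cohort=cohort, **d)
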