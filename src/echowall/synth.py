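"""Synthetic cohort and ultrasound-image generation.

Every downstream stage of the analysis is exercised against data produced
here, with known ground truth:

* :func:`generate_cohort` builds a cohort table whose GSM outcomes are
  linear in a configured set of standardized predictors, with per-predictor
  variance shares (partial R^2), outcome means/SDs, plaque prevalence,
  cross-outcome correlation, and per-quartile odds ratios for high
  atherosclerotic burden all injected at known values.
* :func:`generate_repeat_scans` builds scan-rescan pairs whose measurement
  error is scaled to a target intraclass correlation coefficient.
* :func:`generate_wall_image` builds an 8-bit far-wall image with
  lumen / intima-media / adventitia bands (optionally a plaque), speckled
  texture, and per-region target gray-level medians, returning ground-truth
  masks alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigurationError, SpecificationError
from .selection import code_pack_years, quartile_code

__all__ = [
    "generate_cohort",
    "generate_repeat_scans",
    "WallImageSpec",
    "PlaqueSpec",
    "WallImage",
    "generate_wall_image",
]

# means of the discrete-uniform calibration references, used when leaking
# them into the raw GSM columns
_BLACK_MEAN = 37 / 2.0
_WHITE_MEAN = (104 + 255) / 2.0

# plausible mm ranges used to lay out IMT_max values (eligibility threshold
# 1.5 mm; upper-quartile/high-burden threshold 2.5 mm)
_IMT_FREE_RANGE = (0.55, 1.5)
_IMT_PLAQUE_RANGE = (1.5, 2.5)
_IMT_BURDEN_RANGE = (2.5, 6.0)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _rank_spread(rank: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map integer ranks 0..n-1 monotonically into (lo, hi)."""
    n = len(rank)
    return lo + (hi - lo) * (rank + 0.5) / n


def _center_assignment(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign subjects to centres with counts proportional to centre sizes."""
    weights = np.array([c.n for c in config.centers], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * config.n_subjects).astype(int)
    # largest-remainder apportionment so counts sum exactly to n_subjects
    remainder = weights * config.n_subjects - counts
    for k in np.argsort(remainder)[::-1][: config.n_subjects - counts.sum()]:
        counts[k] += 1
    idx = np.repeat(np.arange(len(config.centers)), counts)
    return rng.permutation(idx)


def _linear_outcome(
    Z: np.ndarray,
    effects,
    mean: float,
    sd: float,
) -> tuple[np.ndarray, float]:
    """Systematic part of an outcome: mean + sum_j sign_j*sqrt(R2_j)*sd*Z_j.

    Returns (linear predictor, residual SD).  Each predictor's population
    incremental R^2 equals its configured share and the outcome variance
    equals sd^2.
    """
    slopes = np.array(
        [np.sign(t.beta) * np.sqrt(t.partial_r2) * sd for t in effects]
    )
    lp = mean + Z @ slopes
    total_r2 = sum(t.partial_r2 for t in effects)
    resid_sd = sd * np.sqrt(1.0 - total_r2)
    return lp, resid_sd


def generate_cohort(
    config: Optional[CohortConfig] = None, seed: Optional[int] = None
) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    The returned frame has one row per subject, with demographics and risk
    factors, thickness measures (``imt_max``, ``pf_cc_imt_mean``), the true
    GSM outcomes (``plaque_gsm``, ``im_gsm``; plaque-GSM is missing for
    subjects without a plaque), raw GSM values carrying a linear calibration
    confounding (``plaque_gsm_raw``, ``im_gsm_raw``), per-image calibration
    references (``black_ref``, ``white_ref``), and independent nuisance
    columns.  Exactly ``round(n_subjects * plaque_fraction)`` subjects have
    ``imt_max >= 1.5``.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects

    # --- demographics and risk factors (independent draws) ---------------
    center_idx = _center_assignment(config, rng)
    centers = config.centers
    cp = config.covariate_params
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "center": [centers[k].name for k in center_idx],
            "country": [centers[k].country for k in center_idx],
            "latitude": np.array([centers[k].latitude for k in center_idx]),
            "sex": (rng.random(n) < config.prop_male).astype(int),
            "age": rng.normal(*cp["age"], n).clip(54, 79),
            "height": rng.normal(*cp["height"], n),
            "waist_hip_ratio": rng.normal(*cp["waist_hip_ratio"], n),
            "sbp": rng.normal(*cp["sbp"], n),
            "dbp": rng.normal(*cp["dbp"], n),
            "educational_level": rng.normal(*cp["educational_level"], n).clip(0, None),
            "mcv": rng.normal(*cp["mcv"], n),
            "fibrates": (rng.random(n) < config.prop_fibrates).astype(int),
            "sartans": (rng.random(n) < config.prop_sartans).astype(int),
        }
    )
    df["pulse_pressure"] = df["sbp"] - df["dbp"]
    ever = rng.random(n) >= config.prop_never_smoker
    pack_years = np.where(ever, rng.lognormal(2.8, 0.8, n), 0.0)
    df["pack_years"] = pack_years
    df["pack_years_code"] = code_pack_years(pack_years)
    creatinine = rng.lognormal(np.log(80.0), 0.2, n)
    df["creatinine"] = creatinine
    df["creatinine_log"] = np.log(creatinine)

    # --- plaque eligibility and thickness variables -----------------------
    severity = rng.standard_normal(n)
    k_plaque = config.n_plaque
    order = np.argsort(-severity, kind="stable")
    plaque = np.zeros(n, dtype=bool)
    plaque[order[:k_plaque]] = True
    df["plaque_present"] = plaque

    noise = rng.standard_normal(n)
    df["pf_cc_imt_mean"] = (0.71 + 0.13 * (0.6 * severity + 0.8 * noise)).clip(0.4, None)
    df["pf_cc_imt_quartile"] = quartile_code(df["pf_cc_imt_mean"].to_numpy())

    # generating thickness-quartile predictor for plaque-GSM: quartiles of
    # the latent severity among plaque carriers
    imt_q = np.full(n, np.nan)
    if k_plaque >= 4:
        imt_q[plaque] = quartile_code(severity[plaque])
    elif k_plaque > 0:
        imt_q[plaque] = 1.0
    df["imt_max_quartile"] = imt_q

    # --- GSM outcomes ------------------------------------------------------
    pl_names = [t.name for t in config.plaque_effects]
    im_names = [t.name for t in config.im_effects]
    Z_pl = np.column_stack(
        [_zscore(df.loc[plaque, t].to_numpy(dtype=float)) for t in pl_names]
    ) if k_plaque > 1 else np.zeros((k_plaque, len(pl_names)))
    Z_im = np.column_stack([_zscore(df[t].to_numpy(dtype=float)) for t in im_names])

    lp_pl, sd_e_pl = _linear_outcome(
        Z_pl, config.plaque_effects, config.gsm_mean_plaque, config.gsm_sd_plaque
    )
    lp_im, sd_e_im = _linear_outcome(
        Z_im, config.im_effects, config.gsm_mean_im, config.gsm_sd_im
    )

    # residual correlation chosen so the marginal plaque/IM correlation hits
    # the target, after accounting for covariance through shared predictors
    e_im = rng.standard_normal(n)
    e_pl_ind = rng.standard_normal(k_plaque)
    target_cov = config.cross_gsm_rho * config.gsm_sd_plaque * config.gsm_sd_im
    if k_plaque > 2 and sd_e_pl > 0 and sd_e_im > 0:
        lp_cov = float(np.cov(lp_pl, lp_im[plaque], ddof=1)[0, 1])
        rho_e = np.clip((target_cov - lp_cov) / (sd_e_pl * sd_e_im), -0.999, 0.999)
    else:
        rho_e = 0.0
    e_pl = rho_e * e_im[plaque] + np.sqrt(1.0 - rho_e ** 2) * e_pl_ind

    im_gsm = lp_im + sd_e_im * e_im
    plaque_gsm = np.full(n, np.nan)
    plaque_gsm[plaque] = lp_pl + sd_e_pl * e_pl
    df["im_gsm"] = im_gsm
    df["plaque_gsm"] = plaque_gsm

    # --- high atherosclerotic burden and IMT_max mm values ----------------
    m_burden = min(int(round(0.25 * n)), k_plaque)
    high_burden = np.zeros(n, dtype=bool)
    if k_plaque >= 8 and m_burden >= 1:
        u = _burden_latent(df, plaque, config, rng)
        ip = np.flatnonzero(plaque)
        top = ip[np.argsort(-u, kind="stable")[:m_burden]]
        high_burden[top] = True
    elif m_burden >= 1:
        ip = np.flatnonzero(plaque)
        high_burden[ip[:m_burden]] = True

    imt = np.empty(n)
    free = ~plaque
    for group, (lo, hi), key in (
        (free, _IMT_FREE_RANGE, severity),
        (plaque & ~high_burden, _IMT_PLAQUE_RANGE, severity),
        (high_burden, _IMT_BURDEN_RANGE, severity),
    ):
        ng = int(group.sum())
        if ng == 0:
            continue
        ranks = np.empty(ng, dtype=int)
        ranks[np.argsort(key[group], kind="stable")] = np.arange(ng)
        imt[group] = _rank_spread(ranks, lo, hi)
    df["imt_max"] = imt

    # --- calibration references and raw GSM -------------------------------
    black = rng.integers(0, 38, n)
    white = rng.integers(104, 256, n)
    df["black_ref"] = black
    df["white_ref"] = white
    bs, ws = config.calib_black_slope, config.calib_white_slope
    shift = bs * (black - _BLACK_MEAN) + ws * (white - _WHITE_MEAN)
    df["im_gsm_raw"] = np.clip(im_gsm + shift, 0.0, 255.0)
    df["plaque_gsm_raw"] = np.clip(plaque_gsm + shift, 0.0, 255.0)

    # --- nuisance candidates (no true effect) ------------------------------
    for j in range(config.n_nuisance):
        if j % 4 == 3:
            df[f"nuisance_{j:02d}"] = (rng.random(n) < 0.3).astype(int)
        else:
            df[f"nuisance_{j:02d}"] = rng.standard_normal(n)

    df.attrs["config"] = config
    return df


def _burden_latent(
    df: pd.DataFrame, plaque: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Latent score whose top quartile defines high atherosclerotic burden.

    Joint per-quartile coefficients for plaque-GSM and IM-GSM are calibrated
    so that *marginal* covariate-adjusted logistic models (one GSM at a
    time, as in the reported analysis) recover the configured odds ratios,
    despite the correlation between the two quartile codes.
    """
    ip = np.flatnonzero(plaque)
    qp = quartile_code(df.loc[plaque, "plaque_gsm"].to_numpy())
    qim = quartile_code(df.loc[plaque, "im_gsm"].to_numpy())

    cov_names = list(config.burden_covariate_logor)
    C = np.column_stack(
        [_zscore(df.loc[plaque, c].to_numpy(dtype=float)) for c in cov_names]
    )
    gamma = np.array([config.burden_covariate_logor[c] for c in cov_names])

    # residualize the quartile codes on the adjustment covariates, then
    # solve the 2x2 omitted-variable system for the joint coefficients
    D = np.column_stack([np.ones(len(ip)), C])
    qp_r = qp - D @ np.linalg.lstsq(D, qp, rcond=None)[0]
    qim_r = qim - D @ np.linalg.lstsq(D, qim, rcond=None)[0]
    b_im_on_p = float(qp_r @ qim_r) / float(qp_r @ qp_r)
    b_p_on_im = float(qp_r @ qim_r) / float(qim_r @ qim_r)
    m = np.array(
        [np.log(config.or_per_quartile_plaque), np.log(config.or_per_quartile_im)]
    )
    A = np.array([[1.0, b_im_on_p], [b_p_on_im, 1.0]])
    a_p, a_im = np.linalg.solve(A, m)

    u = a_p * qp + a_im * qim + C @ gamma + rng.logistic(size=len(ip))
    return u


def generate_repeat_scans(
    cohort: pd.DataFrame,
    variable: str = "plaque_gsm",
    icc_target: float = 0.75,
    n_pairs: int = 138,
    seed: int = 0,
    sigma_between: Optional[float] = None,
) -> pd.DataFrame:
    """Generate scan-rescan pairs with error scaled to an ICC target.

    For each sampled subject the two scans are the subject's true GSM value
    plus independent Gaussian errors with variance sigma_e^2 chosen so that
    sigma_b^2 / (sigma_b^2 + sigma_e^2) equals ``icc_target``, where
    sigma_b^2 is the between-subject variance of the sampled variable
    (by default its full-cohort variance).
    """
    if not (0.0 < icc_target < 1.0):
        raise ConfigurationError(f"ICC target must lie in (0, 1), got {icc_target}")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    values = cohort[variable].dropna()
    if len(values) < 2:
        raise ValueError(f"not enough non-missing values of {variable!r}")
    rng = np.random.default_rng(seed)
    n_pairs = min(n_pairs, len(values))
    take = rng.choice(len(values), size=n_pairs, replace=False)
    truth = values.to_numpy(dtype=float)[take]
    sb = values.std(ddof=1) if sigma_between is None else float(sigma_between)
    sigma_e = sb * np.sqrt((1.0 - icc_target) / icc_target)
    scan1 = truth + rng.normal(0.0, sigma_e, n_pairs)
    scan2 = truth + rng.normal(0.0, sigma_e, n_pairs)
    idx = values.index[take]
    if "subject_id" in cohort.columns:
        subject_id = cohort.loc[idx, "subject_id"].to_numpy()
    else:
        subject_id = idx.astype(str)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "variable": variable,
            "scan1": scan1,
            "scan2": scan2,
            "truth": truth,
        }
    )


# ---------------------------------------------------------------------------
# wall images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaqueSpec:
    """An elliptical plaque protruding from the far wall.

    ``center`` and ``axes`` are (row, col) pixel coordinates/half-axes;
    ``imt_mm`` is the lesion thickness equivalent carried as metadata.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    median: float
    imt_mm: float = 2.0


@dataclass
class WallImageSpec:
    """Geometry, per-region target medians and speckle of a far-wall image.

    Bands are half-open row ranges ordered lumen -> intima-media ->
    adventitia with increasing depth.  ``dispersion`` scales the speckle
    spread around each region's target median (0 gives uniform regions).
    """

    width: int = 256
    height: int = 192
    lumen_band: tuple[int, int] = (0, 64)
    im_band: tuple[int, int] = (64, 96)
    adventitia_band: tuple[int, int] = (96, 192)
    target_medians: Mapping[str, float] = field(
        default_factory=lambda: {"lumen": 10.0, "im": 44.0, "adventitia": 180.0}
    )
    plaque: Optional[PlaqueSpec] = None
    speckle: str = "rayleigh"
    dispersion: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        bands = [self.lumen_band, self.im_band, self.adventitia_band]
        for lo, hi in bands:
            if not (0 <= lo < hi <= self.height):
                raise SpecificationError(f"band ({lo}, {hi}) outside image height")
        if not (bands[0][1] <= bands[1][0] and bands[1][1] <= bands[2][0]):
            raise SpecificationError(
                "bands must be disjoint and ordered lumen -> IM -> adventitia"
            )
        tm = self.target_medians
        if not (tm["lumen"] < tm["im"] < tm["adventitia"]):
            raise SpecificationError(
                "target medians must be ordered lumen < IM < adventitia"
            )
        if self.speckle not in {"rayleigh"}:
            raise SpecificationError(f"unknown speckle model {self.speckle!r}")
        if self.dispersion < 0:
            raise SpecificationError("dispersion must be >= 0")


@dataclass
class WallImage:
    """An 8-bit far-wall image with ground-truth region masks."""

    image: np.ndarray  # uint8, height x width
    masks: dict[str, np.ndarray]  # region name -> bool array
    spec: WallImageSpec


_RAYLEIGH_MEDIAN = np.sqrt(2.0 * np.log(2.0))  # median of a unit Rayleigh


def _speckle_field(
    target: float, size: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative Rayleigh speckle with median pinned at ``target``.

    The unit-median factor (R / median(R)) is raised to ``dispersion``: a
    monotone transform, so the median stays at the target while the spread
    scales with the dispersion.  Zero dispersion gives a uniform region.
    """
    if dispersion == 0:
        return np.full(size, float(target))
    factor = (rng.rayleigh(1.0, size) / _RAYLEIGH_MEDIAN) ** dispersion
    return target * factor


def generate_wall_image(spec: WallImageSpec) -> WallImage:
    """Render a speckled far-wall image from its specification.

    Per-region pixel medians land within ~2 gray levels of the configured
    targets (quantization aside); ground-truth masks, including the plaque
    if present, are returned alongside the image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((spec.height, spec.width), dtype=float)
    masks: dict[str, np.ndarray] = {}
    bands = {
        "lumen": spec.lumen_band,
        "im": spec.im_band,
        "adventitia": spec.adventitia_band,
    }
    for name, (lo, hi) in bands.items():
        mask = np.zeros((spec.height, spec.width), dtype=bool)
        mask[lo:hi, :] = True
        masks[name] = mask
        img[mask] = _speckle_field(
            spec.target_medians[name], int(mask.sum()), spec.dispersion, rng
        )
    if spec.plaque is not None:
        from skimage.draw import ellipse

        rr, cc = ellipse(
            *spec.plaque.center, *spec.plaque.axes, shape=(spec.height, spec.width)
        )
        pmask = np.zeros((spec.height, spec.width), dtype=bool)
        pmask[rr, cc] = True
        if not pmask.any():
            raise SpecificationError("plaque ellipse has no pixels inside the image")
        img[pmask] = _speckle_field(
            spec.plaque.median, int(pmask.sum()), spec.dispersion, rng
        )
        for name in bands:
            masks[name] &= ~pmask
        masks["plaque"] = pmask
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return WallImage(image=img, masks=masks, spec=spec)
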