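"""Risk stratification models built on the GSM phenotypes.

Covers the correlation between plaque-GSM and IM-GSM, logistic prediction
of each (median-dichotomized) GSM from its retained determinants with a
paired comparison of the two ROC AUCs, and the association between GSM
quartiles and high atherosclerotic burden (IMT_max in the upper quartile,
>= 2.5 mm in the reference cohort): a per-quartile ordinal odds ratio and a
4x4 quartile-by-quartile OR grid, both adjusted for the strongest
determinants of IMT_max (latitude, sex, age, educational level, pulse
pressure and pack-years category).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import ADJUSTMENT_COVARIATES
from .selection import quartile_code

__all__ = [
    "AucComparison",
    "ORGrid",
    "correlate_gsm",
    "predict_dichotomized_gsm",
    "or_per_quartile",
    "or_grid",
    "high_burden_indicator",
    "auc_with_influence",
]


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlate_gsm(plaque_gsm, im_gsm) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between paired GSM phenotypes."""
    x = np.asarray(plaque_gsm, dtype=float)
    y = np.asarray(im_gsm, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    x, y = x[mask], y[mask]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# AUC machinery (midrank placements + Hajek-projection covariance)
# ---------------------------------------------------------------------------

def auc_with_influence(y: np.ndarray, score: np.ndarray) -> tuple[float, np.ndarray]:
    """Empirical AUC and per-subject influence values.

    The influence decomposition generalizes the DeLong variance: for two
    AUCs on the same subjects (even with different case/control labels),
    ``cov = (h_a @ h_b) / n^2`` estimates their sampling covariance, and the
    usual DeLong variance is recovered when the labels coincide.
    """
    y = np.asarray(y).astype(bool)
    score = np.asarray(score, dtype=float)
    n = len(y)
    m, q = int(y.sum()), int((~y).sum())
    if m == 0 or q == 0:
        raise ValueError("AUC undefined: one outcome class is empty")
    order = np.argsort(score, kind="mergesort")
    ranks_all = np.empty(n)
    ranks_all[order] = _midrank(score[order])
    # placements: fraction of the other class below each observation
    v10 = (ranks_all[y] - _midrank_within(score[y])) / q  # per case
    v01 = 1.0 - (ranks_all[~y] - _midrank_within(score[~y])) / m  # per control
    auc = float(v10.mean())
    h = np.zeros(n)
    h[y] = (n / m) * (v10 - auc)
    h[~y] = (n / q) * (v01 - auc)
    return auc, h


def _midrank(sorted_x: np.ndarray) -> np.ndarray:
    """Midranks (1-based) of an already-sorted vector."""
    n = len(sorted_x)
    out = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and sorted_x[j] == sorted_x[i]:
            j += 1
        out[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    return out


def _midrank_within(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    out = np.empty(len(x))
    out[order] = _midrank(x[order])
    return out


def delong_ci(auc: float, h: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(h)
    se = float(np.sqrt((h @ h) / n ** 2))
    z = stats.norm.ppf(0.5 + level / 2)
    return max(auc - z * se, 0.0), min(auc + z * se, 1.0)


# ---------------------------------------------------------------------------
# dichotomized-GSM prediction
# ---------------------------------------------------------------------------

@dataclass
class AucComparison:
    """Paired comparison of the two dichotomized-GSM prediction AUCs."""

    auc_plaque: float
    ci_plaque: tuple[float, float]
    auc_im: float
    ci_im: tuple[float, float]
    p_difference: float
    n: int

    def to_json_dict(self) -> dict:
        return {
            "auc_plaque": self.auc_plaque,
            "ci_plaque": list(self.ci_plaque),
            "auc_im": self.auc_im,
            "ci_im": list(self.ci_im),
            "p_difference": self.p_difference,
            "n": self.n,
        }


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """Logistic fit with a ridge fallback when separation breaks the MLE."""
    D = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            if np.all(np.isfinite(res.bse)) and np.all(res.bse < 1e3):
                return res, False
        except Exception:
            pass
        # penalized fallback for separated or ill-conditioned fits; escalate
        # the L2 penalty until the fit is numerically stable
        res = None
        for alpha in (1e-4, 1e-2, 1.0, 100.0):
            try:
                res = model.fit_regularized(
                    alpha=alpha, L1_wt=0.0, disp=0, maxiter=500
                )
                if np.all(np.isfinite(res.params)):
                    break
            except Exception:
                res = None
        if res is None:
            raise RuntimeError("logistic fit failed even with L2 penalty")
    return res, True


def predict_dichotomized_gsm(
    data: pd.DataFrame,
    plaque_predictors: Sequence[str],
    im_predictors: Sequence[str],
) -> AucComparison:
    """Logistic prediction of above-median plaque-GSM and IM-GSM.

    Both models are fitted and evaluated on the common complete-case
    subject set (subjects with both phenotypes and all predictors).  AUCs
    carry DeLong-style confidence intervals; the difference p-value uses
    the paired influence-function covariance of the two empirical AUCs.
    """
    cols = sorted(set(plaque_predictors) | set(im_predictors))
    sub = data[["plaque_gsm", "im_gsm"] + cols].dropna()
    n = len(sub)
    if n < 20:
        raise ValueError("too few complete cases for AUC comparison")
    y_pl = (sub["plaque_gsm"] > sub["plaque_gsm"].median()).to_numpy()
    y_im = (sub["im_gsm"] > sub["im_gsm"].median()).to_numpy()
    res_pl, _ = _fit_logit(np.asarray(sub[list(plaque_predictors)], dtype=float), y_pl)
    res_im, _ = _fit_logit(np.asarray(sub[list(im_predictors)], dtype=float), y_im)
    s_pl = res_pl.predict(
        sm.add_constant(np.asarray(sub[list(plaque_predictors)], dtype=float),
                        has_constant="add")
    )
    s_im = res_im.predict(
        sm.add_constant(np.asarray(sub[list(im_predictors)], dtype=float),
                        has_constant="add")
    )
    auc_pl, h_pl = auc_with_influence(y_pl, s_pl)
    auc_im, h_im = auc_with_influence(y_im, s_im)
    var_pl = (h_pl @ h_pl) / n ** 2
    var_im = (h_im @ h_im) / n ** 2
    cov = (h_pl @ h_im) / n ** 2
    se_diff = np.sqrt(max(var_pl + var_im - 2 * cov, 1e-300))
    z = (auc_im - auc_pl) / se_diff
    p = 2.0 * stats.norm.sf(abs(z))
    return AucComparison(
        auc_plaque=auc_pl,
        ci_plaque=delong_ci(auc_pl, h_pl),
        auc_im=auc_im,
        ci_im=delong_ci(auc_im, h_im),
        p_difference=float(p),
        n=n,
    )


# ---------------------------------------------------------------------------
# high atherosclerotic burden
# ---------------------------------------------------------------------------

def high_burden_indicator(data: pd.DataFrame) -> pd.Series:
    """High atherosclerotic burden: IMT_max in its upper quartile."""
    imt = data["imt_max"].astype(float)
    q3 = imt.quantile(0.75)
    return (imt > q3).astype(int)


def _burden_frame(
    data: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Complete-case analysis frame: plaque carriers with both phenotypes."""
    burden = high_burden_indicator(data)
    cols = ["plaque_gsm", "im_gsm", "imt_max"] + list(covariates)
    sub = data[cols].assign(_burden=burden).dropna()
    if len(sub) < 50:
        raise ValueError("too few complete cases for burden models")
    qp = quartile_code(sub["plaque_gsm"].to_numpy())
    qim = quartile_code(sub["im_gsm"].to_numpy())
    C = np.column_stack(
        [stats.zscore(sub[c].to_numpy(dtype=float), ddof=1) for c in covariates]
    )
    return sub, qp, qim, C


def or_per_quartile(
    data: pd.DataFrame,
    which: str = "plaque",
    covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
) -> dict[str, float]:
    """Adjusted OR for high burden per one-quartile GSM increase.

    Fits a logistic model with the chosen GSM quartile entered as an
    ordinal 1-4 term plus the adjustment covariates, and returns the
    exponentiated slope with its Wald 95% CI.
    """
    if which not in {"plaque", "im"}:
        raise ValueError("which must be 'plaque' or 'im'")
    sub, qp, qim, C = _burden_frame(data, covariates)
    qx = qp if which == "plaque" else qim
    X = np.column_stack([qx, C])
    res, penalized = _fit_logit(X, sub["_burden"].to_numpy())
    b = float(res.params[1])
    se = float(res.bse[1]) if np.isfinite(res.bse[1]) else np.nan
    z = stats.norm.ppf(0.975)
    return {
        "odds_ratio": float(np.exp(b)),
        "ci_low": float(np.exp(b - z * se)),
        "ci_high": float(np.exp(b + z * se)),
        "p_value": float(res.pvalues[1]),
        "n": len(sub),
        "penalized": bool(penalized),
    }


@dataclass
class ORGrid:
    """4x4 odds-ratio grid for high burden across GSM quartile pairs.

    Rows index plaque-GSM quartiles, columns IM-GSM quartiles; the
    reference cell (plaque Q4, IM Q1) has OR 1 by construction.  Cells with
    no subjects are reported as NaN.  ``quadratic_p`` carries supplementary
    p-values for a quadratic quartile term (U-shape), computed
    descriptively.
    """

    odds_ratio: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_per_cell: pd.DataFrame
    covariates: tuple[str, ...]
    reference: tuple[int, int] = (4, 1)
    quadratic_p: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def to_tsv(self, path) -> None:
        rows = []
        for qp in (1, 2, 3, 4):
            for qim in (1, 2, 3, 4):
                rows.append(
                    {
                        "plaque_gsm_quartile": qp,
                        "im_gsm_quartile": qim,
                        "odds_ratio": self.odds_ratio.loc[qp, qim],
                        "ci_low": self.ci_low.loc[qp, qim],
                        "ci_high": self.ci_high.loc[qp, qim],
                        "n": self.n_per_cell.loc[qp, qim],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def or_grid(
    data: pd.DataFrame,
    covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
) -> ORGrid:
    """Quartile-by-quartile adjusted OR grid for high burden.

    One logistic model with 15 cell indicators (reference: plaque-GSM Q4
    with IM-GSM Q1) plus the standardized adjustment covariates.
    """
    sub, qp, qim, C = _burden_frame(data, covariates)
    y = sub["_burden"].to_numpy()
    cells = [(a, b) for a in (1, 2, 3, 4) for b in (1, 2, 3, 4)]
    ref = (4, 1)
    counts = {c: int(np.sum((qp == c[0]) & (qim == c[1]))) for c in cells}
    model_cells = [c for c in cells if c != ref and counts[c] > 0]
    dummies = np.column_stack(
        [((qp == a) & (qim == b)).astype(float) for a, b in model_cells]
    )
    X = np.column_stack([dummies, C])
    res, penalized = _fit_logit(X, y)
    z = stats.norm.ppf(0.975)

    idx = pd.Index([1, 2, 3, 4], name="plaque_gsm_quartile")
    colix = pd.Index([1, 2, 3, 4], name="im_gsm_quartile")
    OR = pd.DataFrame(np.nan, index=idx, columns=colix)
    LO = OR.copy()
    HI = OR.copy()
    N = pd.DataFrame(0, index=idx, columns=colix)
    OR.loc[ref[0], ref[1]] = 1.0
    LO.loc[ref[0], ref[1]] = 1.0
    HI.loc[ref[0], ref[1]] = 1.0
    for c in cells:
        N.loc[c[0], c[1]] = counts[c]
    for j, (a, b) in enumerate(model_cells):
        coef = float(res.params[1 + j])
        se = float(res.bse[1 + j])
        OR.loc[a, b] = np.exp(coef)
        LO.loc[a, b] = np.exp(coef - z * se)
        HI.loc[a, b] = np.exp(coef + z * se)

    # supplementary U-shape check: quadratic quartile term per phenotype
    quad_p = {}
    for name, qx in (("plaque", qp), ("im", qim)):
        qc = qx - qx.mean()
        Xq = np.column_stack([qc, qc ** 2, C])
        rq, _ = _fit_logit(Xq, y)
        quad_p[name] = float(rq.pvalues[2])

    return ORGrid(
        odds_ratio=OR,
        ci_low=LO,
        ci_high=HI,
        n_per_cell=N,
        covariates=tuple(covariates),
        reference=ref,
        quadratic_p=quad_p,
        n=len(sub),
    )
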