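"""Determinant selection for GSM outcomes.

Implements the statistical core of the analysis: variable coding
(pack-years categories, quartile codes), a Bonferroni-corrected univariate
screen across outcome quartiles, forward/backward stepwise regression, a
repeated split-sample stability-selection procedure (predictors selected in
a random training half must also validate in the testing half, over many
random splits), and the final multiple linear regression with a sequential
partial-R^2 decomposition that is additive to the whole-model R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Candidate",
    "CandidatePanel",
    "SelectionReport",
    "ModelFit",
    "quartile_code",
    "code_pack_years",
    "univariate_screen",
    "stepwise_select",
    "cross_validated_selection",
    "fit_final_model",
]

#: significance threshold of the univariate screen: Bonferroni correction of
#: alpha = 0.05 for 73 independent comparisons.
BONFERRONI_ALPHA = 0.0007

_COLLINEARITY_TOL = 1e-10


# ---------------------------------------------------------------------------
# variable coding
# ---------------------------------------------------------------------------

def quartile_code(x: np.ndarray | pd.Series) -> np.ndarray:
    """Code a numeric vector into quartiles 1-4.

    Boundaries are the 25/50/75 percentiles of the analysis sample; values
    equal to a boundary fall in the lower quartile.  NaNs propagate.
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values to form quartiles")
    q1, q2, q3 = np.percentile(x[finite], [25, 50, 75])
    code = np.full(x.shape, np.nan)
    code[finite] = (
        1.0
        + (x[finite] > q1).astype(float)
        + (x[finite] > q2).astype(float)
        + (x[finite] > q3).astype(float)
    )
    return code


def code_pack_years(pack_years: np.ndarray | pd.Series) -> np.ndarray:
    """Code lifelong smoking exposure into four categories.

    Category 0 is never smokers (pack-years exactly 0); categories 1-3 are
    the tertiles of pack-years among ever smokers, with values on a tertile
    boundary assigned to the lower category.  The coding is monotone in
    pack-years.
    """
    x = np.asarray(pack_years, dtype=float)
    finite = np.isfinite(x)
    if np.any(x[finite] < 0):
        raise ValueError("pack-years cannot be negative")
    code = np.full(x.shape, np.nan)
    zero = finite & (x == 0)
    ever = finite & (x > 0)
    code[zero] = 0.0
    n_ever = int(ever.sum())
    if n_ever == 0:
        return code
    if n_ever < 3:
        # too few ever-smokers for tertiles: rank the few directly
        order = np.argsort(x[ever], kind="stable")
        small = np.empty(n_ever)
        # map the smallest to 1, the largest to 3 (a single smoker gets 1)
        labels = [1.0] if n_ever == 1 else [1.0, 3.0]
        small[order] = labels
        code[ever] = small
        return code
    t1, t2 = np.percentile(x[ever], [100 / 3, 200 / 3])
    code[ever] = 1.0 + (x[ever] > t1).astype(float) + (x[ever] > t2).astype(float)
    return code


# ---------------------------------------------------------------------------
# candidate panel / univariate screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """A screened variable: name, distributional kind, declared transform.

    ``kind`` chooses the test across outcome quartiles: ``normal`` -> one-way
    ANOVA (with Bonferroni post hoc), ``skewed`` -> Kruskal-Wallis on the
    log scale, ``categorical``/``binary`` -> chi-square or Fisher's exact.
    """

    name: str
    kind: str = "normal"
    transform: str = "identity"

    def __post_init__(self):
        if self.kind not in {"normal", "skewed", "binary", "categorical"}:
            raise ValueError(f"unknown candidate kind {self.kind!r}")
        if self.transform not in {"identity", "log", "tertile-code", "quartile-code"}:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class CandidatePanel:
    """The candidate variables screened for one GSM outcome."""

    outcome: str
    candidates: Sequence[Candidate]

    def __post_init__(self):
        names = [c.name for c in self.candidates]
        if len(names) != len(set(names)):
            raise ValueError("duplicate candidates in panel")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.candidates]


def _transformed(values: np.ndarray, cand: Candidate) -> np.ndarray:
    if cand.transform == "log":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log(values)
        out[~np.isfinite(out)] = np.nan
        return out
    if cand.transform == "tertile-code":
        finite = np.isfinite(values)
        out = np.full(values.shape, np.nan)
        if finite.sum() >= 3:
            t1, t2 = np.percentile(values[finite], [100 / 3, 200 / 3])
            out[finite] = (
                1.0 + (values[finite] > t1).astype(float) + (values[finite] > t2).astype(float)
            )
        return out
    if cand.transform == "quartile-code":
        return quartile_code(values)
    return values.astype(float)


def univariate_screen(
    data: pd.DataFrame,
    panel: CandidatePanel,
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """Screen each candidate against quartiles of the outcome.

    Returns one row per candidate with the test used, its statistic and
    p-value, a standardized trend beta (slope of the standardized candidate
    on the quartile index 1-4), and a significance flag at ``alpha``.
    """
    y = np.asarray(data[panel.outcome], dtype=float)
    groups = quartile_code(y)
    rows = []
    for cand in panel.candidates:
        raw = np.asarray(data[cand.name], dtype=float)
        x = _transformed(raw, cand)
        mask = np.isfinite(x) & np.isfinite(groups)
        if mask.sum() == 0:
            rows.append(
                dict(candidate=cand.name, test="none", statistic=np.nan,
                     p_value=np.nan, trend_beta=np.nan, significant=False,
                     excluded=True, note="all values missing")
            )
            continue
        xg = [x[mask & (groups == q)] for q in (1, 2, 3, 4)]
        note = ""
        if cand.kind in ("normal", "skewed"):
            if any(len(g) < 2 for g in xg):
                stat, p, test = np.nan, np.nan, "none"
                note = "quartile group too small"
            elif cand.kind == "normal":
                stat, p = stats.f_oneway(*xg)
                test = "anova"
            else:
                stat, p = stats.kruskal(*xg)
                test = "kruskal"
        else:
            # contingency table: candidate levels x outcome quartiles
            levels = np.unique(x[mask])
            table = np.array(
                [[np.sum((x == lv) & mask & (groups == q)) for q in (1, 2, 3, 4)]
                 for lv in levels]
            )
            table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
            if table.shape[0] < 2 or table.shape[1] < 2:
                stat, p, test = np.nan, np.nan, "none"
                note = "degenerate contingency table"
            else:
                chi2, p_chi, _, expected = stats.chi2_contingency(table)
                if (expected < 5).any():
                    if table.shape == (2, 2):
                        _, p = stats.fisher_exact(table)
                        stat, test = np.nan, "fisher"
                    else:
                        stat, p, test = chi2, p_chi, "chi2"
                        note = "low expected counts; exact test unavailable for r x c"
                else:
                    stat, p, test = chi2, p_chi, "chi2"
        # standardized trend across quartiles
        xs = x[mask]
        sd = xs.std(ddof=1)
        if sd > 0 and len(xs) > 2:
            z = (xs - xs.mean()) / sd
            g = groups[mask]
            slope = np.cov(z, g, ddof=1)[0, 1] / np.var(g, ddof=1)
        else:
            slope = np.nan
        rows.append(
            dict(candidate=cand.name, test=test, statistic=stat, p_value=p,
                 trend_beta=slope, significant=bool(np.isfinite(p) and p < alpha),
                 excluded=False, note=note)
        )
    return pd.DataFrame(rows).set_index("candidate")


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS with intercept; returns (beta, p-values, rss). X excludes intercept."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    rss = float(resid @ resid)
    df = n - D.shape[1]
    if df <= 0:
        return beta, np.full(D.shape[1], np.nan), rss
    sigma2 = rss / df
    XtX_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, p, rss


def stepwise_select(
    data: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    entry_p: float = 0.05,
    stay_p: float = 0.10,
    max_iter: int | None = None,
) -> list[str]:
    """Forward-backward stepwise linear regression.

    At each round the candidate with the smallest entry p-value joins the
    model if that p-value is below ``entry_p``; any included predictor whose
    p-value exceeds ``stay_p`` is then dropped.  Iterates to a fixed point.
    Deterministic given the data; ties are broken by candidate order.
    Candidates that are numerically collinear with the current model are
    skipped.
    """
    cols = list(candidates)
    mask = np.isfinite(np.asarray(data[outcome], dtype=float))
    for c in cols:
        mask &= np.isfinite(np.asarray(data[c], dtype=float))
    y = np.asarray(data.loc[mask, outcome], dtype=float)
    X = np.asarray(data.loc[mask, cols], dtype=float)
    n = len(y)
    if n == 0:
        return []
    if entry_p <= 0:
        return []

    selected: list[int] = []
    Q = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis of current design
    yr = y - Q @ (Q.T @ y)
    seen: set[frozenset] = set()
    max_iter = max_iter or (2 * len(cols) + 10)

    for _ in range(max_iter):
        changed = False
        remaining = [j for j in range(len(cols)) if j not in selected]
        if remaining:
            Xr = X[:, remaining]
            Z = Xr - Q @ (Q.T @ Xr)
            zz = (Z ** 2).sum(axis=0)
            norms = (Xr ** 2).sum(axis=0)
            ok = zz > _COLLINEARITY_TOL * np.maximum(norms, 1.0)
            zy = Z.T @ yr
            rss0 = float(yr @ yr)
            with np.errstate(divide="ignore", invalid="ignore"):
                gain = np.where(ok, zy ** 2 / zz, 0.0)
            df = n - Q.shape[1] - 1
            if df > 0:
                rss1 = np.maximum(rss0 - gain, 0.0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    f = gain / (rss1 / df)
                p_add = np.where(ok, stats.f.sf(f, 1, df), np.inf)
                best = int(np.argmin(p_add))
                if p_add[best] < entry_p:
                    j = remaining[best]
                    q_new = Z[:, best] / np.sqrt(zz[best])
                    Q = np.column_stack([Q, q_new])
                    yr = yr - q_new * (q_new @ yr)
                    selected.append(j)
                    changed = True
        # backward pass
        while len(selected) > 0:
            _, p, _ = _ols_pvalues(X[:, selected], y)
            p_pred = p[1:]  # skip intercept
            worst = int(np.argmax(np.nan_to_num(p_pred, nan=np.inf)))
            if np.isfinite(p_pred[worst]) and p_pred[worst] > stay_p:
                selected.pop(worst)
                # rebuild orthonormal basis after a drop
                D = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
                Q, _ = np.linalg.qr(D)
                yr = y - Q @ (Q.T @ y)
                changed = True
            else:
                break
        key = frozenset(selected)
        if not changed or key in seen:
            break
        seen.add(key)
    return [cols[j] for j in selected]


# ---------------------------------------------------------------------------
# split-sample stability selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-candidate selection/validation frequencies over random splits."""

    outcome: str
    n_iterations: int
    threshold: float
    seed: int
    table: pd.DataFrame  # index: candidate; columns: selected_count, validated_count, frequency
    retained: list[str] = field(default_factory=list)
    iteration_log: list[list[str]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_iterations": self.n_iterations,
            "threshold": self.threshold,
            "seed": self.seed,
            "retained": list(self.retained),
            "candidates": {
                name: {
                    "selected_count": int(row["selected_count"]),
                    "validated_count": int(row["validated_count"]),
                    "frequency": float(row["frequency"]),
                }
                for name, row in self.table.iterrows()
            },
        }


def cross_validated_selection(
    data: pd.DataFrame,
    panel: CandidatePanel,
    n_iterations: int = 200,
    threshold: float = 0.70,
    entry_p: float = 0.05,
    stay_p: float = 0.10,
    seed: int = 0,
    validation: str = "per_coefficient",
) -> SelectionReport:
    """Repeated random half-split stability selection.

    Each iteration splits the data into random halves, runs stepwise
    selection on the training half, refits the selected model on the testing
    half, and counts a candidate as *validated* when it was selected and its
    testing-half coefficient is significant at p < 0.05 (``validation=
    'per_coefficient'``) or the testing-half whole-model F-test is
    significant (``validation='model_f'``).  Candidates validated in at
    least ``threshold`` of the iterations are retained.
    """
    if validation not in {"per_coefficient", "model_f"}:
        raise ValueError(f"unknown validation mode {validation!r}")
    names = panel.names
    n = len(data)
    if n < 40:
        raise ValueError("need at least 40 rows for half-sample selection")
    if not names:
        raise ValueError("candidate panel is empty")
    rng = np.random.default_rng(seed)
    selected_count = {c: 0 for c in names}
    validated_count = {c: 0 for c in names}
    iteration_log: list[list[str]] = []

    y_all = np.asarray(data[panel.outcome], dtype=float)
    X_all = np.asarray(data[names], dtype=float)

    for _ in range(n_iterations):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[: n // 2], perm[n // 2:]
        train = data.iloc[train_idx]
        chosen = stepwise_select(train, panel.outcome, names, entry_p, stay_p)
        iteration_log.append(chosen)
        for c in chosen:
            selected_count[c] += 1
        if not chosen:
            continue
        cols = [names.index(c) for c in chosen]
        y_t = y_all[test_idx]
        X_t = X_all[np.ix_(test_idx, cols)]
        m = np.isfinite(y_t) & np.isfinite(X_t).all(axis=1)
        if m.sum() <= len(cols) + 1:
            continue
        _, p, rss = _ols_pvalues(X_t[m], y_t[m])
        if validation == "per_coefficient":
            for c, pv in zip(chosen, p[1:]):
                if np.isfinite(pv) and pv < 0.05:
                    validated_count[c] += 1
        else:
            yt = y_t[m]
            tss = float(((yt - yt.mean()) ** 2).sum())
            k = len(cols)
            dfd = m.sum() - k - 1
            if tss > 0 and dfd > 0 and rss < tss:
                f = ((tss - rss) / k) / (rss / dfd)
                if stats.f.sf(f, k, dfd) < 0.05:
                    for c in chosen:
                        validated_count[c] += 1

    table = pd.DataFrame(
        {
            "selected_count": [selected_count[c] for c in names],
            "validated_count": [validated_count[c] for c in names],
        },
        index=pd.Index(names, name="candidate"),
    )
    table["frequency"] = table["validated_count"] / n_iterations
    retained = [c for c in names if table.loc[c, "frequency"] >= threshold]
    return SelectionReport(
        outcome=panel.outcome,
        n_iterations=n_iterations,
        threshold=threshold,
        seed=seed,
        table=table,
        retained=retained,
        iteration_log=iteration_log,
    )


# ---------------------------------------------------------------------------
# final model
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Final multiple-regression fit with additive partial-R^2 shares."""

    outcome: str
    n_used: int
    whole_model_r2: float
    table: pd.DataFrame
    # index: predictor (in decreasing-contribution order); columns:
    # beta_semi_std, p_value, partial_r2, partial_corr_sq

    def to_json_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_used": self.n_used,
            "whole_model_r2": self.whole_model_r2,
            "predictors": {
                name: {k: float(row[k]) for k in row.index}
                for name, row in self.table.iterrows()
            },
        }


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    D = np.column_stack([np.ones(len(y)), X]) if X.shape[1] else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan


def fit_final_model(data: pd.DataFrame, outcome: str, retained: Sequence[str]) -> ModelFit:
    """OLS of the outcome on the retained predictors with partial R^2.

    Betas are semi-standardized (outcome units per predictor SD; quartile-
    coded predictors enter as ordinal codes).  Partial R^2 is the sequential
    incremental R^2 with predictors entered in order of decreasing
    contribution (greedy), so the shares are additive to the whole-model
    R^2.  Squared partial correlations are reported as a secondary column.
    """
    retained = list(retained)
    if not retained:
        raise ValueError("retained predictor set is empty")
    cols = [outcome] + retained
    sub = data[cols].dropna()
    n = len(sub)
    if n < 10 * len(retained):
        warnings.warn(
            f"only {n} complete cases for {len(retained)} predictors",
            stacklevel=2,
        )
    y = np.asarray(sub[outcome], dtype=float)
    X = np.asarray(sub[retained], dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < len(retained) + 1:
        # identify a minimal collinear set via QR pivoting
        from scipy.linalg import qr

        D = np.column_stack([np.ones(n), X])
        _, R, piv = qr(D, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [retained[j - 1] for j in piv[diag < 1e-8 * diag.max()] if j > 0]
        raise ValueError(f"rank-deficient design; collinear predictors: {bad}")

    beta, p, rss = _ols_pvalues(X, y)
    sds = X.std(axis=0, ddof=1)
    beta_semi = beta[1:] * sds
    whole = _r2(X, y)

    # greedy sequential decomposition: largest incremental R^2 first
    order: list[int] = []
    increments: list[float] = []
    current = 0.0
    remaining = list(range(len(retained)))
    while remaining:
        gains = []
        for j in remaining:
            r2_with = _r2(X[:, order + [j]], y)
            gains.append(r2_with - current)
        k = int(np.argmax(gains))
        order.append(remaining[k])
        increments.append(gains[k])
        current += gains[k]
        remaining.pop(k)

    # squared partial correlations from full-model t statistics
    df = n - len(retained) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = stats.t.isf(p[1:] / 2.0, df) ** 2
        partial_corr_sq = np.where(np.isinf(t2), 1.0, t2 / (t2 + df))

    table = pd.DataFrame(
        {
            "beta_semi_std": beta_semi[order],
            "p_value": p[1:][order],
            "partial_r2": increments,
            "partial_corr_sq": partial_corr_sq[order],
        },
        index=pd.Index([retained[j] for j in order], name="predictor"),
    )
    return ModelFit(outcome=outcome, n_used=n, whole_model_r2=whole, table=table)
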