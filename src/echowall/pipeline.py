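"""End-to-end orchestration: simulate -> measure -> adjust -> select ->
model -> stratify -> report.

:func:`run_pipeline` executes every stage on a :class:`~echowall.config.
RunConfig`, writing interchange files (CSV/TSV/JSON/YAML, optionally PNG
figures) plus a Markdown report and a manifest with versions and seeds into
a run directory.  Stage failures abort with a stage-tagged error.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ADJUSTMENT_COVARIATES, CohortConfig, RunConfig
from .gsm import adjust_for_calibration, reproducibility_stats
from .risk import correlate_gsm, or_grid, or_per_quartile, predict_dichotomized_gsm
from .selection import (
    Candidate,
    CandidatePanel,
    cross_validated_selection,
    fit_final_model,
    univariate_screen,
)
from .synth import generate_cohort, generate_repeat_scans

log = logging.getLogger("echowall")

# candidate variables with a potential true effect, shared by both outcomes
_BASE_CANDIDATES: tuple[tuple[str, str], ...] = (
    ("latitude", "normal"),
    ("sex", "binary"),
    ("age", "normal"),
    ("height", "normal"),
    ("waist_hip_ratio", "normal"),
    ("sbp", "normal"),
    ("dbp", "normal"),
    ("educational_level", "normal"),
    ("mcv", "normal"),
    ("fibrates", "binary"),
    ("sartans", "binary"),
    ("pack_years_code", "categorical"),
    ("creatinine_log", "normal"),
)


def default_panel(data: pd.DataFrame, outcome: str) -> CandidatePanel:
    """The regression candidate panel for one GSM outcome.

    Includes the shared risk-factor candidates, the outcome's thickness
    quartile code, and every nuisance column present in the data.
    """
    thickness = "imt_max_quartile" if "plaque" in outcome else "pf_cc_imt_quartile"
    cands = [Candidate(name, kind) for name, kind in _BASE_CANDIDATES]
    cands.append(Candidate(thickness, "categorical", "identity"))
    for col in data.columns:
        if col.startswith("nuisance_"):
            kind = "binary" if set(pd.unique(data[col].dropna())) <= {0, 1} else "normal"
            cands.append(Candidate(col, kind))
    return CandidatePanel(outcome=outcome, candidates=cands)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage and write all outputs under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    timers: dict[str, float] = {}

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = _stage(name)(fn)(*args, **kwargs)
        timers[name] = round(time.perf_counter() - t0, 3)
        return out

    cohort = timed("simulate", _simulate, config, outdir)
    timed("measure", _measure_and_adjust, config, cohort, outdir)
    reports, fits = timed("select", _select_and_model, config, cohort, outdir)
    risk = timed("stratify", _stratify, config, cohort, reports, fits, outdir)
    timed("report", _report, config, cohort, reports, fits, risk, outdir)

    manifest = {
        "echowall_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "cohort_seed": config.cohort.seed,
        "n_subjects": len(cohort),
        "stage_seconds": timers,
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _simulate(config: RunConfig, outdir: Path) -> pd.DataFrame:
    cohort = generate_cohort(config.cohort, seed=config.cohort.seed)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    dictionary = {
        "plaque_gsm": "true plaque gray-scale median (missing without plaque)",
        "im_gsm": "true intima-media gray-scale median",
        "plaque_gsm_raw": "plaque GSM with per-image calibration confounding",
        "im_gsm_raw": "IM GSM with per-image calibration confounding",
        "black_ref": "per-image reference black (darkest lumen section, 0-37)",
        "white_ref": "per-image reference white (brightest adventitia, 104-255)",
        "imt_max": "maximum intima-media thickness across segments/sides (mm)",
        "pf_cc_imt_mean": "plaque-free common-carotid mean IMT (mm)",
        "plaque_present": "IMT_max >= 1.5 mm",
        "pack_years_code": "0 never smoker; 1-3 tertiles among ever smokers",
        "nuisance_*": "independent noise candidates with no true effect",
    }
    (outdir / "data_dictionary.json").write_text(json.dumps(dictionary, indent=2))
    return cohort


def _measure_and_adjust(config: RunConfig, cohort: pd.DataFrame, outdir: Path) -> None:
    for var in ("plaque_gsm", "im_gsm"):
        cohort[f"{var}_adj"] = adjust_for_calibration(
            cohort[f"{var}_raw"], cohort["black_ref"], cohort["white_ref"]
        )
    cc = config.cohort
    stats_out = {}
    for var, icc in (("plaque_gsm", cc.icc_plaque), ("im_gsm", cc.icc_im)):
        pairs = generate_repeat_scans(
            cohort, variable=var, icc_target=icc,
            n_pairs=cc.n_repeat_scans, seed=config.seed + 1,
        )
        stats_out[var] = reproducibility_stats(pairs)
        stats_out[var]["icc_target"] = icc
    (outdir / "reproducibility.json").write_text(json.dumps(stats_out, indent=2))


def _select_and_model(config: RunConfig, cohort: pd.DataFrame, outdir: Path):
    reports, fits = {}, {}
    for short, outcome, frame in (
        ("plaque", "plaque_gsm_adj", cohort[cohort["plaque_present"]]),
        ("im", "im_gsm_adj", cohort),
    ):
        panel = default_panel(frame, outcome)
        screen = univariate_screen(frame, panel)
        screen.to_csv(outdir / f"screen_{short}.tsv", sep="\t")
        rep = cross_validated_selection(
            frame, panel,
            n_iterations=config.n_iterations,
            threshold=config.retention_threshold,
            entry_p=config.entry_p, stay_p=config.stay_p,
            seed=config.seed,
        )
        reports[short] = rep
        (outdir / f"selection_{short}.json").write_text(
            json.dumps(rep.to_json_dict(), indent=2)
        )
        rep.table.to_csv(outdir / f"selection_{short}.tsv", sep="\t")
        with open(outdir / f"selection_{short}_iterations.log", "w") as fh:
            for i, chosen in enumerate(rep.iteration_log):
                fh.write(f"{i}\t{','.join(chosen)}\n")
        if rep.retained:
            fit = fit_final_model(frame, outcome, rep.retained)
            fits[short] = fit
            (outdir / f"model_{short}.json").write_text(
                json.dumps(fit.to_json_dict(), indent=2)
            )
            fit.table.to_csv(outdir / f"model_{short}.tsv", sep="\t")
        else:
            log.warning("no retained predictors for %s; final model skipped", outcome)
    return reports, fits


def _stratify(config: RunConfig, cohort: pd.DataFrame, reports, fits, outdir: Path):
    out: dict = {}
    plaque_sub = cohort[cohort["plaque_present"]]
    r, p = correlate_gsm(plaque_sub["plaque_gsm_adj"], plaque_sub["im_gsm_adj"])
    out["correlation"] = {"r": r, "p": p, "n": int(plaque_sub["plaque_gsm_adj"].notna().sum())}

    preds_pl = reports["plaque"].retained or _top_candidates(reports["plaque"], 3)
    preds_im = reports["im"].retained or _top_candidates(reports["im"], 3)
    work = cohort.rename(
        columns={"plaque_gsm_adj": "plaque_gsm_use", "im_gsm_adj": "im_gsm_use"}
    )
    work = work.drop(columns=["plaque_gsm", "im_gsm"]).rename(
        columns={"plaque_gsm_use": "plaque_gsm", "im_gsm_use": "im_gsm"}
    )
    try:
        auc = predict_dichotomized_gsm(work, preds_pl, preds_im)
        out["auc_comparison"] = auc.to_json_dict()
    except ValueError as exc:
        out["auc_comparison"] = {"error": str(exc)}
    try:
        out["or_per_quartile"] = {
            "plaque": or_per_quartile(work, "plaque"),
            "im": or_per_quartile(work, "im"),
        }
        grid = or_grid(work)
        grid.to_tsv(outdir / "or_grid.tsv")
        out["or_grid_quadratic_p"] = grid.quadratic_p
        if config.make_figures:
            _plot_or_grid(grid, outdir / "or_grid.png")
    except ValueError as exc:
        out["or_per_quartile"] = {"error": str(exc)}
    (outdir / "risk_models.json").write_text(json.dumps(out, indent=2))
    return out


def _top_candidates(report, k: int) -> list[str]:
    tab = report.table.sort_values("frequency", ascending=False)
    return list(tab.index[:k])


def _plot_or_grid(grid, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(111, projection="3d")
    xs, ys, zs = [], [], []
    for qp in (1, 2, 3, 4):
        for qim in (1, 2, 3, 4):
            v = grid.odds_ratio.loc[qp, qim]
            if np.isfinite(v):
                xs.append(qp)
                ys.append(qim)
                zs.append(v)
    ax.bar3d(np.array(xs) - 0.4, np.array(ys) - 0.4, 0, 0.8, 0.8, zs, shade=True)
    ax.set_xlabel("plaque-GSM quartile")
    ax.set_ylabel("IM-GSM quartile")
    ax.set_zlabel("OR for high burden")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _report(config, cohort, reports, fits, risk, outdir: Path) -> None:
    lines = [
        "# Echolucency analysis report",
        "",
        f"Subjects: {len(cohort)}; plaque carriers: "
        f"{int(cohort['plaque_present'].sum())}; master seed: {config.seed}.",
        "",
    ]
    for short, label in (("plaque", "plaque-GSM"), ("im", "IM-GSM")):
        rep = reports[short]
        lines.append(f"## {label} determinants")
        lines.append("")
        lines.append(
            f"Stability selection: {rep.n_iterations} random half-splits, "
            f"retention threshold {rep.threshold:.0%}; retained "
            f"{len(rep.retained)} predictor(s): {', '.join(rep.retained) or 'none'}."
        )
        lines.append("")
        if short in fits:
            fit = fits[short]
            lines.append(
                f"Final model (n = {fit.n_used}): whole-model R^2 = "
                f"{100 * fit.whole_model_r2:.1f}%."
            )
            lines.append("")
            lines.append("| Predictor | Beta per SD | p | Partial R^2 |")
            lines.append("|---|---|---|---|")
            for name, row in fit.table.iterrows():
                lines.append(
                    f"| {name} | {row['beta_semi_std']:.2f} | "
                    f"{row['p_value']:.2g} | {100 * row['partial_r2']:.1f}% |"
                )
            lines.append("")
    lines.append("## Risk stratification")
    lines.append("")
    corr = risk.get("correlation", {})
    if corr:
        lines.append(
            f"Pearson r(plaque-GSM, IM-GSM) = {corr['r']:.2f} "
            f"(p = {corr['p']:.2g}, n = {corr['n']})."
        )
    auc = risk.get("auc_comparison", {})
    if "auc_plaque" in auc:
        lines.append(
            f"AUC for median-dichotomized GSM: plaque {auc['auc_plaque']:.3f}, "
            f"IM {auc['auc_im']:.3f} (difference p = {auc['p_difference']:.2g})."
        )
    orq = risk.get("or_per_quartile", {})
    if "plaque" in orq:
        lines.append(
            f"OR for high burden per GSM quartile: plaque "
            f"{orq['plaque']['odds_ratio']:.2f} "
            f"({orq['plaque']['ci_low']:.2f}-{orq['plaque']['ci_high']:.2f}); "
            f"IM {orq['im']['odds_ratio']:.2f} "
            f"({orq['im']['ci_low']:.2f}-{orq['im']['ci_high']:.2f})."
        )
    lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
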