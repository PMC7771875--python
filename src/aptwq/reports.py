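"""Publication-style result tables and the machine-readable summary.

``cohort_statistics`` computes the full statistical battery on a final
cohort; ``render_tables`` formats it with display rounding (group averages
2 dp, AUC 3 dp, sensitivity/specificity 1 dp).  The JSON summary always
carries full-precision floats; the rendered tables are for human
comparison only.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .grading import (
    DEFAULT_PROB_CUTOFF,
    METRIC_COLUMNS,
    ThresholdRule,
    classify_cohort,
    combined_misclassified,
    fit_combined_model,
    reassigned_suspected_lgg,
)
from .stats import (
    hosmer_lemeshow,
    mann_whitney,
    nagelkerke_r2,
    omnibus_test,
    roc_curve,
    shapiro_wilk,
    subgroup_means,
)

_DESCRIPTIVE_METRICS = ("mean", "max", "min", "range")


def group_descriptives(cohort: CohortTable) -> pd.DataFrame:
    """Per-group Average/Minimum/Maximum/Range of each APTw statistic (%)."""
    rows = []
    for metric in _DESCRIPTIVE_METRICS:
        col = METRIC_COLUMNS[metric]
        for grp, sub in cohort.df.groupby("group"):
            v = sub[col]
            rows.append(
                {
                    "metric": metric,
                    "group": grp,
                    "n": len(v),
                    "average": v.mean(),
                    "sd": v.std(),
                    "minimum": v.min(),
                    "maximum": v.max(),
                    "spread": v.max() - v.min(),
                }
            )
    return pd.DataFrame(rows)


def mann_whitney_table(cohort: CohortTable) -> pd.DataFrame:
    """HGG-vs-LGG Mann-Whitney U per APTw statistic."""
    df = cohort.df
    hgg = df[df["group"] == "HGG"]
    lgg = df[df["group"] == "LGG"]
    rows = []
    for metric in _DESCRIPTIVE_METRICS:
        col = METRIC_COLUMNS[metric]
        r = mann_whitney(hgg[col], lgg[col])
        rows.append(
            {
                "metric": metric,
                "u": r.u_statistic,
                "mean_rank_hgg": r.mean_rank_a,
                "mean_rank_lgg": r.mean_rank_b,
                "p_exact": r.p_exact,
                "p_asymptotic": r.p_asymptotic,
            }
        )
    return pd.DataFrame(rows)


def roc_table(cohort: CohortTable, prob_cutoff: float = DEFAULT_PROB_CUTOFF) -> dict:
    """ROC analysis per APTw statistic plus the combined logistic model.

    Returns a dict with the per-metric DataFrame, the fitted combined model
    and its diagnostics, and the model's misclassified subjects at both the
    configured probabilistic cutoff and the conventional 0.5 threshold.
    """
    df = cohort.df[cohort.df["group"].isin(("HGG", "LGG"))]
    labels = df["group"]
    rows = []
    for metric in ("mean", "max", "range"):
        r = roc_curve(df[METRIC_COLUMNS[metric]], labels, positive="HGG")
        rows.append(
            {
                "metric": metric,
                "auc": r.auc,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "cutoff": r.optimal_cutoff,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
        )
    model = fit_combined_model(cohort)
    fitted_roc = roc_curve(model.fitted, (model.outcome == 1), positive=True)
    chi2, dof, p_omnibus = omnibus_test(model)
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(model)
    rows.append(
        {
            "metric": "combined",
            "auc": fitted_roc.auc,
            "ci_low": fitted_roc.ci95[0],
            "ci_high": fitted_roc.ci95[1],
            "cutoff": prob_cutoff,
            "sensitivity": fitted_roc.sensitivity,
            "specificity": fitted_roc.specificity,
        }
    )
    return {
        "table": pd.DataFrame(rows),
        "model": model,
        "nagelkerke_r2": nagelkerke_r2(model),
        "omnibus": {"chi2": chi2, "df": dof, "p": p_omnibus},
        "hosmer_lemeshow": {"chi2": hl_chi2, "df": hl_df, "p": hl_p},
        "fitted_youden_cutoff": fitted_roc.optimal_cutoff,
        "misclassified_at_cutoff": combined_misclassified(model, cohort, prob_cutoff),
        "misclassified_at_half": combined_misclassified(model, cohort, 0.5),
    }


def normality_screen(cohort: CohortTable) -> pd.DataFrame:
    """Shapiro-Wilk W/p of each APTw statistic over the glioma subjects."""
    df = cohort.df[cohort.df["group"].isin(("HGG", "LGG"))]
    rows = []
    for metric in _DESCRIPTIVE_METRICS:
        w, p = shapiro_wilk(df[METRIC_COLUMNS[metric]])
        rows.append({"metric": metric, "w": w, "p": p})
    return pd.DataFrame(rows)


def cohort_statistics(
    cohort: CohortTable,
    rules: tuple = (ThresholdRule("mean", 2.0), ThresholdRule("max", 2.48)),
    prob_cutoff: float = DEFAULT_PROB_CUTOFF,
) -> dict:
    """The full statistical battery on an already-final cohort."""
    audits = {f"{r.metric}>{r.cutoff}": classify_cohort(cohort, r) for r in rules}
    out = {
        "descriptives": group_descriptives(cohort),
        "mann_whitney": mann_whitney_table(cohort),
        "normality": normality_screen(cohort),
        "roc": roc_table(cohort, prob_cutoff=prob_cutoff),
        "threshold_audits": audits,
        "reassigned_suspected_lgg": {
            name: reassigned_suspected_lgg(a) for name, a in audits.items()
        },
    }
    df = cohort.df
    if "mgmt_status" in df.columns and (df["mgmt_status"] != "unknown").any():
        out["subgroup_mgmt"] = subgroup_means(cohort, "mgmt", "mean")
    if "idh_status" in df.columns and (df["idh_status"] != "unknown").any():
        out["subgroup_idh"] = subgroup_means(cohort, "idh", "mean")
    return out


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-away-from-zero at display precision (so 2.595
    prints as 2.60, matching the usual clinical-table convention rather
    than binary round-half-even).

    The value is first snapped to 8 decimals to absorb binary float error
    (e.g. a mean of two-decimal inputs stored as 2.5949999999999998).
    """
    snapped = Decimal(str(x)).quantize(Decimal("1e-8"))
    q = Decimal(1).scaleb(-ndigits)
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x, nd):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return f"{round_half_up(float(x), nd):.{nd}f}"


def render_tables(results: dict) -> str:
    """Human-readable replicas of the descriptive, U-test, and ROC tables."""
    lines = []
    lines.append("APTw signal descriptives by group (percent)")
    lines.append(f"{'metric':<8}{'group':<6}{'n':>3}{'Average':>9}{'Min':>7}{'Max':>7}")
    for _, r in results["descriptives"].iterrows():
        lines.append(
            f"{r['metric']:<8}{r['group']:<6}{r['n']:>3}"
            f"{_fmt(r['average'], 2):>9}{_fmt(r['minimum'], 2):>7}{_fmt(r['maximum'], 2):>7}"
        )
    lines.append("")
    lines.append("Mann-Whitney U, HGG vs LGG")
    lines.append(f"{'metric':<8}{'U':>6}{'p(exact)':>10}{'p(asym)':>10}")
    for _, r in results["mann_whitney"].iterrows():
        lines.append(
            f"{r['metric']:<8}{r['u']:>6.1f}{_fmt(r['p_exact'], 3):>10}"
            f"{_fmt(r['p_asymptotic'], 3):>10}"
        )
    lines.append("")
    lines.append("ROC analysis, HGG vs LGG")
    lines.append(
        f"{'metric':<10}{'AUC':>6}{'95% CI':>16}{'Cutoff':>8}{'Sens%':>7}{'Spec%':>7}"
    )
    for _, r in results["roc"]["table"].iterrows():
        ci = f"{r['ci_low']:.3f}-{r['ci_high']:.3f}"
        lines.append(
            f"{r['metric']:<10}{r['auc']:>6.3f}{ci:>16}{r['cutoff']:>8.2f}"
            f"{100 * r['sensitivity']:>7.1f}{100 * r['specificity']:>7.1f}"
        )
    roc = results["roc"]
    lines.append(
        f"Combined model: Nagelkerke R2 {roc['nagelkerke_r2']:.3f}, "
        f"omnibus p {roc['omnibus']['p']:.4g}, "
        f"Hosmer-Lemeshow p {roc['hosmer_lemeshow']['p']:.3f}"
    )
    lines.append(
        "Misclassified at cutoff "
        f"{results['roc']['table'].iloc[-1]['cutoff']:.2f}: "
        f"{roc['misclassified_at_cutoff']}; at 0.50: {roc['misclassified_at_half']}"
    )
    for name, audit in results["threshold_audits"].items():
        sens = _fmt(None if audit.sensitivity is None else 100 * audit.sensitivity, 1)
        spec = _fmt(None if audit.specificity is None else 100 * audit.specificity, 1)
        lines.append(
            f"Rule {name}: {audit.n_correct}/{audit.n_total} correct "
            f"(sens {sens}%, spec {spec}%); "
            f"misclassified {audit.misclassified_ids()}"
        )
    for key, title in (("subgroup_mgmt", "MGMT"), ("subgroup_idh", "IDH")):
        if key in results:
            tab = results[key]
            cells = ", ".join(
                f"{idx}: n={int(r['n'])} mean={_fmt(r['mean'], 2)}"
                for idx, r in tab.iterrows()
            )
            lines.append(f"{title} strata (APTw mean %): {cells}")
    return "\n".join(lines) + "\n"


def summary_dict(results: dict) -> dict:
    """Full-precision JSON-serializable summary of ``cohort_statistics``."""
    roc = results["roc"]
    model = roc["model"]
    out = {
        "descriptives": results["descriptives"].to_dict(orient="records"),
        "mann_whitney": results["mann_whitney"].to_dict(orient="records"),
        "normality": results["normality"].to_dict(orient="records"),
        "roc": roc["table"].to_dict(orient="records"),
        "combined_model": {
            "intercept": model.intercept,
            "coefficients": {k: float(v) for k, v in model.coefficients.items()},
            "converged": model.converged,
            "n_iter": model.n_iter,
            "nagelkerke_r2": roc["nagelkerke_r2"],
            "omnibus": roc["omnibus"],
            "hosmer_lemeshow": roc["hosmer_lemeshow"],
            "misclassified_at_cutoff": [int(s) for s in roc["misclassified_at_cutoff"]],
            "misclassified_at_half": [int(s) for s in roc["misclassified_at_half"]],
        },
        "threshold_audits": {
            name: {
                "n_correct": a.n_correct,
                "n_total": a.n_total,
                "sensitivity": a.sensitivity,
                "specificity": a.specificity,
                "misclassified": [int(s) for s in a.misclassified_ids()],
            }
            for name, a in results["threshold_audits"].items()
        },
        "reassigned_suspected_lgg": {
            k: [int(s) for s in v] for k, v in results["reassigned_suspected_lgg"].items()
        },
    }
    for key in ("subgroup_mgmt", "subgroup_idh"):
        if key in results:
            out[key] = results[key].reset_index().to_dict(orient="records")
    return out
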