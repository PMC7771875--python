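"""Cohort assembly (exclusion rules) and glioma grade prediction.

Grade is predicted either by a fixed threshold on one APTw statistic
(strictly greater than the cutoff means high grade) or by a combined
logistic regression on mean, max, and range.  Metastases pass through
threshold rules for reporting but never enter sensitivity/specificity,
which are defined over histological HGG vs LGG only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .stats import LogisticModel, logistic_fit

#: Predictor-name -> cohort-column mapping for threshold rules and models.
METRIC_COLUMNS = {
    "mean": "aptw_mean",
    "max": "aptw_max",
    "min": "aptw_min",
    "range": "aptw_range",
}

#: Default probability cutoff of the combined model (the ROC-derived
#: probabilistic operating point; see docs/methods.md for its caveats).
DEFAULT_PROB_CUTOFF = 0.38

#: Smallest group size retained for statistical analysis.
MIN_GROUP_SIZE = 4


@dataclass(frozen=True)
class ThresholdRule:
    """Classify HGG when ``metric`` is strictly greater than ``cutoff`` (%).

    Boundary equality is deliberately low grade: the rules are quoted as
    "> cutoff".
    """

    metric: str
    cutoff: float

    def __post_init__(self):
        if self.metric not in METRIC_COLUMNS:
            raise ValueError(f"metric must be one of {sorted(METRIC_COLUMNS)}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @classmethod
    def parse(cls, text: str) -> "ThresholdRule":
        """Parse ``"metric:cutoff"``, e.g. ``"mean:2.0"``."""
        metric, _, cutoff = text.partition(":")
        return cls(metric=metric.strip(), cutoff=float(cutoff))


def apply_exclusions(
    cohort: CohortTable, *, min_group_size: int = MIN_GROUP_SIZE
) -> CohortTable:
    """Drop subjects flagged for exclusion and groups below the minimum size.

    Flagged subjects (radiological progression after histological sampling)
    go first; any group then smaller than ``min_group_size`` (e.g. an n = 2
    metastasis group) is removed entirely.  Reasons are recorded in the
    returned table's ``exclusion_log``.  Idempotent.
    """
    df = cohort.df
    log = []
    for _, row in df[df["excluded"]].iterrows():
        reason = row.get("exclusion_reason", "") or "flagged for exclusion"
        log.append({"subject_id": row["subject_id"], "reason": reason})
    kept = df[~df["excluded"]]
    sizes = kept["group"].value_counts()
    for grp, size in sizes.items():
        if size < min_group_size:
            for sid in kept.loc[kept["group"] == grp, "subject_id"]:
                log.append(
                    {
                        "subject_id": sid,
                        "reason": f"group {grp} has n = {size} < {min_group_size}",
                    }
                )
            kept = kept[kept["group"] != grp]
    out = CohortTable(
        kept.reset_index(drop=True),
        provenance=cohort.provenance,
        exclusion_log=list(cohort.exclusion_log) + log,
    )
    return out


def threshold_classify(record, rule: ThresholdRule) -> tuple[str, bool]:
    """Predict the grade of one subject row; returns (predicted, correct).

    ``correct`` compares the prediction against the histological group,
    with metastases counted correct when predicted HGG-like is irrelevant —
    a MET row's correctness is judged against 'HGG' never matching, so the
    caller normally reports METs separately.
    """
    col = METRIC_COLUMNS[rule.metric]
    value = record[col] if isinstance(record, (dict, pd.Series)) else getattr(record, col)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"subject is missing metric {rule.metric!r}")
    predicted = "HGG" if value > rule.cutoff else "LGG"
    truth = record["group"] if isinstance(record, (dict, pd.Series)) else record.group
    return predicted, predicted == truth


@dataclass
class ClassificationAudit:
    """Per-subject audit and confusion summary of a threshold rule."""

    rule: ThresholdRule
    per_subject: pd.DataFrame
    n_correct: int
    n_total: int
    sensitivity: float | None
    specificity: float | None

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total

    def misclassified_ids(self) -> list:
        wrong = self.per_subject[~self.per_subject["correct"]]
        return list(wrong["subject_id"])


def classify_cohort(cohort: CohortTable, rule: ThresholdRule) -> ClassificationAudit:
    """Apply a threshold rule to every subject and tally the confusion.

    Sensitivity = correctly-called HGG / histological HGG; specificity the
    same for LGG.  An absent group leaves its rate None (missing, not 0).
    Metastasis rows receive predictions in the audit but are excluded from
    both rates and from the correct/total counts.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rows = []
    for _, rec in cohort.df.iterrows():
        predicted, correct = threshold_classify(rec, rule)
        rows.append(
            {
                "subject_id": rec["subject_id"],
                "group": rec["group"],
                "initial_dx": rec.get("initial_dx", ""),
                "value": rec[METRIC_COLUMNS[rule.metric]],
                "predicted": predicted,
                "correct": correct,
            }
        )
    per_subject = pd.DataFrame(rows)
    glioma = per_subject[per_subject["group"].isin(("HGG", "LGG"))]
    hgg = glioma[glioma["group"] == "HGG"]
    lgg = glioma[glioma["group"] == "LGG"]
    sens = float(hgg["correct"].mean()) if len(hgg) else None
    spec = float(lgg["correct"].mean()) if len(lgg) else None
    return ClassificationAudit(
        rule=rule,
        per_subject=per_subject,
        n_correct=int(glioma["correct"].sum()),
        n_total=len(glioma),
        sensitivity=sens,
        specificity=spec,
    )


def reassigned_suspected_lgg(audit: ClassificationAudit) -> list:
    """Subjects radiologically suspected LGG that the rule reassigns to HGG
    and whose histology confirms HGG."""
    df = audit.per_subject
    sel = (df["initial_dx"] == "LGG") & (df["predicted"] == "HGG") & (df["group"] == "HGG")
    return list(df.loc[sel, "subject_id"])


def fit_combined_model(
    cohort: CohortTable, predictors: tuple = ("mean", "max", "range")
) -> LogisticModel:
    """Fit the combined logistic model P(HGG) on the glioma subjects.

    Requires at least two subjects per class; metastases are dropped before
    fitting.  Non-convergence or separation is flagged by the fitter, never
    silent.
    """
    df = cohort.df[cohort.df["group"].isin(("HGG", "LGG"))]
    y = (df["group"] == "HGG").astype(float).to_numpy()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class to fit the model")
    cols = [METRIC_COLUMNS[p] for p in predictors]
    X = df[cols].to_numpy(dtype=float)
    model = logistic_fit(X, y, predictor_names=tuple(predictors))
    model.subject_ids = list(df["subject_id"])  # audit trail for predictions
    return model


def predict_combined(
    model: LogisticModel, record, prob_cutoff: float = DEFAULT_PROB_CUTOFF
) -> str:
    """Predict HGG when the fitted probability exceeds ``prob_cutoff``."""
    cols = [METRIC_COLUMNS[p] for p in model.predictor_names]
    if isinstance(record, (dict, pd.Series)):
        x = np.array([float(record[c]) for c in cols])
    else:
        x = np.asarray(record, dtype=float)
    p = float(model.predict_proba(x.reshape(1, -1))[0])
    return "HGG" if p > prob_cutoff else "LGG"


def combined_misclassified(
    model: LogisticModel, cohort: CohortTable, prob_cutoff: float
) -> list:
    """Subject ids whose combined-model call at ``prob_cutoff`` contradicts
    histology (glioma subjects only)."""
    df = cohort.df[cohort.df["group"].isin(("HGG", "LGG"))]
    wrong = []
    for _, rec in df.iterrows():
        if predict_combined(model, rec, prob_cutoff) != rec["group"]:
            wrong.append(rec["subject_id"])
    return wrong
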