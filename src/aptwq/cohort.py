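"""Subject-level cohort tables: the packaged reference cohort and a seeded
cohort simulator.

A cohort table holds one row per subject with histology, molecular status,
and the per-subject APTw ROI statistics (mean / max / min, in percent of
S0).  The within-subject range is defined as max - min and is always
derived, never stored.  The packaged reference cohort is a 26-subject
glioma/metastasis series (16 high-grade glioma, 6 low-grade glioma after
exclusions) shipped as CSV inside the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import PhantomSpecError

#: Columns every cohort table must carry.
REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "aptw_mean",
    "aptw_max",
    "aptw_min",
    "excluded",
)

GROUPS = ("LGG", "HGG", "MET")


def _group_from_grade(grade) -> str:
    """WHO grade 2 -> LGG; grades 3-4 -> HGG; no grade -> MET."""
    if pd.isna(grade):
        return "MET"
    return "LGG" if int(grade) == 2 else "HGG"


@dataclass
class CohortTable:
    """A validated subject table plus its provenance (fixture | simulated)."""

    df: pd.DataFrame
    provenance: str = "fixture"
    exclusion_log: list = field(default_factory=list)

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        df["excluded"] = df["excluded"].astype(bool)
        if df["subject_id"].duplicated().any():
            raise ValueError("subject ids must be unique")
        bad = df[~(
            (df["aptw_min"] <= df["aptw_mean"] + 1e-9)
            & (df["aptw_mean"] <= df["aptw_max"] + 1e-9)
        )]
        if len(bad):
            raise ValueError(
                f"min <= mean <= max violated for subjects {list(bad['subject_id'])}"
            )
        unknown_groups = set(df["group"]) - set(GROUPS)
        if unknown_groups:
            raise ValueError(f"unknown groups: {sorted(unknown_groups)}")
        df["aptw_range"] = df["aptw_max"] - df["aptw_min"]
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def group_sizes(self) -> dict:
        return self.df["group"].value_counts().to_dict()

    def subset(self, mask) -> "CohortTable":
        return CohortTable(
            self.df[mask].reset_index(drop=True),
            provenance=self.provenance,
            exclusion_log=list(self.exclusion_log),
        )

    def to_csv(self, path) -> None:
        self.df.drop(columns=["aptw_range"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "file") -> "CohortTable":
        df = pd.read_csv(path)
        if "excluded" not in df.columns:
            df["excluded"] = False
        df["excluded"] = df["excluded"].fillna(False).astype(bool)
        return cls(df, provenance=provenance)


def load_table1_fixture() -> CohortTable:
    """Load the packaged 26-subject reference cohort.

    Subjects flagged for exclusion: two LGG with radiological progression
    after histological sampling, and the two metastases (group too small for
    statistical analysis).  The within-subject range column is derived as
    max - min on load.
    """
    with resources.files("aptwq.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["excluded"] = df["excluded"].astype(bool)
    df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    df["who_grade"] = df["who_grade"].astype("Int64")
    assert (df["group"] == df["who_grade"].map(_group_from_grade)).all()
    return CohortTable(df, provenance="fixture")


@dataclass(frozen=True)
class CohortSimParams:
    """Generative parameters of the cohort simulator.

    Per-group sizes and (mu, sd) pairs — in percent — for the subject-level
    APTw mean, max, and min; defaults are the reference cohort's group
    statistics.  ``correlation`` is the common correlation between the three
    statistics within a subject (they are strongly concordant in practice).
    """

    group_sizes: dict = field(
        default_factory=lambda: {"HGG": 16, "LGG": 6, "MET": 2}
    )
    group_params: dict = field(
        default_factory=lambda: {
            "HGG": {"mean": (2.60, 0.97), "max": (3.23, 1.00), "min": (1.81, 0.91)},
            "LGG": {"mean": (1.49, 0.50), "max": (1.95, 0.39), "min": (1.01, 0.69)},
            "MET": {"mean": (2.49, 0.33), "max": (2.98, 0.30), "min": (1.76, 0.64)},
        }
    )
    correlation: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must lie in [0, 1)")


_MAX_DRAWS = 1000


def simulate_cohort_table(params: CohortSimParams) -> CohortTable:
    """Draw a synthetic cohort honouring min <= mean <= max per subject.

    Each subject's (mean, max, min) triple is drawn from a correlated
    trivariate normal (rejection-sampled until ordered, so effectively a
    truncated normal on the ordered region).  Deterministic under the seed.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    sid = 1
    for grp in ("HGG", "LGG", "MET"):
        n = params.group_sizes.get(grp, 0)
        if n == 0:
            continue
        p = params.group_params[grp]
        mu = np.array([p["mean"][0], p["max"][0], p["min"][0]])
        sd = np.array([p["mean"][1], p["max"][1], p["min"][1]])
        cov = np.outer(sd, sd) * (
            params.correlation * np.ones((3, 3)) + (1 - params.correlation) * np.eye(3)
        )
        if np.all(sd == 0) and not (mu[2] <= mu[0] <= mu[1]):
            raise PhantomSpecError(
                f"infeasible parameters for {grp}: degenerate means are unordered"
            )
        if np.any(sd > 0):
            # eigen factor instead of Cholesky: tolerates zero-variance metrics
            evals, evecs = np.linalg.eigh(cov)
            factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
        else:
            factor = np.zeros((3, 3))
        for _ in range(n):
            for attempt in range(_MAX_DRAWS):
                m, mx, mn = mu + factor @ rng.standard_normal(3)
                if mn <= m <= mx:
                    break
            else:
                raise PhantomSpecError(
                    f"could not draw an ordered (min, mean, max) triple for {grp}"
                )
            rows.append(
                {
                    "subject_id": sid,
                    "sex": "M" if rng.random() < 18 / 22 else "F",
                    "age": int(rng.integers(26, 77)),
                    "histology": {"HGG": "Glioblastoma", "LGG": "Diffuse astrocytoma",
                                  "MET": "Metastasis"}[grp],
                    "who_grade": {"HGG": 4, "LGG": 2, "MET": pd.NA}[grp],
                    "group": grp,
                    "initial_dx": grp,
                    "idh_status": "unknown",
                    "mgmt_status": "unknown",
                    "aptw_mean": float(m),
                    "aptw_max": float(mx),
                    "aptw_min": float(mn),
                    "excluded": False,
                    "exclusion_reason": "",
                }
            )
            sid += 1
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "sex", "age", "histology", "who_grade", "group",
            "initial_dx", "idh_status", "mgmt_status",
            "aptw_mean", "aptw_max", "aptw_min", "excluded", "exclusion_reason",
        ],
    )
    return CohortTable(df, provenance="simulated")
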