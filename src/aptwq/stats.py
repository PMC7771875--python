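"""Nonparametric, ROC, and logistic-regression machinery for two-group
biomarker evaluation.

Conventions follow common clinical-statistics practice:

* Mann-Whitney U uses midranks for ties and reports the U of the side with
  the smaller rank sum; the exact two-sided p-value is computed from the
  permutation null distribution of U whenever ``n1 * n2`` is small enough,
  alongside the tie-corrected normal approximation.
* The empirical ROC takes the trapezoidal AUC (equal to the concordance
  probability with half credit for ties) and selects the operating point
  maximizing Youden's J = sensitivity + specificity - 1; the reported
  cutoff is the midpoint between the two adjacent distinct observed scores,
  with J-ties broken toward higher specificity.  The AUC confidence
  interval uses DeLong's variance estimate.
* Logistic regression is fitted by Newton-Raphson maximum likelihood with
  goodness-of-fit diagnostics (likelihood-ratio omnibus test, Nagelkerke
  R^2, Hosmer-Lemeshow calibration over tied-preserving probability bins).
"""

from __future__ import annotations

import functools
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SeparationError

# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

#: Largest n1*n2 for which the exact permutation p-value is computed.
EXACT_LIMIT = 100_000


@dataclass(frozen=True)
class MannWhitneyResult:
    """Two-sided Mann-Whitney comparison of two independent samples."""

    u_statistic: float  # U from the smaller rank-sum side
    u_a: float  # U based on group a's rank sum
    n_a: int
    n_b: int
    mean_rank_a: float
    mean_rank_b: float
    p_asymptotic: float
    p_exact: float | None = None

    @property
    def p_value(self) -> float:
        """Exact p when available, else the tie-corrected normal p."""
        return self.p_exact if self.p_exact is not None else self.p_asymptotic


@functools.lru_cache(maxsize=64)
def _exact_u_counts(n1: int, n2: int) -> tuple:
    """Counts of rank-sum values for choosing ``n1`` of ranks 1..n1+n2
    (tie-free null distribution), by dynamic programming."""
    N = n1 + n2
    max_sum = n1 * N
    table = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            table[k, r:] += table[k - 1, :-r]
    return tuple(table[n1])


def _exact_p_tiefree(n1: int, n2: int, u_min: float) -> float:
    counts = np.asarray(_exact_u_counts(n1, n2))
    # rank sums run from n1(n1+1)/2 upward; U = R - n1(n1+1)/2
    base = n1 * (n1 + 1) // 2
    u_values = np.arange(counts.size) - base
    total = counts.sum()
    p_low = counts[u_values <= u_min + 1e-9].sum() / total
    return min(1.0, 2.0 * p_low)


def _exact_p_enumeration(ranks: np.ndarray, n_small: int, u_min: float) -> float:
    """Exact two-sided p by full enumeration over assignments (handles ties)."""
    N = ranks.size
    base = n_small * (n_small + 1) / 2.0
    n_other = N - n_small
    max_u = n_small * n_other
    count_le = 0
    total = 0
    for combo in itertools.combinations(range(N), n_small):
        u = ranks[list(combo)].sum() - base
        u = min(u, max_u - u)  # smaller-side U of this assignment
        total += 1
        if u <= u_min + 1e-9:
            count_le += 1
    # counting smaller-side U already folds both tails together
    return min(1.0, count_le / total)


def mann_whitney(group_a, group_b, *, continuity: bool = False) -> MannWhitneyResult:
    """Mann-Whitney U test with midranks for ties.

    ``u_statistic`` is the U of the side with the smaller rank sum.  The
    asymptotic p-value is the tie-corrected normal approximation, by default
    without continuity correction (the convention of the major clinical
    statistics packages); ``continuity=True`` applies the 0.5 correction,
    which tracks the exact p much more closely at small n.  The exact
    p-value is computed from the permutation null whenever
    ``n_a * n_b <= EXACT_LIMIT``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one value")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    u_min = min(u_a, u_b)

    # tie-corrected normal approximation
    N = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)) if N > 1 else 0.0
    var = n_a * n_b / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        p_asym = 1.0
    else:
        dev = abs(u_a - n_a * n_b / 2.0)
        if continuity:
            dev = max(dev - 0.5, 0.0)
        p_asym = min(1.0, 2.0 * sps.norm.sf(dev / np.sqrt(var)))

    p_exact = None
    if n_a * n_b <= EXACT_LIMIT:
        n1 = min(n_a, n_b)
        if tie_counts.size == N:  # no ties: closed-form null distribution
            p_exact = _exact_p_tiefree(n1, max(n_a, n_b), u_min)
        else:
            p_exact = _exact_p_enumeration(ranks, n1, u_min)

    return MannWhitneyResult(
        u_statistic=float(u_min),
        u_a=float(u_a),
        n_a=n_a,
        n_b=n_b,
        mean_rank_a=float(ranks[:n_a].mean()),
        mean_rank_b=float(ranks[n_a:].mean()),
        p_asymptotic=float(p_asym),
        p_exact=None if p_exact is None else float(p_exact),
    )


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC of a score against a binary label."""

    auc: float
    ci95: tuple
    ci_method: str
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    coordinates: pd.DataFrame = field(repr=False, compare=False, default=None)


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple:
    """DeLong 95% CI for the AUC via placement values."""
    m, n = pos.size, neg.size
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(0.975)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_curve(scores, labels, positive="HGG") -> RocResult:
    """Empirical ROC with the Youden-midpoint optimal operating point.

    ``labels`` may be booleans, 0/1, or group strings compared against
    ``positive``.  A subject is called positive at threshold t when
    score > t (strictly).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([lab == positive if isinstance(lab, str) else bool(lab) for lab in labels])
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pos, neg = scores[y], scores[~y]
    m, n = pos.size, neg.size

    # concordance-form AUC (half credit for cross-group ties)
    ranks = sps.rankdata(scores)
    auc = (ranks[y].sum() - m * (m + 1) / 2.0) / (m * n)

    distinct = np.unique(scores)
    # interior candidate thresholds: midpoints of adjacent distinct scores,
    # framed by all-positive / all-negative extremes for the coordinate list
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    rows = []
    for t in thresholds:
        sens = np.mean(pos > t)
        spec = np.mean(neg <= t)
        rows.append((t, sens, spec, sens + spec - 1.0))
    coords = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "youden"])

    interior = coords.iloc[1:-1] if len(coords) > 2 else coords
    best_j = interior["youden"].max()
    ties = interior[np.isclose(interior["youden"], best_j)]
    # break ties toward higher specificity (i.e. the higher threshold)
    best = ties.sort_values(["specificity", "threshold"]).iloc[-1]

    return RocResult(
        auc=float(auc),
        ci95=_delong_ci(pos, neg, float(auc)),
        ci_method="delong",
        optimal_cutoff=float(best["threshold"]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        youden=float(best["youden"]),
        coordinates=coords,
    )


# --------------------------------------------------------------------------
# Logistic regression
# --------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """A fitted binary logistic regression (intercept first in ``params``)."""

    params: np.ndarray
    predictor_names: tuple
    fitted: np.ndarray
    outcome: np.ndarray
    llf: float
    llnull: float
    converged: bool
    n_iter: int
    separation: bool
    n: int

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> dict:
        return dict(zip(self.predictor_names, self.params[1:]))

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = self.params[0] + X @ self.params[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def logistic_fit(
    X,
    y,
    predictor_names: tuple | None = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticModel:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    Convergence on the log-likelihood change (default 1e-8, at most 25
    iterations, with step halving).  Complete separation is detected via
    diverging linear predictors and flagged (``separation=True`` plus a
    warning), never silently; a singular design raises
    :class:`SeparationError`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X row count must match y length")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    n, k = X.shape
    if predictor_names is None:
        predictor_names = tuple(f"x{i + 1}" for i in range(k))
    design = np.column_stack([np.ones(n), X])

    beta = np.zeros(k + 1)
    ll = _log_likelihood(y, np.full(n, 0.5))
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = design.T @ (y - p)
        hess = (design * w[:, None]).T @ design
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix: degenerate or collinear design"
            ) from None
        # step-halving line search on the log-likelihood
        scale = 1.0
        for _ in range(30):
            trial = beta + scale * step
            ll_new = _log_likelihood(y, 1.0 / (1.0 + np.exp(-design @ trial)))
            if ll_new >= ll - 1e-14:
                break
            scale /= 2.0
        beta = beta + scale * step
        d_ll = ll_new - ll
        ll = ll_new
        if np.max(np.abs(design @ beta)) > 30.0:
            separation = True
        if abs(d_ll) < tol:
            converged = True
            break
    fitted = 1.0 / (1.0 + np.exp(-(design @ beta)))
    # complete separation: every fitted probability collapsed onto 0 or 1
    if np.min(np.maximum(fitted, 1.0 - fitted)) > 1.0 - 1e-6:
        separation = True
    if separation:
        warnings.warn(
            "logistic fit shows diverging linear predictors (possible complete "
            "separation); coefficients are unreliable",
            stacklevel=2,
        )
    if not converged:
        warnings.warn(
            f"logistic fit did not converge in {max_iter} Newton iterations",
            stacklevel=2,
        )
    p = fitted
    p_bar = y.mean()
    llnull = _log_likelihood(y, np.full(n, p_bar))
    return LogisticModel(
        params=beta,
        predictor_names=tuple(predictor_names),
        fitted=p,
        outcome=y,
        llf=ll,
        llnull=llnull,
        converged=converged,
        n_iter=it,
        separation=separation,
        n=n,
    )


def nagelkerke_r2(model: LogisticModel) -> float:
    """Nagelkerke's rescaled R^2: Cox-Snell divided by its maximum."""
    n = model.n
    cox_snell = 1.0 - np.exp(2.0 * (model.llnull - model.llf) / n)
    max_attainable = 1.0 - np.exp(2.0 * model.llnull / n)
    return float(cox_snell / max_attainable) if max_attainable > 0 else 0.0


def omnibus_test(model: LogisticModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of the model against the intercept-only null:
    (chi2, df, p)."""
    chi2 = 2.0 * (model.llf - model.llnull)
    df = len(model.predictor_names)
    return float(chi2), df, float(sps.chi2.sf(chi2, df))


def hosmer_lemeshow(model: LogisticModel, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration test over fitted-probability bins.

    Bins are deciles of the fitted probabilities with ties kept together;
    if fewer distinct probabilities than requested groups exist, the group
    count is reduced with a warning.  Returns (chi2, df, p).
    """
    y = model.outcome
    p = model.fitted
    try:
        bins = pd.qcut(p, groups, duplicates="drop")
    except ValueError:
        bins = pd.qcut(p, min(groups, len(np.unique(p))), duplicates="drop")
    g = bins.categories.size
    if g < groups:
        warnings.warn(
            f"Hosmer-Lemeshow groups reduced from {groups} to {g} (tied fitted "
            "probabilities)",
            stacklevel=2,
        )
    if g < 3:
        raise ValueError("too few distinct fitted probabilities for the test")
    dfm = pd.DataFrame({"y": y, "p": p, "bin": bins})
    chi2 = 0.0
    for _, sub in dfm.groupby("bin", observed=True):
        o1, e1 = sub["y"].sum(), sub["p"].sum()
        o0, e0 = len(sub) - o1, len(sub) - e1
        if e1 > 0:
            chi2 += (o1 - e1) ** 2 / e1
        if e0 > 0:
            chi2 += (o0 - e0) ** 2 / e0
    df = g - 2
    return float(chi2), df, float(sps.chi2.sf(chi2, df))


# --------------------------------------------------------------------------
# Normality screen and descriptive strata
# --------------------------------------------------------------------------


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's algorithm, 3 <= n <= 5000)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if v.size > 5000:
        raise ValueError("Shapiro-Wilk supports at most 5000 observations")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk W is undefined for a constant sample")
    w, p = sps.shapiro(v)
    return float(w), float(p)


_STRATIFIERS = {"mgmt": "mgmt_status", "idh": "idh_status"}
_STRATA = {
    "mgmt": ("methylated", "non-methylated"),
    "idh": ("wildtype", "mutant"),
}
_METRICS = {"mean": "aptw_mean", "max": "aptw_max", "min": "aptw_min", "range": "aptw_range"}

#: Minimum per-stratum size for hypothesis testing (below it, descriptive only).
MIN_TESTABLE_N = 4


def subgroup_means(cohort, stratifier: str, metric: str = "mean") -> pd.DataFrame:
    """Descriptive APTw statistics per molecular stratum (MGMT or IDH).

    Subjects with unknown status are dropped (the dropped count is in
    ``result.attrs['n_unknown_dropped']``); strata with fewer than
    ``MIN_TESTABLE_N`` subjects are flagged insufficient for testing.
    Empty strata report NaN, never zero.
    """
    if stratifier not in _STRATIFIERS:
        raise ValueError(f"stratifier must be one of {sorted(_STRATIFIERS)}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    df = cohort.df
    col, mcol = _STRATIFIERS[stratifier], _METRICS[metric]
    known = df[df[col].isin(_STRATA[stratifier])]
    n_dropped = len(df) - len(known)
    out = (
        known.groupby(col)[mcol]
        .agg(n="count", mean="mean", sd="std")
        .reindex(_STRATA[stratifier])
    )
    out["n"] = out["n"].fillna(0).astype(int)
    out["insufficient_for_testing"] = out["n"] < MIN_TESTABLE_N
    out.index.name = "stratum"
    out.attrs["n_unknown_dropped"] = n_dropped
    out.attrs["metric"] = metric
    return out
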