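"""Ordered-trend and correlation statistics for soil time-course data.

Implements the statistical layer used to judge whether degrader
populations and enzyme activities rise over incubation time, and whether
cross-soil quantities co-vary:

- Spearman rank correlation with mid-ranks for ties (exact permutation
  p-value at small n, t-approximation otherwise);
- Williams' step-down trend test against a time-0 control, using
  amalgamated (isotonic) treatment means;
- the Shirley-Williams' rank-based analogue;
- exact-enumeration two-sided Mann-Whitney U for small samples;
- a one-sample Kolmogorov-Smirnov normality check (Lilliefors-corrected
  by default, since the normal's moments are estimated from the data).

Williams-type reference values are not transcribed from printed tables;
they are (1 - alpha) quantiles of the statistic's null distribution
obtained by seeded Monte-Carlo simulation and cached per design
(group-size vector, alpha).  The one-stage case collapses to an ordinary
one-sided pooled-t comparison, which pins the machinery to the exact
Student-t quantile.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "OrderedGroups",
    "StageResult",
    "TrendTestResult",
    "CorrelationResult",
    "UTestResult",
    "spearman",
    "pava_isotonic",
    "williams_test",
    "shirley_williams_test",
    "mann_whitney_u",
    "ks_normality",
]

DEFAULT_NULL_REPS = 50_000
DEFAULT_NULL_SEED = 186_282  # fixed so cached reference values are reproducible


# ---------------------------------------------------------------------------
# result containers


@dataclass
class OrderedGroups:
    """A control group plus treatment groups ordered by dose/time."""

    control: np.ndarray
    groups: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.groups = [(str(lbl), np.asarray(v, dtype=float)) for lbl, v in self.groups]
        if len(self.groups) < 1:
            raise ValueError("need at least one group beyond the control")
        if self.control.size == 0 or any(v.size == 0 for _, v in self.groups):
            raise ValueError("every group must be non-empty")

    @property
    def n_vector(self) -> tuple[int, ...]:
        return (self.control.size, *(v.size for _, v in self.groups))

    @property
    def k(self) -> int:
        return len(self.groups)


@dataclass
class StageResult:
    label: str
    statistic: float
    critical_value: float
    reject: bool


@dataclass
class TrendTestResult:
    """Step-down trend-test outcome; stages run from the top dose downward."""

    method: str
    direction: str
    alpha: float
    stages: list[StageResult] = field(default_factory=list)
    seed: int | None = None
    n_null_reps: int | None = None

    @property
    def rejected_labels(self) -> list[str]:
        return [s.label for s in self.stages if s.reject]

    def __post_init__(self) -> None:
        # step-down contract: rejections are a contiguous prefix of the
        # stage list (i.e. a suffix of the dose ordering)
        seen_accept = False
        for s in self.stages:
            if s.reject and seen_accept:
                raise AssertionError("non-contiguous step-down rejections")
            if not s.reject:
                seen_accept = True


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    p_method: str = "t-approximation"


@dataclass
class UTestResult:
    u_statistic: float
    p_value: float
    method: str
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# Spearman


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x: Sequence[float], y: Sequence[float], exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the two rank vectors.  The two-sided
    p-value is computed by full permutation enumeration for n <= 9 and by
    the t-approximation t = rho*sqrt((n-2)/(1-rho^2)) otherwise.  A
    constant input vector leaves rho undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("Spearman correlation needs n >= 4")
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, "undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # permute one rank vector; rho is monotone in sum(rx_perm * ry)
        perms = np.array(list(itertools.permutations(rx)))
        rx_c = perms - rx.mean()
        ry_c = ry - ry.mean()
        rhos = (rx_c @ ry_c) / np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, p, n, "exact-permutation")
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n, "t-approximation")
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, p, n, "t-approximation")


# ---------------------------------------------------------------------------
# PAVA isotonic amalgamation


def pava_isotonic(
    means: Sequence[float],
    weights: Sequence[float] | None = None,
    direction: str = "increase",
) -> np.ndarray:
    """Weighted pool-adjacent-violators amalgamation.

    Returns the monotone (non-decreasing for ``direction="increase"``)
    vector minimising the weighted squared distance to ``means``; adjacent
    violating blocks are pooled into their weighted mean, so the weighted
    grand mean is preserved.
    """
    m = np.asarray(means, dtype=float)
    w = np.ones_like(m) if weights is None else np.asarray(weights, dtype=float)
    if m.shape != w.shape:
        raise ValueError("means and weights must have equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    sign = 1.0 if direction == "increase" else -1.0
    vals = list(sign * m)
    wts = list(w)
    counts = [1] * len(vals)  # block lengths
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 0.0:  # violation: pool the two blocks
            tw = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tw
            wts[i] = tw
            counts[i] += counts[i + 1]
            del vals[i + 1], wts[i + 1], counts[i + 1]
            i = max(i - 1, 0)  # pooling may create an upstream violation
        else:
            i += 1
    out = np.repeat(vals, counts)
    return sign * out


# ---------------------------------------------------------------------------
# Monte-Carlo null reference values (Williams-type)

_CRITVAL_CACHE: dict[tuple, np.ndarray] = {}


def _williams_stage_stats(X: np.ndarray, n_vec: Sequence[int]) -> np.ndarray:
    """Stage statistics t-bar_i (i = 1..k) for a batch of datasets.

    ``X`` is (reps, N) with columns ordered control then groups 1..k.
    The pooled variance uses every group; the stage-i amalgamated top
    mean is max over u of the weighted mean of group means u..i (the
    closed form of the PAVA fitted value at the top position).
    """
    n_vec = np.asarray(n_vec)
    k = len(n_vec) - 1
    N = int(n_vec.sum())
    edges = np.concatenate([[0], np.cumsum(n_vec)])
    means = np.stack(
        [X[:, edges[j] : edges[j + 1]].mean(axis=1) for j in range(k + 1)], axis=1
    )
    ss = sum(
        ((X[:, edges[j] : edges[j + 1]] - means[:, [j]]) ** 2).sum(axis=1)
        for j in range(k + 1)
    )
    s2 = ss / (N - (k + 1))
    out = np.empty((X.shape[0], k))
    for i in range(1, k + 1):
        # M-hat_i = max_u mean(groups u..i), weights n_j
        best = None
        for u in range(1, i + 1):
            wsum = n_vec[u : i + 1].sum()
            avg = (means[:, u : i + 1] * n_vec[u : i + 1]).sum(axis=1) / wsum
            best = avg if best is None else np.maximum(best, avg)
        denom = np.sqrt(s2 * (1.0 / n_vec[i] + 1.0 / n_vec[0]))
        out[:, i - 1] = (best - means[:, 0]) / denom
    return out


def _shirley_stage_stats(X: np.ndarray, n_vec: Sequence[int]) -> np.ndarray:
    """Rank-based stage statistics for a batch of (continuous) datasets."""
    n_vec = np.asarray(n_vec)
    k = len(n_vec) - 1
    edges = np.concatenate([[0], np.cumsum(n_vec)])
    reps = X.shape[0]
    out = np.empty((reps, k))
    for i in range(1, k + 1):
        Ni = int(edges[i + 1])
        R = sps.rankdata(X[:, :Ni], axis=1)
        rmeans = np.stack(
            [R[:, edges[j] : edges[j + 1]].mean(axis=1) for j in range(i + 1)], axis=1
        )
        V = Ni * (Ni + 1) / 12.0  # no ties in the simulated continuous null
        best = None
        for u in range(1, i + 1):
            wsum = n_vec[u : i + 1].sum()
            avg = (rmeans[:, u : i + 1] * n_vec[u : i + 1]).sum(axis=1) / wsum
            best = avg if best is None else np.maximum(best, avg)
        denom = np.sqrt(V * (1.0 / n_vec[i] + 1.0 / n_vec[0]))
        out[:, i - 1] = (best - rmeans[:, 0]) / denom
    return out


def null_critical_values(
    method: str,
    n_vec: Sequence[int],
    alpha: float = 0.025,
    n_reps: int = DEFAULT_NULL_REPS,
    seed: int = DEFAULT_NULL_SEED,
) -> np.ndarray:
    """(1 - alpha) null quantiles of the stage statistics, by simulation.

    Returns one reference value per step-down stage i = 1..k.  Results
    are cached per (method, n-vector, alpha, reps, seed).
    """
    key = (method, tuple(int(n) for n in n_vec), float(alpha), int(n_reps), int(seed))
    if key not in _CRITVAL_CACHE:
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n_reps, int(np.sum(n_vec))))
        stats_fn = {"williams": _williams_stage_stats, "shirley_williams": _shirley_stage_stats}[method]
        tbar = stats_fn(X, n_vec)
        _CRITVAL_CACHE[key] = np.quantile(tbar, 1.0 - alpha, axis=0)
    return _CRITVAL_CACHE[key]


# ---------------------------------------------------------------------------
# Williams' and Shirley-Williams' step-down tests


def _as_ordered_groups(data) -> OrderedGroups:
    if isinstance(data, OrderedGroups):
        return data
    control, *rest = data
    return OrderedGroups(control=np.asarray(control, dtype=float),
                         groups=[(f"group{i + 1}", np.asarray(v, dtype=float))
                                 for i, v in enumerate(rest)])


def williams_test(
    data,
    direction: str = "increase",
    alpha: float = 0.025,
    n_null_reps: int = DEFAULT_NULL_REPS,
    seed: int = DEFAULT_NULL_SEED,
) -> TrendTestResult:
    """Williams' step-down trend test against the control.

    At stage i the treatment means of groups 1..i are amalgamated
    isotonically (weights = group sizes) and the top amalgamated mean is
    compared with the control mean on the pooled within-group standard
    error.  Testing starts at the highest dose and stops at the first
    non-rejection, so rejections form a contiguous suffix of the dose
    ordering.  One-tailed; default alpha 0.025.
    """
    g = _as_ordered_groups(data)
    if any(n < 2 for n in g.n_vector):
        raise ValueError("Williams' test needs >= 2 observations per group")
    sign = 1.0 if direction == "increase" else -1.0
    groups = [sign * g.control] + [sign * v for _, v in g.groups]
    labels = [lbl for lbl, _ in g.groups]
    n_vec = np.asarray(g.n_vector)
    k = g.k
    N = int(n_vec.sum())
    means = np.array([v.mean() for v in groups])
    ss = sum(float(((v - v.mean()) ** 2).sum()) for v in groups)
    s2 = ss / (N - (k + 1))
    crit = null_critical_values("williams", n_vec, alpha, n_null_reps, seed)
    stages: list[StageResult] = []
    go_on = True
    for i in range(k, 0, -1):
        amal = pava_isotonic(means[1 : i + 1], n_vec[1 : i + 1], "increase")
        m_hat = float(amal[-1])
        if s2 == 0.0:
            # degenerate: all observations are constants within groups
            tbar = math.inf if m_hat > means[0] else 0.0
            reject = go_on and m_hat > means[0]
        else:
            tbar = (m_hat - means[0]) / math.sqrt(s2 * (1 / n_vec[i] + 1 / n_vec[0]))
            reject = go_on and tbar > crit[i - 1]
        stages.append(StageResult(labels[i - 1], float(tbar), float(crit[i - 1]), reject))
        go_on = go_on and reject
    return TrendTestResult("williams", direction, alpha, stages, seed, n_null_reps)


def shirley_williams_test(
    data,
    direction: str = "increase",
    alpha: float = 0.025,
    n_null_reps: int = DEFAULT_NULL_REPS,
    seed: int = DEFAULT_NULL_SEED,
) -> TrendTestResult:
    """Shirley's nonparametric analogue of Williams' step-down test.

    At each stage the observations of the control and the groups still in
    play are re-ranked jointly (mid-ranks for ties), the treatment mean
    ranks are amalgamated isotonically, and the top amalgamated mean rank
    is compared with the control mean rank on a tie-corrected rank
    variance.  Being rank-based, the outcome is invariant to strictly
    monotone transformations of the data.
    """
    g = _as_ordered_groups(data)
    if any(n < 2 for n in g.n_vector):
        raise ValueError("Shirley-Williams' test needs >= 2 observations per group")
    sign = 1.0 if direction == "increase" else -1.0
    groups = [sign * g.control] + [sign * v for _, v in g.groups]
    labels = [lbl for lbl, _ in g.groups]
    n_vec = np.asarray(g.n_vector)
    k = g.k
    crit = null_critical_values("shirley_williams", n_vec, alpha, n_null_reps, seed)
    stages: list[StageResult] = []
    go_on = True
    for i in range(k, 0, -1):
        pool = np.concatenate(groups[: i + 1])
        Ni = pool.size
        R = _midranks(pool)
        edges = np.concatenate([[0], np.cumsum(n_vec[: i + 1])])
        rmeans = np.array([R[edges[j] : edges[j + 1]].mean() for j in range(i + 1)])
        # tie-corrected rank variance
        _, t_counts = np.unique(pool, return_counts=True)
        tie_term = float(((t_counts**3 - t_counts)).sum())
        V = (Ni * (Ni + 1) / 12.0) * (1.0 - tie_term / (Ni**3 - Ni)) if Ni > 1 else 0.0
        amal = pava_isotonic(rmeans[1:], n_vec[1 : i + 1], "increase")
        m_hat = float(amal[-1])
        if V == 0.0:
            tbar = math.inf if m_hat > rmeans[0] else 0.0
            reject = go_on and m_hat > rmeans[0]
        else:
            tbar = (m_hat - rmeans[0]) / math.sqrt(V * (1 / n_vec[i] + 1 / n_vec[0]))
            reject = go_on and tbar > crit[i - 1]
        stages.append(StageResult(labels[i - 1], float(tbar), float(crit[i - 1]), reject))
        go_on = go_on and reject
    return TrendTestResult("shirley_williams", direction, alpha, stages, seed, n_null_reps)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_from_samples(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a (pairs where a > b, ties count 1/2)."""
    pooled = np.concatenate([a, b])
    r = _midranks(pooled)
    ra = r[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 14
) -> UTestResult:
    """Two-sided Mann-Whitney U test.

    For n1 + n2 <= ``exact_max_n`` the p-value is exact: every
    C(n1+n2, n1) assignment of the pooled observations (mid-ranks under
    ties) is enumerated and the two-sided p is the probability of a U at
    least as far from its null mean n1*n2/2 as the observed one.  Larger
    samples use the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u_obs = _u_from_samples(a, b)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        r = _midranks(pooled)
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = r[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return UTestResult(u_obs, hits / total, "exact", n1, n2)
    # normal approximation with tie correction and continuity correction
    pooled = np.concatenate([a, b])
    N = n1 + n2
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float((t_counts**3 - t_counts).sum())
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var == 0:
        return UTestResult(u_obs, 1.0, "normal-approximation", n1, n2)
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, float(2 * sps.norm.sf(max(z, 0.0))))
    return UTestResult(u_obs, p, "normal-approximation", n1, n2)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov normality


def ks_normality(values: Sequence[float], lilliefors: bool = True) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated moments.

    Returns (statistic, p).  The default p-value is Lilliefors-corrected,
    which is the honest reference distribution when mean and SD come from
    the same data; ``lilliefors=False`` gives the plain KS p (known to be
    conservative in this setting).  Constant data is degenerate and is
    reported as decisively non-normal (p = 0).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("normality check needs n >= 5")
    if np.ptp(x) == 0:
        return float("nan"), 0.0
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm", pvalmethod="table")
        return float(stat), float(p)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(stat), float(p)
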