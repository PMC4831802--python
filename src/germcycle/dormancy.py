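"""Zone-level dormancy statistics.

A mitotic zone is *dormant* when none of its cells is progressing through the
cycle; operationally, dormant zones are those with no EdU-positive cell after
labeling.  Continuous-labeling time courses are modeled by a two-state
(dormant/active) Markov switch: with stationary dormant fraction pi_D and
dormant-to-active rate k_DA per hour, the probability a zone is still
unlabeled after t hours of continuous labeling is

    U(t) = pi_D * exp(-k_DA * t)

(a zone labels essentially the instant it becomes active, because with ~260
cells some are always in or about to enter S phase).  First-labeling times
are interval-censored — labeled by t or not — so group comparisons use a
Gehan-score permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GonadSample",
    "IntervalObs",
    "SwitchingFit",
    "CVResult",
    "classify_dormant",
    "expected_mphase_count",
    "labeling_curve",
    "fit_switching",
    "mitotic_index",
    "cv_with_bootstrap",
    "ic_rank_test",
    "bonferroni",
    "sister_arm_agreement",
    "dormancy_proportion_test",
]


@dataclass
class GonadSample:
    """One mitotic zone's per-cell measurements plus experiment metadata.

    ``cells`` is a DataFrame with columns dna_content (float), edu (bool/0-1)
    and ph3 (bool/0-1).  Exactly one of chase_h (pulse-chase) or label_h
    (continuous labeling) applies, per ``assay``.
    """

    worm_id: str
    arm: str
    condition: str
    assay: str  # "pulse_chase" | "continuous"
    cells: pd.DataFrame
    pulse_h: float = 0.0
    chase_h: float | None = None
    label_h: float | None = None
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ("L", "R"):
            raise ValueError("arm must be 'L' or 'R'")
        if self.assay not in ("pulse_chase", "continuous"):
            raise ValueError("assay must be 'pulse_chase' or 'continuous'")
        for t in (self.pulse_h, self.chase_h, self.label_h):
            if t is not None and t < 0:
                raise ValueError("times must be non-negative")
        if len(self.cells) == 0 and not self.flagged_empty:
            raise ValueError("empty cell table must be explicitly flagged")

    @property
    def gonad_id(self) -> str:
        return f"{self.worm_id}/{self.arm}"


@dataclass(frozen=True)
class IntervalObs:
    """Interval (left, right] known to contain a zone's first-labeling time.

    A continuous assay of duration t yields (0, t] if the zone labeled and
    (t, inf) if it did not.
    """

    left: float
    right: float

    def __post_init__(self) -> None:
        if not (0 <= self.left < self.right):
            raise ValueError("need 0 <= left < right")

    @classmethod
    def from_assay(cls, duration: float, labeled: bool) -> "IntervalObs":
        return cls(0.0, duration) if labeled else cls(duration, math.inf)


@dataclass(frozen=True)
class SwitchingFit:
    pi_d: float
    k_da: float
    objective: float  # negative log-likelihood at the optimum
    n: int
    boundary: bool = False  # degenerate data (all labeled / none labeled)

    def unlabeled_prob(self, t) -> np.ndarray:
        return self.pi_d * np.exp(-self.k_da * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class CVResult:
    cv: float
    ci_low: float
    ci_high: float
    level: float
    reps: int
    seed: int


def classify_dormant(g: GonadSample) -> bool:
    """Dormant iff no cell in the zone is EdU-positive."""
    if len(g.cells) == 0:
        raise ValueError("cannot classify a zone with no cells")
    return not bool(np.asarray(g.cells["edu"]).astype(bool).any())


def expected_mphase_count(n: int, f_m: float) -> float:
    """Expected number of M-phase cells in a randomly arrested zone: n * f_m.

    E.g. a ~260-cell zone with a 10% M fraction would show ~26 M-phase cells
    if its cells were merely paused at random positions — far more than ever
    observed, which is why zones lacking any S-phase label are interpreted as
    dormant rather than unluckily sampled.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= f_m <= 1.0:
        raise ValueError("f_m must lie in [0, 1]")
    return n * f_m


def labeling_curve(summary: pd.DataFrame, level: float = 0.83) -> pd.DataFrame:
    """Per-duration unlabeled fractions with two-sided binomial CIs.

    ``summary`` needs columns label_h and labeled (0/1).  The default 83%
    level follows the error-bar convention of the source figures.  Exact
    (Clopper-Pearson) intervals.
    """
    if len(summary) == 0:
        raise ValueError("no observations")
    rows = []
    for duration, grp in summary.groupby("label_h"):
        n = len(grp)
        if n == 0:
            raise ValueError(f"empty group at duration {duration}")
        n_unl = int(n - np.asarray(grp["labeled"]).astype(bool).sum())
        lo, hi = _binom_ci(n_unl, n, level)
        rows.append(
            {
                "label_h": float(duration),
                "n": n,
                "n_unlabeled": n_unl,
                "fraction_unlabeled": n_unl / n,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows).sort_values("label_h", ignore_index=True)


def _binom_ci(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def fit_switching(observations: list[IntervalObs]) -> SwitchingFit:
    """Maximum-likelihood (pi_D, k_DA) under U(t) = pi_D exp(-k_DA t).

    Each observation is a Bernoulli draw: unlabeled at its assay duration
    with probability U(t).  Degenerate datasets (all labeled everywhere, or
    none labeled anywhere) return boundary-flagged fits instead of failing.
    """
    if not observations:
        raise ValueError("no observations")
    unlabeled = np.array([math.isinf(o.right) for o in observations])
    t = np.array([o.left if math.isinf(o.right) else o.right for o in observations])
    n = len(observations)
    if not unlabeled.any():
        return SwitchingFit(0.0, 0.0, 0.0, n, boundary=True)
    if unlabeled.all():
        return SwitchingFit(1.0, 0.0, 0.0, n, boundary=True)

    def nll(theta):
        pi_d, k_da = theta
        u = np.clip(pi_d * np.exp(-k_da * t), 1e-12, 1.0 - 1e-12)
        return -(np.log(u)[unlabeled].sum() + np.log1p(-u)[~unlabeled].sum())

    # moment start: unlabeled fraction at the shortest duration approximates pi_D
    t0 = t.min()
    pi0 = float(np.clip(unlabeled[t == t0].mean(), 0.05, 0.95))
    best = None
    for k0 in (0.01, 0.1, 0.5, 2.0):
        res = optimize.minimize(
            nll, x0=[pi0, k0], method="L-BFGS-B", bounds=[(1e-6, 1.0), (0.0, None)]
        )
        if best is None or res.fun < best.fun:
            best = res
    pi_d, k_da = best.x
    return SwitchingFit(float(pi_d), float(k_da), float(best.fun), n)


def mitotic_index(g: GonadSample) -> float:
    """Fraction of the zone's cells that are PH3-positive (in M phase)."""
    if len(g.cells) == 0:
        raise ValueError("cannot compute an index over zero cells")
    ph3 = np.asarray(g.cells["ph3"]).astype(bool)
    return float(ph3.mean())


def cv_with_bootstrap(
    values, level: float = 0.95, reps: int = 2000, seed: int = 0
) -> CVResult:
    """Coefficient of variation (sample SD / mean) with a percentile bootstrap CI."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    cv = float(x.std(ddof=1) / mean)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(reps, x.size))
    samples = x[idx]
    means = samples.mean(axis=1)
    means[means == 0] = np.nan
    cvs = samples.std(axis=1, ddof=1) / means
    alpha = 1.0 - level
    lo, hi = np.nanpercentile(cvs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CVResult(cv, float(lo), float(hi), level, reps, seed)


def _gehan_scores(obs: list[IntervalObs]) -> tuple[np.ndarray, np.ndarray]:
    left = np.array([o.left for o in obs])
    right = np.array([o.right for o in obs])
    return left, right


def _score_matrix(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """s[i, j] = +1 if interval i is entirely after j, -1 if entirely before."""
    after = left[:, None] >= right[None, :]
    before = right[:, None] <= left[None, :]
    return after.astype(np.int8) - before.astype(np.int8)


def ic_rank_test(
    group_a: list[IntervalObs],
    group_b: list[IntervalObs],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Gehan-type two-sample rank test for interval-censored labeling times.

    U = sum over (i in A, j in B) of s(i, j) with s = +1 when interval i lies
    entirely after interval j, -1 when entirely before, 0 when they overlap.
    The two-sided p-value comes from the permutation distribution of the
    group labels (add-one estimator), so it is exact up to Monte-Carlo error
    and makes no asymptotic assumption.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if n_perm < 999:
        raise ValueError("n_perm must be at least 999")
    la, ra = _gehan_scores(group_a)
    lb, rb = _gehan_scores(group_b)
    left = np.concatenate([la, lb])
    right = np.concatenate([ra, rb])
    s = _score_matrix(left, right).astype(float)
    n_a = la.size
    n = left.size
    a0 = np.zeros(n)
    a0[:n_a] = 1.0
    u_obs = a0 @ s @ (1.0 - a0)
    rng = np.random.default_rng(seed)
    perms = np.tile(a0, (n_perm, 1))
    for row in perms:
        rng.shuffle(row)
    u_perm = np.sum((perms @ s) * (1.0 - perms), axis=1)
    p = (1.0 + np.sum(np.abs(u_perm) >= abs(u_obs) - 1e-12)) / (n_perm + 1.0)
    return float(u_obs), float(min(p, 1.0))


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) elementwise."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def sister_arm_agreement(
    pairs, n_perm: int = 1999, seed: int = 0
) -> tuple[float, float]:
    """Fraction of worms whose two gonadal arms share EdU status, with a
    permutation p-value against arm independence (second arms shuffled across
    worms, preserving the marginal rates)."""
    arr = np.asarray(list(pairs), dtype=bool)
    if arr.size == 0:
        raise ValueError("no pairs")
    a, b = arr[:, 0], arr[:, 1]
    agree = float(np.mean(a == b))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_b = rng.permutation(b)
        if np.mean(a == perm_b) >= agree - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return agree, float(p)


def dormancy_proportion_test(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 dormancy contingency table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
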