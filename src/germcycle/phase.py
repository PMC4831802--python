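"""Phase inference by circular Earth Mover's Distance template matching.

A zone's cycle progression since the EdU pulse is a position on the unit
circle (one revolution = one full cell cycle).  The observed EdU+/EdU-
DNA-content histogram pair is compared with each library template by a
circular EMD — circular because division wraps content from 2n back to 1n —
and the best-fitting template's phase is the estimate.  Cohorts of zones are
summarized on the circle by the mean phase and the resultant length R, with
the dispersion displayed as a wedge of width 1/R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .labeling import HistogramPair, TemplateLibrary

__all__ = [
    "PhaseEstimate",
    "PhaseSummary",
    "ProgressionFit",
    "circular_emd",
    "match_phase",
    "circular_summary",
    "initial_progression_rate",
    "average_cycling_rate",
]

WEDGE_R_CAP = 0.05
WEDGE_WIDTH_CAP = 20.0


@dataclass(frozen=True)
class PhaseEstimate:
    """Best-fit cycle phase for one zone; ``dormant`` flags zones with no
    EdU+ cells, for which the labeled-cohort phase is undefined."""

    gonad_id: str
    phase: float
    distance: float
    margin: float
    dormant: bool = False


@dataclass(frozen=True)
class PhaseSummary:
    mean_phase: float
    resultant: float
    wedge_width: float
    n: int


@dataclass(frozen=True)
class ProgressionFit:
    rate: float  # cycles per hour
    intercept: float  # cycle fraction at chase time 0
    window: tuple[float, float]  # hours of chase time used
    se: float


def circular_emd(h1, h2) -> float:
    """Exact 1-D Earth Mover's Distance between circular histograms, in bins.

    Ground distance between bins i and j is min(|i-j|, B-|i-j|).  Histograms
    are normalized to unit mass internally.  Computed by the
    cumulative-difference/median algorithm: with F = cumsum(p - q), the
    optimal transport cost is sum |F - median(F)|.
    """
    p = np.asarray(h1, dtype=float)
    q = np.asarray(h2, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("histograms must be 1-D with equal bin counts")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("histogram counts must be non-negative")
    sp, sq = p.sum(), q.sum()
    if sp == 0 or sq == 0:
        raise ValueError("cannot compute EMD for a zero-mass histogram")
    f = np.cumsum(p / sp - q / sq)
    return float(np.abs(f - np.median(f)).sum())


def match_phase(
    obs: HistogramPair,
    lib: TemplateLibrary,
    weight_mode: str = "class_fraction",
    lam: float = 0.0,
    gonad_id: str = "",
) -> PhaseEstimate:
    """Match an observed histogram pair to the library's best template.

    The combined cost per template is w+ * EMD(EdU+ parts) + w- * EMD(EdU-
    parts), with w+ the mean of the observed and template EdU+ fractions
    (``weight_mode="class_fraction"``) or 0.5 (``"equal"``), plus an optional
    penalty ``lam * |frac_pos_obs - frac_pos_template|``.  Ties break toward
    the smaller phase.  Zones with zero EdU+ cells are refused with a
    dormant-or-unlabeled flag: their labeled cohort does not exist.
    """
    if obs.n_bins != lib.templates[0].n_bins:
        raise ValueError("observation and library bin counts differ")
    if obs.counts_pos.sum() == 0:
        return PhaseEstimate(gonad_id, math.nan, math.nan, math.nan, dormant=True)
    costs = np.empty(lib.k)
    for j, tmpl in enumerate(lib.templates):
        if weight_mode == "class_fraction":
            w_pos = 0.5 * (obs.frac_pos + tmpl.frac_pos)
        elif weight_mode == "equal":
            w_pos = 0.5
        else:
            raise ValueError(f"unknown weight_mode {weight_mode!r}")
        cost = w_pos * circular_emd(obs.counts_pos, tmpl.counts_pos)
        cost += (1.0 - w_pos) * circular_emd(obs.counts_neg, tmpl.counts_neg)
        if lam:
            cost += lam * abs(obs.frac_pos - tmpl.frac_pos)
        costs[j] = cost
    best = int(np.argmin(costs))  # argmin returns the first (smallest phase) tie
    margin = float(np.partition(costs, 1)[1] - costs[best]) if lib.k > 1 else 0.0
    return PhaseEstimate(gonad_id, float(lib.phases[best]), float(costs[best]), margin)


def circular_summary(
    phases,
    r_cap: float = WEDGE_R_CAP,
    width_cap: float = WEDGE_WIDTH_CAP,
) -> PhaseSummary:
    """Circular mean phase and resultant length R of a cohort.

    R is the magnitude of the mean unit vector at angles 2*pi*phase; the
    wedge width is 1/R, capped at ``width_cap`` when R < ``r_cap`` (a display
    convention — R itself is the quantitative output).
    """
    phases = np.asarray(list(phases), dtype=float)
    if phases.size == 0:
        raise ValueError("cannot summarize an empty phase list")
    angles = 2.0 * np.pi * phases
    z = np.mean(np.exp(1j * angles))
    r = float(np.abs(z))
    mean_phase = float(np.angle(z) / (2.0 * np.pi) % 1.0)
    width = 1.0 / r if r >= r_cap else width_cap
    return PhaseSummary(mean_phase, r, width, phases.size)


def _circular_diff(b: float, a: float) -> float:
    """Signed circular difference b - a mapped to [-0.5, 0.5)."""
    return (b - a + 0.5) % 1.0 - 0.5


def initial_progression_rate(
    estimates_by_time: dict[float, list[float]],
    max_window: float | None = None,
    t_c_nominal: float | None = None,
) -> ProgressionFit:
    """Least-squares progression rate (cycles/h) from phases grouped by chase time.

    Per-time circular mean phases are unwrapped assuming the true phase moves
    by less than half a cycle between consecutive chase times (sampling at
    least twice per cycle); ambiguous steps raise rather than guess.  Only
    chase times within ``max_window`` (default: half the nominal cycle, if
    given) are used.  Dormant-flagged estimates must be excluded upstream.
    """
    if max_window is None:
        max_window = (t_c_nominal / 2.0) if t_c_nominal else math.inf
    times = sorted(t for t in estimates_by_time if t <= max_window and estimates_by_time[t])
    if len(times) < 2:
        raise ValueError("need phase estimates at >= 2 distinct chase times in the window")
    means = [circular_summary(estimates_by_time[t]).mean_phase for t in times]
    unwrapped = [means[0]]
    for prev, cur in zip(means, means[1:]):
        d = _circular_diff(cur, prev)
        if abs(d) >= 0.5 - 1e-12:
            raise ValueError(
                "phase step of half a cycle between consecutive chase times: "
                "unwrapping is ambiguous; use denser chase times"
            )
        unwrapped.append(unwrapped[-1] + d)
    fit = stats.linregress(times, unwrapped)
    return ProgressionFit(
        rate=float(fit.slope),
        intercept=float(fit.intercept),
        window=(times[0], times[-1]),
        se=float(fit.stderr),
    )


def average_cycling_rate(p_active: float, rate: float) -> float:
    """Average cycling rate = fraction of active zones x their progression rate."""
    if not 0.0 <= p_active <= 1.0:
        raise ValueError("p_active must lie in [0, 1]")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return p_active * rate
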