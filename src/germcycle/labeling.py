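"""EdU pulse, chase and continuous-labeling simulation, plus histogram templates.

EdU is incorporated only by cells replicating DNA, i.e. cells that traverse
S phase while (a) label is available and (b) the zone is in the active state.
Dormancy freezes all ages; a label, once acquired, is never lost (no dilution
tracking: the analysis follows label presence over at most ~1.5 cycles).

The template library is the matching target for phase inference: DNA-content
histogram pairs (EdU+ / EdU-) of one simulated pulse-labeled population,
recorded at K evenly spaced fractions of cycle completion after the pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycle import CycleParams, ZonePopulation, _as_rng, advance, dna_content, sample_steady_state

__all__ = [
    "ActivitySchedule",
    "HistogramPair",
    "TemplateLibrary",
    "default_bin_edges",
    "pulse_label",
    "chase",
    "continuous_label",
    "make_histogram_pair",
    "build_template_library",
]

DEFAULT_BINS = 32
DEFAULT_PULSE_H = 0.5  # matches the short end of the 0.5-8 h feeding pulses
DEFAULT_K = 20


@dataclass(frozen=True)
class ActivitySchedule:
    """Disjoint, sorted intervals (hours) during which a zone is active."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.intervals:
            if not (start < end):
                raise ValueError(f"empty or inverted interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("intervals must be disjoint and sorted")
            prev_end = end

    @classmethod
    def full(cls, t: float) -> "ActivitySchedule":
        return cls(((0.0, float(t)),)) if t > 0 else cls(())

    @classmethod
    def none(cls) -> "ActivitySchedule":
        return cls(())

    @property
    def end(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def active_time(self, t: float) -> float:
        """Total active hours within [0, t]; non-decreasing in t."""
        return float(
            sum(max(0.0, min(end, t) - max(start, 0.0)) for start, end in self.intervals)
        )

    def active_at(self, t: float) -> bool:
        """Whether the zone is active at time ``t`` (intervals half-open [s, e))."""
        return any(start <= t < end for start, end in self.intervals)

    def clip(self, lo: float, hi: float) -> "ActivitySchedule":
        """Restrict to [lo, hi] and shift so the window starts at 0."""
        out = []
        for start, end in self.intervals:
            s, e = max(start, lo), min(end, hi)
            if s < e:
                out.append((s - lo, e - lo))
        return ActivitySchedule(tuple(out))


@dataclass
class HistogramPair:
    """Binned DNA-content histograms of EdU+ and EdU- cells.

    Bins span [1, 2] and are interpreted circularly: division wraps content
    from 2n back to 1n, so the last bin is adjacent to the first.
    """

    bin_edges: np.ndarray
    counts_pos: np.ndarray
    counts_neg: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts_pos = np.asarray(self.counts_pos, dtype=float)
        self.counts_neg = np.asarray(self.counts_neg, dtype=float)
        b = self.bin_edges.size - 1
        if self.counts_pos.size != b or self.counts_neg.size != b:
            raise ValueError("counts must have len(bin_edges) - 1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts_pos < 0) or np.any(self.counts_neg < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def total(self) -> float:
        return float(self.counts_pos.sum() + self.counts_neg.sum())

    @property
    def empty(self) -> bool:
        return self.total == 0

    @property
    def frac_pos(self) -> float:
        """EdU+ fraction of all cells; NaN for an empty histogram."""
        return float(self.counts_pos.sum() / self.total) if self.total > 0 else float("nan")


@dataclass
class TemplateLibrary:
    """K histogram pairs at evenly spaced cycle-completion phases j/K."""

    params: CycleParams
    k: int
    templates: list[HistogramPair]
    pulse_duration: float
    n_sim: int
    noise_cv: float = 0.0

    @property
    def phases(self) -> np.ndarray:
        return np.arange(self.k) / self.k

    @property
    def bin_edges(self) -> np.ndarray:
        return self.templates[0].bin_edges


def default_bin_edges(n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-width circular bins on the [1n, 2n] content axis."""
    return np.linspace(1.0, 2.0, n_bins + 1)


def _traverses_s(ages: np.ndarray, arc: float, params: CycleParams) -> np.ndarray:
    """Cells whose age arc [age, age+arc] (mod 1) intersects the S interval.

    With arc = 0 this reduces to 'currently in S'.  arc >= 1 covers everyone.
    """
    s0, s1 = params.s_interval
    if arc >= 1.0:
        return np.ones(ages.shape, dtype=bool)
    hit = (ages < s1) & (ages + arc >= s0)
    wrap = ages + arc >= 1.0 + s0
    return hit | wrap


def pulse_label(
    population: ZonePopulation, pulse_duration: float, params: CycleParams
) -> ZonePopulation:
    """Label cells whose trajectory over the (fully active) pulse touches S.

    The pulse must be shorter than one cycle so no cell can pass through S
    twice.  Ages advance by pulse_duration / t_c.
    """
    if pulse_duration < 0:
        raise ValueError("pulse_duration must be non-negative")
    if pulse_duration >= params.t_c:
        raise ValueError("pulse_duration must be shorter than one cycle length")
    arc = pulse_duration / params.t_c
    newly = _traverses_s(population.ages, arc, params)
    out = advance(population, pulse_duration, params)
    out.labeled = population.labeled | newly
    return out


def _check_schedule(schedule: ActivitySchedule, t: float) -> None:
    if t < 0:
        raise ValueError("t must be non-negative")
    for start, end in schedule.intervals:
        if start < 0 or end > t + 1e-12:
            raise ValueError(f"schedule interval ({start}, {end}) exceeds window [0, {t}]")


def chase(
    population: ZonePopulation,
    schedule: ActivitySchedule,
    t: float,
    params: CycleParams,
) -> ZonePopulation:
    """Unlabeled growth for ``t`` hours; ages advance only during active intervals."""
    _check_schedule(schedule, t)
    return advance(population, schedule.active_time(t), params)


def continuous_label(
    population: ZonePopulation,
    schedule: ActivitySchedule,
    t: float,
    params: CycleParams,
) -> ZonePopulation:
    """Label present throughout [0, t]; cells label whenever they replicate.

    Because cells only move (and only replicate) while the zone is active, a
    cell labels iff its arc over the total active time intersects S.  A fully
    dormant window labels nothing, even for cells parked inside S.
    """
    _check_schedule(schedule, t)
    active = schedule.active_time(t)
    out = advance(population, active, params)
    if active > 0:
        out.labeled = population.labeled | _traverses_s(
            population.ages, active / params.t_c, params
        )
    return out


def make_histogram_pair(
    population: ZonePopulation,
    bin_edges: np.ndarray,
    params: CycleParams,
    noise_cv: float = 0.0,
    seed=None,
) -> HistogramPair:
    """Bin per-cell DNA content (with multiplicative Gaussian measurement noise).

    Content = dna_content(age) * (1 + N(0, noise_cv)), clamped to [1, 2],
    binned separately for EdU+ and EdU- cells.  An empty population yields a
    zero histogram flagged via ``HistogramPair.empty`` rather than an error.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    bin_edges = np.asarray(bin_edges, dtype=float)
    if population.n == 0:
        b = bin_edges.size - 1
        return HistogramPair(bin_edges, np.zeros(b), np.zeros(b))
    content = dna_content(population.ages, params)
    if noise_cv > 0:
        rng = _as_rng(seed)
        content = content * (1.0 + rng.normal(0.0, noise_cv, size=content.shape))
    content = np.clip(content, bin_edges[0], bin_edges[-1])
    pos, _ = np.histogram(content[population.labeled], bins=bin_edges)
    neg, _ = np.histogram(content[~population.labeled], bins=bin_edges)
    return HistogramPair(bin_edges, pos, neg)


def build_template_library(
    params: CycleParams,
    k: int = DEFAULT_K,
    pulse_duration: float = DEFAULT_PULSE_H,
    n_sim: int = 100_000,
    bin_edges: np.ndarray | None = None,
    seed=0,
    noise_cv: float = 0.0,
) -> TemplateLibrary:
    """Simulate the K-point template library for phase matching.

    One steady-state population of ``n_sim`` cells is pulse-labeled, then its
    histogram pair is recorded after advancing by phase j/k of a cycle for
    j = 0..k-1.  Phase 0 is the state immediately after the pulse; advancing
    a further full cycle reproduces it (circular axis).  ``noise_cv``
    defaults to 0 (analytic content); set it to the measurement noise of the
    observations so templates and data are comparable.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    rng = _as_rng(seed)
    pop = sample_steady_state(n_sim, params, rng)
    pop = pulse_label(pop, pulse_duration, params)
    templates = []
    for j in range(k):
        shifted = advance(pop, (j / k) * params.t_c, params)
        templates.append(
            make_histogram_pair(shifted, bin_edges, params, noise_cv=noise_cv, seed=rng)
        )
    return TemplateLibrary(params, k, templates, pulse_duration, int(n_sim), noise_cv)
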