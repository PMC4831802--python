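"""Deterministic kinematics of a cycling germ-cell population.

A cell's position in the cycle is its *age*, the fraction of one full cycle
completed, in [0, 1).  Phase boundaries are cumulative fractions of the cycle
(G1, S, G2, M in that order); DNA content runs from 1n in G1 to 2n through
G2/M and snaps back to 1n at division, which makes the content axis circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PHASE_NAMES = ("G1", "S", "G2", "M")

__all__ = [
    "PHASE_NAMES",
    "CycleParams",
    "ZonePopulation",
    "make_cycle_params",
    "wildtype_params",
    "dna_content",
    "phase_label",
    "sample_steady_state",
    "advance",
]


class CycleParamError(ValueError):
    """Invalid cell-cycle parameterisation."""


@dataclass(frozen=True)
class CycleParams:
    """Cell-cycle phase fractions and total cycle length.

    Parameters
    ----------
    f_g1, f_s, f_g2, f_m
        Fractions of one cycle spent in G1, S, G2 and M.  Each must lie in
        (0, 1) and they must sum to 1 (tolerance 1e-9).
    t_c
        Total cycle length in hours; must be positive.  The wild-type preset
        uses 5.5 h with an M fraction of 0.10.
    """

    f_g1: float
    f_s: float
    f_g2: float
    f_m: float
    t_c: float

    def __post_init__(self) -> None:
        for name in ("f_g1", "f_s", "f_g2", "f_m"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise CycleParamError(f"{name} must be finite, got {v!r}")
            if not 0.0 < v < 1.0:
                raise CycleParamError(f"{name} must lie in (0, 1), got {v}")
        total = self.f_g1 + self.f_s + self.f_g2 + self.f_m
        if abs(total - 1.0) > 1e-9:
            raise CycleParamError(
                f"phase fractions must sum to 1 (got {total!r}); "
                "check f_g1/f_s/f_g2/f_m"
            )
        if not (np.isfinite(self.t_c) and self.t_c > 0):
            raise CycleParamError(f"t_c must be a positive duration, got {self.t_c!r}")

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative phase boundaries [f_g1, f_g1+f_s, f_g1+f_s+f_g2]."""
        return np.cumsum([self.f_g1, self.f_s, self.f_g2])

    @property
    def s_interval(self) -> tuple[float, float]:
        """Half-open S-phase age interval [start, end)."""
        return (self.f_g1, self.f_g1 + self.f_s)


def make_cycle_params(
    f_g1: float, f_s: float, f_g2: float, f_m: float, t_c: float
) -> CycleParams:
    """Validate and build a :class:`CycleParams`."""
    return CycleParams(f_g1, f_s, f_g2, f_m, t_c)


def wildtype_params() -> CycleParams:
    """Wild-type young-adult preset: ~5.5 h cycle, M-phase ~10% of the cycle.

    The non-M fractions are configurable defaults (G1 40%, S 30%, G2 20%)
    chosen to give a realistic S fraction; only f_m and t_c are anchored to
    measurements.
    """
    return CycleParams(0.4, 0.3, 0.2, 0.1, 5.5)


@dataclass
class ZonePopulation:
    """Per-cell state of one mitotic zone: cycle ages and EdU label flags."""

    ages: np.ndarray
    labeled: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if self.labeled is None:
            self.labeled = np.zeros(self.ages.shape, dtype=bool)
        else:
            self.labeled = np.asarray(self.labeled, dtype=bool)
        if self.ages.ndim != 1 or self.labeled.shape != self.ages.shape:
            raise ValueError("ages and labeled must be 1-D arrays of equal length")
        if self.ages.size and (self.ages.min() < 0 or self.ages.max() >= 1):
            raise ValueError("ages must lie in [0, 1)")

    @property
    def n(self) -> int:
        return self.ages.size

    def copy(self) -> "ZonePopulation":
        return ZonePopulation(self.ages.copy(), self.labeled.copy())


def _check_ages(age: np.ndarray) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if age.size and (np.min(age) < 0 or np.max(age) >= 1):
        raise ValueError("age must lie in [0, 1)")
    return age


def dna_content(age, params: CycleParams):
    """Relative DNA content in [1, 2] at a given cycle age.

    1.0 through G1, a linear ramp 1→2 across S (replication), and a 2.0
    plateau through G2 and M.  Continuous at the G1/S and S/G2 boundaries.
    Accepts scalars or arrays.
    """
    scalar = np.isscalar(age)
    a = _check_ages(np.atleast_1d(age))
    s0, s1 = params.s_interval
    content = np.where(
        a < s0, 1.0, np.where(a < s1, 1.0 + (a - s0) / params.f_s, 2.0)
    )
    return float(content[0]) if scalar else content


def phase_label(age, params: CycleParams):
    """Phase label (G1/S/G2/M) by half-open, lower-inclusive age intervals."""
    scalar = np.isscalar(age)
    a = _check_ages(np.atleast_1d(age))
    idx = np.searchsorted(params.boundaries, a, side="right")
    labels = np.asarray(PHASE_NAMES)[idx]
    return str(labels[0]) if scalar else labels


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_steady_state(
    n: int, params: CycleParams, seed, density: str = "uniform"
) -> ZonePopulation:
    """Sample a steady-state zone of ``n`` unlabeled cells.

    ``density`` selects the cycle-position distribution: ``"uniform"`` (the
    default closed-population model) or ``"exponential"`` for the
    exponentially-growing alternative with density proportional to 2**(1-age).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _as_rng(seed)
    u = rng.random(int(n))
    if density == "uniform":
        ages = u
    elif density == "exponential":
        # inverse CDF of f(a) = ln2 * 2**(1-a) on [0,1)
        ages = -np.log2(1.0 - u / 2.0)
    else:
        raise ValueError(f"unknown steady-state density {density!r}")
    return ZonePopulation(ages)


def advance(population: ZonePopulation, dt: float, params: CycleParams) -> ZonePopulation:
    """Advance every cell by ``dt`` hours of active cycling (mod one cycle).

    Label flags are preserved; the population is closed (no birth, death or
    meiotic efflux), so a full cycle (dt = t_c) is the identity on ages.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    ages = np.mod(population.ages + dt / params.t_c, 1.0)
    return replace(population.copy(), ages=ages)
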