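"""Seeded generators of synthetic per-gonad cell tables and labeling summaries.

Condition presets bundle a generative model per genotype-like condition:
cell-cycle parameters, the dormant/active switching chain (stationary dormant
fraction pi_D and rates k_DA, k_AD), zone-size distribution, DNA-content
measurement noise, and EdU/PH3 scoring error rates.  The preset dormant
fractions are anchored to the published 1 h continuous-labeling fractions
(wild type ~5%, fog-1 55%, fog-2 17%, with inx-22; fog-2 and spe-8 close to
wild type); switching rates and noise levels are calibration choices
documented in the methods note.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .capacity import simulate_activity
from .cycle import CycleParams, _as_rng, phase_label, sample_steady_state, wildtype_params
from .dormancy import GonadSample
from .labeling import continuous_label

__all__ = [
    "ConditionPreset",
    "builtin_presets",
    "generate_pulse_chase",
    "generate_continuous",
    "generate_sister_arms",
]


@dataclass(frozen=True)
class ConditionPreset:
    """Generative model for one experimental condition."""

    name: str
    cycle: CycleParams
    pi_d: float  # stationary dormant fraction
    k_da: float  # dormant -> active, per hour
    k_ad: float  # active -> dormant, per hour
    zone_size_mean: float = 260.0
    zone_size_sd: float = 20.0
    noise_cv: float = 0.06
    edu_fn: float = 0.005
    edu_fp: float = 1e-4
    ph3_miss: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_d <= 1.0:
            raise ValueError("pi_d must lie in [0, 1]")
        if self.k_da < 0 or self.k_ad < 0:
            raise ValueError("rates must be non-negative")
        if self.k_da + self.k_ad > 0:
            stationary = self.k_ad / (self.k_ad + self.k_da)
            if abs(stationary - self.pi_d) > 1e-6:
                raise ValueError(
                    "pi_d inconsistent with rates: expected k_ad/(k_ad+k_da) "
                    f"= {stationary:.6f}, got pi_d = {self.pi_d}"
                )
        for name in ("noise_cv", "edu_fn", "edu_fp", "ph3_miss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.zone_size_mean <= 0 or self.zone_size_sd < 0:
            raise ValueError("zone size parameters out of range")

    @property
    def p_active(self) -> float:
        return 1.0 - self.pi_d

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cycle"] = asdict(self.cycle)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionPreset":
        d = dict(d)
        d["cycle"] = CycleParams(**d["cycle"])
        return cls(**d)


def _preset(name: str, pi_d: float, k_da: float, **kw) -> ConditionPreset:
    # derive k_ad from the stationary constraint pi_d = k_ad / (k_ad + k_da)
    k_ad = k_da * pi_d / (1.0 - pi_d) if pi_d < 1 else 1.0
    return ConditionPreset(name, wildtype_params(), pi_d, k_da, k_ad, **kw)


def builtin_presets() -> dict[str, ConditionPreset]:
    """Named presets mirroring the day-1 continuous-labeling conditions.

    Dormant fractions: wild type 0.05, fog-1 0.55, fog-2 0.17, with
    inx-22; fog-2 (0.08) and spe-8 (0.07) close to wild type.  All share the
    wild-type cycle (5.5 h, 10% M).  Switching rates are calibration choices:
    fog-like conditions exit dormancy slowly (full labeling takes in excess
    of 6 h) and re-enter it within a few hours of activity, dispersing their
    pulse-chase phases; wild-type-like conditions switch on a much slower
    timescale so that active zones stay synchronized over a 6 h chase, as
    observed for young hermaphrodites.
    """
    return {
        p.name: p
        for p in (
            _preset("wt_day1", 0.05, 0.25),
            _preset("fog1_day1", 0.55, 0.30),
            _preset("fog2_day1", 0.17, 0.35),
            _preset("inx22_fog2_day1", 0.08, 0.40),
            _preset("spe8_day1", 0.07, 0.40),
        )
    }


def _zone_size(rng: np.random.Generator, preset: ConditionPreset) -> int:
    while True:
        n = rng.normal(preset.zone_size_mean, preset.zone_size_sd)
        if n >= 1:
            return int(round(n))


def _emit_cells(
    rng: np.random.Generator,
    pop,
    preset: ConditionPreset,
    zone_active: bool,
) -> pd.DataFrame:
    """Measured per-cell table: noisy DNA content, misclassified EdU, PH3.

    Dormant zones carry no M-phase figures (their cells arrest outside M), so
    PH3 is emitted only for zones active at assay time.
    """
    content = _measured_content(rng, pop, preset)
    edu = pop.labeled.copy()
    flip_fn = rng.random(pop.n) < preset.edu_fn
    flip_fp = rng.random(pop.n) < preset.edu_fp
    edu = np.where(edu, ~flip_fn, flip_fp)
    in_m = phase_label(pop.ages, preset.cycle) == "M"
    ph3 = zone_active & in_m & (rng.random(pop.n) >= preset.ph3_miss)
    return pd.DataFrame(
        {
            "dna_content": content,
            "edu": edu.astype(bool),
            "ph3": ph3.astype(bool),
        }
    )


def _measured_content(rng, pop, preset: ConditionPreset) -> np.ndarray:
    from .cycle import dna_content

    content = dna_content(pop.ages, preset.cycle)
    if preset.noise_cv > 0:
        content = content * (1.0 + rng.normal(0.0, preset.noise_cv, size=pop.n))
    return np.clip(content, 1.0, 2.0)


def generate_pulse_chase(
    preset: ConditionPreset,
    chase_times,
    n_per_time: int,
    seed: int,
    pulse_h: float = 0.5,
) -> list[GonadSample]:
    """Synthetic pulse-chase cohort: one GonadSample per zone.

    Per zone: a steady-state population of truncated-normal size, an activity
    schedule simulated over pulse + chase, EdU labeling during the active
    part of the pulse, dormancy-interrupted progression during the chase,
    then measurement noise and scoring errors.  Deterministic given seed.
    """
    if n_per_time < 1:
        raise ValueError("n_per_time must be at least 1")
    chase_times = list(chase_times)
    samples = []
    root = np.random.SeedSequence(seed)
    time_seqs = root.spawn(len(chase_times))
    for ti, chase_h in enumerate(chase_times):
        for wi, child in enumerate(time_seqs[ti].spawn(n_per_time)):
            rng = np.random.default_rng(child)
            n = _zone_size(rng, preset)
            pop = sample_steady_state(n, preset.cycle, rng)
            window = pulse_h + chase_h
            initial_active = rng.random() >= preset.pi_d
            schedule = simulate_activity(
                preset.k_da, preset.k_ad, window, initial_active, rng
            )
            pop = continuous_label(
                pop, schedule.clip(0.0, pulse_h), pulse_h, preset.cycle
            )
            if chase_h > 0:
                from .labeling import chase as run_chase

                pop = run_chase(
                    pop, schedule.clip(pulse_h, window), chase_h, preset.cycle
                )
            zone_active = schedule.active_at(window - 1e-9)
            cells = _emit_cells(rng, pop, preset, zone_active)
            samples.append(
                GonadSample(
                    worm_id=f"{preset.name}_c{chase_h:g}_w{wi:03d}",
                    arm="L",
                    condition=preset.name,
                    assay="pulse_chase",
                    cells=cells,
                    pulse_h=pulse_h,
                    chase_h=float(chase_h),
                )
            )
    return samples


def generate_continuous(
    preset: ConditionPreset,
    durations,
    n_per_duration: int,
    seed: int,
    per_cell: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[GonadSample]]:
    """Synthetic continuous-labeling summary (and optionally cell tables).

    Each zone's labeled status comes from per-cell labeling under its own
    simulated activity schedule.  The summary rows (worm_id, arm, condition,
    label_h, labeled) feed labeling_curve and fit_switching directly.
    """
    durations = list(durations)
    if not durations:
        raise ValueError("durations must be non-empty")
    rows = []
    samples = []
    root = np.random.SeedSequence(seed)
    duration_seqs = root.spawn(len(durations))
    for di, duration in enumerate(durations):
        for wi, child in enumerate(duration_seqs[di].spawn(n_per_duration)):
            rng = np.random.default_rng(child)
            n = _zone_size(rng, preset)
            pop = sample_steady_state(n, preset.cycle, rng)
            initial_active = rng.random() >= preset.pi_d
            schedule = simulate_activity(
                preset.k_da, preset.k_ad, duration, initial_active, rng
            )
            pop = continuous_label(pop, schedule, duration, preset.cycle)
            labeled = bool(pop.labeled.any())
            worm_id = f"{preset.name}_d{duration:g}_w{wi:03d}"
            rows.append(
                {
                    "worm_id": worm_id,
                    "arm": "L",
                    "condition": preset.name,
                    "label_h": float(duration),
                    "labeled": int(labeled),
                }
            )
            if per_cell:
                zone_active = schedule.active_at(duration - 1e-9)
                cells = _emit_cells(rng, pop, preset, zone_active)
                samples.append(
                    GonadSample(
                        worm_id=worm_id,
                        arm="L",
                        condition=preset.name,
                        assay="continuous",
                        cells=cells,
                        label_h=float(duration),
                    )
                )
    summary = pd.DataFrame(rows)
    return (summary, samples) if per_cell else summary


def generate_sister_arms(
    preset: ConditionPreset, n_worms: int, rho: float, seed: int
) -> pd.DataFrame:
    """Paired arm activity states with within-worm correlation ``rho``.

    Both arms share the marginal active probability 1 - pi_d; with
    probability rho the right arm copies the left (rho=1 identical arms,
    rho=0 independent).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = _as_rng(seed)
    p = preset.p_active
    left = rng.random(n_worms) < p
    copy = rng.random(n_worms) < rho
    right = np.where(copy, left, rng.random(n_worms) < p)
    return pd.DataFrame(
        {
            "worm_id": [f"{preset.name}_w{i:03d}" for i in range(n_worms)],
            "active_l": left.astype(bool),
            "active_r": right.astype(bool),
        }
    )
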