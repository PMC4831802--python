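# Methods

## Cycle kinematics and the steady-state assumption

The population model is deliberately minimal: a closed set of cells, each
described by a single age coordinate φ ∈ [0, 1) advancing at 1/T_c per hour
while the zone is active and frozen while it is dormant. There is no birth,
death, meiotic efflux or per-cell cycle-length variability; all stochasticity
enters at the zone level (switching) and at measurement (noise, scoring
errors). This is the right level of description for the quantities computed
here — zone-level phase, synchrony, dormancy — and deliberately wrong for
questions about flux through the zone.

Steady state defaults to a uniform age distribution, the self-consistent
choice for a closed population. For an exponentially growing population the
age density would instead be proportional to 2^(1−φ);
`sample_steady_state(..., density="exponential")` provides it, and template
generation accepts either. The difference is second-order for phase matching
because the template and the synthetic data use the same density.

DNA content maps from age as 1n through G1, a linear ramp across S, and a 2n
plateau through G2/M, wrapping to 1n at division. Phase intervals are
half-open and lower-inclusive (age exactly f_G1 is S). Defaults: f_G1 = 0.4,
f_S = 0.3, f_G2 = 0.2, f_M = 0.1, T_c = 5.5 h. Only f_M ≈ 0.1 and
T_c ≈ 5.5 h are anchored to measured values; the other fractions are
package defaults chosen to give a realistic S fraction and are exposed on
every preset.

## EdU labeling

A cell labels iff it traverses any part of S phase while label is present
*and* the zone is active — dormant cells do not replicate, so a cell parked
inside S during a fully dormant window stays unlabeled. Labels never dilute:
the analysis tracks label presence over at most ~1.5 cycles, not intensity.
The pulse is restricted to less than one cycle (single-pass assumption);
continuous labeling has no such restriction, and one full cycle of activity
labels every cell. An active 260-cell zone contains an S-phase cell with
probability ≈ 1 − (1 − f_S)^260 ≈ 1, which justifies treating a zone's
first-labeling time as the onset of its first active interval — the
zone-level approximation behind the switching model below.

## Template library and circular EMD matching

Templates are generated by forward Monte-Carlo: one steady-state population
of n_sim = 10^5 cells is pulse-labeled (default pulse 0.5 h) and its
EdU+/EdU− histogram pair recorded after advancing by j/K of a cycle,
j = 0..K−1, K = 20. Defaults: 32 equal-width bins on [1, 2]; template
noise_cv should be set to the measurement noise of the observations (0 gives
analytic content, used by exactness tests). An analytic-convolution
generator was considered and rejected: at n_sim = 10^5 the Monte-Carlo
binning error is far below one EMD bin and the simulation path is the same
code the rest of the package exercises.

Matching uses the exact 1-D circular Earth Mover's Distance with ground
distance min(|i−j|, B−|i−j|) in bin units, computed by the
cumulative-difference/median algorithm (cost = Σ|F − median F| with
F = cumsum(p − q)); the test suite checks it against a brute-force
transportation LP. Circularity matters: histograms just before and just
after division are nearly identical biologically but maximally distant on a
linear axis.

The EdU+ and EdU− histograms are combined as
w⁺·EMD(pos) + w⁻·EMD(neg) with w⁺ the mean of the observed and template
EdU+ fractions (w⁻ = 1 − w⁺), so each class is weighted by roughly the mass
it carries; an optional additive penalty λ·|Δfrac_pos| (default λ = 0) is
exposed. Phase estimates are restricted to the K-point grid (0.05-cycle
resolution); no interpolation. Zones with zero EdU+ cells are refused with a
dormant flag — the labeled-cohort phase does not exist for them. Ties break
toward the smaller phase.

Cohort summaries use standard circular statistics: resultant length R of the
unit vectors at angles 2πφ, wedge width 1/R capped at 20 when R < 0.05 (the
cap is a display convention; R is the quantitative output). Progression
rates are least-squares slopes of per-time circular mean phases, unwrapped
under the assumption |Δphase| < 0.5 between consecutive chase times;
ambiguous steps raise an error rather than guess, so chase designs must
sample at least twice per cycle. The default fitting window is T_c/2 because
"initial" rates are meant to exclude later dormancy episodes.

## Dormancy and switching

Dormancy is zone-level: no EdU+ cell after labeling. The continuous-labeling
model is U(t) = π_D·exp(−k_DA·t), i.e. a zone remains unlabeled iff it
started dormant (probability π_D, the stationary dormant fraction) and has
not yet switched on (rate k_DA). Each assayed zone is a Bernoulli draw at
its duration; (π_D, k_DA) are fit by bounded maximum likelihood from
multiple starts. Degenerate datasets (all labeled everywhere / none labeled
anywhere) return boundary-flagged fits.

Group comparisons of interval-censored labeling times use a Gehan-score
permutation test: score +1/−1/0 for pairs of intervals that are disjoint in
one order, the other, or overlapping, with a two-sided permutation p-value
(add-one estimator, ≥ 999 permutations). When all intervals degenerate to
points the test's decisions agree with the ordinary two-sample rank test,
which is checked in the suite. A nonparametric NPMLE-based test was out of
scope by design; the Gehan permutation test is the declared generalization.

Confidence-interval conventions follow the figures this pipeline serves:
83% binomial CIs on labeling curves (error-bar convention), 95% for CV
contrasts, 99% available for capacity CVs. The CV bootstrap resamples
gonads (percentile intervals, seeded). Fisher's exact test and Bonferroni
adjustment are delegated to scipy/numpy.

## Synthetic data

The generator is first-class: it produces the same tables the pipeline
ingests, with the statistical structure the analysis assumes — steady-state
ages, zone-level switching schedules during pulse and chase, multiplicative
Gaussian DNA-content noise, EdU misclassification, PH3 emission.

Preset anchors (stationary dormant fractions) follow the published 1 h
continuous-labeling fractions: wild type 0.05, fog-1 0.55, fog-2 0.17, with
inx-22; fog-2 (0.08) and spe-8 (0.07) close to wild type. All share the
wild-type cycle. Switching rates are calibration choices, not measured
constants: fog-like conditions use k_DA ≈ 0.3/h (full labeling takes in
excess of 6 h; active dwells of a few hours disperse pulse-chase phases),
while wild-type-like conditions use k_DA = 0.25/h with correspondingly slow
k_AD (mean active dwell ~76 h), because young-adult zones are observed to
progress in near-synchrony across a > 1-cycle chase — fast wild-type
switching would contradict that observation while leaving the stationary
fraction unchanged.

Other defaults: zone size truncated-normal (260 ± 20); noise_cv = 0.06;
edu_fn = 0.005 and edu_fp = 1e-4. The false-positive rate is deliberately an
order of magnitude below the false-negative rate: dormancy classification
reads ~260 cells per zone, so a per-cell fp of 0.005 would mislabel ~73% of
dormant zones as active, whereas 1e-4 keeps zone-level classification
near-perfect (~2.6% error), matching how unambiguous dormancy scoring is in
practice. Dormant zones emit no PH3+ cells: the arithmetic above (26
expected M-phase figures, never observed) implies arrested zones do not park
in M, and the mitotic-index CV analysis depends on that.

What the generator does not emulate: spatial structure within the zone,
label dilution, cell flux into meiosis, staining batch effects, segmentation
errors beyond the binary misclassification rates. Tests passing on this
generator therefore validate the inference machinery under the stated model,
not the imaging pipeline upstream of it.

## Capacity bet-hedging simulation

Switching is a two-state continuous-time Markov chain with exponential
dwells (means 1/k_DA dormant, 1/k_AD active); the dwell family is the
minimal declared choice and is isolated behind `simulate_activity`.
Depletion is linear in active time at rate r, floored at zero; initial
capacities are truncated-normal with mean c0 and CV 0.12 (the day-0
brood-size CV), and a warning flags parameterizations where truncation
removes > 5% of the mass. The CV series is reported against the *realized*
CV at t = 0, not the nominal one, to avoid small-n bias. The default scan
covers dwell means log-spaced over 0.5–100 h per state with r chosen per
grid point so mean capacity loss over 48 h lands on targets between 30% and
70%, n = 2000 individuals, initial states drawn from the stationary
distribution, CV ratios averaged over seed replicates. Slow switching
(dwells comparable to the horizon) maximizes amplification: the population
splits into nearly-always-dormant and nearly-always-active individuals.

## Numerical choices and problem sizes

All randomness flows through numpy Generators; every public API takes a seed
or Generator, and cohort generators derive per-gonad streams from a
SeedSequence so outputs are byte-identical across runs. Test and example
problem sizes (template n_sim 3–5×10^4, cohorts of 10–500 zones, capacity
n = 2000–10^4) were chosen so each statistical assertion has a comfortable
margin over its sampling error. Validation errors are raised early and name
the offending quantity; empty histograms and boundary-degenerate fits are
flagged on the returned object rather than raised, since both are legitimate
states of real data.

## Known limitations

- Phase estimates are grid-restricted (0.05 cycle); systematic quantization
  bias up to half a grid step can survive averaging when all zones in a
  cohort sit at the same true phase.
- The switching fit assumes zones are exchangeable within a condition;
  worm-level correlation (sister arms agree ~92% of the time) is modeled in
  the generator but not exploited by the fit.
- The U(t) model ignores the (tiny) per-cell delay between zone activation
  and first S-phase traversal.
- The capacity simulation demonstrates achievability of large CV
  amplification under the declared model; it does not fit observed brood
  distributions.
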