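"""Infer per-gonad cell-cycle phase from EdU/DNA-content histograms.

Builds the simulated template library, generates synthetic pulse-chase
cohorts for a wild-type-like and a fog-1-like condition, matches each zone's
histogram pair to the library by circular Earth Mover's Distance, and
summarizes each cohort on the circle.
"""

import numpy as np

import germcycle as gc

presets = gc.builtin_presets()
params = gc.wildtype_params()

# templates carry the same measurement noise as the synthetic observations
lib = gc.build_template_library(params, n_sim=50_000, seed=0, noise_cv=0.06)

print(f"template library: {lib.k} phases, pulse {lib.pulse_duration} h, "
      f"{lib.templates[0].n_bins} circular bins on [1n, 2n]\n")

for name in ("wt_day1", "fog1_day1"):
    preset = presets[name]
    by_time = {}
    for chase_h in (0.0, 2.0, 4.0, 6.0):
        samples = gc.generate_pulse_chase(preset, [chase_h], 10, seed=1 + int(chase_h))
        phases = []
        n_dormant = 0
        for g in samples:
            edu = g.cells["edu"].to_numpy(bool)
            content = g.cells["dna_content"].to_numpy()
            pos, _ = np.histogram(content[edu], bins=lib.bin_edges)
            neg, _ = np.histogram(content[~edu], bins=lib.bin_edges)
            est = gc.match_phase(gc.HistogramPair(lib.bin_edges, pos, neg), lib)
            if est.dormant:
                n_dormant += 1
            else:
                phases.append(est.phase)
        s = gc.circular_summary(phases)
        by_time[chase_h] = phases
        print(f"{name:12s} chase {chase_h:3.0f} h: mean phase {s.mean_phase:.2f}, "
              f"R = {s.resultant:.2f}, wedge width {s.wedge_width:4.1f}, "
              f"{n_dormant} zone(s) unlabeled")
    fit = gc.initial_progression_rate(by_time, t_c_nominal=params.t_c)
    avg = gc.average_cycling_rate(preset.p_active, fit.rate)
    print(f"{name:12s} initial progression rate {fit.rate:.3f} cycles/h "
          f"(1/t_c = {1 / params.t_c:.3f}); average rate "
          f"{avg:.2f} cycles/h after weighting by the {preset.p_active:.0%} "
          f"active fraction\n")

print("R near 1 means zones progressed in near-synchrony after the pulse; "
      "wide wedges (low R) indicate zones stochastically pausing during the "
      "chase, as for the fog-1-like condition.")
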