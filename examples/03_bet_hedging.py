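"""Bet-hedging simulation: can stochastic dormancy triple capacity variability?

Individuals switch between dormant and active gonad states (exponential
dwells) and lose reproductive capacity only while active.  The scan asks how
large an increase in the population CV of remaining capacity is achievable
over 48 h, starting from a baseline CV of 0.12, across switching timescales
and depletion rates producing 30-70% mean capacity loss.
"""

import numpy as np

import germcycle as gc

base = gc.CapacityParams(n=2000, cv0=0.12, horizon=48.0, seed=1)
table, best = gc.bet_hedging_scan(base, n_seeds=3)

print(f"scanned {len(table)} grid points "
      f"(5x5 dwell means 0.5-100 h, 5 depletion targets, n={base.n})")
print(f"max CV amplification: {best['cv_ratio']:.1f}-fold at "
      f"mean dwells {1 / best['k_da']:.1f} h dormant / "
      f"{1 / best['k_ad']:.1f} h active, "
      f"mean capacity loss {best['mean_loss_fraction']:.0%}")

# a single trajectory at the best grid point, for the time course
from dataclasses import replace

params = replace(base, k_da=best["k_da"], k_ad=best["k_ad"], r=best["r"],
                 p_active0=best["k_da"] / (best["k_da"] + best["k_ad"]))
traj = gc.simulate_population(params, times=np.linspace(0, 48, 7))
print("\nCV of remaining capacity over time at that grid point:")
for t, cv in zip(traj.times, traj.cv_series):
    print(f"  {t:4.0f} h: CV = {cv:.2f}")
print("\nslow switching splits the population into lucky (mostly dormant) "
      "and unlucky (mostly active) individuals, so the spread of remaining "
      "capacity grows far beyond its initial value.")
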