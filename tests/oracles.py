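"""Independent oracles used by the test suite.

These are deliberately slow, brute-force computations kept separate from the
implementations they check.
"""

import numpy as np
from scipy.optimize import linprog


def circular_emd_lp(p, q) -> float:
    """Circular EMD by solving the transportation linear program directly.

    Variables x[i, j] >= 0 move mass from bin i of p to bin j of q at cost
    min(|i-j|, B-|i-j|); row sums must equal p, column sums q.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    b = p.size
    i, j = np.meshgrid(np.arange(b), np.arange(b), indexing="ij")
    cost = np.minimum(np.abs(i - j), b - np.abs(i - j)).ravel()
    a_eq = np.zeros((2 * b, b * b))
    for r in range(b):
        a_eq[r, r * b : (r + 1) * b] = 1.0  # row sum = p[r]
        a_eq[b + r, r::b] = 1.0  # column sum = q[r]
    res = linprog(
        cost,
        A_eq=a_eq,
        b_eq=np.concatenate([p, q]),
        bounds=(0, None),
        method="highs",
    )
    assert res.success, res.message
    return float(res.fun)


def two_point_mixture_cv(frac_active, loss_fraction, cv0):
    """CV after deterministic depletion of the active half of a population.

    Active individuals lose loss_fraction * mean capacity; SDs are unchanged
    within each group.  Returns CV(final) / CV(initial).
    """
    pa = frac_active
    mu_a, mu_d = 1.0 - loss_fraction, 1.0
    mean = pa * mu_a + (1 - pa) * mu_d
    within = cv0**2  # both groups keep variance (cv0 * mu0)^2 with mu0 = 1
    between = pa * (1 - pa) * (mu_a - mu_d) ** 2
    return float(np.sqrt(within + between) / mean / cv0)
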