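"""Independent brute-force oracles shared by the test modules.

These re-derive results from first principles by a different computational
route than the package (full sorted lists instead of partial selection,
complex-exponential resultants instead of sin/cos sums) so that agreement is
evidence, not tautology.
"""

import numpy as np
from scipy import stats


def analogue_oracle(temp0, temp1, ids, north, east, dist, k_temp, k_dist):
    """Exhaustive double-ranking nearest-thermal-analogue reference.

    For each start cell: full sort of all candidates by (|temperature
    difference|, id), truncate to k_temp; full sort of the survivors by
    (distance, id), truncate to k_dist; average the displacement vectors.
    """
    out = {}
    for i in range(len(ids)):
        by_temp = sorted(range(len(ids)), key=lambda j: (abs(temp1[j] - temp0[i]), ids[j]))
        cand = by_temp[:k_temp]
        by_dist = sorted(cand, key=lambda j: (dist[i, j], ids[j]))[:k_dist]
        out[ids[i]] = (
            float(np.mean([east[i, j] for j in by_dist])),
            float(np.mean([north[i, j] for j in by_dist])),
        )
    return out


def ww_oracle(a1_deg, a2_deg):
    """Textbook-formula Watson-Williams reference via complex resultants."""
    z1 = np.exp(1j * np.radians(np.asarray(a1_deg, float)))
    z2 = np.exp(1j * np.radians(np.asarray(a2_deg, float)))
    n1, n2 = len(z1), len(z2)
    N = n1 + n2
    R1, R2 = abs(z1.sum()), abs(z2.sum())
    R = abs(z1.sum() + z2.sum())
    rw = (R1 + R2) / N
    if rw < 0.53:
        k = 2 * rw + rw**3 + 5 * rw**5 / 6
    elif rw < 0.85:
        k = -0.4 + 1.39 * rw + 0.43 / (1 - rw)
    else:
        k = 1.0 / (rw**3 - 4 * rw**2 + 3 * rw)
    K = 1 + 3 / (8 * k)
    F = K * ((N - 2) * (R1 + R2 - R)) / (N - (R1 + R2))
    return F, float(stats.f.sf(F, 1, N - 2))
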