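"""Independent brute-force oracles used by the test suite.

These are deliberately naive (two loops, O(n^2) pair counting) and share no
code with the implementation they check.
"""

import math

import numpy as np


def kappa_two_loop(table, scheme: str) -> float:
    """Literal two-loop weighted kappa: 1 - sum(w p_obs) / sum(w p_exp)."""
    t = np.asarray(table, dtype=float)
    k = t.shape[0]
    n = t.sum()
    row = [t[i, :].sum() / n for i in range(k)]
    col = [t[:, j].sum() / n for j in range(k)]
    num = 0.0
    den = 0.0
    for i in range(k):
        for j in range(k):
            d = abs(i - j)
            if scheme == "none":
                w = 1.0 if d > 0 else 0.0
            elif scheme == "linear":
                w = d / (k - 1)
            else:  # quadratic
                w = (d / (k - 1)) ** 2
            num += w * t[i, j] / n
            den += w * row[i] * col[j]
    return 1.0 - num / den


def tau_b_pair_counting(x, y) -> float:
    """O(n^2) concordant/discordant pair counting with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    # pairs tied in x (including double ties) and in y
    tx = sum(
        int(c * (c - 1) // 2) for c in np.unique(x, return_counts=True)[1]
    )
    ty = sum(
        int(c * (c - 1) // 2) for c in np.unique(y, return_counts=True)[1]
    )
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (concordant - discordant) / denom
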