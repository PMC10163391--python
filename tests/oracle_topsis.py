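"""Independent brute-force TOPSIS: naive pure-Python loops, no shared code.

Used only as a test oracle against the vectorised implementation.
"""

import math


def brute_force_topsis(values, directions, weights, normalization="vector"):
    """values: list of n rows (lists of m floats); returns list of n gaps."""
    n = len(values)
    m = len(values[0])

    r = [[0.0] * m for _ in range(n)]
    for j in range(m):
        col = [values[i][j] for i in range(n)]
        if normalization == "vector":
            norm = math.sqrt(sum(v * v for v in col))
            if norm == 0:
                raise ValueError("all-zero column")
            for i in range(n):
                r[i][j] = values[i][j] / norm
        elif normalization == "minmax":
            lo, hi = min(col), max(col)
            for i in range(n):
                r[i][j] = 0.5 if hi == lo else (values[i][j] - lo) / (hi - lo)
        else:
            raise ValueError(normalization)

    wsum = sum(weights)
    v = [[r[i][j] * weights[j] / wsum for j in range(m)] for i in range(n)]

    best, worst = [], []
    for j in range(m):
        col = [v[i][j] for i in range(n)]
        if directions[j] == "gap_increasing":
            best.append(min(col))
            worst.append(max(col))
        else:
            best.append(max(col))
            worst.append(min(col))

    gaps = []
    for i in range(n):
        d_plus = math.sqrt(sum((v[i][j] - best[j]) ** 2 for j in range(m)))
        d_minus = math.sqrt(sum((v[i][j] - worst[j]) ** 2 for j in range(m)))
        gaps.append(0.5 if d_plus + d_minus == 0 else d_plus / (d_plus + d_minus))
    return gaps
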