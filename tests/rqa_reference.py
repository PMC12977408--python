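"""Exhaustive O(N^2) reference implementation of RR and %DET.

Deliberately naive (explicit loops over every (i, j) pair and every
diagonal) so it can serve as an oracle for the vectorized implementation.
Distances are evaluated in float32, matching the implementation under test,
so the comparison can be exact.
"""

import numpy as np


def rqa_reference(values, eps, lmin, theiler):
    """Return (rr, pct_det) computed from first principles."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)].astype(np.float32)
    n = v.size
    eps = np.float32(eps)
    rec = np.zeros((n, n), dtype=bool)
    n_rec = 0
    for i in range(n):
        for j in range(n):
            if abs(i - j) < theiler:
                continue
            if np.float32(abs(v[i] - v[j])) <= eps:
                rec[i, j] = True
                n_rec += 1
    det = 0
    for k in range(max(theiler, 1), n):
        for sign in (1, -1):
            run = 0
            for i in range(n - k):
                a, b = (i, i + k) if sign == 1 else (i + k, i)
                if rec[a, b]:
                    run += 1
                else:
                    if run >= lmin:
                        det += run
                    run = 0
            if run >= lmin:
                det += run
    excluded = n + 2 * sum(n - k for k in range(1, theiler))
    total = n * n - excluded
    rr = n_rec / total
    pct_det = det / n_rec if n_rec else float("nan")
    return rr, pct_det
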