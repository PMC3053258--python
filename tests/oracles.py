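"""Independent brute-force oracles used by the test suite.

These recompute reference results by exhaustive enumeration or direct
summation, independently of the package's optimized code paths.
"""

from functools import lru_cache

import numpy as np

from plantpin.folding import MIN_LOOP, _PAIR_E, encode, structure_energy


def enumerate_structures(sequence: str):
    """All nested secondary structures (min hairpin loop 3) of a short sequence."""
    enc = encode(sequence)
    n = len(sequence)

    def pairable(i, j):
        return np.isfinite(_PAIR_E[enc[i], enc[j]])

    @lru_cache(maxsize=None)
    def gen(i, j):
        if j - i < 0:
            return ("",)
        out = ["." + s for s in gen(i + 1, j)]
        for k in range(i + MIN_LOOP + 1, j + 1):
            if pairable(i, k):
                for inner in gen(i + 1, k - 1):
                    for rest in gen(k + 1, j):
                        out.append("(" + inner + ")" + rest)
        return tuple(out)

    return gen(0, n - 1)


def bruteforce_fold(sequence: str):
    """Minimum-energy structure by exhaustive enumeration; ties broken by
    the lexicographically smallest dot-bracket string."""
    scored = [(structure_energy(sequence, s), s) for s in enumerate_structures(sequence)]
    best_e = min(e for e, _ in scored)
    best_s = min(s for e, s in scored if abs(e - best_e) < 1e-6)
    return best_e, best_s


def bruteforce_ks(x, y):
    """sup |ECDF_x - ECDF_y| by direct evaluation at every sample point."""
    pts = sorted(set(x) | set(y))
    d = 0.0
    for t in pts:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        d = max(d, abs(fx - fy))
    return d
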