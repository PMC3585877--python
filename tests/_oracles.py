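"""Independent brute-force oracles used only by the test suite.

Each oracle re-implements a pipeline computation by direct enumeration,
sharing nothing with the implementation path it checks (beyond the pinned
tie-break and tolerance conventions that define the quantity itself).
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

#: the same pinned relative tolerance the Fisher implementation uses when
#: judging "probability does not exceed the observed table's".
FISHER_REL_TOL = Fraction(10**7 + 1, 10**7)


def threshold_oracle(values, labels):
    """Exhaustive search for the min-error max-margin threshold.

    Enumerates every candidate cut (midpoints of adjacent distinct sorted
    values plus +-infinity) under both orientations and minimises the
    lexicographic key (errors, -margin, cut, orientation rank) with
    low_is_responder ranked first.  Returns (errors, margin, cut, orientation).
    """
    vs = sorted(set(values))
    cuts = (
        [-math.inf]
        + [0.5 * (a + b) for a, b in zip(vs, vs[1:])]
        + [math.inf]
    )
    best = None
    for orient_rank, orient in enumerate(["low_is_responder", "high_is_responder"]):
        for cut in cuts:
            if orient == "low_is_responder":
                preds = [v < cut for v in values]
            else:
                preds = [v > cut for v in values]
            errors = sum(p != bool(l) for p, l in zip(preds, labels))
            if math.isinf(cut):
                margin = 0.0
            else:
                margin = min(abs(v - cut) for v in values)
            # mirror the pinned tie-break convention: margins compare at
            # 1e-9 resolution so float noise cannot decide between cuts
            key = (errors, -round(margin, 9), cut, orient_rank)
            if best is None or key < best:
                best = key
    errors, neg_margin, cut, orient_rank = best
    orient = "low_is_responder" if orient_rank == 0 else "high_is_responder"
    return errors, -neg_margin, cut, orient


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact-rational enumeration of all tables.

    Enumerates every table with the observed margins, computes each
    hypergeometric probability as an exact Fraction, and sums those whose
    probability is <= the observed one under the pinned 1e-7 relative
    tolerance.  Returns a float.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def num(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x)

    cutoff = Fraction(num(a)) * FISHER_REL_TOL
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if Fraction(num(x)) <= cutoff:
            total += Fraction(num(x), denom)
    return float(min(total, Fraction(1)))


def mwu_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (no ties).

    Enumerates every assignment of the pooled ranks to the first sample
    and counts assignments whose U deviates from the null centre
    n_x*n_y/2 at least as much as the observed U.
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled + list(x) + list(y))) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    n1, n2 = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    centre = n1 * n2 / 2
    dev = abs(u_obs - centre)
    count = 0
    total = 0
    all_ranks = list(range(1, n1 + n2 + 1))
    for subset in itertools.combinations(all_ranks, n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        if abs(u - centre) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total
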