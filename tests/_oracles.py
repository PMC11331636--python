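"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's closed-form routines: probabilities
are obtained by enumerating the joint stage-1/stage-2 outcome space, and
binomial terms come from exact rational arithmetic where tolerances demand
it. Keep them slow and obvious.
"""

from fractions import Fraction
from math import comb

from scipy.stats import binom as _binom


def exact_pmf(k: int, n: int, p: Fraction) -> Fraction:
    return comb(n, k) * p**k * (1 - p) ** (n - k)


def exact_cdf(k: int, n: int, p: Fraction) -> Fraction:
    return sum(exact_pmf(i, n, p) for i in range(k + 1))


def joint_enumeration(r1: int, n1: int, r: int, n: int, p: float):
    """Partition the outcome space of a two-stage trial by enumeration.

    Returns (stop, continue_reject, continue_accept): the probabilities of
    stopping at stage 1, of continuing and rejecting (x1 > r1 and x > r),
    and of continuing and accepting.
    """
    n2 = n - n1
    stop = cont_reject = cont_accept = 0.0
    for x1 in range(n1 + 1):
        p1 = float(_binom.pmf(x1, n1, p))
        if x1 <= r1:
            stop += p1
            continue
        for x2 in range(n2 + 1):
            joint = p1 * float(_binom.pmf(x2, n2, p))
            if x1 + x2 > r:
                cont_reject += joint
            else:
                cont_accept += joint
    return stop, cont_reject, cont_accept


def brute_force_reject(r1: int, n1: int, r: int, n: int, p: float) -> float:
    return joint_enumeration(r1, n1, r, n, p)[1]
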