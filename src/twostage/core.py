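"""Exact probability calculations for two-stage binomial designs.

A two-stage design ``(r1, n1, r, n)`` evaluates ``n1`` subjects at an interim
look, stops for futility if the observed response count ``x1 <= r1``, and
otherwise continues to a total of ``n`` subjects, rejecting the null
hypothesis when the total response count ``x > r``.

All quantities are computed with the exact binomial distribution; no normal
approximation is used anywhere. Binomial terms are evaluated through scipy's
log-space implementation, which is stable for sample sizes well beyond 500.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import binom as _binom

__all__ = [
    "DesignParams",
    "TwoStageDesign",
    "OperatingCharacteristics",
    "DegenerateRuleWarning",
    "binom_pmf",
    "binom_cdf",
    "pet",
    "reject_probability",
    "type1_error",
    "expected_sample_size",
    "alpha_no_stop",
    "operating_characteristics",
    "interim_pvalue_threshold",
]


class DegenerateRuleWarning(UserWarning):
    """Raised when a futility rule stops the trial with certainty."""


def _check_probability(name: str, value: float, *, open_interval: bool = False) -> None:
    lo_ok = value > 0 if open_interval else value >= 0
    hi_ok = value < 1 if open_interval else value <= 1
    if not (lo_ok and hi_ok):
        bounds = "(0, 1)" if open_interval else "[0, 1]"
        raise ValueError(f"{name} must lie in {bounds}, got {value!r}")


@dataclass(frozen=True)
class DesignParams:
    """The one-sided test problem H0: p <= p0 vs H1: p > p0.

    Parameters
    ----------
    p0 : float
        Highest response rate at which the treatment is deemed unsuccessful.
    pa : float
        Lowest response rate warranting further study; must exceed ``p0``.
    alpha : float
        Targeted one-sided nominal significance level.
    beta : float
        Targeted type II error rate (power target is ``1 - beta``).
    """

    p0: float
    pa: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _check_probability("p0", self.p0, open_interval=True)
        _check_probability("pa", self.pa, open_interval=True)
        if not self.p0 < self.pa:
            raise ValueError(f"p0 must be < pa, got p0={self.p0!r}, pa={self.pa!r}")
        _check_probability("alpha", self.alpha, open_interval=True)
        _check_probability("beta", self.beta, open_interval=True)


@dataclass(frozen=True)
class TwoStageDesign:
    """A design tuple (r1, n1, r, n).

    Stop for futility after stage 1 if ``x1 <= r1`` out of ``n1``; otherwise
    continue to ``n`` subjects total and reject H0 if ``x > r``.
    """

    r1: int
    n1: int
    r: int
    n: int

    def __post_init__(self) -> None:
        for name in ("r1", "n1", "r", "n"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
        if not 1 <= self.n1 < self.n:
            raise ValueError(f"need 1 <= n1 < n, got n1={self.n1}, n={self.n}")
        if not 0 <= self.r1 <= self.n1:
            raise ValueError(f"need 0 <= r1 <= n1, got r1={self.r1}, n1={self.n1}")
        if not self.r1 <= self.r <= self.n:
            raise ValueError(f"need r1 <= r <= n, got r1={self.r1}, r={self.r}, n={self.n}")

    @property
    def n2(self) -> int:
        """Stage-2 sample size, n - n1."""
        return self.n - self.n1

    def astuple(self) -> tuple[int, int, int, int]:
        return (self.r1, self.n1, self.r, self.n)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """The reported performance measures of a two-stage design.

    ``alpha_d`` is the attained type I error with the futility rule enforced;
    ``alpha_no_stop`` is the type I error of the final test when the rule is
    ignored and the trial always proceeds to stage 2. ``power_d`` is the
    attained power ``1 - beta_d`` under ``pa``.
    """

    ratio: float
    pet_pa: float
    pet_p0: float
    alpha_d: float
    alpha_no_stop: float
    power_d: float
    en_p0: float
    en_pa: float
    n_max: int

    def __post_init__(self) -> None:
        for name in ("ratio", "pet_pa", "pet_p0", "alpha_d", "alpha_no_stop", "power_d"):
            _check_probability(name, getattr(self, name))


def binom_pmf(k: int, n: int, p: float) -> float:
    """Exact binomial probability mass C(n,k) p^k (1-p)^(n-k)."""
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in 0..n, got k={k}, n={n}")
    _check_probability("p", p)
    return float(_binom.pmf(k, n, p))


def binom_cdf(k: int, n: int, p: float) -> float:
    """Cumulative binomial probability P(X <= k).

    ``k = -1`` denotes the empty sum and returns 0; ``k > n`` is an error.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if k > n:
        raise ValueError(f"k must be <= n, got k={k}, n={n}")
    _check_probability("p", p)
    if k < 0:
        return 0.0
    return float(_binom.cdf(k, n, p))


def pet(design: TwoStageDesign, p: float) -> float:
    """Probability of early termination, B(r1, n1, p)."""
    return binom_cdf(design.r1, design.n1, p)


def reject_probability(design: TwoStageDesign, p: float) -> float:
    """Probability of rejecting H0 under the two-stage rule at true rate p.

    Sums ``b(i, n1, p) * P(x > r | x1 = i)`` over all continuation outcomes
    ``i > r1``. For ``i > r`` the stage-1 count alone already exceeds the
    rejection threshold, so the conditional factor is 1 (equivalently,
    ``1 - B(r - i, n2, p)`` with the empty-sum convention ``B(k<0) = 0``).
    """
    _check_probability("p", p)
    r1, n1, r, n = design.astuple()
    n2 = design.n2
    total = 0.0
    for i in range(r1 + 1, n1 + 1):
        tail = 1.0 if r - i < 0 else float(_binom.sf(r - i, n2, p))
        total += float(_binom.pmf(i, n1, p)) * tail
    return total


def type1_error(design: TwoStageDesign, p0: float) -> float:
    """Attained type I error: 1 - P(stop early) - P(continue and accept).

    Algebraically identical to ``reject_probability(design, p0)``; both
    forms are kept because they partition the outcome space differently.
    """
    _check_probability("p0", p0)
    r1, n1, r, n = design.astuple()
    n2 = design.n2
    accept = binom_cdf(r1, n1, p0)
    for i in range(r1 + 1, min(n1, r) + 1):
        # r - i may exceed n2, in which case acceptance is certain given x1=i
        accept += float(_binom.pmf(i, n1, p0)) * binom_cdf(min(r - i, n2), n2, p0)
    return 1.0 - accept


def expected_sample_size(design: TwoStageDesign, p: float) -> float:
    """EN(p) = n1 + (1 - PET(p)) * (n - n1)."""
    return design.n1 + (1.0 - pet(design, p)) * design.n2


def alpha_no_stop(design: TwoStageDesign, p0: float) -> float:
    """Type I error of the final test x > r when the futility rule is ignored."""
    _check_probability("p0", p0)
    return float(_binom.sf(design.r, design.n, p0))


def operating_characteristics(
    design: TwoStageDesign, params: DesignParams
) -> OperatingCharacteristics:
    """Compute all reported operating characteristics of a design."""
    return OperatingCharacteristics(
        ratio=design.n1 / design.n,
        pet_pa=pet(design, params.pa),
        pet_p0=pet(design, params.p0),
        alpha_d=type1_error(design, params.p0),
        alpha_no_stop=alpha_no_stop(design, params.p0),
        power_d=reject_probability(design, params.pa),
        en_p0=expected_sample_size(design, params.p0),
        en_pa=expected_sample_size(design, params.pa),
        n_max=design.n,
    )


def interim_pvalue_threshold(design: TwoStageDesign, p0: float) -> float:
    """p-value-scale futility boundary equivalent to the count rule x1 <= r1.

    The interim p-value for an observed stage-1 count ``x1`` is the
    upper-tail exact binomial probability ``P(X1 >= x1 | p0)``. The returned
    threshold ``a0`` is the p-value of ``x1 = r1 + 1``, so that stopping when
    ``p_interim > a0`` reproduces the count rule exactly for every ``x1``.

    Note: the upper-tail p-value convention is a documented implementation
    choice; both rule formalisms are interconvertible under it.
    """
    if design.r1 == design.n1:
        warnings.warn(
            "r1 = n1: the futility rule stops the trial with certainty",
            DegenerateRuleWarning,
            stacklevel=2,
        )
    _check_probability("p0", p0)
    # P(X1 >= r1 + 1) = 1 - B(r1, n1, p0)
    return float(_binom.sf(design.r1, design.n1, p0))


def interim_pvalue(x1: int, n1: int, p0: float) -> float:
    """Upper-tail exact binomial interim p-value P(X1 >= x1 | p0)."""
    if not 0 <= x1 <= n1:
        raise ValueError(f"x1 must lie in 0..n1, got x1={x1}, n1={n1}")
    _check_probability("p0", p0)
    return float(_binom.sf(x1 - 1, n1, p0))
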