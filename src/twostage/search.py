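"""Exhaustive-search derivation of two-stage binomial designs.

Implements the single-stage exact binomial design, Simon's optimal and
minimax designs, Kim's modified variants (which add a bound on the
probability of wrongly stopping for futility and a window for the interim
fraction n1/n), and the optimized-futility-boundary design that fixes
(n, r) at the single-stage values and maximizes the probability of
correctly stopping for futility subject to admissible constraints.

The Simon/Kim searches enumerate every tuple (r1, n1, r, n) up to n_max.
Internally the enumeration is vectorized per (n, n1) pair: the rejection
probability of every (r1, r) combination is obtained from one reverse
cumulative sum of the matrix b(i, n1, p) * (1 - B(r - i, n2, p)). Results
are identical to the scalar routines in :mod:`twostage.core` (tested), just
faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterator, Literal, Mapping

import numpy as np
from scipy.stats import binom as _binom

from .core import (
    DesignParams,
    OperatingCharacteristics,
    TwoStageDesign,
    operating_characteristics,
)

__all__ = [
    "AdmissibleConstraints",
    "SearchConfig",
    "DesignCatalog",
    "InfeasibleSearchError",
    "single_stage_design",
    "enumerate_feasible_designs",
    "simon_optimal",
    "simon_minimax",
    "kim_modified",
    "optimized_futility_design",
    "default_n_max",
    "build_catalog",
]

SINGLE_STAGE_CAP = 1000

DESIGN_FAMILIES = (
    "single_stage",
    "simon_optimal",
    "simon_minimax",
    "kim_optimal",
    "kim_minimax",
    "optimized",
)


class InfeasibleSearchError(Exception):
    """No design satisfies the requested constraints.

    ``constraint`` names the first constraint that emptied the candidate set,
    to support CLI diagnostics.
    """

    def __init__(self, message: str, constraint: str):
        super().__init__(message)
        self.constraint = constraint


def _as_fraction(value) -> Fraction:
    """Normalize a ratio bound given as Fraction, string ('1/3') or float.

    Floats are snapped to the nearest small-denominator rational so that
    e.g. ``1/3`` given in floating point compares exactly against integer
    cross-multiplication.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, int):
        return Fraction(value)
    return Fraction(value).limit_denominator(10**6)


@dataclass(frozen=True)
class AdmissibleConstraints:
    """Bounds defining the admissible set for the constrained searches.

    ``pow_loss`` is the acceptable overall power loss relative to the
    single-stage power target; ``pi_wrong`` the upper bound on the
    probability of wrongly stopping for futility PET(pa); ``ratio_lower`` /
    ``ratio_upper`` bound the interim fraction n1/n (inclusive);
    ``pet_pa_bound_kim`` is the looser wrong-stop bound used by the Kim
    variants (0.1 by default).
    """

    pow_loss: float = 0.05
    pi_wrong: float = 0.05
    ratio_lower: Fraction = Fraction(1, 3)
    ratio_upper: Fraction = Fraction(2, 3)
    pet_pa_bound_kim: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.pow_loss < 1:
            raise ValueError(f"pow_loss must lie in [0, 1), got {self.pow_loss!r}")
        if not 0 <= self.pi_wrong <= 1:
            raise ValueError(f"pi_wrong must lie in [0, 1], got {self.pi_wrong!r}")
        if not 0 <= self.pet_pa_bound_kim <= 1:
            raise ValueError(
                f"pet_pa_bound_kim must lie in [0, 1], got {self.pet_pa_bound_kim!r}"
            )
        lo = _as_fraction(self.ratio_lower)
        hi = _as_fraction(self.ratio_upper)
        if not 0 < lo < hi < 1:
            raise ValueError(
                f"need 0 < ratio_lower < ratio_upper < 1, got {lo} and {hi}"
            )
        object.__setattr__(self, "ratio_lower", lo)
        object.__setattr__(self, "ratio_upper", hi)

    def validate_against(self, params: DesignParams) -> None:
        """Check the power-loss bound against the test problem's beta."""
        if not self.pow_loss < 1 - params.beta:
            raise ValueError(
                f"pow_loss must be < 1 - beta = {1 - params.beta}, got {self.pow_loss!r}"
            )


@dataclass(frozen=True)
class SearchConfig:
    """Search plumbing: enumeration bound and tie-break policy.

    ``n_max=None`` resolves to ``max(100, 2 * single-stage n)`` for the
    parameters at hand. The only implemented tie-break policy is
    ``"default"``: optimal-type searches break EN(p0) ties by minimal n,
    then n1, then r1, then r; minimax-type searches break n ties by minimal
    EN(p0), then n1, then r1, then r; the optimized search breaks PET(p0)
    ties by minimal n1, then r1.
    """

    n_max: int | None = None
    tie_break_policy: Literal["default"] = "default"

    def __post_init__(self) -> None:
        if self.n_max is not None and self.n_max < 2:
            raise ValueError(f"n_max must be >= 2, got {self.n_max!r}")
        if self.tie_break_policy != "default":
            raise ValueError(f"unknown tie_break_policy {self.tie_break_policy!r}")

    def resolve_n_max(self, params: DesignParams) -> int:
        if self.n_max is not None:
            return self.n_max
        return default_n_max(params)


def default_n_max(params: DesignParams) -> int:
    """Default enumeration bound: max(100, twice the single-stage n)."""
    n_single, _ = single_stage_design(params)
    return max(100, 2 * n_single)


def single_stage_design(params: DesignParams) -> tuple[int, int]:
    """Smallest single-stage exact binomial design (n, r).

    Returns the smallest ``n`` for which some critical value ``r`` gives a
    one-sided level-``alpha`` test (reject when ``x > r``) with power at
    least ``1 - beta`` at ``pa``; ``r`` is the smallest value meeting the
    alpha condition at that ``n`` (which maximizes power among valid r).
    """
    for n in range(1, SINGLE_STAGE_CAP + 1):
        r_grid = np.arange(n + 1)
        level_ok = _binom.sf(r_grid, n, params.p0) <= params.alpha
        if not level_ok.any():
            continue
        r = int(r_grid[level_ok][0])
        if float(_binom.sf(r, n, params.pa)) >= 1 - params.beta:
            return n, r
    raise InfeasibleSearchError(
        f"no single-stage design with n <= {SINGLE_STAGE_CAP} attains "
        f"alpha={params.alpha} and power {1 - params.beta}",
        constraint="single_stage_cap",
    )


def _ratio_in_bounds(n1: int, n: int, lo: Fraction, hi: Fraction) -> bool:
    # integer cross-multiplication; inclusive on both sides
    return (
        n1 * lo.denominator >= n * lo.numerator
        and n1 * hi.denominator <= n * hi.numerator
    )


def _stage_matrices(n1: int, n: int, p: float) -> np.ndarray:
    """Rejection probability of every (r1, r) pair for fixed (n1, n).

    Returns ``R`` of shape ``(n1 + 1, n + 1)`` with
    ``R[r1, r] = sum_{i=r1+1}^{n1} b(i, n1, p) * (1 - B(r - i, n2, p))``,
    using the convention ``B(k < 0) = 0`` (stage-1 counts already above r
    reject outright).
    """
    n2 = n - n1
    i = np.arange(n1 + 1)
    r = np.arange(n + 1)
    pmf1 = _binom.pmf(i, n1, p)
    # survival of stage-2 count: P(X2 > k) for k = 0..n2; k < 0 -> 1
    sf2 = _binom.sf(np.arange(n2 + 1), n2, p)
    k = r[None, :] - i[:, None]
    tail = np.where(k < 0, 1.0, sf2[np.clip(k, 0, n2)])
    terms = pmf1[:, None] * tail
    # R[r1] sums rows r1+1..n1
    rev = np.cumsum(terms[::-1], axis=0)[::-1]
    out = np.zeros((n1 + 1, n + 1))
    out[:n1, :] = rev[1:, :]
    return out


def enumerate_feasible_designs(
    params: DesignParams, n_max: int
) -> Iterator[TwoStageDesign]:
    """Yield every feasible tuple (r1, n1, r, n) with n <= n_max.

    Feasible means attained type I error <= alpha and power >= 1 - beta,
    both exact. Deterministic order: n ascending, then n1, r1, r ascending.
    """
    if n_max < 2:
        raise ValueError(f"n_max must be >= 2, got {n_max!r}")
    pow_target = 1 - params.beta
    for n in range(2, n_max + 1):
        for n1 in range(1, n):
            alpha_mat = _stage_matrices(n1, n, params.p0)
            power_mat = _stage_matrices(n1, n, params.pa)
            feasible = (alpha_mat <= params.alpha) & (power_mat >= pow_target)
            if not feasible.any():
                continue
            for r1 in range(n1 + 1):
                row = feasible[r1]
                for r in range(r1, n + 1):
                    if row[r]:
                        yield TwoStageDesign(r1=r1, n1=n1, r=r, n=n)


@lru_cache(maxsize=64)
def _sweep(
    params: DesignParams,
    n_max: int,
    pet_pa_bound: float | None,
    ratio_lower: Fraction | None,
    ratio_upper: Fraction | None,
) -> Mapping[str, TwoStageDesign | None]:
    """One pass over all (n, n1) finding the optimal and minimax designs.

    Applies the optional Kim-style constraints (wrong-stop bound, interim
    ratio window) before the selection criteria. Returns a dict with keys
    ``"optimal"`` and ``"minimax"`` (None where the feasible set is empty)
    plus diagnostic flags recording which constraint emptied the set.
    """
    pow_target = 1 - params.beta
    best_opt: tuple | None = None  # (en, n, n1, r1, r)
    best_mm: tuple | None = None  # (n, en, n1, r1, r)
    mm_done = False
    saw_feasible_base = False
    saw_ratio_ok = False

    for n in range(2, n_max + 1):
        if best_mm is not None and n > best_mm[0]:
            mm_done = True
        for n1 in range(1, n):
            ratio_ok = (
                ratio_lower is None
                or _ratio_in_bounds(n1, n, ratio_lower, ratio_upper)
            )
            if ratio_ok and ratio_lower is not None:
                saw_ratio_ok = True
            # EN(p0) >= n1 for any design, so n1 beyond the incumbent EN
            # cannot improve the optimal criterion
            opt_can_improve = best_opt is None or n1 < best_opt[0]
            want_opt = opt_can_improve and ratio_ok
            want_mm = (not mm_done) and ratio_ok
            if not (want_opt or want_mm):
                continue

            alpha_mat = _stage_matrices(n1, n, params.p0)
            power_mat = _stage_matrices(n1, n, params.pa)
            feasible = (alpha_mat <= params.alpha) & (power_mat >= pow_target)
            # r < r1 violates the design invariant
            r_grid = np.arange(n + 1)
            feasible &= r_grid[None, :] >= np.arange(n1 + 1)[:, None]
            if not feasible.any():
                continue
            if ratio_lower is not None:
                saw_feasible_base = True

            pet_p0 = _binom.cdf(np.arange(n1 + 1), n1, params.p0)
            if pet_pa_bound is not None:
                pet_pa = _binom.cdf(np.arange(n1 + 1), n1, params.pa)
                feasible &= (pet_pa <= pet_pa_bound)[:, None]
                if not feasible.any():
                    continue

            en = n1 + (1.0 - pet_p0) * (n - n1)
            rows = np.flatnonzero(feasible.any(axis=1))
            for r1 in rows:
                r = int(np.argmax(feasible[r1]))  # smallest feasible r
                cand_opt = (float(en[r1]), n, n1, int(r1), r)
                if want_opt and (best_opt is None or cand_opt < best_opt):
                    best_opt = cand_opt
                cand_mm = (n, float(en[r1]), n1, int(r1), r)
                if want_mm and (best_mm is None or cand_mm < best_mm):
                    best_mm = cand_mm

    def _mk(key: tuple | None, kind: str) -> TwoStageDesign | None:
        if key is None:
            return None
        if kind == "optimal":
            _, n, n1, r1, r = key
        else:
            n, _, n1, r1, r = key
        return TwoStageDesign(r1=r1, n1=n1, r=r, n=n)

    return {
        "optimal": _mk(best_opt, "optimal"),
        "minimax": _mk(best_mm, "minimax"),
        "saw_feasible_base": saw_feasible_base,
        "saw_ratio_ok": saw_ratio_ok,
    }


def _unconstrained_has_feasible(params: DesignParams, n_max: int) -> bool:
    res = _sweep(params, n_max, None, None, None)
    return res["optimal"] is not None


def simon_optimal(
    params: DesignParams, config: SearchConfig = SearchConfig()
) -> TwoStageDesign:
    """Feasible design minimizing the expected sample size under the null."""
    n_max = config.resolve_n_max(params)
    design = _sweep(params, n_max, None, None, None)["optimal"]
    if design is None:
        raise InfeasibleSearchError(
            f"no feasible two-stage design with n <= {n_max} for {params}",
            constraint="n_max",
        )
    return design


def simon_minimax(
    params: DesignParams, config: SearchConfig = SearchConfig()
) -> TwoStageDesign:
    """Feasible design with minimal total n; EN(p0) breaks ties."""
    n_max = config.resolve_n_max(params)
    design = _sweep(params, n_max, None, None, None)["minimax"]
    if design is None:
        raise InfeasibleSearchError(
            f"no feasible two-stage design with n <= {n_max} for {params}",
            constraint="n_max",
        )
    return design


def kim_modified(
    params: DesignParams,
    constraints: AdmissibleConstraints = AdmissibleConstraints(),
    config: SearchConfig = SearchConfig(),
    variant: Literal["optimal", "minimax"] = "optimal",
) -> TwoStageDesign:
    """Simon-type search with wrong-stop and interim-fraction constraints.

    Filters the feasible tuples by ``PET(pa) <= pet_pa_bound_kim`` and
    ``ratio_lower <= n1/n <= ratio_upper`` (inclusive, checked by integer
    cross-multiplication), then applies the Simon optimal or minimax
    selection criterion.
    """
    if variant not in ("optimal", "minimax"):
        raise ValueError(f"variant must be 'optimal' or 'minimax', got {variant!r}")
    n_max = config.resolve_n_max(params)
    res = _sweep(
        params,
        n_max,
        constraints.pet_pa_bound_kim,
        constraints.ratio_lower,
        constraints.ratio_upper,
    )
    design = res[variant]
    if design is None:
        if not _unconstrained_has_feasible(params, n_max):
            binding = "n_max"
        elif not res["saw_feasible_base"]:
            binding = "ratio_bounds"
        else:
            binding = "pet_pa_bound_kim"
        raise InfeasibleSearchError(
            f"no feasible constrained design with n <= {n_max} for {params}; "
            f"binding constraint: {binding}",
            constraint=binding,
        )
    return design


def optimized_futility_design(
    params: DesignParams,
    constraints: AdmissibleConstraints = AdmissibleConstraints(),
) -> TwoStageDesign:
    """Futility boundary maximizing PET(p0) around a fixed single-stage test.

    (n, r) are taken from :func:`single_stage_design` and never adjusted, so
    the resulting futility rule is valid as a non-binding rule: ignoring it
    cannot inflate the type I error above alpha. Over all (n1, r1) with the
    interim fraction inside the ratio window, PET(pa) <= pi_wrong, and
    two-stage power >= 1 - beta - pow_loss, the pair maximizing PET(p0) is
    returned (ties: minimal n1, then minimal r1).
    """
    constraints.validate_against(params)
    n, r = single_stage_design(params)
    lo, hi = constraints.ratio_lower, constraints.ratio_upper
    pow_floor = 1 - params.beta - constraints.pow_loss

    n1_values = [n1 for n1 in range(1, n) if _ratio_in_bounds(n1, n, lo, hi)]
    if not n1_values:
        raise InfeasibleSearchError(
            f"no stage-1 size n1 satisfies {lo} <= n1/{n} <= {hi}",
            constraint="ratio_bounds",
        )

    best: tuple | None = None  # (-pet_p0, n1, r1)
    saw_pet_ok = False
    for n1 in n1_values:
        pet_pa = _binom.cdf(np.arange(n1 + 1), n1, params.pa)
        power = _stage_matrices(n1, n, params.pa)[:, r]
        admissible = (pet_pa <= constraints.pi_wrong) & (power >= pow_floor)
        admissible &= np.arange(n1 + 1) <= r  # design invariant r1 <= r
        if (pet_pa <= constraints.pi_wrong).any():
            saw_pet_ok = True
        if not admissible.any():
            continue
        # PET(p0) increases in r1, so only the largest admissible r1 can win;
        # admissible r1 form a prefix 0..r1_max (pet_pa rises and power falls
        # in r1), hence the last True entry.
        r1 = int(np.flatnonzero(admissible)[-1])
        pet_p0 = float(_binom.cdf(r1, n1, params.p0))
        cand = (-pet_p0, n1, r1)
        if best is None or cand < best:
            best = cand
    if best is None:
        binding = "pow_loss" if saw_pet_ok else "pi_wrong"
        raise InfeasibleSearchError(
            f"no admissible (n1, r1) for fixed (n, r) = ({n}, {r}); "
            f"binding constraint: {binding}",
            constraint=binding,
        )
    _, n1, r1 = best
    return TwoStageDesign(r1=r1, n1=n1, r=r, n=n)


@dataclass(frozen=True)
class DesignCatalog:
    """All derived designs for one test problem, with their characteristics.

    ``entries`` maps a design-family name to a pair
    ``(design, OperatingCharacteristics)``; the single-stage entry stores
    the pair ``(r, n)`` in a degenerate one-stage representation
    ``(r1=-1 is not allowed, so it is kept as the raw tuple)``.
    """

    params: DesignParams
    constraints: AdmissibleConstraints
    entries: Mapping[str, tuple] = field(default_factory=dict)
    single_stage: tuple[int, int] | None = None  # (n, r)


def build_catalog(
    params: DesignParams,
    constraints: AdmissibleConstraints = AdmissibleConstraints(),
    config: SearchConfig = SearchConfig(),
) -> DesignCatalog:
    """Derive every design family for one test problem.

    Families whose searches are infeasible are recorded with the raised
    error in place of the (design, characteristics) pair.
    """
    entries: dict[str, tuple] = {}
    searches = {
        "simon_optimal": lambda: simon_optimal(params, config),
        "simon_minimax": lambda: simon_minimax(params, config),
        "kim_optimal": lambda: kim_modified(params, constraints, config, "optimal"),
        "kim_minimax": lambda: kim_modified(params, constraints, config, "minimax"),
        "optimized": lambda: optimized_futility_design(params, constraints),
    }
    for name, fn in searches.items():
        try:
            design = fn()
        except InfeasibleSearchError as err:
            entries[name] = (None, err)
        else:
            entries[name] = (design, operating_characteristics(design, params))
    return DesignCatalog(
        params=params,
        constraints=constraints,
        entries=entries,
        single_stage=single_stage_design(params),
    )
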