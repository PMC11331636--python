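# twostage

Exact two-stage binomial designs for single-arm phase II trials with binary
endpoints: Simon's optimal and minimax designs, Kim's modified variants, and
an optimized **non-binding** futility boundary that maximizes the probability
of correctly stopping for futility around a fixed single-stage test.

A design `(r1, n1, r, n)` evaluates `n1` subjects, stops for futility when
the interim response count `x1 <= r1`, and otherwise continues to `n`
subjects total, rejecting `H0: p <= p0` when the total count `x > r`. All
probabilities (type I error, power, probability of early termination,
expected sample size) are exact binomial quantities — no approximations.

The optimized futility design fixes `(n, r)` at the smallest single-stage
exact binomial design for the requested level and power, then chooses
`(n1, r1)` to maximize `PET(p0)` subject to:

- `ratio_lower <= n1/n <= ratio_upper` (default `1/3 .. 2/3`),
- `PET(pa) <= pi_wrong` (default `0.05`),
- two-stage power `>= 1 - beta - pow_loss` (default power loss `0.05`).

Because the critical boundary `r` is never adjusted to exhaust alpha,
ignoring the futility rule cannot inflate the type I error — the rule is
valid as a non-binding boundary.

## Library

```python
from twostage import (
    DesignParams, AdmissibleConstraints, SearchConfig,
    simon_optimal, simon_minimax, kim_modified,
    optimized_futility_design, operating_characteristics,
)

params = DesignParams(p0=0.25, pa=0.40, alpha=0.05, beta=0.20)
design = optimized_futility_design(params, AdmissibleConstraints())
design.astuple()                            # (10, 39, 21, 62)
operating_characteristics(design, params)   # PET, power, EN, alpha with/without stopping
```

`twostage.run_scenario_grid` derives all five design families across a
ladder of `p0` values (default `0.05 .. 0.75` step `0.05`, `pa = p0 + 0.15`)
and returns a long-format table, one row per scenario x family.

The interim futility rule can be expressed equivalently on the p-value
scale via `interim_pvalue_threshold`; the interim p-value convention is the
upper-tail exact binomial probability `P(X1 >= x1 | p0)`.

## CLI

```sh
twostage optimized    --p0 0.25 --pa 0.40 --alpha 0.05 --beta 0.20
twostage single-stage --p0 0.25 --pa 0.40
twostage simon --variant minimax --p0 0.25 --pa 0.40
twostage kim   --variant optimal --p0 0.25 --pa 0.40
twostage grid  --p0-min 0.05 --p0-max 0.75 --output table.csv --format csv
twostage verify --p0 0.25 --pa 0.40 --r1 10 --n1 39 --r 21 --n 62 \
    --simulate 100000 --seed 7
```

Outputs are `text` (default), `csv`, or `json` via `--format`; `--output`
writes to a file. A flat key-value YAML config file can pre-set any flag
(`twostage --config run.yaml optimized`); explicit flags win. Exit codes:
`0` success, `2` argument error, `3` infeasible search. `-v` enables search
traces, `-q` silences progress.

Grid CSV columns (fixed order): `p0, pa, alpha, beta, design, r1, n1, r, n,
ratio, pet_p0, pet_pa, alpha_d, alpha_no_stop, power_d, en_p0, en_pa,
status`. Infeasible cells are kept with `status=infeasible:<constraint>`.

## Conventions

- Feasibility uses non-strict inequalities: type I error `<= alpha`, power
  `>= 1 - beta`.
- Ratio bounds are inclusive and checked by integer cross-multiplication;
  float bounds are snapped to nearest small-denominator rationals.
- Tie-breaks are deterministic: optimal-type searches minimize `EN(p0)`,
  then `n`, `n1`, `r1`, `r`; minimax-type searches minimize `n`, then
  `EN(p0)`, `n1`, `r1`, `r`; the optimized search maximizes `PET(p0)`,
  breaking ties toward smaller `n1`, then `r1`.
- The Simon/Kim enumeration bound defaults to `max(100, 2x single-stage n)`
  and is overridable via `SearchConfig(n_max=...)` / `--n-max`.
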