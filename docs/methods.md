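# Methods

## Model

The multistage model treats each of `C` at-risk stem cells as an
independent lineage. Over `t` years at `k` divisions/year, each of `M`
required driver mutations arises independently with probability `u` per
division, giving a per-driver probability `x = 1 − exp(−u·k·t)` and a
lifetime risk

```
p = 1 − {1 − (1−e_c)·[(1−e_d)·x]^M}^C
```

`e_c` is the immune system's per-cell efficiency at detecting a fully
transformed cancer cell, `e_d` its per-driver efficiency at detecting a
cell carrying any driver mutation. Setting either to zero recovers the
single-policing forms; setting both recovers the basic model. We permit
both nonzero simultaneously with multiplicative semantics, although the
comparative analysis never combines them.

Assumptions inherited from the model: all drivers share one rate `u`
(recessive loss semantics), no clonal expansion between driver hits, no
stem-cell niche structure, no time variation in `u` or `k`, and `u` and
`k` enter only through their product (so any statement about `u·k` can
be carried by either factor; MR scaling is applied through `k` to avoid
conflating it with evolved changes in `u`).

`M` is real-valued in evaluation so the added-drivers solver can report
fractional ΔM; the forward calibration always selects integer `M`.

## Numerical choices

All probability arithmetic runs in log space: the per-cell risk is
`exp(log1p(−e_c) + M·log((1−e_d)·x))` and the cohort risk
`−expm1(C·log1p(−q))`. Naive powers fail at whale scale (`C ≈ 7.5×10¹¹`
with `q ≈ 10⁻¹⁴`). Tests compare against literal-form oracles evaluated
in 60-digit arithmetic (mpmath) at 10⁻¹² relative tolerance.

The small-risk approximation `p ≈ C·(u·k·t)^M` carries a leading
relative error of `M·u·k·t/2` (from `x < u·k·t`) plus `p/2` (from the
outer expansion); it is within 1% of the exact form only when
`M·u·k·t ≲ 0.015`, and the test suite asserts exactly that bound rather
than a blanket claim.

Inversions are closed-form: with `q = 1 − (1−p_target)^(1/C)` (computed
via `expm1`/`log1p`),

- mutation rate: `u = −log(1 − q^(1/M)) / (k·t)`
- total drivers: `M′ = ln q / ln x`
- cancer-cell escape: `1−e_c = q / x^M` (log-space)
- per-driver escape: `1−e_d = q^(1/M) / x`

Each solution is re-inserted into the exact risk equation and the
achieved risk stored; tests require agreement with the target to 10⁻⁶
absolute (10⁻⁹ relative for calibration). An independent bracketed
root-finder (`scipy.optimize.brentq` in `log₁₀ u` over [−15, −2], and
analogous brackets for `M`, `e_c`, `e_d`) cross-checks every closed
form; it is a check, never the implementation.

Calibration's tie-break (two integer `M` equidistant from the `u`
anchor on the log scale) goes to the smaller `M`; no study input
triggers it. The mouse cell count is carried at full precision
(2×10⁸/3000 = 66,666.67), never rounded to an integer.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| species masses | 0.02 / 60 / 150,000 kg | mouse, human, blue whale |
| lifespans `t` | 2 / 80 / 90 yr | exposure horizons |
| colorectal | `C=2×10⁸`, `k=73`/yr | human stem-cell compartment |
| hepatocellular | `C=3.01×10⁸`, `k=0.9125`/yr | " |
| esophageal | `C=6.6528×10⁶`, `k=33.2`/yr | " |
| `beta` | 0, −0.15, −0.3 | MR exponent applied to `k` via mass ratio |
| `p_target` | 0.01 | hypothetical mouse lifetime risk anchor |
| `u_anchor` | 10⁻⁵/division | target for the calibrated mutation rate |
| `M_max` | 10 | upper bound of the integer-M search |

The human is the reference species: its `C` and `k` are the measured
values and both the mouse and the whale are derived from it by mass
ratio (count) and mass-ratio^beta (rate). Writing MR scaling against
cell-count ratios instead of mass ratios is numerically identical here
because tissue size is proportional to body mass; the constant is
absorbed in the reference rate.

## Simulation

`simulate.simulate_cohort` realizes the model's generative reading: per
cell and per driver, the acquisition division is a geometric waiting
time with success probability `u` (exactly the per-division Bernoulli
process, vectorized so cost is independent of the division count);
acquired drivers then each escape detection with probability `1−e_d`
and a fully transformed cell escapes with `1−e_c`. A replicate cohort
develops cancer if any cell completes the process; the empirical
incidence across replicates is compared with the analytic `p`.

The Bernoulli-per-division process differs from the exponential form by
O(u) in the per-driver probability (`1−(1−u)^n` vs `1−exp(−u·n)`); at
the tested `u ≤ 2×10⁻³` this bias is far below Monte Carlo noise. The
standard error uses an Agresti–Coull-style adjusted proportion
`(cancers+2)/(replicates+4)` so saturated runs keep a usable band.

The random-scenario generator samples `C ∈ [200, 3000]` and
`u ∈ [2×10⁻⁴, 2×10⁻³]` log-uniformly, `M ∈ {1..4}`, divisions in
[50, 400], 1200 replicates — chosen once to put typical risks in an
informative mid-range at desk scale (a guard refuses `C > 10⁶` and
`u > 10⁻²`). What the simulation validates is the *equation's* internal
consistency — independence across cells and drivers, the policing
semantics — not the model's biological fidelity: real tissues have
clonal competition, niche structure, and non-identical drivers that
neither the equation nor the simulator represents.

## Detected inconsistencies in the published table

Reproducing the comparative table from its stated procedure matches 60
of 72 hypothesis cells and 8 of 9 baselines within 2% plus printed
precision. The exceptions, which we report as computed rather than
force into agreement:

- **Intermediate-scaling esophageal baseline**: the stated procedure
  (mouse `k = 33.2·3000^0.15`, `M = 2`, 1% target) yields
  `u = 9.66×10⁻⁶`, not the printed `1.32×10⁻⁵`. The printed human and
  whale columns of that row *are* self-consistent with the printed
  baseline, so the discrepancy is confined to the baseline calibration;
  our whole row therefore differs (e.g. human fold 660, not 900).
- **Two intermediate-scaling whale folds** (colorectal 920,
  hepatocellular 3,450): each contradicts its own row's per-driver
  escape column, whose reciprocal (the small-x identity
  `fold ≈ 1/(1−e_d)`) gives ≈822 and ≈11,500 — the values our solver
  produces and verifies by round-trip.
- **No-scaling whale esophageal cancer-cell escape** printed as
  `7.40×10⁻¹¹` versus computed `7.23×10⁻¹¹` (2.4%), consistent with
  computation from the rounded 3-sig-fig baseline `u`.

## Design choices

- Inverse solving and calibration use the exact risk form, never the
  small-p approximation; the approximation exists for the analytic
  scaling arguments (where it is the point) and as a documented
  fast path.
- Species smaller or shorter-lived than the baseline return sentinel
  solutions (fold 1, ΔM 0, escape 1) flagged `no_change_needed`,
  rather than raising, so scans over arbitrary species grids work.
- CSV is the canonical table format (full-precision companion columns
  included); Markdown output mirrors the printed style (capital-E,
  3 significant figures, ΔM to one decimal) for visual diffing.
- The table pipeline is pure and deterministic: identical bytes on
  every run at a fixed configuration.

## Limitations

The package quantifies required parameter changes; it does not model
the evolutionary dynamics (effective population sizes, selection
coefficients, costs) by which such changes would spread, nor
immunoediting dynamics, nor fits to observed incidence data. The 1%
mouse anchor is a modeling device, not an empirical incidence.
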