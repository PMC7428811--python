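# petostage

Peto's paradox, quantified: large, long-lived animals should get far more
cancer than small, short-lived ones under the multistage model of
carcinogenesis — yet they don't. `petostage` implements the multistage
model with immune-policing extensions and metabolic-rate allometry, and
solves the inverse problems that ask *how much* each candidate
resolution of the paradox would have to change a parameter to hold
lifetime cancer risk constant from a mouse to a human to a blue whale.

It is aimed at comparative oncologists and evolutionary biologists who
want the paradox's arithmetic to be reproducible and extensible to
other species, tissues, or scaling assumptions.

## The model

Cancer initiates when any one of `C` at-risk stem cells, dividing `k`
times per year for `t` years with a driver-mutation probability `u` per
division, accumulates `M` driver mutations. With immune detection of
cancer cells (efficiency `e_c`) and of cells bearing any driver
mutation (efficiency `e_d`), the lifetime risk is

```
p = 1 − {1 − (1−e_c) · [(1−e_d) · (1 − e^(−u·k·t))]^M}^C
```

which for small `p` is approximately `C·(1−e_c)·[(1−e_d)·u·k·t]^M`.
All evaluation is in log space (`log1p`/`expm1`), so whale-scale cell
counts (`C ≈ 7.5×10¹¹`) with per-cell risks below 10⁻¹⁴ are exact.

The comparative scaffold: tissue stem-cell counts scale with body mass;
the division rate optionally scales with a metabolic-rate (MR) exponent
`beta` (`k ∝ mass-ratio^beta`, with `beta ∈ {0, −0.15, −0.3}`; cellular
metabolic rate itself scales as `W^−0.3`). A hypothetical mouse is
calibrated to a 1% lifetime risk per cancer by choosing the integer
`M ≥ 2` that keeps `u` nearest 10⁻⁵/division, then each evolutionary
hypothesis is solved in closed form for the change that restores 1% at
human or blue-whale scale: the fold-reduction in `u`, the added driver
mutations ΔM, or the maximum immune escape probability (`1−e_c` or
`1−e_d`).

## Worked example

```
$ petostage calibrate --tissue colorectal --scaling -0.3
colorectal beta=-0.3: M=4 u=1.234E-05 achieved_risk=0.01
```

Under full MR scaling the hypothetical mouse colon (66,667 stem cells,
dividing ~806 times/yr) needs four driver mutations and
`u = 1.23×10⁻⁵`/division to sit at a 1% lifetime risk.

```
$ petostage solve --tissue colorectal --species human --hypothesis mutation_rate
mutation_rate colorectal/human beta=0: value=578.334 achieved_risk=0.01 unmitigated=1
```

Carrying the no-MR mouse baseline to human size and longevity drives
colorectal risk to ~100%; holding it at 1% by lowering the somatic
mutation rate alone would require a 578-fold reduction. The full table
(`petostage table2` or `python analysis/02_reproduce_table2.py`)
begins:

```
| beta  | tissue         | species    | baseline_M | baseline_u | unmitigated_risk_pct | mutation_fold | policing_cancer_escape | policing_driver_escape | added_drivers |
|-------|----------------|------------|------------|------------|----------------------|---------------|------------------------|------------------------|---------------|
| 0.0   | colorectal     | human      | 3          | 3.66E-05   | 100%                 | 578           | 7.08E-09               | 1.92E-03               | 11.4          |
| 0.0   | colorectal     | blue_whale | 3          | 3.66E-05   | 100%                 | 8,830         | 2.07E-12               | 1.27E-04               | 17.4          |
```

Read: without any change, a human-scale colon reaches ~100% lifetime
risk; keeping it at 1% requires *either* a 578-fold lower mutation
rate, *or* an immune system from which only 7 cancer cells per billion
escape, *or* only ~2 driver-bearing cells per thousand escaping, *or*
11.4 additional driver mutations' worth of genetic suppression (~6
extra recessive tumor suppressor genes). The blue whale needs more of
everything except under strong MR scaling.

## Layout

- `src/petostage/` — the library: risk equations (`model_core`),
  scaling rules (`allometry`), baseline calibration (`calibration`),
  hypothesis solvers (`solvers`), Monte Carlo oracle (`simulate`),
  table assembly and CLI (`report`, `cli`).
- `analysis/01…04_*.py` — narrative drivers: calibrate baselines,
  reproduce the scaling table, the metabolic-rate scaling arguments,
  and the simulation validation. Each writes its tables under
  `results/`.
- `tests/` — unit, property, and end-to-end suites.

Species/tissue constants ship in `src/petostage/data/default_config.yaml`
and can be overridden with `--config your.yaml`.

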