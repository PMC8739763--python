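# txseq

A decision-analytic Markov cohort model comparing lifetime outcomes of
**live-donor-first (LD-DD)** versus **deceased-donor-first (DD-LD)** kidney
transplant sequencing for recipients starting at ages 3–25, with yearly
cycles to age 90. The model reports expected remaining life-years and
expected deceased-donor kidneys used per recipient, for four sequence
options (`LD-DD`, `DD-LD`, `DD-DD`, `LD-LD`) under configurable assumptions:
live-donor availability, preemptive-retransplant probabilities, an
age-dependent retransplant-candidacy schedule, and an optional third
(deceased-donor, never preemptive) transplant.

## Layout

| module | purpose |
| --- | --- |
| `txseq.parameters` | rate tables, candidacy schedule, scenario config, rate/probability conversions |
| `txseq.markov` | state space, per-cycle transition rows, deterministic cohort solver |
| `txseq.microsim` | individual-level simulation oracle; log-normal Monte Carlo uncertainty (percentile 95% CIs) |
| `txseq.scenarios` | comparison grids, one-way sensitivity suite, age sweeps, named presets |
| `txseq.synthetic` | random structurally-valid rate-table generator and the packaged calibration fixture |
| `txseq.io` / `txseq.cli` | CSV/YAML I/O, run manifests, command-line interface |

Age-stratified inputs travel as long-format CSV
(`age_lo, age_hi, field, value, units`); annual rates per person-year, with
transplant rates optionally given per 100 person-years. The packaged
calibration fixture is a deterministic, plausibility-calibrated stand-in
for registry-derived inputs; its transplant rates (40/15/12 per 100
patient-waiting-years) are exact published values, all other fields are
approximations chosen so the qualitative orderings of the published
comparisons emerge.

## CLI

```sh
# one scenario: occupancy, survival curve, summary
txseq run --sequence DD-LD --start-age 8 --out out/run

# two options with a 1000-trial percentile 95% CI
txseq compare --start-age 5 --option1 LD-DD --option2 DD-LD \
    --trials 1000 --seed 7 --out out/compare

# net life-years by starting age for a named preset, plus a plot
txseq sweep --preset optimal --out out/sweep
txseq report --preset baseline --format svg --out out/report

# one-way sensitivity suite at one age
txseq sensitivity --start-age 15 --out out/sens

# synthetic rate table (long-format CSV + generator-spec echo)
txseq simulate-data --seed 1 --out out/data
```

Every subcommand writes a `manifest.json` (seed, config echo, input
checksums, package version); identical invocations produce identical
result files. A custom rate table is supplied with `--table rates.csv`.

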