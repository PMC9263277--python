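# isofv

Isokinetic force-velocity (F-v) profiling and 2-point-method screening for
single-joint dynamometry (knee extension/flexion), from raw torque-time
traces to a full method-agreement analysis:

- **signal_processing** — zero-phase Butterworth filtering (2nd order, 5 Hz)
  of 500 Hz torque traces, isokinetic-plateau detection, per-repetition peak
  extraction, best-of-last-four selection, isometric peaks.
- **fv_profiling** — torque → normalized force (`(T/lever)/mass^(2/3)`),
  angular → linear velocity (`ω·π/180·lever`), linear / quadratic / 2-point
  F-v fits; `F0`, `v0 = −F0/Sfv`, `Sfv`, `Pmax = F0·v0/4`; Fisher z of fit
  correlations.
- **agreement_stats** — paired t with Cohen's d, two-way mixed ICC
  (single/average, consistency/agreement) with F-distribution 95% CIs,
  SEM (`sd_bias/√2`), within-individual CV% with chi-square CI,
  MDC (`1.96·√2·SEM`), Bland-Altman limits, Shapiro-Wilk gate.
- **combination_screening** — all 36 two-velocity combinations of the
  9-velocity protocol (30–300°/s) screened per parameter against the 9-point
  linear method; validity = ICC CI lower bound ≥ 0.75, p ≥ 0.05, CV CI
  lower bound ≤ 10%.
- **synthetic_data** — seeded Hill-hyperbola cohort generator (quasilinear
  over 30–300°/s, concave-up truth, multiplicative noise) plus torque-trace
  synthesis, so the whole pipeline is testable without any measurement data.
- **interface** — CLI and pipeline orchestration.

## CLI

```sh
isofv simulate --seed 5 --out sim/            # points.csv, anthropometrics.csv, truth.json
isofv simulate --seed 5 --out sim/ --traces   # + per-trial 500 Hz trace CSVs
isofv signal   --config traces.yaml --out points.csv
isofv profile  --points sim/points.csv --out prof/
isofv screen   --points sim/points.csv --out scr/ --task KE
```

`screen` writes `screening.csv` (one row per task × parameter × combination,
with the full agreement battery and validity flag) and `ranking.json`
(top combinations per parameter). `profile` writes per-subject linear and
quadratic profiles, the polynomial-vs-linear fit comparison on Fisher-z
values, and the fitted-F0 vs measured-isometric-force comparison.

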