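# netpol

Stochastic modeling of RNA polymerase II (RNAPII) early elongation, and the
accompanying analysis of nascent-transcription and nucleosome-positioning
data — NET-seq, TEF-seq (elongation-factor-associated NET-seq), and
MNase-seq-derived nucleosome dyad calls — for budding-yeast-style genomes.

It is written for genomicists who want to (i) relate the *shape* of a
NET-seq profile over the first 1,000 nt of a gene to underlying transcription
kinetics, and (ii) run the bespoke normalization and dyad-anchored
computations these assays require, on real tracks or on synthetic data with
known ground truth.

## The model

Transcription of a 1,000-nt gene body is simulated as a discrete-time
stochastic process over a population of identical genes. Each engaged
polymerase occupies a 40-nt footprint and is in one of three states:
**moving**, **stalled**, or **backtracked**. Per time step (dt = 0.005 min):

- initiation at position 1 with probability min(α·dt, 1), blocked while the
  promoter is occluded by a polymerase footprint;
- a moving polymerase stalls with probability k_stall·dt, otherwise hops
  n ~ Poisson(v·dt) nt (v in nt/min), truncated by the footprint of the next
  polymerase downstream — a truncated hop is a *collision*;
- stalled polymerases backtrack (k_bt·dt) or resume (k_rs·dt); backtracked
  polymerases resume with k_rb·dt;
- collisions resolve by state: the upstream polymerase always stalls, and a
  stalled downstream polymerase is terminated by the impact;
- a polymerase may carry an early-termination site ~ Poisson(μ_term)
  (assigned at initiation with probability p_term) and is removed on reaching
  it; reaching the gene end removes it as completed.

Two positional windows (boundary `window1_end`) carry independent
stall/backtrack/resume rates, so early- and late-body regulation (e.g. the
nucleosomal barrier) can differ. The model's observable is the final-snapshot
occupancy of active sites — the simulated analogue of a NET-seq profile.

Profiles are fitted by a Latin-hypercube sweep over rate bounds: each
parameter set is simulated, 10-nt binned and normalized, and ranked against a
gene's binned profile by the Kolmogorov–Smirnov statistic. Six metrics are
read from the best-fitting sets: initiation/elongation ratio, moving ratio
(moving / stalled+backtracked) in each window, window-1 size, mean
early-termination location, and processivity (% reaching 1,000 nt).
Conditions are compared per gene with paired Cohen's d
(d = mean(Δ)/sd(Δ), |d| ≥ 0.8 "large") and paired t-tests.

Track processing implements no-tag background subtraction anchored on a
high-background RNAPIII locus (corrected = FLAG − r̄·notag, with r̄ the mean
FLAG/no-tag ratio over 10-nt bins of the SCR1 window), spike-in calibration
by median-of-ratios size factors, trimmed-mean metagenes with the standard
gene filters, and dyad-anchored statistics: TEF/NET ratio metagenes, the
one-tailed paired flank test (−60..−10 vs +10..+60 nt around a dyad),
per-gene z-scored profile shapes, NDR length, nucleosome spacing, and
expression-group spacing curves.

## Worked example

```python
from netpol.simulator import ModelParameters, simulate_population

params = ModelParameters()          # baseline regime, 1,000-nt gene
occ, met = simulate_population(params, population_size=500, seed=1)
print(f"processivity {met.processivity:.1f}%")
print(f"moving ratio w1 {met.moving_ratio_w1:.2f}  w2 {met.moving_ratio_w2:.2f}")
print(f"initiated {met.initiated} completed {met.completed} "
      f"early {met.early_terminated} collision {met.collision_terminated}")
```

prints

```
processivity 77.8%
moving ratio w1 1.14  w2 2.95
initiated 19102 completed 14862 early 1743 collision 2148
```

i.e. under the default rates 77.8% of initiating polymerases traverse the
full 1,000 nt; the remainder terminate early (9%) or are removed by
collisions with stalled polymerases (11%); polymerases spend relatively more
time stalled/backtracked in window 1 (ratio 1.14) than in window 2 (2.95),
producing the characteristic 5′ occupancy elevation. `occ.counts` holds the
per-nt occupancy profile that fitting consumes.

An end-to-end synthetic study (generate data, normalize, fit both
conditions, compare metrics, nucleosome statistics) runs from a config:

```bash
netpol run-all --config examples/run.ini --out runs/demo
```

See `netpol --help` for the individual stages (`simulate`, `sweep`, `fit`,
`compare`, `normalize`, `metagene`, `dyads`, `synth`).

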