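# Methods

This note documents the model and the analysis conventions implemented in
`netpol`, the choices made where the design was genuinely open, and the
limits of what the synthetic-data tests demonstrate.

## The polymerase population model

Transcription over a synthetic 1,000-nt gene body is a discrete-time Markov
process on a population of independent, identical genes. State per engaged
polymerase: active-site position (1-based nt from the TSS), kinetic state
(MOVING / STALLED / BACKTRACKED), and an optional early-termination site.
Polymerases exclude each other over a fixed 40-nt footprint.

**Discrete-time scheme.** The time step is dt = 0.005 min and runs cover 40
simulated minutes (8,000 steps), long relative to a single transit
(0.25–2 min at 0.5–4 kb/min), so the final snapshot samples steady state.
First-order rates k (min⁻¹) become per-step Bernoulli probabilities k·dt;
constructing `ModelParameters` fails if any k·dt would exceed 1 (the user is
told to reduce dt). Initiation alone uses min(α·dt, 1), since an initiation
"rate" above 1/dt simply saturates the promoter. Elongation is a per-step
hop n ~ Poisson(v·dt) nt, which accommodates mean displacements above 1
nt/step (e.g. 10 nt at 2 kb/min) while remaining stochastic.

**Update order.** Within a step, engaged polymerases are updated
most-downstream first, so nobody moves into space vacated upstream within
the same step — the standard sweep for exclusion processes. Initiation is
attempted after the movement sweep; a polymerase initiated in a step takes
its first hop in the next one. State transitions are mutually exclusive per
step: a moving polymerase first tests stalling, and only otherwise hops; a
stalled polymerase tests backtracking and only otherwise resumption (one
uniform draw decides both branches with the exact joint probabilities).

**Occlusion, collisions, termination.** Initiation is blocked while any
active site lies within 40 nt of position 1. A hop is truncated so the
polymerase stays ≥ 40 nt behind its downstream neighbour; a truncated
nonzero hop is a collision. Resolution depends only on the two states:
the upstream (moving) polymerase stalls in every case, and a STALLED
downstream polymerase is terminated by the impact (MOVING and BACKTRACKED
neighbours are unaffected). Early termination: with probability p_term an
initiating polymerase draws a site ~ Poisson(μ_term), redrawn while the draw
is 0 or beyond the gene; it is removed on reaching the site. Reaching or
passing position 1,000 removes the polymerase as completed, so engaged
positions span 1..999. Backtracked polymerases do not change position: the
observable is the active-site/RNA-3′-end coordinate, and no backtracking
displacement distribution is modeled.

**Bookkeeping and invariants.** Per gene, `initiated = engaged + completed +
early_terminated + collision_terminated` holds exactly at every step, and
footprint exclusion is asserted at every step in `validate=True` runs. The
`collisions` counter additionally records every truncation event, including
those that terminate nobody.

**Outputs.** The occupancy profile is the sum over the population of
final-snapshot active-site positions. Measured metrics: moving ratio
(# MOVING / # STALLED+BACKTRACKED among engaged polymerases) per window at
the final snapshot — a window with no stopped polymerase yields `inf`, an
empty window `NaN` — and processivity = completed/initiated (%). The final
snapshot (rather than a time average) matches the occupancy-output
convention; at 8,000 steps the snapshot is well past burn-in.

**Engines.** The default engine is a numba kernel; a pure-Python reference
engine implements the identical per-step semantics and is cross-checked
against it statistically in the tests. The two engines consume different
random streams, so they agree in distribution, not bit-for-bit. For a fixed
seed and engine, runs are bit-reproducible; sweep simulations derive child
seeds from (seed, set index), making libraries order-independent.

## Fitting

Parameter libraries are sampled by Latin-hypercube sampling
(`scipy.stats.qmc`) over per-dimension bounds. Default bounds (all
overridable, `ParameterRanges`): initiation 0.1–10 min⁻¹, elongation 0.5–4
kb/min, window-1 end 50–500 nt, stall/backtrack/resume rates 0–20 min⁻¹,
early-termination mean 50–800 nt and probability 0–0.5 — a deliberately
broad, biologically plausible envelope for yeast RNAPII kinetics.

Profiles (simulated and experimental) are restricted to the first 1,000 nt,
10-nt binned, and normalized to sum to 1. Goodness of fit is the
Kolmogorov–Smirnov statistic, max over bins of the absolute CDF difference.
All 100 bins enter the comparison by default; an optional bin mask can
exclude regions (e.g. the promoter-proximal bins, where the assay is not
expected to be reliable). Genes enter fitting if longer than 1,000 nt with
first-1,000-nt totals strictly greater than the mean over all length-passing
genes. Per-gene metrics average the k best-fitting sets (`NaN`-aware mean;
an undefined moving ratio drops that set from that metric only). The
package default is k = 10; the desk-scale recovery experiment uses k = 1,
the proportional scaling of keeping ~0.07% of the library. Paired condition
comparisons report Cohen's d = mean(b−a)/sd(b−a) (sample sd), magnitude
labels at |d| = 0.2/0.5/0.8, and a two-sided paired t-test; identical
vectors give d = 0, p = 1, and a constant nonzero difference raises a
degenerate-input error rather than returning ±inf.

The growth-curve utility restricts an OD₆₀₀ series to the exponential
window (0.2–0.7), and returns log 2 · elapsed / (log ODmax − log ODmin),
with elapsed the time span of the in-window measurements.

## Track processing conventions

Coordinates are 0-based half-open internally (BED convention); anchored
windows use offset 0 = the anchor nucleotide, positive offsets in the
direction of transcription, so the conventional position "+1" (first
transcribed nt) is offset 0 of a TSS anchor. Minus-strand genes read
reversed from the minus-strand array.

**No-tag correction.** corrected = FLAG − r̄·notag, with r̄ the mean over
10-nt bins of the FLAG/no-tag count ratio inside the SCR1 window (default
chrV:442007–442458, treated as 1-based inclusive; strand-summed; bins with
zero no-tag counts are skipped; an all-zero no-tag window is an error).
Corrected values may go negative; the metagene gene filter discards genes
with any negative value in the plotted window, which also makes the filter
sensitive to diffuse no-tag coverage — see the generator notes below.

**Spike-in calibration.** Size factors are the median-of-ratios estimator
computed directly: per gene with nonzero counts in every sample, the
geometric mean across samples; per sample, the median over those genes of
count/geomean, taken on the natural scale. Experimental tracks are divided
by their sample's factor.

**Metagenes.** Gene filters: protein-coding, > 750 nt, no negative
corrected value in the plotted window, and not more than 1.5× the summed
signal in the 150 nt upstream of the TSS than in the first 150 nt
downstream (strictly-greater genes are discarded; this guards against
mis-annotated TSSs). Per relative position, the mean across genes excludes
the top and bottom 1% of per-gene values (ceil of 1% per tail; at least 3
genes required); a global-quantile trimming mode is available since the
original description does not fully pin the trimming unit down. Binning to
10 nt follows trimming.

## Dyad-anchored analyses

Dyad calls carry labels −1, +1..+4 per gene and replicate; a labeling helper
assigns +1 to the first dyad at TSS-relative position ≥ 1 (configurable
upstream tolerance) and −1 to the last upstream dyad. Geometry: NDR length =
pos(+1) − pos(−1); spacing = distance between adjacent labeled dyads; all
TSS-relative with TSS = +1. Cross-condition comparisons form per-replicate
medians across genes and compare conditions by a two-sided paired t-test
across replicates. The phased-gene filter keeps protein-coding genes
≥ 600 nt with ≥ 4 dyads (or exactly 4, configurable) in TSS+1..+600 in
every replicate.

TEF/NET ratio metagenes divide the two identically-built (trimmed, binned)
metagenes bin-wise, masking bins with zero NET mean. The flank asymmetry
test compares, per gene, the TEF/NET ratio of flank means over −60..−10 vs
+10..+60 nt around a labeled dyad (the ±10 nt core is excluded), dropping
genes without NET signal in either flank, with a one-tailed paired t-test
(upstream < downstream). Per-gene shape normalization z-scores a profile
with the population sd; constant profiles are excluded. Expression-group
spacing splits genes into equal-size quantile groups by any gene-level
covariate (NET-seq density in the first 500 nt, or +1-dyad position) and
reports per-group medians and sds of spacing.

## The synthetic-data generator

One synthetic chromosome with 200 genes (1.2–2.2 kb, both strands, 0.4–0.9
kb intergenic gaps) by default. NET tracks Poisson-sample
depth·shape·spike-factor per nt, where the shape is the simulator's
occupancy for the condition's parameters extended past 1,000 nt at its
plateau; per-gene depths are lognormal around 50 reads per first-1,000 nt.
A shared background field (default 0.0005 counts/nt in gene bodies, 5/nt
over a 452-nt SCR1-like hot locus) enters the tagged samples at
`notag_ratio` (default 2) times the no-tag rate, so the printed correction
formula is exactly the right estimator in expectation; the diffuse gene-body
rate is kept low because the negative-value gene filter is, by construction,
sensitive to any no-tag count at a signal-free position. Spike-in tables
scale a shared lognormal base expression by declared per-sample factors
(default 1 and 2). Dyads sit at a −1/+1 NDR of 170 nt and 165-nt spacing
with per-replicate Gaussian jitter (sd 4 nt, 3 replicates); a mutant
condition can widen every spacing beyond +1 by a declared increment. TEF
tracks multiply the NET expectation by a dyad-locked sinusoid (default 20%
amplitude, period = spacing, zero at the dyad and positive downstream)
and/or a flat boost over downstream dyad flanks, before Poisson sampling.
`noise=False` returns expectations instead of Poisson draws. Everything is
bit-reproducible from the generator seed, and truth tables record every
generating value.

What the generator does **not** emulate: sequence content and mappability,
read-level artifacts (PCR duplicates, soft-clipping), overlapping or
bidirectional transcription units, 3′-end/termination-zone signal, replicate
track pairs for NET/TEF (only dyad calls are replicated), and any coupling
between nucleosome positions and the simulated polymerase kinetics (the
windows absorb nucleosome effects; dyads are generated independently).
Passing tests therefore demonstrate the correctness of the computations
under these statistical assumptions, not robustness to the full messiness of
real libraries.

## Desk-scale study sizes

Routine and test runs use: simulator populations of 500–4,000 genes
(8,000 steps each); a 256-set Latin-hypercube library at 500 genes per set
with truth shapes at 2,000 genes; ~50 reads/gene sequencing noise with 5
synthetic genes per truth condition; 200-gene, deep-coverage (1,000
reads/gene) datasets for the flank-test Monte-Carlo (100 null seeds, 20
power seeds); and 200 genes × 3 replicates for spacing recovery. Recovery
experiments draw truth regimes from a documented sub-range with all
processes active (`netpol.experiments.TRUTH_RANGES`), because corner regimes
— no stalling (infinite moving ratio) or a 50-nt window 1 holding a couple
of reads — are not identifiable from a binned profile and say nothing about
the fitting machinery.

## Known limitations

- **Library density bounds metric recovery.** With a 256-set library over
  13 dimensions, the best-fitting neighbours of a profile are sparse in
  parameter space, which caps how well k-best-averaged metrics can track the
  generating values under realistic read noise; rank correlations for the
  window-1 moving ratio at this scale sit near, and sometimes below, 0.8.
  Full-scale sweeps (10⁵ sets and larger populations, as the method is meant
  to be run) are reachable through the same API but are not the default.
- The KS statistic compares binned CDFs and is insensitive to which window a
  density difference falls in; distinct parameter sets can be near-degenerate
  in shape (notably initiation and elongation scale the profile jointly and
  are constrained only through their ratio).
- The discrete-time scheme allows at most one state transition per
  polymerase per step; rates must satisfy k·dt ≤ 1 and results at k·dt
  near 1 should be treated with caution (the default dt keeps all default
  bounds at k·dt ≤ 0.1).
- The flank test's per-gene statistic is a ratio of flank means, which
  carries a finite-coverage Jensen bias: E[mean_TEF/mean_NET] exceeds the
  true ratio by roughly 1/m, with m the expected NET counts in the flank.
  Because the occupancy shape generally leaves the two flanks of a dyad
  unequally covered, the biases do not cancel in the paired difference and
  the test is mildly anti-conservative at moderate coverage (type-I error
  around 0.1 rather than 0.05 at ~50 NET counts per flank, as the
  Monte-Carlo calibration shows at some seeds). The bias scales as 1/m and
  is negligible in the deep-coverage regime the assay is run in; a
  TEF-share statistic T/(T+N), exactly unbiased per flank, would remove it
  at the cost of departing from the conventional ratio readout.
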