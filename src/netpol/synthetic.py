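"""Synthetic data with known ground truth for every pipeline input.

The generator lays out a single synthetic chromosome of protein-coding genes
on both strands, then emulates the statistical structure of the real assays:

* **NET tracks**: per-gene expected signal is the simulator's steady-state
  occupancy shape for the condition's parameters (extended past 1,000 nt at
  the plateau level), scaled by a per-gene sequencing depth and the sample's
  spike-in scale factor, Poisson-sampled, plus a shared additive Poisson
  background.
* **No-tag track**: the background alone (its own Poisson realization),
  sharing an SCR1-like hot locus with the tagged samples, whose tagged-sample
  background is ``notag_ratio`` times the no-tag rate so the printed
  correction formula is exactly the right estimator in expectation.
* **Spike-in counts**: a genes x samples table with declared per-sample
  scale factors.
* **Dyads**: phased nucleosomes at NDR + i * spacing with per-replicate
  jitter, three replicates by default.
* **TEF tracks**: the NET expectation multiplied by a dyad-locked modulation
  (a sinusoid of the nucleosomal period and/or a flat boost over downstream
  dyad flanks) before Poisson sampling.

Truth tables record every generating value, so each downstream estimate can
be checked against its generating quantity. All outputs are bit-identical
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .simulator import ModelParameters, simulate_population

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "make_condition_pair"]

CHROM = "synI"


def default_params() -> ModelParameters:
    """Baseline ("wild-type-like") transcription regime for the generator."""
    return ModelParameters()


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating conditions for one synthetic sample.

    Defaults are sized for routine runs: 200 genes, a sequencing depth of
    about 50 reads per gene over the first 1000 nt, three dyad replicates,
    nucleosome spacing 165 nt with a 170-nt NDR, and a 20% dyad-locked TEF
    modulation.
    """

    n_genes: int = 200
    seed: int = 0
    gene_length_range: tuple[int, int] = (1200, 2200)
    intergenic_range: tuple[int, int] = (400, 900)
    params: ModelParameters = field(default_factory=default_params)
    sim_population: int = 500
    mean_reads_per_gene: float = 50.0
    depth_sigma: float = 0.6          # lognormal sd of per-gene depth
    spike_scale: float = 1.0          # this sample's spike-in factor
    spike_factors: tuple[float, ...] = (1.0, 2.0)  # factors of the sample set
    n_spike_genes: int = 40
    spike_mean: float = 200.0
    background_rate: float = 0.0005   # expected no-tag counts per nt (gene bodies
                                      # see little untagged background; it is
                                      # concentrated at the SCR1-like locus)
    notag_ratio: float = 2.0          # tagged-sample background multiplier
    scr1_rate: float = 5.0            # per-nt background rate at the hot locus
    scr1_length: int = 452
    nuc_spacing: float = 165.0
    spacing_increment: float = 0.0    # added to every spacing beyond +1
    plus1_pos: float = 60.0           # TSS-relative +1 dyad position
    ndr_len: float = 170.0
    dyad_jitter_sd: float = 4.0
    n_replicates: int = 3
    tef_amplitude: float = 0.2        # sinusoidal TEF/NET modulation
    tef_down_boost: float = 0.0       # flat boost over downstream dyad flanks
    noise: bool = True                # Poisson sampling on/off

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.sim_population < 1:
            raise ConfigError("n_genes and sim_population must be >= 1")
        if self.mean_reads_per_gene <= 0 or self.spike_scale <= 0:
            raise ConfigError("scales must be > 0")
        if abs(self.tef_amplitude) >= 1.0:
            raise ConfigError("tef_amplitude must satisfy |A| < 1 "
                              "(expectations must stay positive)")
        if self.tef_down_boost < 0:
            raise ConfigError("tef_down_boost must be >= 0")
        if self.background_rate < 0 or self.scr1_rate < 0:
            raise ConfigError("background rates must be >= 0")


@dataclass
class SyntheticDataset:
    """One generated sample plus shared annotation, dyads, and truth."""

    spec: SyntheticSpec
    annotation: pd.DataFrame
    net: "object"       # SignalTrack
    tef: "object"
    notag: "object"
    dyads: pd.DataFrame          # labeled dyad calls, all replicates
    spike_counts: pd.DataFrame   # spike-in genes x samples
    truth: dict


def _layout_genome(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    cursor = 1000  # leave margin for upstream windows
    for i in range(spec.n_genes):
        length = int(rng.integers(*spec.gene_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        end = start + length
        tss, pas = (start, end - 1) if strand == "+" else (end - 1, start)
        rows.append({"gene_id": f"g{i:04d}", "chrom": CHROM, "start": start,
                     "end": end, "strand": strand, "tss": tss, "pas": pas,
                     "length": length, "biotype": "protein_coding"})
        cursor = end + int(rng.integers(*spec.intergenic_range))
    return pd.DataFrame(rows)


def _gene_shape(spec: SyntheticSpec, length: int, occ_shape: np.ndarray) -> np.ndarray:
    """Per-nt expected signal shape over a whole gene, normalized to sum 1
    over the first min(1000, length) nt."""
    L = occ_shape.size
    if length <= L:
        shape = occ_shape[:length].copy()
    else:
        plateau = occ_shape[-100:].mean()
        shape = np.concatenate([occ_shape, np.full(length - L, plateau)])
    head = shape[:min(1000, length)].sum()
    return shape / head if head > 0 else shape


def _dyad_template(spec: SyntheticSpec, n_dyads: int = 5) -> np.ndarray:
    """TSS-relative expected dyad positions for labels -1, +1..+4."""
    pos = [spec.plus1_pos - spec.ndr_len]
    p = spec.plus1_pos
    pos.append(p)
    for _ in range(n_dyads - 2):
        p = p + spec.nuc_spacing + spec.spacing_increment
        pos.append(p)
    return np.asarray(pos, dtype=float)


def generate_dataset(spec: SyntheticSpec,
                     annotation: pd.DataFrame | None = None,
                     occ_shape: np.ndarray | None = None) -> SyntheticDataset:
    """Generate one synthetic sample (annotation, tracks, dyads, truth).

    ``annotation`` and ``occ_shape`` can be supplied to share a genome layout
    or a pre-simulated occupancy shape between conditions (see
    :func:`make_condition_pair`).
    """
    from .seqproc import SignalTrack  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    if annotation is None:
        annotation = _layout_genome(spec, rng)
    if occ_shape is None:
        occ, _ = simulate_population(spec.params, spec.sim_population,
                                     seed=int(rng.integers(2**31)))
        total = occ.counts.sum()
        if total == 0:
            raise ConfigError("simulator produced an empty occupancy; "
                              "raise initiation or the population size")
        occ_shape = occ.counts / total

    chrom_len = int(annotation["end"].max() + 2000)
    # SCR1-like hot locus in the intergenic margin at the chromosome start
    scr1_start1 = 301  # 1-based
    scr1_window = (CHROM, scr1_start1, scr1_start1 + spec.scr1_length - 1)

    bg_rate = {s: np.full(chrom_len, spec.background_rate / 2.0) for s in "+-"}
    for s in "+-":
        bg_rate[s][scr1_start1 - 1:scr1_start1 - 1 + spec.scr1_length] = spec.scr1_rate / 2.0

    signal = {s: np.zeros(chrom_len) for s in "+-"}
    dyad_template = _dyad_template(spec)
    depths = np.exp(rng.normal(np.log(spec.mean_reads_per_gene),
                               spec.depth_sigma, size=len(annotation)))
    tef_mult = {s: np.ones(chrom_len) for s in "+-"}
    dyad_truth_rows = []
    for (idx, row), depth in zip(annotation.iterrows(), depths):
        shape = _gene_shape(spec, row.length, occ_shape)
        expected = depth * shape * spec.spike_scale
        offsets = np.arange(row.length)
        if row.strand == "+":
            gpos = row.tss + offsets
        else:
            gpos = row.tss - offsets
        signal[row.strand][gpos] += expected
        # dyad-locked TEF modulation over the gene body
        mult = np.ones(row.length)
        if spec.tef_amplitude != 0.0:
            rel = offsets - (spec.plus1_pos - 1)  # distance from +1 dyad nt
            mult *= 1.0 + spec.tef_amplitude * np.sin(
                2.0 * np.pi * rel / spec.nuc_spacing)
        if spec.tef_down_boost > 0.0:
            for rel_dyad in dyad_template[1:]:
                lo = int(rel_dyad - 1 + 10)
                hi = int(rel_dyad - 1 + 60) + 1
                lo, hi = max(lo, 0), min(hi, row.length)
                if lo < hi:
                    mult[lo:hi] *= 1.0 + spec.tef_down_boost
        tef_mult[row.strand][gpos] = mult
        for lab, rel in zip(("-1", "+1", "+2", "+3", "+4"), dyad_template):
            dyad_truth_rows.append({"gene_id": row.gene_id, "label": lab,
                                    "rel_pos": float(rel)})

    def _sample(rate: dict[str, np.ndarray]) -> dict[str, dict[str, np.ndarray]]:
        if spec.noise:
            return {CHROM: {s: rng.poisson(rate[s]).astype(float) for s in "+-"}}
        return {CHROM: {s: rate[s].copy() for s in "+-"}}

    net_rate = {s: signal[s] + spec.notag_ratio * bg_rate[s] for s in "+-"}
    tef_rate = {s: signal[s] * tef_mult[s] + spec.notag_ratio * bg_rate[s] for s in "+-"}
    net = SignalTrack("net", _sample(net_rate))
    tef = SignalTrack("tef", _sample(tef_rate))
    notag = SignalTrack("notag", _sample(bg_rate))

    # spike-in count table: same base expression across samples, scaled
    base = np.exp(rng.normal(np.log(spec.spike_mean), 0.5, size=spec.n_spike_genes))
    spike_cols = {}
    for j, f in enumerate(spec.spike_factors):
        lam = base * f
        counts = rng.poisson(lam).astype(float) if spec.noise else lam
        spike_cols[f"sample{j + 1}"] = counts
    spike_counts = pd.DataFrame(
        spike_cols, index=[f"sp{i:03d}" for i in range(spec.n_spike_genes)])

    # jittered dyad calls per replicate
    dyad_rows = []
    for rep in range(1, spec.n_replicates + 1):
        for row in annotation.itertuples():
            for lab, rel in zip(("-1", "+1", "+2", "+3", "+4"), dyad_template):
                jit = rng.normal(0.0, spec.dyad_jitter_sd)
                rel_j = rel + jit
                if row.strand == "+":
                    pos = row.tss + int(round(rel_j)) - 1
                else:
                    pos = row.tss - int(round(rel_j)) + 1
                dyad_rows.append({"gene_id": row.gene_id, "label": lab,
                                  "pos": pos, "replicate": rep})
    dyads = pd.DataFrame(dyad_rows)

    truth = {
        "occ_shape": occ_shape,
        "params": spec.params,
        "depths": pd.Series(depths, index=annotation["gene_id"].values, name="depth"),
        "spike_factors": dict(zip(spike_counts.columns, spec.spike_factors)),
        "spike_scale": spec.spike_scale,
        "scr1_window": scr1_window,
        "notag_ratio": spec.notag_ratio,
        "dyad_template": pd.DataFrame(dyad_truth_rows),
        "expected_signal": {s: signal[s] for s in "+-"},
    }
    return SyntheticDataset(spec, annotation, net, tef, notag, dyads,
                            spike_counts, truth)


def make_condition_pair(spec: SyntheticSpec, wt_params: ModelParameters,
                        mut_params: ModelParameters,
                        mut_spacing_increment: float = 0.0,
                        ) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Generate a matched condition pair (e.g. wild type vs a deletion).

    Both datasets share the annotation; the mutant differs only by its
    declared parameter set, an optional nucleosome-spacing increment beyond
    the +1 nucleosome, and its spike-in scale factor (``spec.spike_factors``
    positions 1 and 2). Each condition has its own Poisson realizations.
    """
    wt_spec = replace(spec, params=wt_params, spike_scale=spec.spike_factors[0])
    mut_spec = replace(spec, params=mut_params, seed=spec.seed + 1,
                       spike_scale=spec.spike_factors[1],
                       spacing_increment=mut_spacing_increment)
    wt = generate_dataset(wt_spec)
    mut = generate_dataset(mut_spec, annotation=wt.annotation)
    return wt, mut
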