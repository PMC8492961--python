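"""Reproducible end-to-end experiments on synthetic data.

Each function runs one self-contained study at desk scale — parameter
recovery for the profile-fitting machinery, Monte-Carlo calibration and
power of the dyad flank test, normalization round trips, and
nucleosome-spacing recovery — and returns plain dictionaries of measured
quantities. The problem sizes used here (library of 256 parameter sets at
500 genes per set, truth shapes at 2,000 genes, ~50 reads per gene of
sequencing noise, 200-gene flank experiments at deep coverage) are the
package's standard desk-scale study conditions; docs/methods.md discusses
how they relate to full-scale runs.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy import stats

from .chromatin import compare_position_medians, flank_asymmetry_test, nucleosome_positions
from .fitting import (
    GeneProfile,
    ParameterRanges,
    SimulationLibrary,
    build_library,
    fit_gene,
    lhs_sample,
)
from .seqproc import gene_window_values, notag_correct, spikein_size_factors
from .simulator import ModelParameters, simulate_population
from .synthetic import SyntheticSpec, generate_dataset

__all__ = [
    "baseline_simulation",
    "parameter_recovery",
    "flank_test_calibration",
    "flank_test_power",
    "normalization_recovery",
    "spacing_recovery",
]


def _child_seed(seed: int, label: str) -> int:
    h = zlib.crc32(label.encode())
    return int(np.random.SeedSequence([int(seed), h]).generate_state(1)[0]) & 0x7FFFFFFF


def baseline_simulation(seed: int, population: int = 2000) -> dict:
    """Simulate the baseline transcription regime and report its metrics."""
    occ, met = simulate_population(ModelParameters(), population, seed)
    return {
        "processivity_pct": met.processivity,
        "moving_ratio_w1": met.moving_ratio_w1,
        "moving_ratio_w2": met.moving_ratio_w2,
        "engaged_per_gene": met.engaged / population,
        "collision_terminated_frac": met.collision_terminated / max(met.initiated, 1),
    }


#: Truth regimes for recovery experiments: every process active, windows
#: large enough to hold signal at desk-scale read depth. The sweep library
#: still spans the full default ranges; truths confined to corner regimes
#: (no stalling -> infinite moving ratio; a 50-nt window-1 holding ~2 reads)
#: are not identifiable from binned shapes and say nothing about the fitting
#: machinery.
TRUTH_RANGES = ParameterRanges({
    "initiation_rate": (0.5, 5.0),
    "elongation_rate": (1.0, 3.0),
    "window1_end": (150.0, 450.0),
    "stall_rate_w1": (1.0, 15.0),
    "stall_rate_w2": (1.0, 15.0),
    "backtrack_rate_w1": (0.5, 10.0),
    "backtrack_rate_w2": (0.5, 10.0),
    "resume_stall_w1": (1.0, 15.0),
    "resume_stall_w2": (1.0, 15.0),
    "resume_backtrack_w1": (0.5, 10.0),
    "resume_backtrack_w2": (0.5, 10.0),
    "early_term_mean": (100.0, 600.0),
    "early_term_prob": (0.05, 0.4),
})


def parameter_recovery(seed: int, n_truth: int = 20, n_lhs: int = 236,
                       truth_population: int = 2000, library_population: int = 500,
                       reads_per_gene: float = 50.0, k_best: int = 1,
                       n_noiseless: int = 10, genes_per_truth: int = 5) -> dict:
    """Recover generating parameters by KS fitting against an LHS library.

    Truth parameter sets are drawn from the same default ranges as the
    library. Each truth is simulated at ``truth_population`` genes; its
    shape enters the library alongside ``n_lhs`` Latin-hypercube sets
    simulated at ``library_population`` genes. Noiseless synthetic gene
    profiles are the truth shapes themselves; noisy profiles Poisson-sample
    ~``reads_per_gene`` reads from each shape, with ``genes_per_truth``
    independent synthetic genes per truth condition (each condition's
    recovered metric is the average over its genes, as in the per-condition
    summaries of the full pipeline). Reports the rank-1 recovery rate for
    noiseless profiles and the Spearman correlation between the recovered
    (k-best-averaged) and generating window-1 moving ratio under noise.
    """
    ranges = ParameterRanges()
    truth_sets = lhs_sample(TRUTH_RANGES, n_truth, seed=_child_seed(seed, "truth"))
    lhs_sets = lhs_sample(ranges, n_lhs, seed=_child_seed(seed, "lhs"))
    truth_lib = build_library(truth_sets, truth_population,
                              seed=_child_seed(seed, "truth-sim"))
    lhs_lib = build_library(lhs_sets, library_population,
                            seed=_child_seed(seed, "lhs-sim"))
    library = SimulationLibrary.concat(lhs_lib, truth_lib)
    truth_offset = n_lhs

    rank1 = []
    for i in range(n_noiseless):
        profile = GeneProfile(f"truth{i}", truth_lib.shapes[i].copy())
        res = fit_gene(profile, library, k_best=1)
        rank1.append(res.best_index == truth_offset + i)

    rng = np.random.default_rng(_child_seed(seed, "noise"))
    truth_mr1 = np.array([m.moving_ratio_w1 for m in truth_lib.metrics])
    recovered_mr1 = np.empty(n_truth)
    for i in range(n_truth):
        per_gene = []
        for _g in range(genes_per_truth):
            counts = rng.poisson(reads_per_gene * truth_lib.shapes[i])
            while counts.sum() == 0:
                counts = rng.poisson(reads_per_gene * truth_lib.shapes[i])
            profile = GeneProfile(f"noisy{i}_{_g}", counts / counts.sum())
            res = fit_gene(profile, library, k_best=k_best)
            per_gene.append(res.metrics["moving_ratio_w1"])
        recovered_mr1[i] = np.nanmean(per_gene)
    # infinities are legitimate ranks for a rank correlation; only NaN
    # (a window empty of polymerases) drops a pair
    ok = ~(np.isnan(truth_mr1) | np.isnan(recovered_mr1))
    rho = stats.spearmanr(truth_mr1[ok], recovered_mr1[ok]).statistic
    return {
        "rank1_noiseless": int(sum(rank1)),
        "n_noiseless": n_noiseless,
        "spearman_moving_ratio_w1": float(rho),
        "n_truth": int(ok.sum()),
    }


def _flank_spec(seed: int, n_genes: int, boost: float) -> SyntheticSpec:
    # deep coverage: the dyad flank analysis presumes well-covered genes
    return SyntheticSpec(
        n_genes=n_genes, seed=seed, mean_reads_per_gene=1000.0,
        gene_length_range=(1200, 1500), tef_amplitude=0.0,
        tef_down_boost=boost, n_replicates=1,
    )


def _flank_pvalue(seed: int, n_genes: int, boost: float,
                  annotation, occ_shape) -> float:
    ds = generate_dataset(_flank_spec(seed, n_genes, boost),
                          annotation=annotation, occ_shape=occ_shape)
    _, p = flank_asymmetry_test(ds.tef, ds.net, ds.annotation, ds.dyads, "+2")
    return p


def _flank_template(seed: int, n_genes: int):
    """Shared genome layout and occupancy shape for the Monte-Carlo seeds."""
    base = generate_dataset(_flank_spec(seed, n_genes, 0.0))
    return base.annotation, base.truth["occ_shape"]


def flank_test_calibration(seed: int, n_seeds: int = 100, n_genes: int = 200,
                           alpha: float = 0.05) -> dict:
    """Type-I error of the flank asymmetry test on symmetric-null data."""
    annotation, shape = _flank_template(seed, n_genes)
    rejections = 0
    for i in range(n_seeds):
        p = _flank_pvalue(_child_seed(seed, f"null{i}"), n_genes, 0.0,
                          annotation, shape)
        rejections += p < alpha
    return {"rejections": rejections, "n_seeds": n_seeds,
            "type_i_error": rejections / n_seeds}


def flank_test_power(seed: int, n_seeds: int = 20, n_genes: int = 200,
                     shift: float = 0.10, alpha: float = 0.05) -> dict:
    """Power of the flank test under a downstream occupancy boost."""
    annotation, shape = _flank_template(seed, n_genes)
    hits = 0
    for i in range(n_seeds):
        p = _flank_pvalue(_child_seed(seed, f"alt{i}"), n_genes, shift,
                          annotation, shape)
        hits += p < alpha
    return {"hits": hits, "n_seeds": n_seeds, "power": hits / n_seeds}


def normalization_recovery(seed: int, n_genes: int = 60) -> dict:
    """Round-trip of no-tag correction and spike-in calibration.

    Noiseless data measure exact shape recovery (minimum per-gene cosine
    similarity of the corrected profile to the generating shape); noisy data
    at the default depth measure recovery of the declared spike factor ratio
    of 2.
    """
    clean = generate_dataset(SyntheticSpec(n_genes=n_genes, seed=seed,
                                           noise=False, sim_population=500))
    corrected, _ = notag_correct(clean.net, clean.notag, clean.truth["scr1_window"])
    shape = clean.truth["occ_shape"][:1000]
    cosines = []
    for row in clean.annotation.itertuples():
        win = gene_window_values(corrected, row.chrom, row.strand, row.tss, (0, 1000))
        cosines.append(np.dot(win, shape)
                       / (np.linalg.norm(win) * np.linalg.norm(shape)))
    noisy = generate_dataset(SyntheticSpec(n_genes=n_genes, seed=seed + 1,
                                           sim_population=500))
    factors = spikein_size_factors(noisy.spike_counts)
    return {
        "min_cosine_noiseless": float(np.min(cosines)),
        "spike_factor_ratio": float(factors["sample2"] / factors["sample1"]),
    }


def spacing_recovery(seed: int, n_genes: int = 200, increment: float = 10.0) -> dict:
    """Recover a declared nucleosome-spacing increase in a synthetic mutant.

    The mutant's dyads beyond the +1 nucleosome are spaced ``increment`` nt
    wider; NDR geometry is shared. Reports the median spacing differences
    and the NDR-length difference between conditions.
    """
    shape = np.full(1000, 1e-3)
    spec = SyntheticSpec(n_genes=n_genes, seed=seed)
    wt = generate_dataset(spec, occ_shape=shape)
    mut_spec = SyntheticSpec(n_genes=n_genes, seed=seed + 1,
                             spacing_increment=increment)
    mut = generate_dataset(mut_spec, annotation=wt.annotation, occ_shape=shape)
    cmp = compare_position_medians(
        nucleosome_positions(wt.dyads, wt.annotation),
        nucleosome_positions(mut.dyads, mut.annotation))
    by = cmp.set_index("statistic")["difference"]
    return {
        "spacing_diff_p1_p2": float(by["spacing_p1_p2"]),
        "spacing_diff_p2_p3": float(by["spacing_p2_p3"]),
        "spacing_diff_p3_p4": float(by["spacing_p3_p4"]),
        "ndr_diff": float(by["ndr"]),
        "plus1_diff": float(by["pos_+1"]),
    }
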