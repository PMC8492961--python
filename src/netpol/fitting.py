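"""Latin-hypercube parameter sweeps and KS goodness-of-fit of simulated
occupancy to per-gene nascent-transcription profiles.

Fitting workflow: sample parameter sets by Latin-hypercube sampling over
configurable bounds, simulate each set to obtain a binned occupancy shape,
rank the library against each gene's binned/normalized profile by the
Kolmogorov-Smirnov statistic, and summarize the k best-fitting sets into six
per-gene metrics:

1. initiation-to-elongation ratio (initiation_rate / elongation_rate),
2. moving ratio in window 1,
3. window-1 size (nt),
4. mean early-termination location (nt),
5. moving ratio in window 2,
6. processivity (% of initiated polymerases reaching the gene end).

Paired wild-type-vs-mutant comparisons use Cohen's d for paired samples with
the conventional 0.2/0.5/0.8 magnitude labels and a two-sided paired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .errors import ConfigError, DataError, DegenerateInputError
from .simulator import ModelParameters, OccupancyProfile, SimulatedMetrics, simulate_population

__all__ = [
    "DEFAULT_RANGES",
    "ParameterRanges",
    "GeneProfile",
    "FitResult",
    "METRIC_NAMES",
    "lhs_matrix",
    "lhs_sample",
    "build_library",
    "bin_and_normalize",
    "ks_distance",
    "fit_gene",
    "select_genes_for_fitting",
    "cohens_d_paired",
    "compare_conditions",
    "doubling_time",
]

#: Sampled dimensions, in a fixed order (the remaining ModelParameters fields
#: -- gene_length, footprint, dt, total_time -- are held constant).
SAMPLED_FIELDS = (
    "initiation_rate", "elongation_rate", "window1_end",
    "stall_rate_w1", "stall_rate_w2",
    "backtrack_rate_w1", "backtrack_rate_w2",
    "resume_stall_w1", "resume_stall_w2",
    "resume_backtrack_w1", "resume_backtrack_w2",
    "early_term_mean", "early_term_prob",
)

#: Default sweep bounds: biologically plausible ranges for budding-yeast
#: RNAPII kinetics. Every bound can be overridden.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "initiation_rate": (0.1, 10.0),
    "elongation_rate": (0.5, 4.0),
    "window1_end": (50.0, 500.0),
    "stall_rate_w1": (0.0, 20.0),
    "stall_rate_w2": (0.0, 20.0),
    "backtrack_rate_w1": (0.0, 20.0),
    "backtrack_rate_w2": (0.0, 20.0),
    "resume_stall_w1": (0.0, 20.0),
    "resume_stall_w2": (0.0, 20.0),
    "resume_backtrack_w1": (0.0, 20.0),
    "resume_backtrack_w2": (0.0, 20.0),
    "early_term_mean": (50.0, 800.0),
    "early_term_prob": (0.0, 0.5),
}

METRIC_NAMES = (
    "init_elong_ratio", "moving_ratio_w1", "window1_end",
    "early_term_mean", "moving_ratio_w2", "processivity",
)


@dataclass(frozen=True)
class ParameterRanges:
    """(min, max) bounds per sampled dimension; degenerate bounds are allowed
    and pin that dimension to a constant."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self) -> None:
        for name in SAMPLED_FIELDS:
            if name not in self.bounds:
                raise ConfigError(f"missing bounds for {name!r}")
            lo, hi = self.bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ConfigError(f"bounds for {name!r} must be finite")
            if lo > hi:
                raise ConfigError(f"min > max for {name!r}")
            if lo < 0:
                raise ConfigError(f"bounds for {name!r} must be non-negative")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in SAMPLED_FIELDS])
        hi = np.array([self.bounds[n][1] for n in SAMPLED_FIELDS])
        return lo, hi


def lhs_matrix(lower: np.ndarray, upper: np.ndarray, n_sets: int, seed: int) -> np.ndarray:
    """Latin-hypercube sample of shape (n_sets, d) scaled to [lower, upper].

    For each dimension the n_sets values occupy distinct equal-probability
    strata. Degenerate dimensions (lower == upper) are constant.
    """
    if n_sets < 1:
        raise ConfigError("n_sets must be >= 1")
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    unit = qmc.LatinHypercube(d=lower.size, seed=seed).random(n_sets)
    return lower + unit * (upper - lower)


def lhs_sample(ranges: ParameterRanges, n_sets: int, seed: int,
               base: ModelParameters | None = None) -> list[ModelParameters]:
    """Draw ``n_sets`` parameter sets by Latin-hypercube sampling.

    ``base`` supplies the constant fields (gene_length, footprint, dt,
    total_time). ``window1_end`` is rounded to the nearest nt and clipped to
    [1, gene_length].
    """
    base = base or ModelParameters()
    lo, hi = ranges.as_arrays()
    mat = lhs_matrix(lo, hi, n_sets, seed)
    out = []
    for row in mat:
        kw = dict(zip(SAMPLED_FIELDS, row))
        kw["window1_end"] = int(min(max(round(kw["window1_end"]), 1), base.gene_length))
        out.append(base.with_(**kw))
    return out


def bin_and_normalize(counts: np.ndarray, bin_size: int = 10) -> np.ndarray:
    """Bin a per-nt count vector and normalize bins to sum to 1."""
    counts = np.asarray(counts, dtype=float)
    if counts.size % bin_size:
        raise DataError("profile length must be a multiple of the bin size")
    binned = counts.reshape(-1, bin_size).sum(axis=1)
    total = binned.sum()
    if total <= 0:
        raise DataError("profile has no signal to normalize")
    return binned / total


@dataclass
class GeneProfile:
    """A gene's TSS-anchored first-1000-nt profile, 10-nt binned, normalized."""

    gene_id: str
    bins: np.ndarray  # normalized, sums to 1

    @classmethod
    def from_counts(cls, gene_id: str, counts: np.ndarray, bin_size: int = 10,
                    clip_negative: bool = True) -> "GeneProfile":
        counts = np.asarray(counts, dtype=float)
        if clip_negative:
            counts = np.clip(counts, 0.0, None)
        return cls(gene_id, bin_and_normalize(counts, bin_size))

    @classmethod
    def from_occupancy(cls, gene_id: str, occ: OccupancyProfile,
                       bin_size: int = 10) -> "GeneProfile":
        return cls(gene_id, bin_and_normalize(occ.counts, bin_size))


def ks_distance(profile_a, profile_b) -> float:
    """Kolmogorov-Smirnov statistic between two binned, normalized profiles:
    the maximum over bins of |CDF_a - CDF_b|. Symmetric, in [0, 1]."""
    a = profile_a.bins if isinstance(profile_a, GeneProfile) else np.asarray(profile_a, float)
    b = profile_b.bins if isinstance(profile_b, GeneProfile) else np.asarray(profile_b, float)
    if a.shape != b.shape:
        raise DataError("profiles must share the same bin grid")
    return float(np.abs(np.cumsum(a) - np.cumsum(b)).max())


@dataclass
class SimulationLibrary:
    """A simulated sweep: parameter sets, their binned shapes, and metrics."""

    params: list[ModelParameters]
    shapes: np.ndarray              # (n_sets, n_bins), each row sums to 1
    metrics: list[SimulatedMetrics]

    def __len__(self) -> int:
        return len(self.params)

    @classmethod
    def concat(cls, *libs: "SimulationLibrary") -> "SimulationLibrary":
        return cls(
            params=[p for lib in libs for p in lib.params],
            shapes=np.vstack([lib.shapes for lib in libs]),
            metrics=[m for lib in libs for m in lib.metrics],
        )

    def metric_matrix(self) -> np.ndarray:
        """(n_sets, 6) matrix of the six per-set metrics."""
        rows = []
        for p, m in zip(self.params, self.metrics):
            rows.append([
                p.initiation_rate / p.elongation_rate,
                m.moving_ratio_w1,
                float(p.window1_end),
                p.early_term_mean,
                m.moving_ratio_w2,
                m.processivity,
            ])
        return np.asarray(rows, dtype=float)


def build_library(param_sets: list[ModelParameters], population_size: int, seed: int,
                  bin_size: int = 10) -> SimulationLibrary:
    """Simulate every parameter set and collect binned/normalized shapes.

    Seeds for individual simulations are derived from ``seed`` and the set
    index, so sweeps are reproducible and order-independent.
    """
    if not param_sets:
        raise DataError("empty parameter list")
    shapes = []
    metrics = []
    for i, p in enumerate(param_sets):
        child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]) & 0x7FFFFFFF
        occ, met = simulate_population(p, population_size, child)
        total = occ.counts.sum()
        if total == 0:
            # an all-zero profile (e.g. initiation 0) gets a uniform shape so
            # KS against it is well defined
            shapes.append(np.full(p.gene_length // bin_size, bin_size / p.gene_length))
        else:
            shapes.append(bin_and_normalize(occ.counts, bin_size))
        metrics.append(met)
    return SimulationLibrary(list(param_sets), np.vstack(shapes), metrics)


@dataclass
class FitResult:
    """Ranked fit of one gene against a simulation library."""

    gene_id: str
    order: np.ndarray       # library indices sorted by ascending KS distance
    distances: np.ndarray   # KS distance in the same (sorted) order
    metrics: dict[str, float]  # mean over the k best sets

    @property
    def best_index(self) -> int:
        return int(self.order[0])

    @property
    def best_distance(self) -> float:
        return float(self.distances[0])


def fit_gene(profile: GeneProfile, library: SimulationLibrary, k_best: int = 10,
             bin_mask: np.ndarray | None = None) -> FitResult:
    """Rank all library shapes by KS distance to ``profile``; summarize the
    ``k_best`` lowest-distance sets into the six per-gene metrics (mean over
    the retained sets).

    ``bin_mask`` optionally excludes bins (e.g. the early simulation peak)
    from the comparison; the masked shapes are renormalized before the CDFs
    are formed.
    """
    if len(library) == 0:
        raise DataError("empty simulation library")
    shapes = library.shapes
    target = profile.bins
    if shapes.shape[1] != target.size:
        raise DataError("library and profile bin grids differ")
    if bin_mask is not None:
        keep = np.asarray(bin_mask, bool)
        shapes = shapes[:, keep]
        shapes = shapes / shapes.sum(axis=1, keepdims=True)
        target = target[keep]
        target = target / target.sum()
    d = np.abs(np.cumsum(shapes, axis=1) - np.cumsum(target)).max(axis=1)
    order = np.argsort(d, kind="stable")
    k = min(k_best, len(library))
    top = order[:k]
    mmat = library.metric_matrix()[top]
    with np.errstate(invalid="ignore"):
        # a parameter set whose window held no polymerase at the final
        # snapshot has an undefined moving ratio there; it is left out of
        # the k-best average for that metric
        metrics = {name: float(np.nanmean(mmat[:, j]))
                   for j, name in enumerate(METRIC_NAMES)}
    return FitResult(profile.gene_id, order, d[order], metrics)


def select_genes_for_fitting(totals: pd.DataFrame) -> pd.DataFrame:
    """Two-stage gene filter for profile fitting.

    ``totals`` must have columns ``gene_id``, ``length`` and
    ``counts_first_1000`` (total reads in the first 1000 nt from the TSS).
    Stage 1 keeps genes longer than 1000 nt; stage 2 keeps, of those, genes
    whose first-1000-nt total is strictly greater than the mean total over
    all stage-1 genes.
    """
    required = {"gene_id", "length", "counts_first_1000"}
    if not required.issubset(totals.columns):
        raise DataError(f"totals table needs columns {sorted(required)}")
    stage1 = totals[totals["length"] > 1000]
    if stage1.empty:
        return stage1
    mean_counts = stage1["counts_first_1000"].mean()
    return stage1[stage1["counts_first_1000"] > mean_counts].reset_index(drop=True)


_D_LABELS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


def _label(d: float) -> str:
    a = abs(d)
    for cut, name in _D_LABELS:
        if a < cut:
            return name
    return "large"


def cohens_d_paired(values_a, values_b) -> tuple[float, str, float]:
    """Paired Cohen's d with magnitude label and two-sided paired-t p-value.

    d = mean(b - a) / sd(b - a) with the sample (ddof=1) standard deviation;
    positive d means an increase in condition b. |d| in [0.2, 0.5) is labeled
    small, [0.5, 0.8) medium, >= 0.8 large.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired vectors must be 1-D and of equal length")
    if a.size < 2:
        raise DataError("need at least two pairs")
    diff = b - a
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff.mean() == 0.0:
            return 0.0, _label(0.0), 1.0
        raise DegenerateInputError("all paired differences identical and nonzero")
    d = float(diff.mean() / sd)
    p = float(stats.ttest_rel(b, a).pvalue)
    return d, _label(d), p


def compare_conditions(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                       metric_names=METRIC_NAMES) -> pd.DataFrame:
    """Per-metric paired comparison of two conditions over shared genes.

    Both frames must be indexed by gene id (or carry a ``gene_id`` column)
    with one column per metric. Returns a table with Cohen's d, magnitude
    label and two-sided paired-t p-value per metric, sign convention
    b relative to a.
    """
    def _prep(df):
        if "gene_id" in df.columns:
            df = df.set_index("gene_id")
        return df

    a = _prep(metrics_a)
    b = _prep(metrics_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise DataError("need at least two shared genes")
    rows = []
    for name in metric_names:
        va = a.loc[shared, name].to_numpy(float)
        vb = b.loc[shared, name].to_numpy(float)
        ok = np.isfinite(va) & np.isfinite(vb)
        d, lab, p = cohens_d_paired(va[ok], vb[ok])
        rows.append({"metric": name, "cohens_d": d, "magnitude": lab,
                     "p_value": p, "n_genes": int(ok.sum())})
    return pd.DataFrame(rows)


def doubling_time(times, ods, od_window: tuple[float, float] = (0.2, 0.7)) -> float:
    """Culture doubling time (same unit as ``times``) from an OD600 series.

    Restricts the series to the exponential window (OD 0.2-0.7 by default)
    and evaluates log(2) * elapsed_time / (log(max OD) - log(min OD)) over
    that window.
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if t.shape != od.shape:
        raise DataError("times and ODs must align")
    lo, hi = od_window
    mask = (od >= lo) & (od <= hi)
    if mask.sum() < 2:
        raise DataError("too few measurements inside the OD window")
    t, od = t[mask], od[mask]
    od_min, od_max = od.min(), od.max()
    if od_max <= od_min:
        raise DataError("no growth inside the OD window")
    elapsed = t.max() - t.min()
    return float(math.log(2) * elapsed / (math.log(od_max) - math.log(od_min)))
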