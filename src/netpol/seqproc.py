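"""Nascent-transcription (NET-seq / TEF-seq) track processing.

Three operations defined by the study design:

* **No-tag correction** — immunoprecipitation background is estimated from a
  high-background RNAPIII locus (SCR1, chrV:442007-442458 in sacCer3) that is
  captured equally in tagged and untagged samples. The FLAG/no-tag ratio is
  computed per 10-nt bin over that window, averaged, and the scaled no-tag
  track subtracted: corrected = flag - r * notag.
* **Spike-in calibration** — per-sample size factors from the spike-in
  species' gene counts via the median-of-ratios estimator (per gene the
  geometric mean across samples; per sample the median over all-nonzero genes
  of count/geomean). Experimental tracks are divided by their factor.
* **Metagenes** — per-position trimmed means across filtered genes around a
  TSS/PAS/dyad anchor, 10-nt binned. Gene filters: protein-coding, > 750 nt,
  no negative corrected values in the plotted window, and not more than 1.5x
  the signal upstream of the TSS (-150..0) than downstream (+1..+150).

Coordinates are 0-based half-open internally; relative (anchor) coordinates
use offset 0 = the anchor nucleotide, so the conventional position "+1" (first
transcribed nt) is offset 0 for a TSS anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "SCR1_WINDOW",
    "SignalTrack",
    "MetageneResult",
    "gene_window_values",
    "notag_correct",
    "spikein_size_factors",
    "filter_genes_for_metagene",
    "trimmed_mean_profile",
    "bin_profile",
    "metagene",
]

#: SCR1 locus used for background estimation: (chrom, start, end), 1-based
#: inclusive as printed for the sacCer3 assembly.
SCR1_WINDOW = ("chrV", 442007, 442458)


@dataclass
class SignalTrack:
    """Strand-resolved per-nucleotide 3'-end counts for one sample.

    ``data`` maps chromosome -> strand ("+"/"-") -> float array of
    per-position values (counts, or corrected/calibrated signal).
    """

    sample: str
    data: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    species: str = "experimental"

    def chrom_length(self, chrom: str) -> int:
        return len(next(iter(self.data[chrom].values())))

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[chrom][strand]

    def copy_like(self, sample: str | None = None) -> "SignalTrack":
        return SignalTrack(
            sample or self.sample,
            {c: {s: arr.copy() for s, arr in strands.items()}
             for c, strands in self.data.items()},
            self.species,
        )

    def combine(self, other: "SignalTrack", fn) -> "SignalTrack":
        if set(self.data) != set(other.data):
            raise DataError("tracks cover different chromosomes")
        out = {}
        for c, strands in self.data.items():
            if set(strands) != set(other.data[c]):
                raise DataError(f"strand mismatch on {c}")
            out[c] = {}
            for s, arr in strands.items():
                o = other.data[c][s]
                if arr.shape != o.shape:
                    raise DataError(f"length mismatch on {c}{s}")
                out[c][s] = fn(arr, o)
        return SignalTrack(self.sample, out, self.species)

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            self.sample,
            {c: {s: arr / factor for s, arr in strands.items()}
             for c, strands in self.data.items()},
            self.species,
        )


def _window_counts_both_strands(track: SignalTrack, chrom: str,
                                start0: int, end0: int) -> np.ndarray:
    strands = track.data[chrom]
    total = np.zeros(end0 - start0, dtype=float)
    for arr in strands.values():
        total += arr[start0:end0]
    return total


def notag_correct(flag_track: SignalTrack, notag_track: SignalTrack,
                  scr1_window: tuple[str, int, int] = SCR1_WINDOW,
                  bin_size: int = 10) -> tuple[SignalTrack, float]:
    """Subtract scaled no-tag background: corrected = flag - r * notag.

    The scaling r is the mean over 10-nt bins of the FLAG/no-tag ratio inside
    the SCR1 window (strand-summed; bins with zero no-tag counts are
    skipped). Corrected values may be negative; the metagene gene filter
    discards affected genes. Returns (corrected_track, r).
    """
    chrom, start1, end1 = scr1_window
    if chrom not in flag_track.data or chrom not in notag_track.data:
        raise DataError(f"SCR1 chromosome {chrom!r} missing from tracks")
    start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
    flag_w = _window_counts_both_strands(flag_track, chrom, start0, end0)
    notag_w = _window_counts_both_strands(notag_track, chrom, start0, end0)
    n_bins = math.ceil(len(flag_w) / bin_size)
    ratios = []
    for i in range(n_bins):
        f = flag_w[i * bin_size:(i + 1) * bin_size].sum()
        n = notag_w[i * bin_size:(i + 1) * bin_size].sum()
        if n > 0:
            ratios.append(f / n)
    if not ratios:
        raise DataError("no no-tag signal in the SCR1 window; ratio undefined")
    r = float(np.mean(ratios))
    corrected = flag_track.combine(notag_track, lambda a, b: a - r * b)
    return corrected, r


def spikein_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from a spike-in genes x samples table.

    Per gene, the geometric mean across samples is formed using only genes
    with nonzero counts in every sample; per sample, the factor is the median
    over those genes of count/geomean. Experimental tracks are then divided
    by their sample's factor.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0:
        raise DataError("empty spike-in count table")
    full = (mat > 0).all(axis=1)
    if not full.any():
        raise DataError("no spike-in gene has nonzero counts in all samples")
    sub = mat[full]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def gene_window_values(track: SignalTrack, chrom: str, strand: str, anchor: int,
                       window: tuple[int, int]) -> np.ndarray | None:
    """Transcription-oriented signal in a window around an anchor position.

    ``anchor`` is the 0-based genomic coordinate of the anchor nucleotide
    (TSS, PAS, or dyad). ``window`` is (start_offset, end_offset), half-open
    in oriented offsets where offset 0 is the anchor nt and positive offsets
    run in the direction of transcription. Minus-strand genes read from the
    minus-strand array, reversed. Returns None if the window leaves the
    chromosome.
    """
    lo, hi = window
    length = track.chrom_length(chrom)
    arr = track.get(chrom, strand)
    if strand == "+":
        g0, g1 = anchor + lo, anchor + hi
        if g0 < 0 or g1 > length:
            return None
        return arr[g0:g1].astype(float)
    g0, g1 = anchor - hi + 1, anchor - lo + 1
    if g0 < 0 or g1 > length:
        return None
    return arr[g0:g1][::-1].astype(float)


def _closed(interval: tuple[int, int]) -> tuple[int, int]:
    """Closed offset interval (field convention) -> half-open offsets."""
    a, b = interval
    return a, b + 1


def filter_genes_for_metagene(track: SignalTrack, annotation: pd.DataFrame,
                              window: tuple[int, int] = (-250, 750),
                              min_length: int = 750,
                              upstream: tuple[int, int] = (-150, -1),
                              downstream: tuple[int, int] = (0, 149),
                              ratio: float = 1.5) -> pd.DataFrame:
    """Gene filters applied before metagene construction.

    Keeps protein-coding genes longer than ``min_length`` nt whose corrected
    signal has no negative value inside the plotted ``window`` (half-open
    offsets around the TSS) and whose summed signal in the upstream window
    is not more than ``ratio`` times the downstream window (strictly-greater
    genes are discarded, guarding against mis-annotated TSSs). Default
    upstream/downstream offsets correspond to positions -150..0 and +1..+150
    in the TSS=+1 convention. Genes whose window leaves the chromosome are
    dropped.
    """
    keep = []
    for row in annotation.itertuples():
        if getattr(row, "biotype", "protein_coding") != "protein_coding":
            continue
        if row.length <= min_length:
            continue
        win = gene_window_values(track, row.chrom, row.strand, row.tss, window)
        if win is None or (win < 0).any():
            continue
        up = gene_window_values(track, row.chrom, row.strand, row.tss, _closed(upstream))
        down = gene_window_values(track, row.chrom, row.strand, row.tss, _closed(downstream))
        if up is None or down is None:
            continue
        if up.sum() > ratio * down.sum():
            continue
        keep.append(row.gene_id)
    return annotation[annotation["gene_id"].isin(keep)].reset_index(drop=True)


def trimmed_mean_profile(matrix: np.ndarray, trim: float = 0.01) -> np.ndarray:
    """Per-position mean across genes excluding the top and bottom ``trim``
    fraction (ceil of trim * n genes at each tail) of per-gene values."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 3:
        raise DataError("trimmed mean needs at least 3 genes")
    k = math.ceil(trim * n)
    if 2 * k >= n:
        raise DataError("trim fraction removes every gene")
    srt = np.sort(matrix, axis=0)
    return srt[k:n - k].mean(axis=0)


def bin_profile(values: np.ndarray, bin_size: int = 10) -> np.ndarray:
    """Mean of consecutive ``bin_size`` positions (length must divide)."""
    values = np.asarray(values, dtype=float)
    if values.size % bin_size:
        raise DataError("window length must be a multiple of the bin size")
    return values.reshape(-1, bin_size).mean(axis=1)


@dataclass
class MetageneResult:
    """Binned average signal around an anchor, across a set of genes."""

    anchor: str
    window: tuple[int, int]
    bins: np.ndarray
    n_genes: int
    bin_size: int = 10

    def bin_offsets(self) -> np.ndarray:
        """Offset of the first position of each bin relative to the anchor."""
        return np.arange(self.window[0], self.window[1], self.bin_size)


def metagene(track: SignalTrack, annotation: pd.DataFrame,
             anchor: str = "tss", window: tuple[int, int] = (-250, 750),
             trim: float = 0.01, bin_size: int = 10,
             anchor_positions: pd.Series | None = None,
             trim_mode: str = "per_position") -> MetageneResult:
    """Average signal profile around an anchor across genes.

    ``anchor`` selects the annotation column ("tss" or "pas") unless
    ``anchor_positions`` (a gene_id-indexed Series of 0-based genomic
    positions, e.g. +1 dyads) is given. Per relative position the mean across
    genes is taken after removing the top and bottom ``trim`` fraction of
    per-gene values (``trim_mode="per_position"``), or after removing values
    outside the global trim/1-trim quantiles of all window values
    (``trim_mode="global"``); then 10-nt binning.
    """
    rows = []
    used = 0
    for row in annotation.itertuples():
        if anchor_positions is not None:
            if row.gene_id not in anchor_positions.index:
                continue
            pos = int(anchor_positions.loc[row.gene_id])
        else:
            pos = int(getattr(row, anchor))
        win = gene_window_values(track, row.chrom, row.strand, pos, window)
        if win is None:
            continue
        rows.append(win)
        used += 1
    if used < 3:
        raise DataError("metagene needs at least 3 genes with full windows")
    matrix = np.vstack(rows)
    if trim_mode == "per_position":
        prof = trimmed_mean_profile(matrix, trim)
    elif trim_mode == "global":
        lo, hi = np.quantile(matrix, [trim, 1 - trim])
        masked = np.where((matrix >= lo) & (matrix <= hi), matrix, np.nan)
        prof = np.nanmean(masked, axis=0)
    else:
        raise DataError(f"unknown trim_mode {trim_mode!r}")
    return MetageneResult(anchor, window, bin_profile(prof, bin_size), used, bin_size)
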