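"""Nucleosome-dyad-anchored analyses.

Inputs are nucleosome dyad calls (one genomic position per nucleosome per
gene per replicate, labeled -1, +1, +2, +3, +4 relative to the TSS) together
with normalized signal tracks. The module computes:

* elongation-factor occupancy on polymerase (TEF/NET ratio) metagenes around
  dyads, and the one-tailed paired flank test for dyad asymmetry
  (upstream -60..-10 vs downstream +10..+60 of the dyad, per gene);
* per-gene shape normalization (z-scoring) of profiles so distribution shape
  can be compared independently of expression level;
* nucleosome position / NDR-length / spacing statistics with per-replicate
  medians and cross-replicate paired tests;
* the gene filter for phased-nucleosome analyses and expression-group
  spacing curves.

Dyad tables are DataFrames with columns ``gene_id``, ``label`` (one of
"-1", "+1".."+4"), ``pos`` (0-based genomic dyad coordinate) and
``replicate``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .seqproc import MetageneResult, SignalTrack, gene_window_values, metagene

__all__ = [
    "DYAD_LABELS",
    "label_dyads",
    "tss_relative_position",
    "ratio_metagene",
    "flank_asymmetry_test",
    "shape_normalize_gene",
    "nucleosome_positions",
    "replicate_position_summary",
    "compare_position_medians",
    "mnase_gene_filter",
    "expression_group_spacing",
]

DYAD_LABELS = ("-1", "+1", "+2", "+3", "+4")


def tss_relative_position(pos: int, tss: int, strand: str) -> int:
    """Genomic position -> TSS-relative position with the TSS at +1."""
    if strand == "+":
        return pos - tss + 1
    return tss - pos + 1


def label_dyads(dyads: pd.DataFrame, annotation: pd.DataFrame,
                upstream_tolerance: int = 0, max_plus: int = 4) -> pd.DataFrame:
    """Assign -1/+1/.../+N labels to unlabeled per-gene dyad calls.

    The +1 nucleosome is the first dyad at TSS-relative position
    >= 1 - upstream_tolerance, the -1 the last dyad upstream of it;
    subsequent downstream dyads are +2, +3, ... up to ``max_plus``.
    """
    ann = annotation.set_index("gene_id")
    out = []
    for (gene, rep), grp in dyads.groupby(["gene_id", "replicate"]):
        if gene not in ann.index:
            continue
        g = ann.loc[gene]
        rel = grp["pos"].map(lambda p: tss_relative_position(int(p), int(g.tss), g.strand))
        grp = grp.assign(rel=rel).sort_values("rel")
        down = grp[grp["rel"] >= 1 - upstream_tolerance]
        up = grp[grp["rel"] < 1 - upstream_tolerance]
        if not up.empty:
            r = up.iloc[-1]
            out.append((gene, "-1", int(r.pos), rep))
        for i, (_, r) in enumerate(down.iterrows()):
            if i >= max_plus:
                break
            out.append((gene, f"+{i + 1}", int(r.pos), rep))
    return pd.DataFrame(out, columns=["gene_id", "label", "pos", "replicate"])


def _dyad_positions(dyads: pd.DataFrame, label: str, replicate=None) -> pd.Series:
    sub = dyads[dyads["label"] == label]
    if replicate is not None:
        sub = sub[sub["replicate"] == replicate]
    else:
        # average over replicates for anchoring purposes
        sub = sub.groupby("gene_id", as_index=False)["pos"].mean()
        return pd.Series(sub["pos"].round().astype(int).values, index=sub["gene_id"])
    return pd.Series(sub["pos"].astype(int).values, index=sub["gene_id"])


def ratio_metagene(tef_track: SignalTrack, net_track: SignalTrack,
                   annotation: pd.DataFrame, dyads: pd.DataFrame,
                   anchor_label: str = "+1", window: tuple[int, int] = (-100, 600),
                   trim: float = 0.01, bin_size: int = 10) -> MetageneResult:
    """Binned TEF/NET ratio metagene anchored at a nucleosome dyad.

    The TEF and NET metagenes are built identically (trimmed mean, 10-nt
    bins) around each gene's dyad of ``anchor_label``; the result is their
    bin-wise ratio. Bins whose NET mean is zero are masked (NaN).
    """
    anchors = _dyad_positions(dyads, anchor_label)
    tef = metagene(tef_track, annotation, window=window, trim=trim,
                   bin_size=bin_size, anchor_positions=anchors)
    net = metagene(net_track, annotation, window=window, trim=trim,
                   bin_size=bin_size, anchor_positions=anchors)
    if not (net.bins > 0).any():
        raise DataError("NET metagene is zero everywhere; ratio undefined")
    ratio = np.where(net.bins > 0, tef.bins / np.where(net.bins > 0, net.bins, 1.0), np.nan)
    return MetageneResult(f"dyad{anchor_label}", window, ratio, tef.n_genes, bin_size)


def flank_asymmetry_test(tef_track: SignalTrack, net_track: SignalTrack,
                         annotation: pd.DataFrame, dyads: pd.DataFrame,
                         nucleosome_label: str = "+2",
                         upstream: tuple[int, int] = (-60, -10),
                         downstream: tuple[int, int] = (10, 60),
                         ) -> tuple[pd.DataFrame, float]:
    """One-tailed paired test for lower factor occupancy upstream of a dyad.

    For each gene the TEF/NET ratio is computed over the upstream
    (-60..-10 nt from the dyad) and downstream (+10..+60 nt) flanks as the
    ratio of flank means; genes lacking NET signal in either flank are
    dropped. The per-gene pairs are compared by a one-tailed paired Student's
    t-test (alternative: upstream < downstream). Returns (per-gene table, p).
    """
    anchors = _dyad_positions(dyads, nucleosome_label)
    ann = annotation.set_index("gene_id")
    up0, up1 = upstream[0], upstream[1] + 1
    dn0, dn1 = downstream[0], downstream[1] + 1
    rows = []
    for gene, dpos in anchors.items():
        if gene not in ann.index:
            continue
        g = ann.loc[gene]
        vals = {}
        ok = True
        for name, (a, b) in (("up", (up0, up1)), ("down", (dn0, dn1))):
            tef = gene_window_values(tef_track, g.chrom, g.strand, int(dpos), (a, b))
            net = gene_window_values(net_track, g.chrom, g.strand, int(dpos), (a, b))
            if tef is None or net is None or net.mean() <= 0:
                ok = False
                break
            vals[name] = tef.mean() / net.mean()
        if ok:
            rows.append({"gene_id": gene, "upstream": vals["up"],
                         "downstream": vals["down"]})
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise DataError("flank test needs at least two genes")
    res = stats.ttest_rel(table["upstream"], table["downstream"], alternative="less")
    return table, float(res.pvalue)


def shape_normalize_gene(profile: np.ndarray) -> np.ndarray:
    """Z-score a gene profile: (x - mean)/sd, so only the shape remains.

    Uses the population (ddof=0) standard deviation. A constant profile has
    no shape; it raises and callers exclude the gene.
    """
    x = np.asarray(profile, dtype=float)
    sd = x.std()
    if sd == 0:
        raise DataError("constant profile; shape undefined")
    return (x - x.mean()) / sd


def nucleosome_positions(dyads: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-replicate nucleosome geometry table.

    Returns TSS-relative dyad positions (TSS = +1) for labels -1 and +1..+4,
    NDR length = pos(+1) - pos(-1), and spacings between adjacent labeled
    nucleosomes (columns ``spacing_p1_p2`` etc.). Genes missing a labeled
    dyad get NaN for the statistics that need it.
    """
    ann = annotation.set_index("gene_id")
    rows = []
    for (gene, rep), grp in dyads.groupby(["gene_id", "replicate"]):
        if gene not in ann.index:
            continue
        g = ann.loc[gene]
        rel = {}
        for _, r in grp.iterrows():
            rel[r["label"]] = tss_relative_position(int(r["pos"]), int(g.tss), g.strand)
        row = {"gene_id": gene, "replicate": rep}
        for lab in DYAD_LABELS:
            row[f"pos_{lab}"] = rel.get(lab, np.nan)
        row["ndr"] = (rel["+1"] - rel["-1"]
                      if "+1" in rel and "-1" in rel else np.nan)
        for a, b in (("+1", "+2"), ("+2", "+3"), ("+3", "+4")):
            row[f"spacing_p{a[1]}_p{b[1]}"] = (rel[b] - rel[a]
                                               if a in rel and b in rel else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_position_summary(positions: pd.DataFrame) -> pd.DataFrame:
    """Median of each geometry statistic across genes, per replicate."""
    stat_cols = [c for c in positions.columns if c not in ("gene_id", "replicate")]
    return positions.groupby("replicate")[stat_cols].median()


def compare_position_medians(positions_a: pd.DataFrame, positions_b: pd.DataFrame,
                             ) -> pd.DataFrame:
    """Cross-replicate paired comparison of nucleosome geometry medians.

    Per statistic, per-replicate medians across genes are formed for each
    condition and compared by a two-sided paired t-test across replicates
    (replicates are matched by id). Returns per-statistic medians-of-medians,
    their difference (b - a), and the p-value.
    """
    sa = replicate_position_summary(positions_a)
    sb = replicate_position_summary(positions_b)
    shared = sa.index.intersection(sb.index)
    if len(shared) < 2:
        raise DataError("need at least two shared replicates")
    rows = []
    for col in sa.columns:
        va = sa.loc[shared, col].to_numpy(float)
        vb = sb.loc[shared, col].to_numpy(float)
        if np.isnan(va).any() or np.isnan(vb).any():
            continue
        if np.allclose(va - vb, (va - vb)[0]):
            p = np.nan if (va - vb)[0] != 0 else 1.0
        else:
            p = float(stats.ttest_rel(vb, va).pvalue)
        rows.append({"statistic": col, "median_a": float(np.median(va)),
                     "median_b": float(np.median(vb)),
                     "difference": float(np.median(vb) - np.median(va)),
                     "p_value": p})
    return pd.DataFrame(rows)


def mnase_gene_filter(dyads: pd.DataFrame, annotation: pd.DataFrame,
                      min_length: int = 600, first_nt: int = 600,
                      n_peaks: int = 4, mode: str = "at_least") -> pd.DataFrame:
    """Filter genes for phased-nucleosome analyses.

    Keeps protein-coding genes of length >= ``min_length`` nt that have
    ``n_peaks`` dyads (``mode`` "at_least" or "exactly") within TSS-relative
    positions +1..``first_nt`` in **every** replicate present in ``dyads``.
    """
    if mode not in ("at_least", "exactly"):
        raise DataError(f"unknown mode {mode!r}")
    ann = annotation.set_index("gene_id")
    replicates = sorted(dyads["replicate"].unique())
    keep = []
    for gene, grp in dyads.groupby("gene_id"):
        if gene not in ann.index:
            continue
        g = ann.loc[gene]
        if getattr(g, "biotype", "protein_coding") != "protein_coding":
            continue
        if g.length < min_length:
            continue
        ok = True
        for rep in replicates:
            sub = grp[grp["replicate"] == rep]
            rel = sub["pos"].map(lambda p: tss_relative_position(int(p), int(g.tss), g.strand))
            count = int(((rel >= 1) & (rel <= first_nt)).sum())
            if (mode == "at_least" and count < n_peaks) or \
               (mode == "exactly" and count != n_peaks):
                ok = False
                break
        if ok:
            keep.append(gene)
    return annotation[annotation["gene_id"].isin(keep)].reset_index(drop=True)


def expression_group_spacing(expression: pd.Series, spacing: pd.Series,
                             n_groups: int = 8) -> pd.DataFrame:
    """Nucleosome spacing as a function of transcription level.

    Genes are split into ``n_groups`` equal-size groups by expression (e.g.
    NET-seq counts in the first 500 nt from the TSS); per group the median
    expression and the median and standard deviation of spacing are
    reported. Group 1 is the lowest-expression group.
    """
    shared = expression.index.intersection(spacing.index)
    expr = expression.loc[shared].astype(float)
    spc = spacing.loc[shared].astype(float)
    ok = expr.notna() & spc.notna()
    expr, spc = expr[ok], spc[ok]
    if len(expr) < n_groups:
        raise DataError("fewer genes than groups")
    order = expr.rank(method="first")
    groups = pd.qcut(order, n_groups, labels=False) + 1
    rows = []
    for gid, idx in pd.Series(expr.index, index=groups).groupby(level=0):
        genes = idx.values
        rows.append({
            "group": int(gid),
            "n_genes": len(genes),
            "median_expression": float(expr.loc[genes].median()),
            "median_spacing": float(spc.loc[genes].median()),
            "sd_spacing": float(spc.loc[genes].std(ddof=1)),
        })
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
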