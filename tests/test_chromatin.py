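"""Dyad-anchored statistics: labeling, geometry, ratio metagenes, the flank
asymmetry test, shape normalization, and expression-group spacing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netpol.chromatin import (
    compare_position_medians,
    expression_group_spacing,
    flank_asymmetry_test,
    label_dyads,
    mnase_gene_filter,
    nucleosome_positions,
    ratio_metagene,
    shape_normalize_gene,
    tss_relative_position,
)
from netpol.errors import DataError
from netpol.seqproc import SignalTrack


def _annotation(entries):
    df = pd.DataFrame(entries, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["length"] = df["end"] - df["start"]
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    df["pas"] = np.where(df["strand"] == "+", df["end"] - 1, df["start"])
    df["biotype"] = "protein_coding"
    return df


def _dyads_from_rel(ann, rel_by_label, replicates=(1,)):
    rows = []
    for row in ann.itertuples():
        for rep in replicates:
            for lab, rel in rel_by_label.items():
                pos = row.tss + rel - 1 if row.strand == "+" else row.tss - rel + 1
                rows.append({"gene_id": row.gene_id, "label": lab,
                             "pos": pos, "replicate": rep})
    return pd.DataFrame(rows)


REL = {"-1": -110, "+1": 60, "+2": 225, "+3": 390, "+4": 555}


class TestShapeNormalize:
    def test_hand_worked_zscore(self):
        z = shape_normalize_gene([0, 0, 4, 0])
        root3 = np.sqrt(3)
        assert np.allclose(z, [-1 / root3, -1 / root3, 3 / root3, -1 / root3])

    def test_constant_profile_rejected(self):
        with pytest.raises(DataError):
            shape_normalize_gene([2.0, 2.0, 2.0])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=50))
    def test_mean_zero_sd_one_and_scale_invariance(self, values):
        x = np.asarray(values)
        if x.std() == 0:
            return
        z = shape_normalize_gene(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(z, shape_normalize_gene(10 * x), atol=1e-9)


class TestNucleosomePositions:
    def test_definitions(self):
        ann = _annotation([("g1", "c1", 5000, 7000, "+")])
        dyads = _dyads_from_rel(ann, REL)
        tbl = nucleosome_positions(dyads, ann)
        row = tbl.iloc[0]
        assert row["pos_+1"] == 60 and row["pos_-1"] == -110
        assert row["ndr"] == 170
        assert row["spacing_p1_p2"] == 165
        assert row["spacing_p2_p3"] == 165
        assert row["spacing_p3_p4"] == 165

    def test_translation_and_strand_flip_invariance(self):
        ann_p = _annotation([("g1", "c1", 5000, 7000, "+")])
        ann_m = _annotation([("g1", "c1", 50_000, 52_000, "-")])
        t_p = nucleosome_positions(_dyads_from_rel(ann_p, REL), ann_p)
        t_m = nucleosome_positions(_dyads_from_rel(ann_m, REL), ann_m)
        cols = [c for c in t_p.columns if c not in ("gene_id", "replicate")]
        assert t_p[cols].equals(t_m[cols])

    def test_missing_label_gives_nan(self):
        ann = _annotation([("g1", "c1", 5000, 7000, "+")])
        rel = {k: v for k, v in REL.items() if k != "+3"}
        tbl = nucleosome_positions(_dyads_from_rel(ann, rel), ann)
        assert np.isnan(tbl.iloc[0]["spacing_p2_p3"])
        assert tbl.iloc[0]["ndr"] == 170

    def test_spacing_shift_detected_between_conditions(self):
        ann = _annotation([(f"g{i}", "c1", 5000 + 3000 * i, 7000 + 3000 * i, "+")
                           for i in range(20)])
        wt = _dyads_from_rel(ann, REL, replicates=(1, 2, 3))
        mut_rel = dict(REL)
        for k, shift in (("+2", 10), ("+3", 20), ("+4", 30)):
            mut_rel[k] = REL[k] + shift
        mut = _dyads_from_rel(ann, mut_rel, replicates=(1, 2, 3))
        cmp = compare_position_medians(nucleosome_positions(wt, ann),
                                       nucleosome_positions(mut, ann))
        by = cmp.set_index("statistic")["difference"]
        assert by["spacing_p1_p2"] == 10
        assert by["spacing_p2_p3"] == 10
        assert by["ndr"] == 0


class TestLabelDyads:
    def test_round_trip(self):
        ann = _annotation([("g1", "c1", 5000, 7000, "+"),
                           ("g2", "c1", 9000, 11_000, "-")])
        truth = _dyads_from_rel(ann, REL)
        unlabeled = truth.drop(columns="label")
        labeled = label_dyads(unlabeled, ann)
        merged = labeled.merge(truth, on=["gene_id", "pos", "replicate"],
                               suffixes=("_new", "_true"))
        assert len(merged) == len(truth)
        assert (merged["label_new"] == merged["label_true"]).all()


class TestMnaseFilter:
    def test_short_gene_dropped(self):
        ann = _annotation([("g1", "c1", 5000, 5500, "+")])
        dyads = _dyads_from_rel(ann, REL)
        assert mnase_gene_filter(dyads, ann).empty

    def test_requires_peaks_in_every_replicate(self):
        ann = _annotation([("g1", "c1", 5000, 7000, "+")])
        rel4 = {"+1": 80, "+2": 245, "+3": 410, "+4": 575}
        dy = _dyads_from_rel(ann, rel4, replicates=(1, 2, 3))
        assert list(mnase_gene_filter(dy, ann)["gene_id"]) == ["g1"]
        # third replicate loses one peak -> excluded
        dy3 = dy[~((dy["replicate"] == 3) & (dy["label"] == "+4"))]
        assert mnase_gene_filter(dy3, ann).empty

    def test_exactly_mode(self):
        ann = _annotation([("g1", "c1", 5000, 7000, "+")])
        rel5 = {"+1": 60, "+2": 180, "+3": 300, "+4": 420, "+5": 540}
        dy = _dyads_from_rel(ann, rel5)
        assert mnase_gene_filter(dy, ann, mode="at_least").shape[0] == 1
        assert mnase_gene_filter(dy, ann, mode="exactly").empty


class TestExpressionGroups:
    def test_equal_size_quantile_split(self):
        expr = pd.Series(np.arange(16, dtype=float), index=[f"g{i}" for i in range(16)])
        spc = pd.Series(165.0, index=expr.index)
        out = expression_group_spacing(expr, spc, n_groups=8)
        assert list(out["n_genes"]) == [2] * 8

    def test_monotone_generator_recovered(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(400)]
        dens = pd.Series(10 ** rng.uniform(0, 3, 400), index=genes)
        spc = pd.Series(180 - 10 * np.log10(dens) + rng.normal(0, 1, 400),
                        index=genes)
        out = expression_group_spacing(dens, spc, n_groups=8)
        med = out["median_spacing"].to_numpy()
        assert (np.diff(med) < 0).all()

    def test_fewer_genes_than_groups_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(DataError):
            expression_group_spacing(s, s, n_groups=8)


def _flank_dataset(n_genes=30, boost=0.0, dyad_spike=None, seed=0):
    """Deterministic-ish tracks with per-gene NET level and TEF = NET * mod."""
    rng = np.random.default_rng(seed)
    entries = []
    length = n_genes * 2000 + 4000
    net_p = np.zeros(length)
    tef_p = np.zeros(length)
    for i in range(n_genes):
        start = 2000 + i * 2000
        entries.append((f"g{i}", "c1", start, start + 1500, "+"))
        level = rng.uniform(5, 15)
        net_p[start:start + 1500] = level
        mod = np.ones(1500)
        rel2 = 225 - 1  # offset of the +2 dyad
        mod[rel2 + 10:rel2 + 61] *= 1.0 + boost
        tef_p[start:start + 1500] = level * mod
        if dyad_spike is not None:
            tef_p[start + rel2] = dyad_spike
    ann = _annotation(entries)
    net = SignalTrack("net", {"c1": {"+": net_p, "-": np.zeros(length)}})
    tef = SignalTrack("tef", {"c1": {"+": tef_p, "-": np.zeros(length)}})
    dyads = _dyads_from_rel(ann, REL)
    return net, tef, ann, dyads


class TestRatioMetagene:
    def test_identical_tracks_give_unit_ratio(self):
        net, _, ann, dyads = _flank_dataset()
        res = ratio_metagene(net, net, ann, dyads, window=(-100, 600))
        defined = ~np.isnan(res.bins)
        assert defined.any()
        assert np.allclose(res.bins[defined], 1.0)

    def test_zero_net_bins_masked(self):
        net, tef, ann, dyads = _flank_dataset()
        res = ratio_metagene(tef, net, ann, dyads, anchor_label="+1",
                             window=(-300, 100))
        # bins upstream of the gene have zero NET coverage -> NaN, not inf
        assert np.isnan(res.bins[:10]).any()
        assert not np.isinf(res.bins[~np.isnan(res.bins)]).any()


class TestFlankAsymmetry:
    def test_downstream_boost_detected(self):
        net, tef, ann, dyads = _flank_dataset(boost=0.2, seed=1)
        table, p = flank_asymmetry_test(tef, net, ann, dyads, "+2")
        assert p < 1e-6
        assert (table["downstream"] > table["upstream"]).all()

    def test_core_spike_ignored(self):
        """The +/-10 nt core is excluded, so a spike at the dyad itself
        cannot drive the test."""
        net, tef, ann, dyads = _flank_dataset(boost=0.1, seed=2)
        t_clean, p_clean = flank_asymmetry_test(tef, net, ann, dyads, "+2")
        net2, tef2, ann2, dyads2 = _flank_dataset(boost=0.1, dyad_spike=1e6, seed=2)
        t_spiked, p_spiked = flank_asymmetry_test(tef2, net2, ann2, dyads2, "+2")
        assert p_spiked == pytest.approx(p_clean)
        assert np.allclose(t_clean[["upstream", "downstream"]],
                           t_spiked[["upstream", "downstream"]])

    def test_too_few_genes_rejected(self):
        net, tef, ann, dyads = _flank_dataset(n_genes=1)
        with pytest.raises(DataError):
            flank_asymmetry_test(tef, net, ann, dyads, "+2")


def test_tss_relative_positions():
    assert tss_relative_position(100, 100, "+") == 1
    assert tss_relative_position(109, 100, "+") == 10
    assert tss_relative_position(91, 100, "-") == 10
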