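"""Anchor selection, metagene aggregation and expression gene sets."""

import numpy as np
import pandas as pd
import pytest

import nucdyn as nd
from nucdyn.aggregate import (ANCHOR_KINDS, FOLD_PRESETS, LENGTH_WINDOW_1800,
                              oscillation_amplitude, profile_periodicity)

from conftest import make_track


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                       "start", "end", "tss", "tts"])


def _calls(mids, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "midpoint": mids, "height": 2.0,
                         "well_positioned": True,
                         "dist_left": np.nan, "dist_right": np.nan})


PLUS_GENE = _genes([("g1", "chr1", "+", 1000, 2001, 1000, 2000)])
MINUS_GENE = _genes([("g1", "chr1", "-", 1000, 2001, 2000, 1000)])


class TestSelectAnchor:
    def test_plus_strand_definitions(self):
        calls = _calls([950, 1080, 1230])
        a, _ = nd.select_anchor(PLUS_GENE, calls, "+1N")
        assert a.anchor.iloc[0] == 1080
        a, _ = nd.select_anchor(PLUS_GENE, calls, "-1N")
        assert a.anchor.iloc[0] == 950
        a, _ = nd.select_anchor(PLUS_GENE, calls, "TSS")
        assert a.anchor.iloc[0] == 1000

    def test_central_nucleosome_closest_to_midgene(self):
        calls = _calls([1400, 1520, 1600])
        a, _ = nd.select_anchor(PLUS_GENE, calls, "CN")
        assert a.anchor.iloc[0] == 1520            # closest to 1500

    def test_central_tie_goes_upstream(self):
        calls = _calls([1400, 1600])               # both 100 from mid 1500
        a, _ = nd.select_anchor(PLUS_GENE, calls, "CN")
        assert a.anchor.iloc[0] == 1400
        a, _ = nd.select_anchor(MINUS_GENE, calls, "CN")
        assert a.anchor.iloc[0] == 1600            # upstream for a minus gene

    def test_terminal_nucleosome_upstream_of_tts(self):
        calls = _calls([1850, 1950, 2100])
        a, _ = nd.select_anchor(PLUS_GENE, calls, "TN")
        assert a.anchor.iloc[0] == 1950

    def test_minus_strand_mirrors_plus(self):
        """Mirroring all coordinates turns +1N of a + gene into +1N of a - gene."""
        L = 3000
        plus_calls = _calls([950, 1080, 1230])
        mirrored = _calls(sorted(L - 1 - m for m in [950, 1080, 1230]))
        g_minus = _genes([("g1", "chr1", "-", L - 2001, L - 1000,
                           L - 1 - 1000, L - 1 - 2000)])
        for kind in ("+1N", "-1N", "CN", "TN"):
            a_plus, _ = nd.select_anchor(PLUS_GENE, plus_calls, kind)
            a_minus, _ = nd.select_anchor(g_minus, mirrored, kind)
            assert a_minus.anchor.iloc[0] == L - 1 - a_plus.anchor.iloc[0]

    def test_gene_without_candidate_is_skipped(self):
        calls = _calls([500])                       # nothing downstream of TSS
        a, skipped = nd.select_anchor(PLUS_GENE, calls, "+1N")
        assert a.empty and skipped == ["g1"]

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            nd.select_anchor(PLUS_GENE, _calls([1100]), "+2N")


class TestAggregateProfile:
    def test_single_gene_identity(self, rng):
        occ = rng.random(5000) + 0.5
        track = make_track({"chr1": occ})
        anchors = pd.DataFrame([("g1", "chr1", "+", 2000, "+1N")],
                               columns=["gene_id", "chrom", "strand", "anchor", "kind"])
        prof = nd.aggregate_profile(track, anchors, flank=100)
        np.testing.assert_allclose(prof.mean_occupancy, occ[1900:2101])
        assert (prof.n_genes == 1).all()

    def test_constant_track_invariance(self):
        track = make_track({"chr1": np.ones(4000)})
        anchors = pd.DataFrame([("g1", "chr1", "+", 2000, "TSS"),
                                ("g2", "chr1", "-", 1500, "TSS")],
                               columns=["gene_id", "chrom", "strand", "anchor", "kind"])
        prof = nd.aggregate_profile(track, anchors, flank=500)
        np.testing.assert_allclose(prof.mean_occupancy, 1.0)

    def test_minus_strand_window_is_reversed(self, rng):
        occ = rng.random(1000)
        track = make_track({"chr1": occ})
        anchors = pd.DataFrame([("g1", "chr1", "-", 500, "TSS")],
                               columns=["gene_id", "chrom", "strand", "anchor", "kind"])
        prof = nd.aggregate_profile(track, anchors, flank=50)
        np.testing.assert_allclose(prof.mean_occupancy, occ[550:449:-1])

    def test_edge_attrition_tracked(self):
        track = make_track({"chr1": np.ones(300)})
        anchors = pd.DataFrame([("g1", "chr1", "+", 10, "TSS")],
                               columns=["gene_id", "chrom", "strand", "anchor", "kind"])
        prof = nd.aggregate_profile(track, anchors, flank=50)
        assert prof.n_genes.iloc[0] == 0 and np.isnan(prof.mean_occupancy.iloc[0])
        assert prof.n_genes.iloc[-1] == 1

    def test_empty_anchor_set_raises(self):
        with pytest.raises(ValueError):
            nd.aggregate_profile(make_track({"chr1": np.ones(100)}),
                                 pd.DataFrame(columns=["gene_id", "chrom", "strand",
                                                       "anchor", "kind"]), 10)

    def test_strand_symmetry_of_aggregate(self):
        """Mirroring the genome (coords and strands) leaves the profile unchanged."""
        cfg = nd.SimConfig(chrom_length=80_000, n_genes=15, seed=13, coverage=50)
        _, genes, chromatin, reads = nd.simulate_dataset(cfg, ["a"])
        track, _ = nd.track_from_reads(reads["a"])
        calls = nd.call_peaks(track)
        anchors, _ = nd.select_anchor(genes, calls, "+1N")
        prof = nd.aggregate_profile(track, anchors, flank=400)
        L = cfg.chrom_length
        m_track = make_track({"chr1": track.data["chr1"][::-1].copy()})
        m_anchors = anchors.copy()
        m_anchors["anchor"] = L - 1 - m_anchors["anchor"]
        m_anchors["strand"] = m_anchors["strand"].map({"+": "-", "-": "+"})
        m_prof = nd.aggregate_profile(m_track, m_anchors, flank=400)
        np.testing.assert_allclose(prof.mean_occupancy, m_prof.mean_occupancy)


class TestExpressionSelection:
    def _expr_genes(self):
        g = _genes([(f"g{i}", "chr1", "+", i * 3000, i * 3000 + 1800,
                     i * 3000, i * 3000 + 1799) for i in range(6)])
        g["expression_fold"] = [3.9, 4.1, 20.0, 64.0, 180.0, 1.0]
        return g

    def test_bin_boundaries(self):
        sel = nd.select_genes_by_expression(self._expr_genes(), (4, 16))
        assert list(sel.gene_id) == ["g1"]          # 3.9 below, 20 above

    def test_n_zero_and_short_supply(self):
        genes = self._expr_genes()
        assert nd.select_genes_by_expression(genes, (4, 16), n=0).empty
        sel = nd.select_genes_by_expression(genes, (4, 16), n=10)
        assert len(sel) == 1                        # all matches, with a warning

    def test_planted_bins_recovered_exactly(self, rng):
        rows, expect = [], {}
        gid = 0
        for lo, hi in [(4, 16), (16, 64), (64, 180)]:
            ids = []
            for _ in range(10):
                rows.append((f"g{gid:03d}", "chr1", "+", gid * 3000,
                             gid * 3000 + 1800, gid * 3000, gid * 3000 + 1799,
                             float(rng.uniform(lo, hi - 0.01))))
                ids.append(f"g{gid:03d}")
                gid += 1
            expect[(lo, hi)] = set(ids)
        genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start",
                                            "end", "tss", "tts", "expression_fold"])
        for bin_, ids in expect.items():
            sel = nd.select_genes_by_expression(genes, bin_, n=10)
            assert set(sel.gene_id) == ids

    def test_length_window_and_presets(self):
        genes = self._expr_genes()
        genes.loc[1, "tts"] = genes.loc[1, "tss"] + 500     # too short for ~1800 bp
        sel = nd.select_genes_by_expression(genes, (4, 16),
                                            length_window=LENGTH_WINDOW_1800)
        assert sel.empty
        assert FOLD_PRESETS["overexpressed"] == 1.5 and FOLD_PRESETS["strong"] == 4.0

    def test_missing_expression_column(self):
        with pytest.raises(ValueError):
            nd.select_genes_by_expression(PLUS_GENE, (4, 16))


def test_cn_alignment_symmetric_without_fuzz():
    """CN-aligned aggregate of fuzz-free arrays is symmetric about offset 0."""
    # ~1800 bp genes so the +/-300 bp window stays inside the periodic gene
    # body and never reaches the (asymmetric) promoter NDR
    cfg = nd.SimConfig(n_chromosomes=1, chrom_length=300_000, n_genes=80,
                       seed=17, coverage=50, fuzziness_sd=0, gene_length_mean=1800)
    _, genes, chromatin, reads = nd.simulate_dataset(cfg, ["a"])
    track, _ = nd.track_from_reads(reads["a"], level=3)   # jitter-free peaks
    calls = nd.call_peaks(track)
    anchors, _ = nd.select_anchor(genes, calls, "CN")
    prof = nd.aggregate_profile(track, anchors, flank=300)
    v = prof.set_index("offset")["mean_occupancy"]
    asym = max(abs(v[o] - v[-o]) for o in range(1, 301))
    assert asym <= 0.05 * v.max()


def test_plus1_alignment_sharper_and_periodic():
    cfg = nd.SimConfig(n_chromosomes=2, chrom_length=300_000, n_genes=200,
                       seed=4, coverage=50, gene_length_mean=1200)
    _, genes, chromatin, reads = nd.simulate_dataset(cfg, ["a"])
    track, _ = nd.track_from_reads(reads["a"])
    calls = nd.call_peaks(track)
    plus1, _ = nd.select_anchor(genes, calls, "+1N")
    tss, _ = nd.select_anchor(genes, calls, "TSS")
    p1 = nd.aggregate_profile(track, plus1, flank=1000)
    pt = nd.aggregate_profile(track, tss, flank=1000)
    assert len(plus1) >= 190
    assert abs(profile_periodicity(p1) - 152) <= 4
    assert oscillation_amplitude(p1) > oscillation_amplitude(pt)
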