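"""EIP arithmetic, junction parsing, gating, aggregation, variance and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicemorph import splicing as sp

VOXEL_EVENTS = None  # placeholder to keep namespace tidy


def make_annotation():
    inc = [
        sp.Junction("chr3", 100, 199, 1),
        sp.Junction("chr3", 250, 349, 1),
    ]
    exc = [sp.Junction("chr3", 100, 349, 1)]
    return [sp.ExonEvent(gene="Adgrl2", event="9", inclusion=inc,
                         exclusion=exc)]


class TestEIP:
    @pytest.mark.parametrize(
        "I,E,expected", [(10, 0, 1.0), (0, 5, 0.0), (10, 5, 0.5)]
    )
    def test_values(self, I, E, expected):
        assert sp.compute_eip(I, E) == pytest.approx(expected)

    def test_uncovered_event_is_missing(self):
        assert np.isnan(sp.compute_eip(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sp.compute_eip(-1, 2)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_bounds(self, I, E):
        eip = sp.compute_eip(I, E)
        if I + E > 0:
            assert 0.0 <= eip <= 1.0
        if I > 0 and E == 0:
            assert eip == 1.0
        if E > 0 and I == 0:
            assert eip == 0.0


class TestVariantEIP:
    @pytest.mark.parametrize(
        "Ia,Ib,E,expected",
        [
            (5, 5, 0, (0.5, 0.5)),
            (0, 0, 10, (0.0, 0.0)),
            (6, 2, 1, (6 / 9, 2 / 9)),
        ],
    )
    def test_values(self, Ia, Ib, E, expected):
        a, b = sp.compute_variant_eip(Ia, Ib, E)
        assert (a, b) == pytest.approx(expected)

    def test_all_zero_is_missing(self):
        a, b = sp.compute_variant_eip(0, 0, 0)
        assert np.isnan(a) and np.isnan(b)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 10**4), st.integers(0, 10**4), st.integers(0, 10**4))
    def test_sum_bounded_by_one(self, Ia, Ib, E):
        a, b = sp.compute_variant_eip(Ia, Ib, E)
        if Ia + Ib + E > 0:
            assert a + b <= 1 + 1e-9
            if E == 0 and Ia + Ib > 0:
                assert a + b == pytest.approx(1.0)


class TestSJTab:
    def test_inclusion_reads_summed(self, tmp_path):
        path = tmp_path / "SJ.out.tab"
        path.write_text(
            "chr3\t100\t199\t1\t1\t1\t5\t0\t30\n"
            "chr3\t250\t349\t1\t1\t1\t5\t2\t30\n"
        )
        table, side = sp.read_sj_tab(path, make_annotation())
        assert table.loc[0, "I"] == 10
        assert table.loc[0, "E"] == 0
        assert side.empty

    def test_empty_file_gives_zero_counts(self, tmp_path):
        path = tmp_path / "SJ.out.tab"
        path.write_text("")
        table, _ = sp.read_sj_tab(path, make_annotation())
        assert (table[["I", "E"]] == 0).all().all()

    def test_unmatched_junction_goes_to_side_table(self, tmp_path):
        path = tmp_path / "SJ.out.tab"
        path.write_text("chr9\t1\t99\t1\t1\t1\t7\t0\t30\n")
        table, side = sp.read_sj_tab(path, make_annotation())
        assert (table[["I", "E"]] == 0).all().all()
        assert len(side) == 1 and side.loc[0, "unique_reads"] == 7

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "SJ.out.tab"
        path.write_text("chr3\t100\t199\t1\t1\t1\t5\t0\t30\nbroken line\n")
        with pytest.raises(ValueError, match="line 2"):
            sp.read_sj_tab(path, make_annotation())

    def test_strand_mismatch_not_counted_when_strand_aware(self, tmp_path):
        path = tmp_path / "SJ.out.tab"
        path.write_text("chr3\t100\t199\t2\t1\t1\t5\t0\t30\n")
        table, side = sp.read_sj_tab(path, make_annotation())
        assert table.loc[0, "I"] == 0
        table2, _ = sp.read_sj_tab(
            path, make_annotation(), match_strand=False
        )
        assert table2.loc[0, "I"] == 5


class TestDetectionGate:
    def test_no_reads_fails(self):
        table = pd.DataFrame({"cell": ["c"], "event": ["e"], "I": [0],
                              "E": [0]})
        totals = pd.Series({"c": 1e6})
        assert not sp.detection_gate(table, totals).iloc[0]

    def test_boundary_equals_threshold_fails(self):
        # CPM(I) = 1 -> log2(2) = 1, not > 1
        table = pd.DataFrame({"cell": ["c"], "event": ["e"], "I": [1],
                              "E": [0]})
        totals = pd.Series({"c": 1e6})
        assert not sp.detection_gate(table, totals).iloc[0]

    def test_clear_detection_passes(self):
        table = pd.DataFrame({"cell": ["c"], "event": ["e"], "I": [4],
                              "E": [0]})
        totals = pd.Series({"c": 1e6})
        assert sp.detection_gate(table, totals).iloc[0]

    def test_exclusion_reads_alone_suffice(self):
        table = pd.DataFrame({"cell": ["c"], "event": ["e"], "I": [0],
                              "E": [4]})
        totals = pd.Series({"c": 1e6})
        assert sp.detection_gate(table, totals).iloc[0]


class TestAggregation:
    def test_unanimous_cells(self):
        table = pd.DataFrame(
            {
                "cell": ["c0", "c1"],
                "event": ["e", "e"],
                "I": [10, 20],
                "E": [0, 0],
            }
        )
        cells = sp.cell_eip_table(table)
        labels = pd.Series(["s"] * 2, index=["c0", "c1"])
        eip, n = sp.aggregate_by_subclass(cells, labels, min_cells=1)
        assert eip.loc["s", "e"] == 1.0
        assert n.loc["s", "e"] == 2

    def test_small_subclass_dropped(self):
        table = pd.DataFrame(
            {"cell": [f"c{i}" for i in range(60)], "event": "e",
             "I": 10, "E": 0}
        )
        cells = sp.cell_eip_table(table)
        labels = pd.Series(["s"] * 60, index=table["cell"])
        eip, _ = sp.aggregate_by_subclass(cells, labels, min_cells=100)
        assert eip.empty

    def test_estimator_recovers_truth_within_3se(self, junction_sim):
        truth, table, matrix = junction_sim
        cells = sp.cell_eip_table(table, matrix.cell_totals)
        eip, n = sp.aggregate_by_subclass(
            cells, matrix.labels, min_cells=100
        )
        for event in truth.psi.index:
            psi = truth.psi.loc[event, "glut"]
            per_cell = cells[(cells["event"] == event)
                             & cells["eip"].notna()]["eip"]
            se = per_cell.std(ddof=1) / np.sqrt(len(per_cell))
            assert abs(eip.loc["glut", event] - psi) <= 3 * se + 1e-12

    def test_pooled_mode_matches_formula(self):
        table = pd.DataFrame(
            {
                "cell": ["c0", "c1"],
                "event": ["e", "e"],
                "I": [10, 0],
                "E": [0, 10],
            }
        )
        cells = sp.cell_eip_table(table)
        labels = pd.Series(["s"] * 2, index=["c0", "c1"])
        pooled, _ = sp.aggregate_by_subclass(
            cells, labels, min_cells=1, mode="pooled"
        )
        # pooled I=10, E=10 -> 10/30
        assert pooled.loc["s", "e"] == pytest.approx(1 / 3)


class TestSplicingVariation:
    def test_constant_eip_zero_variance(self):
        m = pd.DataFrame({"e": [0.5, 0.5, 0.5]},
                         index=["s1", "s2", "s3"])
        res = sp.splicing_variation(m, {"e": "g"})
        assert res["event_variance"]["e"] == 0

    def test_population_variance(self):
        m = pd.DataFrame({"e": [0.0, 1.0]}, index=["s1", "s2"])
        res = sp.splicing_variation(m, {"e": "g"})
        assert res["event_variance"]["e"] == pytest.approx(0.25)

    def test_family_fractions_sum_to_one(self, rng):
        events = [f"e{i}" for i in range(9)]
        genes = {e: f"Adgrl{i % 3 + 1}" for i, e in enumerate(events)}
        m = pd.DataFrame(
            rng.uniform(size=(6, 9)), columns=events,
            index=[f"s{i}" for i in range(6)],
        )
        res = sp.splicing_variation(m, genes)
        assert res["family_fraction"].sum() == pytest.approx(1.0)

    def test_single_gene_takes_whole_family(self):
        m = pd.DataFrame({"e1": [0.0, 1.0], "e2": [0.3, 0.3]},
                         index=["s1", "s2"])
        res = sp.splicing_variation(m, {"e1": "g1", "e2": "g2"})
        assert res["family_fraction"]["g1"] == pytest.approx(1.0)

    def test_undersampled_event_skipped_with_warning(self):
        m = pd.DataFrame({"e": [0.5, np.nan]}, index=["s1", "s2"])
        with pytest.warns(UserWarning, match="<2 subclasses"):
            res = sp.splicing_variation(m, {"e": "g"})
        assert "e" not in res["event_variance"].index


class TestPCA:
    def make_two_cluster_matrix(self, rng):
        high = 0.9 + 0.02 * rng.standard_normal((6, 8))
        low = 0.1 + 0.02 * rng.standard_normal((5, 8))
        X = np.clip(np.vstack([high, low]), 0, 1)
        return pd.DataFrame(
            X,
            index=[f"neuron{i}" for i in range(6)]
            + [f"endo{i}" for i in range(5)],
            columns=[f"e{j}" for j in range(8)],
        )

    def test_two_clusters_separate_on_pc1(self, rng):
        m = self.make_two_cluster_matrix(rng)
        emb = sp.pca_embed(m)
        pc1 = emb.scores["PC1"]
        assert (pc1[:6] > 0).all() != (pc1[6:] > 0).all()  # opposite signs

    def test_reconstruction(self, rng):
        m = self.make_two_cluster_matrix(rng)
        emb = sp.pca_embed(m)
        recon = (
            emb.scores.to_numpy() @ emb.loadings.to_numpy().T
            + emb.column_means.to_numpy()
        )
        np.testing.assert_allclose(recon, m.to_numpy(), atol=1e-8)

    def test_missing_values_rejected(self):
        m = pd.DataFrame([[0.1, np.nan], [0.2, 0.3]])
        with pytest.raises(ValueError, match="missing"):
            sp.pca_embed(m)

    def test_degenerate_zero_variance_flagged(self):
        m = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]])
        emb = sp.pca_embed(m)
        assert emb.degenerate

    def test_sign_convention_deterministic(self, rng):
        m = self.make_two_cluster_matrix(rng)
        a = sp.pca_embed(m)
        b = sp.pca_embed(m.iloc[::-1])  # permuted rows
        for pc in ("PC1", "PC2"):
            peak = a.loadings[pc].abs().idxmax()
            assert a.loadings.loc[peak, pc] > 0
            assert b.loadings.loc[b.loadings[pc].abs().idxmax(), pc] > 0

    def test_explained_ratios_nonincreasing_in_unit_interval(self, rng):
        m = self.make_two_cluster_matrix(rng)
        r = sp.pca_embed(m).explained_variance_ratio
        assert (r >= 0).all() and (r <= 1).all()
        assert (np.diff(r) <= 1e-12).all()


class TestExonCodingImpact:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGATG", (6, True, 2)), ("ATGA", (4, False, None))],
    )
    def test_arithmetic(self, seq, expected):
        assert sp.exon_coding_impact(seq) == expected

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            sp.exon_coding_impact("ATGN")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.exon_coding_impact("")

    def test_packaged_mini_exon_encodes_four_residues(self):
        table = sp.load_exon_table()
        seq = table.query("gene == 'Adgrl2' and exon == '9'")[
            "sequence"
        ].item()
        assert sp.exon_coding_impact(seq) == (12, True, 4)
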