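import numpy as np
import pandas as pd
import pytest

from methmark.expression import (classify_region, concordance,
                                 concordance_table, expression_status,
                                 location_expression_table, log_cpm,
                                 tissue_repression)

from conftest import make_sheet


def entry(pos, strand="+", gene="G", tss=None, start=None, end=None):
    return {"pos": float(pos), "strand": strand, "gene": gene,
            "tss_pos": float(tss) if tss is not None else np.nan,
            "gene_start": float(start) if start is not None else np.nan,
            "gene_end": float(end) if end is not None else np.nan}


class TestClassifyRegion:
    def test_upstream_of_tss_is_promoter(self):
        assert classify_region(entry(9000, tss=10000, start=10000,
                                     end=20000)) == "promoter"

    def test_one_past_the_downstream_boundary_is_gene_body(self):
        assert classify_region(entry(10301, tss=10000, start=10000,
                                     end=20000)) == "gene_body"

    def test_no_gene_is_intergenic(self):
        assert classify_region(entry(500, gene="")) == "intergenic"

    def test_promoter_window_is_strand_oriented(self):
        # minus strand: upstream means larger coordinates
        assert classify_region(entry(11000, strand="-", tss=10000,
                                     start=5000, end=10000)) == "promoter"
        assert classify_region(entry(9000, strand="-", tss=10000,
                                     start=5000, end=10000)) == "gene_body"

    def test_mirroring_about_tss_preserves_class(self):
        # plus-strand probe at TSS-1000 == minus-strand probe at TSS+1000
        plus = classify_region(entry(9000, "+", tss=10000, start=10000,
                                     end=20000))
        minus = classify_region(entry(11000, "-", tss=10000, start=0,
                                      end=10000))
        assert plus == minus == "promoter"

    def test_gene_without_tss_rejected(self):
        with pytest.raises(ValueError, match="tss"):
            classify_region(entry(100, tss=None, start=50, end=200))


class TestLogCpm:
    def test_single_gene_normalization_identity(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        out = log_cpm(counts, pseudocount=0.5)
        assert out.iloc[0, 0] == pytest.approx(np.log2(1e6 + 0.5))

    def test_cpm_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)))
        cpm = 2.0 ** log_cpm(counts) - 0.5
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_matches_per_cell_brute_force(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, size=(5, 3)),
                              index=list("abcde"))
        out = log_cpm(counts, pseudocount=0.5)
        for g in counts.index:
            for s in counts.columns:
                expected = np.log2(
                    counts.at[g, s] / counts[s].sum() * 1e6 + 0.5)
                assert out.at[g, s] == pytest.approx(expected)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]})
        with pytest.raises(ValueError):
            log_cpm(counts)


def _expr_fixture(t_cpm, c_cpm):
    """log-CPM frame for one gene from raw CPM group values."""
    vals = np.log2(np.concatenate([t_cpm, c_cpm]) + 0.5)
    cols = [f"t{i}" for i in range(len(t_cpm))] + \
           [f"c{i}" for i in range(len(c_cpm))]
    logcpm = pd.DataFrame([vals], index=["G"], columns=cols)
    sheet = make_sheet(cols, ["tumor"] * len(t_cpm)
                       + ["adjacent"] * len(c_cpm))
    return logcpm, sheet


class TestExpressionStatus:
    def test_low_medians_in_both_groups(self):
        logcpm, sheet = _expr_fixture(np.full(10, 0.2), np.full(10, 0.1))
        assert expression_status("G", logcpm, sheet) == "not_expressed"

    def test_clear_shift_called_up(self):
        rng = np.random.default_rng(2)
        t = 2.0 ** rng.normal(8, 0.5, size=30)
        c = 2.0 ** rng.normal(5, 0.5, size=30)
        logcpm, sheet = _expr_fixture(t, c)
        assert expression_status("G", logcpm, sheet) == "up"

    def test_identical_groups_unchanged(self):
        logcpm, sheet = _expr_fixture(np.full(10, 50.0), np.full(10, 50.0))
        assert expression_status("G", logcpm, sheet) == "unchanged"

    def test_swapping_groups_flips_direction(self):
        rng = np.random.default_rng(3)
        t = 2.0 ** rng.normal(8, 0.5, size=30)
        c = 2.0 ** rng.normal(5, 0.5, size=30)
        logcpm, sheet = _expr_fixture(t, c)
        flipped = sheet.copy()
        flipped["group"] = flipped["group"].map(
            {"tumor": "adjacent", "adjacent": "tumor"})
        assert expression_status("G", logcpm, flipped) == "down"

    def test_small_group_falls_back_to_mannwhitney(self):
        logcpm, sheet = _expr_fixture(np.full(5, 100.0),
                                      np.linspace(10, 12, 10))
        with pytest.warns(UserWarning, match="Mann-Whitney"):
            expression_status("G", logcpm, sheet)


class TestConcordance:
    @pytest.mark.parametrize("region,status,expected", [
        ("promoter", "down", True),
        ("promoter", "up", False),     # the SEPT9-like exception
        ("gene_body", "up", True),
        ("gene_body", "down", False),  # the AMN-like exception
        ("promoter", "unchanged", None),
        ("intergenic", "down", None),
    ])
    def test_rules(self, region, status, expected):
        assert concordance(region, status) is expected


class TestTissueRepression:
    def _tpm(self, liver, others):
        cols = ["liver"] + [f"t{i}" for i in range(len(others))]
        return pd.DataFrame([[liver] + list(others)], index=["G"],
                            columns=cols)

    def test_repressed_in_index(self):
        tpm = self._tpm(0.1, [20.0] * 10)
        assert tissue_repression("G", tpm) == "repressed_in_index"

    def test_broadly_silent(self):
        tpm = self._tpm(0.1, [0.5] * 10)
        assert tissue_repression("G", tpm) == "broadly_silent"

    def test_expressed_in_index(self):
        tpm = self._tpm(50.0, [20.0] * 10)
        assert tissue_repression("G", tpm) == "expressed_in_index"

    def test_absent_gene_rejected(self):
        with pytest.raises(ValueError):
            tissue_repression("X", self._tpm(1, [1, 1]))

    def test_planted_patterns_recovered(self, small_data):
        truth = small_data.truth
        for _, row in truth.genes.iterrows():
            got = tissue_repression(row["gene"], small_data.tpm)
            assert got == row["tissue_pattern"]


class TestLocationTable:
    def test_distinct_gene_rule(self):
        records = pd.DataFrame({
            "probe_id": ["cg1", "cg2"], "gene": ["G1", "G1"],
            "region": ["promoter", "promoter"],
            "expr_status": ["down", "down"], "concordant": [True, True]})
        table = location_expression_table(records)
        assert table.loc["promoter", "n_cpgs"] == 2
        assert table.loc["promoter", "n_genes"] == 1
        assert table.loc["promoter", "genes_down"] == 1

    def test_empty_input_all_zero(self):
        records = pd.DataFrame(columns=["probe_id", "gene", "region",
                                        "expr_status", "concordant"])
        assert (location_expression_table(records).to_numpy() == 0).all()

    def test_planted_region_split_recovered(self, small_data, small_result):
        cfg = small_data.config
        table = small_result.location_table
        truth_regions = small_data.truth.probes.loc[
            small_data.truth.probes["class"].isin(
                ("panel_branch_a", "panel_branch_b")), "region"]
        for region in ("promoter", "gene_body", "intergenic"):
            assert table.loc[region, "n_cpgs"] == (truth_regions == region).sum()
        assert table.loc["total", "n_cpgs"] == cfg.n_panel


class TestConcordanceTable:
    def test_planted_coupling_recovered(self, small_data, small_result):
        truth = small_data.truth
        effects = dict(zip(truth.genes["gene"], truth.genes["effect"]))
        recs = small_result.concordance
        sig = recs[recs["expr_status"].isin(("down", "up"))]
        assert len(sig) > 0
        rate = sig["concordant"].astype(bool).mean()
        assert rate >= 0.9
        for _, row in sig.iterrows():
            assert effects[row["gene"]] == row["expr_status"]
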