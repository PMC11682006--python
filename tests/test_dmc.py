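import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methmark import (bh_adjust, cgi_subset, classify_dmc, cluster_qc,
                      dmc_test, global_hyper_enrichment, group_mean_beta)

from conftest import make_beta, make_sheet


def brute_force_bh(p):
    """Textbook step-up: q_(i) = min over j >= i of m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = running
    return q


class TestGroupMeans:
    def test_constant_matrix(self):
        beta = make_beta(np.full((3, 4), 0.5))
        sheet = make_sheet(beta.columns, ["tumor"] * 4)
        assert group_mean_beta(beta, sheet, "tumor").tolist() == [0.5] * 3

    def test_simple_arithmetic(self):
        beta = make_beta([[0.1, 0.2, 0.6]])
        sheet = make_sheet(beta.columns, ["healthy"] * 3)
        assert group_mean_beta(beta, sheet, "healthy").iloc[0] == pytest.approx(0.3)

    def test_matches_column_subset_means(self):
        rng = np.random.default_rng(3)
        beta = make_beta(rng.uniform(size=(1000, 10)))
        groups = ["tumor"] * 6 + ["healthy"] * 4
        sheet = make_sheet(beta.columns, groups)
        expected = beta.to_numpy()[:, :6].mean(axis=1)
        np.testing.assert_allclose(
            group_mean_beta(beta, sheet, "tumor").to_numpy(), expected)

    def test_empty_group_rejected(self):
        beta = make_beta([[0.1]])
        sheet = make_sheet(beta.columns, ["tumor"])
        with pytest.raises(ValueError):
            group_mean_beta(beta, sheet, "blood")


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 21))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p),
                                       atol=1e-12)
            # identical call sets at the working threshold
            assert ((bh_adjust(p) < 0.05) == (brute_force_bh(p) < 0.05)).all()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_q_at_least_p_and_monotone_in_rank(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestClassify:
    @pytest.mark.parametrize("delta,significant,expected", [
        (0.25, True, "hyper"),
        (-0.25, True, "hypo"),
        (0.2, True, "ns"),          # strict inequality at the boundary
        (-0.2, True, "ns"),
        (0.5, False, "ns"),
    ])
    def test_threshold_rules(self, delta, significant, expected):
        assert classify_dmc(delta, significant, 0.2) == expected


class TestDmcTest:
    def _paired(self, case_vals, ctrl_vals):
        case_vals, ctrl_vals = np.asarray(case_vals), np.asarray(ctrl_vals)
        beta = make_beta(np.hstack([case_vals, ctrl_vals]))
        groups = (["tumor"] * case_vals.shape[1]
                  + ["healthy"] * ctrl_vals.shape[1])
        return beta, make_sheet(beta.columns, groups)

    def test_identical_groups_yield_no_calls(self):
        vals = np.random.default_rng(0).uniform(size=(50, 4))
        beta, sheet = self._paired(vals, vals)
        rec = dmc_test(beta, sheet, "tumor", "healthy")
        assert (rec["delta"] == 0).all()
        assert (rec["status"] == "ns").all()

    def test_planted_effects_recovered_with_low_false_calls(self):
        rng = np.random.default_rng(42)
        n_null, n_planted, n_case, n_ctrl = 5000, 50, 100, 30
        case = rng.beta(2, 38, size=(n_null + n_planted, n_case))
        ctrl = rng.beta(2, 38, size=(n_null + n_planted, n_ctrl))
        # planted case mean 0.5, sd ~0.05 -> delta ~0.45
        case[:n_planted] = rng.beta(49.5, 49.5, size=(n_planted, n_case))
        beta, sheet = self._paired(case, ctrl)
        rec = dmc_test(beta, sheet, "tumor", "healthy").set_index("probe_id")
        planted = beta.index[:n_planted]
        assert (rec.loc[planted, "status"] == "hyper").sum() >= 48
        null_called = (rec.drop(planted)["status"] != "ns").sum()
        assert null_called <= 1

    def test_case_control_swap_negates_delta_and_flips_calls(self):
        rng = np.random.default_rng(5)
        case = rng.beta(30, 10, size=(20, 10))
        ctrl = rng.beta(2, 38, size=(20, 10))
        beta, sheet = self._paired(case, ctrl)
        fwd = dmc_test(beta, sheet, "tumor", "healthy").set_index("probe_id")
        rev = dmc_test(beta, sheet, "healthy", "tumor").set_index("probe_id")
        np.testing.assert_allclose(fwd["delta"], -rev.loc[fwd.index, "delta"])
        flipped = rev.loc[fwd.index, "status"].map(
            {"hyper": "hypo", "hypo": "hyper", "ns": "ns"})
        assert (fwd["status"] == flipped).all()

    def test_zero_variance_probes_do_not_crash(self):
        beta = make_beta([[0.5] * 6, [0.1] * 3 + [0.9] * 3])
        sheet = make_sheet(beta.columns, ["tumor"] * 3 + ["healthy"] * 3)
        rec = dmc_test(beta, sheet, "tumor", "healthy").set_index("probe_id")
        assert rec.loc["cg00000", "p_value"] == 1.0
        assert rec.loc["cg00001", "p_value"] == 0.0
        assert rec.loc["cg00001", "zero_variance"]

    def test_small_groups_rejected(self):
        beta = make_beta([[0.1, 0.2]])
        sheet = make_sheet(beta.columns, ["tumor", "healthy"])
        with pytest.raises(ValueError):
            dmc_test(beta, sheet, "tumor", "healthy")


class TestCgiSubset:
    def _manifest(self, beta, in_cgi):
        return pd.DataFrame({
            "chrom": "chr1", "pos": 100.0, "strand": "+",
            "in_cgi": in_cgi, "gene": "", "tss_pos": np.nan,
            "gene_start": np.nan, "gene_end": np.nan}, index=beta.index)

    def test_all_cgi_is_identity(self):
        beta = make_beta(np.random.default_rng(0).uniform(size=(5, 2)))
        sub = cgi_subset(beta, self._manifest(beta, [True] * 5))
        pd.testing.assert_frame_equal(sub, beta)

    def test_filter_matches_brute_force(self):
        rng = np.random.default_rng(8)
        beta = make_beta(rng.uniform(size=(1000, 2)))
        flags = rng.random(1000) < 0.4
        sub = cgi_subset(beta, self._manifest(beta, flags))
        assert sub.index.tolist() == [p for p, f in zip(beta.index, flags) if f]

    def test_probe_absent_from_manifest_rejected(self):
        beta = make_beta([[0.1], [0.2]])
        mf = self._manifest(beta.iloc[:1], [True])
        with pytest.raises(ValueError, match="absent"):
            cgi_subset(beta, mf)


class TestEnrichment:
    def _records(self, n_hyper, n_hypo, n_ns=0):
        return pd.DataFrame({"status": ["hyper"] * n_hyper
                             + ["hypo"] * n_hypo + ["ns"] * n_ns})

    def test_symmetric_counts_give_p_one(self):
        assert global_hyper_enrichment(self._records(50, 50))[2] == pytest.approx(1.0)

    def test_exact_two_sided_binomial(self):
        # P(X<=2) + P(X>=8) for X ~ Bin(10, 0.5) = 112/1024
        n_hyper, n_hypo, p = global_hyper_enrichment(self._records(8, 2))
        assert (n_hyper, n_hypo) == (8, 2)
        assert p == pytest.approx(112 / 1024)

    def test_hyper_skewed_simulation_is_enriched(self):
        """Hyper-dominant planted run: strong global hypermethylation signal."""
        assert global_hyper_enrichment(self._records(95, 10, 500))[2] < 1e-3

    def test_no_significant_records_rejected(self):
        with pytest.raises(ValueError):
            global_hyper_enrichment(self._records(0, 0, 5))


class TestClusterQC:
    def test_separable_clouds_agree_perfectly(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(0.1, 0.02, size=(30, 10)).clip(0, 1)
        hi = rng.normal(0.8, 0.02, size=(30, 10)).clip(0, 1)
        beta = make_beta(np.hstack([hi, lo]))
        sheet = make_sheet(beta.columns, ["tumor"] * 10 + ["healthy"] * 10)
        _, agreement = cluster_qc(beta, sheet)
        assert agreement == 1.0

    def test_identical_samples_fall_back_to_majority(self):
        beta = make_beta(np.full((5, 10), 0.4))
        sheet = make_sheet(beta.columns, ["tumor"] * 6 + ["healthy"] * 4)
        _, agreement = cluster_qc(beta, sheet)
        assert agreement == pytest.approx(0.6)

    def test_missing_values_rejected(self):
        beta = make_beta([[0.1, np.nan], [0.2, 0.3]])
        sheet = make_sheet(beta.columns, ["tumor", "healthy"])
        with pytest.raises(ValueError):
            cluster_qc(beta, sheet)

    def test_synthetic_discovery_separates_tumors(self, small_data, small_result):
        from methmark import merge_cohorts
        merged, sheet = merge_cohorts(
            [m for m, _ in small_data.cohorts.discovery],
            [s for _, s in small_data.cohorts.discovery])
        candidates = small_result.dmc_records.loc[
            small_result.dmc_records["status"] == "hyper", "probe_id"]
        _, agreement = cluster_qc(merged.loc[candidates], sheet)
        assert agreement >= 0.95
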