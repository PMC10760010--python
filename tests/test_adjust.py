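"""The meta-reductive adjustment: closed form vs leave-one-out oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as st_sp

from metareduce import (
    SimulationConfig,
    adjust_marker,
    adjust_table,
    ivw_pool,
    leave_one_out_meta,
    meta_analyze,
    recompute_significance,
    simulate_cohorts,
)

from conftest import make_table


class TestAdjustMarker:
    def test_three_cohort_closed_form(self):
        """Removing (0.3, 0.1) from the pool of three equal-weight cohorts."""
        meta = ivw_pool([(0.1, 0.1), (0.2, 0.1), (0.3, 0.1)])
        assert meta.B == pytest.approx(0.2, rel=1e-14)
        assert meta.SE**2 == pytest.approx(1 / 300, rel=1e-14)
        r = adjust_marker(meta.B, meta.SE, 0.3, 0.1)
        assert r.status == "adjusted"
        assert r.w_n == pytest.approx(100.0)
        assert r.denom == pytest.approx(2 / 3, rel=1e-14)
        assert r.B_adj == pytest.approx(0.15, rel=1e-12)
        assert r.SE_adj**2 == pytest.approx(0.005, rel=1e-12)
        # independent oracle: direct meta of the two remaining cohorts
        oracle = ivw_pool([(0.1, 0.1), (0.2, 0.1)])
        assert r.B_adj == pytest.approx(oracle.B, rel=1e-12)
        assert r.SE_adj == pytest.approx(oracle.SE, rel=1e-12)

    def test_two_cohort_identity(self):
        meta = ivw_pool([(0.12, 0.08), (-0.05, 0.2)])
        r = adjust_marker(meta.B, meta.SE, -0.05, 0.2)
        assert r.B_adj == pytest.approx(0.12, rel=1e-12)
        assert r.SE_adj == pytest.approx(0.08, rel=1e-12)

    def test_fixed_point_when_cohort_sits_at_pooled_effect(self):
        meta = ivw_pool([(0.2, 0.1), (0.2, 0.05), (0.2, 0.3)])
        r = adjust_marker(meta.B, meta.SE, 0.2, 0.05)
        assert r.B_adj == pytest.approx(meta.B, rel=1e-14)
        assert r.SE_adj > meta.SE

    def test_dominant_cohort_degeneracy(self):
        r = adjust_marker(0.2, 0.1, 0.2, 0.1)  # se_n == SE -> d == 0 exactly
        assert r.status == "dominant_cohort"
        assert np.isnan(r.B_adj) and np.isnan(r.SE_adj)

    def test_inconsistent_inputs(self):
        # cohort claims more weight than the whole meta: se_n < SE
        r = adjust_marker(0.2, 0.1, 0.2, 0.05)
        assert r.status == "inconsistent_inputs"
        assert np.isnan(r.B_adj)

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            adjust_marker(float("inf"), 0.1, 0.1, 0.2)
        with pytest.raises(ValueError, match="positive"):
            adjust_marker(0.1, 0.0, 0.1, 0.2)

    @settings(max_examples=300, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.01, 2)), min_size=2, max_size=7
        ),
        st.integers(0, 6),
    )
    def test_matches_loo_oracle_on_random_pools(self, pairs, idx):
        """Closed-form removal == brute-force re-pool of the rest."""
        idx = idx % len(pairs)
        meta = ivw_pool(pairs)
        rest = [p for i, p in enumerate(pairs) if i != idx]
        oracle = ivw_pool(rest)
        r = adjust_marker(meta.B, meta.SE, *pairs[idx])
        assert r.status == "adjusted"
        assert r.B_adj == pytest.approx(oracle.B, rel=1e-9, abs=1e-9)
        assert r.SE_adj == pytest.approx(oracle.SE, rel=1e-9)
        # monotone information removal
        assert r.SE_adj >= meta.SE
        # round trip: pooling the result with the removed cohort recovers the meta
        back = ivw_pool([(r.B_adj, r.SE_adj), pairs[idx]])
        assert back.B == pytest.approx(meta.B, rel=1e-9, abs=1e-12)
        assert back.SE == pytest.approx(meta.SE, rel=1e-9)

    def test_rejected_equation_grouping_fails_identity(self):
        """The alternative reading of the adjustment formula (the leading
        pooled effect kept outside the fraction) breaks the forced
        two-cohort identity; the implemented grouping satisfies it."""
        meta = ivw_pool([(0.12, 0.08), (-0.05, 0.2)])
        w_n = 1 / 0.2**2
        d = 1 - meta.SE**2 * w_n
        wrong = meta.B + (meta.B * w_n - (-0.05) * w_n) / d
        assert wrong != pytest.approx(0.12, rel=1e-3)
        right = (meta.B - meta.SE**2 * (-0.05) * w_n) / d
        assert right == pytest.approx(0.12, rel=1e-12)


class TestRecomputeSignificance:
    def test_null_point(self):
        z, p = recompute_significance(0.0, 0.3)
        assert z == 0.0 and p == 1.0

    def test_five_percent_quantile(self):
        _, p = recompute_significance(1.959964 * 0.2, 0.2)
        assert p == pytest.approx(0.05, rel=1e-4)

    def test_sign_symmetry_and_range(self):
        for b in (0.01, 1.0, 40.0):
            z1, p1 = recompute_significance(b, 1.0)
            z2, p2 = recompute_significance(-b, 1.0)
            assert p1 == p2
            assert z1 == -z2
            assert 0 < p1 <= 1

    def test_matches_normal_oracle(self):
        z, p = recompute_significance(0.37, 0.11)
        assert p == pytest.approx(2 * st_sp.norm.sf(abs(0.37 / 0.11)), rel=1e-12)


class TestAdjustTable:
    def test_passthrough_bookkeeping(self):
        meta = make_table([
            {"marker_id": f"rs{i}", "effect_allele": "A", "other_allele": "G",
             "beta": 0.1 * i, "se": 0.05} for i in (1, 2, 3)
        ])
        cohort = make_table([
            {"marker_id": f"rs{i}", "effect_allele": "A", "other_allele": "G",
             "beta": 0.05, "se": 0.2} for i in (1, 3)
        ])
        out, report = adjust_table(meta, cohort)
        assert len(out) == 3
        status = dict(zip(out.marker_ids, out.df["status"]))
        assert status == {"rs1": "adjusted", "rs2": "passthrough_not_in_cohort",
                          "rs3": "adjusted"}
        # passthrough keeps meta values verbatim
        row = out.df[out.df["marker_id"] == "rs2"].iloc[0]
        assert row["beta"] == 0.2 and row["se"] == 0.05
        assert report.exclusions["not_in_cohort"] == 1

    def test_matches_loo_oracle_full_overlap(self, small_config):
        tables, _ = simulate_cohorts(small_config)
        meta = meta_analyze(tables)
        for k, cohort in enumerate(tables):
            out, _ = adjust_table(meta, cohort)
            oracle = leave_one_out_meta(tables, k)
            assert (out.df["status"] == "adjusted").all()
            odf = oracle.df.set_index("marker_id").reindex(out.marker_ids)
            np.testing.assert_allclose(out.df["beta"], odf["beta"], rtol=1e-10)
            np.testing.assert_allclose(out.df["se"], odf["se"], rtol=1e-10)

    def test_swapped_cohort_alleles_still_match_oracle(self, small_config):
        from metareduce import perturb_alleles
        tables, _ = simulate_cohorts(small_config)
        meta = meta_analyze(tables)
        perturbed, _ = perturb_alleles(tables[1], fraction_swapped=0.5, seed=99)
        out, _ = adjust_table(meta, perturbed)
        oracle = leave_one_out_meta(tables, 1)
        odf = oracle.df.set_index("marker_id").reindex(out.marker_ids)
        np.testing.assert_allclose(out.df["beta"], odf["beta"], rtol=1e-10)

    def test_output_follows_meta_order(self, small_config):
        tables, _ = simulate_cohorts(small_config)
        meta = meta_analyze(tables)
        shuffled = tables[0]
        shuffled.df = shuffled.df.sample(frac=1, random_state=0).reset_index(drop=True)
        out, _ = adjust_table(meta, shuffled)
        assert list(out.marker_ids) == list(meta.marker_ids)

    def test_iterated_removal_of_two_cohorts(self, small_config):
        """Removing two cohorts one after the other equals the direct
        meta-analysis of the remaining cohorts."""
        tables, _ = simulate_cohorts(small_config)
        meta = meta_analyze(tables)
        once, _ = adjust_table(meta, tables[3])
        twice, _ = adjust_table(once, tables[1])
        oracle = meta_analyze([tables[0], tables[2]])
        odf = oracle.df.set_index("marker_id").reindex(twice.marker_ids)
        assert (twice.df["status"] == "adjusted").all()
        np.testing.assert_allclose(twice.df["beta"].astype(float),
                                   odf["beta"].astype(float), rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(twice.df["se"].astype(float),
                                   odf["se"].astype(float), rtol=1e-10)

    def test_input_precision_sensitivity(self, small_config):
        """Truncating inputs bounds the adjusted-vs-oracle error; the
        discrepancy shrinks as printed precision increases."""
        tables, _ = simulate_cohorts(small_config)

        def max_abs_err(decimals):
            rounded = []
            for t in tables:
                c = make_table([], source_label=t.source_label)
                c.df = t.df.copy()
                c.df["beta"] = c.df["beta"].round(decimals)
                c.df["se"] = c.df["se"].round(decimals)
                rounded.append(c)
            meta = meta_analyze(rounded)
            out, _ = adjust_table(meta, rounded[0])
            oracle = leave_one_out_meta(tables, 0)
            ok = (out.df["status"] == "adjusted").to_numpy()
            odf = oracle.df.set_index("marker_id").reindex(out.marker_ids[ok])
            return float(np.max(np.abs(
                out.df.loc[ok, "beta"].to_numpy() - odf["beta"].to_numpy()
            )))

        errs = [max_abs_err(d) for d in (4, 6, 8)]
        # each two extra digits should shrink the discrepancy ~100-fold
        assert errs[1] < errs[0] / 10
        assert errs[2] < errs[1] / 10
        assert errs[2] < 1e-5
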