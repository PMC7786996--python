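"""Pairing, Yuen-TOST machinery, epsilon calibration and discovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from evtwin import (
    CohortConfig,
    DiscoveryConfig,
    calibrate_epsilon,
    discover_evcpgs,
    independence_check,
    pair_abs_diffs,
    simulate_twin_cohort,
    twin_concordance,
    yuen_tost,
)
from evtwin.equivalence import PairingIndex


class TestPairing:
    def test_two_families_enumerate_correctly(self, tiny_sheet):
        row = pd.Series([0.1, 0.2, 0.4, 0.8], index=tiny_sheet["sample_id"], name="cg0")
        d = pair_abs_diffs(row, tiny_sheet)
        assert len(d.twin_diffs) == 2
        assert len(d.unrelated_diffs) == 4  # C(4,2) - 2 co-twin pairs
        assert sorted(np.round(d.twin_diffs, 6)) == [pytest.approx(0.1), pytest.approx(0.4)]

    def test_equal_betas_give_zero_diffs(self, tiny_sheet):
        row = pd.Series([0.3] * 4, index=tiny_sheet["sample_id"], name="cg0")
        d = pair_abs_diffs(row, tiny_sheet)
        assert (d.twin_diffs == 0).all() and (d.unrelated_diffs == 0).all()

    def test_family_without_two_members_rejected(self):
        sheet = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "b1"],
                "individual_id": ["a1", "a2", "a3", "b1"],
                "family_id": ["A", "A", "A", "B"],
            }
        )
        row = pd.Series([0.1] * 4, index=sheet["sample_id"], name="cg0")
        with pytest.raises(ValueError, match="exactly 2"):
            pair_abs_diffs(row, sheet)

    @pytest.mark.parametrize("seed", range(5))
    def test_disjoint_matching_is_a_perfect_cotwin_free_matching(self, seed):
        n = 3
        sheet = pd.DataFrame(
            {
                "sample_id": [f"f{i}t{j}" for i in range(n) for j in (1, 2)],
                "individual_id": [f"f{i}t{j}" for i in range(n) for j in (1, 2)],
                "family_id": [f"F{i}" for i in range(n) for _ in (1, 2)],
            }
        )
        p = PairingIndex(sheet["sample_id"], sheet)
        a, b = p.unrelated_pairs("disjoint", seed=seed)
        assert len(a) == n
        used = np.concatenate([a, b])
        assert len(np.unique(used)) == 2 * n
        assert (p.family_of[a] != p.family_of[b]).all()

    def test_subsample_mode_draws_without_replacement(self, tiny_sheet):
        p = PairingIndex(tiny_sheet["sample_id"], tiny_sheet)
        a, b = p.unrelated_pairs("subsample", k=3, seed=0)
        assert len(a) == 3
        assert len({(x, y) for x, y in zip(a, b)}) == 3


class TestYuenTost:
    def test_identical_samples_are_equivalent(self, rng):
        x = rng.normal(0.1, 0.01, 200)
        res = yuen_tost(x, x, epsilon=0.05)
        assert res.delta_hat == 0.0
        assert res.p_equiv < 1e-10

    def test_trim_zero_reduces_to_welch(self, rng):
        """At zero trimming, statistic, SE and df equal the Welch t oracle."""
        for _ in range(100):
            n1, n2 = rng.integers(8, 60, size=2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.3, 1.7, n2)
            eps = float(rng.uniform(0.05, 1.0))
            res = yuen_tost(x, y, epsilon=eps, trim=0.0)
            v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
            se = np.sqrt(v1 + v2)
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
            assert res.delta_hat == pytest.approx(x.mean() - y.mean(), abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)

    def test_over_trimmed_sample_rejected(self):
        with pytest.raises(ValueError):
            yuen_tost(np.arange(5.0), np.arange(5.0), epsilon=0.1, trim=0.45)

    def test_zero_se_degenerate_convention(self):
        x = np.full(10, 0.2)
        with pytest.warns(UserWarning):
            res = yuen_tost(x, x, epsilon=0.1)
        assert res.p_equiv == 0.0 and res.degenerate
        with pytest.warns(UserWarning):
            res = yuen_tost(x, x + 0.5, epsilon=0.1)
        assert res.p_equiv == 1.0

    def test_argument_order_symmetry(self, rng):
        x = rng.normal(0.1, 0.03, 80)
        y = rng.normal(0.12, 0.05, 120)
        a = yuen_tost(x, y, epsilon=0.05)
        b = yuen_tost(y, x, epsilon=0.05)
        assert a.p_equiv == pytest.approx(b.p_equiv, rel=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_p_equiv_non_increasing_in_epsilon(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.1, 0.04, 60)
        y = rng.normal(0.13, 0.05, 60)
        ps = [yuen_tost(x, y, epsilon=e).p_equiv for e in np.linspace(0.01, 0.3, 12)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))


class TestEpsilonCalibration:
    def test_constant_vector_returns_constant(self):
        assert calibrate_epsilon(np.full(7, 0.042), q=0.3) == pytest.approx(0.042)

    def test_interpolated_median_of_decile_grid(self):
        v = np.arange(0.01, 0.101, 0.01)
        assert calibrate_epsilon(v, q=0.5) == pytest.approx(0.055)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2])
    def test_quantile_out_of_range(self, q):
        with pytest.raises(ValueError):
            calibrate_epsilon([0.1, 0.2], q=q)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            calibrate_epsilon(np.zeros(5), q=0.5)


class TestDiscovery:
    def test_identical_branches_intersect_to_single_branch_result(self, small_cohort):
        one = discover_evcpgs([small_cohort.beta], small_cohort.sheet)
        three = discover_evcpgs([small_cohort.beta] * 3, small_cohort.sheet)
        assert set(three.evcpgs) == set(one.evcpgs)

    def test_mismatched_branches_rejected(self, small_cohort):
        other = small_cohort.beta.iloc[:-1]
        with pytest.raises(ValueError, match="share"):
            discover_evcpgs([small_cohort.beta, other], small_cohort.sheet)

    def test_final_set_nested_in_branch_sets(self, small_cohort):
        noisy = small_cohort.beta + np.random.default_rng(1).normal(0, 0.005, small_cohort.beta.shape)
        noisy = noisy.clip(0.001, 0.999)
        res = discover_evcpgs([small_cohort.beta, noisy], small_cohort.sheet)
        for br in res.branches:
            assert set(res.evcpgs) <= set(br.significant) <= set(br.tested)

    def test_pure_genetic_probes_fail_equivalence(self):
        """Strong mQTL signal: unrelated variation exceeds the margin, so
        equivalence is rejected for >= 99% of tested genetic probes."""
        cfg = CohortConfig(
            n_pairs=100,
            n_cpgs=300,
            class_fractions={"error_only": 0.0, "genetic": 1.0, "stochastic": 0.0, "mixed": 0.0},
            effect_range=(0.15, 0.15),
            maf_range=(0.3, 0.3),
            seed=12,
        )
        cohort = simulate_twin_cohort(cfg)
        res = discover_evcpgs([cohort.beta], cohort.sheet, cfg=DiscoveryConfig(epsilon=0.028))
        br = res.branches[0]
        assert br.m_tested > 250
        assert (br.results["tm_unrel"] - br.results["tm_twin"] >= br.results["epsilon"]).mean() > 0.95
        assert len(res.evcpgs) <= 0.01 * br.m_tested


class TestConcordance:
    def test_identical_twins_have_unit_concordance(self):
        sheet = pd.DataFrame(
            {
                "sample_id": list("abcd"),
                "individual_id": list("abcd"),
                "family_id": ["A", "A", "B", "B"],
            }
        )
        beta = pd.DataFrame([[0.2, 0.2, 0.8, 0.8]], index=["cg0"], columns=sheet["sample_id"])
        out = twin_concordance(beta, sheet)
        assert out.loc[0, "concordance"] == pytest.approx(1.0)

    def test_constant_probe_flagged_with_zero_range(self, tiny_sheet):
        beta = pd.DataFrame([[0.5] * 4], index=["cg0"], columns=tiny_sheet["sample_id"])
        out = twin_concordance(beta, tiny_sheet)
        assert out.loc[0, "range"] == 0.0
        assert out.loc[0, "concordance"] == 0.0
        assert bool(out.loc[0, "zero_variance"])

    def test_independent_cotwins_have_near_zero_concordance(self):
        cfg = CohortConfig(
            n_pairs=2000,
            n_cpgs=20,
            class_fractions={"error_only": 0.0, "genetic": 0.0, "stochastic": 1.0, "mixed": 0.0},
            seed=8,
        )
        cohort = simulate_twin_cohort(cfg)
        out = twin_concordance(cohort.beta, cohort.sheet)
        assert np.abs(out["concordance"]).max() < 0.1


class TestIndependenceCheck:
    def test_small_cohort_rejected(self):
        cohort = simulate_twin_cohort(CohortConfig(n_pairs=5, n_cpgs=30, seed=1))
        with pytest.raises(ValueError, match="10 twin pairs"):
            independence_check(cohort.beta, cohort.sheet, n_resamples=1)

    def test_agreement_rates_are_valid_fractions(self, small_cohort):
        table, summary = independence_check(
            small_cohort.beta, small_cohort.sheet, n_resamples=2, seed=3
        )
        assert table["agreement"].between(0, 1).all()
        assert 0 <= summary["overall_agreement"] <= 1

    def test_disjoint_matchings_confirm_all_pairs_decisions(self, default_cohort):
        """Exhausting all unrelated pairs does not distort discovery: across
        25 disjoint-matching reruns the overall decision agreement and the
        majority-vote recovery of the evCpG set both stay above 0.9.  Single
        disjoint runs rest on n_pairs unrelated differences, so their
        per-run re-flagging of evCpGs is intrinsically noisier."""
        table, summary = independence_check(
            default_cohort.beta, default_cohort.sheet, n_resamples=25, seed=7
        )
        assert summary["overall_agreement"] >= 0.9
        assert summary["majority_vote_agreement"] >= 0.9
        # non-significant (genetically driven) decisions are rock stable
        ns = table.loc[~table["all_pairs_significant"], "agreement"]
        assert ns.mean() >= 0.95
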