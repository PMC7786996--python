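"""Generator contracts: class structure, exchangeability, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evtwin import (
    CohortConfig,
    WgbsSimConfig,
    probe_variability,
    simulate_aging_cohort,
    simulate_replicates,
    simulate_twin_cohort,
    simulate_wgbs_pair,
)
from evtwin.equivalence import PairingIndex


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_pairs": 1},
        {"n_cpgs": 0},
        {"class_fractions": {"error_only": 0.5, "genetic": 0.4, "stochastic": 0.05, "mixed": 0.0}},
        {"class_fractions": {"error_only": 1.0, "bogus": 0.0}},
        {"sigma_meas": -0.1},
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.1, 0.6)},
        {"effect_range": (-0.1, 0.2)},
        {"n_batches": 0},
    ],
)
def test_cohort_config_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        CohortConfig(**kwargs)


def test_all_betas_inside_unit_interval(small_cohort):
    vals = small_cohort.beta.to_numpy()
    assert ((vals > 0) & (vals < 1)).all()


def test_seed_fixes_every_output_bit_exactly():
    cfg = CohortConfig(n_pairs=5, n_cpgs=50, seed=42)
    a = simulate_twin_cohort(cfg)
    b = simulate_twin_cohort(cfg)
    pd.testing.assert_frame_equal(a.beta, b.beta)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    w1 = simulate_wgbs_pair(WgbsSimConfig(n_sites=500, seed=3))
    w2 = simulate_wgbs_pair(WgbsSimConfig(n_sites=500, seed=3))
    pd.testing.assert_frame_equal(w1.twin1, w2.twin1)
    pd.testing.assert_frame_equal(w1.twin2, w2.twin2)


def test_genetic_twins_identical_without_noise():
    """Co-twins share genotype, so zero measurement noise means |dbeta| = 0."""
    cfg = CohortConfig(
        n_pairs=20,
        n_cpgs=50,
        class_fractions={"error_only": 0.0, "genetic": 1.0, "stochastic": 0.0, "mixed": 0.0},
        sigma_meas=0.0,
        seed=2,
    )
    cohort = simulate_twin_cohort(cfg)
    p = PairingIndex(cohort.beta.columns, cohort.sheet)
    mat = cohort.beta.to_numpy()
    assert np.abs(mat[:, p.twin_a] - mat[:, p.twin_b]).max() == 0.0


def test_stochastic_twin_and_unrelated_diffs_exchangeable():
    """Twin and unrelated |dbeta| draws share one distribution (KS, a=0.01)."""
    cfg = CohortConfig(
        n_pairs=200,
        n_cpgs=100,
        class_fractions={"error_only": 0.0, "genetic": 0.0, "stochastic": 1.0, "mixed": 0.0},
        sigma_meas=0.0,
        seed=3,
    )
    cohort = simulate_twin_cohort(cfg)
    p = PairingIndex(cohort.beta.columns, cohort.sheet)
    mat = cohort.beta.to_numpy()[:50]
    twin = np.abs(mat[:, p.twin_a] - mat[:, p.twin_b]).ravel()
    rng = np.random.default_rng(0)
    pick = rng.choice(len(p.unrel_a), size=200, replace=False)
    unrel = np.abs(mat[:, p.unrel_a[pick]] - mat[:, p.unrel_b[pick]]).ravel()
    assert stats.ks_2samp(twin[:10000], unrel[:10000]).pvalue > 0.01


def test_error_only_observed_sd_matches_delta_method(default_cohort):
    """At baseline 0.5, sd_beta ~ 0.25 * sigma_meas = 0.03 for noise-only CpGs."""
    truth = default_cohort.truth.set_index("probe_id")
    near_half = truth.index[
        (truth["class"] == "error_only") & ((truth["baseline"] - 0.5).abs() < 0.02)
    ]
    sds = default_cohort.beta.loc[near_half].std(axis=1, ddof=1)
    assert abs(sds.mean() - 0.03) < 0.005


def test_genetic_effect_recovered_by_genotype_regression(default_cohort):
    """Per-allele effect comes back from OLS on the simulated genotype."""
    truth = default_cohort.truth.set_index("probe_id")
    gen = truth.index[(truth["class"] == "genetic") & (truth["maf"] > 0.1)]
    g = default_cohort.genotype.loc[gen].to_numpy()
    b = default_cohort.beta.loc[gen].to_numpy()
    est = np.array([np.polyfit(gi, bi, 1)[0] for gi, bi in zip(g, b)])
    bias = est - truth.loc[gen, "effect"].to_numpy()
    assert abs(bias.mean()) < 0.01


# --- replicates -------------------------------------------------------------


def test_replicates_unknown_mode_and_small_k(small_cohort):
    with pytest.raises(ValueError):
        simulate_replicates(small_cohort, "bogus", k=2, seed=0)
    with pytest.raises(ValueError):
        simulate_replicates(small_cohort, "technical", k=1, seed=0)


def test_technical_replicates_bit_identical_without_noise():
    cfg = CohortConfig(n_pairs=5, n_cpgs=40, sigma_meas=0.0, seed=4)
    cohort = simulate_twin_cohort(cfg)
    beta, sheet = simulate_replicates(cohort, "technical", k=2, seed=1)
    for ind in cohort.sheet["individual_id"]:
        cols = sheet.loc[sheet["individual_id"] == ind, "sample_id"]
        sub = beta[list(cols)].to_numpy()
        assert (sub[:, 0] == sub[:, 1]).all()


def test_longitudinal_replicates_keep_high_icc_for_stochastic_probes():
    """With sigma_time = 0 replicates differ only by measurement noise, so the
    ICC of stochastic probes approaches sigma_s^2 / (sigma_s^2 + sigma_m^2)."""
    cfg = CohortConfig(n_pairs=100, n_cpgs=300, sigma_stoch=0.5, sigma_meas=0.1, seed=5)
    cohort = simulate_twin_cohort(cfg)
    beta, sheet = simulate_replicates(cohort, "longitudinal", k=2, sigma_time=0.0, seed=6)
    var = probe_variability(beta, sheet).set_index("probe_id")
    truth = cohort.truth.set_index("probe_id")
    stoch = truth.index[truth["class"] == "stochastic"]
    err = truth.index[truth["class"] == "error_only"]
    assert var.loc[stoch, "icc"].median() > 0.9
    assert var.loc[err, "icc"].median() < 0.1


def test_chip_batch_dominates_genetic_probes():
    """Probe-specific chip effects at batch_shift >= stochastic spread make
    the first principal component of genetic probes separate the batches."""
    cohort = simulate_twin_cohort(CohortConfig(n_pairs=3, n_cpgs=2000, seed=11))
    truth = cohort.truth.set_index("probe_id")
    gen = truth.index[(truth["class"] == "genetic") & (truth["effect"] >= 0.1)]
    beta, sheet = simulate_replicates(
        cohort, "technical", k=2, seed=3, n_batches=2, batch_shift=1.0
    )
    batch = sheet.set_index("sample_id").loc[beta.columns, "batch"].to_numpy()
    x = beta.loc[gen].to_numpy().T
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    assert max(pc1[batch == "chip0"].max(), pc1[batch == "chip1"].max()) > 0
    assert (
        pc1[batch == "chip0"].max() < pc1[batch == "chip1"].min()
        or pc1[batch == "chip1"].max() < pc1[batch == "chip0"].min()
    )


# --- aging cohort -----------------------------------------------------------


def test_aging_cohort_preconditions():
    with pytest.raises(ValueError):
        simulate_aging_cohort(10)
    with pytest.raises(ValueError):
        simulate_aging_cohort(100, age_range=(50.0, 50.0))
    with pytest.raises(ValueError):
        simulate_aging_cohort(100, n_cpgs={"bogus": 10})


def test_aging_cohort_shapes_and_truth():
    beta, sheet, truth = simulate_aging_cohort(60, n_cpgs={"clock": 5, "drift": 5, "neither": 10}, seed=1)
    assert beta.shape == (20, 60)
    assert set(truth["class"]) == {"clock", "drift", "neither"}
    assert sheet["age"].between(14, 94).all()
    assert ((beta.to_numpy() > 0) & (beta.to_numpy() < 1)).all()


# --- WGBS pair --------------------------------------------------------------


def test_wgbs_config_rejects_invalid():
    with pytest.raises(ValueError):
        WgbsSimConfig(mean_coverage=0)
    with pytest.raises(ValueError):
        WgbsSimConfig(region=(1_900_000, 2_100_000))
    with pytest.raises(ValueError):
        WgbsSimConfig(frac_blacklist=1.5)


def test_wgbs_counts_and_discordant_truth():
    pair = simulate_wgbs_pair(WgbsSimConfig(n_sites=2000, seed=9))
    for t in (pair.twin1, pair.twin2):
        assert (t["count_methylated"] <= t["count_total"]).all()
        assert (t["count_total"] > 0).all()
        assert t["beta"].between(0, 1).all()
    assert pair.truth["discordant"].sum() > 0
    assert (pair.truth.loc[pair.truth["discordant"], "in_region"]).all()
    # blacklist BED covers exactly the flagged positions
    flagged = set(pair.truth.loc[pair.truth["blacklisted"], "pos"])
    assert set(pair.blacklist["end"]) == flagged
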