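"""Forward simulator: transmission genetics, selection response, sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gpsmap.sim_forward import (Scenario, assign_qtl_architecture,
                                generate_founders, pve_metaregression,
                                sample_individuals, simulate_scenario,
                                uneven_sampling_rate, _batch_gametes)


def small_scenario(**overrides):
    base = dict(n_chrom=2, sites_per_chrom=500, n_founders=200, ne_target=50,
                n_qtl=20, n_crosses=200, n_generations=5, burn_in=2,
                selection="tbv_truncation", n_sampled=400,
                n_males_selected=10, n_females_selected=80, seed=0,
                founder_burnin_generations=20)
    base.update(overrides)
    return Scenario(**base)


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def test_founder_heterozygosity_matches_frequencies():
    pool = generate_founders(small_scenario(seed=1))
    p = pool.frequencies()
    seg = (p > 0) & (p < 1)
    dos = pool.haps[0::2] + pool.haps[1::2]
    het = (dos[:, seg] == 1).mean()
    expected = np.mean(2 * p[seg] * (1 - p[seg]))
    assert abs(het - expected) / expected < 0.2


def test_founders_reproducible():
    p1 = generate_founders(small_scenario(seed=2))
    p2 = generate_founders(small_scenario(seed=2))
    np.testing.assert_array_equal(p1.haps, p2.haps)
    np.testing.assert_array_equal(p1.pos_bp, p2.pos_bp)


def test_drift_variance_scales_with_ne():
    """Smaller Ne drifts more: var(delta p) ~ p(1-p)/(2 Ne) per generation."""
    var_by_ne = {}
    for ne in (50, 250):
        sc = small_scenario(ne_target=ne, seed=3,
                            founder_burnin_generations=0)
        rng = np.random.default_rng(sc.seed)
        pool = generate_founders(sc, rng)
        p0 = pool.frequencies()
        sc2 = small_scenario(ne_target=ne, seed=3,
                             founder_burnin_generations=10)
        pool2 = generate_founders(sc2, np.random.default_rng(sc2.seed))
        p1 = pool2.frequencies()
        mid = (p0 > 0.2) & (p0 < 0.8)
        var_by_ne[ne] = np.var((p1 - p0)[mid])
    assert var_by_ne[50] > var_by_ne[250]


# ---------------------------------------------------------------------------
# QTL architecture
# ---------------------------------------------------------------------------

def test_gamma_effect_moments():
    sc = small_scenario(n_qtl=500, sites_per_chrom=2000, qtl_dist="gamma",
                        seed=4, founder_burnin_generations=2)
    rng = np.random.default_rng(99)
    pool = generate_founders(sc, rng)
    draws = []
    for _ in range(20):
        _, eff = assign_qtl_architecture(pool, sc, rng)
        draws.append(np.abs(eff))
    draws = np.concatenate(draws)  # 10,000 draws
    shape = 0.42
    assert abs(draws.mean() - shape) / shape < 0.1
    assert abs(draws.var() - shape) / shape < 0.1
    signed, _ = assign_qtl_architecture(pool, sc, rng)


def test_zero_qtl_and_reproducibility():
    sc = small_scenario(n_qtl=0, seed=5)
    pool = generate_founders(sc)
    idx, eff = assign_qtl_architecture(pool, sc)
    assert len(idx) == 0 and len(eff) == 0
    sc2 = small_scenario(seed=6)
    pool2 = generate_founders(sc2)
    a = assign_qtl_architecture(pool2, sc2, np.random.default_rng(1))
    b = assign_qtl_architecture(pool2, sc2, np.random.default_rng(1))
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_too_many_qtl_errors():
    sc = small_scenario(seed=7)
    pool = generate_founders(sc)
    with pytest.raises(ValueError, match="exceeds"):
        assign_qtl_architecture(pool, small_scenario(n_qtl=10 ** 6, seed=7))


# ---------------------------------------------------------------------------
# Meiosis invariants
# ---------------------------------------------------------------------------

def test_gametes_without_recombination_are_parental():
    sc = small_scenario(recomb_factor=0.0, seed=8)
    pool = generate_founders(sc)
    rng = np.random.default_rng(0)
    slices = pool.chromosome_slices()
    pos_mb = [pool.pos_bp[s:e] / 1e6 for s, e in slices]
    gam = _batch_gametes(pool.haps, np.arange(20), slices, pos_mb,
                         sc.chrom_length_mb, 0.0, rng)
    for i in range(20):
        a, b = pool.haps[2 * i], pool.haps[2 * i + 1]
        for s, e in slices:
            seg = gam[i, s:e]
            assert np.array_equal(seg, a[s:e]) or np.array_equal(seg, b[s:e])


def test_offspring_dosage_is_sum_of_transmitted_alleles():
    truth = simulate_scenario(small_scenario(seed=9))
    for dos in truth.generation_dosage:
        assert set(np.unique(dos)) <= {0, 1, 2}
    assert np.all((truth.qtl_freq >= 0) & (truth.qtl_freq <= 1))


# ---------------------------------------------------------------------------
# Selection response
# ---------------------------------------------------------------------------

def test_truncation_selection_increases_tbv():
    up = 0
    for seed in range(10, 14):
        truth = simulate_scenario(small_scenario(seed=seed))
        mean_tbv = truth.mean_tbv_by_generation()
        if np.all(np.diff(mean_tbv) > -1e-9):
            up += 1
    assert up >= 3  # response to selection in nearly all replicates


def test_random_mating_shows_no_trend():
    slopes = []
    for seed in range(20, 26):
        truth = simulate_scenario(small_scenario(selection="random",
                                                 seed=seed))
        y = truth.mean_tbv_by_generation()
        g = np.arange(len(y))
        res = stats.linregress(g, y)
        slopes.append(res.pvalue)
    # under drift the slope is only occasionally "significant"
    assert np.mean(np.array(slopes) < 0.01) < 0.5


def test_neutral_drift_variance_against_wright_fisher():
    """Frequency-change variance over t generations tracks the WF formula
    with Ne from the realized parent counts, within a factor allowing for
    family-size inflation."""
    sc = small_scenario(selection="random", seed=30, n_generations=6,
                        n_qtl=200, qtl_dist="normal")
    truth = simulate_scenario(sc)
    p0 = truth.qtl_freq[0]
    pt = truth.qtl_freq[-1]
    mid = (p0 > 0.2) & (p0 < 0.8)
    observed = np.var((pt - p0)[mid])
    n_m, n_f = sc.n_males_selected, sc.n_females_selected
    ne = 4 * n_m * n_f / (n_m + n_f)  # unequal sex-ratio effective size
    t = sc.n_generations
    expected = np.mean(p0[mid] * (1 - p0[mid])) * \
        (1 - (1 - 1 / (2 * ne)) ** t)
    assert 0.5 * expected < observed < 2.5 * expected


# ---------------------------------------------------------------------------
# Sampling schemes
# ---------------------------------------------------------------------------

def test_even_sampling_counts():
    truth = simulate_scenario(small_scenario(seed=40, n_generations=5,
                                             n_crosses=250))
    geno, samples = sample_individuals(truth, sampling="even", n_sampled=1000,
                                       seed=1)
    counts = samples["generation"].value_counts()
    assert (counts == 200).all()


def test_uneven_sampling_monotone_toward_recent():
    truth = simulate_scenario(small_scenario(seed=41, n_generations=5,
                                             n_crosses=400))
    geno, samples = sample_individuals(truth, sampling="uneven",
                                       n_sampled=600, seed=2)
    counts = samples["generation"].value_counts().sort_index().to_numpy()
    assert np.all(np.diff(counts) >= 0)
    r = uneven_sampling_rate(10)
    w = np.exp(-r * (10 - np.arange(1, 11)))
    assert w[-3:].sum() / w.sum() == pytest.approx(0.6, abs=1e-6)


def test_sampling_exhausted_generation_warns():
    truth = simulate_scenario(small_scenario(seed=42, n_crosses=50,
                                             n_males_selected=5,
                                             n_females_selected=20))
    with pytest.warns(UserWarning, match="exhausted"):
        geno, samples = sample_individuals(truth, sampling="even",
                                           n_sampled=400, seed=3)
    assert len(samples) <= 400


def test_sampling_reproducible():
    truth = simulate_scenario(small_scenario(seed=43))
    g1, s1 = sample_individuals(truth, seed=4)
    g2, s2 = sample_individuals(truth, seed=4)
    np.testing.assert_array_equal(g1.dosage, g2.dosage)
    pd.testing.assert_frame_equal(s1, s2)


# ---------------------------------------------------------------------------
# Performance scoring + meta-regression
# ---------------------------------------------------------------------------

def test_negative_q_threshold_yields_no_positives(sim_panel):
    from gpsmap.sim_forward import evaluate_gpsm_performance
    truth, geno, samples = sim_panel
    rep = evaluate_gpsm_performance(geno, samples, truth, q_threshold=-1.0)
    assert rep.n_significant == 0
    assert rep.true_positives == 0 and rep.false_positives == 0


def test_fixed_qtl_excluded_from_detectable(sim_panel):
    from gpsmap.sim_forward import evaluate_gpsm_performance
    truth, geno, samples = sim_panel
    rep = evaluate_gpsm_performance(geno, samples, truth)
    fixed = np.sum((truth.qtl_freq[-1] == 0) | (truth.qtl_freq[-1] == 1))
    assert rep.n_detectable_qtl <= len(truth.qtl_idx) - fixed


def test_pve_metaregression_planted_signal():
    rng = np.random.default_rng(50)
    n_gen = np.tile([5, 10, 20], 40)
    pve = 0.02 * n_gen + rng.normal(0, 0.01, len(n_gen))
    tab = pd.DataFrame({"pve": pve, "n_generations": n_gen,
                        "n_crosses": 1000, "qtl_dist": ["normal"] * len(pve)})
    out = pve_metaregression(tab, predictors=["n_generations", "n_crosses",
                                              "qtl_dist"])
    assert out["params"].loc["n_generations", "coef"] == pytest.approx(
        0.02, abs=0.002)
    assert out["params"].loc["n_generations", "p"] < 0.01
    assert set(out["aliased"]) == {"n_crosses", "qtl_dist"}


def test_pve_metaregression_zero_variance_response():
    tab = pd.DataFrame({"pve": [0.5] * 10,
                        "n_generations": np.tile([5, 10], 5)})
    out = pve_metaregression(tab, predictors=["n_generations"])
    assert np.allclose(out["params"]["coef"], 0.0)


def test_scenario_validation():
    with pytest.raises(ValueError):
        small_scenario(n_crosses=0)
    with pytest.raises(ValueError):
        small_scenario(selection="magic")
    with pytest.raises(ValueError):
        small_scenario(qtl_dist="cauchy")
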