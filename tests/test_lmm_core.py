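"""Numerical-core oracles: GRM, REML, per-SNP GLS, multi-GRM, multivariate."""

import numpy as np
import pandas as pd
import pytest

from gpsmap.io_formats import GenotypeMatrix
from gpsmap.lmm_core import (Grm, ScanConfig, ScanEngine, assoc_scan,
                             compute_grm, multi_component_reml, mv_scan,
                             reml_single, LOG_LAMBDA_RANGE,
                             _profiled_reml_loglik)
from tests.conftest import make_random_geno


def _simulate_polygenic(grm, h2, rng, extra=None):
    """Phenotype with the requested GRM-structured variance fraction."""
    n = grm.n
    L = grm.eigenvectors * np.sqrt(np.maximum(grm.eigenvalues, 0.0))
    u = L @ rng.normal(size=n)
    u = u / u.std() * np.sqrt(h2)
    return u + rng.normal(0.0, np.sqrt(1.0 - h2), n)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def test_grm_matches_entrywise_oracle():
    """3x2 dosage: every entry equals the hand-computed standardized product."""
    dosage = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
    snps = pd.DataFrame({"chrom": "1", "pos_bp": [100, 200],
                         "id": ["a", "b"], "allele1": "A", "allele0": "B"})
    geno = GenotypeMatrix(["x", "y", "z"], snps, dosage)
    grm = compute_grm(geno, maf_min=0.0)
    p = dosage.mean(axis=0) / 2.0
    W = (dosage - 2 * p) / np.sqrt(2 * p * (1 - p))
    expected = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            expected[i, j] = sum(W[i, k] * W[j, k] for k in range(2)) / 2
    np.testing.assert_allclose(grm.matrix, expected, atol=1e-12)


def test_grm_duplicated_individuals_share_entries():
    geno = make_random_geno(6, 200, seed=4)
    geno.dosage[1] = geno.dosage[0]
    grm = compute_grm(geno)
    assert grm.matrix[0, 0] == pytest.approx(grm.matrix[1, 1], abs=1e-10)
    assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0], abs=1e-10)


def test_grm_monomorphic_column_excluded():
    geno = make_random_geno(20, 50, seed=5)
    geno.dosage[:, 7] = 2.0
    grm = compute_grm(geno)
    pre = geno.subset(snp_idx=[j for j in range(50) if j != 7])
    grm_pre = compute_grm(pre)
    assert grm.m_used == grm_pre.m_used
    np.testing.assert_allclose(grm.matrix, grm_pre.matrix, atol=1e-12)


def test_grm_structure_invariants(random_grm, random_geno):
    g = random_grm
    n = g.n
    assert np.allclose(g.matrix, g.matrix.T, atol=1e-10)
    assert abs(np.trace(g.matrix) - n) / n < 0.02
    recon = (g.eigenvectors * g.eigenvalues) @ g.eigenvectors.T
    assert np.max(np.abs(g.matrix - recon)) < 1e-8
    with pytest.raises(ValueError, match="polymorphic"):
        compute_grm(make_random_geno(5, 3, seed=0), maf_min=0.49)
    with pytest.raises(MemoryError):
        compute_grm(random_geno, max_n=10)


# ---------------------------------------------------------------------------
# Single-component REML
# ---------------------------------------------------------------------------

def test_reml_recovers_simulated_pve(random_grm):
    """Mean PVE over replicates close to the simulated truth of 0.5."""
    rng = np.random.default_rng(42)
    est = [reml_single(_simulate_polygenic(random_grm, 0.5, rng),
                       random_grm).pve for _ in range(10)]
    assert abs(np.mean(est) - 0.5) < 0.1


def test_reml_loglik_beats_grid(random_grm):
    """Returned optimum dominates a 101-point grid on log lambda."""
    rng = np.random.default_rng(7)
    y = _simulate_polygenic(random_grm, 0.4, rng)
    vc = reml_single(y, random_grm)
    d = np.maximum(random_grm.eigenvalues, 0.0)
    U = random_grm.eigenvectors
    X = np.ones((random_grm.n, 1))
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)
    ystar, Xstar = U.T @ y, U.T @ X
    grid = np.linspace(*LOG_LAMBDA_RANGE, 101)
    grid_ll = [_profiled_reml_loglik(np.exp(g), d, ystar, Xstar, logdet_xtx)
               for g in grid]
    assert vc.loglik >= max(grid_ll) - 1e-9


def test_reml_centering_invariance(random_grm):
    rng = np.random.default_rng(8)
    y = _simulate_polygenic(random_grm, 0.3, rng)
    vc_raw = reml_single(y, random_grm)
    vc_centered = reml_single(y - y.mean() + 5.0, random_grm)
    assert vc_raw.pve == pytest.approx(vc_centered.pve, abs=1e-8)


def test_reml_degenerate_inputs(random_grm):
    with pytest.raises(ValueError, match="constant"):
        reml_single(np.ones(random_grm.n), random_grm)
    ident = Grm.from_matrix(np.eye(50), m_used=0)
    vc = reml_single(np.random.default_rng(0).normal(size=50), ident)
    assert any("unidentifiable" in w for w in vc.warnings)


# ---------------------------------------------------------------------------
# Per-SNP scan
# ---------------------------------------------------------------------------

def test_scan_matches_dense_gls_oracle():
    """Beta and SE equal brute-force GLS with V = sa2 G + se2 I."""
    geno = make_random_geno(50, 30, seed=9)
    grm = compute_grm(geno)
    rng = np.random.default_rng(10)
    y = _simulate_polygenic(grm, 0.4, rng)
    vc = reml_single(y, grm)
    tab = assoc_scan(geno, y, grm, vc=vc)
    n = 50
    W = vc.lam * grm.matrix + np.eye(n)
    Winv = np.linalg.inv(W)
    for j in [0, 7, 29]:
        X = np.column_stack([np.ones(n), geno.dosage[:, j]])
        beta = np.linalg.solve(X.T @ Winv @ X, X.T @ Winv @ y)
        r = y - X @ beta
        sigma2 = (r @ Winv @ r) / (n - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ Winv @ X)[1, 1])
        assert tab["beta"][j] == pytest.approx(beta[1], abs=1e-8)
        assert tab["se"][j] == pytest.approx(se, abs=1e-8)


def test_scan_null_calibration():
    """Type-I error at alpha = 0.05 over 10,000 independent null SNPs."""
    geno = make_random_geno(200, 10_000, seed=12)
    grm = compute_grm(geno)
    y = np.random.default_rng(13).normal(size=200)
    tab = assoc_scan(geno, y, grm)
    frac = float(np.nanmean(tab["p_wald"] < 0.05))
    assert abs(frac - 0.05) < 0.01


def test_scan_reduces_to_ols_when_no_genetic_variance():
    geno = make_random_geno(80, 40, seed=14)
    grm = compute_grm(geno)
    y = np.random.default_rng(15).normal(size=80)
    from gpsmap.lmm_core import VarianceComponents
    vc = VarianceComponents(sigma_a2=0.0, sigma_e2=1.0, pve=0.0, pve_se=0.0,
                            loglik=0.0, lam=0.0)
    tab = assoc_scan(geno, y, grm, vc=vc)
    x = geno.dosage[:, 3]
    slope = np.polyfit(x, y, 1)[0]
    assert tab["beta"][3] == pytest.approx(slope, abs=1e-10)


def test_scan_sample_reordering_invariance():
    geno = make_random_geno(60, 100, seed=16)
    grm = compute_grm(geno)
    rng = np.random.default_rng(17)
    y = _simulate_polygenic(grm, 0.3, rng)
    tab = assoc_scan(geno, y, grm)
    perm = rng.permutation(60)
    geno_p = geno.subset(sample_idx=perm)
    grm_p = compute_grm(geno_p)
    tab_p = assoc_scan(geno_p, y[perm], grm_p)
    np.testing.assert_allclose(tab["beta"], tab_p["beta"], atol=1e-6)
    np.testing.assert_allclose(tab["p_wald"], tab_p["p_wald"], atol=1e-6)


# ---------------------------------------------------------------------------
# Multi-GRM
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def two_grms():
    g1 = compute_grm(make_random_geno(400, 800, seed=20))
    g2 = compute_grm(make_random_geno(400, 800, seed=21))
    return g1, g2


def test_multi_grm_recovers_variance_fractions(two_grms):
    """Mean estimates across replicates within 2 SE of 0.3 / 0.2."""
    g1, g2 = two_grms
    rng = np.random.default_rng(22)
    n = g1.n

    def sim_u(G, var):
        L = G.eigenvectors * np.sqrt(np.maximum(G.eigenvalues, 0.0))
        u = L @ rng.normal(size=n)
        return u / u.std() * np.sqrt(var)

    est, ses = [], []
    for _ in range(5):
        y = sim_u(g1, 0.3) + sim_u(g2, 0.2) + rng.normal(0, np.sqrt(0.5), n)
        vc = multi_component_reml(y, [g1, g2])
        est.append(vc.component_pve)
        ses.append(vc.component_pve_se)
    mean = np.mean(est, axis=0)
    se_of_mean = np.mean(ses, axis=0) / np.sqrt(len(est))
    assert abs(mean[0] - 0.3) < 2 * max(se_of_mean[0], 0.05)
    assert abs(mean[1] - 0.2) < 2 * max(se_of_mean[1], 0.05)


def test_multi_grm_duplicate_flagged(two_grms):
    g1, _ = two_grms
    y = np.random.default_rng(23).normal(size=g1.n)
    with pytest.raises(ValueError, match="non-identifiable"):
        multi_component_reml(y, [g1, g1])


def test_multi_grm_summary_layout(two_grms):
    """One PVE + SE row per GRM plus the total, three-partition style."""
    g1, g2 = two_grms
    rng = np.random.default_rng(24)
    y = rng.normal(size=g1.n)
    vc = multi_component_reml(y, [g1, g2])
    tab = vc.summary_table()
    assert list(tab["component"]) == ["G1", "G2", "total"]
    assert (tab["se"].dropna() >= 0).all()
    assert vc.pve == pytest.approx(tab["pve"].iloc[:-1].sum(), abs=1e-10)


def test_multi_grm_needs_two_to_four(two_grms):
    g1, _ = two_grms
    y = np.random.default_rng(0).normal(size=g1.n)
    with pytest.raises(ValueError, match="2-4"):
        multi_component_reml(y, [g1])


# ---------------------------------------------------------------------------
# Multivariate scan
# ---------------------------------------------------------------------------

def test_mv_scan_single_trait_reduces_to_univariate(random_geno, random_grm):
    y = np.random.default_rng(25).normal(size=random_geno.n_samples)
    uni = assoc_scan(random_geno, y, random_grm)
    mv = mv_scan(random_geno, y[:, None], random_grm)
    np.testing.assert_allclose(mv["p_mv"], uni["p_wald"], atol=1e-8)


def test_mv_scan_rejects_duplicated_columns(random_geno, random_grm):
    y = np.random.default_rng(26).normal(size=random_geno.n_samples)
    with pytest.raises(ValueError, match="duplicated|collinear"):
        mv_scan(random_geno, np.column_stack([y, y]), random_grm)
    with pytest.raises(ValueError, match="at most 5"):
        mv_scan(random_geno,
                np.random.default_rng(0).normal(size=(random_geno.n_samples, 6)),
                random_grm)


def test_mv_scan_joint_null_calibration():
    """Two independent null traits: joint d-df test holds its size."""
    geno = make_random_geno(200, 10_000, seed=27)
    grm = compute_grm(geno)
    Y = np.random.default_rng(28).normal(size=(200, 2))
    tab = mv_scan(geno, Y, grm)
    frac = float(np.nanmean(tab["p_mv"] < 0.05))
    assert abs(frac - 0.05) < 0.01
    null = tab.attrs["null_fit"]
    assert null.v_genetic.shape == (2, 2)
    assert abs(null.genetic_correlation[0, 1]) <= 1.0
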