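"""Mixed-model association machinery against independent oracles.

The REML spectral shortcut is checked against a direct-determinant
restricted likelihood and a brute-force grid search; GLS reduces to OLS
when the covariance is the identity; the summary statistics are checked on
closed-form fixtures.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cwqtl import mixed_gwas as mg
from cwqtl import synthetic_data as sd
from tests.conftest import table_from_dosage


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def direct_reml_loglik(delta: float, y, X, K) -> float:
    """Restricted log-likelihood of Var(y) = s_a2 (K + delta I), profiled
    over s_a2, via explicit determinants (EMMA closed form)."""
    n, p = X.shape
    V = K + delta * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    q = n - p
    ypy = float(y @ P @ y)
    _, ldV = np.linalg.slogdet(V)
    _, ldXViX = np.linalg.slogdet(XtViX)
    _, ldXX = np.linalg.slogdet(X.T @ X)
    return 0.5 * (
        q * np.log(q / (2 * np.pi)) - q - q * np.log(ypy) - ldV - ldXViX + ldXX
    )


def ols_f_tests(y, X0, G):
    """Dense-solve OLS oracle: F and beta for adding each column of G to X0."""
    out = []
    for j in range(G.shape[1]):
        X1 = np.column_stack([X0, G[:, j]])
        b1, rss1_arr, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss1 = float(((y - X1 @ b1) ** 2).sum())
        b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
        rss0 = float(((y - X0 @ b0) ** 2).sum())
        df = len(y) - X1.shape[1]
        f = (rss0 - rss1) / (rss1 / df)
        out.append((b1[-1], f, float(stats.f.sf(f, 1, df))))
    return out


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


class TestSnpQc:
    def test_low_call_rate_excluded(self):
        d = np.ones((20, 1))
        d[:3, 0] = np.nan  # 15% missing
        _, report = mg.snp_qc(table_from_dosage(d))
        assert report["failed_criterion"].tolist() == ["call_rate"]

    def test_exact_hwe_fixture_retained(self):
        # AA=25, AB=50, BB=25 -> chi2 = 0, p = 1
        d = np.repeat([2.0, 1.0, 0.0], [25, 50, 25])[:, None]
        kept, report = mg.snp_qc(table_from_dosage(d))
        assert len(report) == 0 and len(kept.snp_marker_ids) == 1
        assert mg.hwe_chi2_pvalue(25, 50, 25) == 1.0

    def test_hwe_deviation_hand_arithmetic(self):
        # counts AA=60, AB=20, BB=20: p=0.7 so expected (49, 42, 9);
        # chi2 = 11^2/49 + 22^2/42 + 11^2/9 = 27.44 -> p < 0.001, excluded
        chi2_hand = 121 / 49 + 484 / 42 + 121 / 9
        assert abs(chi2_hand - 27.4376) < 1e-3
        p = mg.hwe_chi2_pvalue(60, 20, 20)
        assert abs(p - stats.chi2.sf(chi2_hand, 1)) < 1e-12
        d = np.repeat([2.0, 1.0, 0.0], [60, 20, 20])[:, None]
        _, report = mg.snp_qc(table_from_dosage(d))
        assert report["failed_criterion"].tolist() == ["hwe"]

    def test_monomorphic_is_maf_exclusion_not_error(self):
        d = np.full((50, 1), 2.0)
        _, report = mg.snp_qc(table_from_dosage(d))
        assert report["failed_criterion"].tolist() == ["maf"]


# ---------------------------------------------------------------------------
# IBS kinship
# ---------------------------------------------------------------------------


class TestIbsKinship:
    def test_self_sharing_is_one(self):
        d = np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        S = mg.raw_ibs(table_from_dosage(d))
        assert np.allclose(np.diag(S), 1.0)

    def test_hand_counted_pair(self):
        # dosages (0,2,1) vs (0,0,1): sharing (1, 0, 1) -> mean 2/3
        d = np.array([[0.0, 2.0, 1.0], [0.0, 0.0, 1.0]])
        S = mg.raw_ibs(table_from_dosage(d))
        assert abs(S[0, 1] - 2 / 3) < 1e-12

    def test_duplicate_individual_matches_diagonal(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(6, 30)).astype(float)
        d[5] = d[0]
        S = mg.raw_ibs(table_from_dosage(d))
        assert abs(S[0, 5] - S[0, 0]) < 1e-12

    def test_no_shared_markers_is_error(self):
        d = np.array([[0.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="jointly observed"):
            mg.raw_ibs(table_from_dosage(d))

    def test_normalized_matrix_is_psd_with_unit_mean_diagonal(self, small_gwas):
        kin = small_gwas["kinship"]
        w = np.linalg.eigvalsh(kin.values)
        assert w[0] >= -1e-9
        n = len(kin.individual_ids)
        # trace is n up to the logged PSD ridge
        assert abs(np.trace(kin.values) - n) <= n * kin.ridge + 1e-9


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _reml_fixture(n=50, h2=0.5, seed=0):
    rng = np.random.default_rng(seed)
    cfg = sd.default_config(
        seed=seed, n_sires=n // 5, offspring_per_sire=5, n_snp=80,
        n_founder_haplotypes=max(40, 2 * (n // 5)),
    )
    g, p, t = sd.simulate_population(cfg)
    gq, _ = mg.snp_qc(g)
    kin = mg.ibs_kinship(gq)
    X = np.column_stack([np.ones(len(p)), p["age"].to_numpy(float)])
    y = p["trait"].to_numpy()
    del rng, h2
    return y, X, kin


class TestRemlFit:
    def test_matches_grid_search_oracle(self):
        y, X, kin = _reml_fixture(n=50, seed=3)
        vc = mg.reml_fit(y, X, kin)
        xi, U = mg._projected_spectrum(kin.values, X)
        eta2 = (U.T @ y) ** 2
        grid = np.exp(np.linspace(-10, 10, 2001) * np.log(10) / 1)  # log10 grid
        grid = 10 ** np.linspace(-10, 10, 2001)
        ll = [mg._restricted_loglik(d, xi, eta2) for d in grid]
        best = grid[int(np.argmax(ll))]
        step = 20 / 2000  # log10 units
        assert abs(np.log10(vc.delta) - np.log10(best)) <= step + 1e-9

    def test_spectral_equals_direct_determinant(self):
        y, X, kin = _reml_fixture(n=50, seed=4)
        xi, U = mg._projected_spectrum(kin.values, X)
        eta2 = (U.T @ y) ** 2
        rng = np.random.default_rng(5)
        for delta in 10 ** rng.uniform(-2, 2, size=10):
            a = mg._restricted_loglik(delta, xi, eta2)
            b = direct_reml_loglik(delta, y, X, kin.values)
            assert abs(a - b) <= 1e-8 * abs(b)

    def test_pure_noise_gives_near_zero_h2(self):
        rng = np.random.default_rng(6)
        X_d, _ = sd.simulate_unstructured(400, 600, seed=7, polygenic_h2=0.0)
        table = table_from_dosage(X_d)
        kin = mg.ibs_kinship(table)
        y = rng.normal(size=400)
        X = np.ones((400, 1))
        vc = mg.reml_fit(y, X, kin)
        assert vc.h2 < 0.15

    def test_identity_kinship_reports_unidentifiable(self):
        n = 60
        rng = np.random.default_rng(8)
        kin = mg.KinshipMatrix([f"i{k}" for k in range(n)], np.eye(n))
        vc = mg.reml_fit(rng.normal(size=n), np.ones((n, 1)), kin)
        assert not vc.identifiable

    def test_recovers_planted_heritability(self):
        cfg = sd.default_config(seed=11, n_sires=100, offspring_per_sire=20)
        g, p, t = sd.simulate_population(cfg)
        gq, _ = mg.snp_qc(g)
        kin = mg.ibs_kinship(gq)
        X = mg.build_covariate_matrix(p)
        vc = mg.reml_fit(p, X, kin)
        assert abs(vc.h2 - t.realized_variances["h2_total"]) < 0.08


# ---------------------------------------------------------------------------
# GLS scan
# ---------------------------------------------------------------------------


class TestGlsScan:
    def test_identity_covariance_equals_ols_oracle(self):
        rng = np.random.default_rng(9)
        n, m = 80, 12
        G = rng.integers(0, 3, size=(n, m)).astype(float)
        y = rng.normal(size=n) + G[:, 0] * 0.8
        X0 = np.column_stack([np.ones(n), rng.normal(size=n)])
        kin = mg.KinshipMatrix([f"i{k}" for k in range(n)], np.eye(n))
        vc = mg.VarianceComponents(1.0, 1.0, 0.5, 0.0, delta=1.0)
        recs = mg.gls_scan(y, X0, kin, G, vc)
        oracle = ols_f_tests(y, X0, G)
        for rec, (b, f, p) in zip(recs, oracle):
            assert abs(rec.beta - b) < 1e-8
            assert abs(rec.f_stat - f) < 1e-6 * max(1, f)
            assert abs(rec.p_value - p) < 1e-8

    def test_conditioning_marker_flagged_collinear(self, small_gwas):
        g = small_gwas["genotypes"]
        mid = g.snp_marker_ids[0]
        recs = mg.gls_scan(
            small_gwas["phenotypes"], small_gwas["covariates"],
            small_gwas["kinship"], g, small_gwas["vc"], conditioning_markers=[mid],
        )
        rec = next(r for r in recs if r.marker_id == mid)
        assert rec.flagged == "collinear"

    def test_degenerate_marker_p_one(self):
        rng = np.random.default_rng(10)
        n = 40
        G = np.column_stack([np.full(n, 1.0), rng.integers(0, 3, n).astype(float)])
        kin = mg.KinshipMatrix([f"i{k}" for k in range(n)], np.eye(n))
        vc = mg.VarianceComponents(1.0, 1.0, 0.5, 0.0, delta=1.0)
        recs = mg.gls_scan(rng.normal(size=n), np.ones((n, 1)), kin, G, vc)
        assert recs[0].flagged == "degenerate" and recs[0].p_value == 1.0

    def test_missing_dosage_mean_imputed(self):
        rng = np.random.default_rng(11)
        n = 60
        g = rng.integers(0, 3, size=(n, 1)).astype(float)
        g[:5, 0] = np.nan
        y = rng.normal(size=n)
        kin = mg.KinshipMatrix([f"i{k}" for k in range(n)], np.eye(n))
        vc = mg.VarianceComponents(1.0, 1.0, 0.5, 0.0, delta=1.0)
        recs = mg.gls_scan(y, np.ones((n, 1)), kin, g, vc)
        gi = np.where(np.isnan(g[:, 0]), np.nanmean(g[:, 0]), g[:, 0])
        (b, f, p), = ols_f_tests(y, np.ones((n, 1)), gi[:, None])
        assert abs(recs[0].beta - b) < 1e-8


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


class TestLambdaGc:
    def test_uniform_quantiles_give_one(self):
        m = 5001
        pvals = (np.arange(m) + 0.5) / m
        assert abs(mg.lambda_gc(pvals) - 1.0) < 1e-3

    def test_scale_equivariance(self):
        m = 4001
        q = stats.chi2.isf((np.arange(m) + 0.5) / m, df=1)
        lam1 = mg.lambda_gc(stats.chi2.sf(q, df=1))
        lam2 = mg.lambda_gc(stats.chi2.sf(2 * q, df=1))
        assert abs(lam2 - 2 * lam1) < 1e-6

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            mg.lambda_gc(np.full(10, 0.5))


class TestThresholdAndFraction:
    def test_bonferroni_published_scale(self):
        thr = mg.bonferroni_threshold(0.05, 39011)
        assert float(f"{thr:.3g}") == 1.28e-6

    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 1, 0.05), (0.05, 50, 0.001)]
    )
    def test_bonferroni_simple(self, alpha, m, expected):
        assert mg.bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_fraction_one_third(self):
        v = mg.variance_explained_fraction(0.636, 0.423)
        assert abs(v - (0.636 - 0.423) / 0.636) < 1e-15
        assert abs(v - 1 / 3) < 0.01

    @pytest.mark.parametrize("h", [0.2, 0.9])
    def test_fraction_limits(self, h):
        assert mg.variance_explained_fraction(h, h) == 0.0
        assert mg.variance_explained_fraction(h, 0.0) == 1.0

    def test_fraction_rejects_increase(self):
        with pytest.raises(ValueError):
            mg.variance_explained_fraction(0.4, 0.5)


class TestPairwiseR2:
    def test_self_is_one(self, small_gwas):
        g = small_gwas["genotypes"]
        mid = g.snp_marker_ids[0]
        assert mg.pairwise_r2(g, mid, mid) == 1.0

    def test_monomorphic_is_nan(self):
        d = np.column_stack([np.full(20, 2.0), np.tile([0.0, 2.0], 10)])
        t = table_from_dosage(d)
        assert np.isnan(mg.pairwise_r2(t, "snp0000", "snp0001"))

    def test_phased_fixture_counting_oracle(self):
        # haplotype counts AB=40, Ab=10, aB=10, ab=40 paired without double
        # heterozygotes, so EM equals counting:
        # D = 0.4 - 0.25 = 0.15, r2 = D^2 / (0.5^4) = 0.36
        hapA = [1] * 50 + [0] * 50
        hapB = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        # pair haplotypes within the same A-allele class (A hom or a hom)
        order = np.argsort(hapA, kind="stable")[::-1]
        a = np.array(hapA)[order].reshape(50, 2).sum(axis=1).astype(float)
        b = np.array(hapB)[order].reshape(50, 2).sum(axis=1).astype(float)
        t = table_from_dosage(np.column_stack([a, b]))
        r2 = mg.pairwise_r2(t, "snp0000", "snp0001")
        assert abs(r2 - 0.36) < 1e-6
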