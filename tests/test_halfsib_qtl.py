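"""Half-sib interval mapping: transmission deduction, Prob(Q), scans."""

import numpy as np
import pytest

from cwqtl import halfsib_qtl as hq
from cwqtl import synthetic_data as sd


def make_phase(positions, hap_q, hap_nq):
    n = len(positions)
    return hq.SirePhase(
        sire_id="sireX",
        marker_ids=[f"m{j}" for j in range(n)],
        positions_cM=np.asarray(positions, float),
        haplotypes=np.vstack([hap_q, hap_nq]),
    )


class TestDeducePaternalAllele:
    def test_unique_compatibility(self):
        call = hq.deduce_paternal_allele((152, 160), (152, 148))
        assert call.status == "determined" and call.paternal_allele == 152

    def test_homozygous_sire_always_ambiguous(self):
        assert hq.deduce_paternal_allele((152, 152), (152, 148)).status == "ambiguous"

    def test_offspring_carrying_both_sire_alleles_ambiguous(self):
        # enumeration: paternal could be 152 (dam gave 160) or 160 (dam gave 152)
        assert hq.deduce_paternal_allele((152, 160), (152, 160)).status == "ambiguous"

    def test_homozygous_offspring_determined(self):
        call = hq.deduce_paternal_allele((152, 160), (152, 152))
        assert call.status == "determined" and call.paternal_allele == 152

    def test_no_shared_allele_is_mendel_error(self):
        assert hq.deduce_paternal_allele((152, 160), (148, 144)).status == "mendel_error"


class TestProbQGrid:
    def test_informative_marker_gives_zero_or_one(self):
        phase = make_phase([0.0, 20.0], hap_q=[1, 1], hap_nq=[2, 2])
        # offspring received Q allele (1) at both markers, dam contributed 3
        off = np.array([[[1, 3], [1, 3]]])
        grid = hq.prob_q_grid(phase, off, step_cM=2.0)
        assert grid.prob_q[0, 0] == 1.0
        assert grid.prob_q[0, -1] == 1.0

    def test_no_informative_markers_gives_half(self):
        phase = make_phase([0.0, 20.0], hap_q=[1, 1], hap_nq=[2, 2])
        off = np.array([[[1, 2], [1, 2]]])  # both ambiguous
        grid = hq.prob_q_grid(phase, off, step_cM=2.0)
        assert np.all(grid.prob_q == 0.5)

    def test_midpoint_between_concordant_flanks(self):
        # flanks 10 cM away on each side, both Q: r = 0.0906 per flank,
        # brute-force over the four paternal gamete classes:
        # P = (1-r)^2 / ((1-r)^2 + r^2) = 0.9902
        phase = make_phase([0.0, 20.0], hap_q=[1, 1], hap_nq=[2, 2])
        off = np.array([[[1, 3], [1, 3]]])
        grid = hq.prob_q_grid(phase, off, step_cM=10.0)
        r = 0.5 * (1 - np.exp(-0.2))
        classes = {  # (left state, right state): prob mass
            ("Q", "Q"): (1 - r) * (1 - r),
            ("Q", "n"): (1 - r) * r,
            ("n", "Q"): r * (1 - r),
            ("n", "n"): r * r,
        }
        expected = classes[("Q", "Q")] / (classes[("Q", "Q")] + classes[("n", "n")])
        mid = grid.prob_q[0, list(grid.positions_cM).index(10.0)]
        assert abs(mid - expected) < 1e-12
        assert abs(expected - 0.990) < 5e-4

    def test_single_flank_decays_toward_half(self):
        phase = make_phase([0.0, 100.0], hap_q=[1, 1], hap_nq=[2, 2])
        off = np.array([[[1, 3], [1, 2]]])  # only left marker informative
        grid = hq.prob_q_grid(phase, off, step_cM=20.0)
        p = grid.prob_q[0]
        assert p[0] == 1.0
        assert np.all(np.diff(p) < 0)  # monotone decay
        assert p[-1] > 0.5

    def test_continuity_between_informative_markers(self):
        phase = make_phase([0.0, 40.0], hap_q=[1, 1], hap_nq=[2, 2])
        off = np.array([[[1, 3], [2, 3]]])  # left Q, right non-Q
        grid = hq.prob_q_grid(phase, off, step_cM=1.0)
        p = grid.prob_q[0]
        assert p[0] == 1.0 and p[-1] == 0.0
        assert np.all(np.abs(np.diff(p)) < 0.06)  # no jumps on a 1-cM grid


class TestRegressionScan:
    def _binary_family(self, seed=0, n=120, effect=1.0):
        rng = np.random.default_rng(seed)
        state = rng.integers(0, 2, size=n)
        y = 5.0 + effect * state + rng.normal(0, 1, n)
        cov = rng.normal(size=(n, 1))
        grid = hq.ProbQGrid(np.array([0.0]), state[:, None].astype(float))
        return y, cov, grid, state

    def test_binary_prob_q_equals_anova_oracle(self):
        y, cov, grid, state = self._binary_family(seed=1)
        prof = hq.regression_scan(y, cov, grid)
        # direct least-squares oracle
        X0 = np.column_stack([np.ones(len(y)), cov])
        X1 = np.column_stack([X0, state])
        rss0 = float(((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2).sum())
        rss1 = float(((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2).sum())
        f_oracle = (rss0 - rss1) / (rss1 / (len(y) - X1.shape[1]))
        assert abs(prof.f_stats[0] - f_oracle) < 1e-8

    def test_shift_invariance(self):
        y, cov, grid, _ = self._binary_family(seed=2)
        f1 = hq.regression_scan(y, cov, grid).f_stats
        f2 = hq.regression_scan(y + 1000.0, cov, grid).f_stats
        np.testing.assert_allclose(f1, f2, rtol=1e-8)

    def test_null_mean_f_near_one(self):
        rng = np.random.default_rng(3)
        n = 200
        fam = sd.simulate_halfsib_family(
            seed=3, n_offspring=n, marker_pos_cM=np.arange(0, 101, 10.0)
        )
        phase = make_phase(fam["marker_pos_cM"], fam["sire_pairs"][:, 0], fam["sire_pairs"][:, 1])
        grid = hq.prob_q_grid(phase, fam["offspring_pairs"])
        y = rng.normal(size=n)
        prof = hq.regression_scan(y, None, grid)
        assert 0.5 < prof.f_stats.mean() < 2.0

    def test_constant_prob_q_flagged_zero(self):
        y = np.random.default_rng(4).normal(size=50)
        grid = hq.ProbQGrid(np.array([0.0]), np.full((50, 1), 0.5))
        prof = hq.regression_scan(y, None, grid)
        assert prof.f_stats[0] == 0.0 and prof.flags["constant_prob_q"] == [0]

    def test_peak_localizes_planted_qtl(self):
        hits = 0
        for seed in range(15):
            fam = sd.simulate_halfsib_family(
                seed=100 + seed, n_offspring=300,
                marker_pos_cM=np.arange(0, 101, 10.0),
                qtl_pos_cM=45.0, qtl_effect=0.5, residual_sd=1.0,
            )
            phase = make_phase(
                fam["marker_pos_cM"], fam["sire_pairs"][:, 0], fam["sire_pairs"][:, 1]
            )
            grid = hq.prob_q_grid(phase, fam["offspring_pairs"])
            prof = hq.regression_scan(fam["phenotype"], None, grid)
            hits += abs(prof.peak_position - 45.0) <= 10.0
        assert hits >= 12  # >= 80% of replicates


class TestPermutationThreshold:
    def _grid(self, seed=0, n=150):
        fam = sd.simulate_halfsib_family(
            seed=seed, n_offspring=n, marker_pos_cM=np.arange(0, 101, 10.0)
        )
        phase = make_phase(fam["marker_pos_cM"], fam["sire_pairs"][:, 0], fam["sire_pairs"][:, 1])
        return fam, hq.prob_q_grid(phase, fam["offspring_pairs"])

    def test_thresholds_monotone_in_alpha(self):
        fam, grid = self._grid(seed=5)
        thr = hq.permutation_threshold(
            fam["phenotype"], None, grid, n_perm=1000, seed=1
        )
        assert thr[0.001] >= thr[0.01] >= thr[0.05]

    def test_seeded_determinism(self):
        fam, grid = self._grid(seed=6)
        t1 = hq.permutation_threshold(
            fam["phenotype"], None, grid, n_perm=300, alphas=(0.05, 0.01), seed=9
        )
        t2 = hq.permutation_threshold(
            fam["phenotype"], None, grid, n_perm=300, alphas=(0.05, 0.01), seed=9
        )
        assert t1 == t2

    def test_alpha_below_resolution_rejected(self):
        fam, grid = self._grid(seed=7)
        with pytest.raises(ValueError):
            hq.permutation_threshold(
                fam["phenotype"], None, grid, n_perm=100, alphas=(0.001,), seed=0
            )


class TestBootstrapCi:
    def test_degenerate_peak_single_point_region(self):
        # overwhelming signal at one grid point -> every bootstrap peaks there
        rng = np.random.default_rng(8)
        n = 120
        state = rng.integers(0, 2, n).astype(float)
        y = 100.0 * state + rng.normal(0, 0.01, n)
        C = np.column_stack([state, np.full(n, 0.5), np.full(n, 0.5)])
        grid = hq.ProbQGrid(np.array([0.0, 2.0, 4.0]), C)
        regions, freqs = hq.bootstrap_ci(y, None, grid, n_boot=200, seed=0)
        assert regions == [(0.0, 0.0)]
        assert freqs[0] == 1.0

    def test_bimodal_peaks_fragment_region(self):
        freqs = np.array([0.0, 0.60, 0.0, 0.01, 0.0, 0.38, 0.01])
        pos = np.arange(0.0, 14.0, 2.0)
        regions = hq.peak_frequency_regions(freqs, pos, level=0.95)
        assert regions == [(2.0, 2.0), (10.0, 10.0)]

    def test_accumulation_reaches_level(self):
        rng = np.random.default_rng(9)
        freqs = rng.dirichlet(np.ones(20))
        pos = np.arange(20.0)
        regions = hq.peak_frequency_regions(freqs, pos, level=0.95)
        mass = sum(
            freqs[(pos >= a) & (pos <= b)].sum() for a, b in regions
        )
        assert mass >= 0.95
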