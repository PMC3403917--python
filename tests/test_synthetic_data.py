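"""Generator contracts: haplotype structure, meiosis, phenotype model, panels."""

import numpy as np
import pytest

from cwqtl import synthetic_data as sd
from cwqtl.synthetic_data import (
    QtlSpec,
    _haldane_r,
    _interval_switch_probs,
    _meiosis_origins,
    build_founder_haplotypes,
    default_config,
    emit_variant_panel,
    gene_drop_population,
    haplotype_r2,
    select_extremes,
    simulate_population,
)


class TestFounderPool:
    def test_shapes_and_exact_carrier_counts(self):
        cfg = default_config(
            seed=1, n_founder_haplotypes=10, n_snp=10,
            qtl_specs=(QtlSpec("1", 50.0, 30.0, 0.5),),
            map_length_cM=(100.0,),
        )
        pool = build_founder_haplotypes(cfg)
        assert pool.haplotypes.shape[0] == 10
        qcol = pool.columns_of_kind("qtn")
        assert len(qcol) == 1
        # q_freq=0.5 with 10 haplotypes -> exactly 5 carriers
        assert pool.haplotypes[:, qcol[0]].sum() == 5

    def test_unreachable_q_freq_raises(self):
        cfg = default_config(
            seed=1, n_founder_haplotypes=10,
            qtl_specs=(QtlSpec("1", 50.0, 30.0, 0.01),),
        )
        with pytest.raises(ValueError, match="unreachable"):
            build_founder_haplotypes(cfg)

    def test_tag_r2_meets_floor_by_direct_counting(self):
        cfg = default_config(seed=2)
        pool = build_founder_haplotypes(cfg)
        names = pool.loci["name"].tolist()
        for qi in range(3):
            q = pool.haplotypes[:, names.index(f"qtn_{qi}")]
            tag = pool.haplotypes[:, names.index(f"tag_q{qi}_0")]
            # counting oracle: 2x2 haplotype table -> r2 = D^2/(pq pq)
            p1 = q.mean()
            p2 = tag.mean()
            p12 = (q & tag).mean()
            d = p12 - p1 * p2
            r2 = d * d / (p1 * (1 - p1) * p2 * (1 - p2))
            assert r2 >= cfg.tag_r2_floor
            assert abs(r2 - haplotype_r2(q, tag)) < 1e-12


class TestMeiosis:
    def test_zero_distance_never_recombines(self):
        import pandas as pd

        loci = pd.DataFrame(dict(chromosome="1", position_cM=[10.0, 10.0]))
        sw = _interval_switch_probs(loci)
        origins = _meiosis_origins(500, sw, np.random.default_rng(0))
        assert (origins[:, 0] == origins[:, 1]).all()

    def test_haldane_recombination_fraction(self):
        # 10 cM -> r = 0.5(1 - e^-0.2) = 0.0906; 10,000 gametes, 3 MC SE
        import pandas as pd

        loci = pd.DataFrame(dict(chromosome="1", position_cM=[0.0, 10.0]))
        sw = _interval_switch_probs(loci)
        origins = _meiosis_origins(10_000, sw, np.random.default_rng(1))
        obs = (origins[:, 0] != origins[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(obs - expected) < 3 * se
        assert abs(expected - 0.0906) < 5e-4
        assert abs(_haldane_r(10.0) - expected) < 1e-15


class TestGeneDrop:
    def test_dosages_valid_and_mendelian_vs_sire(self, small_population):
        cfg, genotypes, _, truth = small_population
        d = genotypes.snp_dosage
        assert np.isin(d, (0.0, 1.0, 2.0)).all()
        # paternal allele at every locus must come from the sire's pool haplotypes
        pool = truth.pool
        snp_cols = pool.columns_of_kind("snp")
        sire_haps = pool.haplotypes[truth.sire_hap_index]  # (n_sires, 2, n_loci)
        pat = np.take_along_axis(
            sire_haps[truth.sire_of], truth.paternal_origin[:, None, :], axis=1
        )[:, 0, :]
        # offspring dosage minus paternal allele must be a valid maternal allele
        maternal = d - (pat[:, snp_cols] == 1)
        assert np.isin(maternal, (0.0, 1.0)).all()

    def test_allele_frequency_preserved(self):
        cfg = default_config(seed=9, n_sires=100, offspring_per_sire=20)
        pool = build_founder_haplotypes(cfg)
        genotypes, truth = gene_drop_population(pool, cfg)
        for qi, q in enumerate(cfg.qtl_specs):
            founder_freq = pool.haplotypes[:, pool.loci["name"].tolist().index(f"qtn_{qi}")].mean()
            off_freq = truth.qtl_dosage[:, qi].mean() / 2
            se = np.sqrt(founder_freq * (1 - founder_freq) / (2 * cfg.n_offspring))
            # drift through 100 sire draws adds variance; allow a generous band
            assert abs(off_freq - founder_freq) < 6 * se + 0.02

    def test_seeded_determinism(self):
        cfg = default_config(seed=7, n_sires=5, offspring_per_sire=5, n_snp=40)
        g1, p1, t1 = simulate_population(cfg)
        g2, p2, t2 = simulate_population(cfg)
        np.testing.assert_array_equal(g1.snp_dosage, g2.snp_dosage)
        np.testing.assert_array_equal(t1.qtl_dosage, t2.qtl_dosage)
        np.testing.assert_array_equal(p1["trait"].to_numpy(), p2["trait"].to_numpy())


class TestPhenotypes:
    def test_no_variance_sources_gives_constant(self):
        cfg = default_config(
            seed=3, n_sires=5, offspring_per_sire=4, n_snp=30,
            qtl_specs=(QtlSpec("1", 50.0, 0.0, 0.5),),
            polygenic_h2=0.0, residual_sd_kg=0.0,
            fixed_effects=sd.FixedEffects(
                age_slope_kg_per_month=0.0,
                year_effects_kg={"2004": 0.0},
                house_effects_kg={"A": 0.0},
            ),
        )
        _, pheno, _ = simulate_population(cfg)
        assert pheno["trait"].std() == 0.0

    def test_single_qtl_group_difference_is_twice_effect(self):
        cfg = default_config(
            seed=4, n_sires=20, offspring_per_sire=10, n_snp=30,
            qtl_specs=(QtlSpec("1", 50.0, 12.5, 0.5),),
            polygenic_h2=0.0, residual_sd_kg=0.0,
            fixed_effects=sd.FixedEffects(
                age_slope_kg_per_month=0.0,
                year_effects_kg={"2004": 0.0},
                house_effects_kg={"A": 0.0},
            ),
        )
        _, pheno, truth = simulate_population(cfg)
        y = pheno["trait"].to_numpy()
        dos = truth.qtl_dosage[:, 0]
        assert dos.min() == 0 and dos.max() == 2
        diff = y[dos == 2].mean() - y[dos == 0].mean()
        assert abs(diff - 25.0) < 1e-9

    def test_variance_decomposition_matches_analytic(self):
        # 2p(1-p)a^2 per QTL under HWE vs realized sample variance at n=5,000
        cfg = default_config(
            seed=5, n_sires=250, offspring_per_sire=20, n_founder_haplotypes=600
        )
        _, _, truth = simulate_population(cfg)
        analytic = sum(
            2 * q.q_freq * (1 - q.q_freq) * q.effect_kg_per_allele**2
            for q in cfg.qtl_specs
        )
        realized = truth.realized_variances["qtl"]
        assert abs(realized - analytic) / analytic < 0.12
        assert abs(truth.realized_variances["h2_total"] - 0.636) < 0.03


class TestSelectExtremes:
    @staticmethod
    def _pheno(n, rng, sires=None):
        import pandas as pd

        return pd.DataFrame(
            dict(
                individual_id=[f"i{k}" for k in range(n)],
                trait=rng.normal(size=n),
                sire_id=sires if sires is not None else [f"s{k}" for k in range(n)],
            )
        )

    def test_tail_sizes_15_percent(self):
        pheno = self._pheno(1000, np.random.default_rng(0))
        high, low = select_extremes(pheno, 0.15)
        assert len(high) == 150 and len(low) == 150

    def test_half_sib_exclusion_keeps_more_extreme(self):
        import pandas as pd

        pheno = pd.DataFrame(
            dict(
                individual_id=["a", "b", "c", "d"],
                trait=[10.0, 9.0, 1.0, 2.0],
                sire_id=["s1", "s1", "s2", "s3"],
            )
        )
        high, low = select_extremes(pheno, 0.5, no_half_sib=True)
        assert "a" in high and "b" not in high  # a is the more extreme half-sib

    def test_fraction_half_partitions_everyone(self):
        pheno = self._pheno(100, np.random.default_rng(1))
        high, low = select_extremes(pheno, 0.5)
        assert sorted(high + low) == sorted(pheno["individual_id"])

    def test_bad_fraction_rejected(self):
        pheno = self._pheno(10, np.random.default_rng(2))
        with pytest.raises(ValueError):
            select_extremes(pheno, 0.6)


class TestVariantPanelEmission:
    def test_single_consistent_site_survives(self):
        cfg = default_config(seed=6)
        panel, _, _, _ = emit_variant_panel(cfg, n_consistent=1, n_decoys_per_kind=0)
        from cwqtl.qtn_filter import segregation_filter

        cands = segregation_filter(panel)
        assert sum(c.passed for c in cands) == 1

    def test_decoys_fail_their_criterion(self):
        from cwqtl.qtn_filter import segregation_filter

        cfg = default_config(seed=7)
        panel, _, _, _ = emit_variant_panel(cfg, n_consistent=0, n_decoys_per_kind=3)
        cands = segregation_filter(panel)
        assert sum(c.passed for c in cands) == 0
        assert any(1 in c.failing_criteria for c in cands)
        assert any(2 in c.failing_criteria for c in cands)
        assert any(3 in c.failing_criteria for c in cands)
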