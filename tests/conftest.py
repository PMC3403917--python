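import numpy as np
import pandas as pd
import pytest

from cwqtl import mixed_gwas as mg
from cwqtl import synthetic_data as sd
from cwqtl.io_formats import GenotypeTable, MarkerMap


def make_marker_map(n_snp: int, chromosome: str = "1") -> MarkerMap:
    return MarkerMap(
        pd.DataFrame(
            dict(
                marker_id=[f"snp{j:04d}" for j in range(n_snp)],
                chromosome=chromosome,
                position_bp=np.arange(1, n_snp + 1) * 1000,
                position_cM=np.arange(n_snp, dtype=float),
                marker_type="snp",
            )
        )
    )


def table_from_dosage(dosage: np.ndarray, chromosome: str = "1") -> GenotypeTable:
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    return GenotypeTable(
        individual_ids=[f"i{k}" for k in range(n)],
        markers=make_marker_map(m, chromosome),
        snp_dosage=dosage,
        ms_pairs=np.empty((n, 0, 2), int),
    )


@pytest.fixture(scope="session")
def small_population():
    """One small simulated half-sib population shared across read-only tests."""
    cfg = sd.default_config(seed=42, n_sires=15, offspring_per_sire=12, n_snp=150)
    genotypes, phenotypes, truth = sd.simulate_population(cfg)
    return cfg, genotypes, phenotypes, truth


@pytest.fixture(scope="session")
def small_gwas(small_population):
    """QC'd genotypes, kinship, covariates and null REML fit for the small population."""
    cfg, genotypes, phenotypes, truth = small_population
    gq, _ = mg.snp_qc(genotypes)
    kin = mg.ibs_kinship(gq)
    X = mg.build_covariate_matrix(phenotypes)
    vc = mg.reml_fit(phenotypes, X, kin)
    return dict(
        cfg=cfg, genotypes=gq, phenotypes=phenotypes, truth=truth,
        kinship=kin, covariates=X, vc=vc,
    )
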