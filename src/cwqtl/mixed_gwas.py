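"""Variance-component association machinery (EMMAX-style two-stage mixed model).

The model is ``Var(y) = sigma_a^2 * S + sigma_e^2 * I`` with S a normalized
IBS relatedness matrix estimated from genome-wide SNP. REML estimation
profiles the restricted likelihood over the variance ratio
``delta = sigma_e^2 / sigma_a^2`` using a one-time spectral decomposition of
S projected off the fixed-effect design; per-marker tests are then
generalized least-squares F-tests with the variance parameters held fixed
(the two-stage approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import GenotypeTable

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = 0.4549364231195728  # median of the 1-df chi-square law

__all__ = [
    "QcThresholds",
    "KinshipMatrix",
    "VarianceComponents",
    "AssociationRecord",
    "GwasRunSummary",
    "snp_qc",
    "hwe_chi2_pvalue",
    "raw_ibs",
    "ibs_kinship",
    "reml_fit",
    "gls_scan",
    "lambda_gc",
    "bonferroni_threshold",
    "variance_explained_fraction",
    "pairwise_r2",
    "build_covariate_matrix",
]


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QcThresholds:
    """Marker quality-control cutoffs: call rate > 0.95, MAF > 0.01 and a
    Hardy-Weinberg chi-square p-value > 0.001 by default."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 0.001


def hwe_chi2_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square test of observed genotype counts against HWE expectation."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    if np.any(expected == 0):
        return 1.0  # monomorphic: nothing to test
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc(
    genotypes: GenotypeTable, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Apply call-rate, MAF and HWE filters to the SNP markers.

    Returns the filtered table and an exclusion report listing each removed
    marker with the first criterion it failed (call_rate, maf, hwe).
    Monomorphic markers fall under the MAF rule.
    """
    D = genotypes.snp_dosage
    ids = genotypes.snp_marker_ids
    n = D.shape[0]
    keep, report = [], []
    for j, mid in enumerate(ids):
        col = D[:, j]
        called = ~np.isnan(col)
        call_rate = called.mean() if n else 0.0
        if call_rate <= thresholds.min_call_rate:
            report.append((mid, "call_rate", call_rate))
            continue
        c = col[called]
        freq = c.mean() / 2.0 if c.size else 0.0
        maf = min(freq, 1.0 - freq)
        if maf <= thresholds.min_maf:
            report.append((mid, "maf", maf))
            continue
        n_bb = int((c == 0).sum())
        n_ab = int((c == 1).sum())
        n_aa = int((c == 2).sum())
        p_hwe = hwe_chi2_pvalue(n_aa, n_ab, n_bb)
        if p_hwe <= thresholds.min_hwe_p:
            report.append((mid, "hwe", p_hwe))
            continue
        keep.append(mid)
    report_df = pd.DataFrame(report, columns=["marker_id", "failed_criterion", "value"])
    return genotypes.subset_snps(keep), report_df


# ---------------------------------------------------------------------------
# IBS kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Normalized pairwise IBS allele-sharing matrix.

    ``values`` is symmetric PSD (after a logged ridge repair if needed).
    Normalization is Gower-style: the raw IBS matrix is double-centered and
    rescaled so its trace equals n. Centering matters: raw IBS is an affine
    compression of the genetic covariance (a large constant baseline plus
    row/column offsets that the fixed-effect projection annihilates), and
    without removing it the REML variance ratio lands on a shrunken scale
    and pseudoheritability is badly inflated. The constant-part removal
    leaves the association tests unchanged up to the absorbed intercept.
    """

    individual_ids: list[str]
    values: np.ndarray
    scale_constant: float = 1.0
    ridge: float = 0.0

    def __post_init__(self) -> None:
        V = np.asarray(self.values, float)
        if V.shape != (len(self.individual_ids),) * 2:
            raise ValueError("kinship matrix shape mismatch")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = (V + V.T) / 2.0


def raw_ibs(genotypes: GenotypeTable) -> np.ndarray:
    """Unnormalized mean allele-sharing matrix (entries in [0, 1])."""
    D = genotypes.snp_dosage
    n, m = D.shape
    if m == 0:
        raise ValueError("no SNP markers for kinship")
    called = ~np.isnan(D)
    counts = called.astype(float) @ called.astype(float).T
    if np.any(counts == 0):
        raise ValueError("a pair of individuals shares no jointly observed markers")
    P = [np.where(called & (D == k), 1.0, 0.0) for k in (0.0, 1.0, 2.0)]
    S = P[0] @ P[0].T + P[1] @ P[1].T + P[2] @ P[2].T
    S += 0.5 * (P[0] @ P[1].T + P[1] @ P[0].T + P[1] @ P[2].T + P[2] @ P[1].T)
    return S / counts


def ibs_kinship(genotypes: GenotypeTable) -> KinshipMatrix:
    """Mean per-marker allele sharing (0, 1/2 or 1) over jointly called SNP.

    Sharing at one marker between dosages a and b is ``1 - |a - b| / 2``.
    Pairs with zero jointly observed markers are an error. The raw matrix
    is double-centered (Gower), rescaled so its trace equals n, then
    ridge-repaired to be positive semidefinite (minimum eigenvalue >=
    1e-8); centering constant and ridge are logged.
    """
    S = raw_ibs(genotypes)
    n = S.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    S = J @ ((S + S.T) / 2.0) @ J
    scale = n / np.trace(S)
    S = S * scale
    logger.info("ibs_kinship: Gower trace rescale constant %.6g", scale)
    w = np.linalg.eigvalsh((S + S.T) / 2.0)
    ridge = 0.0
    if w[0] < 1e-8:
        ridge = 1e-8 - float(w[0])
        S = S + ridge * np.eye(n)
        logger.info("ibs_kinship: PSD ridge %.3g added", ridge)
    return KinshipMatrix(
        individual_ids=list(genotypes.individual_ids),
        values=S,
        scale_constant=scale,
        ridge=ridge,
    )


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


def build_covariate_matrix(phenotypes: pd.DataFrame) -> np.ndarray:
    """Intercept + age + slaughter-year and slaughterhouse indicator columns."""
    n = len(phenotypes)
    cols = [np.ones(n), phenotypes["age"].to_numpy(float)]
    for cat in ("slaughter_year", "slaughterhouse"):
        levels = pd.Categorical(phenotypes[cat])
        for lev in levels.categories[1:]:  # first level absorbed by intercept
            cols.append((levels == lev).astype(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    return X


# ---------------------------------------------------------------------------
# REML via spectral decomposition
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    reml_loglik: float
    delta: float
    identifiable: bool = True

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")


def _projected_spectrum(K: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nonzero-eigenpair decomposition of (I - P_X) K (I - P_X).

    Returns (xi, U) with xi the n-p retained eigenvalues and U the matching
    eigenvectors; U' y are the error contrasts entering the restricted
    likelihood.
    """
    n, p = X.shape
    Q, _ = np.linalg.qr(X)
    M = np.eye(n) - Q @ Q.T
    MKM = M @ K @ M
    w, V = np.linalg.eigh((MKM + MKM.T) / 2.0)
    order = np.argsort(w)[::-1]
    keep = order[: n - p]
    return w[keep], V[:, keep]


def _restricted_loglik(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    """Profile restricted log-likelihood at variance ratio delta = s_e2/s_a2."""
    q = len(xi)
    denom = xi + delta
    if np.any(denom <= 0):
        return -np.inf
    s = float(np.sum(eta2 / denom))
    return 0.5 * (
        q * np.log(q / (2.0 * np.pi)) - q - q * np.log(s) - float(np.sum(np.log(denom)))
    )


def reml_fit(
    phenotypes: pd.DataFrame | np.ndarray,
    covariates: np.ndarray,
    kinship: KinshipMatrix,
    grid_size: int = 100,
    delta_bounds: tuple[float, float] = (1e-5, 1e5),
) -> VarianceComponents:
    """REML variance components of ``Var(y) = s_a2 * S + s_e2 * I``.

    The restricted likelihood is profiled over ``delta = s_e2/s_a2`` on a
    log-grid followed by bounded scalar refinement between the best grid
    neighbours (ties broken toward larger delta, i.e. smaller h2). If the
    likelihood is flat across the whole range — e.g. S is the identity —
    h2 is reported unidentifiable.
    """
    y = (
        phenotypes["trait"].to_numpy(float)
        if isinstance(phenotypes, pd.DataFrame)
        else np.asarray(phenotypes, float)
    )
    X = np.asarray(covariates, float)
    xi, U = _projected_spectrum(kinship.values, X)
    eta2 = (U.T @ y) ** 2
    q = len(xi)

    grid = np.logspace(np.log10(delta_bounds[0]), np.log10(delta_bounds[1]), grid_size)
    ll = np.array([_restricted_loglik(d, xi, eta2) for d in grid])
    if not np.any(np.isfinite(ll)):
        raise ValueError("restricted likelihood non-finite across the search range")
    best = int(np.flatnonzero(ll == ll.max())[-1])  # tie toward larger delta
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(np.exp(t), xi, eta2),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    loglik = -float(res.fun)
    if loglik < ll[best] - 1e-12:  # refinement must not lose to the grid
        delta, loglik = float(grid[best]), float(ll[best])

    sigma_a2 = float(np.sum(eta2 / (xi + delta)) / q)
    sigma_e2 = delta * sigma_a2
    h2 = sigma_a2 / (sigma_a2 + sigma_e2) if sigma_a2 + sigma_e2 > 0 else float("nan")
    identifiable = (ll.max() - ll.min()) > 1e-6
    if not identifiable:
        logger.warning("reml_fit: flat restricted likelihood; h2 unidentifiable")
    return VarianceComponents(
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        h2=h2,
        reml_loglik=loglik,
        delta=delta,
        identifiable=identifiable,
    )


# ---------------------------------------------------------------------------
# GLS association scan
# ---------------------------------------------------------------------------


@dataclass
class AssociationRecord:
    marker_id: str
    beta: float
    f_stat: float
    p_value: float
    n_used: int
    flagged: str = ""


@dataclass
class GwasRunSummary:
    lambda_gc: float
    n_markers_tested: int
    bonferroni_alpha: float
    covariates: list[str] = field(default_factory=list)
    conditioning_markers: list[str] = field(default_factory=list)


def _whitening_transform(
    kinship: KinshipMatrix, vc: VarianceComponents
) -> np.ndarray:
    """W with W V W' = I for V proportional to S + delta I."""
    w, U = np.linalg.eigh(kinship.values)
    lam = np.clip(w, 0.0, None) + vc.delta
    return (U / np.sqrt(lam)) @ U.T


def gls_scan(
    phenotypes: pd.DataFrame | np.ndarray,
    covariates: np.ndarray,
    kinship: KinshipMatrix,
    genotypes: GenotypeTable | np.ndarray,
    vc: VarianceComponents,
    conditioning_markers: list[str] | None = None,
    marker_ids: list[str] | None = None,
) -> list[AssociationRecord]:
    """Per-marker GLS F-tests with variance parameters fixed at the null fit.

    Whitening by ``V^{-1/2}`` (V proportional to S + delta I) reduces each
    marker test to OLS on rotated data. Missing dosages are mean-imputed
    per marker; conditioning markers enter the fixed design as dosage
    covariates and their own records are flagged collinear. Zero-variance
    markers are flagged degenerate with p = 1.
    """
    y = (
        phenotypes["trait"].to_numpy(float)
        if isinstance(phenotypes, pd.DataFrame)
        else np.asarray(phenotypes, float)
    )
    if isinstance(genotypes, GenotypeTable):
        D = genotypes.snp_dosage
        ids = genotypes.snp_marker_ids
    else:
        D = np.asarray(genotypes, float)
        ids = marker_ids or [f"m{j}" for j in range(D.shape[1])]
    n = len(y)
    X0 = np.asarray(covariates, float)
    conditioning_markers = conditioning_markers or []
    cond_cols = []
    for mid in conditioning_markers:
        col = D[:, ids.index(mid)].copy()
        col = np.where(np.isnan(col), np.nanmean(col), col)
        cond_cols.append(col)
    X = np.column_stack([X0] + cond_cols) if cond_cols else X0
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # drop redundant conditioning columns rather than failing
        logger.warning("gls_scan: conditioning column collinear with covariates")
    W = _whitening_transform(kinship, vc)
    yw = W @ y
    Xw = W @ X
    Q, _ = np.linalg.qr(Xw)
    resid_y = yw - Q @ (Q.T @ yw)
    p_cols = X.shape[1] + 1  # fixed effects + tested marker
    df = n - p_cols
    cond_set = set(conditioning_markers)

    # mean-impute, whiten and residualize all markers at once
    Dm = np.where(np.isnan(D), np.nanmean(D, axis=0), D)
    Gw = W @ Dm
    Gr = Gw - Q @ (Q.T @ Gw)
    gTg = np.einsum("ij,ij->j", Gr, Gr)
    gTy = Gr.T @ resid_y
    rss0 = float(resid_y @ resid_y)

    records: list[AssociationRecord] = []
    for j, mid in enumerate(ids):
        if mid in cond_set:
            records.append(AssociationRecord(mid, np.nan, np.nan, np.nan, n, "collinear"))
            continue
        if gTg[j] <= 1e-12 * max(gTg.max(), 1.0):
            records.append(AssociationRecord(mid, 0.0, 0.0, 1.0, n, "degenerate"))
            continue
        beta = gTy[j] / gTg[j]
        rss1 = rss0 - gTy[j] ** 2 / gTg[j]
        rss1 = max(rss1, 1e-300)
        f = (rss0 - rss1) / (rss1 / df)
        p = float(stats.f.sf(f, 1, df))
        records.append(AssociationRecord(mid, float(beta), float(f), max(p, 5e-324), n))
    return records


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def lambda_gc(records: list[AssociationRecord] | np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square equivalent of the
    p-values divided by the null chi-square median (0.4549)."""
    if isinstance(records, (list, tuple)):
        pvals = np.array(
            [r.p_value for r in records if np.isfinite(r.p_value)], dtype=float
        )
    else:
        pvals = np.asarray(records, float)
    if len(pvals) < 100:
        raise ValueError("lambda_gc needs at least 100 association records")
    chi2 = stats.chi2.isf(pvals, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def bonferroni_threshold(alpha: float, n_markers: int) -> float:
    """Genome-wide per-test significance level alpha / n_markers."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return alpha / n_markers


def variance_explained_fraction(h2_full: float, h2_conditioned: float) -> float:
    """Share of genetic variance attributed to the conditioned-on loci:
    (h2_full - h2_conditioned) / h2_full."""
    if not 0.0 <= h2_conditioned <= 1.0 or not 0.0 < h2_full <= 1.0:
        raise ValueError("heritabilities must lie in [0,1] with h2_full > 0")
    if h2_conditioned > h2_full:
        raise ValueError(
            "conditioning increased apparent heritability (h2_conditioned > h2_full)"
        )
    return (h2_full - h2_conditioned) / h2_full


def pairwise_r2(
    genotypes: GenotypeTable, marker_a: str, marker_b: str
) -> float:
    """LD r2 between two biallelic markers from EM haplotype frequencies.

    Returns nan when either marker is monomorphic (r2 undefined).
    """
    from . import ld_mapping  # local import: ld_mapping does not import us

    a = genotypes.dosage_of(marker_a)
    b = genotypes.dosage_of(marker_b)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if np.nanstd(a) == 0 or np.nanstd(b) == 0:
        return float("nan")
    if marker_a == marker_b:
        return 1.0
    pairs_a = _dosage_to_pairs(a)
    pairs_b = _dosage_to_pairs(b)
    freqs = ld_mapping.em_two_locus_single(pairs_a, pairs_b)
    freqs.pop("_loglik", None)
    pA = sum(f for (ha, _), f in freqs.items() if ha == 1)
    pB = sum(f for (_, hb), f in freqs.items() if hb == 1)
    if not 0 < pA < 1 or not 0 < pB < 1:
        return float("nan")
    pAB = freqs.get((1, 1), 0.0)
    d = pAB - pA * pB
    return float(d * d / (pA * (1 - pA) * pB * (1 - pB)))


def _dosage_to_pairs(dosage: np.ndarray) -> np.ndarray:
    pairs = np.zeros((len(dosage), 2), dtype=int)
    pairs[dosage == 1, 1] = 1
    pairs[dosage == 2] = 1
    return pairs
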