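"""Half-sib regression interval mapping.

Offspring of a phased sire are scanned along a cM grid: at each position
the probability that the paternal chromosome descends from the sire's Q
haplotype (Prob(Q)) is computed from the nearest informative flanking
markers under the Haldane map function, and an F-statistic compares the
least-squares fit with and without the Prob(Q) column. Significance
thresholds come from permutations of the phenotype (Churchill-Doerge) and
confidence regions from the bootstrap distribution of the profile peak,
accumulated highest-frequency-first so the region may be fragmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import MISSING_ALLELE

__all__ = [
    "PaternalCall",
    "SirePhase",
    "ProbQGrid",
    "QtlScanProfile",
    "deduce_paternal_allele",
    "prob_q_grid",
    "regression_scan",
    "permutation_threshold",
    "bootstrap_ci",
    "peak_frequency_regions",
]


def _haldane_r(d_cM: float | np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


# ---------------------------------------------------------------------------
# Paternal-allele deduction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PaternalCall:
    status: str  # determined | ambiguous | mendel_error
    paternal_allele: int | None = None


def deduce_paternal_allele(
    sire_pair: Sequence[int], offspring_pair: Sequence[int]
) -> PaternalCall:
    """Which sire allele was transmitted, when allele content determines it.

    Determined only when the sire is heterozygous and exactly one of his
    alleles is compatible with the offspring genotype. A homozygous sire or
    an offspring carrying both sire alleles is ambiguous; an offspring
    sharing no allele with the sire is a Mendelian error.
    """
    s1, s2 = int(sire_pair[0]), int(sire_pair[1])
    offspring = {int(offspring_pair[0]), int(offspring_pair[1])}
    if MISSING_ALLELE in (s1, s2) or MISSING_ALLELE in offspring:
        return PaternalCall("ambiguous")
    compatible = {a for a in (s1, s2) if a in offspring}
    if not compatible:
        return PaternalCall("mendel_error")
    if s1 == s2 or len(compatible) == 2:
        return PaternalCall("ambiguous")
    return PaternalCall("determined", paternal_allele=compatible.pop())


# ---------------------------------------------------------------------------
# Sire phase and Prob(Q)
# ---------------------------------------------------------------------------


@dataclass
class SirePhase:
    """Ordered sire haplotypes over the family markers, Q haplotype first."""

    sire_id: str
    marker_ids: list[str]
    positions_cM: np.ndarray
    haplotypes: np.ndarray  # (2, n_markers); row 0 is the Q haplotype
    q_haplotype_label: str = "Q"

    def __post_init__(self) -> None:
        self.positions_cM = np.asarray(self.positions_cM, float)
        self.haplotypes = np.asarray(self.haplotypes, int).reshape(2, -1)
        if self.haplotypes.shape[1] != len(self.marker_ids):
            raise ValueError("phase must cover all family markers")
        if np.any(np.diff(self.positions_cM) < 0):
            raise ValueError("marker positions must be sorted")

    def genotype_pair(self, j: int) -> tuple[int, int]:
        return int(self.haplotypes[0, j]), int(self.haplotypes[1, j])


@dataclass
class ProbQGrid:
    positions_cM: np.ndarray  # grid positions
    prob_q: np.ndarray  # (n_offspring, n_positions) in [0,1]

    def __post_init__(self) -> None:
        self.positions_cM = np.asarray(self.positions_cM, float)
        self.prob_q = np.asarray(self.prob_q, float)
        if np.any((self.prob_q < -1e-12) | (self.prob_q > 1 + 1e-12)):
            raise ValueError("Prob(Q) out of [0,1]")


def prob_q_grid(
    sire_phase: SirePhase,
    offspring_pairs: np.ndarray,
    step_cM: float = 2.0,
) -> ProbQGrid:
    """Per-offspring Prob(Q) along a regular cM grid.

    ``offspring_pairs`` is (n_offspring, n_markers, 2). For each offspring
    the markers where paternal transmission is deducible and the sire's two
    haplotypes carry different alleles become informative anchors; between
    anchors Prob(Q) follows the nearest-flank recombination-class
    enumeration under Haldane (no interference); with a single flank it
    decays toward 1/2; with no informative marker it is 1/2.
    """
    pos = sire_phase.positions_cM
    off = np.asarray(offspring_pairs, int)
    n, m, _ = off.shape
    if m != len(pos):
        raise ValueError("offspring genotypes do not match the sire phase markers")
    grid = np.arange(pos[0], pos[-1] + 1e-9, step_cM)
    if grid[-1] < pos[-1] - 1e-9:
        grid = np.append(grid, pos[-1])
    probs = np.full((n, len(grid)), 0.5)
    hap_q = sire_phase.haplotypes[0]
    hap_nq = sire_phase.haplotypes[1]
    informative_marker = hap_q != hap_nq
    for i in range(n):
        states: list[tuple[float, int]] = []  # (position, 1 if Q transmitted)
        for j in range(m):
            if not informative_marker[j]:
                continue
            call = deduce_paternal_allele(sire_phase.genotype_pair(j), off[i, j])
            if call.status != "determined":
                continue
            states.append((pos[j], 1 if call.paternal_allele == hap_q[j] else 0))
        if not states:
            continue
        s_pos = np.array([p for p, _ in states])
        s_val = np.array([v for _, v in states])
        left = np.searchsorted(s_pos, grid, side="right") - 1
        right = np.searchsorted(s_pos, grid, side="left")
        for g, x in enumerate(grid):
            li, ri = left[g], right[g]
            has_l, has_r = li >= 0, ri < len(s_pos)
            if has_l and has_r and li == ri:  # exactly at an informative marker
                probs[i, g] = float(s_val[li])
                continue
            if has_l and has_r:
                rl = float(_haldane_r(x - s_pos[li]))
                rr = float(_haldane_r(s_pos[ri] - x))
                tl_q = 1 - rl if s_val[li] == 1 else rl
                tl_n = rl if s_val[li] == 1 else 1 - rl
                tr_q = 1 - rr if s_val[ri] == 1 else rr
                tr_n = rr if s_val[ri] == 1 else 1 - rr
                probs[i, g] = tl_q * tr_q / (tl_q * tr_q + tl_n * tr_n)
            elif has_l:
                rl = float(_haldane_r(x - s_pos[li]))
                probs[i, g] = 1 - rl if s_val[li] == 1 else rl
            elif has_r:
                rr = float(_haldane_r(s_pos[ri] - x))
                probs[i, g] = 1 - rr if s_val[ri] == 1 else rr
    return ProbQGrid(positions_cM=grid, prob_q=probs)


# ---------------------------------------------------------------------------
# Regression scan
# ---------------------------------------------------------------------------


@dataclass
class QtlScanProfile:
    positions_cM: np.ndarray
    f_stats: np.ndarray
    peak_position: float
    thresholds: dict = field(default_factory=dict)
    ci_regions: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.any(X.std(axis=0) == 0):  # add intercept unless one is present
        X = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    return X


def _profile_f(
    y: np.ndarray, X0: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """F statistics of adding each column of C to the base design X0.

    Returns (F, flags) where flags marks columns constant after covariate
    adjustment (F set to 0 there).
    """
    n = len(y)
    Q, _ = np.linalg.qr(X0)
    ry = y - Q @ (Q.T @ y)
    Cr = C - Q @ (Q.T @ C)
    cc = np.einsum("ij,ij->j", Cr, Cr)
    cy = Cr.T @ ry
    rss0 = float(ry @ ry)
    dfe = n - X0.shape[1] - 1
    flags = cc <= 1e-12 * max(1.0, float(np.max(cc, initial=0.0)))
    num = np.where(flags, 0.0, cy**2 / np.where(flags, 1.0, cc))
    rss1 = np.maximum(rss0 - num, 1e-300)
    F = np.where(flags, 0.0, num / (rss1 / dfe))
    return F, flags


def regression_scan(
    phenotypes: np.ndarray,
    covariates: np.ndarray | None,
    prob_q: ProbQGrid,
) -> QtlScanProfile:
    """F-statistic profile of phenotype on Prob(Q) after covariate adjustment.

    At each grid position F = ((RSS0 - RSS1)/1) / (RSS1/(n - p)) where RSS1
    adds the Prob(Q) column. The profile peak is the leftmost maximum.
    """
    y = np.asarray(phenotypes, float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 offspring")
    X0 = _design(covariates, n)
    F, flags = _profile_f(y, X0, prob_q.prob_q)
    peak = float(prob_q.positions_cM[int(np.argmax(F))])
    return QtlScanProfile(
        positions_cM=prob_q.positions_cM.copy(),
        f_stats=F,
        peak_position=peak,
        flags={"constant_prob_q": np.flatnonzero(flags).tolist()},
    )


def permutation_threshold(
    phenotypes: np.ndarray,
    covariates: np.ndarray | None,
    prob_q: ProbQGrid,
    n_perm: int = 10_000,
    alphas: Sequence[float] = (0.05, 0.01, 0.001),
    seed: int = 0,
) -> dict[float, float]:
    """Empirical genome(chromosome)-wise thresholds from phenotype permutations.

    Trait values are shuffled against the fixed covariate and Prob(Q) rows
    (simple Churchill-Doerge permutation; any covariate-trait association is
    deliberately broken too). For each permutation the profile maximum is
    recorded; the threshold at level alpha is the empirical (1 - alpha)
    quantile of the maxima.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if any(a < 1.0 / n_perm for a in alphas):
        raise ValueError("alpha below 1/n_perm is unsupported")
    y = np.asarray(phenotypes, float)
    n = len(y)
    X0 = _design(covariates, n)
    Q, _ = np.linalg.qr(X0)
    C = prob_q.prob_q
    Cr = C - Q @ (Q.T @ C)
    cc = np.einsum("ij,ij->j", Cr, Cr)
    good = cc > 1e-12 * max(1.0, float(np.max(cc, initial=0.0)))
    dfe = n - X0.shape[1] - 1

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y[perms].T  # (n, n_perm)
    Ry = Yp - Q @ (Q.T @ Yp)
    rss0 = np.einsum("ij,ij->j", Ry, Ry)
    num = (Cr[:, good].T @ Ry) ** 2 / cc[good, None]  # (n_good, n_perm)
    F = num / ((rss0[None, :] - num) / dfe)
    maxima = F.max(axis=0)
    return {
        float(a): float(np.quantile(maxima, 1.0 - a, method="higher")) for a in alphas
    }


def bootstrap_ci(
    phenotypes: np.ndarray,
    covariates: np.ndarray | None,
    prob_q: ProbQGrid,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Bootstrap confidence region for the QTL position.

    Offspring are resampled with replacement to the original family size,
    the scan repeated, and the profile-peak positions collected. The region
    is the smallest set of grid positions, accumulated in decreasing
    peak-frequency order, with total frequency >= ``level``; contiguous
    grid runs are merged, so the region may be fragmented. Returns
    (regions, per-position peak frequencies).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = np.asarray(phenotypes, float)
    n = len(y)
    X0 = _design(covariates, n)
    C = prob_q.prob_q
    grid = prob_q.positions_cM
    G = len(grid)
    p = X0.shape[1]
    dfe = n - p - 1
    rng = np.random.default_rng(seed)
    peak_counts = np.zeros(G, dtype=int)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xs, ys, Cs = X0[idx], y[idx], C[idx]
        A = Xs.T @ Xs
        Ainv = np.linalg.pinv(A)
        b = Xs.T @ ys
        yy = float(ys @ ys)
        rss0 = yy - float(b @ Ainv @ b)
        CtX = Cs.T @ Xs  # (G, p)
        cty = Cs.T @ ys
        ctc = np.einsum("ij,ij->j", Cs, Cs)
        U = CtX @ Ainv
        cc_adj = ctc - np.einsum("ij,ij->i", U, CtX)
        cy_adj = cty - U @ b
        good = cc_adj > 1e-10 * max(1.0, float(np.max(cc_adj, initial=0.0)))
        num = np.zeros(G)
        num[good] = cy_adj[good] ** 2 / cc_adj[good]
        F = np.where(good, num / np.maximum((rss0 - num) / dfe, 1e-300), 0.0)
        peak_counts[int(np.argmax(F))] += 1
    freqs = peak_counts / n_boot
    return peak_frequency_regions(freqs, grid, level), freqs


def peak_frequency_regions(
    freqs: np.ndarray, positions: np.ndarray, level: float
) -> list[tuple[float, float]]:
    """Smallest set of grid positions with total peak frequency >= level.

    Positions are accumulated in decreasing frequency order (ties broken
    leftmost-first) and contiguous grid runs merged into (start, end)
    regions, which may therefore be fragmented.
    """
    freqs = np.asarray(freqs, float)
    positions = np.asarray(positions, float)
    G = len(freqs)
    order = np.lexsort((np.arange(G), -freqs))
    cum = np.cumsum(freqs[order])
    take = int(np.searchsorted(cum, level - 1e-12)) + 1
    selected = np.sort(order[: min(take, G)])
    regions: list[tuple[float, float]] = []
    start = prev = selected[0]
    for s in selected[1:]:
        if s == prev + 1:
            prev = s
            continue
        regions.append((float(positions[start]), float(positions[prev])))
        start = prev = s
    regions.append((float(positions[start]), float(positions[prev])))
    return regions
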