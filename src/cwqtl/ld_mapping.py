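"""Case/control LD mapping over sliding pairs of contiguous markers.

For each pair of adjacent (typically multi-allelic microsatellite) markers,
two-locus haplotype frequencies are estimated per phenotype group with an
EM algorithm for unphased genotypes, converted to integer haplotype counts,
and compared between groups with Fisher's exact test — a 2xn table over all
haplotypes plus optional 2x2 tests for tracked haplotypes (e.g. a sire's Q
haplotype), skipped when the haplotype is seen fewer than 6 times in both
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import MISSING_ALLELE, GenotypeTable

__all__ = [
    "HaplotypeFreqTable",
    "WindowTestResult",
    "em_two_locus",
    "em_two_locus_single",
    "haplotype_counts",
    "largest_remainder_counts",
    "fisher_exact_2x2",
    "fisher_exact_2xn",
    "scan_windows",
]

EM_TOL = 1e-8
EM_MAX_ITER = 1000
LOW_COUNT_THRESHOLD = 6


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimation
# ---------------------------------------------------------------------------


def _diplotype_options(ga: tuple, gb: tuple) -> list[tuple[tuple, tuple]]:
    """Possible phased diplotypes {(h1, h2)} for one unphased two-locus genotype."""
    (a1, a2), (b1, b2) = ga, gb
    d1 = ((a1, b1), (a2, b2))
    if a1 == a2 or b1 == b2:
        return [d1]
    d2 = ((a1, b2), (a2, b1))
    return [d1, d2]


def em_two_locus_single(
    pairs_a: np.ndarray, pairs_b: np.ndarray
) -> dict[tuple, float]:
    """ML two-locus haplotype frequencies for one sample of unphased pairs.

    ``pairs_a``/``pairs_b`` are (n, 2) integer allele arrays (sorted pairs,
    :data:`MISSING_ALLELE` for missing); individuals missing at either locus
    are dropped. Initialization is uniform over the cross-product of
    observed alleles, so the run is deterministic and label-symmetric. The
    observed-data log-likelihood is checked to be non-decreasing at every
    iteration.
    """
    pa = np.asarray(pairs_a, int)
    pb = np.asarray(pairs_b, int)
    ok = (pa != MISSING_ALLELE).all(axis=1) & (pb != MISSING_ALLELE).all(axis=1)
    pa, pb = pa[ok], pb[ok]
    n = len(pa)
    if n == 0:
        raise ValueError("no jointly called individuals for EM")
    alleles_a = sorted(set(pa.ravel()))
    alleles_b = sorted(set(pb.ravel()))
    haps = [(a, b) for a in alleles_a for b in alleles_b]
    freq = {h: 1.0 / len(haps) for h in haps}
    options = [_diplotype_options(tuple(pa[i]), tuple(pb[i])) for i in range(n)]

    def diplotype_prob(d, f):
        h1, h2 = d
        p = f[h1] * f[h2]
        return 2.0 * p if h1 != h2 else p

    prev_ll = -np.inf
    for _ in range(EM_MAX_ITER):
        counts = {h: 0.0 for h in haps}
        ll = 0.0
        for opts in options:
            probs = [diplotype_prob(d, freq) for d in opts]
            tot = sum(probs)
            if tot <= 0:
                tot = len(opts) * 1e-300
                probs = [1e-300] * len(opts)
            ll += np.log(tot)
            for d, p in zip(opts, probs):
                w = p / tot
                counts[d[0]] += w
                counts[d[1]] += w
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        new = {h: c / (2.0 * n) for h, c in counts.items()}
        delta = max(abs(new[h] - freq[h]) for h in haps)
        freq = new
        if delta < EM_TOL and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    freq["_loglik"] = prev_ll  # type: ignore[assignment]
    return freq


@dataclass
class HaplotypeFreqTable:
    """EM haplotype-frequency estimates for one marker pair, per group."""

    marker_a: str
    marker_b: str
    haplotypes: list[tuple]
    frequencies: dict[str, dict[tuple, float]]
    em_loglik: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for grp, f in self.frequencies.items():
            tot = sum(f.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"group {grp!r}: frequencies sum to {tot}")
            if any(v < -1e-12 for v in f.values()):
                raise ValueError(f"group {grp!r}: negative frequency")


def em_two_locus(
    genotypes: GenotypeTable,
    marker_a: str,
    marker_b: str,
    groups: dict[str, Sequence[str]],
) -> HaplotypeFreqTable:
    """Per-group EM haplotype frequencies for two (possibly multi-allelic) markers."""
    frequencies: dict[str, dict[tuple, float]] = {}
    logliks: dict[str, float] = {}
    hap_union: set[tuple] = set()
    for grp, ids in groups.items():
        sub = genotypes.subset_individuals(list(ids))
        pa = sub.pairs_of(marker_a)
        pb = sub.pairs_of(marker_b)
        f = em_two_locus_single(pa, pb)
        logliks[grp] = float(f.pop("_loglik"))
        frequencies[grp] = f
        hap_union |= set(f)
    haplotypes = sorted(hap_union)
    for grp in frequencies:
        frequencies[grp] = {h: frequencies[grp].get(h, 0.0) for h in haplotypes}
    return HaplotypeFreqTable(
        marker_a=marker_a,
        marker_b=marker_b,
        haplotypes=haplotypes,
        frequencies=frequencies,
        em_loglik=logliks,
    )


# ---------------------------------------------------------------------------
# Frequencies -> integer counts
# ---------------------------------------------------------------------------


def largest_remainder_counts(frequencies: Sequence[float], total: int) -> np.ndarray:
    """Integer counts summing exactly to ``total`` by largest-remainder rounding."""
    f = np.asarray(frequencies, float)
    raw = f * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        remainders = raw - base
        order = np.argsort(-remainders, kind="mergesort")
        base[order[:short]] += 1
    return base


def haplotype_counts(
    freq_table: HaplotypeFreqTable, group_sizes: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-group haplotype counts: frequency x 2N, largest-remainder rounded."""
    out = {}
    for grp, f in freq_table.frequencies.items():
        two_n = 2 * group_sizes[grp]
        out[grp] = largest_remainder_counts(
            [f[h] for h in freq_table.haplotypes], two_n
        )
    return out


# ---------------------------------------------------------------------------
# Fisher exact tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 integer table (zero margin -> 1)."""
    t = np.asarray(table, int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 integer table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _log_table_prob(table: np.ndarray) -> float:
    """Log fixed-margin (multivariate hypergeometric) probability of a table."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = int(table.sum())
    lp = sum(lgamma(v + 1) for v in r) + sum(lgamma(v + 1) for v in c)
    lp -= lgamma(n + 1) + sum(lgamma(v + 1) for v in table.ravel())
    return lp


def _enumerate_2xn_pvalue(table: np.ndarray) -> float:
    """Exact two-sided p by DFS over all 2xn tables with the observed margins."""
    r1 = int(table[0].sum())
    c = table.sum(axis=0).astype(int)
    obs_lp = _log_table_prob(table)
    n_cols = len(c)
    total = 0.0
    suffix_cap = np.concatenate([np.cumsum(c[::-1])[::-1], [0]])

    def rec(j: int, remaining: int, row: list[int]) -> None:
        nonlocal total
        if j == n_cols:
            if remaining == 0:
                t = np.vstack([row, c - np.array(row)])
                lp = _log_table_prob(t)
                if lp <= obs_lp + 1e-9:
                    total += np.exp(lp)
            return
        lo = max(0, remaining - int(suffix_cap[j + 1]))
        hi = min(int(c[j]), remaining)
        for x in range(lo, hi + 1):
            rec(j + 1, remaining - x, row + [x])

    rec(0, r1, [])
    return float(min(total, 1.0))


def _n_candidate_tables(table: np.ndarray) -> float:
    c = table.sum(axis=0)
    return float(np.prod(c + 1.0))


def fisher_exact_2xn(
    table: np.ndarray | Sequence[Sequence[int]],
    max_enumeration: float = 2e5,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided exact p for a 2xn table.

    Full enumeration over fixed-margin tables when the candidate count is
    below ``max_enumeration``; otherwise seeded Monte-Carlo with ``n_mc``
    Patefield draws from the fixed-margin null and the add-one estimator
    p = (1 + #{draws at most as probable}) / (n_mc + 1), so p > 0 always.
    """
    t = np.asarray(table, int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2 or (t < 0).any():
        raise ValueError("need a non-negative 2xn integer table with n >= 2")
    keep = t.sum(axis=0) > 0  # empty haplotype columns carry no information
    t = t[:, keep]
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return 1.0
    if t.shape[1] == 2:
        return fisher_exact_2x2(t)
    if _n_candidate_tables(t) <= max_enumeration:
        return _enumerate_2xn_pvalue(t)
    obs_lp = _log_table_prob(t)
    rng = np.random.default_rng(seed)
    draws = stats.random_table(t.sum(axis=1), t.sum(axis=0)).rvs(
        n_mc, random_state=rng
    )
    from scipy.special import gammaln

    # margins are fixed, so only the cell-factorial term varies across draws
    lps = -gammaln(np.asarray(draws) + 1.0).sum(axis=(1, 2))
    obs_cells = -gammaln(t + 1.0).sum()
    hits = int(np.sum(lps <= obs_cells + 1e-9))
    del obs_lp
    return float((1 + hits) / (n_mc + 1))


# ---------------------------------------------------------------------------
# Sliding-window scan
# ---------------------------------------------------------------------------


@dataclass
class WindowTestResult:
    marker_a: str
    marker_b: str
    p_overall: float
    haplotypes: list[tuple]
    counts: dict[str, np.ndarray]
    tracked: dict[str, dict] = field(default_factory=dict)

    def tracked_p(self, label: str):
        return self.tracked[label]["p"]


def scan_windows(
    genotypes: GenotypeTable,
    heavy_ids: Sequence[str],
    light_ids: Sequence[str],
    tracked_haplotypes: dict[str, Sequence[tuple]] | None = None,
    mc_seed: int = 0,
) -> list[WindowTestResult]:
    """Test every pair of contiguous microsatellite markers along the map.

    Per window: EM haplotype frequencies in the heavy and light groups,
    integer counts, a 2xn overall Fisher test, and — for each tracked
    haplotype (one (allele_a, allele_b) pair per window, e.g. a sire's Q
    haplotype alleles) — a 2x2 test of that haplotype against all others,
    skipped with an excluded flag when its count is below 6 in both groups.
    """
    if set(heavy_ids) & set(light_ids):
        raise ValueError("heavy and light groups must be disjoint")
    ms_ids = genotypes.ms_marker_ids
    if len(ms_ids) < 2:
        raise ValueError("need at least two microsatellite markers to scan")
    groups = {"heavy": list(heavy_ids), "light": list(light_ids)}
    sizes = {g: len(ids) for g, ids in groups.items()}
    results: list[WindowTestResult] = []
    for w, (ma, mb) in enumerate(zip(ms_ids[:-1], ms_ids[1:])):
        ft = em_two_locus(genotypes, ma, mb, groups)
        counts = haplotype_counts(ft, sizes)
        table = np.vstack([counts["heavy"], counts["light"]])
        p_overall = fisher_exact_2xn(table, seed=mc_seed + w)
        tracked_out: dict[str, dict] = {}
        for label, hap_list in (tracked_haplotypes or {}).items():
            hap = tuple(hap_list[w])
            if hap in ft.haplotypes:
                hi = ft.haplotypes.index(hap)
                ch, cl = int(counts["heavy"][hi]), int(counts["light"][hi])
            else:
                ch = cl = 0
            if ch < LOW_COUNT_THRESHOLD and cl < LOW_COUNT_THRESHOLD:
                tracked_out[label] = dict(p=None, excluded=True, counts=(ch, cl))
                continue
            t22 = np.array(
                [
                    [ch, int(counts["heavy"].sum()) - ch],
                    [cl, int(counts["light"].sum()) - cl],
                ]
            )
            tracked_out[label] = dict(
                p=fisher_exact_2x2(t22), excluded=False, counts=(ch, cl)
            )
        results.append(
            WindowTestResult(
                marker_a=ma,
                marker_b=mb,
                p_overall=p_overall,
                haplotypes=ft.haplotypes,
                counts=counts,
                tracked=tracked_out,
            )
        )
    return results
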