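"""Synthetic pedigreed populations with planted carcass-weight QTL.

The generator emulates the structure the downstream analyses assume: a
general population of paternal half-sib families, genome-wide SNP with
block LD, three additive QTL whose causative loci (QTN) are untyped but
tagged by nearby SNP in strong LD, a polygenic background realized as many
small additive effects at the genotyped SNP themselves (so an IBS kinship
genuinely captures it), fixed environmental effects on the phenotype, and
phenotype-extreme sample selection.

Founder haplotypes are mosaics of a small set of ancestral haplotypes with
an exponential block-switch process along the map, which produces LD that
decays with genetic distance. Meiosis uses the Haldane map function
(independent crossovers, no interference), matching the assumptions of the
half-sib interval-mapping module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, IntervalSet, MarkerMap, VariantPanel

__all__ = [
    "QtlSpec",
    "FixedEffects",
    "SimulationConfig",
    "FounderPool",
    "TruthRecord",
    "default_config",
    "build_founder_haplotypes",
    "gene_drop_population",
    "assign_phenotypes",
    "select_extremes",
    "emit_variant_panel",
    "simulate_population",
    "simulate_unstructured",
    "simulate_halfsib_family",
    "simulate_ld_mapping_groups",
    "haplotype_r2",
]


@dataclass(frozen=True)
class QtlSpec:
    """One additive QTL: map position, allele-substitution effect, Q frequency."""

    chromosome: str
    position_cM: float
    effect_kg_per_allele: float
    q_freq: float

    def __post_init__(self) -> None:
        if not 0.0 < self.q_freq < 1.0:
            raise ValueError(f"q_freq must be in (0,1), got {self.q_freq}")


@dataclass(frozen=True)
class FixedEffects:
    """Environmental fixed effects entering the phenotype model."""

    age_slope_kg_per_month: float = 2.0
    year_effects_kg: dict = field(
        default_factory=lambda: {"2004": 0.0, "2005": 6.0, "2006": -5.0}
    )
    house_effects_kg: dict = field(default_factory=lambda: {"A": 0.0, "B": 7.0})
    age_range_months: tuple = (25, 35)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated population.

    Defaults mirror the discovery design the pipeline targets: ~1,200
    steers in paternal half-sib families, three additive QTL with allele
    substitution effects 28.4 / 35.3 / 35.0 kg at Q frequencies
    0.754 / 0.200 / 0.115 (QTL variance ~947 kg2 under HWE), and a
    polygenic/residual split (polygenic share 0.267 of phenotypic
    variance, residual SD 30.6 kg) chosen so total heritability is ~0.64
    and pseudoheritability after conditioning on the three QTL is ~0.42 —
    i.e. the QTL "explain" about one-third of the genetic variance on the
    heritability-drop scale. 15% phenotype extremes feed the LD-mapping
    group selection.
    """

    seed: int = 0
    n_founder_haplotypes: int = 200
    n_sires: int = 60
    offspring_per_sire: int = 20
    n_snp: int = 450
    n_microsat: int = 0
    map_length_cM: tuple = (100.0, 100.0, 100.0)
    qtl_specs: tuple = (
        QtlSpec("1", 50.0, 28.4, 0.754),
        QtlSpec("2", 50.0, 35.3, 0.200),
        QtlSpec("3", 50.0, 35.0, 0.115),
    )
    polygenic_h2: float = 0.267
    residual_sd_kg: float = 30.6
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    extreme_fraction: float = 0.15
    intercept_kg: float = 450.0
    # LD-structure knobs
    n_ancestral_haplotypes: int = 12
    block_switch_per_cM: float = 0.05
    tag_r2_targets: tuple = (1.0, 0.85, 0.7)
    tag_offsets_cM: tuple = (0.05, 0.4, 0.8)
    tag_r2_floor: float = 0.65

    def __post_init__(self) -> None:
        if not 0.0 <= self.polygenic_h2 < 1.0:
            raise ValueError("polygenic_h2 must be in [0,1)")
        if self.residual_sd_kg < 0:
            raise ValueError("residual_sd_kg must be >= 0")
        chroms = {q.chromosome for q in self.qtl_specs}
        known = {str(i + 1) for i in range(len(self.map_length_cM))}
        if chroms - known:
            raise ValueError(f"QTL on unknown chromosome: {sorted(chroms - known)}")

    @property
    def n_offspring(self) -> int:
        return self.n_sires * self.offspring_per_sire


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    return replace(SimulationConfig(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# Founder haplotypes
# ---------------------------------------------------------------------------


@dataclass
class FounderPool:
    """Pool of phased founder haplotypes over all loci (markers + hidden QTN).

    ``loci`` has columns ``chromosome, position_cM, kind, name`` with kind in
    {snp, microsatellite, qtn}; ``haplotypes`` is (H, n_loci) of integer
    allele labels (0/1 for SNP and QTN, fragment lengths for microsats).
    """

    loci: pd.DataFrame
    haplotypes: np.ndarray
    config: SimulationConfig

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def marker_map(self) -> MarkerMap:
        f = self.loci.loc[self.loci["kind"] != "qtn"]
        return MarkerMap(
            pd.DataFrame(
                dict(
                    marker_id=f["name"].to_numpy(),
                    chromosome=f["chromosome"].to_numpy(),
                    position_bp=(f["position_cM"].to_numpy() * 1e6).round().astype(int) + 1,
                    position_cM=f["position_cM"].to_numpy(),
                    marker_type=np.where(f["kind"] == "snp", "snp", "microsatellite"),
                )
            )
        )

    def columns_of_kind(self, kind: str) -> np.ndarray:
        return np.flatnonzero((self.loci["kind"] == kind).to_numpy())


def haplotype_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Squared correlation between two binary haplotype vectors (direct count)."""
    a = np.asarray(hap_a, float)
    b = np.asarray(hap_b, float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _flip_to_target_r2(
    q_vec: np.ndarray, target_r2: float, rng: np.random.Generator
) -> np.ndarray:
    """Copy of a Q-indicator vector degraded by random flips until r2 <= target."""
    tag = q_vec.copy()
    if target_r2 >= 1.0:
        return tag
    order = rng.permutation(len(tag))
    for idx in order:
        if haplotype_r2(tag, q_vec) <= target_r2:
            break
        tag[idx] ^= 1
    return tag


def build_founder_haplotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> FounderPool:
    """Build the phased founder pool with planted QTN and tag SNP.

    Each QTN gets exactly ``round(q_freq * H)`` carrier haplotypes; the
    first tag SNP copies the carrier indicator exactly and further tags are
    degraded toward the configured r2 targets, so every QTN has a genotyped
    SNP whose population r2 is at least ``tag_r2_floor``.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    H = config.n_founder_haplotypes
    n_chrom = len(config.map_length_cM)
    total_len = float(sum(config.map_length_cM))

    # background SNP positions, proportional to chromosome length
    rows = []
    remaining = config.n_snp
    for c, length in enumerate(config.map_length_cM):
        take = round(config.n_snp * length / total_len) if c < n_chrom - 1 else remaining
        take = min(take, remaining)
        remaining -= take
        pos = np.linspace(0.0, length, take + 2)[1:-1]
        for j, p in enumerate(pos):
            rows.append((str(c + 1), float(p), "snp", f"snp_c{c + 1}_{j:04d}"))
    for c, length in enumerate(config.map_length_cM):
        if config.n_microsat == 0:
            break
        take = round(config.n_microsat / n_chrom)
        pos = np.linspace(0.0, length, take + 2)[1:-1]
        for j, p in enumerate(pos):
            rows.append((str(c + 1), float(p) + 1e-4, "microsatellite", f"ms_c{c + 1}_{j:03d}"))
    loci = pd.DataFrame(rows, columns=["chromosome", "position_cM", "kind", "name"])

    # ancestral haplotypes and mosaic founders for background loci
    n_bg = len(loci)
    base_freq = rng.uniform(0.15, 0.85, size=n_bg)
    n_anc = config.n_ancestral_haplotypes
    is_ms = (loci["kind"] == "microsatellite").to_numpy()
    anc = np.where(
        rng.random((n_anc, n_bg)) < base_freq, 1, 0
    ).astype(np.int16)
    if is_ms.any():
        # microsat ancestral alleles: fragment lengths 150 + 2k, k in 0..5
        anc[:, is_ms] = 150 + 2 * rng.integers(0, 6, size=(n_anc, int(is_ms.sum())))

    d = np.zeros(n_bg)
    same_chrom = loci["chromosome"].to_numpy()[1:] == loci["chromosome"].to_numpy()[:-1]
    d[1:] = np.where(
        same_chrom, np.diff(loci["position_cM"].to_numpy()), np.inf
    )
    p_switch = 1.0 - np.exp(-config.block_switch_per_cM * d)
    p_switch[0] = 1.0
    switch = rng.random((H, n_bg)) < p_switch
    choice = rng.integers(0, n_anc, size=(H, n_bg))
    # carry forward the ancestral index between switch points
    idx = np.where(switch, np.arange(n_bg), 0)
    idx = np.maximum.accumulate(idx, axis=1)
    anc_index = np.take_along_axis(choice, idx, axis=1)
    haplotypes = anc[anc_index, np.arange(n_bg)]

    # plant QTN + tag SNP
    extra_rows = []
    extra_cols = []
    for qi, q in enumerate(config.qtl_specs):
        n_carrier = int(round(q.q_freq * H))
        if n_carrier <= 0 or n_carrier >= H:
            raise ValueError(
                f"q_freq={q.q_freq} unreachable with {H} founder haplotypes"
            )
        carriers = np.zeros(H, dtype=np.int16)
        carriers[rng.choice(H, size=n_carrier, replace=False)] = 1
        extra_rows.append((q.chromosome, q.position_cM, "qtn", f"qtn_{qi}"))
        extra_cols.append(carriers)
        for ti, (r2_target, off) in enumerate(
            zip(config.tag_r2_targets, config.tag_offsets_cM)
        ):
            tag = _flip_to_target_r2(carriers, r2_target, rng)
            side = 1 if ti % 2 == 0 else -1
            extra_rows.append(
                (q.chromosome, q.position_cM + side * off, "snp", f"tag_q{qi}_{ti}")
            )
            extra_cols.append(tag)
        r2_best = haplotype_r2(extra_cols[-len(config.tag_r2_targets)], carriers)
        if r2_best < config.tag_r2_floor:
            raise ValueError(
                f"best tag r2 {r2_best:.3f} below floor {config.tag_r2_floor}"
            )

    loci = loci.assign(is_tag=False)
    extra = pd.DataFrame(extra_rows, columns=["chromosome", "position_cM", "kind", "name"])
    extra = extra.assign(is_tag=extra["kind"] == "snp")
    loci = pd.concat([loci, extra], ignore_index=True)
    haplotypes = np.hstack([haplotypes, np.column_stack(extra_cols)]) if extra_cols else haplotypes
    # string chromosome sort keeps loci aligned with MarkerMap ordering
    order = np.lexsort(
        (loci["position_cM"].to_numpy(), loci["chromosome"].to_numpy())
    )
    loci = loci.iloc[order].reset_index(drop=True)
    haplotypes = haplotypes[:, order]
    return FounderPool(loci=loci, haplotypes=haplotypes.astype(np.int16), config=config)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Ground truth emitted next to a simulated population."""

    qtl_specs: tuple
    qtl_dosage: np.ndarray  # (n_offspring, n_qtl)
    sire_of: np.ndarray  # sire index per offspring
    sire_hap_index: np.ndarray  # (n_sires, 2) rows into the founder pool
    paternal_origin: np.ndarray  # (n_offspring, n_loci) in {0,1}
    pool: FounderPool
    polygenic_value: np.ndarray | None = None
    realized_variances: dict = field(default_factory=dict)
    fixed_effect_draws: pd.DataFrame | None = None

    @property
    def loci(self) -> pd.DataFrame:
        return self.pool.loci


def _haldane_r(d_cM: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


def _interval_switch_probs(loci: pd.DataFrame) -> np.ndarray:
    """Per-interval transmission switch probabilities; 0.5 across chromosomes."""
    pos = loci["position_cM"].to_numpy()
    chrom = loci["chromosome"].to_numpy()
    r = np.empty(len(loci))
    r[0] = 0.5  # random start phase
    same = chrom[1:] == chrom[:-1]
    r[1:] = np.where(same, _haldane_r(np.diff(pos)), 0.5)
    return r


def _meiosis_origins(
    n_gametes: int, switch_probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n_gametes, n_loci) array of parental haplotype origins in {0,1}."""
    flips = rng.random((n_gametes, len(switch_probs))) < switch_probs
    return np.bitwise_xor.accumulate(flips.astype(np.int8), axis=1) & 1


def gene_drop_population(
    pool: FounderPool, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, TruthRecord]:
    """Drop genes through one generation of paternal half-sib families.

    Sires take two haplotypes each from the pool without replacement; every
    offspring has its own dam drawn (with replacement) from the pool.
    Offspring haplotypes are recombinant mosaics under the Haldane map
    function, and the paternal haplotype of origin at every locus is
    recorded for Prob(Q) ground truth.
    """
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    H = pool.n_haplotypes
    n_sires, k = config.n_sires, config.offspring_per_sire
    n_off = n_sires * k
    if 2 * n_sires > H:
        raise ValueError("founder pool too small for the requested number of sires")
    loci = pool.loci
    n_loci = len(loci)
    switch_probs = _interval_switch_probs(loci)

    sire_hap_index = rng.choice(H, size=(n_sires, 2), replace=False)
    sire_haps = pool.haplotypes[sire_hap_index]  # (n_sires, 2, n_loci)
    sire_of = np.repeat(np.arange(n_sires), k)

    pat_origin = _meiosis_origins(n_off, switch_probs, rng)
    pat_parent = sire_haps[sire_of]  # (n_off, 2, n_loci)
    cols = np.arange(n_loci)
    paternal = np.take_along_axis(pat_parent, pat_origin[:, None, :], axis=1)[:, 0, :]

    dam_hap_index = rng.integers(0, H, size=(n_off, 2))
    dam_parent = pool.haplotypes[dam_hap_index]
    mat_origin = _meiosis_origins(n_off, switch_probs, rng)
    maternal = np.take_along_axis(dam_parent, mat_origin[:, None, :], axis=1)[:, 0, :]

    snp_cols = pool.columns_of_kind("snp")
    ms_cols = pool.columns_of_kind("microsatellite")
    qtn_cols = pool.columns_of_kind("qtn")

    snp_dosage = (paternal[:, snp_cols] == 1).astype(float) + (
        maternal[:, snp_cols] == 1
    ).astype(float)
    ms_pairs = np.stack([paternal[:, ms_cols], maternal[:, ms_cols]], axis=2).astype(int)
    qtl_dosage = (paternal[:, qtn_cols] == 1).astype(float) + (
        maternal[:, qtn_cols] == 1
    ).astype(float)

    ids = [f"ind{c:05d}" for c in range(n_off)]
    table = GenotypeTable(
        individual_ids=ids,
        markers=pool.marker_map(),
        snp_dosage=snp_dosage,
        ms_pairs=ms_pairs,
        counted_allele={m: "1" for m in pool.marker_map().marker_ids},
    )
    truth = TruthRecord(
        qtl_specs=config.qtl_specs,
        qtl_dosage=qtl_dosage,
        sire_of=sire_of,
        sire_hap_index=sire_hap_index,
        paternal_origin=pat_origin,
        pool=pool,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def assign_phenotypes(
    genotypes: GenotypeTable,
    truth: TruthRecord,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Phenotype = intercept + fixed effects + QTL + polygene + residual.

    The polygenic value is a weighted sum of the genotyped SNP dosages with
    i.i.d. normal weights, rescaled so its sample variance matches the
    variance implied by ``polygenic_h2`` (interpreted as the polygenic
    share of the total phenotypic variance net of fixed effects). The
    planted QTL tag SNP get zero weight: the genetic effect of a QTL
    region is the QTN itself, and giving its perfect-LD tags additional
    causal weights would silently inflate the locus's allele-substitution
    effect beyond the planted value.
    """
    rng = np.random.default_rng(config.seed + 2 if rng is None else rng)
    n = genotypes.n_individuals
    fe = config.fixed_effects

    effects = np.array([q.effect_kg_per_allele for q in config.qtl_specs])
    qtl_value = truth.qtl_dosage @ effects
    v_qtl = float(np.var(qtl_value)) if len(effects) else 0.0
    v_e = config.residual_sd_kg**2
    ph2 = config.polygenic_h2
    if ph2 >= 1.0:
        raise ValueError("polygenic_h2 must be < 1")
    v_poly = ph2 * (v_qtl + v_e) / (1.0 - ph2)

    X = genotypes.snp_dosage
    if np.isnan(X).any():
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    weights = rng.normal(size=X.shape[1])
    snp_loci = truth.pool.loci.loc[truth.pool.loci["kind"] == "snp"]
    if "is_tag" in snp_loci.columns:
        weights[snp_loci["is_tag"].to_numpy(bool)] = 0.0
    g = (X - X.mean(axis=0)) @ weights
    sd = g.std()
    if v_poly > 0 and sd == 0:
        raise ValueError("cannot realize a polygenic background on monomorphic SNP")
    polygenic = g * (np.sqrt(v_poly) / sd) if v_poly > 0 else np.zeros(n)

    ages = rng.integers(fe.age_range_months[0], fe.age_range_months[1] + 1, size=n)
    years = rng.choice(list(fe.year_effects_kg), size=n)
    houses = rng.choice(list(fe.house_effects_kg), size=n)
    year_val = np.array([fe.year_effects_kg[y] for y in years])
    house_val = np.array([fe.house_effects_kg[h] for h in houses])
    residual = rng.normal(0.0, config.residual_sd_kg, size=n)

    y = (
        config.intercept_kg
        + fe.age_slope_kg_per_month * (ages - np.mean(ages))
        + year_val
        + house_val
        + qtl_value
        + polygenic
        + residual
    )
    truth.polygenic_value = polygenic
    total = v_qtl + float(np.var(polygenic)) + float(np.var(residual))
    truth.realized_variances = dict(
        qtl=v_qtl,
        polygenic=float(np.var(polygenic)),
        residual=float(np.var(residual)),
        total=total,
        h2_total=(v_qtl + float(np.var(polygenic))) / total if total > 0 else float("nan"),
    )
    pheno = pd.DataFrame(
        dict(
            individual_id=genotypes.individual_ids,
            trait=y,
            age=ages,
            slaughter_year=pd.Categorical([str(v) for v in years]),
            slaughterhouse=pd.Categorical([str(v) for v in houses]),
            sire_id=[f"sire{s:03d}" for s in truth.sire_of],
        )
    )
    truth.fixed_effect_draws = pheno[["individual_id", "age", "slaughter_year", "slaughterhouse"]]
    return pheno


def simulate_population(
    config: SimulationConfig,
) -> tuple[GenotypeTable, pd.DataFrame, TruthRecord]:
    """Build founders, gene-drop and assign phenotypes; fully seed-determined."""
    pool = build_founder_haplotypes(config)
    genotypes, truth = gene_drop_population(pool, config)
    phenotypes = assign_phenotypes(genotypes, truth, config)
    return genotypes, phenotypes, truth


# ---------------------------------------------------------------------------
# Extreme selection
# ---------------------------------------------------------------------------


def select_extremes(
    phenotypes: pd.DataFrame,
    fraction: float = 0.15,
    no_half_sib: bool = False,
) -> tuple[list[str], list[str]]:
    """Select the high and low phenotype tails.

    Tail size is ``floor(fraction * n)`` before half-sib exclusion. With
    ``no_half_sib``, each tail keeps at most one offspring per sire — the
    more extreme one — mirroring extreme-group designs that exclude
    half-sibs to avoid family confounding.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if no_half_sib and "sire_id" not in phenotypes.columns:
        raise ValueError("no_half_sib requires a sire_id column")
    n_tail = int(np.floor(fraction * len(phenotypes)))
    ordered = phenotypes.sort_values("trait", kind="mergesort")
    low = ordered.head(n_tail)
    high = ordered.tail(n_tail).iloc[::-1]

    def dedup(tail: pd.DataFrame) -> list[str]:
        if not no_half_sib:
            return tail["individual_id"].tolist()
        seen: set[str] = set()
        kept = []
        for _, row in tail.iterrows():  # rows ordered most-extreme first
            if row["sire_id"] in seen:
                continue
            seen.add(row["sire_id"])
            kept.append(row["individual_id"])
        return kept

    return dedup(high), dedup(low)


# ---------------------------------------------------------------------------
# Variant panel emission
# ---------------------------------------------------------------------------

_DECOY_KINDS = (
    "het_in_two_sires",
    "qhom_het",
    "q_equals_qhom",
    "missing_sire_call",
    "random",
)


def emit_variant_panel(
    config: SimulationConfig,
    n_consistent: int = 1,
    n_decoys_per_kind: int = 0,
    n_random: int = 0,
    rng: np.random.Generator | None = None,
    chromosome: str = "14",
    region_bp: tuple[int, int] = (22_800_000, 23_700_000),
) -> tuple[VariantPanel, IntervalSet, IntervalSet, dict[str, np.ndarray]]:
    """Emit a 7-animal resequencing panel plus annotations and depth tracks.

    The panel holds 3 QTL-segregating (heterozygous) sires, 3 Q-homozygous
    sires and one q-homozygous steer. ``n_consistent`` sites satisfy the
    segregation pattern by construction; decoys violate one named criterion
    each; ``n_random`` sites get uniformly random genotype classes. Returns
    (panel, coding intervals, conserved intervals, per-animal depth arrays
    over the target region).
    """
    rng = np.random.default_rng(config.seed + 3 if rng is None else rng)
    animals = [f"het_sire{i}" for i in range(3)] + [f"Qhom{i}" for i in range(3)] + ["qhom0"]
    roles = {a: ("het_sire" if a.startswith("het") else "Q_hom" if a.startswith("Q") else "q_hom")
             for a in animals}

    start, end = region_bp
    sites: list[dict] = []
    gts: list[list[str]] = []

    def consistent_row() -> list[str]:
        return ["het"] * 3 + ["hom_alt"] * 3 + ["hom_ref"]

    for _ in range(n_consistent):
        sites.append(_random_site(rng, chromosome, start, end))
        gts.append(consistent_row())
    for kind in _DECOY_KINDS[:-1]:
        for _ in range(n_decoys_per_kind):
            row = consistent_row()
            if kind == "het_in_two_sires":
                row[rng.integers(0, 3)] = "hom_ref"
            elif kind == "qhom_het":
                row[3 + rng.integers(0, 3)] = "het"
            elif kind == "q_equals_qhom":
                row[6] = "hom_alt"
            elif kind == "missing_sire_call":
                row[rng.integers(0, 3)] = "missing"
            sites.append(_random_site(rng, chromosome, start, end))
            gts.append(row)
    for _ in range(n_random):
        sites.append(_random_site(rng, chromosome, start, end))
        gts.append(list(rng.choice(["hom_ref", "het", "hom_alt", "missing"], size=7)))

    frame = (
        pd.DataFrame(sites)
        .sort_values("position", kind="mergesort")
        .reset_index(drop=True)
    )
    order = np.argsort([s["position"] for s in sites], kind="stable")
    genotypes = np.array(gts, dtype=object)[order] if gts else np.empty((0, 7), object)
    panel = VariantPanel(sites=frame, animal_ids=animals, genotypes=genotypes, roles=roles)

    # annotations: a few coding exons and conserved elements inside the region
    span = end - start
    coding = IntervalSet(
        pd.DataFrame(
            dict(
                chromosome=[chromosome] * 3,
                start=[start + span // 10, start + span // 2, start + 8 * span // 10],
                end=[start + span // 10 + 2000, start + span // 2 + 1500, start + 8 * span // 10 + 800],
                label=["exon1", "exon2", "exon3"],
            )
        )
    )
    conserved = IntervalSet(
        pd.DataFrame(
            dict(
                chromosome=[chromosome] * 2,
                start=[start + span // 4, start + 3 * span // 4],
                end=[start + span // 4 + 500, start + 3 * span // 4 + 700],
                label=["cons1", "cons2"],
            )
        )
    )
    depth = {
        a: {chromosome: (start, rng.poisson(lam=float(rng.uniform(26, 59)), size=span).astype(int))}
        for a in animals
    }
    return panel, coding, conserved, depth


def _random_site(rng: np.random.Generator, chrom: str, start: int, end: int) -> dict:
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    if rng.random() < 0.07:  # occasional simple indel
        alt = ref + "".join(rng.choice(list("ACGT"), size=2))
    return dict(
        chromosome=chrom,
        position=int(rng.integers(start + 1, end + 1)),
        ref=str(ref),
        alt=str(alt),
        type="snp" if len(alt) == 1 else "indel",
    )


# ---------------------------------------------------------------------------
# Light-weight generators for focused tests
# ---------------------------------------------------------------------------


def simulate_unstructured(
    n_individuals: int,
    n_markers: int,
    seed: int,
    polygenic_h2: float = 0.3,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Unrelated individuals, unlinked SNP, polygenic-only phenotype.

    Returns (dosage matrix, phenotype). Every marker carries an i.i.d.
    small additive effect scaled so the realized polygenic share of the
    phenotypic variance equals ``polygenic_h2``; no major QTL exist, so a
    calibrated association scan should behave like a null.
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_markers)
    X = rng.binomial(2, maf, size=(n_individuals, n_markers)).astype(float)
    g = (X - X.mean(axis=0)) @ rng.normal(size=n_markers)
    if polygenic_h2 > 0:
        g *= np.sqrt(polygenic_h2) / g.std()
        e = rng.normal(0.0, np.sqrt(1.0 - polygenic_h2), size=n_individuals)
    else:
        g = np.zeros(n_individuals)
        e = rng.normal(size=n_individuals)
    return X, g + e


def simulate_halfsib_family(
    seed: int,
    n_offspring: int,
    marker_pos_cM: Sequence[float],
    qtl_pos_cM: float | None = None,
    qtl_effect: float = 0.0,
    residual_sd: float = 1.0,
    informative_prob: float = 1.0,
) -> dict:
    """One sire family of multi-allelic markers for interval-mapping tests.

    The sire is heterozygous with private alleles (1/2) at every marker, so
    paternal transmission is deducible wherever the dam contributed a
    non-sire allele (probability ``informative_prob``; otherwise the dam
    donates the sire's other allele, making the marker ambiguous).
    Haplotype 0 is the Q haplotype. Phenotype = qtl_effect * [paternal
    origin at the QTL position is Q] + intercept + noise.
    """
    rng = np.random.default_rng(seed)
    pos = np.asarray(marker_pos_cM, float)
    loci = pd.DataFrame(dict(chromosome="1", position_cM=pos))
    switch = _interval_switch_probs(loci)
    origin = _meiosis_origins(n_offspring, switch, rng)  # 0 => Q haplotype

    sire_pairs = np.tile(np.array([1, 2]), (len(pos), 1))  # Q allele first
    paternal_allele = np.where(origin == 0, 1, 2)
    informative = rng.random((n_offspring, len(pos))) < informative_prob
    dam_allele = np.where(
        informative, 3 + rng.integers(0, 2, size=origin.shape), np.where(origin == 0, 2, 1)
    )
    offspring_pairs = np.stack([paternal_allele, dam_allele], axis=2)
    offspring_pairs = np.sort(offspring_pairs, axis=2)

    if qtl_pos_cM is not None and qtl_effect != 0.0:
        if qtl_pos_cM in pos:
            raise ValueError("qtl_pos_cM must fall strictly between markers")
        all_pos = np.sort(np.append(pos, qtl_pos_cM))
        qtl_idx = int(np.searchsorted(all_pos, qtl_pos_cM))
        loci_q = pd.DataFrame(dict(chromosome="1", position_cM=all_pos))
        # re-drop with the QTL locus included so origins stay consistent
        rng = np.random.default_rng(seed)
        switch_q = _interval_switch_probs(loci_q)
        origin_all = _meiosis_origins(n_offspring, switch_q, rng)
        marker_cols = np.array(
            [i for i in range(len(all_pos)) if i != qtl_idx], dtype=int
        )
        origin = origin_all[:, marker_cols]
        paternal_allele = np.where(origin == 0, 1, 2)
        rng2 = np.random.default_rng(seed + 1)
        informative = rng2.random((n_offspring, len(pos))) < informative_prob
        dam_allele = np.where(
            informative, 3 + rng2.integers(0, 2, size=origin.shape), np.where(origin == 0, 2, 1)
        )
        offspring_pairs = np.sort(np.stack([paternal_allele, dam_allele], axis=2), axis=2)
        q_state = origin_all[:, qtl_idx] == 0
    else:
        q_state = np.zeros(n_offspring, dtype=bool)

    rng_ph = np.random.default_rng(seed + 2)
    y = 10.0 + qtl_effect * q_state.astype(float) + rng_ph.normal(0, residual_sd, n_offspring)
    return dict(
        marker_pos_cM=pos,
        sire_pairs=sire_pairs,
        offspring_pairs=offspring_pairs,
        paternal_origin=origin,
        q_state=q_state,
        phenotype=y,
    )


def simulate_ld_mapping_groups(
    seed: int,
    n_heavy: int,
    n_light: int,
    n_markers: int,
    n_alleles: int = 4,
    shifted_marker: int | None = None,
    shift: float = 0.35,
) -> tuple[GenotypeTable, list[str], list[str]]:
    """Two phenotype groups of unphased microsatellite genotypes.

    All markers share allele frequencies between groups except
    ``shifted_marker`` (and its right neighbour), where the heavy group's
    first-allele frequency is raised by ``shift`` — a planted local signal
    for the sliding-window haplotype scan.
    """
    rng = np.random.default_rng(seed)
    alleles = 150 + 2 * np.arange(n_alleles)
    base = rng.dirichlet(np.ones(n_alleles) * 3.0, size=n_markers)
    freqs = {"heavy": base.copy(), "light": base.copy()}
    if shifted_marker is not None:
        for m in (shifted_marker, min(shifted_marker + 1, n_markers - 1)):
            f = freqs["heavy"][m].copy()
            f[0] = min(f[0] + shift, 0.95)
            freqs["heavy"][m] = f / f.sum()

    ids: list[str] = []
    groups = {"heavy": [], "light": []}
    pairs = []
    for grp, n in (("heavy", n_heavy), ("light", n_light)):
        for i in range(n):
            iid = f"{grp}{i:04d}"
            ids.append(iid)
            groups[grp].append(iid)
            geno = np.empty((n_markers, 2), dtype=int)
            for m in range(n_markers):
                geno[m] = alleles[rng.choice(n_alleles, size=2, p=freqs[grp][m])]
            pairs.append(np.sort(geno, axis=1))
    ms_pairs = np.stack(pairs)  # (n, n_markers, 2)
    markers = MarkerMap(
        pd.DataFrame(
            dict(
                marker_id=[f"ms{m:03d}" for m in range(n_markers)],
                chromosome="14",
                position_bp=np.arange(n_markers) * 100_000 + 22_800_001,
                position_cM=np.arange(n_markers) * 0.1,
                marker_type="microsatellite",
            )
        )
    )
    table = GenotypeTable(
        individual_ids=ids,
        markers=markers,
        snp_dosage=np.empty((len(ids), 0)),
        ms_pairs=ms_pairs,
    )
    return table, groups["heavy"], groups["light"]
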