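"""Allele-substitution-effect estimation and the end-to-end pipeline driver.

Effects are reported in kg per Q allele from the same GLS machinery as the
association scan, with the Q-allele (or Q-haplotype) dosage as the tested
column. The pipeline driver chains the stages — simulate, QC, kinship,
REML, GWAS, conditioned scan, half-sib scan, LD mapping, QTN filtering and
effect estimation — writing per-stage TSVs plus a machine-readable run
summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import halfsib_qtl, ld_mapping, mixed_gwas, qtn_filter, synthetic_data
from .io_formats import GenotypeTable, write_genotypes, write_phenotypes
from .mixed_gwas import (
    AssociationRecord,
    KinshipMatrix,
    VarianceComponents,
    bonferroni_threshold,
    build_covariate_matrix,
    gls_scan,
    ibs_kinship,
    lambda_gc,
    reml_fit,
    snp_qc,
    variance_explained_fraction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EffectEstimate",
    "PipelineConfig",
    "q_haplotype_dosage",
    "loco_kinship",
    "estimate_effect",
    "run_pipeline",
    "STAGES",
    "stage_closure",
]


# ---------------------------------------------------------------------------
# Q-haplotype dosage
# ---------------------------------------------------------------------------


def q_haplotype_dosage(
    genotypes: GenotypeTable,
    marker_a: str,
    marker_b: str,
    q_alleles: tuple[int, int],
) -> np.ndarray:
    """Per-individual count (0/1/2) of the two-marker Q haplotype.

    Phase-unambiguous individuals are counted directly. For double
    heterozygotes the most probable diplotype under the population EM
    haplotype frequencies decides the count, with ties broken toward the
    smaller (non-Q) dosage. Missing calls give nan.
    """
    pa = genotypes.pairs_of(marker_a) if marker_a in genotypes.ms_marker_ids else None
    if pa is None:
        pa = mixed_gwas._dosage_to_pairs(genotypes.dosage_of(marker_a))
        pb = mixed_gwas._dosage_to_pairs(genotypes.dosage_of(marker_b))
        # nan dosages became (0,0); re-mark them missing
        pa[np.isnan(genotypes.dosage_of(marker_a))] = -1
        pb[np.isnan(genotypes.dosage_of(marker_b))] = -1
    else:
        pb = genotypes.pairs_of(marker_b)
    qa, qb = q_alleles
    if qa not in set(pa.ravel()) or qb not in set(pb.ravel()):
        raise ValueError(f"Q haplotype alleles {q_alleles} absent from the data")
    freqs = ld_mapping.em_two_locus_single(pa, pb)
    freqs.pop("_loglik", None)

    n = len(pa)
    dosage = np.full(n, np.nan)
    for i in range(n):
        ga, gb = tuple(pa[i]), tuple(pb[i])
        if -1 in ga or -1 in gb:
            continue
        options = ld_mapping._diplotype_options(ga, gb)
        if len(options) == 1:
            d = options[0]
        else:
            probs = []
            for opt in options:
                h1, h2 = opt
                p = freqs.get(h1, 0.0) * freqs.get(h2, 0.0)
                probs.append(2.0 * p if h1 != h2 else p)
            counts = [sum(1 for h in opt if h == (qa, qb)) for opt in options]
            best = max(
                range(len(options)), key=lambda k: (probs[k], -counts[k])
            )  # tie -> smaller Q dosage
            d = options[best]
        dosage[i] = sum(1 for h in d if h == (qa, qb))
    return dosage


# ---------------------------------------------------------------------------
# Effect estimation
# ---------------------------------------------------------------------------


@dataclass
class EffectEstimate:
    locus: str
    effect_kg_per_allele: float
    standard_error: float
    p_value: float
    q_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_frequency <= 1.0:
            raise ValueError("q_frequency must be in [0,1]")


def loco_kinship(genotypes: GenotypeTable, chromosome: str) -> KinshipMatrix:
    """IBS kinship leaving out the markers on one chromosome.

    Used when estimating the effect of a locus on that chromosome: keeping
    the locus's own tag SNP inside the relatedness matrix lets the random
    effect absorb part of the QTL signal and shrinks the fixed-effect
    estimate (proximal contamination).
    """
    f = genotypes.markers.frame
    keep = f.loc[
        (f["marker_type"] == "snp") & (f["chromosome"] != chromosome), "marker_id"
    ].tolist()
    if not keep:
        raise ValueError(f"no markers left after excluding chromosome {chromosome!r}")
    return ibs_kinship(genotypes.subset_snps(keep))


def estimate_effect(
    phenotypes: pd.DataFrame | np.ndarray,
    covariates: np.ndarray,
    kinship: KinshipMatrix,
    vc: VarianceComponents,
    dosage: np.ndarray,
    locus: str = "locus",
) -> EffectEstimate:
    """Allele-substitution effect of a Q-dosage column via the GLS fit.

    This is exactly the association-scan test applied to one dosage
    vector, so the estimate agrees with ``gls_scan`` on the same column.
    """
    d = np.asarray(dosage, float)
    if np.nanstd(d) == 0:
        raise ValueError("constant dosage: effect not estimable")
    rec = gls_scan(
        phenotypes, covariates, kinship, d[:, None], vc, marker_ids=[locus]
    )[0]
    se = (
        abs(rec.beta) / np.sqrt(rec.f_stat)
        if rec.f_stat > 0
        else float("inf")
    )
    return EffectEstimate(
        locus=locus,
        effect_kg_per_allele=rec.beta,
        standard_error=float(se),
        p_value=rec.p_value,
        q_frequency=float(np.nanmean(d) / 2.0),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

STAGES = (
    "simulate",
    "qc",
    "kinship",
    "reml",
    "gwas",
    "condition",
    "halfsib-scan",
    "ldmap",
    "filter-qtn",
    "effects",
)

_STAGE_DEPS = {
    "simulate": (),
    "qc": ("simulate",),
    "kinship": ("qc",),
    "reml": ("kinship",),
    "gwas": ("reml",),
    "condition": ("gwas",),
    "halfsib-scan": (),
    "ldmap": (),
    "filter-qtn": (),
    "effects": ("reml",),
}


def stage_closure(stage: str) -> list[str]:
    """Dependency closure of one stage, in pipeline order."""
    needed: set[str] = set()

    def add(s: str) -> None:
        for d in _STAGE_DEPS[s]:
            add(d)
        needed.add(s)

    add(stage)
    return [s for s in STAGES if s in needed]


@dataclass
class PipelineConfig:
    """Run configuration; every stochastic stage derives its seed from ``seed``."""

    outdir: str = "cwqtl_run"
    seed: int = 0
    stages: tuple = STAGES
    sim: synthetic_data.SimulationConfig | None = None
    qc: mixed_gwas.QcThresholds = field(default_factory=mixed_gwas.QcThresholds)
    alpha: float = 0.05
    perm_alphas: tuple = (0.05, 0.01, 0.001)
    n_perm: int = 1000
    n_boot: int = 1000
    min_depth: int = 4
    n_panel_decoys_per_kind: int = 2
    n_panel_random: int = 50

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = synthetic_data.default_config(seed=self.seed)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(artifacts: dict, name: str, stage: str):
    if name not in artifacts:
        raise RuntimeError(
            f"stage {stage!r} requires artifact {name!r}; enable the stage that produces it"
        )
    return artifacts[name]


def _records_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            marker_id=[r.marker_id for r in records],
            beta=[r.beta for r in records],
            f_stat=[r.f_stat for r in records],
            p_value=[r.p_value for r in records],
            n_used=[r.n_used for r in records],
            flagged=[r.flagged for r in records],
        )
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the requested stages in order; returns the run directory.

    Per-stage TSVs, a JSON run summary (lambda_GC, h2 before/after
    conditioning, variance-explained fraction, Bonferroni threshold,
    effect estimates) and a structured log line per stage are written under
    ``config.outdir``. Identical config and seed give identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    try:
        version = metadata.version("cwqtl")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    log_lines = [f"run config_hash={cfg_hash} seed={config.seed} cwqtl={version}"]
    summary: dict = {"config_hash": cfg_hash, "seed": config.seed}
    artifacts: dict = {}
    stages = [s for s in STAGES if s in set(config.stages)]
    sim = config.sim

    for stage in stages:
        for dep in _STAGE_DEPS[stage]:
            if dep not in stages:
                raise RuntimeError(
                    f"stage {stage!r} depends on {dep!r}, which is not enabled"
                )

    if "simulate" in stages:
        genotypes, phenotypes, truth = synthetic_data.simulate_population(sim)
        artifacts.update(genotypes=genotypes, phenotypes=phenotypes, truth=truth)
        write_genotypes(genotypes, outdir / "genotypes.tsv")
        write_phenotypes(phenotypes, outdir / "phenotypes.tsv")
        log_lines.append(
            f"simulate n={genotypes.n_individuals} snp={len(genotypes.snp_marker_ids)} "
            f"seed={sim.seed}"
        )

    if "qc" in stages:
        genotypes = _require(artifacts, "genotypes", "qc")
        filtered, report = snp_qc(genotypes, config.qc)
        artifacts["qc_genotypes"] = filtered
        report.to_csv(outdir / "qc_exclusions.tsv", sep="\t", index=False)
        log_lines.append(
            f"qc kept={len(filtered.snp_marker_ids)} excluded={len(report)}"
        )

    if "kinship" in stages:
        filtered = _require(artifacts, "qc_genotypes", "kinship")
        kin = ibs_kinship(filtered)
        artifacts["kinship"] = kin
        pd.DataFrame(kin.values, index=kin.individual_ids, columns=kin.individual_ids).to_csv(
            outdir / "kinship.tsv", sep="\t"
        )
        log_lines.append(f"kinship scale={kin.scale_constant:.6g} ridge={kin.ridge:.3g}")

    if "reml" in stages:
        kin = _require(artifacts, "kinship", "reml")
        phenotypes = _require(artifacts, "phenotypes", "reml")
        X = build_covariate_matrix(phenotypes)
        vc = reml_fit(phenotypes, X, kin)
        artifacts.update(covariates=X, vc=vc)
        summary["h2_full"] = vc.h2
        summary["sigma_a2"] = vc.sigma_a2
        summary["sigma_e2"] = vc.sigma_e2
        log_lines.append(f"reml h2={vc.h2:.4f} delta={vc.delta:.4g}")

    if "gwas" in stages:
        records = gls_scan(
            artifacts["phenotypes"],
            _require(artifacts, "covariates", "gwas"),
            artifacts["kinship"],
            artifacts["qc_genotypes"],
            artifacts["vc"],
        )
        artifacts["gwas_records"] = records
        frame = _records_frame(records)
        frame.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
        thr = bonferroni_threshold(config.alpha, len(records))
        summary["bonferroni_threshold"] = thr
        summary["n_markers_tested"] = len(records)
        summary["lambda_gc"] = lambda_gc(records) if len(records) >= 100 else None
        log_lines.append(
            f"gwas markers={len(records)} lambda_gc={summary['lambda_gc']}"
        )

    if "condition" in stages:
        records = _require(artifacts, "gwas_records", "condition")
        frame = _records_frame(records)
        thr = summary["bonferroni_threshold"]
        genotypes = artifacts["qc_genotypes"]
        chrom_of = dict(
            zip(
                genotypes.markers.frame["marker_id"],
                genotypes.markers.frame["chromosome"],
            )
        )
        frame = frame.assign(chromosome=[chrom_of[m] for m in frame["marker_id"]])
        sig = frame.loc[frame["p_value"] < thr]
        top_markers = (
            sig.sort_values("p_value", kind="mergesort").groupby("chromosome").head(1)
        )["marker_id"].tolist()
        artifacts["top_markers"] = sorted(top_markers)
        cond_records = gls_scan(
            artifacts["phenotypes"],
            artifacts["covariates"],
            artifacts["kinship"],
            genotypes,
            artifacts["vc"],
            conditioning_markers=artifacts["top_markers"],
        )
        artifacts["conditioned_records"] = cond_records
        _records_frame(cond_records).to_csv(
            outdir / "gwas_conditioned.tsv", sep="\t", index=False
        )
        summary["conditioning_markers"] = artifacts["top_markers"]
        log_lines.append(f"condition on={artifacts['top_markers']}")

    if "halfsib-scan" in stages:
        fam = synthetic_data.simulate_halfsib_family(
            seed=config.seed + 11,
            n_offspring=300,
            marker_pos_cM=np.arange(0.0, 101.0, 10.0),
            qtl_pos_cM=45.0,
            qtl_effect=0.8,
            residual_sd=1.0,
        )
        phase = halfsib_qtl.SirePhase(
            sire_id="sire0",
            marker_ids=[f"ms{j}" for j in range(len(fam["marker_pos_cM"]))],
            positions_cM=fam["marker_pos_cM"],
            haplotypes=fam["sire_pairs"].T,
        )
        grid = halfsib_qtl.prob_q_grid(phase, fam["offspring_pairs"])
        profile = halfsib_qtl.regression_scan(fam["phenotype"], None, grid)
        alphas = [a for a in config.perm_alphas if a >= 1.0 / config.n_perm]
        profile.thresholds = halfsib_qtl.permutation_threshold(
            fam["phenotype"], None, grid, n_perm=config.n_perm,
            alphas=alphas, seed=config.seed + 12,
        )
        profile.ci_regions, _ = halfsib_qtl.bootstrap_ci(
            fam["phenotype"], None, grid, n_boot=config.n_boot, seed=config.seed + 13
        )
        artifacts["halfsib_profile"] = profile
        pd.DataFrame(
            dict(position_cM=profile.positions_cM, f_stat=profile.f_stats)
        ).to_csv(outdir / "halfsib_scan.tsv", sep="\t", index=False)
        summary["halfsib_peak_cM"] = profile.peak_position
        summary["halfsib_thresholds"] = {
            str(a): t for a, t in profile.thresholds.items()
        }
        summary["halfsib_ci_regions"] = profile.ci_regions
        log_lines.append(
            f"halfsib-scan peak={profile.peak_position} ci={profile.ci_regions}"
        )

    if "ldmap" in stages:
        table, heavy, light = synthetic_data.simulate_ld_mapping_groups(
            seed=config.seed + 21,
            n_heavy=142,
            n_light=145,
            n_markers=8,
            shifted_marker=3,
        )
        results = ld_mapping.scan_windows(
            table, heavy, light, mc_seed=config.seed + 22
        )
        artifacts["ldmap_results"] = results
        pd.DataFrame(
            dict(
                marker_a=[r.marker_a for r in results],
                marker_b=[r.marker_b for r in results],
                p_overall=[r.p_overall for r in results],
            )
        ).to_csv(outdir / "ld_mapping.tsv", sep="\t", index=False)
        best = min(results, key=lambda r: r.p_overall)
        summary["ldmap_best_window"] = [best.marker_a, best.marker_b]
        summary["ldmap_best_p"] = best.p_overall
        log_lines.append(f"ldmap best={summary['ldmap_best_window']} p={best.p_overall:.3g}")

    if "filter-qtn" in stages:
        panel, coding, conserved, depth = synthetic_data.emit_variant_panel(
            sim,
            n_consistent=1,
            n_decoys_per_kind=config.n_panel_decoys_per_kind,
            n_random=config.n_panel_random,
        )
        candidates = qtn_filter.segregation_filter(panel)
        qtn_filter.annotate_candidates(candidates, coding, conserved)
        audit = qtn_filter.coverage_audit(depth, coding, min_depth=config.min_depth)
        artifacts.update(panel=panel, candidates=candidates, coverage=audit)
        pd.DataFrame(
            dict(
                chromosome=[c.chromosome for c in candidates],
                position=[c.position for c in candidates],
                type=[c.variant_type for c in candidates],
                passed=[c.passed for c in candidates],
                failing=[",".join(map(str, sorted(c.failing_criteria))) for c in candidates],
                annotations=[",".join(sorted(c.annotations)) for c in candidates],
            )
        ).to_csv(outdir / "candidate_qtn.tsv", sep="\t", index=False)
        summary["n_candidate_qtn"] = sum(c.passed for c in candidates)
        log_lines.append(f"filter-qtn survivors={summary['n_candidate_qtn']}")

    if "effects" in stages:
        truth = _require(artifacts, "truth", "effects")
        kin = artifacts["kinship"]
        X = artifacts["covariates"]
        vc = artifacts["vc"]
        phenotypes = artifacts["phenotypes"]
        estimates = []
        for qi, q in enumerate(truth.qtl_specs):
            est = estimate_effect(
                phenotypes, X, kin, vc, truth.qtl_dosage[:, qi], locus=f"qtn_{qi}"
            )
            estimates.append(est)
        artifacts["effect_estimates"] = estimates
        pd.DataFrame(
            dict(
                locus=[e.locus for e in estimates],
                effect_kg_per_allele=[e.effect_kg_per_allele for e in estimates],
                standard_error=[e.standard_error for e in estimates],
                p_value=[e.p_value for e in estimates],
                q_frequency=[e.q_frequency for e in estimates],
            )
        ).to_csv(outdir / "effects.tsv", sep="\t", index=False)
        Xc = np.column_stack([X, truth.qtl_dosage])
        vc_cond = reml_fit(phenotypes, Xc, kin)
        summary["h2_conditioned"] = vc_cond.h2
        h2_full = summary.get("h2_full", vc.h2)
        summary["variance_explained_fraction"] = variance_explained_fraction(
            h2_full, min(vc_cond.h2, h2_full)
        )
        summary["effects"] = {
            e.locus: dict(
                effect_kg=e.effect_kg_per_allele,
                se=e.standard_error,
                p=e.p_value,
                q_freq=e.q_frequency,
            )
            for e in estimates
        }
        log_lines.append(
            f"effects h2_cond={vc_cond.h2:.4f} "
            f"fraction={summary['variance_explained_fraction']:.4f}"
        )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(asdict(config), default=str)), fh)
    return outdir
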