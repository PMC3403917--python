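"""Readers, writers and the canonical in-memory tables shared by the pipeline.

Conventions
-----------
* VCF and MAP positions are 1-based; BED intervals are 0-based half-open.
* SNP genotypes are stored as counted-allele dosages in {0, 1, 2} with
  ``nan`` marking missing calls.
* Microsatellite genotypes are unordered pairs of integer allele labels
  (fragment lengths); pairs are stored sorted so storage order carries no
  meaning, with ``-1`` as the reserved missing label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MISSING_ALLELE = -1

__all__ = [
    "MISSING_ALLELE",
    "MarkerMap",
    "GenotypeTable",
    "IntervalSet",
    "VariantPanel",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "read_variant_panel",
    "read_intervals",
    "write_intervals",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Genetic/physical map of markers.

    The underlying frame has columns ``marker_id``, ``chromosome``,
    ``position_bp`` (1-based), ``position_cM`` (optional, may be NaN) and
    ``marker_type`` in ``{"snp", "microsatellite"}``. Records are sorted by
    (chromosome, position_bp).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position_bp", "marker_type"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"marker map missing columns: {sorted(missing)}")
        if "position_cM" not in self.frame.columns:
            self.frame = self.frame.assign(position_cM=np.nan)
        f = self.frame
        if f["marker_id"].duplicated().any():
            dup = f.loc[f["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise FormatError(f"duplicate marker id: {dup!r}")
        if (f["position_bp"] < 1).any():
            raise FormatError("position_bp must be >= 1")
        bad = set(f["marker_type"]) - {"snp", "microsatellite"}
        if bad:
            raise FormatError(f"unknown marker_type values: {sorted(bad)}")
        self.frame = (
            f.sort_values(["chromosome", "position_bp"], kind="mergesort")
            .reset_index(drop=True)
        )
        for _, sub in self.frame.groupby("chromosome", sort=False):
            cm = sub["position_cM"].to_numpy(float)
            cm = cm[~np.isnan(cm)]
            if cm.size and np.any(np.diff(cm) < 0):
                raise FormatError("position_cM must be non-decreasing within a chromosome")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def marker_ids(self) -> list[str]:
        return self.frame["marker_id"].tolist()

    def index_of(self, marker_id: str) -> int:
        idx = self.frame.index[self.frame["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(marker_id)
        return int(idx[0])


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Individuals x markers genotype calls.

    ``snp_dosage`` has one column per SNP marker (in map order among SNPs)
    holding counted-allele dosages; ``ms_pairs`` has shape
    (n_individuals, n_microsat, 2) of sorted allele labels with
    :data:`MISSING_ALLELE` for missing. ``counted_allele`` names, per SNP
    marker, the allele whose copies the dosage counts.
    """

    individual_ids: list[str]
    markers: MarkerMap
    snp_dosage: np.ndarray
    ms_pairs: np.ndarray
    counted_allele: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        if len(set(self.individual_ids)) != n:
            raise FormatError("duplicate individual ids")
        snp_ids = self.snp_marker_ids
        ms_ids = self.ms_marker_ids
        self.snp_dosage = np.asarray(self.snp_dosage, dtype=float).reshape(n, len(snp_ids))
        self.ms_pairs = np.asarray(self.ms_pairs, dtype=int).reshape(n, len(ms_ids), 2)
        d = self.snp_dosage
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            raise FormatError("SNP dosages must be 0/1/2 or missing")
        # enforce unorderedness of microsatellite pairs
        self.ms_pairs = np.sort(self.ms_pairs, axis=2)
        half_missing = (self.ms_pairs == MISSING_ALLELE).sum(axis=2) == 1
        if half_missing.any():
            raise FormatError("microsatellite pairs must be fully called or fully missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def snp_marker_ids(self) -> list[str]:
        f = self.markers.frame
        return f.loc[f["marker_type"] == "snp", "marker_id"].tolist()

    @property
    def ms_marker_ids(self) -> list[str]:
        f = self.markers.frame
        return f.loc[f["marker_type"] == "microsatellite", "marker_id"].tolist()

    def dosage_of(self, marker_id: str) -> np.ndarray:
        """Dosage column for one SNP marker (copy)."""
        return self.snp_dosage[:, self.snp_marker_ids.index(marker_id)].copy()

    def pairs_of(self, marker_id: str) -> np.ndarray:
        """(n, 2) allele-pair array for one microsatellite marker (copy)."""
        return self.ms_pairs[:, self.ms_marker_ids.index(marker_id), :].copy()

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeTable":
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        idx = [pos[i] for i in ids]
        return GenotypeTable(
            individual_ids=list(ids),
            markers=self.markers,
            snp_dosage=self.snp_dosage[idx],
            ms_pairs=self.ms_pairs[idx],
            counted_allele=dict(self.counted_allele),
        )

    def subset_snps(self, marker_ids: Sequence[str]) -> "GenotypeTable":
        keep = set(marker_ids)
        snp_ids = self.snp_marker_ids
        cols = [j for j, mid in enumerate(snp_ids) if mid in keep]
        f = self.markers.frame
        keep_rows = f["marker_id"].isin(keep) | (f["marker_type"] == "microsatellite")
        return GenotypeTable(
            individual_ids=list(self.individual_ids),
            markers=MarkerMap(f.loc[keep_rows].reset_index(drop=True)),
            snp_dosage=self.snp_dosage[:, cols],
            ms_pairs=self.ms_pairs,
            counted_allele={m: a for m, a in self.counted_allele.items() if m in keep},
        )


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------


def _read_map_file(path: Path) -> MarkerMap:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: MAP line needs 4 fields")
            chrom, mid, cm, bp = parts[:4]
            try:
                rows.append(
                    dict(
                        marker_id=mid,
                        chromosome=chrom,
                        position_cM=float(cm),
                        position_bp=int(bp),
                        marker_type="snp",
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return MarkerMap(pd.DataFrame(rows))


def read_genotypes(path: str | Path, dialect: str = "tsv") -> GenotypeTable:
    """Read genotypes from ``ped_map`` or ``tsv`` dialect.

    ``ped_map``: PLINK text PED at *path* with a companion ``.map`` file.
    Allele codes are arbitrary strings; ``0`` means missing. The counted
    allele per marker is the alphabetically-first observed allele and is
    logged.

    ``tsv``: a matrix file, first column ``individual_id`` then one column
    per marker holding dosages 0/1/2 or ``NA``, with a companion
    ``<path>.markers.tsv`` marker map.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    if dialect == "ped_map":
        return _read_genotypes_ped(path)
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _read_genotypes_tsv(path: Path) -> GenotypeTable:
    map_path = path.with_suffix(path.suffix + ".markers.tsv")
    mm_frame = pd.read_csv(map_path, sep="\t", dtype={"chromosome": str, "marker_id": str})
    markers = MarkerMap(mm_frame)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"individual_id": str}, na_values=["NA"])
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed TSV: {exc}") from exc
    if "individual_id" not in df.columns:
        raise FormatError(f"{path}: missing 'individual_id' column")
    snp_ids = markers.frame.loc[markers.frame["marker_type"] == "snp", "marker_id"]
    for mid in snp_ids:
        if mid not in df.columns:
            raise FormatError(f"{path}: missing genotype column for marker {mid!r}")
    dosage = df[list(snp_ids)].to_numpy(float)
    bad = ~(np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: line {i + 2}: invalid dosage {dosage[i, j]!r} for marker "
            f"{snp_ids.iloc[j]!r}"
        )
    n = len(df)
    return GenotypeTable(
        individual_ids=df["individual_id"].tolist(),
        markers=markers,
        snp_dosage=dosage,
        ms_pairs=np.empty((n, 0, 2), dtype=int),
    )


def _read_genotypes_ped(path: Path) -> GenotypeTable:
    markers = _read_map_file(path.with_suffix(".map"))
    m = len(markers)
    ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            ids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(ids), m, 2)
    dosage = np.full((len(ids), m), np.nan)
    counted: dict[str, str] = {}
    for j, mid in enumerate(markers.marker_ids):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise FormatError(f"marker {mid!r}: more than two alleles in PED")
        counted_allele = observed[0] if observed else "0"
        counted[mid] = counted_allele
        logger.debug("marker %s: counted allele %s", mid, counted_allele)
        called = (col != "0").all(axis=1)
        dosage[called, j] = (col[called] == counted_allele).sum(axis=1)
    return GenotypeTable(
        individual_ids=ids,
        markers=markers,
        snp_dosage=dosage,
        ms_pairs=np.empty((len(ids), 0, 2), dtype=int),
        counted_allele=counted,
    )


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write the SNP portion of a table in the TSV dialect (plus marker map)."""
    path = Path(path)
    snp_ids = table.snp_marker_ids
    df = pd.DataFrame(table.snp_dosage, columns=snp_ids)
    df.insert(0, "individual_id", table.individual_ids)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = [str(row["individual_id"])]
            for mid in snp_ids:
                v = row[mid]
                cells.append("NA" if pd.isna(v) else str(int(v)))
            fh.write("\t".join(cells) + "\n")
    f = table.markers.frame
    f.loc[f["marker_type"] == "snp"].to_csv(
        path.with_suffix(path.suffix + ".markers.tsv"), sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

REQUIRED_PHENO_COLUMNS = ("individual_id", "trait", "age", "slaughter_year", "slaughterhouse")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype/covariate TSV.

    Required columns: ``individual_id``, ``trait`` (carcass weight, kg),
    ``age``, ``slaughter_year``, ``slaughterhouse``; optional ``sire_id``.
    Year and slaughterhouse are categorical (a year "2003" is the level
    "2003", never the number). Rows with a missing trait are dropped and the
    count logged.
    """
    df = pd.read_csv(
        str(path),
        sep="\t",
        dtype={
            "individual_id": str,
            "slaughter_year": str,
            "slaughterhouse": str,
            "sire_id": str,
        },
    )
    for col in REQUIRED_PHENO_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    n0 = len(df)
    df = df.dropna(subset=["trait"]).reset_index(drop=True)
    if len(df) < n0:
        logger.info("read_phenotypes: excluded %d rows with missing trait", n0 - len(df))
    df["trait"] = df["trait"].astype(float)
    df["age"] = df["age"].astype(int)
    df["slaughter_year"] = pd.Categorical(df["slaughter_year"])
    df["slaughterhouse"] = pd.Categorical(df["slaughterhouse"])
    if not np.isfinite(df["trait"]).all():
        raise FormatError(f"{path}: non-finite trait value")
    if df["individual_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate individual_id")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in df.columns]
    df.to_csv(str(path), sep="\t", index=False, columns=cols)


# ---------------------------------------------------------------------------
# Intervals (BED)
# ---------------------------------------------------------------------------


@dataclass
class IntervalSet:
    """Sorted 0-based half-open genomic intervals with labels."""

    frame: pd.DataFrame  # columns chromosome, start, end, label

    def __post_init__(self) -> None:
        f = self.frame
        required = {"chromosome", "start", "end"}
        if required - set(f.columns):
            raise FormatError("interval set needs chromosome/start/end columns")
        if "label" not in f.columns:
            f = f.assign(label="")
        if (f["start"] >= f["end"]).any():
            bad = f.loc[f["start"] >= f["end"]].iloc[0]
            raise FormatError(
                f"interval start >= end: {bad['chromosome']}:{bad['start']}-{bad['end']}"
            )
        self.frame = f.sort_values(["chromosome", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.frame)

    def chromosomes(self) -> set[str]:
        return set(self.frame["chromosome"])

    def contains(self, chromosome: str, position_1based: int) -> bool:
        """True if the 1-based position falls in any interval (BED convention)."""
        p = position_1based - 1
        f = self.frame
        sub = f.loc[f["chromosome"] == chromosome]
        return bool(((sub["start"] <= p) & (p < sub["end"])).any())

    def contains_many(self, chromosomes: Sequence[str], positions_1based: Sequence[int]) -> np.ndarray:
        return np.array(
            [self.contains(c, p) for c, p in zip(chromosomes, positions_1based)], dtype=bool
        )


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet` (sorted on read)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            rows.append(
                dict(
                    chromosome=parts[0],
                    start=start,
                    end=end,
                    label=parts[3] if len(parts) > 3 else "",
                )
            )
    return IntervalSet(pd.DataFrame(rows, columns=["chromosome", "start", "end", "label"]))


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    intervals.frame.to_csv(str(path), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Variant panel (VCF)
# ---------------------------------------------------------------------------

GT_CLASSES = ("hom_ref", "het", "hom_alt", "missing")


@dataclass
class VariantPanel:
    """Variant calls across the resequencing panel.

    ``sites`` has columns ``chromosome, position, ref, alt, type`` (position
    1-based, type in {snp, indel}); ``genotypes`` is an (n_sites, n_animals)
    array of strings from :data:`GT_CLASSES`; ``roles`` maps each animal id
    to ``het_sire``, ``Q_hom`` or ``q_hom``.
    """

    sites: pd.DataFrame
    animal_ids: list[str]
    genotypes: np.ndarray
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=object).reshape(
            len(self.sites), len(self.animal_ids)
        )
        bad = set(self.genotypes.ravel()) - set(GT_CLASSES)
        if bad:
            raise FormatError(f"unknown genotype classes: {sorted(bad)}")
        if self.roles:
            self.validate_roles()

    def validate_roles(self) -> None:
        counts = pd.Series(list(self.roles.values())).value_counts().to_dict()
        expected = {"het_sire": 3, "Q_hom": 3, "q_hom": 1}
        if counts != expected:
            raise FormatError(f"panel roles must be {expected}, got {counts}")
        unknown = set(self.roles) - set(self.animal_ids)
        if unknown:
            raise FormatError(f"roles assigned to unknown animals: {sorted(unknown)}")

    def animals_with_role(self, role: str) -> list[str]:
        return [a for a in self.animal_ids if self.roles.get(a) == role]


def _classify_gt(sample) -> str:
    alleles = sample.get("GT", (None,))
    if alleles is None or any(a is None for a in alleles):
        return "missing"
    s = set(alleles)
    if s == {0}:
        return "hom_ref"
    if 0 in s:
        return "het"
    if len(s) == 1:
        return "hom_alt"
    return "het"


def read_variant_panel(
    path: str | Path,
    roles: dict[str, str] | None = None,
) -> VariantPanel:
    """Read a GT-only VCF into a :class:`VariantPanel`.

    Multi-allelic records are rejected: the segregation filter reasons about
    exactly two alleles per site and silently splitting records invites
    allele-index bugs. Split such records upstream (e.g. ``bcftools norm``)
    if they are genuinely biallelic per sample.
    """
    vf = pysam.VariantFile(str(path))
    animal_ids = list(vf.header.samples)
    if roles:
        absent = set(roles) - set(animal_ids)
        if absent:
            raise FormatError(f"samples missing from VCF header: {sorted(absent)}")
    rows = []
    gts = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(
                f"{path}: multi-allelic or ALT-less record at {rec.chrom}:{rec.pos}; "
                "split multi-allelic sites upstream"
            )
        alt = rec.alts[0]
        vtype = "snp" if len(rec.ref) == 1 and len(alt) == 1 else "indel"
        rows.append(
            dict(chromosome=rec.chrom, position=rec.pos, ref=rec.ref, alt=alt, type=vtype)
        )
        gts.append([_classify_gt(rec.samples[a]) for a in animal_ids])
    sites = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt", "type"])
    return VariantPanel(
        sites=sites,
        animal_ids=animal_ids,
        genotypes=np.array(gts, dtype=object) if gts else np.empty((0, len(animal_ids)), object),
        roles=roles or {},
    )


_GT_TO_VCF = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_variant_panel(panel: VariantPanel, path: str | Path) -> None:
    """Write a panel as a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(panel.sites["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.animal_ids)
            + "\n"
        )
        for i, row in panel.sites.iterrows():
            gt = "\t".join(_GT_TO_VCF[g] for g in panel.genotypes[i])
            fh.write(
                f"{row['chromosome']}\t{row['position']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT\t{gt}\n"
            )
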