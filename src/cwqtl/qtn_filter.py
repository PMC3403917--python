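"""Segregation-consistency filtering of a 7-animal resequencing panel.

A candidate causative variant (QTN) for a QTL segregating in three sires
must be (1) heterozygous in all three segregating sires, (2) homozygous in
the three Q-homozygous animals and the q-homozygous animal, and (3) carry
opposite alleles between the Q- and q-homozygous animals. Survivors are
annotated against coding and conserved interval sets, and sequencing depth
over the target region is audited for low-coverage gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import IntervalSet, VariantPanel

__all__ = [
    "CandidateQtn",
    "CoverageAudit",
    "segregation_filter",
    "annotate_candidates",
    "coverage_audit",
]

# depth track type: {animal: {chromosome: (start_0based, depth_array)}}
DepthTrack = dict


@dataclass
class CandidateQtn:
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    variant_type: str
    passed: bool
    failing_criteria: frozenset
    annotations: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.passed != (len(self.failing_criteria) == 0):
            raise ValueError("passed must equal failing_criteria being empty")


_HOM = {"hom_ref", "hom_alt"}


def segregation_filter(panel: VariantPanel) -> list[CandidateQtn]:
    """Apply the three segregation-consistency criteria to every site.

    A missing call fails the criterion that needs it (conservative).
    Criterion 2 additionally requires the three Q-homozygotes to share one
    common homozygous genotype, without which criterion 3's "opposite
    alleles" is not well defined; when criterion 2 fails, criterion 3 is
    recorded as failing only if it is determinable and violated.
    """
    panel.validate_roles()
    het_idx = [panel.animal_ids.index(a) for a in panel.animals_with_role("het_sire")]
    qhom_idx = [panel.animal_ids.index(a) for a in panel.animals_with_role("Q_hom")]
    lhom_idx = panel.animal_ids.index(panel.animals_with_role("q_hom")[0])

    out: list[CandidateQtn] = []
    for i, row in panel.sites.iterrows():
        g = panel.genotypes[i]
        failing = set()
        if not all(g[j] == "het" for j in het_idx):
            failing.add(1)
        q_calls = [g[j] for j in qhom_idx]
        l_call = g[lhom_idx]
        q_shared = (
            all(c in _HOM for c in q_calls) and len(set(q_calls)) == 1
        )
        if not (q_shared and l_call in _HOM):
            failing.add(2)
        if q_shared and l_call in _HOM and l_call == q_calls[0]:
            failing.add(3)
        out.append(
            CandidateQtn(
                chromosome=row["chromosome"],
                position=int(row["position"]),
                ref=row["ref"],
                alt=row["alt"],
                variant_type=row["type"],
                passed=not failing,
                failing_criteria=frozenset(failing),
            )
        )
    return out


def annotate_candidates(
    candidates: list[CandidateQtn],
    coding: IntervalSet,
    conserved: IntervalSet,
    effect_table: dict[tuple[str, int], str] | None = None,
) -> list[CandidateQtn]:
    """Flag candidates intersecting coding or conserved intervals (in place).

    Positions are 1-based and interval sets 0-based half-open, so a variant
    at position p lies in [p-1, p). ``effect_table`` optionally maps
    (chromosome, position) to "synonymous"/"nonsynonymous"; nonsynonymous
    exonic variants gain a ``nonsynonymous`` flag. Variants on chromosomes
    absent from both interval sets are an error.
    """
    known = coding.chromosomes() | conserved.chromosomes()
    unmatched = sorted({c.chromosome for c in candidates} - known)
    if unmatched:
        raise ValueError(f"variant chromosomes absent from interval sets: {unmatched}")
    for c in candidates:
        if coding.contains(c.chromosome, c.position):
            c.annotations.add("exonic")
            effect = (effect_table or {}).get((c.chromosome, c.position))
            if effect == "nonsynonymous":
                c.annotations.add("nonsynonymous")
        if conserved.contains(c.chromosome, c.position):
            c.annotations.add("conserved")
    return candidates


@dataclass
class CoverageAudit:
    """Low-coverage subintervals and mean depths over the target intervals."""

    low_coverage: pd.DataFrame  # animal, chromosome, start, end, target_label
    mean_depth: pd.DataFrame  # animal, chromosome, target_start, target_end, mean

    def low_regions(self, animal: str) -> list[tuple[str, int, int]]:
        sub = self.low_coverage.loc[self.low_coverage["animal"] == animal]
        return [
            (r["chromosome"], int(r["start"]), int(r["end"]))
            for _, r in sub.iterrows()
        ]


def _runs_below(depth: np.ndarray, threshold: int) -> list[tuple[int, int]]:
    low = depth < threshold
    if not low.any():
        return []
    diff = np.diff(low.astype(int))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if low[0]:
        starts = np.insert(starts, 0, 0)
    if low[-1]:
        ends = np.append(ends, len(low))
    return list(zip(starts.tolist(), ends.tolist()))


def coverage_audit(
    depth: DepthTrack,
    targets: IntervalSet,
    min_depth: int = 4,
) -> CoverageAudit:
    """Per-animal audit of sequencing depth over the target intervals.

    ``depth`` maps animal -> chromosome -> (track_start, per-base depth
    array) in 0-based coordinates. For each animal and target interval the
    maximal subintervals with depth < ``min_depth`` are reported along with
    the mean depth; bases outside the provided track count as depth 0.
    """
    low_rows, mean_rows = [], []
    for animal, tracks in depth.items():
        for _, t in targets.frame.iterrows():
            chrom, t0, t1 = t["chromosome"], int(t["start"]), int(t["end"])
            track_start, arr = tracks.get(chrom, (0, np.zeros(0, dtype=int)))
            span = np.zeros(t1 - t0, dtype=int)
            lo = max(t0, track_start)
            hi = min(t1, track_start + len(arr))
            if hi > lo:
                span[lo - t0 : hi - t0] = arr[lo - track_start : hi - track_start]
            mean_rows.append(
                dict(
                    animal=animal,
                    chromosome=chrom,
                    target_start=t0,
                    target_end=t1,
                    mean=float(span.mean()) if len(span) else 0.0,
                )
            )
            for s, e in _runs_below(span, min_depth):
                low_rows.append(
                    dict(
                        animal=animal,
                        chromosome=chrom,
                        start=t0 + s,
                        end=t0 + e,
                        target_label=t["label"],
                    )
                )
    return CoverageAudit(
        low_coverage=pd.DataFrame(
            low_rows, columns=["animal", "chromosome", "start", "end", "target_label"]
        ),
        mean_depth=pd.DataFrame(
            mean_rows,
            columns=["animal", "chromosome", "target_start", "target_end", "mean"],
        ),
    )
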