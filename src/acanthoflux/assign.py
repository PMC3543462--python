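"""Taxonomic assignment by nearest-neighbor global alignment.

Each QC-passed read is aligned end-to-end against every reference; its
nearest neighbor is the reference with maximal percent identity (compared
as exact rationals).  A unique maximum transfers that reference's full
lineage; tied maxima transfer the last common ancestor of the tied
lineages.  Reads whose best identity is not strictly above the identity
threshold (default 85%) are left unassigned.  A second, stricter screen
(default 97%) selects reads closely related to named cyst reference
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import PairwiseAlignment, ScoringScheme, global_align
from .qc import Read
from .taxonomy import ReferenceSet, TaxonomicLineage, lca

DEFAULT_IDENTITY_THRESHOLD = Fraction(85, 100)
DEFAULT_CYST_THRESHOLD = Fraction(97, 100)

STATUS_ASSIGNED = "assigned"
STATUS_UNASSIGNED = "unassigned-below-threshold"


def as_fraction(threshold: float | str | Fraction) -> Fraction:
    """Exact threshold: floats go through their decimal string so that 0.85
    means 85/100, not the nearest binary double."""
    if isinstance(threshold, Fraction):
        return threshold
    return Fraction(str(threshold))


@dataclass(frozen=True)
class Assignment:
    """Per-read assignment outcome."""

    read_id: str
    best_identity: Fraction
    tied_ref_ids: tuple[str, ...]
    lineage: TaxonomicLineage
    status: str

    @property
    def assigned(self) -> bool:
        return self.status == STATUS_ASSIGNED


def align_to_references(
    read: Read | str,
    refs: ReferenceSet,
    scoring: ScoringScheme | None = None,
) -> dict[str, PairwiseAlignment]:
    """Align a read (or bare sequence) to every reference."""
    seq = read.sequence if isinstance(read, Read) else read
    scoring = scoring or ScoringScheme()
    return {rec.id: global_align(seq, rec.sequence, scoring) for rec in refs}


def assign_read(
    read: Read | str,
    refs: ReferenceSet,
    scoring: ScoringScheme | None = None,
    threshold: float | str | Fraction = DEFAULT_IDENTITY_THRESHOLD,
    read_id: str | None = None,
) -> Assignment:
    """Nearest-neighbor assignment of one read with LCA tie-breaking.

    The identity threshold is strict: a best identity exactly equal to the
    threshold leaves the read unassigned.
    """
    if read_id is None:
        read_id = read.id if isinstance(read, Read) else "query"
    threshold = as_fraction(threshold)
    alignments = align_to_references(read, refs, scoring)
    best: Fraction | None = None
    tied: list[str] = []
    for rec in refs:
        identity = alignments[rec.id].identity
        if best is None or identity > best:
            best = identity
            tied = [rec.id]
        elif identity == best:
            tied.append(rec.id)
    lineage = lca([refs[ref_id].lineage for ref_id in tied])
    status = STATUS_ASSIGNED if best > threshold else STATUS_UNASSIGNED
    return Assignment(
        read_id=read_id,
        best_identity=best,
        tied_ref_ids=tuple(tied),
        lineage=lineage,
        status=status,
    )


def assign_reads(
    reads: Iterable[Read],
    refs: ReferenceSet,
    scoring: ScoringScheme | None = None,
    threshold: float | str | Fraction = DEFAULT_IDENTITY_THRESHOLD,
) -> list[Assignment]:
    scoring = scoring or ScoringScheme()
    threshold = as_fraction(threshold)
    return [
        assign_read(read, refs, scoring=scoring, threshold=threshold)
        for read in reads
    ]


def filter_by_similarity(
    reads: Sequence[Read],
    refs: ReferenceSet,
    cyst_ref_ids: Sequence[str],
    scoring: ScoringScheme | None = None,
    threshold: float | str | Fraction = DEFAULT_CYST_THRESHOLD,
) -> tuple[list[str], dict[str, int]]:
    """Cyst-similarity screen.

    Retains reads whose identity to at least one named cyst reference is
    strictly above the threshold (default 97%).  Returns the retained read
    ids and, per cyst reference, the count of reads above threshold
    against it (a read matching several cysts counts toward each).
    """
    missing = [c for c in cyst_ref_ids if c not in refs]
    if missing:
        raise ValueError(f"unknown cyst reference id(s): {missing}")
    threshold = as_fraction(threshold)
    scoring = scoring or ScoringScheme()
    per_cyst = {c: 0 for c in cyst_ref_ids}
    retained: list[str] = []
    for read in reads:
        hit = False
        for cyst_id in cyst_ref_ids:
            aln = global_align(read.sequence, refs[cyst_id].sequence, scoring)
            if aln.identity > threshold:
                per_cyst[cyst_id] += 1
                hit = True
        if hit:
            retained.append(read.id)
    return retained, per_cyst


def assignments_to_frame(assignments: Iterable[Assignment]) -> pd.DataFrame:
    """Long-format assignment table (identity as float for readability)."""
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "best_identity": float(a.best_identity),
                "tied_ref_ids": ",".join(a.tied_ref_ids),
                "lineage": str(a.lineage),
                "status": a.status,
            }
            for a in assignments
        ]
    )


def write_assignments_tsv(assignments: Iterable[Assignment], path: str | Path) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)
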