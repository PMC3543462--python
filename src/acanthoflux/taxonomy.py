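"""Clade-annotated reference database: lineages, records, LCA logic.

A reference database binds each V9 18S rRNA sequence to a ranked taxonomic
lineage (root-first, e.g. ``Acantharea;Holacanthida;CladeB;B1``).  The
lowest-common-ancestor (LCA) of a set of lineages — the longest shared
root-first prefix — is what a read receives when several references tie for
nearest neighbor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

LINEAGE_DELIMITER = ";"
#: Lineage returned when tied references share no rank at all.
ROOT_LINEAGE_LABEL = "Unassigned-root"

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC-aware, case-folded)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Upper-case and map U→T (rRNA references mix DNA/RNA conventions)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class TaxonomicLineage:
    """Ordered, root-first taxonomic path.

    Parameters
    ----------
    ranks
        Non-empty labels from root to tip.  Labels may not contain the
        ``;`` delimiter used by the on-disk taxonomy format.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("lineage must have at least one rank")
        for label in self.ranks:
            if not label:
                raise ValueError("lineage labels must be non-empty")
            if LINEAGE_DELIMITER in label:
                raise ValueError(
                    f"lineage label {label!r} contains the delimiter "
                    f"{LINEAGE_DELIMITER!r}"
                )

    @classmethod
    def from_string(cls, text: str) -> "TaxonomicLineage":
        return cls(tuple(part.strip() for part in text.split(LINEAGE_DELIMITER)))

    def __str__(self) -> str:
        return LINEAGE_DELIMITER.join(self.ranks)

    def __len__(self) -> int:
        return len(self.ranks)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ranks)

    def label_at(self, rank: int) -> str:
        """Label at a rank index (negative indices allowed); clamps to tip."""
        if rank >= len(self.ranks):
            return self.ranks[-1]
        return self.ranks[rank]


ROOT_LINEAGE = TaxonomicLineage((ROOT_LINEAGE_LABEL,))


def lca(lineages: Sequence[TaxonomicLineage]) -> TaxonomicLineage:
    """Last common ancestor: the longest root-first common prefix.

    Returns the designated root lineage when the inputs share no rank.

    >>> a = TaxonomicLineage.from_string("A;Chaunacanthida;CladeC;C3")
    >>> b = TaxonomicLineage.from_string("A;Chaunacanthida;CladeC;C4")
    >>> str(lca([a, b]))
    'A;Chaunacanthida;CladeC'
    """
    if not lineages:
        raise ValueError("lca requires at least one lineage")
    prefix = list(lineages[0].ranks)
    for lin in lineages[1:]:
        depth = 0
        for x, y in zip(prefix, lin.ranks):
            if x != y:
                break
            depth += 1
        del prefix[depth:]
        if not prefix:
            return ROOT_LINEAGE
    return TaxonomicLineage(tuple(prefix))


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference sequence with its lineage.  Sequence is stored normalized
    (upper-case, U→T)."""

    id: str
    sequence: str
    lineage: TaxonomicLineage

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reference id must be non-empty")
        if not self.sequence:
            raise ValueError(f"reference {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))


@dataclass
class ReferenceSet:
    """A named collection of reference records with unique ids."""

    records: list[ReferenceRecord]
    name: str = "references"
    _by_id: dict[str, ReferenceRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"reference set {self.name!r} is empty")
        self._by_id = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise ValueError(f"duplicate reference id {rec.id!r}")
            self._by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __getitem__(self, ref_id: str) -> ReferenceRecord:
        return self._by_id[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]


def _read_taxonomy_tsv(taxonomy_path: Path) -> dict[str, TaxonomicLineage]:
    lineages: dict[str, TaxonomicLineage] = {}
    with open(taxonomy_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{taxonomy_path}:{lineno}: expected 'id<TAB>lineage', "
                    f"got {line!r}"
                )
            rec_id, lineage_text = parts
            if rec_id in lineages:
                raise ValueError(
                    f"{taxonomy_path}:{lineno}: duplicate taxonomy id {rec_id!r}"
                )
            lineages[rec_id] = TaxonomicLineage.from_string(lineage_text)
    if not lineages:
        raise ValueError(f"taxonomy file {taxonomy_path} is empty")
    return lineages


def load_reference_set(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    name: str | None = None,
) -> ReferenceSet:
    """Load and validate a reference database from FASTA + taxonomy TSV.

    The taxonomy file is two-column TSV: ``id<TAB>rank1;rank2;...``.  Every
    FASTA id must appear in the TSV (extra TSV rows are tolerated).
    Sequences are upper-cased and U→T normalized on load.
    """
    fasta_path = Path(fasta_path)
    taxonomy_path = Path(taxonomy_path)
    lineages = _read_taxonomy_tsv(taxonomy_path)
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for seq_record in SeqIO.parse(str(fasta_path), "fasta"):
        if seq_record.id in seen:
            raise ValueError(f"duplicate FASTA id {seq_record.id!r} in {fasta_path}")
        seen.add(seq_record.id)
        if seq_record.id not in lineages:
            raise ValueError(
                f"FASTA id {seq_record.id!r} missing from taxonomy file "
                f"{taxonomy_path}"
            )
        records.append(
            ReferenceRecord(
                id=seq_record.id,
                sequence=str(seq_record.seq),
                lineage=lineages[seq_record.id],
            )
        )
    if not records:
        raise ValueError(f"FASTA file {fasta_path} contains no records")
    return ReferenceSet(records=records, name=name or fasta_path.stem)


def write_reference_set(
    refs: ReferenceSet, fasta_path: str | Path, taxonomy_path: str | Path
) -> None:
    """Write FASTA + taxonomy TSV such that a reload round-trips exactly."""
    with open(fasta_path, "w") as fa:
        for rec in refs:
            fa.write(f">{rec.id}\n{rec.sequence}\n")
    with open(taxonomy_path, "w") as tsv:
        for rec in refs:
            tsv.write(f"{rec.id}\t{rec.lineage}\n")


def validate_taxonomy(refs: ReferenceSet, clade_rank: int = -1) -> dict:
    """Report-only validation of a loaded reference set.

    Returns lineage depth distribution, per-clade record counts (clade label
    taken at ``clade_rank``), and rank-label conflicts: the same label
    appearing under two different parent labels.
    """
    depth_distribution: dict[int, int] = {}
    clade_counts: dict[str, int] = {}
    parents: dict[str, set[str]] = {}
    for rec in refs:
        ranks = rec.lineage.ranks
        depth_distribution[len(ranks)] = depth_distribution.get(len(ranks), 0) + 1
        clade = rec.lineage.label_at(clade_rank)
        clade_counts[clade] = clade_counts.get(clade, 0) + 1
        for parent, child in zip(ranks, ranks[1:]):
            parents.setdefault(child, set()).add(parent)
    conflicts = [
        {"label": label, "parents": sorted(seen)}
        for label, seen in sorted(parents.items())
        if len(seen) > 1
    ]
    return {
        "name": refs.name,
        "n_records": len(refs),
        "depth_distribution": {str(k): v for k, v in sorted(depth_distribution.items())},
        "clade_counts": dict(sorted(clade_counts.items())),
        "conflicts": conflicts,
    }


def write_validation_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
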