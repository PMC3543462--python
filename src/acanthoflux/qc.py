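"""Read quality control: exact primer matching/trimming and the sliding
50-bp expected-error window filter.

A read is retained only if (1) the forward primer matches exactly at the 5'
end and the reverse-complemented reverse primer matches exactly at the 3'
end (IUPAC degeneracy honored in the primer only), and (2) no 50-bp window
of the trimmed read has a mean Phred error probability strictly above 1%.
A chimera-screening hook is exposed but performs no filtering by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import reverse_complement

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

# Default primers: the general-eukaryote V9 pair (1389F / 1510R).
DEFAULT_FWD_PRIMER = "TTGTACACACCGCCC"
DEFAULT_REV_PRIMER = "CCTTCYGCAGGTTCACCTAC"


@dataclass(frozen=True)
class Read:
    """A quality-scored nucleotide read (Phred+33 on disk)."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QCConfig:
    """Primer pair and expected-error window parameters."""

    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    window_length: int = 50
    max_window_error: float = 0.01

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if not 0 < self.max_window_error < 1:
            raise ValueError("max_window_error must be in (0, 1)")


def primer_matches(primer: str, segment: str) -> bool:
    """Exact-position primer match; degeneracy in the primer only.

    An ``N`` (or any non-ACGT symbol) in the read matches nothing.
    """
    if len(primer) != len(segment):
        return False
    for p, s in zip(primer.upper(), segment.upper()):
        allowed = IUPAC_SETS.get(p)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {p!r} in primer")
        if s not in allowed:
            return False
    return True


def primer_match_and_trim(
    read: Read, cfg: QCConfig
) -> tuple[Read | None, str | None]:
    """Require exact forward and reverse primer matches; trim both spans.

    The forward primer must match at position 0 and the reverse complement
    of the reverse primer at the 3' end.  Returns ``(trimmed, None)`` on
    success or ``(None, reason)`` with reason one of ``too-short``,
    ``no-fwd-primer``, ``no-rev-primer``.
    """
    fwd = cfg.fwd_primer.upper()
    rev_rc = reverse_complement(cfg.rev_primer)
    if len(read) < len(fwd) + len(rev_rc) + 1:
        return None, "too-short"
    if not primer_matches(fwd, read.sequence[: len(fwd)]):
        return None, "no-fwd-primer"
    if not primer_matches(rev_rc, read.sequence[len(read) - len(rev_rc):]):
        return None, "no-rev-primer"
    start, stop = len(fwd), len(read) - len(rev_rc)
    return (
        Read(
            id=read.id,
            sequence=read.sequence[start:stop],
            qualities=read.qualities[start:stop],
        ),
        None,
    )


def phred_to_error_prob(qualities: Sequence[int]) -> np.ndarray:
    """Per-base error probability p = 10^(−Q/10)."""
    return np.power(10.0, -np.asarray(qualities, dtype=float) / 10.0)


def worst_window_error(read: Read, cfg: QCConfig) -> float:
    """Maximum mean error probability over all sliding windows (step 1).

    Reads shorter than the window length are evaluated as one full-length
    window.
    """
    if len(read) == 0:
        raise ValueError("empty read has no windows")
    p = phred_to_error_prob(read.qualities)
    w = min(cfg.window_length, len(p))
    # sliding means via cumulative sum; numerically safe at these sizes
    csum = np.concatenate(([0.0], np.cumsum(p)))
    means = (csum[w:] - csum[:-w]) / w
    return float(means.max())


def window_error_filter(read: Read, cfg: QCConfig) -> tuple[bool, float | None, str | None]:
    """Pass/fail under the expected-error window rule (strict ``>``).

    Returns ``(passed, worst_window_mean, reason)``; reason is ``window``
    on failure, ``empty`` for a zero-length read.
    """
    if len(read) == 0:
        return False, None, "empty"
    worst = worst_window_error(read, cfg)
    # absolute guard so a window whose true mean equals the limit is kept
    # (strict "more than") despite accumulated rounding in the sliding sum
    if worst > cfg.max_window_error + 1e-12:
        return False, worst, "window"
    return True, worst, None


ChimeraHook = Callable[[list[Read]], list[Read]]


def run_qc(
    reads: Iterable[Read],
    cfg: QCConfig,
    chimera_hook: ChimeraHook | None = None,
) -> tuple[list[Read], dict[str, int]]:
    """Apply primer matching then the window filter to a read set.

    Returns the retained reads and per-reason rejection counts; the counts
    plus the retained count always partition the input exactly.  The
    chimera hook (if given) runs last on the retained reads and may only
    remove reads; removals are counted under ``chimera``.
    """
    counts = {
        "input": 0, "retained": 0, "too-short": 0,
        "no-fwd-primer": 0, "no-rev-primer": 0, "window": 0,
        "empty": 0, "chimera": 0,
    }
    retained: list[Read] = []
    for read in reads:
        counts["input"] += 1
        trimmed, reason = primer_match_and_trim(read, cfg)
        if trimmed is None:
            counts[reason] += 1
            continue
        passed, _, reason = window_error_filter(trimmed, cfg)
        if not passed:
            counts[reason] += 1
            continue
        retained.append(trimmed)
    if chimera_hook is not None:
        kept = chimera_hook(retained)
        kept_ids = {r.id for r in kept}
        if not kept_ids <= {r.id for r in retained}:
            raise ValueError("chimera hook may only remove reads")
        counts["chimera"] = len(retained) - len(kept)
        retained = [r for r in retained if r.id in kept_ids]
    counts["retained"] = len(retained)
    return retained, counts


def read_fastq(path: str | Path) -> list[Read]:
    """Load Phred+33 FASTQ into Read objects (sequences upper-cased)."""
    reads: list[Read] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        try:
            reads.append(
                Read(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record #{i} in {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
        rec.letter_annotations["phred_quality"] = list(read.qualities)
        records.append(rec)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fastq")
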