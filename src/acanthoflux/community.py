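"""Community composition summaries by sample, clade and depth zone.

Assigned reads are tabulated into per-sample clade counts and fractions,
samples are binned into depth zones (photic 0–100 m, mesopelagic
100–1000 m, deep 1000–3000 m), and group fractions (e.g. acantharian reads
as a percentage of all protist reads) are computed.  Clades below a
display floor (default 1% of a sample) are masked in display output but
kept in the data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assign import Assignment

DEPTH_ZONES = ["0-100 m", "100-1000 m", "1000-3000 m", "below-3000 m"]


def bin_by_depth_zone(depth_m: float) -> str:
    """Half-open depth bins [0,100), [100,1000), [1000,3000]; deeper is
    its own zone.  Negative depth is an error."""
    if depth_m < 0:
        raise ValueError(f"negative depth: {depth_m}")
    if depth_m < 100:
        return DEPTH_ZONES[0]
    if depth_m < 1000:
        return DEPTH_ZONES[1]
    if depth_m <= 3000:
        return DEPTH_ZONES[2]
    return DEPTH_ZONES[3]


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata CSV: sample_id, station, depth_m, size_fraction.
    Adds the derived depth-zone column."""
    meta = pd.read_csv(path)
    required = {"sample_id", "station", "depth_m", "size_fraction"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    meta = meta.copy()
    meta["zone"] = meta["depth_m"].map(bin_by_depth_zone)
    return meta


def tabulate_composition(
    assignments: pd.DataFrame,
    metadata: pd.DataFrame,
    clade_rank: int = 1,
    display_floor: float = 0.01,
) -> pd.DataFrame:
    """Per-sample clade counts and fractions from assigned reads.

    ``assignments`` needs columns sample_id, lineage, status; only assigned
    reads enter the composition (unassigned reads are excluded from the
    denominator).  The clade label is the lineage rank at ``clade_rank``
    (clamped to the tip for shallower lineages).  Output columns:
    sample_id, station, zone, size_fraction, clade, count, fraction,
    masked — ``masked`` marks clades under the display floor; counts and
    fractions are never altered by masking.
    """
    known = set(metadata["sample_id"])
    unknown = set(assignments["sample_id"]) - known
    if unknown:
        raise ValueError(f"assignments reference unknown sample id(s): {sorted(unknown)}")
    assigned = assignments[assignments["status"] == "assigned"].copy()

    def clade_of(lineage: str) -> str:
        ranks = [r.strip() for r in str(lineage).split(";")]
        return ranks[clade_rank] if clade_rank < len(ranks) else ranks[-1]

    assigned["clade"] = assigned["lineage"].map(clade_of)
    counts = (
        assigned.groupby(["sample_id", "clade"]).size().rename("count").reset_index()
    )
    totals = counts.groupby("sample_id")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    counts["masked"] = counts["fraction"] < display_floor
    out = counts.merge(
        metadata[["sample_id", "station", "zone", "size_fraction"]],
        on="sample_id",
        how="left",
    )
    return out[
        ["sample_id", "station", "zone", "size_fraction", "clade",
         "count", "fraction", "masked"]
    ].sort_values(["sample_id", "clade"], ignore_index=True)


def pivot_by_zone(composition: pd.DataFrame) -> pd.DataFrame:
    """Zone × clade pivot of read counts (summed over samples), ordered
    surface to deep."""
    pivot = (
        composition.pivot_table(
            index="zone", columns="clade", values="count", aggfunc="sum", fill_value=0
        )
        .reindex([z for z in DEPTH_ZONES if z in set(composition["zone"])])
    )
    pivot.columns.name = None
    return pivot


def fraction_of_group(group_counts: int, total_counts: int) -> float:
    """Percentage of a read total belonging to a group, e.g. acantharian
    reads among all protist reads."""
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    if not 0 <= group_counts <= total_counts:
        raise ValueError("group_counts must be between 0 and total_counts")
    return 100.0 * group_counts / total_counts


def attach_samples(
    assignments: Iterable[Assignment], sample_ids: Sequence[str] | str
) -> pd.DataFrame:
    """Helper: join Assignment objects with their sample of origin."""
    from .assign import assignments_to_frame

    frame = assignments_to_frame(assignments)
    frame["sample_id"] = (
        sample_ids if isinstance(sample_ids, str) else list(sample_ids)
    )
    return frame
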