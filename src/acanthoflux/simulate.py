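"""Synthetic inputs with machine-readable truth.

Two generators emulate the pipeline's input streams:

* a clade-structured V9 reference database plus error-bearing,
  quality-scored amplicon reads (forward primer + mutated insert +
  reverse-complemented reverse primer), each read carrying its true source
  lineage in a sidecar table;
* sequential sediment-trap bottle series: a Gaussian seawater-strontium
  background (~8 µg mL⁻¹) plus sparse cyst-flux spikes of known injected
  mass, with the implied true flux recorded per spiked bottle.

Both are deterministic: the same config and seed give byte-identical
output files.  The error model is substitution-only; indels can be enabled
but default to zero (the V9 region is short and the downstream filters are
quality-based, so substitutions dominate the realistic failure modes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER, Read
from .taxonomy import (
    ReferenceRecord,
    ReferenceSet,
    TaxonomicLineage,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Amplicon simulation parameters.

    Defaults describe a 4-clade acantharian V9 mock community: ~130-bp
    amplicons, clades ~20% diverged from a common root, ~2% divergence
    within a clade, and a 1% per-base sequencing substitution rate.
    ``quality_model`` maps the error state of a base to its Phred score:
    correctly copied bases get Q40 (p=1e-4), substituted bases Q20
    (p=1e-2), so emitted qualities are informative about true errors.
    """

    seed: int = 0
    n_clades: int = 4
    refs_per_clade: int = 5
    ref_length: int = 130
    between_clade_divergence: float = 0.20
    within_clade_divergence: float = 0.02
    read_error_rate: float = 0.01
    indel_rate: float = 0.0
    quality_model: dict = field(
        default_factory=lambda: {"correct": 40, "error": 20}
    )
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER

    def __post_init__(self) -> None:
        for name in ("between_clade_divergence", "within_clade_divergence",
                     "read_error_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.within_clade_divergence >= self.between_clade_divergence > 0:
            raise ValueError(
                "within_clade_divergence must be below between_clade_divergence"
            )
        if self.n_clades < 1 or self.refs_per_clade < 1 or self.ref_length < 1:
            raise ValueError("n_clades, refs_per_clade, ref_length must be >= 1")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``;
    substituted bases are drawn uniformly from the three other bases."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hit):
        # shift by 1..3 in base space => always a different base
        shift = rng.integers(1, 4, size=len(hit))
        idx = _base_index(out[hit])
        out[hit] = _BASES[(idx + shift) % 4]
    return out


_BASE_TO_IDX = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


def _base_index(arr: np.ndarray) -> np.ndarray:
    return _BASE_TO_IDX[arr]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _concretize(primer: str) -> str:
    """Replace IUPAC ambiguity codes with their first compatible base."""
    from .qc import IUPAC_SETS

    return "".join(min(IUPAC_SETS[b]) for b in primer)


def generate_reference_set(
    cfg: SimulationConfig,
) -> tuple[ReferenceSet, dict[str, str]]:
    """Simulate a clade-structured reference database.

    One random root sequence is drawn; each clade ancestor diverges from it
    at ``between_clade_divergence``, and each reference diverges from its
    clade ancestor at ``within_clade_divergence``.  Lineages are two-rank:
    ``Acantharea;Clade<k>``.  Returns the set and an id→clade map.
    """
    rng = np.random.default_rng(cfg.seed)
    root = _BASES[rng.integers(0, 4, size=cfg.ref_length)]
    records: list[ReferenceRecord] = []
    clade_map: dict[str, str] = {}
    for k in range(cfg.n_clades):
        clade = f"Clade{chr(ord('A') + k) if k < 26 else k}"
        ancestor = _mutate(root, cfg.between_clade_divergence, rng)
        for r in range(cfg.refs_per_clade):
            seq = _mutate(ancestor, cfg.within_clade_divergence, rng)
            ref_id = f"ref_{clade}_{r:02d}"
            records.append(
                ReferenceRecord(
                    id=ref_id,
                    sequence=_to_str(seq),
                    lineage=TaxonomicLineage(("Acantharea", clade)),
                )
            )
            clade_map[ref_id] = clade
    return ReferenceSet(records=records, name="synthetic-refs"), clade_map


def simulate_reads(
    refs: ReferenceSet, n_reads: int, cfg: SimulationConfig
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate amplicon reads with known truth.

    Each read is ``fwd_primer + mutated_reference + revcomp(rev_primer)``.
    Substituted insert bases receive ``quality_model['error']``; all other
    bases (including primer bases) ``quality_model['correct']``.  Returns
    the reads and a truth table (read_id, source_ref, lineage).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    q_ok = int(cfg.quality_model["correct"])
    q_err = int(cfg.quality_model["error"])
    # degenerate primer positions carry a concrete base in a real amplicon;
    # resolve each to the lexically first compatible base
    fwd = _concretize(cfg.fwd_primer.upper())
    rev_rc = _concretize(reverse_complement(cfg.rev_primer))
    ref_records = refs.records
    pick = rng.integers(0, len(ref_records), size=n_reads)
    reads: list[Read] = []
    truth_rows: list[tuple[str, str, str]] = []
    for i in range(n_reads):
        rec = ref_records[pick[i]]
        src = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        insert = _mutate(src, cfg.read_error_rate, rng)
        errored = insert != src
        if cfg.indel_rate > 0:
            insert, errored = _apply_indels(insert, errored, cfg.indel_rate, rng)
        quals = np.where(errored, q_err, q_ok)
        read_id = f"read_{i:06d}"
        sequence = fwd + _to_str(insert) + rev_rc
        qualities = (
            (q_ok,) * len(fwd) + tuple(int(q) for q in quals) + (q_ok,) * len(rev_rc)
        )
        reads.append(Read(id=read_id, sequence=sequence, qualities=qualities))
        truth_rows.append((read_id, rec.id, str(rec.lineage)))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "source_ref", "lineage"])
    return reads, truth


def _apply_indels(
    insert: np.ndarray, errored: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Optional per-base indels: deletion or single-base insertion, 50/50."""
    out_b: list[int] = []
    out_e: list[bool] = []
    for b, e in zip(insert, errored):
        if rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out_b.append(int(_BASES[rng.integers(0, 4)]))
            out_e.append(True)
        out_b.append(int(b))
        out_e.append(bool(e))
    return np.array(out_b, dtype=np.uint8), np.array(out_e, dtype=bool)


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sediment-trap series simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrapSimConfig:
    """Sediment-trap bottle-series simulation parameters.

    Defaults describe one deployment of a 0.66 m² conical trap cycling
    9 sequential 500-mL bottles at 28 days each (~8.5 months), with a
    seawater Sr background of 8.0 ± 0.2 µg mL⁻¹ and two cyst-flux spikes
    of 4 and 8 mg Sr — the per-bottle loads implied by observed
    episodic acantharian fluxes of ~0.1–0.5 mg Sr m⁻² d⁻¹.
    """

    seed: int = 0
    n_bottles: int = 9
    background_mean: float = 8.0
    background_sd: float = 0.2
    bottle_volume: float = 500.0
    collection_area: float = 0.66
    period_days: float = 28.0
    spikes: tuple[tuple[int, float], ...] = ((3, 4000.0), (7, 8000.0))
    trap_id: str = "trap-sim"

    def __post_init__(self) -> None:
        if self.n_bottles < 3:
            raise ValueError("n_bottles must be >= 3")
        if self.background_mean <= 0 or self.background_sd < 0:
            raise ValueError("background parameters must be positive")
        if self.bottle_volume <= 0 or self.collection_area <= 0 or self.period_days <= 0:
            raise ValueError("volume, area and period must be positive")
        for idx, mass in self.spikes:
            if not 0 <= idx < self.n_bottles:
                raise ValueError(f"spike index {idx} out of range")
            if mass < 0:
                raise ValueError("spike mass must be non-negative")


def simulate_trap_series(cfg: TrapSimConfig):
    """Simulate one trap bottle series and its truth flux table.

    Bottle concentration = Normal(background_mean, background_sd) plus
    ``injected_mass / volume`` for spiked bottles.  Negative background
    draws are resampled (and logged) so the background stays approximately
    Gaussian.  Truth flux per spiked bottle is
    ``injected_mass_mg / (collection_area × period_days)``.

    Returns ``(TrapSeries, truth DataFrame)``; the truth table has columns
    bottle_id, injected_sr_ug, truth_sr_flux.
    """
    from .srflux import TrapBottle, TrapSeries  # local import, avoids cycle

    rng = np.random.default_rng(cfg.seed)
    spikes = dict(cfg.spikes)
    bottles = []
    truth_rows = []
    for i in range(cfg.n_bottles):
        conc = rng.normal(cfg.background_mean, cfg.background_sd)
        n_resampled = 0
        while conc < 0:
            n_resampled += 1
            conc = rng.normal(cfg.background_mean, cfg.background_sd)
        if n_resampled:
            logger.warning(
                "bottle %d: resampled %d negative background draw(s)", i, n_resampled
            )
        injected = spikes.get(i, 0.0)
        conc += injected / cfg.bottle_volume
        bottle_id = f"B{i + 1:02d}"
        bottles.append(
            TrapBottle(
                trap_id=cfg.trap_id,
                bottle_id=bottle_id,
                duration_days=cfg.period_days,
                volume_ml=cfg.bottle_volume,
                sr_conc=conc,
            )
        )
        truth_rows.append(
            (
                bottle_id,
                injected,
                (injected / 1000.0) / (cfg.collection_area * cfg.period_days)
                if injected
                else 0.0,
            )
        )
    series = TrapSeries(
        trap_id=cfg.trap_id, collection_area=cfg.collection_area, bottles=bottles
    )
    truth = pd.DataFrame(
        truth_rows, columns=["bottle_id", "injected_sr_ug", "truth_sr_flux"]
    )
    return series, truth
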