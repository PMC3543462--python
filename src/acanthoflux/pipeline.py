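"""End-to-end orchestration: qc → assign → summarize (+ independent
sediment-trap flux analysis), with a config file, deterministic outputs
and a run manifest.

The manifest records input file hashes, the effective configuration and
per-stage record counts; identical config and inputs reproduce the output
directory byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import assign as assign_mod
from . import community, qc, srflux, taxonomy
from .align import ScoringScheme

logger = logging.getLogger(__name__)


class PipelineConfigError(Exception):
    """Invalid or incomplete pipeline configuration."""


class PipelineStageError(Exception):
    """A stage failed; carries the stage name for error reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Paths, thresholds and scoring for one pipeline run."""

    output_dir: Path = Path("acanthoflux-out")
    reads: Path | None = None
    references: Path | None = None
    taxonomy: Path | None = None
    metadata: Path | None = None
    trap: Path | None = None
    poc_table: Path | None = None
    sample_id: str = "sample1"
    seed: int = 0
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    identity_threshold: str = "0.85"
    cyst_threshold: str = "0.97"
    cyst_ids: tuple[str, ...] = ()
    clade_rank: int = 1
    display_floor: float = 0.01
    background_cutoff: float = srflux.DEFAULT_BACKGROUND_CUTOFF
    c_sr_value: float = 0.120
    c_sr_sd: float = 0.022
    collection_area: float = srflux.DEFAULT_COLLECTION_AREA

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: dict, **overrides) -> "PipelineConfig":
        raw = dict(raw)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        paths = raw.pop("paths", {})
        for key in ("reads", "references", "taxonomy", "output_dir",
                    "metadata", "trap", "poc_table"):
            if key in paths and key not in raw:
                raw[key] = paths[key]
        try:
            qc_cfg = qc.QCConfig(**raw.pop("qc", {}))
            scoring = ScoringScheme(**raw.pop("scoring", {}))
            for key in ("reads", "references", "taxonomy", "output_dir",
                        "metadata", "trap", "poc_table"):
                if raw.get(key) is not None:
                    raw[key] = Path(raw[key])
            if "cyst_ids" in raw:
                raw["cyst_ids"] = tuple(raw["cyst_ids"])
            return cls(qc=qc_cfg, scoring=scoring, **raw)
        except (TypeError, ValueError) as exc:
            raise PipelineConfigError(str(exc)) from exc

    def validate(self, require_amplicon: bool = True) -> None:
        missing = []
        if require_amplicon:
            for name in ("reads", "references", "taxonomy"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    missing.append(name)
        for name in ("metadata", "trap", "poc_table"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                missing.append(name)
        if missing:
            raise PipelineConfigError(
                f"missing input path(s): {', '.join(missing)}"
            )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = asdict(cfg)
    for key, value in echo.items():
        if isinstance(value, Path):
            echo[key] = str(value)
    return echo


def run_pipeline(cfg: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute all configured stages and write outputs plus a manifest.

    With ``dry_run`` the configuration and input paths are validated and
    the manifest (without stage results) is returned; nothing is written.
    """
    has_amplicon = cfg.reads is not None
    if not has_amplicon and cfg.trap is None:
        raise PipelineConfigError("config provides neither reads nor a trap CSV")
    cfg.validate(require_amplicon=has_amplicon)
    manifest: dict = {
        "config": _config_echo(cfg),
        "inputs": {},
        "stages": {},
    }
    for name in ("reads", "references", "taxonomy", "metadata", "trap", "poc_table"):
        path = getattr(cfg, name)
        if path is not None and Path(path).exists():
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
    if dry_run:
        return manifest

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if has_amplicon:
        # --- reference loading -------------------------------------------
        try:
            refs = taxonomy.load_reference_set(cfg.references, cfg.taxonomy)
        except (ValueError, OSError) as exc:
            raise PipelineStageError("references", str(exc)) from exc
        report = taxonomy.validate_taxonomy(refs)
        taxonomy.write_validation_report(report, out / "taxonomy_report.json")
        manifest["stages"]["references"] = {"n_records": len(refs)}

        # --- qc -----------------------------------------------------------
        try:
            reads = qc.read_fastq(cfg.reads)
            retained, counts = qc.run_qc(reads, cfg.qc)
        except (ValueError, OSError) as exc:
            raise PipelineStageError("qc", str(exc)) from exc
        qc.write_fastq(retained, out / "qc_passed.fastq")
        with open(out / "qc_counts.json", "w") as handle:
            json.dump(counts, handle, indent=2, sort_keys=True)
            handle.write("\n")
        manifest["stages"]["qc"] = counts

        # --- assignment ---------------------------------------------------
        try:
            assignments = assign_mod.assign_reads(
                retained, refs, scoring=cfg.scoring,
                threshold=cfg.identity_threshold,
            )
        except ValueError as exc:
            raise PipelineStageError("assign", str(exc)) from exc
        assign_mod.write_assignments_tsv(assignments, out / "assignments.tsv")
        n_assigned = sum(a.assigned for a in assignments)
        manifest["stages"]["assign"] = {
            "input": len(assignments),
            "assigned": n_assigned,
            "unassigned": len(assignments) - n_assigned,
        }

        if cfg.cyst_ids:
            try:
                retained_ids, per_cyst = assign_mod.filter_by_similarity(
                    retained, refs, list(cfg.cyst_ids),
                    scoring=cfg.scoring, threshold=cfg.cyst_threshold,
                )
            except ValueError as exc:
                raise PipelineStageError("cyst-screen", str(exc)) from exc
            with open(out / "cyst_similarity.json", "w") as handle:
                json.dump(
                    {"retained_read_ids": retained_ids, "per_cyst_counts": per_cyst},
                    handle, indent=2, sort_keys=True,
                )
                handle.write("\n")
            manifest["stages"]["cyst-screen"] = {"retained": len(retained_ids)}

        # --- community summary -------------------------------------------
        if cfg.metadata is not None:
            try:
                meta = community.load_metadata(cfg.metadata)
                frame = community.attach_samples(assignments, cfg.sample_id)
                comp = community.tabulate_composition(
                    frame, meta, clade_rank=cfg.clade_rank,
                    display_floor=cfg.display_floor,
                )
            except ValueError as exc:
                raise PipelineStageError("summarize", str(exc)) from exc
            comp.to_csv(out / "composition.csv", index=False)
            community.pivot_by_zone(comp).to_csv(out / "zone_pivot.csv")
            manifest["stages"]["summarize"] = {
                "n_samples": int(comp["sample_id"].nunique()),
                "n_clades": int(comp["clade"].nunique()),
            }

    # --- sediment-trap flux (independent of the amplicon branch) ---------
    if cfg.trap is not None:
        try:
            poc = None
            if cfg.poc_table is not None:
                import pandas as pd

                poc_df = pd.read_csv(cfg.poc_table)
                poc = dict(zip(poc_df["bottle_id"].astype(str),
                               poc_df["total_poc_flux"].astype(float)))
            all_results = []
            backgrounds = {}
            for series in srflux.read_trap_csv(cfg.trap, cfg.collection_area):
                bg, results = srflux.analyze_series(
                    series,
                    cutoff=cfg.background_cutoff,
                    ratio=srflux.CSrRatio(cfg.c_sr_value, cfg.c_sr_sd),
                    total_poc_flux=poc,
                )
                backgrounds[series.trap_id] = {
                    "mean": bg.mean, "sd": bg.sd,
                    "n_bottles_used": bg.n_bottles_used, "cutoff": bg.cutoff,
                }
                frame = srflux.flux_results_to_frame(results)
                frame.insert(0, "trap_id", series.trap_id)
                all_results.append(frame)
        except (ValueError, OSError, KeyError) as exc:
            raise PipelineStageError("srflux", str(exc)) from exc
        import pandas as pd

        flux = pd.concat(all_results, ignore_index=True)
        flux.to_csv(out / "flux.csv", index=False)
        with open(out / "background.json", "w") as handle:
            json.dump(backgrounds, handle, indent=2, sort_keys=True)
            handle.write("\n")
        manifest["stages"]["srflux"] = {
            "n_bottles": int(len(flux)),
            "n_significant": int(flux["significant"].sum()),
        }

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
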