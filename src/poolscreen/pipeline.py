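"""End-to-end orchestration of the screen analysis from a single config file.

A run proceeds library -> counts -> differential -> hit calls for the main
screen (and optionally a counter-screen under a generic lethal pressure),
subtracts counter-screen hits, and scores the final list against user gene
sets.  Counts come either from simulation (optionally routed through FASTQ
emission and re-quantification) or from real per-sample FASTQ files listed in
a sample sheet.  All result tables are written with fixed column order and
formatting so that re-running an identical config and seed reproduces them
byte for byte; the run manifest records versions, the seed, and a hash of the
config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .design import (
    LibraryDesign,
    design_library,
    read_manifest,
    validate_library,
    write_manifest,
)
from .differential import run_differential
from .enrichment import enrich, read_gmt
from .hits import HitCriteria, call_hits, hit_gene_set, subtract_counter_screen
from .quantify import (
    CountMatrix,
    DEFAULT_BARCODE_OFFSET,
    concat_pools,
    merge_columns,
    quantify,
    read_counts_tsv,
    write_counts_tsv,
)
from .simulate import EffectProfile, SimulationConfig, emit_fastq, simulate_screen_counts

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)

# offset added to the top-level seed for the counter-screen simulation so the
# two screens are independent but jointly reproducible
COUNTER_SEED_OFFSET = 1_000_003

SAMPLE_SHEET_COLUMNS = ["sample_id", "pool", "condition", "replicate", "file"]

FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class ScreenSource:
    """Where one screen's counts come from: simulation or FASTQ files."""

    simulate: Mapping[str, Any] | None = None  # SimulationConfig fields + 'effects'
    sample_sheet: str | None = None
    fastq_dir: str | None = None
    max_mismatches: int = 0
    barcode_offset: int = DEFAULT_BARCODE_OFFSET
    via_fastq: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.sample_sheet is None):
            raise ValueError("exactly one of 'simulate' or 'sample_sheet' required")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "poolscreen_out"
    log_level: str = "INFO"
    library_manifest: str | None = None
    library_design: Mapping[str, Any] | None = None
    screen: ScreenSource | None = None
    counter_screen: ScreenSource | None = None
    hit_criteria: HitCriteria = field(default_factory=HitCriteria)
    gmt: str | None = None
    enrichment_fdr: float = 0.1
    ease: bool = False
    raw: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.library_manifest is None) == (self.library_design is None):
            raise ValueError("exactly one of library manifest or design block required")
        if self.screen is None:
            raise ValueError("a 'screen' block is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data, base=Path(path).parent)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any], base: Path | None = None) -> "PipelineConfig":
        def resolve(p: str | None) -> str | None:
            if p is None or base is None:
                return p
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        lib = data.get("library", {})
        screen = data.get("screen")
        if screen is None:
            raise ValueError("config requires a 'screen' block")

        def source(block: Mapping[str, Any]) -> ScreenSource:
            return ScreenSource(
                simulate=block.get("simulate"),
                sample_sheet=resolve(block.get("sample_sheet")),
                fastq_dir=resolve(block.get("fastq_dir")),
                max_mismatches=int(block.get("max_mismatches", 0)),
                barcode_offset=int(block.get("barcode_offset", DEFAULT_BARCODE_OFFSET)),
                via_fastq=bool(block.get("via_fastq", False)),
            )

        counter = data.get("counter_screen")
        enr = data.get("enrichment", {})
        return cls(
            seed=int(data.get("seed", 0)),
            outdir=resolve(data.get("outdir", "poolscreen_out")),
            log_level=str(data.get("log_level", "INFO")),
            library_manifest=resolve(lib.get("manifest")),
            library_design=lib.get("design"),
            screen=source(screen),
            counter_screen=source(counter) if counter else None,
            hit_criteria=HitCriteria(**data.get("hit_criteria", {})),
            gmt=resolve(enr.get("gmt")),
            enrichment_fdr=float(enr.get("fdr_threshold", 0.1)),
            ease=bool(enr.get("ease", False)),
            raw=dict(data),
        )


@dataclass
class RunReport:
    outdir: Path
    library: LibraryDesign
    counts: CountMatrix
    differential: pd.DataFrame
    hit_calls: pd.DataFrame
    hits_main: set[str]
    hits_counter: set[str] | None
    final_hits: list[str]
    enrichment: pd.DataFrame | None
    manifest: dict[str, Any]


def _load_sample_sheet(path: str, fastq_dir: str | None) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str, "file": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in sample sheet")
    bad = set(sheet["condition"]) - {"reference", "treated"}
    if bad:
        raise ValueError(f"sample sheet conditions must be reference/treated, got {sorted(bad)}")
    for pool, grp in sheet.groupby("pool"):
        for cond in ("reference", "treated"):
            if not (grp["condition"] == cond).any():
                raise ValueError(f"pool {pool}: sample sheet missing the {cond} arm")
    if fastq_dir:
        sheet["file"] = [str(Path(fastq_dir) / f) for f in sheet["file"]]
    return sheet


def _counts_from_fastq(sheet: pd.DataFrame, library: LibraryDesign, src: ScreenSource) -> CountMatrix:
    per_pool = []
    for pool, grp in sheet.groupby("pool"):
        cols = [
            quantify(
                row.file,
                library,
                int(pool),
                max_mismatches=src.max_mismatches,
                barcode_offset=src.barcode_offset,
                sample_id=row.sample_id,
                condition=row.condition,
                replicate=int(row.replicate),
            )
            for row in grp.itertuples(index=False)
        ]
        per_pool.append(merge_columns(cols))
    return concat_pools(per_pool, library)


def _simulated_counts(
    library: LibraryDesign, src: ScreenSource, seed: int, outdir: Path, tag: str
) -> CountMatrix:
    block = dict(src.simulate or {})
    effects_spec = block.pop("effects", {}) or {}
    n_affected = block.pop("n_affected", None)
    block.pop("seed", None)
    cfg = SimulationConfig(seed=seed, **block)
    effects = EffectProfile.from_gene_effects(
        library, {str(g): float(v) for g, v in effects_spec.items()}, n_affected=n_affected
    )
    ref, trt = simulate_screen_counts(library, effects, cfg)
    if not src.via_fastq:
        return concat_pools([ref, trt], library)

    # route through FASTQ emission and re-quantification
    fastq_dir = outdir / "fastq" / tag
    fastq_dir.mkdir(parents=True, exist_ok=True)
    per_pool = []
    for pool in sorted(library.constructs["pool"].unique()):
        cols = []
        for arm_matrix in (ref, trt):
            block_m = arm_matrix.pool_block(pool, library)
            for sid in block_m.sample_ids:
                fq = fastq_dir / f"{sid}.fastq.gz"
                emit_fastq(block_m.column(sid), library, pool, cfg, fq, sample_id=sid)
                meta = block_m.samples.loc[sid]
                cols.append(
                    quantify(
                        fq,
                        library,
                        pool,
                        max_mismatches=src.max_mismatches,
                        barcode_offset=cfg.barcode_offset,
                        sample_id=sid,
                        condition=str(meta["condition"]),
                        replicate=int(meta["replicate"]),
                    )
                )
        per_pool.append(merge_columns(cols))
    return concat_pools(per_pool, library)


def _screen_counts(
    library: LibraryDesign, src: ScreenSource, seed: int, outdir: Path, tag: str
) -> CountMatrix:
    if src.simulate is not None:
        return _simulated_counts(library, src, seed, outdir, tag)
    sheet = _load_sample_sheet(src.sample_sheet, src.fastq_dir)
    return _counts_from_fastq(sheet, library, src)


def _serialize_hits(calls: pd.DataFrame) -> pd.DataFrame:
    out = calls.copy()
    out["enriched_pools"] = [",".join(str(p) for p in t) for t in out["enriched_pools"]]
    out["failure_reasons"] = [";".join(t) for t in out["failure_reasons"]]
    return out


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage; write result tables and a run manifest to outdir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    incomplete = outdir / "INCOMPLETE"
    incomplete.write_text("run started\n")

    stage = "library"
    try:
        if config.library_manifest:
            library = read_manifest(config.library_manifest)
        else:
            library = design_library(seed=config.seed, **dict(config.library_design))
        validate_library(library)
        write_manifest(library, outdir / "library.tsv")

        stage = "counts"
        counts = _screen_counts(library, config.screen, config.seed, outdir, "main")
        write_counts_tsv(counts, outdir / "counts.tsv")

        stage = "differential"
        diff = run_differential(counts, library)
        _write_table(diff, outdir / "differential.tsv")

        stage = "hit_calling"
        calls = call_hits(diff, library, config.hit_criteria)
        _write_table(_serialize_hits(calls), outdir / "hits.tsv")
        hits_main = hit_gene_set(calls)

        hits_counter: set[str] | None = None
        if config.counter_screen is not None:
            stage = "counter_screen"
            c_counts = _screen_counts(
                library,
                config.counter_screen,
                config.seed + COUNTER_SEED_OFFSET,
                outdir,
                "counter",
            )
            write_counts_tsv(c_counts, outdir / "counts_counter.tsv")
            c_diff = run_differential(c_counts, library)
            _write_table(c_diff, outdir / "differential_counter.tsv")
            c_calls = call_hits(c_diff, library, config.hit_criteria)
            _write_table(_serialize_hits(c_calls), outdir / "hits_counter.tsv")
            hits_counter = hit_gene_set(c_calls)

        stage = "subtraction"
        final = subtract_counter_screen(hits_main, hits_counter or set())
        (outdir / "hits_final.txt").write_text("".join(g + "\n" for g in final))

        enrichment_table: pd.DataFrame | None = None
        if config.gmt:
            stage = "enrichment"
            gene_sets = read_gmt(config.gmt)
            universe = set(library.genes)
            enrichment_table = enrich(
                set(final), gene_sets, universe, config.enrichment_fdr, ease=config.ease
            )
            _write_table(enrichment_table, outdir / "enrichment.tsv")

        stage = "manifest"
        import numpy as np_mod
        import scipy as sp_mod

        manifest = {
            "poolscreen_version": __version__,
            "numpy_version": np_mod.__version__,
            "scipy_version": sp_mod.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config.raw, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "n_constructs": len(library),
            "n_hits_main": len(hits_main),
            "n_hits_counter": None if hits_counter is None else len(hits_counter),
            "n_final_hits": len(final),
        }
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        incomplete.write_text(f"failed at stage: {stage}\n{exc}\n")
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    incomplete.unlink(missing_ok=True)
    logger.info("pipeline complete: %d final hits", len(final))
    return RunReport(
        outdir=outdir,
        library=library,
        counts=counts,
        differential=diff,
        hit_calls=calls,
        hits_main=hits_main,
        hits_counter=hits_counter,
        final_hits=final,
        enrichment=enrichment_table,
        manifest=manifest,
    )
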