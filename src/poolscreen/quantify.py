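"""Barcode quantification: FASTQ reads -> integer shRNA x sample counts.

Reads carry the library barcode at a fixed offset inside a constant flank, so
assignment is direct mismatch-tolerant matching against the known barcode set
rather than full alignment.  A read is assigned iff exactly one barcode of the
sample's pool lies within ``max_mismatches`` Hamming distance of the read
segment at the barcode offset; everything else (no match, ambiguous match,
read too short) increments the column's unassigned counter, so
``assigned + unassigned == total`` holds for every sample.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import FLANK_5P, LibraryDesign, min_pairwise_distance_ok

__all__ = [
    "CountMatrix",
    "BarcodeIndex",
    "FastqFormatError",
    "DEFAULT_BARCODE_OFFSET",
    "quantify",
    "merge_columns",
    "concat_pools",
    "write_counts_tsv",
    "read_counts_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_BARCODE_OFFSET = len(FLANK_5P)

CONDITIONS = ("reference", "treated")

SAMPLE_FIELDS = ["pool", "condition", "replicate", "unassigned_reads", "total_reads"]


class FastqFormatError(ValueError):
    """Unreadable or truncated FASTQ record, reported with its record index."""


@dataclass
class CountMatrix:
    """Integer shRNA x sample counts plus per-sample metadata.

    ``counts``: DataFrame, rows indexed by shrna_id (fixed library order),
    columns sample_id.  ``samples``: DataFrame indexed by sample_id with
    columns ``pool``, ``condition``, ``replicate``, ``unassigned_reads``,
    ``total_reads``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample metadata disagree")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        bad = [c for c in self.samples["condition"] if c not in CONDITIONS]
        if bad:
            raise ValueError(f"unknown conditions {sorted(set(bad))}; expected {CONDITIONS}")
        assigned = self.counts.sum(axis=0)
        conserved = assigned + self.samples["unassigned_reads"] == self.samples["total_reads"]
        if not conserved.all():
            broken = list(self.samples.index[~conserved])
            raise ValueError(f"read conservation violated for samples {broken}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shrna_ids(self) -> pd.Index:
        return self.counts.index

    def column(self, sample_id: str) -> pd.Series:
        return self.counts[sample_id]

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.samples["condition"] == condition).to_numpy()

    def pool_block(self, pool_index: int, library: LibraryDesign) -> "CountMatrix":
        """Restrict to one pool's shRNAs and samples."""
        rows = library.pool_constructs(pool_index)["shrna_id"]
        cols = self.samples.index[self.samples["pool"] == pool_index]
        if len(cols) == 0:
            raise ValueError(f"no samples for pool {pool_index}")
        return CountMatrix(self.counts.loc[rows, cols].copy(), self.samples.loc[cols].copy())

    def pools(self) -> list[int]:
        return sorted(self.samples["pool"].unique())


class BarcodeIndex:
    """Hash index of one pool's barcodes and (optionally) their 1-mismatch
    neighborhoods.  With pairwise barcode distance >= 3 the neighborhoods are
    disjoint, so lookup is exact and unambiguous; overlapping neighborhoods
    (distance-violating libraries) are marked ambiguous and never assigned.
    """

    _AMBIG = object()

    def __init__(self, barcodes: Sequence[str], shrna_ids: Sequence[str], max_mismatches: int):
        if max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        self.barcode_length = len(barcodes[0])
        self.max_mismatches = max_mismatches
        self._exact: dict[str, object] = {}
        for bc, sid in zip(barcodes, shrna_ids):
            self._exact[bc] = self._AMBIG if bc in self._exact else sid
        self._variants: dict[str, object] = {}
        if max_mismatches == 1:
            for bc, sid in zip(barcodes, shrna_ids):
                for i in range(len(bc)):
                    for base in "ACGT":
                        if base == bc[i]:
                            continue
                        var = bc[:i] + base + bc[i + 1 :]
                        if var in self._variants and self._variants[var] is not sid:
                            self._variants[var] = self._AMBIG
                        else:
                            self._variants[var] = sid

    def lookup(self, segment: str) -> str | None:
        hit = self._exact.get(segment)
        if hit is None and self.max_mismatches == 1:
            hit = self._variants.get(segment)
        return None if hit is None or hit is self._AMBIG else hit  # type: ignore[return-value]

    def is_near(self, segment: str) -> bool:
        """True if segment is within max(1, max_mismatches) of any barcode."""
        if segment in self._exact:
            return True
        if self._variants:
            return segment in self._variants
        # even at max_mismatches=0, treat 1-neighborhoods as near (spike-in rejection)
        for i in range(len(segment)):
            for base in "ACGT":
                var = segment[:i] + base + segment[i + 1 :]
                if var in self._exact:
                    return True
        return False


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(path: str | Path):
    """Yield (index, sequence); wrap parser errors with the record index."""
    idx = 0
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(f"bad FASTQ record at index {idx}: {exc}") from exc
            yield idx, rec[1]
            idx += 1


def quantify(
    fastq_path: str | Path,
    library: LibraryDesign,
    pool_index: int,
    max_mismatches: int = 0,
    barcode_offset: int = DEFAULT_BARCODE_OFFSET,
    sample_id: str | None = None,
    condition: str = "reference",
    replicate: int = 1,
    offset_scan: bool = False,
) -> CountMatrix:
    """Count barcode-assigned reads of one FASTQ sample against one pool.

    ``max_mismatches=1`` is accepted only when the pool's barcodes keep
    pairwise Hamming distance >= 3, which makes single-mismatch assignment
    unambiguous.  ``offset_scan`` tries every read offset and requires a
    unique construct hit (for reads whose barcode position is unknown).
    """
    block = library.pool_constructs(pool_index)
    barcodes = block["barcode"].tolist()
    if max_mismatches == 1 and not min_pairwise_distance_ok(barcodes, 3):
        raise ValueError(
            "max_mismatches=1 requires pairwise barcode Hamming distance >= 3"
        )
    index = BarcodeIndex(barcodes, block["shrna_id"].tolist(), max_mismatches)
    L = index.barcode_length
    counts: dict[str, int] = dict.fromkeys(block["shrna_id"], 0)
    unassigned = 0
    total = 0
    short_reads = 0
    for _, seq in _iter_fastq(fastq_path):
        total += 1
        if offset_scan:
            hits = {
                h
                for off in range(len(seq) - L + 1)
                if (h := index.lookup(seq[off : off + L])) is not None
            }
            hit = hits.pop() if len(hits) == 1 else None
        else:
            if len(seq) < barcode_offset + L:
                short_reads += 1
                unassigned += 1
                continue
            hit = index.lookup(seq[barcode_offset : barcode_offset + L])
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
    if short_reads:
        logger.warning(
            "%s: %d reads shorter than offset+barcode length counted as unassigned",
            fastq_path,
            short_reads,
        )
    if sample_id is None:
        sample_id = Path(fastq_path).name.removesuffix(".gz").removesuffix(".fastq")
    counts_df = pd.DataFrame({sample_id: pd.Series(counts, dtype=int)})
    counts_df = counts_df.loc[block["shrna_id"]]
    samples = pd.DataFrame(
        {
            "pool": [pool_index],
            "condition": [condition],
            "replicate": [replicate],
            "unassigned_reads": [unassigned],
            "total_reads": [total],
        },
        index=pd.Index([sample_id], name="sample_id"),
    )
    return CountMatrix(counts_df, samples)


def merge_columns(columns: Iterable[CountMatrix]) -> CountMatrix:
    """Merge single-pool count columns into one matrix in canonical sample order.

    All inputs must share the same row order and pool; duplicate sample ids
    are an error.  Canonical order is (condition, replicate, sample_id), so the
    result is invariant to input order.
    """
    cols = list(columns)
    if not cols:
        raise ValueError("no columns to merge")
    ref_rows = cols[0].counts.index
    for c in cols[1:]:
        if not c.counts.index.equals(ref_rows):
            raise ValueError("mismatched row sets between columns")
    pools = {int(p) for c in cols for p in c.samples["pool"]}
    if len(pools) != 1:
        raise ValueError(f"columns span multiple pools: {sorted(pools)}")
    counts = pd.concat([c.counts for c in cols], axis=1)
    samples = pd.concat([c.samples for c in cols], axis=0)
    if samples.index.duplicated().any():
        dupes = sorted(set(samples.index[samples.index.duplicated()]))
        raise ValueError(f"duplicate sample_ids: {dupes}")
    order = samples.sort_values(["condition", "replicate"], kind="stable").index
    samples = samples.loc[order]
    return CountMatrix(counts[order], samples)


def concat_pools(matrices: Iterable[CountMatrix], library: LibraryDesign) -> CountMatrix:
    """Stack per-pool matrices into one library-wide matrix (zeros off-pool)."""
    mats = list(matrices)
    all_rows = pd.Index(library.constructs["shrna_id"])
    counts = pd.DataFrame(0, index=all_rows, columns=[], dtype=int)
    samples = []
    for m in mats:
        block = m.counts.reindex(all_rows, fill_value=0).astype(int)
        counts = pd.concat([counts, block], axis=1)
        samples.append(m.samples)
    sample_df = pd.concat(samples, axis=0)
    if sample_df.index.duplicated().any():
        raise ValueError("duplicate sample_ids across pools")
    return CountMatrix(counts, sample_df)


# ---------------------------------------------------------------------------
# Count matrix TSV: '#'-prefixed per-sample metadata lines, then the table.
# ---------------------------------------------------------------------------


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as out:
        for sid, row in matrix.samples.iterrows():
            out.write(
                "#sample\t%s\t%d\t%s\t%d\t%d\t%d\n"
                % (
                    sid,
                    row["pool"],
                    row["condition"],
                    row["replicate"],
                    row["unassigned_reads"],
                    row["total_reads"],
                )
            )
        matrix.counts.rename_axis("shrna_id").to_csv(out, sep="\t")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    meta: dict[str, list] = {}
    with open(path) as handle:
        lines = handle.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        parts = line.rstrip("\n").split("\t")
        if parts[0] != "#sample" or len(parts) != 7:
            raise ValueError(f"bad metadata line in {path}: {line!r}")
        meta[parts[1]] = [int(parts[2]), parts[3], int(parts[4]), int(parts[5]), int(parts[6])]
    from io import StringIO

    counts = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col="shrna_id")
    counts = counts.astype(int)
    samples = pd.DataFrame.from_dict(meta, orient="index", columns=SAMPLE_FIELDS)
    samples.index.name = "sample_id"
    return CountMatrix(counts, samples.loc[counts.columns])
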