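"""Pooled shRNA library construction and screen-design arithmetic.

A pooled knockdown library assigns each target gene a handful of hairpin
constructs, each identified by a unique barcode and placed in one of several
sub-library pools so that no gene has two constructs in the same pool.  This
module builds such libraries reproducibly (for simulation and testing),
validates their structural invariants, reads and writes the manifest formats
used by the rest of the pipeline, and performs the bench arithmetic that sizes
a screen (cells to seed at a given multiplicity of infection, genomic DNA per
specimen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LibraryConstraintError",
    "ShRNAConstruct",
    "LibraryDesign",
    "DesignBudget",
    "design_library",
    "validate_library",
    "coverage_calculator",
    "min_pairwise_distance_ok",
    "construct_sequence",
    "write_manifest",
    "read_manifest",
    "write_pool_fasta",
    "FLANK_5P",
    "LOOP_3P",
]

# Constant sequence context flanking the barcode in every construct, modeled on
# the mir-30 scaffold of GIPZ hairpins.  Reads carry the barcode at a fixed
# offset equal to len(FLANK_5P).
FLANK_5P = "TGCTGTTGACAGTGAGCG"
LOOP_3P = "TAGTGAAGCCACAGATGTATGCCTACTGCCTCGGACTTCAAGGGGCTA"

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class LibraryConstraintError(ValueError):
    """An infeasible or violated library design constraint, named explicitly."""


@dataclass(frozen=True)
class ShRNAConstruct:
    """One hairpin construct: barcode-tagged knockdown reagent for one gene."""

    shrna_id: str
    gene_id: str
    pool_index: int
    barcode: str


@dataclass
class LibraryDesign:
    """A pooled library: gene -> shRNA -> pool -> barcode assignments.

    ``constructs`` is a DataFrame with columns ``shrna_id``, ``gene_id``,
    ``pool``, ``barcode`` in a fixed, reproducible row order.
    """

    constructs: pd.DataFrame
    n_pools: int
    barcode_length: int
    seed: int | None = None

    def __post_init__(self) -> None:
        required = ["shrna_id", "gene_id", "pool", "barcode"]
        missing = [c for c in required if c not in self.constructs.columns]
        if missing:
            raise LibraryConstraintError(f"manifest missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.constructs)

    def iter_constructs(self) -> Iterator[ShRNAConstruct]:
        for row in self.constructs.itertuples(index=False):
            yield ShRNAConstruct(row.shrna_id, row.gene_id, int(row.pool), row.barcode)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.constructs["gene_id"].unique())

    def pool_constructs(self, pool_index: int) -> pd.DataFrame:
        block = self.constructs[self.constructs["pool"] == pool_index]
        if block.empty:
            raise LibraryConstraintError(f"pool {pool_index} has no constructs")
        return block

    def pool_sizes(self) -> pd.Series:
        return self.constructs["pool"].value_counts().sort_index()

    def gene_of(self) -> pd.Series:
        """shrna_id -> gene_id mapping."""
        return self.constructs.set_index("shrna_id")["gene_id"]


@dataclass(frozen=True)
class DesignBudget:
    """Cells and genomic DNA needed to keep every construct represented."""

    n_shrnas: int
    coverage: int
    moi: float
    cells_to_seed: int
    gdna_per_replicate_ng: float
    n_pcr_replicates: int
    gdna_total_ug: float


# ---------------------------------------------------------------------------
# Barcode generation: uniform random sequences with pairwise Hamming distance
# >= min_distance, enforced by rejection.  Two sequences at distance <= d-1
# must agree on at least one of d contiguous chunks (pigeonhole), so chunk
# hashing finds every candidate collision without an all-pairs scan.
# ---------------------------------------------------------------------------


def _random_distinct_barcodes(
    n: int, length: int, rng: np.random.Generator, min_distance: int = 3
) -> np.ndarray:
    if 4**length < 4 * n:
        raise LibraryConstraintError(
            f"barcode_length {length} too short for {n} barcodes at distance {min_distance}"
        )
    bounds = np.linspace(0, length, min_distance + 1).astype(int)
    chunks = [slice(bounds[i], bounds[i + 1]) for i in range(min_distance)]
    maps: list[dict[bytes, list[int]]] = [dict() for _ in chunks]
    accepted = np.empty((n, length), dtype=np.uint8)
    count = 0
    while count < n:
        batch = rng.integers(0, 4, size=(max(1024, n - count), length), dtype=np.uint8)
        for row in batch:
            if count == n:
                break
            candidates: set[int] = set()
            keys = [row[sl].tobytes() for sl in chunks]
            for m, key in zip(maps, keys):
                candidates.update(m.get(key, ()))
            ok = True
            for idx in candidates:
                if np.count_nonzero(accepted[idx] != row) < min_distance:
                    ok = False
                    break
            if not ok:
                continue
            accepted[count] = row
            for m, key in zip(maps, keys):
                m.setdefault(key, []).append(count)
            count += 1
    return accepted


def _decode(rows: np.ndarray) -> list[str]:
    return [bytes(BASES[r]).decode() for r in rows]


def min_pairwise_distance_ok(barcodes: list[str], min_distance: int) -> bool:
    """True iff every pair of barcodes differs at >= min_distance positions.

    Uses the same chunk-pigeonhole argument as the generator, so it scales to
    full library size.
    """
    if not barcodes:
        return True
    length = len(barcodes[0])
    if any(len(b) != length for b in barcodes):
        return False
    arr = np.frombuffer("".join(barcodes).encode(), dtype=np.uint8).reshape(
        len(barcodes), length
    )
    bounds = np.linspace(0, length, min_distance + 1).astype(int)
    chunks = [slice(bounds[i], bounds[i + 1]) for i in range(min_distance)]
    maps: list[dict[bytes, list[int]]] = [dict() for _ in chunks]
    for i, row in enumerate(arr):
        candidates: set[int] = set()
        keys = [row[sl].tobytes() for sl in chunks]
        for m, key in zip(maps, keys):
            candidates.update(m.get(key, ()))
        for j in candidates:
            if np.count_nonzero(arr[j] != row) < min_distance:
                return False
        for m, key in zip(maps, keys):
            m.setdefault(key, []).append(i)
    return True


# ---------------------------------------------------------------------------
# Library design
# ---------------------------------------------------------------------------


def _per_gene_counts(
    n_genes: int,
    lo: int,
    hi: int,
    total: int | None,
    n_pools: int,
    equal_pools: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    counts = rng.integers(lo, hi + 1, size=n_genes)
    if total is None and equal_pools:
        # choose the achievable multiple of n_pools closest to the draw
        total = int(round(counts.sum() / n_pools)) * n_pools
        total = int(np.clip(total, math.ceil(n_genes * lo / n_pools) * n_pools,
                            (n_genes * hi // n_pools) * n_pools))
    if total is not None:
        while counts.sum() != total:
            diff = int(total - counts.sum())
            if diff > 0:
                room = np.flatnonzero(counts < hi)
                take = rng.choice(room, size=min(diff, room.size), replace=False)
                counts[take] += 1
            else:
                room = np.flatnonzero(counts > lo)
                take = rng.choice(room, size=min(-diff, room.size), replace=False)
                counts[take] -= 1
    return counts


def design_library(
    n_genes: int,
    per_gene_min: int = 4,
    per_gene_max: int = 7,
    n_pools: int = 10,
    equal_pools: bool = False,
    total_constructs: int | None = None,
    barcode_length: int = 22,
    seed: int = 0,
    min_barcode_distance: int = 3,
) -> LibraryDesign:
    """Design a pooled library with per-gene construct counts in a fixed range.

    Each gene receives between ``per_gene_min`` and ``per_gene_max`` constructs,
    no two in the same pool.  Pool assignment fills the currently least-loaded
    pools first, which keeps pool sizes within one of each other and, when
    ``equal_pools`` is set and the total is divisible by ``n_pools``, exactly
    equal.  Barcodes are uniform random sequences kept at pairwise Hamming
    distance >= ``min_barcode_distance`` so that single-mismatch read
    assignment is unambiguous by construction.

    Raises
    ------
    LibraryConstraintError
        If the constraint set is infeasible (range outside pool count,
        total outside the per-gene range, indivisible equal-pool total).
    """
    if n_genes < 1:
        raise LibraryConstraintError("n_genes must be >= 1")
    if per_gene_min < 1:
        raise LibraryConstraintError("per_gene_min must be >= 1")
    if per_gene_max < per_gene_min:
        raise LibraryConstraintError("per_gene_max must be >= per_gene_min")
    if per_gene_max > n_pools:
        raise LibraryConstraintError(
            f"per_gene_max ({per_gene_max}) exceeds n_pools ({n_pools}): "
            "a gene's constructs must occupy distinct pools"
        )
    if total_constructs is not None:
        if not n_genes * per_gene_min <= total_constructs <= n_genes * per_gene_max:
            raise LibraryConstraintError(
                f"total_constructs ({total_constructs}) outside feasible range "
                f"[{n_genes * per_gene_min}, {n_genes * per_gene_max}]"
            )
        if equal_pools and total_constructs % n_pools != 0:
            raise LibraryConstraintError(
                f"equal_pools requires total_constructs ({total_constructs}) "
                f"divisible by n_pools ({n_pools})"
            )

    rng = np.random.default_rng(seed)
    counts = _per_gene_counts(
        n_genes, per_gene_min, per_gene_max, total_constructs, n_pools, equal_pools, rng
    )
    total = int(counts.sum())

    # least-filled-first pool assignment; random tie-breaking among equal fills
    fills = np.zeros(n_pools, dtype=int)
    width = len(str(n_genes - 1))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]
    pools_col = np.empty(total, dtype=int)
    gene_col: list[str] = []
    shrna_col: list[str] = []
    pos = 0
    for gid, k in zip(gene_ids, counts):
        order = rng.permutation(n_pools)
        order = order[np.argsort(fills[order], kind="stable")]
        chosen = np.sort(order[:k])
        fills[chosen] += 1
        pools_col[pos : pos + k] = chosen + 1
        gene_col.extend([gid] * int(k))
        shrna_col.extend(f"{gid}_sh{j + 1}" for j in range(int(k)))
        pos += k

    barcodes = _decode(
        _random_distinct_barcodes(total, barcode_length, rng, min_barcode_distance)
    )
    frame = pd.DataFrame(
        {
            "shrna_id": shrna_col,
            "gene_id": gene_col,
            "pool": pools_col,
            "barcode": barcodes,
        }
    )
    design = LibraryDesign(frame, n_pools=n_pools, barcode_length=barcode_length, seed=seed)
    if equal_pools:
        sizes = design.pool_sizes()
        if sizes.nunique() != 1:
            raise LibraryConstraintError(
                f"equal_pools unsatisfied after assignment: pool sizes {sizes.tolist()}"
            )
    return design


def validate_library(
    design: LibraryDesign,
    per_gene_min: int | None = None,
    per_gene_max: int | None = None,
    equal_pools: bool = False,
    min_barcode_distance: int | None = None,
) -> None:
    """Re-check every structural invariant; raise LibraryConstraintError on failure."""
    df = design.constructs
    if df.empty:
        raise LibraryConstraintError("library is empty")
    if df["barcode"].duplicated().any():
        raise LibraryConstraintError("duplicate barcodes in library")
    if df["shrna_id"].duplicated().any():
        raise LibraryConstraintError("duplicate shrna_ids in library")
    if (df["gene_id"].astype(str) == "").any():
        raise LibraryConstraintError("empty gene_id")
    if not df["pool"].between(1, design.n_pools).all():
        raise LibraryConstraintError("pool index out of range")
    if (df["barcode"].str.len() != design.barcode_length).any():
        raise LibraryConstraintError("barcode length mismatch")
    if not df["barcode"].str.fullmatch("[ACGT]+").all():
        raise LibraryConstraintError("barcode contains non-ACGT characters")
    per_gene = df.groupby("gene_id", sort=False).size()
    if per_gene_min is not None and (per_gene < per_gene_min).any():
        raise LibraryConstraintError("a gene has fewer constructs than per_gene_min")
    if per_gene_max is not None and (per_gene > per_gene_max).any():
        raise LibraryConstraintError("a gene has more constructs than per_gene_max")
    if df.duplicated(subset=["gene_id", "pool"]).any():
        raise LibraryConstraintError("a gene has two constructs in the same pool")
    if equal_pools and design.pool_sizes().nunique() != 1:
        raise LibraryConstraintError("pools are not equally sized")
    if min_barcode_distance is not None and not min_pairwise_distance_ok(
        df["barcode"].tolist(), min_barcode_distance
    ):
        raise LibraryConstraintError(
            f"pairwise barcode Hamming distance < {min_barcode_distance}"
        )


# ---------------------------------------------------------------------------
# Screen-design arithmetic
# ---------------------------------------------------------------------------


def coverage_calculator(
    n_shrnas: int,
    coverage: int = 1000,
    moi: float = 0.3,
    gdna_per_replicate_ng: float = 825.0,
    n_pcr_replicates: int = 8,
) -> DesignBudget:
    """Cells to seed and gDNA budget for a pooled screen.

    ``cells_to_seed = ceil(n_shrnas * coverage / moi)`` keeps every construct at
    the requested copy number after transduction at the given multiplicity of
    infection; the gDNA total is the PCR input summed over technical replicates
    (ng -> ug).
    """
    if moi <= 0:
        raise ValueError("moi must be > 0")
    if min(n_shrnas, coverage, n_pcr_replicates) < 0 or gdna_per_replicate_ng < 0:
        raise ValueError("inputs must be non-negative")
    cells = math.ceil(n_shrnas * coverage / moi)
    gdna_total = n_pcr_replicates * gdna_per_replicate_ng / 1000.0
    return DesignBudget(
        n_shrnas=n_shrnas,
        coverage=coverage,
        moi=moi,
        cells_to_seed=cells,
        gdna_per_replicate_ng=gdna_per_replicate_ng,
        n_pcr_replicates=n_pcr_replicates,
        gdna_total_ug=gdna_total,
    )


# ---------------------------------------------------------------------------
# Manifest and reference I/O
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["shrna_id", "gene_id", "pool", "barcode"]


def construct_sequence(barcode: str, length: int | None = None) -> str:
    """Reference sequence of one construct: 5' flank, barcode, 3' scaffold.

    Padded (by cycling the 3' scaffold) or truncated to ``length`` when given;
    the barcode always sits at offset ``len(FLANK_5P)``.
    """
    seq = FLANK_5P + barcode
    pad = LOOP_3P
    target = length if length is not None else len(seq) + len(LOOP_3P)
    while len(seq) < target:
        seq += pad
    return seq[:target]


def write_manifest(design: LibraryDesign, path: str | Path) -> None:
    design.constructs[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path, n_pools: int | None = None) -> LibraryDesign:
    df = pd.read_csv(path, sep="\t", dtype={"shrna_id": str, "gene_id": str, "barcode": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryConstraintError(f"manifest {path} missing columns: {missing}")
    lengths = df["barcode"].str.len().unique()
    if len(lengths) != 1:
        raise LibraryConstraintError("manifest barcodes have mixed lengths")
    return LibraryDesign(
        df[MANIFEST_COLUMNS].copy(),
        n_pools=int(n_pools if n_pools is not None else df["pool"].max()),
        barcode_length=int(lengths[0]),
        seed=None,
    )


def write_pool_fasta(
    design: LibraryDesign, pool_index: int, path: str | Path, length: int | None = None
) -> None:
    """Write one pool's construct reference sequences as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    block = design.pool_constructs(pool_index)
    records = [
        SeqRecord(
            Seq(construct_sequence(row.barcode, length)),
            id=row.shrna_id,
            description=f"gene={row.gene_id} pool={row.pool}",
        )
        for row in block.itertuples(index=False)
    ]
    seqio_write(records, str(path), "fasta")
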