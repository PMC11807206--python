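"""Gene-level hit calling from per-shRNA statistics, and counter-screen subtraction.

A gene is a hit when the conjunction of four rules holds on its constructs'
differential results: at least ``min_enriched`` significantly enriched shRNAs
(FDR below threshold, positive log2FC); those enriched shRNAs spread over at
least ``min_enriched`` distinct pools (when required); at least one enriched
shRNA at or above the log2FC threshold (more than two-fold by default); and no
significantly depleted shRNA for the gene (when required).  Every violated
rule is recorded, not just the first, so calls are auditable.  The
counter-screen subtraction removes genes that also score under a generic
lethal pressure, leaving treatment-specific hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import LibraryDesign

__all__ = [
    "HitCriteria",
    "GeneHitCall",
    "call_hits",
    "hit_gene_set",
    "subtract_counter_screen",
    "REASON_TOO_FEW_ENRICHED",
    "REASON_NOT_DISTINCT_POOLS",
    "REASON_LFC_BELOW_THRESHOLD",
    "REASON_DEPLETED_PRESENT",
    "REASON_INSUFFICIENT_CONSTRUCTS",
]

REASON_TOO_FEW_ENRICHED = "too_few_enriched"
REASON_NOT_DISTINCT_POOLS = "not_distinct_pools"
REASON_LFC_BELOW_THRESHOLD = "max_lfc_below_threshold"
REASON_DEPLETED_PRESENT = "depleted_shrna_present"
REASON_INSUFFICIENT_CONSTRUCTS = "insufficient_constructs"


@dataclass(frozen=True)
class HitCriteria:
    """Thresholds of the gene-level selection rule."""

    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0
    min_enriched: int = 2
    require_distinct_pools: bool = True
    exclude_if_any_depleted: bool = True

    def __post_init__(self) -> None:
        if self.fdr_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_enriched < 1:
            raise ValueError("min_enriched must be >= 1")


@dataclass(frozen=True)
class GeneHitCall:
    gene_id: str
    n_enriched: int
    enriched_pools: frozenset[int]
    max_log2fc_enriched: float
    n_depleted: int
    is_hit: bool
    failure_reasons: tuple[str, ...]


def call_hits(
    results: pd.DataFrame,
    library: LibraryDesign,
    criteria: HitCriteria = HitCriteria(),
) -> pd.DataFrame:
    """Apply the hit rule to every gene in the library.

    ``results`` is a per-shRNA differential table (columns ``shrna_id``,
    ``gene_id``, ``pool``, ``log2fc``, ``fdr``).  Returns one row per library
    gene with audit fields and the full list of violated rules.  A result row
    referencing an shRNA absent from the library is an error.
    """
    lib = library.constructs
    unknown = set(results["shrna_id"]) - set(lib["shrna_id"])
    if unknown:
        raise KeyError(f"results reference unknown shRNAs: {sorted(unknown)[:5]}")

    res = results.copy()
    res["enriched"] = (res["fdr"] < criteria.fdr_threshold) & (res["log2fc"] > 0)
    res["depleted"] = (res["fdr"] < criteria.fdr_threshold) & (res["log2fc"] < 0)

    lib_counts = lib.groupby("gene_id", sort=False).size()
    rows = []
    grouped = dict(list(res.groupby("gene_id", sort=False)))
    for gene in lib["gene_id"].unique():
        sub = grouped.get(gene)
        if sub is None:
            sub = res.iloc[0:0]
        enr = sub[sub["enriched"]]
        n_enriched = len(enr)
        pools = frozenset(int(p) for p in enr["pool"])
        max_lfc = float(enr["log2fc"].max()) if n_enriched else float("-inf")
        n_depleted = int(sub["depleted"].sum())

        reasons: list[str] = []
        if int(lib_counts.get(gene, 0)) < criteria.min_enriched:
            reasons.append(REASON_INSUFFICIENT_CONSTRUCTS)
        if n_enriched < criteria.min_enriched:
            reasons.append(REASON_TOO_FEW_ENRICHED)
        if criteria.require_distinct_pools and len(pools) < criteria.min_enriched:
            reasons.append(REASON_NOT_DISTINCT_POOLS)
        if not (n_enriched and max_lfc >= criteria.lfc_threshold):
            reasons.append(REASON_LFC_BELOW_THRESHOLD)
        if criteria.exclude_if_any_depleted and n_depleted > 0:
            reasons.append(REASON_DEPLETED_PRESENT)

        rows.append(
            {
                "gene_id": gene,
                "n_enriched": n_enriched,
                "enriched_pools": tuple(sorted(pools)),
                "max_log2fc_enriched": max_lfc if n_enriched else np.nan,
                "n_depleted": n_depleted,
                "is_hit": not reasons,
                "failure_reasons": tuple(reasons),
            }
        )
    return pd.DataFrame(rows)


def hit_gene_set(calls: pd.DataFrame) -> set[str]:
    return set(calls.loc[calls["is_hit"], "gene_id"])


def subtract_counter_screen(hits_main: set[str], hits_counter: set[str]) -> list[str]:
    """Treatment-specific hits: main hits minus counter-screen hits, sorted
    for deterministic serialization."""
    return sorted(set(hits_main) - set(hits_counter))
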