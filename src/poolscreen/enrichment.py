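"""Gene-set over-representation of the final hit list.

For each gene set, the overlap k between the hit list (size n) and the set's
members restricted to the universe (size K, universe size N) is scored with
the exact hypergeometric upper tail P(X >= k); BH FDR is applied across all
supplied terms with significance at FDR < 0.1 by default.  Gene sets are read
from GMT files (term, description, members per tab-separated line).  An
EASE-style conservative variant (scoring k-1 successes) is available behind a
flag for comparability with DAVID-like tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust

__all__ = ["GeneSet", "read_gmt", "write_gmt", "enrich"]

RESULT_COLUMNS = [
    "term_id",
    "term_name",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "fdr",
    "significant",
]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id} has no members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln + 1}: GMT line needs id, name, >=1 member")
            sets.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as out:
        for gs in gene_sets:
            out.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.members)]) + "\n")


def enrich(
    hits: set[str],
    gene_sets: Sequence[GeneSet],
    universe: set[str],
    fdr_threshold: float = 0.1,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    Members are intersected with the universe before testing; terms with empty
    intersection are reported with k = 0 and p = 1.  With ``ease`` the
    conservative EASE score (upper tail at k-1 overlapping genes) is used.
    Rows are sorted by p-value then term_id.
    """
    stray = sorted(hits - universe)
    if stray:
        raise ValueError(f"hit genes outside the universe: {stray}")
    N = len(universe)
    n = len(hits)
    rows = []
    for gs in gene_sets:
        members = gs.members & universe
        K = len(members)
        k = len(hits & members)
        k_score = max(k - 1, 0) if ease else k
        p = 1.0 if k_score == 0 else float(hypergeom.sf(k_score - 1, N, K, n))
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-2])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
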