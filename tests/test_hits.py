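"""Gene-level hit calling: rule examples, brute-force oracle, monotonicity,
and counter-screen subtraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poolscreen as ps
from poolscreen.hits import (
    REASON_DEPLETED_PRESENT,
    REASON_LFC_BELOW_THRESHOLD,
    REASON_NOT_DISTINCT_POOLS,
    REASON_TOO_FEW_ENRICHED,
)


def library_from(rows):
    """LibraryDesign from (shrna_id, gene_id, pool) rows; barcodes synthetic."""
    df = pd.DataFrame(rows, columns=["shrna_id", "gene_id", "pool"])
    df["barcode"] = [
        "".join("ACGT"[(i >> (2 * j)) & 3] for j in range(8)) for i in range(len(df))
    ]
    return ps.LibraryDesign(df, n_pools=int(df["pool"].max()), barcode_length=8)


def results_from(rows):
    """Differential table from (shrna_id, gene_id, pool, log2fc, fdr) rows."""
    df = pd.DataFrame(rows, columns=["shrna_id", "gene_id", "pool", "log2fc", "fdr"])
    df["p_value"] = df["fdr"]
    return df


def test_two_enriched_distinct_pools_is_hit():
    lib = library_from([("a1", "A", 1), ("a2", "A", 3)])
    res = results_from([("a1", "A", 1, 1.5, 0.01), ("a2", "A", 3, 0.6, 0.03)])
    calls = ps.call_hits(res, lib)
    assert calls.loc[0, "is_hit"]
    assert calls.loc[0, "n_enriched"] == 2
    assert calls.loc[0, "enriched_pools"] == (1, 3)


def test_same_pool_enrichment_is_rejected():
    lib = library_from([("a1", "A", 2), ("a2", "A", 3)])
    res = results_from([("a1", "A", 2, 1.5, 0.01), ("a2", "A", 2, 1.2, 0.02)])
    calls = ps.call_hits(res, lib)
    assert not calls.loc[0, "is_hit"]
    assert REASON_NOT_DISTINCT_POOLS in calls.loc[0, "failure_reasons"]


def test_lfc_threshold_and_depletion_rules():
    lib = library_from(
        [("a1", "A", 1), ("a2", "A", 2), ("b1", "B", 1), ("b2", "B", 2), ("b3", "B", 3)]
    )
    res = results_from(
        [
            ("a1", "A", 1, 0.8, 0.01),
            ("a2", "A", 2, 0.9, 0.02),
            ("b1", "B", 1, 1.2, 0.01),
            ("b2", "B", 2, 1.1, 0.02),
            ("b3", "B", 3, -0.4, 0.01),
        ]
    )
    calls = ps.call_hits(res, lib).set_index("gene_id")
    assert not calls.loc["A", "is_hit"]
    assert calls.loc["A", "failure_reasons"] == (REASON_LFC_BELOW_THRESHOLD,)
    assert not calls.loc["B", "is_hit"]
    assert calls.loc["B", "failure_reasons"] == (REASON_DEPLETED_PRESENT,)


def test_dmt1_style_two_shrna_hit():
    # a gene with exactly two enriched shRNAs in different pools, one above
    # the two-fold mark, and nothing depleted: the canonical minimal hit
    lib = library_from(
        [("d1", "DMT1", 2), ("d2", "DMT1", 7), ("d3", "DMT1", 9), ("n1", "OTHER", 2)]
    )
    res = results_from(
        [
            ("d1", "DMT1", 2, 1.8, 0.004),
            ("d2", "DMT1", 7, 0.7, 0.03),
            ("d3", "DMT1", 9, 0.2, 0.8),
            ("n1", "OTHER", 2, 0.1, 0.9),
        ]
    )
    calls = ps.call_hits(res, lib).set_index("gene_id")
    assert calls.loc["DMT1", "is_hit"]
    assert calls.loc["DMT1", "n_enriched"] == 2
    assert not calls.loc["OTHER", "is_hit"]


def test_unknown_shrna_rejected():
    lib = library_from([("a1", "A", 1), ("a2", "A", 2)])
    res = results_from([("zz", "A", 1, 1.0, 0.01)])
    with pytest.raises(KeyError, match="zz"):
        ps.call_hits(res, lib)


# ------------------------------------------------------------------ oracle


def hit_oracle(results, library, criteria):
    """Independent enumeration of the rule conjunction, gene by gene."""
    hits = set()
    lib_counts = library.constructs.groupby("gene_id").size()
    for gene in library.constructs["gene_id"].unique():
        sub = results[results["gene_id"] == gene]
        enr = [
            (int(r.pool), float(r.log2fc))
            for r in sub.itertuples()
            if r.fdr < criteria.fdr_threshold and r.log2fc > 0
        ]
        dep = [
            r for r in sub.itertuples() if r.fdr < criteria.fdr_threshold and r.log2fc < 0
        ]
        ok = len(enr) >= criteria.min_enriched
        if criteria.require_distinct_pools:
            ok = ok and len({p for p, _ in enr}) >= criteria.min_enriched
        ok = ok and any(l >= criteria.lfc_threshold for _, l in enr)
        if criteria.exclude_if_any_depleted:
            ok = ok and not dep
        ok = ok and int(lib_counts[gene]) >= criteria.min_enriched
        if ok:
            hits.add(gene)
    return hits


@st.composite
def random_screen_table(draw):
    n_genes = draw(st.integers(1, 6))
    n_pools = 4
    lib_rows, res_rows = [], []
    for g in range(n_genes):
        gene = f"G{g}"
        k = draw(st.integers(1, n_pools))
        pools = draw(
            st.permutations(list(range(1, n_pools + 1))).map(lambda p: p[:k])
        )
        for j, pool in enumerate(pools):
            sid = f"{gene}_sh{j}"
            lib_rows.append((sid, gene, pool))
            lfc = draw(st.floats(-3, 3, allow_nan=False))
            fdr = draw(st.floats(0.001, 1.0))
            res_rows.append((sid, gene, pool, lfc, fdr))
    return library_from(lib_rows), results_from(res_rows)


@settings(max_examples=80, deadline=None)
@given(random_screen_table(), st.booleans(), st.booleans())
def test_call_hits_matches_enumeration_oracle(table, distinct, exclude_depleted):
    lib, res = table
    criteria = ps.HitCriteria(
        fdr_threshold=0.05,
        lfc_threshold=1.0,
        min_enriched=2,
        require_distinct_pools=distinct,
        exclude_if_any_depleted=exclude_depleted,
    )
    calls = ps.call_hits(res, lib, criteria)
    assert ps.hit_gene_set(calls) == hit_oracle(res, lib, criteria)


@settings(max_examples=40, deadline=None)
@given(random_screen_table())
def test_relaxing_thresholds_never_removes_hits(table):
    lib, res = table
    base = ps.HitCriteria(0.05, 1.0, 2, True, exclude_if_any_depleted=False)
    hits = ps.hit_gene_set(ps.call_hits(res, lib, base))
    relaxations = [
        ps.HitCriteria(0.2, 1.0, 2, True, exclude_if_any_depleted=False),
        ps.HitCriteria(0.05, 0.5, 2, True, exclude_if_any_depleted=False),
        ps.HitCriteria(0.05, 1.0, 1, True, exclude_if_any_depleted=False),
        ps.HitCriteria(0.05, 1.0, 2, False, exclude_if_any_depleted=False),
    ]
    for criteria in relaxations:
        assert hits <= ps.hit_gene_set(ps.call_hits(res, lib, criteria))


def test_gene_with_single_construct_reports_insufficient():
    from poolscreen.hits import REASON_INSUFFICIENT_CONSTRUCTS

    lib = library_from([("a1", "A", 1)])
    res = results_from([("a1", "A", 1, 2.0, 0.001)])
    calls = ps.call_hits(res, lib)
    assert not calls.loc[0, "is_hit"]
    assert REASON_INSUFFICIENT_CONSTRUCTS in calls.loc[0, "failure_reasons"]


# ------------------------------------------------- counter-screen subtraction


def test_subtraction_examples():
    assert ps.subtract_counter_screen({"A", "B", "C"}, {"B"}) == ["A", "C"]
    assert ps.subtract_counter_screen({"A", "B"}, {"A", "B"}) == []
    assert ps.subtract_counter_screen(set(), {"A"}) == []


def test_subtraction_output_sorted_deterministically():
    out = ps.subtract_counter_screen({"Z", "A", "M"}, set())
    assert out == sorted(out)
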