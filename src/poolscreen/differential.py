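"""Differential shRNA representation between reference and treated arms.

Counts are normalized to counts per million (CPM) for reporting, and each
construct is tested for a shift in relative representation with an exact
negative-binomial conditional test: replicate counts are first scaled to the
geometric-mean library size, arm totals are formed (a sum of n iid NB(mu, phi)
variables is NB with mean n*mu and dispersion phi/n), and the test conditions
on the construct's combined total T.  Under the null of equal proportional
representation the conditional law of the treated-arm total given T is known,
and the two-sided p-value is the probability mass of every split whose
probability does not exceed that of the observed split.  Dispersions are
method-of-moments estimates moderated toward the common (library-wide) value,
in the spirit of shrinkage estimators used for small-replicate count data.
False-discovery control is Benjamini-Hochberg within each pool, matching the
per-pool 3 vs 3 experimental unit of the screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

from .design import LibraryDesign
from .quantify import CountMatrix

__all__ = [
    "DispersionEstimate",
    "cpm",
    "estimate_dispersion",
    "exact_nb_pvalue",
    "test_shrna",
    "run_differential",
    "bh_adjust",
    "DISPERSION_FLOOR",
]

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8

RESULT_COLUMNS = [
    "shrna_id",
    "gene_id",
    "pool",
    "mean_cpm_ref",
    "mean_cpm_trt",
    "log2fc",
    "dispersion",
    "p_value",
    "fdr",
    "all_zero",
]


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count / column_sum * 1e6, per sample."""
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    sums = frame.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {list(zero)}")
    return frame / sums * 1e6


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DispersionEstimate:
    """Per-shRNA moderated NB dispersions plus the common estimate."""

    per_shrna: pd.Series
    common: float
    prior_df: float


def _size_normalized(matrix: CountMatrix) -> tuple[pd.DataFrame, pd.Series]:
    libsizes = matrix.counts.sum(axis=0)
    zero = libsizes.index[libsizes == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {list(zero)}")
    geo = float(np.exp(np.log(libsizes.to_numpy(dtype=float)).mean()))
    return matrix.counts * (geo / libsizes), libsizes


def estimate_dispersion(
    matrix: CountMatrix,
    prior_df: float = 40.0,
    fallback_dispersion: float = 0.1,
) -> DispersionEstimate:
    """Method-of-moments NB dispersion on size-normalized counts, shrunk
    toward the common value with weight prior_df / (prior_df + residual df).

    With a single replicate per arm no within-arm variance exists; the
    estimate falls back to ``fallback_dispersion`` with a warning.
    """
    norm, _ = _size_normalized(matrix)
    conditions = matrix.samples["condition"]
    resid_df = 0
    num = pd.Series(0.0, index=norm.index)
    den = 0.0
    for arm in ("reference", "treated"):
        cols = conditions.index[conditions == arm]
        n = len(cols)
        if n < 2:
            continue
        sub = norm[cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (v - m) / (m**2)
        raw[m <= 0] = np.nan
        num += np.nan_to_num(raw) * (n - 1)
        den += n - 1
        resid_df += n - 1
    if den == 0:
        logger.warning(
            "single replicate per arm: falling back to common dispersion %.3g",
            fallback_dispersion,
        )
        common = fallback_dispersion
        per = pd.Series(common, index=norm.index)
        return DispersionEstimate(per.clip(lower=DISPERSION_FLOOR), common, prior_df)
    raw_combined = num / den
    common = max(0.0, float(np.nanmean(raw_combined)))
    w = prior_df / (prior_df + resid_df)
    per = w * common + (1 - w) * raw_combined.clip(lower=0.0).fillna(common)
    return DispersionEstimate(per.clip(lower=DISPERSION_FLOOR), common, prior_df)


def _arm_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if phi < 1e-10:
        return poisson.logpmf(k, mean)
    r = 1.0 / phi
    return nbinom.logpmf(k, r, r / (r + mean))


def exact_nb_pvalue(y_treated: int, total: int, n_treated: int, n_reference: int, phi: float) -> float:
    """Two-sided exact NB conditional p-value for a treated/reference split.

    Arm totals are NB(n*mu, phi/n); conditioning on the combined total T, the
    p-value is the summed probability of every split k in 0..T whose
    conditional probability is <= that of the observed split (so the modal
    split yields p = 1).
    """
    if total == 0:
        return 1.0
    if not 0 <= y_treated <= total:
        raise ValueError("observed treated total outside [0, total]")
    mu = total / (n_treated + n_reference)
    k = np.arange(total + 1)
    lp = _arm_logpmf(k, n_treated * mu, phi / n_treated) + _arm_logpmf(
        total - k, n_reference * mu, phi / n_reference
    )
    lp -= logsumexp(lp)
    keep = lp <= lp[y_treated] + 1e-10
    return float(min(1.0, np.exp(logsumexp(lp[keep]))))


def test_shrna(
    matrix: CountMatrix,
    library: LibraryDesign | None = None,
    pseudocount: float = 0.5,
    dispersion: DispersionEstimate | None = None,
    prior_df: float = 40.0,
) -> pd.DataFrame:
    """Per-shRNA differential representation within one pool.

    Returns a DataFrame with CPM means, pseudocount-stabilized log2 fold
    change (treated vs reference), moderated dispersion, exact NB conditional
    p-value, and BH-adjusted FDR across the pool's constructs.  Constructs
    with zero counts in every sample get p = 1, log2fc = 0, and an
    ``all_zero`` flag.
    """
    pools = matrix.samples["pool"].unique()
    if len(pools) != 1:
        raise ValueError(f"test_shrna expects a single-pool matrix, got pools {sorted(pools)}")
    conditions = matrix.samples["condition"]
    n_trt = int((conditions == "treated").sum())
    n_ref = int((conditions == "reference").sum())
    if n_trt < 1 or n_ref < 1:
        raise ValueError("both a reference and a treated arm are required")
    if dispersion is None:
        dispersion = estimate_dispersion(matrix, prior_df=prior_df)

    cpms = cpm(matrix)
    trt_cols = conditions.index[conditions == "treated"]
    ref_cols = conditions.index[conditions == "reference"]
    mean_trt = cpms[trt_cols].mean(axis=1)
    mean_ref = cpms[ref_cols].mean(axis=1)
    log2fc = np.log2((mean_trt + pseudocount) / (mean_ref + pseudocount))

    norm, _ = _size_normalized(matrix)
    y_trt = norm[trt_cols].sum(axis=1).round().astype(int)
    y_ref = norm[ref_cols].sum(axis=1).round().astype(int)

    gene_map = library.gene_of() if library is not None else None
    p_values = np.ones(len(matrix.counts.index))
    all_zero = np.zeros(len(matrix.counts.index), dtype=bool)
    for i, sid in enumerate(matrix.counts.index):
        t = int(y_trt.loc[sid] + y_ref.loc[sid])
        if t == 0:
            all_zero[i] = True
            continue
        p_values[i] = exact_nb_pvalue(
            int(y_trt.loc[sid]), t, n_trt, n_ref, float(dispersion.per_shrna.loc[sid])
        )
    log2fc = log2fc.where(~all_zero, 0.0)

    out = pd.DataFrame(
        {
            "shrna_id": matrix.counts.index,
            "gene_id": (
                gene_map.reindex(matrix.counts.index).to_numpy()
                if gene_map is not None
                else pd.NA
            ),
            "pool": int(pools[0]),
            "mean_cpm_ref": mean_ref.to_numpy(),
            "mean_cpm_trt": mean_trt.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "dispersion": dispersion.per_shrna.reindex(matrix.counts.index).to_numpy(),
            "p_value": p_values,
            "fdr": bh_adjust(p_values),
            "all_zero": all_zero,
        }
    ).reset_index(drop=True)
    return out[RESULT_COLUMNS]


def run_differential(
    matrix: CountMatrix,
    library: LibraryDesign,
    pseudocount: float = 0.5,
    prior_df: float = 40.0,
) -> pd.DataFrame:
    """Test every pool independently and stack the per-pool result tables.

    Each pool has its own replicate specimens, dispersion estimate, and BH
    adjustment, mirroring the screen's per-pool experimental design.
    """
    frames = []
    for pool in matrix.pools():
        block = matrix.pool_block(pool, library)
        frames.append(test_shrna(block, library, pseudocount=pseudocount, prior_df=prior_df))
    return pd.concat(frames, axis=0, ignore_index=True)
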