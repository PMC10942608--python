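"""Per-feature allelic-imbalance tests (ASE and ASCA) and their filters.

In a hybrid cell both alleles share one trans-acting environment, so a
departure of the human:chimpanzee allelic read ratio from 1:1 measures
cis-regulatory divergence. The test is an exact two-sided binomial test
on the normalized allelic counts summed by species within a cell type,
followed by Benjamini-Hochberg correction within each cell type and
reference genome. A feature is called imbalanced only if it is
significant under both the human- and chimpanzee-referenced runs and
survives the mapping-bias and replicate-consistency filters.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AllelicCountTable
from .qc_normalize import dual_reference_filter, dual_reference_sign_filter_atac

logger = logging.getLogger(__name__)

FLAG_LOW_COUNT = "low_count"
FLAG_REPLICATE_DISCORDANT = "replicate_discordant"
FLAG_DUAL_REF_DISCORDANT = "dual_ref_discordant"


def compute_lfc(human, chimp, pseudocount: float = 1.0):
    """log2((human + pc) / (chimp + pc)); positive = human-biased."""
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    h = np.asarray(human, dtype=float)
    c = np.asarray(chimp, dtype=float)
    out = np.log2(h + pseudocount) - np.log2(c + pseudocount)
    if np.isscalar(human) or np.ndim(human) == 0:
        return float(out)
    if isinstance(human, pd.Series):
        return pd.Series(out, index=human.index)
    return out


def _round_counts(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (counts are non-negative here)."""
    return np.floor(x + 0.5).astype(np.int64)


def binomial_allelic_test(human_sum, chimp_sum, p0: float = 0.5):
    """Exact two-sided binomial p by equal-tail doubling.

    ``p = min(1, 2 * min(P(X <= k), P(X >= k)))`` with ``k`` the human
    count and ``n = human + chimp``, X ~ Binomial(n, p0). Non-integer
    counts (post-normalization reals) are rounded half away from zero;
    ``n = 0`` gives p = 1 with a warning. Accepts scalars or arrays.
    """
    scalar = np.isscalar(human_sum) or np.ndim(human_sum) == 0
    h = np.atleast_1d(np.asarray(human_sum, dtype=float))
    c = np.atleast_1d(np.asarray(chimp_sum, dtype=float))
    if (h < 0).any() or (c < 0).any():
        raise ValueError("allelic counts must be non-negative")
    if not (np.all(h == np.floor(h)) and np.all(c == np.floor(c))):
        logger.info("non-integer allelic counts rounded half away from zero")
    k = _round_counts(h)
    n = k + _round_counts(c)
    if (n == 0).any():
        warnings.warn("feature(s) with zero total count: p set to 1",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        lower = stats.binom.cdf(k, n, p0)
        upper = stats.binom.sf(k - 1, n, p0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p = np.where(n == 0, 1.0, p)
    if scalar:
        return float(p[0])
    if isinstance(human_sum, pd.Series):
        return pd.Series(p, index=human_sum.index)
    return p


def bh_fdr(p_values) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values in input order.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the sorted p-values. NaN
    entries propagate as NaN and do not count toward ``n``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    n = pv.size
    if n:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(n)
        qv[order] = np.minimum(ranked, 1.0)
        q[finite] = qv
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index)
    return q


def atac_count_filter(table: AllelicCountTable,
                      min_mean: float = 25.0) -> pd.DataFrame:
    """Keep a peak in a cell type if either allele's mean count is high enough.

    Keep iff the mean read count across the cell type's replicates is at
    least ``min_mean`` from the human allele OR from the chimpanzee
    allele; evaluated per cell type, so a peak may pass in one cell type
    and fail in another. Returns a feature x cell_type boolean frame.
    """
    out = {}
    for ct in table.cell_types:
        samples = table.samples_of(ct)
        h_mean = table.human[samples].mean(axis=1)
        c_mean = table.chimp[samples].mean(axis=1)
        out[ct] = (h_mean >= min_mean) | (c_mean >= min_mean)
    return pd.DataFrame(out, index=table.features)


def replicate_sign_discordance_filter(lfc_per_replicate: pd.DataFrame,
                                      big_lfc: float = 1.0) -> pd.Series:
    """Drop features with a strong call contradicted by another replicate.

    Drop iff some replicate has ``|LFC| > big_lfc`` while another
    replicate's LFC has the opposite (non-zero) sign. Frames with a
    single replicate column are exempt (all kept).
    """
    if lfc_per_replicate.shape[1] < 2:
        return pd.Series(True, index=lfc_per_replicate.index)
    m = lfc_per_replicate.to_numpy()
    drop = (
        ((m > big_lfc).any(axis=1) & (m < 0).any(axis=1))
        | ((m < -big_lfc).any(axis=1) & (m > 0).any(axis=1))
    )
    return pd.Series(~drop, index=lfc_per_replicate.index)


def _per_cell_type_stats(table: AllelicCountTable, cell_type: str,
                         pseudocount: float) -> dict[str, pd.Series | pd.DataFrame]:
    samples = table.samples_of(cell_type)
    h = table.human[samples]
    c = table.chimp[samples]
    h_sum, c_sum = h.sum(axis=1), c.sum(axis=1)
    rep_lfc = pd.DataFrame(
        {s: compute_lfc(h[s], c[s], pseudocount) for s in samples},
        index=table.features,
    )
    return {
        "human_sum": h_sum,
        "chimp_sum": c_sum,
        "mean_human": h.mean(axis=1),
        "mean_chimp": c.mean(axis=1),
        "lfc": compute_lfc(h_sum, c_sum, pseudocount),
        "rep_lfc": rep_lfc,
        "p": binomial_allelic_test(h_sum, c_sum),
    }


def call_allelic_imbalance(
    table_refH: AllelicCountTable,
    table_refC: AllelicCountTable,
    alpha: float = 0.05,
    max_abs_diff: float = 1.0,
    pseudocount: float = 1.0,
    min_mean: float = 25.0,
) -> pd.DataFrame:
    """Call per-feature allelic imbalance per cell type under both references.

    For each cell type, allelic counts are summed across all samples of
    that cell type, tested with the exact binomial test, and BH-corrected
    within (cell type x reference). A feature is significant iff its FDR
    is below ``alpha`` under BOTH references, the dual-reference
    fold-change filter passes, and (for ATAC tables) the mean-count and
    replicate-consistency filters pass. The reported ``lfc`` is from the
    human-referenced run.

    Returns a tidy frame: feature_id, cell_type, lfc, lfc_refC,
    mean_human, mean_chimp, p_value, fdr, p_value_refC, fdr_refC,
    significant, filter_flags.
    """
    if not table_refH.features.equals(table_refC.features):
        raise ValueError("reference tables cover different features")
    cts_H, cts_C = table_refH.cell_types, table_refC.cell_types
    if set(cts_H) != set(cts_C):
        raise ValueError(
            f"cell types differ between references: {cts_H} vs {cts_C}"
        )
    assay = table_refH.meta["assay"].iloc[0]
    is_atac = assay == "ATAC"

    if is_atac:
        keep_count_H = atac_count_filter(table_refH, min_mean)
        keep_count_C = atac_count_filter(table_refC, min_mean)

    rows = []
    for ct in cts_H:
        sH = _per_cell_type_stats(table_refH, ct, pseudocount)
        sC = _per_cell_type_stats(table_refC, ct, pseudocount)
        fdr_H = bh_fdr(sH["p"])
        fdr_C = bh_fdr(sC["p"])

        keep_dual = dual_reference_filter(sH["lfc"], sC["lfc"], max_abs_diff)
        flags = pd.DataFrame(index=table_refH.features)
        flags[FLAG_DUAL_REF_DISCORDANT] = ~keep_dual.loc[table_refH.features]
        if is_atac:
            flags[FLAG_LOW_COUNT] = ~(keep_count_H[ct] & keep_count_C[ct])
            keep_rep = (
                replicate_sign_discordance_filter(sH["rep_lfc"])
                & replicate_sign_discordance_filter(sC["rep_lfc"])
                & dual_reference_sign_filter_atac(
                    sH["rep_lfc"], sC["rep_lfc"], max_abs_diff)
            )
            flags[FLAG_REPLICATE_DISCORDANT] = ~keep_rep
        else:
            flags[FLAG_LOW_COUNT] = False
            flags[FLAG_REPLICATE_DISCORDANT] = False

        no_flags = ~flags.any(axis=1)
        significant = (fdr_H < alpha) & (fdr_C < alpha) & no_flags
        flag_str = flags.apply(
            lambda r: ";".join(flags.columns[r.values]), axis=1)

        block = pd.DataFrame({
            "feature_id": table_refH.features,
            "cell_type": ct,
            "lfc": sH["lfc"].values,
            "lfc_refC": sC["lfc"].values,
            "mean_human": sH["mean_human"].values,
            "mean_chimp": sH["mean_chimp"].values,
            "p_value": sH["p"].values,
            "fdr": fdr_H.values,
            "p_value_refC": sC["p"].values,
            "fdr_refC": fdr_C.values,
            "significant": significant.values,
            "filter_flags": flag_str.values,
        })
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def lfc_matrix(results: pd.DataFrame, value: str = "lfc") -> pd.DataFrame:
    """Pivot a tidy result frame to feature x cell_type."""
    return results.pivot(index="feature_id", columns="cell_type", values=value)


def significance_matrix(results: pd.DataFrame) -> pd.DataFrame:
    return results.pivot(index="feature_id", columns="cell_type",
                         values="significant").astype(bool)
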