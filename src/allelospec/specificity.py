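"""Cell-type-specificity calls for genes and peaks.

Two definitions are implemented, following the study design:

* *narrow*: a gene is specific to a cell type if its TPM is below a low
  threshold in every other cell type and above a high threshold in that
  one; a peak is narrow-specific if it was called as a peak in exactly
  one cell type (on depth-matched data).
* *broad*: a gene is specific to a cell type if it is differentially
  expressed versus every other cell type (FDR < alpha for every
  pairwise comparison, under both reference genomes); a peak if its
  pooled-CPM fold-change exceeds a threshold against every other cell
  type.

Pairwise differential expression uses Welch's t-test on log2(CPM + 1) of
total (allelic + non-allelic) counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allelic_tests import bh_fdr
from .io_formats import AllelicCountTable
from .qc_normalize import cpm


@dataclass
class SpecificityCall:
    """Per-feature specificity verdicts (at most one cell type each)."""

    calls: pd.DataFrame  # index feature_id; columns specific_to (str or "")
    criteria: dict


def narrow_specific_genes(tpm: pd.DataFrame, low: float = 1.0,
                          high: float = 1.0) -> SpecificityCall:
    """Narrow specificity from a gene x cell_type mean-TPM matrix.

    Specific to cell type c iff TPM < ``low`` in every other cell type
    and TPM > ``high`` in c.
    """
    if high < low:
        raise ValueError(f"high ({high}) must be >= low ({low})")
    vals = tpm.to_numpy()
    n_ct = vals.shape[1]
    below = vals < low
    n_below = below.sum(axis=1)
    specific = np.full(len(tpm), "", dtype=object)
    # the only candidate cell type is the one not below `low`
    candidate_ok = n_below == n_ct - 1
    for i in np.flatnonzero(candidate_ok):
        j = int(np.flatnonzero(~below[i])[0])
        if vals[i, j] > high:
            specific[i] = tpm.columns[j]
    calls = pd.DataFrame({"specific_to": specific}, index=tpm.index)
    return SpecificityCall(calls=calls, criteria={"low": low, "high": high})


def welch_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p per row of two 2-D arrays.

    Rows where both groups have zero variance get p = 1 (t = 0 when the
    means agree; by convention also 1 when they differ but no variance
    is observed, with a warning).
    """
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("each group needs >= 2 samples")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    zero_var = se2 == 0
    if (zero_var & (mx != my)).any():
        warnings.warn(
            "zero within-group variance with unequal means: p set to 1",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2 ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(zero_var, 1.0, p)


def pairwise_de_test(total_counts: pd.DataFrame, meta: pd.DataFrame,
                     cell_type_a: str, cell_type_b: str) -> pd.Series:
    """Per-gene two-sided Welch p on log2(CPM+1), one cell-type pair."""
    a_ids = meta.index[meta["cell_type"] == cell_type_a]
    b_ids = meta.index[meta["cell_type"] == cell_type_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per cell type, got {len(a_ids)} for "
            f"{cell_type_a} and {len(b_ids)} for {cell_type_b}"
        )
    log_cpm = np.log2(cpm(total_counts) + 1.0)
    p = welch_p(log_cpm[a_ids].to_numpy(), log_cpm[b_ids].to_numpy())
    return pd.Series(p, index=total_counts.index)


def all_pairwise_de(total_counts: pd.DataFrame, meta: pd.DataFrame,
                    cell_types: Sequence[str] | None = None) -> pd.DataFrame:
    """Tidy frame of per-gene BH-corrected p for every cell-type pair.

    Columns: gene, cell_type, other, p, fdr. BH is applied within each
    (unordered) pair and the result recorded symmetrically.
    """
    if cell_types is None:
        cell_types = list(dict.fromkeys(meta["cell_type"]))
    rows = []
    for i, a in enumerate(cell_types):
        for b in cell_types[i + 1:]:
            p = pairwise_de_test(total_counts, meta, a, b)
            q = bh_fdr(p)
            for ct, other in ((a, b), (b, a)):
                rows.append(pd.DataFrame({
                    "gene": total_counts.index, "cell_type": ct,
                    "other": other, "p": p.values, "fdr": q.values,
                }))
    return pd.concat(rows, ignore_index=True)


def broad_specific_genes(pairwise_by_ref: dict[str, pd.DataFrame],
                         alpha: float = 0.05,
                         exclude: Sequence[str] = ()) -> SpecificityCall:
    """Broad specificity: DE versus every other cell type, both references.

    ``pairwise_by_ref`` maps reference tag to the output of
    :func:`all_pairwise_de`. A gene is specific to c iff FDR < alpha for
    every pair (c, c') under both references; cell types in ``exclude``
    are dropped from the comparison grid entirely.
    """
    if not pairwise_by_ref:
        raise ValueError("need pairwise results for at least one reference")
    per_ref_hits = []
    genes = None
    cts: list[str] = []
    for ref, df in pairwise_by_ref.items():
        df = df[~df["cell_type"].isin(exclude) & ~df["other"].isin(exclude)]
        cts = sorted(set(df["cell_type"]) | set(df["other"]))
        wide = df.pivot_table(index="gene", columns=["cell_type", "other"],
                              values="fdr")
        expected = [(c, o) for c in cts for o in cts if o != c]
        missing = [p for p in expected if p not in wide.columns]
        if missing:
            raise ValueError(f"missing pairwise comparison(s): {missing[:4]}")
        hit = pd.DataFrame(index=wide.index)
        for c in cts:
            cols = [(c, o) for o in cts if o != c]
            sub = wide[cols]
            hit[c] = (sub < alpha).all(axis=1) & sub.notna().all(axis=1)
        per_ref_hits.append(hit)
        genes = hit.index if genes is None else genes.intersection(hit.index)

    combined = per_ref_hits[0].loc[genes]
    for h in per_ref_hits[1:]:
        combined = combined & h.loc[genes]
    specific = np.full(len(genes), "", dtype=object)
    arr = combined.to_numpy()
    one_hit = arr.sum(axis=1) == 1
    for i in np.flatnonzero(one_hit):
        specific[i] = combined.columns[int(np.flatnonzero(arr[i])[0])]
    calls = pd.DataFrame({"specific_to": specific}, index=genes)
    return SpecificityCall(calls=calls,
                           criteria={"alpha": alpha, "exclude": list(exclude)})


def downsample_counts(table: AllelicCountTable, target_total: int,
                      seed: int = 0) -> AllelicCountTable:
    """Subsample each sample's counts to exactly ``target_total`` reads.

    Multivariate hypergeometric (without replacement) over the stacked
    human+chimp count vector, so allelic proportions are preserved in
    expectation and totals are exact. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    h = table.human.to_numpy()
    c = table.chimp.to_numpy()
    if not (np.all(h == np.floor(h)) and np.all(c == np.floor(c))):
        raise ValueError("downsampling requires integer counts")
    h = h.astype(np.int64)
    c = c.astype(np.int64)
    out_h = np.empty_like(h)
    out_c = np.empty_like(c)
    n_feat = h.shape[0]
    for k, sid in enumerate(table.sample_ids):
        colors = np.concatenate([h[:, k], c[:, k]])
        total = int(colors.sum())
        if target_total > total:
            raise ValueError(
                f"target_total {target_total} exceeds total {total} of "
                f"sample {sid!r}"
            )
        draw = rng.multivariate_hypergeometric(colors, target_total,
                                               method="marginals")
        out_h[:, k] = draw[:n_feat]
        out_c[:, k] = draw[n_feat:]
    return AllelicCountTable(
        human=pd.DataFrame(out_h, index=table.features, columns=table.sample_ids),
        chimp=pd.DataFrame(out_c, index=table.features, columns=table.sample_ids),
        meta=table.meta.copy(), chrom=table.chrom.copy(),
        reference=table.reference,
    )


def broad_specific_peaks(cpm_by_cell_type: pd.DataFrame,
                         min_abs_lfc: float = 0.5,
                         pseudocount: float = 1.0) -> SpecificityCall:
    """Broad peak specificity from pooled per-cell-type CPM.

    A peak is specific to c iff ``|log2((CPM_c + pc)/(CPM_c' + pc))| >
    min_abs_lfc`` for every other cell type c'. A consistent direction
    across the pairwise comparisons is not required.
    """
    vals = np.log2(cpm_by_cell_type.to_numpy() + pseudocount)
    n_ct = vals.shape[1]
    hits = np.zeros((len(cpm_by_cell_type), n_ct), dtype=bool)
    for j in range(n_ct):
        diffs = np.abs(vals[:, [j]] - np.delete(vals, j, axis=1))
        hits[:, j] = (diffs > min_abs_lfc).all(axis=1)
    # a peak uniquely high AND a peak uniquely low can both pass in
    # absolute terms; the call must name one cell type, so ambiguous
    # rows stay uncalled
    specific = np.full(len(cpm_by_cell_type), "", dtype=object)
    one = hits.sum(axis=1) == 1
    for i in np.flatnonzero(one):
        specific[i] = cpm_by_cell_type.columns[int(np.flatnonzero(hits[i])[0])]
    calls = pd.DataFrame({"specific_to": specific},
                         index=cpm_by_cell_type.index)
    return SpecificityCall(calls=calls, criteria={"min_abs_lfc": min_abs_lfc})


def narrow_specific_peaks(peak_called: pd.DataFrame) -> SpecificityCall:
    """Narrow peak specificity: called as a peak in exactly one cell type."""
    arr = peak_called.to_numpy().astype(bool)
    specific = np.full(len(peak_called), "", dtype=object)
    one = arr.sum(axis=1) == 1
    for i in np.flatnonzero(one):
        specific[i] = peak_called.columns[int(np.flatnonzero(arr[i])[0])]
    calls = pd.DataFrame({"specific_to": specific}, index=peak_called.index)
    return SpecificityCall(calls=calls, criteria={"rule": "called_in_one"})
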