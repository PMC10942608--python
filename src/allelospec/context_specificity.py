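"""dEE/dCAE specificity metrics and ASE-ASCA direction concordance.

dEE (differential expression enrichment) quantifies how specific a
feature's allelic log2 fold-change is to one cell type of a panel: with
target fold-change t, fold-changes of the *opposite* sign in the other
cell types are zeroed and dEE = |t| / sum(|zeroed fold-changes|). It is
1 when the target cell type carries all of the same-sign divergence and
near 1/n when the divergence is shared equally; dCAE is the identical
computation on chromatin-accessibility fold-changes. The metric is
panel-dependent by construction, so integrative RNA/ATAC analyses must
use matching panels (the RNA-only cell type is dropped).

Peak-gene pairing assigns each peak to the gene whose TSS is closest to
the peak midpoint; the concordance test asks whether, among peak-gene
pairs that are both cell-type-specifically imbalanced in the same cell
type, the two fold-changes share a sign more often than the chance
expectation of one half (exact binomial test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .allelic_tests import binomial_allelic_test
from .io_formats import FeatureAnnotation


def dee(lfc_vector: Sequence[float], target_index: int) -> float:
    """dEE of one cell type within a fold-change vector.

    Opposite-sign entries are zeroed, then ``|t| / sum(|zeroed|)``.
    A zero target fold-change returns 0 by convention (a zero effect is
    maximally non-specific).
    """
    v = np.asarray(lfc_vector, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("lfc_vector must be 1-D with length >= 2")
    if not np.isfinite(v).all():
        raise ValueError("non-finite fold-change in input")
    t = v[target_index]
    if t == 0.0:
        return 0.0
    zeroed = np.where(np.sign(v) == np.sign(t), v, 0.0)
    zeroed[target_index] = t
    return float(abs(t) / np.abs(zeroed).sum())


def dee_matrix(lfc: pd.DataFrame) -> pd.DataFrame:
    """dEE (or dCAE) for every (feature, cell type) of an LFC matrix.

    Vectorized version of :func:`dee` applied per entry; returns a frame
    with the same shape and labels.
    """
    v = lfc.to_numpy(dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("non-finite fold-change in input")
    if v.shape[1] < 2:
        raise ValueError("panel must contain >= 2 cell types")
    out = np.zeros_like(v)
    for j in range(v.shape[1]):
        t = v[:, j]
        same_sign = np.sign(v) == np.sign(t)[:, None]
        zeroed = np.where(same_sign, v, 0.0)
        zeroed[:, j] = t
        denom = np.abs(zeroed).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, j] = np.where(t == 0.0, 0.0, np.abs(t) / denom)
    return pd.DataFrame(out, index=lfc.index, columns=lfc.columns)


@dataclass
class DEEProfile:
    feature_id: str
    lfc_by_cell_type: pd.Series
    dee_by_cell_type: pd.Series
    panel: tuple[str, ...]


def specific_imbalance_calls(dee_values: pd.DataFrame,
                             significant: pd.DataFrame,
                             dee_min: float = 0.75) -> pd.DataFrame:
    """Cell-type-specific imbalance: significant AND dEE >= threshold.

    Both inputs are feature x cell_type; the panels must match. Returns
    a boolean frame of the same shape.
    """
    if not dee_values.columns.equals(significant.columns):
        raise ValueError(
            f"panel mismatch: {list(dee_values.columns)} vs "
            f"{list(significant.columns)}"
        )
    common = dee_values.index.intersection(significant.index)
    return (dee_values.loc[common] >= dee_min) & \
        significant.loc[common].astype(bool)


def pair_peaks_to_genes(peaks: Iterable[FeatureAnnotation],
                        genes: Iterable[FeatureAnnotation]) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS.

    Distance is measured from the peak midpoint to the strand-aware TSS;
    0 if the TSS lies inside the peak. Ties are broken by lower gene
    start coordinate, then lexicographic gene id. Peaks on chromosomes
    without genes are left unassigned (with a warning).

    Returns a frame indexed by peak_id with columns gene_id, distance.
    """
    genes = list(genes)
    peaks = list(peaks)
    by_chrom: dict[str, list[FeatureAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    unassigned = 0
    for p in peaks:
        cands = by_chrom.get(p.chrom)
        if not cands:
            unassigned += 1
            continue
        mid = p.midpoint
        best = min(
            cands,
            key=lambda g: (
                0.0 if p.start <= g.tss < p.end else abs(mid - g.tss),
                g.start,
                g.feature_id,
            ),
        )
        d = 0.0 if p.start <= best.tss < p.end else abs(mid - best.tss)
        rows.append((p.feature_id, best.feature_id, float(d)))
    if unassigned:
        warnings.warn(f"{unassigned} peak(s) had no gene on their chromosome "
                      "and were left unassigned", stacklevel=2)
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"]) \
        .set_index("peak_id")


@dataclass
class ConcordanceResult:
    n_pairs: int
    n_same_direction: int
    expected: float
    binom_p: float
    pairs: pd.DataFrame | None = None


def concordance_expectation(n_pairs: int) -> float:
    """Chance expectation of same-direction pairs: half of all pairs."""
    return n_pairs * 0.5


def concordance_from_counts(n_pairs: int, n_same: int) -> ConcordanceResult:
    """Exact binomial concordance test from pair counts alone."""
    if n_pairs == 0:
        warnings.warn("no concordant-call pairs: p undefined", stacklevel=2)
        return ConcordanceResult(0, 0, 0.0, float("nan"))
    p = binomial_allelic_test(n_same, n_pairs - n_same)
    return ConcordanceResult(n_pairs, n_same, concordance_expectation(n_pairs), p)


def concordance_test(gene_calls: pd.DataFrame, peak_calls: pd.DataFrame,
                     gene_lfc: pd.DataFrame, peak_lfc: pd.DataFrame,
                     pairing: pd.DataFrame) -> ConcordanceResult:
    """Direction concordance of matched cell-type-specific ASE and ASCA.

    ``gene_calls`` / ``peak_calls`` are boolean feature x cell_type
    frames from :func:`specific_imbalance_calls` on matched panels;
    ``pairing`` maps peaks to genes. A pair enters the test when a gene
    and its assigned peak are both specifically imbalanced in the SAME
    cell type; it counts as same-direction when the two fold-changes
    share a (non-zero) sign there.
    """
    if not gene_calls.columns.equals(peak_calls.columns):
        raise ValueError("gene and peak panels differ")
    records = []
    for peak_id, row in pairing.iterrows():
        gene_id = row["gene_id"]
        if peak_id not in peak_calls.index or gene_id not in gene_calls.index:
            continue
        both = peak_calls.loc[peak_id] & gene_calls.loc[gene_id]
        for ct in gene_calls.columns[both]:
            g = float(gene_lfc.loc[gene_id, ct])
            k = float(peak_lfc.loc[peak_id, ct])
            if g == 0.0 or k == 0.0:
                continue
            records.append((gene_id, peak_id, ct, g, k,
                            bool(np.sign(g) == np.sign(k))))
    pairs = pd.DataFrame(records, columns=[
        "gene_id", "peak_id", "cell_type", "gene_lfc", "peak_lfc",
        "same_direction",
    ])
    n_pairs = len(pairs)
    n_same = int(pairs["same_direction"].sum()) if n_pairs else 0
    result = concordance_from_counts(n_pairs, n_same)
    result.pairs = pairs
    return result
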