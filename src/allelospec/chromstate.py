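"""Chromatin-state assignment of peaks and per-state divergence summaries.

Peaks are intersected with a 15-state chromatin segmentation (universal
chromHMM-style annotations). Divergence per state is summarized as the
median absolute allelic fold-change, z-scored across states within each
cell type; the relationship between accessibility divergence and
expression divergence is the Pearson correlation between peak and
nearest-gene fold-changes per (state, cell type), computed only where a
state holds at least 15 peaks, with subsets for nominally imbalanced
peaks, promoter-state exclusion, and TSS-proximal vs distal peaks.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import (
    CHROM_STATE_VOCAB,
    PROMOTER_STATES,
    ChromStateAnnotation,
    FeatureAnnotation,
)

#: Minimum peaks per (state, cell type) for a correlation to be reported.
MIN_PEAKS_FOR_CORRELATION = 15

#: TSS distance separating proximal from distal peaks (bases).
PROXIMAL_DISTANCE = 30_000


def _state_trees(states: ChromStateAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in states.intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), st)
            for s, e, st in zip(sub["start"], sub["end"], sub["state"])
        )
    return trees


def assign_state(peaks: Iterable[FeatureAnnotation],
                 states: ChromStateAnnotation,
                 mode: str = "largest_overlap") -> pd.DataFrame:
    """Label peaks with chromatin states.

    ``largest_overlap``: one label per peak — the state covering the
    largest part of the peak, ties broken by vocabulary order (logged
    via the returned ``tie`` column). ``any_overlap``: a peak is
    duplicated into every state it touches. Peaks with no overlap get
    the label ``"none"``.

    Returns a frame with columns peak_id, state (and overlap, tie for
    largest_overlap mode).
    """
    if mode not in ("largest_overlap", "any_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    trees = _state_trees(states)
    vocab_rank = {s: i for i, s in enumerate(states.vocabulary)}
    rows = []
    for p in peaks:
        tree = trees.get(p.chrom)
        hits = tree.overlap(p.start, p.end) if tree else ()
        if not hits:
            if mode == "largest_overlap":
                rows.append((p.feature_id, "none", 0, False))
            else:
                rows.append((p.feature_id, "none"))
            continue
        if mode == "any_overlap":
            for iv in sorted(hits, key=lambda iv: (iv.begin, iv.end)):
                rows.append((p.feature_id, iv.data))
            continue
        overlap_by_state: dict[str, int] = {}
        for iv in hits:
            ov = min(iv.end, p.end) - max(iv.begin, p.start)
            overlap_by_state[iv.data] = overlap_by_state.get(iv.data, 0) + ov
        best_ov = max(overlap_by_state.values())
        winners = sorted(
            (s for s, ov in overlap_by_state.items() if ov == best_ov),
            key=lambda s: vocab_rank.get(s, len(vocab_rank)),
        )
        rows.append((p.feature_id, winners[0], best_ov, len(winners) > 1))
    if mode == "largest_overlap":
        return pd.DataFrame(rows, columns=["peak_id", "state", "overlap",
                                           "tie"])
    return pd.DataFrame(rows, columns=["peak_id", "state"])


def divergence_by_state(asca_lfc: pd.DataFrame, state_labels: pd.Series,
                        mode: str = "zscore_of_median") -> pd.DataFrame:
    """Per-state accessibility divergence, z-scored within each cell type.

    ``asca_lfc`` is peak x cell_type; ``state_labels`` maps peak to
    state. Default mode z-scores the per-state medians of |LFC| across
    states within a cell type ((median - mean of medians) / sd of
    medians); ``median_of_z`` instead z-scores per-peak |LFC| across all
    peaks within the cell type and takes per-state medians of those
    z-scores. Both orderings of the two summaries are defensible
    readings of the divergence summary; the default is the first.

    Returns a tidy frame: state, cell_type, n_peaks, median_abs_lfc,
    divergence_z.
    """
    if mode not in ("zscore_of_median", "median_of_z"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = state_labels.reindex(asca_lfc.index)
    rows = []
    for ct in asca_lfc.columns:
        abs_lfc = asca_lfc[ct].abs()
        grouped = abs_lfc.groupby(labels)
        medians = grouped.median()
        counts = grouped.size()
        if len(medians) < 2:
            warnings.warn("fewer than 2 states present: z undefined",
                          stacklevel=2)
            z = pd.Series(np.nan, index=medians.index)
        elif mode == "zscore_of_median":
            sd = medians.std(ddof=1)
            # identical medians across states: zero divergence contrast
            z = (medians - medians.mean()) / sd if sd > 0 else \
                pd.Series(0.0, index=medians.index)
        else:
            mu, sd = abs_lfc.mean(), abs_lfc.std(ddof=1)
            z = ((abs_lfc - mu) / sd).groupby(labels).median()
        for state in medians.index:
            rows.append((state, ct, int(counts[state]),
                         float(medians[state]), float(z[state])))
    return pd.DataFrame(rows, columns=["state", "cell_type", "n_peaks",
                                       "median_abs_lfc", "divergence_z"])


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transformation (n-2 df)."""
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ase_asca_correlation(
    asca_lfc: pd.DataFrame,
    ase_lfc: pd.DataFrame,
    pairing: pd.DataFrame,
    state_labels: pd.Series,
    peak_p_values: pd.DataFrame | None = None,
    min_peaks: int = MIN_PEAKS_FOR_CORRELATION,
    proximal_distance: float = PROXIMAL_DISTANCE,
    promoter_states: frozenset[str] = PROMOTER_STATES,
) -> pd.DataFrame:
    """Pearson correlation of ASCA vs nearest-gene ASE per (state, cell type).

    Subsets reported: ``all`` peaks; ``nominal_asca`` (peak binomial
    p < 0.05, requires ``peak_p_values``); ``excl_promoter`` (promoter
    states removed); ``proximal`` (< ``proximal_distance`` bases from
    the TSS, promoters removed) and ``distal`` (>= that distance).
    Correlations are only reported for cells of the grid holding at
    least ``min_peaks`` peaks.

    Returns a tidy frame: state, cell_type, subset, n, pearson_r,
    r_p_value.
    """
    pairs = pairing.join(state_labels.rename("state"))
    pairs = pairs[pairs["gene_id"].isin(ase_lfc.index)
                  & pairs.index.isin(asca_lfc.index)]
    rows = []
    for ct in asca_lfc.columns:
        if ct not in ase_lfc.columns:
            continue
        peak_v = asca_lfc.loc[pairs.index, ct].to_numpy()
        gene_v = ase_lfc.loc[pairs["gene_id"], ct].to_numpy()
        base = pd.DataFrame({
            "state": pairs["state"].to_numpy(),
            "peak": peak_v,
            "gene": gene_v,
            "distance": pairs["distance"].to_numpy(),
        }, index=pairs.index)
        subsets: dict[str, pd.DataFrame] = {"all": base}
        if peak_p_values is not None:
            nominal = peak_p_values.loc[pairs.index, ct] < 0.05
            subsets["nominal_asca"] = base[nominal.to_numpy()]
        no_prom = base[~base["state"].isin(promoter_states)]
        subsets["excl_promoter"] = no_prom
        subsets["proximal"] = no_prom[no_prom["distance"] < proximal_distance]
        subsets["distal"] = no_prom[no_prom["distance"] >= proximal_distance]
        for subset_name, sub in subsets.items():
            for state, grp in sub.groupby("state"):
                n = len(grp)
                if n < min_peaks:
                    continue
                r, p = pearson_r(grp["peak"].to_numpy(), grp["gene"].to_numpy())
                rows.append((state, ct, subset_name, n, r, p))
    return pd.DataFrame(rows, columns=["state", "cell_type", "subset", "n",
                                       "pearson_r", "r_p_value"])
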