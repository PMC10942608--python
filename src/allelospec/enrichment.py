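"""2x2 enrichment of allelic imbalance among cell-type-specific features.

The central question: are cell-type-specific genes/peaks more likely to
show allelic imbalance than broadly expressed/accessible ones? The
statistic is the unconditional (sample) odds ratio of the 2x2 table
(specific x imbalanced) with a Wald normal-approximation confidence
interval and p-value, optionally stratified into equal-size bins of a
covariate (expression level, constraint, SNV count), plus a
split-replicate control that computes specificity and imbalance on
disjoint sample halves to guard against circularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import FeatureAnnotation

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class Enrichment2x2:
    """A 2x2 enrichment result.

    Cells: a = specific & imbalanced, b = specific & not, c = not
    specific & imbalanced, d = neither.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float
    stratum_label: str = ""
    zero_cell_corrected: bool = False
    undefined: bool = False


def odds_ratio_wald(a: int, b: int, c: int, d: int,
                    stratum_label: str = "") -> Enrichment2x2:
    """Sample odds ratio with Wald 95% CI and normal-approximation p.

    ``OR = ad/bc``; ``CI = exp(ln OR +- 1.96 * sqrt(1/a+1/b+1/c+1/d))``;
    p from ``z = ln OR / se``. A single zero cell triggers the
    Haldane-Anscombe +0.5 correction of all cells (flagged); two zero
    cells in the same row or column leave the OR undefined (NaN,
    flagged).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cells must be non-negative")
    undefined = (a == 0 and b == 0) or (c == 0 and d == 0) \
        or (a == 0 and c == 0) or (b == 0 and d == 0)
    if undefined:
        return Enrichment2x2(a, b, c, d, np.nan, np.nan, np.nan, np.nan,
                             stratum_label, False, True)
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 if corrected else float(x) for x in (a, b, c, d))
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    log_or = np.log(or_)
    ci_low = float(np.exp(log_or - Z_95 * se))
    ci_high = float(np.exp(log_or + Z_95 * se))
    p = float(2.0 * stats.norm.sf(abs(log_or) / se))
    return Enrichment2x2(a, b, c, d, float(or_), ci_low, ci_high, p,
                         stratum_label, corrected, False)


def enrichment_2x2(specific: pd.Series, imbalanced: pd.Series,
                   stratum_label: str = "") -> Enrichment2x2:
    """Build the (specific x imbalanced) 2x2 over a shared feature universe."""
    if len(specific) == 0:
        raise ValueError("empty feature universe")
    common = specific.index.intersection(imbalanced.index)
    if len(common) == 0:
        raise ValueError("specificity and imbalance cover disjoint features")
    s = specific.loc[common].astype(bool)
    m = imbalanced.loc[common].astype(bool)
    a = int((s & m).sum())
    b = int((s & ~m).sum())
    c = int((~s & m).sum())
    d = int((~s & ~m).sum())
    return odds_ratio_wald(a, b, c, d, stratum_label)


# spec-facing alias: the 2x2 of (specific to this cell type) x
# (significant imbalance in this cell type)
enrichment_specific_vs_imbalanced = enrichment_2x2


def equal_size_bins(stratum_values: pd.Series, n_bins: int = 5) -> pd.Series:
    """Assign features to ``n_bins`` equal-size rank bins (ascending).

    Ties are broken deterministically by feature id; remainder features
    go to the last bins. Returns integer bin labels 0..n_bins-1.
    """
    n = len(stratum_values)
    if n_bins > n:
        raise ValueError(f"more bins ({n_bins}) than features ({n})")
    order = stratum_values.reset_index()
    order.columns = ["feature_id", "value"]
    order = order.sort_values(["value", "feature_id"], kind="mergesort")
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i >= n_bins - rem else 0) for i in range(n_bins)]
    labels = np.repeat(np.arange(n_bins), sizes)
    out = pd.Series(labels, index=order["feature_id"].values)
    return out.loc[stratum_values.index]


def stratified_enrichment(specific: pd.Series, imbalanced: pd.Series,
                          stratum_values: pd.Series,
                          n_bins: int = 5) -> list[Enrichment2x2]:
    """Run the 2x2 within each equal-size bin of a per-feature covariate."""
    common = specific.index.intersection(imbalanced.index) \
        .intersection(stratum_values.index)
    bins = equal_size_bins(stratum_values.loc[common], n_bins)
    results = []
    for i in range(n_bins):
        feats = bins.index[bins == i]
        lo, hi = 100 * i // n_bins, 100 * (i + 1) // n_bins
        results.append(enrichment_2x2(
            specific.loc[feats], imbalanced.loc[feats],
            stratum_label=f"{lo}-{hi}%",
        ))
    return results


def split_samples(meta: pd.DataFrame, split_rule: str = "hybrid_line"
                  ) -> tuple[list[str], list[str]]:
    """Deterministically split samples into two groups.

    ``hybrid_line``: group A = first line (sorted), group B = the rest.
    ``replicate``: odd vs even replicate index. Cell types with no
    sample in one of the halves are excluded with a warning.
    """
    if split_rule == "hybrid_line":
        lines = sorted(meta["hybrid_line"].unique())
        if len(lines) < 2:
            raise ValueError("need >= 2 hybrid lines to split by line")
        in_a = meta["hybrid_line"] == lines[0]
    elif split_rule == "replicate":
        in_a = meta["replicate"] % 2 == 1
    else:
        raise ValueError(f"unknown split rule {split_rule!r}")
    a = meta.index[in_a]
    b = meta.index[~in_a]
    for ct in meta["cell_type"].unique():
        ct_samples = meta.index[meta["cell_type"] == ct]
        if not len(ct_samples.intersection(a)) or \
                not len(ct_samples.intersection(b)):
            warnings.warn(
                f"cell type {ct} has no sample in one split half; excluded",
                stacklevel=2,
            )
            a = a.difference(ct_samples)
            b = b.difference(ct_samples)
    return list(a), list(b)


def split_replicate_control(
    meta: pd.DataFrame,
    specificity_fn: Callable[[list[str]], pd.Series],
    imbalance_fn: Callable[[list[str]], pd.Series],
    split_rule: str = "hybrid_line",
    stratum_label: str = "split_control",
) -> Enrichment2x2:
    """Anti-circularity control: specificity and imbalance on disjoint halves.

    ``specificity_fn`` / ``imbalance_fn`` map a sample-id list to a
    per-feature boolean Series; they are evaluated on split A and split B
    respectively, and the 2x2 is built from the results.
    """
    a, b = split_samples(meta, split_rule)
    specific = specificity_fn(a)
    imbalanced = imbalance_fn(b)
    return enrichment_2x2(specific, imbalanced, stratum_label)


def snv_count_per_feature(features: Iterable[FeatureAnnotation],
                          snv_positions: pd.DataFrame) -> pd.Series:
    """Count SNV positions overlapping each feature (half-open intervals).

    ``snv_positions`` is a BED-like frame with columns chrom, start, end
    (single-base SNVs have end = start + 1).
    """
    features = list(features)
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in snv_positions.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"])
        )
    counts = {}
    for f in features:
        tree = trees.get(f.chrom)
        counts[f.feature_id] = len(tree.overlap(f.start, f.end)) if tree else 0
    return pd.Series(counts, name="snv_count")


def enrichment_to_frame(results: Sequence[Enrichment2x2]) -> pd.DataFrame:
    rows = [{
        "stratum": r.stratum_label, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "odds_ratio": r.odds_ratio, "ci95_low": r.ci95_low,
        "ci95_high": r.ci95_high, "p_value": r.p_value,
        "zero_cell_corrected": r.zero_cell_corrected,
        "undefined": r.undefined,
    } for r in results]
    return pd.DataFrame(rows)
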