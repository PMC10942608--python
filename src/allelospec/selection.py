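"""Lineage-specific selection test on gene-set cis-regulatory divergence.

Under neutral evolution, roughly equal numbers of genes in a pathway
should show human-biased and chimpanzee-biased allelic expression; a
significant directional excess (exact binomial test at p0 = 0.5,
BH-corrected across gene sets) rejects neutrality for that set. The
test is constraint-aware: each gene's interspecies allelic deviation is
compared against the spread of allelic ratios across many individuals
of one species (a cis-regulatory constraint proxy) with a Mann-Whitney
U test, and the signed score ``-log10(p) * sign(interspecies LFC)``
ranks genes for a preranked permutation enrichment. A set is called
under selection only if both the directional binomial test and the
rank-enrichment test pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allelic_tests import bh_fdr
from .io_formats import GeneSet

logger = logging.getLogger(__name__)

#: Largest number of label arrangements enumerated exactly by mann_whitney.
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass
class ConstraintEstimate:
    gene_id: str
    n_individuals_used: int
    ase_variance: float
    excluded_samples: int


def ase_variance(ref_counts: pd.DataFrame, alt_counts: pd.DataFrame,
                 min_count: int = 10) -> pd.DataFrame:
    """Variance of allelic ratios across individuals, per gene.

    Individuals with fewer than ``min_count`` reads from the reference OR
    the alternate allele are excluded for that gene (e.g. 11 ref / 2 alt
    is excluded). The variance is the n-1 sample variance of
    ``ref/(ref+alt)`` over the remaining individuals; NaN (flagged via
    ``n_individuals_used``) when fewer than 2 remain.

    Returns a frame indexed by gene with columns n_individuals_used,
    ase_variance, excluded_samples.
    """
    if not ref_counts.index.equals(alt_counts.index) or \
            not ref_counts.columns.equals(alt_counts.columns):
        raise ValueError("ref and alt tables must share genes and individuals")
    ref = ref_counts.to_numpy(dtype=float)
    alt = alt_counts.to_numpy(dtype=float)
    ok = (ref >= min_count) & (alt >= min_count)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(ok, ref / (ref + alt), np.nan)
    n_used = ok.sum(axis=1)
    var = np.full(len(ref_counts), np.nan)
    enough = n_used >= 2
    if enough.any():
        var[enough] = np.nanvar(ratio[enough], axis=1, ddof=1)
    return pd.DataFrame({
        "n_individuals_used": n_used,
        "ase_variance": var,
        "excluded_samples": ref_counts.shape[1] - n_used,
    }, index=ref_counts.index)


def population_deviations(ref_counts: pd.DataFrame, alt_counts: pd.DataFrame,
                          min_count: int = 10) -> pd.DataFrame:
    """|allelic ratio - 0.5| per gene and individual; NaN where excluded."""
    ref = ref_counts.to_numpy(dtype=float)
    alt = alt_counts.to_numpy(dtype=float)
    ok = (ref >= min_count) & (alt >= min_count)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = np.where(ok, np.abs(ref / (ref + alt) - 0.5), np.nan)
    return pd.DataFrame(dev, index=ref_counts.index,
                        columns=ref_counts.columns)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U of x over y with a two-sided p-value.

    Exact permutation p (enumeration of all label arrangements of the
    pooled sample, tie-aware) when C(nx+ny, nx) <= 20,000; otherwise the
    normal approximation with tie and continuity corrections. The
    two-sided p counts arrangements with |U' - nx*ny/2| >= |U - nx*ny/2|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mu = nx * ny / 2.0

    if math.comb(nx + ny, nx) <= EXACT_ENUMERATION_LIMIT:
        target = abs(u - mu)
        hits = total = 0
        offset = nx * (nx + 1) / 2.0
        for idx in combinations(range(nx + ny), nx):
            u_perm = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u_perm - mu) >= target - 1e-9:
                hits += 1
        return u, hits / total

    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    diff = u - mu
    if diff == 0:
        return u, 1.0
    z = (abs(diff) - 0.5) / math.sqrt(sigma2)
    return u, float(min(1.0, 2.0 * stats.norm.sf(z)))


def lfc_to_ratio_deviation(lfc) -> np.ndarray:
    """|allelic ratio - 0.5| implied by a log2 fold-change."""
    r = np.exp2(np.asarray(lfc, dtype=float))
    return np.abs(r / (1.0 + r) - 0.5)


@dataclass
class GeneSelectionScore:
    gene_id: str
    mw_p: float
    direction: str  # "human" or "chimp"
    signed_score: float


def gene_selection_scores(pop_deviations: pd.DataFrame,
                          interspecies_lfc: pd.DataFrame,
                          min_p: float = 1e-300) -> pd.DataFrame:
    """Signed per-gene selection scores, ranked descending.

    For each gene present in both inputs, the human-chimpanzee allelic
    deviations implied by the per-replicate interspecies LFCs are
    compared with the within-species population deviations by
    Mann-Whitney; the score is ``-log10(p)`` signed positive for
    human-biased genes (mean interspecies LFC > 0) and negative for
    chimpanzee-biased ones.

    Returns a frame with columns mw_p, direction, signed_score indexed
    by gene, sorted by signed_score descending (ties by gene id).
    """
    common = pop_deviations.index.intersection(interspecies_lfc.index)
    skipped = len(pop_deviations.index.union(interspecies_lfc.index)) - len(common)
    if skipped:
        logger.info("gene_selection_scores: %d genes missing from one input "
                    "were skipped", skipped)
    rows = []
    for g in common:
        pop = pop_deviations.loc[g].dropna().to_numpy()
        if pop.size == 0:
            logger.info("gene %s has no usable population samples; skipped", g)
            continue
        lfc_reps = interspecies_lfc.loc[g].dropna().to_numpy()
        if lfc_reps.size == 0:
            continue
        inter_dev = lfc_to_ratio_deviation(lfc_reps)
        _, p = mann_whitney(pop, inter_dev)
        mean_lfc = float(lfc_reps.mean())
        direction = "human" if mean_lfc >= 0 else "chimp"
        sign = 1.0 if direction == "human" else -1.0
        score = -math.log10(max(p, min_p)) * sign
        rows.append((g, p, direction, score))
    df = pd.DataFrame(rows, columns=["gene_id", "mw_p", "direction",
                                     "signed_score"]).set_index("gene_id")
    df = df.sort_values(["signed_score", "gene_id"],
                        ascending=[False, True], kind="mergesort")
    return df


def geneset_binomial(directions: pd.Series,
                     sets: Iterable[GeneSet]) -> pd.DataFrame:
    """Directional binomial test per gene set, BH-corrected across sets.

    ``directions`` maps gene -> "human"/"chimp". For each set, the
    exact two-sided binomial p of the human-biased count at p0 = 0.5
    (equal-tail doubling, capped at 1).
    """
    rows = []
    for gs in sets:
        members = [g for g in gs.members if g in directions.index]
        n = len(members)
        k_human = int((directions.loc[members] == "human").sum()) if n else 0
        if n == 0:
            p = np.nan
        else:
            lower = stats.binom.cdf(k_human, n, 0.5)
            upper = stats.binom.sf(k_human - 1, n, 0.5)
            p = min(1.0, 2.0 * min(lower, upper))
        rows.append((gs.name, k_human, n - k_human, n, p))
    df = pd.DataFrame(rows, columns=["set_name", "n_human_biased",
                                     "n_chimp_biased", "n", "binom_p"])
    df["binom_fdr"] = bh_fdr(df["binom_p"].to_numpy())
    return df.set_index("set_name")


def _es_from_indicator(weights: np.ndarray, in_set: np.ndarray) -> np.ndarray:
    """Weighted KS enrichment score per row of a boolean indicator matrix.

    ``weights`` has length N (|score|^weight in ranking order); ``in_set``
    is (n_rows, N). Ties in the running-sum extremum resolve to the
    first occurrence.
    """
    in_set = np.atleast_2d(in_set)
    n_rows, n = in_set.shape
    hit_w = in_set * weights
    denom = hit_w.sum(axis=1, keepdims=True)
    denom[denom == 0] = np.nan
    p_hit = np.cumsum(hit_w, axis=1) / denom
    k = in_set.sum(axis=1, keepdims=True)
    n_miss = n - k
    n_miss_safe = np.where(n_miss == 0, 1, n_miss)
    p_miss = np.cumsum(~in_set, axis=1) / n_miss_safe
    dev = p_hit - p_miss
    idx = np.abs(dev).argmax(axis=1)
    return dev[np.arange(n_rows), idx]


def preranked_enrichment(signed_scores: pd.Series, gene_set: GeneSet,
                         n_perm: int = 1000, weight: float = 1.0,
                         seed: int = 0) -> tuple[float, float]:
    """Weighted KS enrichment score of a gene set in a signed ranking.

    ``signed_scores`` is sorted descending internally (ties by first
    occurrence). The running sum increments by |score|^weight inside the
    set and decrements uniformly outside; ES is the maximum (signed)
    deviation. The null is ``n_perm`` random same-size gene sets drawn
    with a fixed seed; ``perm_p = (1 + #{|ES_null| >= |ES|}) /
    (1 + n_perm)``.
    """
    order = np.argsort(-signed_scores.to_numpy(), kind="mergesort")
    genes = signed_scores.index.to_numpy()[order]
    scores = signed_scores.to_numpy()[order]
    in_set = np.isin(genes, list(gene_set.members))
    k = int(in_set.sum())
    if k == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} has no genes in the ranking")
    n = len(genes)
    weights = np.abs(scores) ** weight
    es = float(_es_from_indicator(weights, in_set)[0])

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_perm, int(5e6 // max(n, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        null_ind = np.zeros((m, n), dtype=bool)
        for i in range(m):
            null_ind[i, rng.choice(n, size=k, replace=False)] = True
        es_null = _es_from_indicator(weights, null_ind)
        hits += int((np.abs(es_null) >= abs(es) - 1e-12).sum())
        done += m
    perm_p = (1 + hits) / (1 + n_perm)
    return es, perm_p


def preranked_enrichment_batch(signed_scores: pd.Series,
                               sets: Iterable[GeneSet],
                               n_perm: int = 1000, weight: float = 1.0,
                               seed: int = 0) -> pd.DataFrame:
    """ES and permutation p per set, with BH across sets (``es_fdr``)."""
    rows = []
    for i, gs in enumerate(sets):
        es, p = preranked_enrichment(signed_scores, gs, n_perm=n_perm,
                                     weight=weight, seed=seed + i)
        rows.append((gs.name, es, p))
    df = pd.DataFrame(rows, columns=["set_name", "es", "es_perm_p"])
    df["es_fdr"] = bh_fdr(df["es_perm_p"].to_numpy())
    return df.set_index("set_name")


def call_selection(binom_results: pd.DataFrame, es_results: pd.DataFrame,
                   binom_alpha: float = 0.05,
                   es_fdr_max: float = 0.25) -> pd.DataFrame:
    """Final selection verdict per gene set.

    Selected iff the directional binomial FDR is below ``binom_alpha``
    AND the rank-enrichment FDR is below ``es_fdr_max``. Direction is
    the majority allele bias in the set.
    """
    if set(binom_results.index) != set(es_results.index):
        raise ValueError("binomial and enrichment results cover different sets")
    df = binom_results.join(es_results)
    df["selected"] = (df["binom_fdr"] < binom_alpha) & (df["es_fdr"] < es_fdr_max)
    df["direction"] = np.where(
        df["n_human_biased"] >= df["n_chimp_biased"], "human", "chimp")
    return df
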