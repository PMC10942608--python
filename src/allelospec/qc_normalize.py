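"""Contamination correction, chromosome exclusion and count normalization.

The hybrid lines carried a partial chromosome 20 aneuploidy and some
samples contained a small fraction of pure chimpanzee parental cells.
The QC stage therefore (1) drops chr20 features entirely, (2) rescales
each sample's chimpanzee allele counts so the global log2(human/chimp)
ratio over the retained autosomes is exactly zero, and (3) removes
features whose allelic fold-change disagrees between the human- and
chimpanzee-referenced alignment runs (mapping bias).

The contamination correction is a continuous multiplicative rescaling
of chimpanzee counts (equivalent in expectation to subtracting the
contaminating reads but deterministic and proportion-preserving);
counts become real-valued downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AllelicCountTable

#: Chromosomes excluded from the global ratio computation by default:
#: chr20 (aneuploid in the hybrid lines) plus sex chromosomes, so the
#: ratio is computed "across all autosomes except chromosome 20". Sex
#: chromosome features are kept in the table; chr20 should be removed
#: separately with exclude_chromosomes.
DEFAULT_RATIO_EXCLUDE: frozenset[str] = frozenset({"chr20", "chrX", "chrY"})


@dataclass
class NormalizationReport:
    """Per-sample record of the global-ratio correction."""

    per_sample: pd.DataFrame
    # columns: global_human_total, global_chimp_total, scale_factor,
    #          estimated_contamination


def exclude_chromosomes(table: AllelicCountTable,
                        chroms: set[str] | frozenset[str]) -> AllelicCountTable:
    """Drop all features on the listed chromosomes, preserving order."""
    if not chroms:
        return table.copy()
    keep = ~table.chrom.isin(chroms)
    if not keep.any():
        warnings.warn("all features excluded; returning an empty table",
                      stacklevel=2)
    return table.subset_features(table.features[keep])


def estimate_contamination(scale_factor: float) -> float:
    """Contamination fraction implied by a global human/chimp ratio.

    With a fraction ``f`` of pure chimpanzee cells and balanced allelic
    expression, the expected global chimp:human ratio is
    ``1 + 2f/(1-f)``, i.e. the human/chimp scale factor is
    ``r = (1-f)/(1+f)``; inverting gives ``f = (1/r - 1)/(1/r + 1)``.
    Clipped to [0, 1): a sample with excess human reads (r > 1) implies
    no chimpanzee contamination.
    """
    inv = 1.0 / scale_factor
    return float(np.clip((inv - 1.0) / (inv + 1.0), 0.0, np.nextafter(1.0, 0.0)))


def correct_contamination(
    table: AllelicCountTable,
    exclude: set[str] | frozenset[str] = DEFAULT_RATIO_EXCLUDE,
) -> tuple[AllelicCountTable, NormalizationReport]:
    """Force each sample's global log2(human/chimp) over included features to 0.

    Per sample s, ``r_s = sum(human) / sum(chimp)`` over features outside
    ``exclude``; every chimpanzee count of the sample (all features) is
    multiplied by ``r_s``. Applied to every sample. The report records
    the totals, ``r_s`` and the implied contamination estimate.
    """
    include = ~table.chrom.isin(exclude)
    if not include.any():
        raise ValueError("no features outside the excluded chromosomes")
    h_tot = table.human.loc[include.values].sum(axis=0)
    c_tot = table.chimp.loc[include.values].sum(axis=0)
    if (c_tot == 0).any():
        bad = list(c_tot.index[c_tot == 0])
        raise ValueError(f"zero chimpanzee total for sample(s) {bad}")
    r = h_tot / c_tot

    corrected = table.copy()
    corrected.chimp = corrected.chimp * r  # column-wise broadcast
    report = NormalizationReport(per_sample=pd.DataFrame({
        "global_human_total": h_tot,
        "global_chimp_total": c_tot,
        "scale_factor": r,
        "estimated_contamination": r.map(estimate_contamination),
    }))
    return corrected, report


def dual_reference_filter(lfc_refH: pd.Series, lfc_refC: pd.Series,
                          max_abs_diff: float = 1.0) -> pd.Series:
    """Keep features whose LFC agrees between the two reference runs.

    Keep iff ``|lfc_refH - lfc_refC| <= max_abs_diff``. Features present
    under only one reference are dropped with a warning. Returns a
    boolean Series over the union of features.
    """
    common = lfc_refH.index.intersection(lfc_refC.index)
    union = lfc_refH.index.union(lfc_refC.index)
    if len(common) < len(union):
        warnings.warn(
            f"{len(union) - len(common)} features present under only one "
            "reference were dropped", stacklevel=2,
        )
    keep = pd.Series(False, index=union)
    diff = (lfc_refH.loc[common] - lfc_refC.loc[common]).abs()
    keep.loc[common] = diff <= max_abs_diff
    return keep


def dual_reference_sign_filter_atac(lfc_refH: pd.DataFrame,
                                    lfc_refC: pd.DataFrame,
                                    max_abs_diff: float = 1.0) -> pd.Series:
    """Replicate-resolved sign-discordance filter for ATAC peaks.

    Drop a peak iff in at least one replicate the two reference runs give
    opposite-sign LFCs with ``|difference| > max_abs_diff``. A zero LFC
    is sign-compatible with both signs. Inputs are feature x replicate
    frames with matching shape.
    """
    if not lfc_refH.index.equals(lfc_refC.index) or \
            not lfc_refH.columns.equals(lfc_refC.columns):
        raise ValueError("replicate LFC frames must share features and replicates")
    a, b = lfc_refH.to_numpy(), lfc_refC.to_numpy()
    opposite = (np.sign(a) * np.sign(b)) < 0  # zeros are compatible
    big_diff = np.abs(a - b) > max_abs_diff
    drop = (opposite & big_diff).any(axis=1)
    return pd.Series(~drop, index=lfc_refH.index)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per sample (columns)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"non-positive library total for sample(s) {bad}")
    return counts / totals * 1e6


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million given gene lengths in bases.

    Columns sum to 1e6 (within 1e-6).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene length for {missing}")
    if (lengths <= 0).any():
        bad = list(counts.index[lengths <= 0])[:5]
        raise ValueError(f"non-positive gene length for {bad}")
    rate = counts.div(lengths / 1e3, axis=0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero sample(s) {bad}: TPM undefined")
    return rate / totals * 1e6
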