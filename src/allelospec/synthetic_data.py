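"""Synthetic allelic-count data with the structure the analysis assumes.

The generator emulates the hybrid-cell study design: allelic RNA/ATAC
count tables for a panel of cell types (two hybrid lines, replicated),
a mixture of null / shared / cell-type-specific log2 fold-changes,
per-sample contamination by pure chimpanzee cells, dual-reference
mapping-bias artifacts, and population ASE samples with injectable
gene-set directional shifts.

Generative model for allelic counts: per feature g and sample s of cell
type c, the total count N_gs is negative binomial with mean
``depth x expression weight`` (weights log-normal) and size
``dispersion``; the human-allele count is Binomial(N_gs, p_gc) with
p_gc = 2^L / (1 + 2^L) for true log2 fold-change L; contamination f_s
adds round(f_s * N_gs / (1 - f_s)) pure-chimpanzee counts. Mapping bias
is modeled as a reference-conditional LFC distortion on a feature
subset: under exactly one reference genome, a biased feature's human
counts are rescaled by 2^(+-mapbias_shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ATAC_CELL_TYPES,
    CHROM_STATE_VOCAB,
    REF_CHIMP,
    REF_HUMAN,
    RNA_CELL_TYPES,
    AllelicCountTable,
    ChromStateAnnotation,
    FeatureAnnotation,
    GeneSet,
)

#: Chromosome labels over which simulated features are spread. chr20 is
#: included on purpose: the QC stage excludes it (aneuploidy in the real
#: lines) and the exclusion path needs features to act on.
SIM_CHROMS: tuple[str, ...] = tuple(
    f"chr{i}" for i in range(1, 23)
) + ("chrX",)


@dataclass
class SimConfig:
    """Parameters of the allelic-count generator.

    Defaults mirror the study design: 6 RNA / 5 ATAC cell types, 2 hybrid
    lines x 2 replicates, and a 70/15/15 null/shared/specific mixture of
    log2 fold-changes with unit standard deviation.
    """

    n_genes: int = 2000
    n_peaks: int = 3000
    cell_types: tuple[str, ...] = RNA_CELL_TYPES
    atac_cell_types: tuple[str, ...] = ATAC_CELL_TYPES
    n_lines: int = 2
    n_reps_per_line: int = 2
    depth_per_sample: float = 1e6
    pi_null: float = 0.70
    pi_shared: float = 0.15
    pi_specific: float = 0.15
    lfc_sd: float = 1.0
    dispersion: float = 20.0
    contamination: float | Mapping[str, float] = 0.0
    mapbias_fraction: float = 0.05
    mapbias_shift: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.pi_null + self.pi_shared + self.pi_specific
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pi_null + pi_shared + pi_specific must be 1, got {total}")
        for name in ("pi_null", "pi_shared", "pi_specific", "mapbias_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for f in self._contamination_values():
            if f < 0:
                raise ValueError(f"contamination must be >= 0, got {f}")
            if f >= 0.5:
                raise ValueError(
                    f"contamination {f} >= 0.5: the mixture model is invalid"
                )

    def _contamination_values(self) -> list[float]:
        if isinstance(self.contamination, Mapping):
            return list(self.contamination.values())
        return [float(self.contamination)]

    def contamination_for(self, sample_id: str) -> float:
        if isinstance(self.contamination, Mapping):
            return float(self.contamination.get(sample_id, 0.0))
        return float(self.contamination)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated tables."""

    true_lfc: pd.DataFrame            # feature x cell_type
    true_class: pd.Series             # "null" | "shared" | "specific:<ct>"
    true_contamination: pd.Series     # per sample
    mapbias: pd.Series                # per feature: 0 or signed shift applied
    mapbias_reference: pd.Series      # per feature: "", ref_human or ref_chimp


def _sample_grid(cell_types: Sequence[str], n_lines: int,
                 n_reps: int, assay: str) -> pd.DataFrame:
    rows = []
    for ct in cell_types:
        for line in range(1, n_lines + 1):
            for rep in range(1, n_reps + 1):
                sid = f"{ct}_hybrid{line}_rep{rep}"
                rows.append((sid, ct, f"hybrid{line}", rep, assay))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "hybrid_line", "replicate", "assay"]
    ).set_index("sample_id")
    return meta


def _draw_true_lfc(rng: np.random.Generator, features: pd.Index,
                   cell_types: Sequence[str], cfg: SimConfig
                   ) -> tuple[pd.DataFrame, pd.Series]:
    n = len(features)
    classes = rng.choice(
        ["null", "shared", "specific"], size=n,
        p=[cfg.pi_null, cfg.pi_shared, cfg.pi_specific],
    )
    lfc = np.zeros((n, len(cell_types)))
    labels = []
    for i, cls in enumerate(classes):
        if cls == "null":
            labels.append("null")
        elif cls == "shared":
            lfc[i, :] = rng.normal(0.0, cfg.lfc_sd)
            labels.append("shared")
        else:
            j = rng.integers(len(cell_types))
            lfc[i, j] = rng.normal(0.0, cfg.lfc_sd)
            labels.append(f"specific:{cell_types[j]}")
    return (
        pd.DataFrame(lfc, index=features, columns=list(cell_types)),
        pd.Series(labels, index=features, name="true_class"),
    )


def simulate_allelic_counts(
    config: SimConfig, assay: str = "RNA"
) -> tuple[AllelicCountTable, AllelicCountTable, SimTruth]:
    """Simulate paired dual-reference allelic count tables plus truth.

    Returns ``(table_refH, table_refC, truth)``. The two tables are
    identical except for the mapping-biased feature subset, whose human
    counts are distorted under exactly one reference. Fully reproducible
    given ``config.seed``.
    """
    if assay not in ("RNA", "ATAC"):
        raise ValueError(f"assay must be RNA or ATAC, got {assay!r}")
    cell_types = config.cell_types if assay == "RNA" else config.atac_cell_types
    n_feat = config.n_genes if assay == "RNA" else config.n_peaks
    prefix = "gene" if assay == "RNA" else "peak"
    features = pd.Index([f"{prefix}{i:05d}" for i in range(n_feat)],
                        name="feature_id")
    chrom = pd.Series(
        [SIM_CHROMS[i % len(SIM_CHROMS)] for i in range(n_feat)],
        index=features, name="chrom",
    )
    meta = _sample_grid(cell_types, config.n_lines, config.n_reps_per_line, assay)

    ss = np.random.SeedSequence(config.seed)
    rng_lfc, rng_counts, rng_bias = (np.random.default_rng(s) for s in ss.spawn(3))

    true_lfc, true_class = _draw_true_lfc(rng_lfc, features, cell_types, config)
    p_h = np.exp2(true_lfc.to_numpy())
    p_h = p_h / (1.0 + p_h)  # P(read is from the human allele)

    weights = rng_counts.lognormal(mean=0.0, sigma=1.0, size=n_feat)
    weights /= weights.sum()
    mean_counts = config.depth_per_sample * weights  # per feature, per sample

    human = np.empty((n_feat, len(meta)), dtype=np.int64)
    chimp = np.empty_like(human)
    contam = pd.Series(0.0, index=meta.index, name="contamination")
    ct_index = {ct: j for j, ct in enumerate(cell_types)}
    for k, (sid, row) in enumerate(meta.iterrows()):
        j = ct_index[row["cell_type"]]
        p_nb = config.dispersion / (config.dispersion + mean_counts)
        totals = rng_counts.negative_binomial(config.dispersion, p_nb)
        h = rng_counts.binomial(totals, p_h[:, j])
        c = totals - h
        f = config.contamination_for(sid)
        contam[sid] = f
        if f > 0:
            c = c + np.rint(f * totals / (1.0 - f)).astype(np.int64)
        human[:, k], chimp[:, k] = h, c

    human_df = pd.DataFrame(human, index=features, columns=meta.index)
    chimp_df = pd.DataFrame(chimp, index=features, columns=meta.index)

    # mapping bias: distort human counts of a feature subset under exactly
    # one of the two references
    n_bias = int(round(config.mapbias_fraction * n_feat))
    bias_idx = rng_bias.choice(n_feat, size=n_bias, replace=False)
    bias_sign = rng_bias.choice([-1.0, 1.0], size=n_bias)
    bias_ref = rng_bias.choice([REF_HUMAN, REF_CHIMP], size=n_bias)

    mapbias = pd.Series(0.0, index=features, name="mapbias")
    mapbias_reference = pd.Series("", index=features, name="mapbias_reference")
    humanH = human_df.to_numpy().astype(float)
    humanC = human_df.to_numpy().astype(float)
    for idx, sign, ref in zip(bias_idx, bias_sign, bias_ref):
        shift = sign * config.mapbias_shift
        mapbias.iloc[idx] = shift
        mapbias_reference.iloc[idx] = ref
        target = humanH if ref == REF_HUMAN else humanC
        target[idx, :] = np.rint(target[idx, :] * 2.0 ** shift)
    table_refH = AllelicCountTable(
        human=pd.DataFrame(humanH.astype(np.int64), index=features,
                           columns=meta.index),
        chimp=chimp_df.copy(), meta=meta.copy(), chrom=chrom.copy(),
        reference=REF_HUMAN,
    )
    table_refC = AllelicCountTable(
        human=pd.DataFrame(humanC.astype(np.int64), index=features,
                           columns=meta.index),
        chimp=chimp_df.copy(), meta=meta.copy(), chrom=chrom.copy(),
        reference=REF_CHIMP,
    )

    truth = SimTruth(
        true_lfc=true_lfc, true_class=true_class, true_contamination=contam,
        mapbias=mapbias, mapbias_reference=mapbias_reference,
    )
    return table_refH, table_refC, truth


# ---------------------------------------------------------------------------
# population ASE
# ---------------------------------------------------------------------------


def simulate_population_ase(
    n_genes: int,
    n_individuals: int,
    depth: float,
    constraint_profile: float | np.ndarray | pd.Series = 0.05,
    geneset_shift: tuple[GeneSet, str, float] | None = None,
    n_hybrid_reps: int = 4,
    hybrid_lfc_noise_sd: float = 0.1,
    seed: int = 0,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Simulate single-species population ASE plus an interspecies table.

    Per gene, individual allelic ratios are drawn around 0.5 with
    gene-specific spread ``constraint_profile`` (the constraint proxy:
    low spread = constrained cis-regulation), then sampled binomially at
    ``depth`` reads. Genes in an optional shifted set additionally
    receive an interspecies log2 fold-change of the stated sign
    (direction "human" = positive) and magnitude, emitted as a companion
    per-replicate interspecies LFC table.

    Returns a dict with keys ``ref_counts``, ``alt_counts`` (gene x
    individual), ``interspecies_lfc`` (gene x replicate), and
    ``true_lfc`` (per gene).
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    sd = np.broadcast_to(
        np.asarray(constraint_profile, dtype=float), (n_genes,)
    ).copy()
    if (sd < 0).any():
        raise ValueError("constraint_profile spreads must be >= 0")

    true_lfc = pd.Series(0.0, index=genes, name="true_lfc")
    if geneset_shift is not None:
        gs, direction, effect = geneset_shift
        if direction not in ("human", "chimp"):
            raise ValueError(f"direction must be human or chimp, got {direction!r}")
        sign = 1.0 if direction == "human" else -1.0
        members = [g for g in genes if g in gs.members]
        true_lfc[members] = sign * abs(effect)

    ss = np.random.SeedSequence(seed)
    rng_pop, rng_hyb = (np.random.default_rng(s) for s in ss.spawn(2))

    ratios = 0.5 + rng_pop.normal(0.0, sd[:, None], size=(n_genes, n_individuals))
    ratios = np.clip(ratios, 0.01, 0.99)
    totals = rng_pop.poisson(depth, size=(n_genes, n_individuals))
    ref = rng_pop.binomial(totals, ratios)
    alt = totals - ref
    individuals = [f"ind{j:03d}" for j in range(n_individuals)]
    ref_counts = pd.DataFrame(ref, index=genes, columns=individuals)
    alt_counts = pd.DataFrame(alt, index=genes, columns=individuals)

    inter = true_lfc.to_numpy()[:, None] + rng_hyb.normal(
        0.0, hybrid_lfc_noise_sd, size=(n_genes, n_hybrid_reps)
    )
    interspecies = pd.DataFrame(
        inter, index=genes, columns=[f"rep{j + 1}" for j in range(n_hybrid_reps)]
    )
    return {
        "ref_counts": ref_counts,
        "alt_counts": alt_counts,
        "interspecies_lfc": interspecies,
        "true_lfc": true_lfc,
    }


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def simulate_annotations(
    n_peaks: int,
    n_genes: int,
    genome_length: int,
    state_vocab: Sequence[str] = CHROM_STATE_VOCAB,
    n_chroms: int = 5,
    peak_width: int = 500,
    seed: int = 0,
) -> tuple[list[FeatureAnnotation], list[FeatureAnnotation], ChromStateAnnotation]:
    """Place genes and peaks uniformly on a toy genome and tile it with states.

    The genome is split into ``n_chroms`` equal chromosomes. Returns
    ``(genes, peaks, states)`` with feature ids matching the count
    simulator's naming (``gene00000`` / ``peak00000``). Deterministic
    given ``seed``.
    """
    chrom_len = genome_length // n_chroms
    max_width = max(peak_width, 5000)
    if chrom_len <= max_width or (n_peaks + n_genes) * max_width > genome_length * 2:
        raise ValueError(
            f"genome_length {genome_length} too small to place "
            f"{n_genes} genes and {n_peaks} peaks"
        )
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]

    genes = []
    for i in range(n_genes):
        length = int(rng.integers(1000, 5001))
        chrom = chroms[int(rng.integers(n_chroms))]
        start = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(FeatureAnnotation(
            feature_id=f"gene{i:05d}", chrom=chrom, start=start,
            end=start + length, strand=strand, kind="gene",
            gene_length=length,
        ))
    peaks = []
    for i in range(n_peaks):
        chrom = chroms[int(rng.integers(n_chroms))]
        start = int(rng.integers(0, chrom_len - peak_width))
        peaks.append(FeatureAnnotation(
            feature_id=f"peak{i:05d}", chrom=chrom, start=start,
            end=start + peak_width, kind="peak",
        ))

    # tile every chromosome with contiguous state intervals
    rows = []
    vocab = list(state_vocab)
    for chrom in chroms:
        pos = 0
        while pos < chrom_len:
            length = int(rng.integers(1000, 5001))
            end = min(pos + length, chrom_len)
            rows.append((chrom, pos, end, vocab[int(rng.integers(len(vocab)))]))
            pos = end
    states = ChromStateAnnotation(
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]),
        vocabulary=tuple(state_vocab),
    )
    return genes, peaks, states
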