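"""End-to-end pipeline: simulate -> QC -> tests -> downstream summaries.

Every stage writes a TSV into the output directory and a manifest
records the config, seed and SHA-256 of each output, so a rerun with
the same config and seed reproduces all outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allelic_tests import call_allelic_imbalance, lfc_matrix, significance_matrix
from .chromstate import assign_state, ase_asca_correlation, divergence_by_state
from .context_specificity import (
    concordance_test,
    dee_matrix,
    pair_peaks_to_genes,
    specific_imbalance_calls,
)
from .enrichment import enrichment_2x2, enrichment_to_frame
from .io_formats import GeneSet, write_bed, write_count_table, write_gmt
from .qc_normalize import correct_contamination, exclude_chromosomes
from .selection import (
    call_selection,
    gene_selection_scores,
    geneset_binomial,
    population_deviations,
    preranked_enrichment_batch,
)
from .specificity import all_pairwise_de, broad_specific_genes
from .synthetic_data import (
    SimConfig,
    simulate_allelic_counts,
    simulate_annotations,
    simulate_population_ase,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, panel and seed for a full pipeline run."""

    seed: int = 0
    alpha: float = 0.05
    max_abs_diff: float = 1.0
    min_mean: float = 25.0
    dee_min: float = 0.75
    tpm_low: float = 1.0
    tpm_high: float = 1.0
    peak_lfc_min: float = 0.5
    min_count: int = 10
    binom_alpha: float = 0.05
    es_fdr: float = 0.25
    bins: int = 5
    nperm: int = 1000
    exclude_chroms: tuple[str, ...] = ("chr20",)
    sim: SimConfig = field(default_factory=SimConfig)
    # selection-stage simulation sizes
    n_pop_individuals: int = 40
    pop_depth: float = 100.0
    n_gene_sets: int = 8
    gene_set_size: int = 50

    def __post_init__(self) -> None:
        for name in ("alpha", "binom_alpha", "es_fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("max_abs_diff", "min_mean", "dee_min", "tpm_low",
                     "tpm_high", "peak_lfc_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bins < 1 or self.nperm < 1:
            raise ValueError("bins and nperm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        if "exclude_chroms" in raw:
            raw["exclude_chroms"] = tuple(raw["exclude_chroms"])
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_chroms"] = list(self.exclude_chroms)
        d["sim"]["cell_types"] = list(self.sim.cell_types)
        d["sim"]["atac_cell_types"] = list(self.sim.atac_cell_types)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage on simulated inputs and write TSVs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.sim.seed or config.seed)

    # ---- simulate ------------------------------------------------------
    rna_H, rna_C, rna_truth = simulate_allelic_counts(sim, assay="RNA")
    atac_H, atac_C, atac_truth = simulate_allelic_counts(sim, assay="ATAC")
    write_count_table(rna_H, out / "rna_counts_refH.tsv", out / "rna_meta.tsv")
    write_count_table(rna_C, out / "rna_counts_refC.tsv")
    write_count_table(atac_H, out / "atac_counts_refH.tsv",
                      out / "atac_meta.tsv")
    write_count_table(atac_C, out / "atac_counts_refC.tsv")

    genes, peaks, states = simulate_annotations(
        n_peaks=sim.n_peaks, n_genes=sim.n_genes,
        genome_length=300_000_000, seed=config.seed,
    )
    write_bed(genes, out / "genes.bed")
    write_bed(peaks, out / "peaks.bed")
    write_bed(states, out / "states.bed")

    # ---- QC ------------------------------------------------------------
    tables = {}
    qc_reports = []
    for name, table in (("rna_refH", rna_H), ("rna_refC", rna_C),
                        ("atac_refH", atac_H), ("atac_refC", atac_C)):
        t = exclude_chromosomes(table, set(config.exclude_chroms))
        t, report = correct_contamination(t)
        tables[name] = t
        rep = report.per_sample.copy()
        rep.insert(0, "table", name)
        qc_reports.append(rep)
    pd.concat(qc_reports).to_csv(out / "qc_report.tsv", sep="\t")

    # ---- allelic tests -------------------------------------------------
    ase = call_allelic_imbalance(
        tables["rna_refH"], tables["rna_refC"], alpha=config.alpha,
        max_abs_diff=config.max_abs_diff)
    asca = call_allelic_imbalance(
        tables["atac_refH"], tables["atac_refC"], alpha=config.alpha,
        max_abs_diff=config.max_abs_diff, min_mean=config.min_mean)
    ase.to_csv(out / "ase_results.tsv", sep="\t", index=False)
    asca.to_csv(out / "asca_results.tsv", sep="\t", index=False)

    # ---- specificity + enrichment --------------------------------------
    total = tables["rna_refH"].human + tables["rna_refH"].chimp
    total_C = tables["rna_refC"].human + tables["rna_refC"].chimp
    meta = tables["rna_refH"].meta
    pw = {"ref_human": all_pairwise_de(total, meta),
          "ref_chimp": all_pairwise_de(total_C, meta)}
    spec_calls = broad_specific_genes(pw, alpha=config.alpha)
    spec_calls.calls.to_csv(out / "specificity_calls.tsv", sep="\t")

    sig = significance_matrix(ase)
    enr = []
    for ct in tables["rna_refH"].cell_types:
        res = enrichment_2x2(
            spec_calls.calls["specific_to"] == ct, sig[ct],
            stratum_label=ct)
        enr.append(res)
    enrichment_to_frame(enr).to_csv(out / "enrichment.tsv", sep="\t",
                                    index=False)

    # ---- selection ------------------------------------------------------
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = list(tables["rna_refH"].features)
    sets = []
    for i in range(config.n_gene_sets):
        members = rng.choice(gene_ids, size=min(config.gene_set_size,
                                                len(gene_ids)), replace=False)
        sets.append(GeneSet(name=f"set{i:02d}", members=frozenset(members)))
    write_gmt(sets, out / "gene_sets.gmt")
    pop = simulate_population_ase(
        n_genes=len(gene_ids), n_individuals=config.n_pop_individuals,
        depth=config.pop_depth, seed=config.seed + 2,
    )
    pop_dev = population_deviations(pop["ref_counts"], pop["alt_counts"],
                                    min_count=config.min_count)
    # interspecies replicate LFCs from the hybrid data (MN panel column)
    scores = gene_selection_scores(pop_dev, pop["interspecies_lfc"])
    binom = geneset_binomial(scores["direction"], sets)
    es = preranked_enrichment_batch(scores["signed_score"], sets,
                                    n_perm=config.nperm, seed=config.seed + 3)
    selection = call_selection(binom, es, binom_alpha=config.binom_alpha,
                               es_fdr_max=config.es_fdr)
    selection.to_csv(out / "selection.tsv", sep="\t")

    # ---- dEE / dCAE + concordance --------------------------------------
    shared_panel = [ct for ct in tables["atac_refH"].cell_types
                    if ct in tables["rna_refH"].cell_types]
    gene_lfc = lfc_matrix(ase)[shared_panel]
    peak_lfc = lfc_matrix(asca)[shared_panel]
    dee_rna = dee_matrix(gene_lfc)
    dcae_atac = dee_matrix(peak_lfc)
    dee_rna.to_csv(out / "dee.tsv", sep="\t")
    dcae_atac.to_csv(out / "dcae.tsv", sep="\t")

    gene_calls = specific_imbalance_calls(
        dee_rna, significance_matrix(ase)[shared_panel], config.dee_min)
    peak_calls = specific_imbalance_calls(
        dcae_atac, significance_matrix(asca)[shared_panel], config.dee_min)
    pairing = pair_peaks_to_genes(peaks, genes)
    conc = concordance_test(gene_calls, peak_calls, gene_lfc, peak_lfc,
                            pairing)
    with open(out / "concordance.json", "w") as fh:
        json.dump({
            "n_pairs": conc.n_pairs,
            "n_same_direction": conc.n_same_direction,
            "expected": conc.expected,
            "binom_p": None if np.isnan(conc.binom_p) else conc.binom_p,
        }, fh, indent=2)

    # ---- chromatin states ----------------------------------------------
    peak_states = assign_state(peaks, states).set_index("peak_id")["state"]
    div = divergence_by_state(peak_lfc, peak_states)
    div.to_csv(out / "state_divergence.tsv", sep="\t", index=False)
    p_mat = asca.pivot(index="feature_id", columns="cell_type",
                       values="p_value")[shared_panel]
    corr = ase_asca_correlation(peak_lfc, gene_lfc, pairing, peak_states,
                                peak_p_values=p_mat)
    corr.to_csv(out / "state_correlations.tsv", sep="\t", index=False)

    # ---- manifest -------------------------------------------------------
    cfg = config.to_dict()
    cfg_json = json.dumps(cfg, sort_keys=True)
    outputs = sorted(p.name for p in out.iterdir()
                     if p.suffix in (".tsv", ".bed", ".gmt", ".json")
                     and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return out
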