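"""Shared domain types and readers/writers for the pipeline's external formats.

The pipeline exchanges three plain-text formats:

* wide TSV count tables with one ``<sample>_human`` / ``<sample>_chimp``
  column pair per sample (plus ``feature_id`` and ``chrom`` columns),
* BED (0-based, half-open) for feature and chromatin-state annotations,
* GMT for gene sets.

All genomic intervals use the BED convention (0-based, half-open)
throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default cell-type panels. RNA was profiled in six lineages; ATAC in five
#: (no RPE ATAC data).
RNA_CELL_TYPES: tuple[str, ...] = ("MN", "CM", "HP", "PP", "SKM", "RPE")
ATAC_CELL_TYPES: tuple[str, ...] = ("MN", "CM", "HP", "PP", "SKM")

#: 15-label chromatin-state vocabulary (universal chromHMM-style states).
#: The tuple order is also the deterministic tie-break order when a peak
#: overlaps two states equally.
CHROM_STATE_VOCAB: tuple[str, ...] = (
    "TssA",        # active TSS
    "TssAFlnk",    # flanking promoter
    "TxFlnk",
    "Tx",
    "TxWk",
    "EnhG",
    "Enh",
    "ZNF_Rpts",
    "Het",         # heterochromatin
    "TssBiv",      # bivalent promoter
    "BivFlnk",
    "EnhBiv",
    "ReprPC",      # polycomb repressed
    "ReprPCWk",
    "Quies",       # quiescent
)

#: Promoter-related states excluded in promoter-free correlation subsets.
PROMOTER_STATES: frozenset[str] = frozenset({"TssA", "TssAFlnk", "TssBiv"})

REF_HUMAN = "ref_human"
REF_CHIMP = "ref_chimp"

_META_COLUMNS = ("cell_type", "hybrid_line", "replicate", "assay")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing sample (one library)."""

    sample_id: str
    cell_type: str
    hybrid_line: str
    replicate: int
    assay: str  # "RNA" or "ATAC"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if self.assay not in ("RNA", "ATAC"):
            raise ValueError(f"assay must be RNA or ATAC, got {self.assay!r}")


@dataclass
class AllelicCountTable:
    """Feature x sample table of paired human/chimpanzee allele counts.

    ``human`` and ``chimp`` are DataFrames indexed by feature_id with one
    column per sample_id; ``meta`` is indexed by sample_id with columns
    cell_type, hybrid_line, replicate, assay; ``chrom`` maps feature_id to
    its chromosome. ``reference`` records which genome the reads were
    aligned to (``ref_human`` or ``ref_chimp``): the full pipeline is run
    once per reference so that mapping-bias artifacts can be removed by
    requiring concordance between the two runs.

    Counts may be real-valued (post-normalization); raw tables are
    integer.
    """

    human: pd.DataFrame
    chimp: pd.DataFrame
    meta: pd.DataFrame
    chrom: pd.Series
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in (REF_HUMAN, REF_CHIMP):
            raise ValueError(f"reference must be {REF_HUMAN} or {REF_CHIMP}")
        if not self.human.index.equals(self.chimp.index):
            raise ValueError("human and chimp tables have mismatched features")
        if not self.human.columns.equals(self.chimp.columns):
            raise ValueError("human and chimp tables have mismatched samples")
        if not self.human.index.is_unique:
            raise ValueError("feature ids are not unique")
        if not self.human.columns.is_unique:
            raise ValueError("sample ids are not unique")
        missing = self.human.columns.difference(self.meta.index)
        if len(missing):
            raise ValueError(
                f"samples missing from metadata: {sorted(missing)}"
            )
        self.meta = self.meta.loc[self.human.columns, list(_META_COLUMNS)]
        missing_chrom = self.human.index.difference(self.chrom.index)
        if len(missing_chrom):
            raise ValueError(
                f"features missing a chromosome label: {sorted(missing_chrom)[:5]}"
            )
        self.chrom = self.chrom.loc[self.human.index]
        for name, mat in (("human", self.human), ("chimp", self.chimp)):
            vals = mat.to_numpy()
            if np.isnan(vals).any():
                raise ValueError(f"{name} counts contain NaN")
            if (vals < 0).any():
                i, j = np.argwhere(vals < 0)[0]
                raise ValueError(
                    f"negative {name} count at feature "
                    f"{mat.index[i]!r}, sample {mat.columns[j]!r}"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.human.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.human.columns

    @property
    def cell_types(self) -> list[str]:
        seen: list[str] = []
        for ct in self.meta["cell_type"]:
            if ct not in seen:
                seen.append(ct)
        return seen

    def samples_of(self, cell_type: str) -> list[str]:
        m = self.meta["cell_type"] == cell_type
        return list(self.meta.index[m])

    def subset_features(self, features: Sequence | pd.Index) -> "AllelicCountTable":
        features = pd.Index(features)
        return AllelicCountTable(
            human=self.human.loc[features].copy(),
            chimp=self.chimp.loc[features].copy(),
            meta=self.meta.copy(),
            chrom=self.chrom.loc[features].copy(),
            reference=self.reference,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "AllelicCountTable":
        cols = pd.Index(sample_ids)
        return AllelicCountTable(
            human=self.human.loc[:, cols].copy(),
            chimp=self.chimp.loc[:, cols].copy(),
            meta=self.meta.loc[cols].copy(),
            chrom=self.chrom.copy(),
            reference=self.reference,
        )

    def copy(self) -> "AllelicCountTable":
        return AllelicCountTable(
            human=self.human.copy(),
            chimp=self.chimp.copy(),
            meta=self.meta.copy(),
            chrom=self.chrom.copy(),
            reference=self.reference,
        )

    def equals(self, other: "AllelicCountTable") -> bool:
        return (
            self.reference == other.reference
            and self.human.equals(other.human)
            and self.chimp.equals(other.chimp)
            and self.chrom.equals(other.chrom)
            and self.meta.equals(other.meta)
        )


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic interval for a gene or a peak (0-based, half-open)."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "peak"  # "gene" or "peak"
    gene_length: int | None = None
    nearest_gene: str | None = None
    nearest_gene_distance: int | None = None
    snv_count: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval for {self.feature_id}: "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.nearest_gene_distance is not None and self.nearest_gene_distance < 0:
            raise ValueError("nearest_gene distance must be >= 0")
        if self.snv_count < 0:
            raise ValueError("snv_count must be >= 0")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware; genes only)."""
        return self.start if self.strand != "-" else self.end - 1


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ChromStateAnnotation:
    """BED-like chromatin-state segmentation with a fixed label vocabulary."""

    intervals: pd.DataFrame  # columns: chrom, start, end, state
    vocabulary: tuple[str, ...] = CHROM_STATE_VOCAB

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "state"}
        if not req.issubset(self.intervals.columns):
            raise ValueError(f"state intervals need columns {sorted(req)}")
        bad = ~self.intervals["state"].isin(self.vocabulary)
        if bad.any():
            raise ValueError(
                "state labels outside vocabulary: "
                f"{sorted(self.intervals.loc[bad, 'state'].unique())}"
            )
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("degenerate state interval (start >= end)")
        self.intervals = (
            self.intervals.sort_values(["chrom", "start", "end"])
            .reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, meta_path: str | Path,
                     reference: str = REF_HUMAN) -> AllelicCountTable:
    """Read a wide allelic count TSV plus its sample-metadata TSV.

    The count TSV has columns ``feature_id``, ``chrom`` and one
    ``<sample>_human`` / ``<sample>_chimp`` pair per sample. The metadata
    TSV has columns sample_id, cell_type, hybrid_line, replicate, assay.
    """
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "chrom": str})
    if "feature_id" not in df.columns or "chrom" not in df.columns:
        raise ValueError(f"{path}: expected 'feature_id' and 'chrom' columns")
    df = df.set_index("feature_id")
    chrom = df.pop("chrom")

    samples: list[str] = []
    for col in df.columns:
        if col.endswith("_human"):
            sid = col[: -len("_human")]
            if f"{sid}_chimp" not in df.columns:
                raise ValueError(f"{path}: column {sid}_chimp missing")
            samples.append(sid)
        elif not col.endswith("_chimp"):
            raise ValueError(f"{path}: unexpected column {col!r}")

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError(f"{meta_path}: expected a 'sample_id' column")
    meta = meta.set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype(int)
    orphans = [s for s in samples if s not in meta.index]
    if orphans:
        raise ValueError(
            f"samples present in counts but missing from metadata: {orphans}"
        )

    human = df[[f"{s}_human" for s in samples]].copy()
    human.columns = samples
    chimp = df[[f"{s}_chimp" for s in samples]].copy()
    chimp.columns = samples
    return AllelicCountTable(
        human=human, chimp=chimp, meta=meta.loc[samples], chrom=chrom,
        reference=reference,
    )


def write_count_table(table: AllelicCountTable, path: str | Path,
                      meta_path: str | Path | None = None) -> None:
    """Write a table in the wide TSV layout read by :func:`read_count_table`.

    Integer-valued counts round-trip bit-exactly; real-valued counts are
    written with 12 significant digits (round-trip within 1e-9).
    """
    out = pd.DataFrame(index=table.features)
    out["chrom"] = table.chrom
    for s in table.sample_ids:
        out[f"{s}_human"] = table.human[s]
        out[f"{s}_chimp"] = table.chimp[s]
    out.index.name = "feature_id"
    float_fmt = None
    hv, cv = table.human.to_numpy(), table.chimp.to_numpy()
    if not (np.all(hv == np.floor(hv)) and np.all(cv == np.floor(cv))):
        float_fmt = "%.12g"
    else:
        # write integers without a trailing .0
        for s in table.sample_ids:
            out[f"{s}_human"] = out[f"{s}_human"].astype(np.int64)
            out[f"{s}_chimp"] = out[f"{s}_chimp"].astype(np.int64)
    out.to_csv(path, sep="\t", float_format=float_fmt)
    if meta_path is not None:
        meta = table.meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, kind: str = "peak",
             state: bool = False) -> list[FeatureAnnotation] | ChromStateAnnotation:
    """Read a BED file (0-based, half-open), sorted by (chrom, start, end).

    With ``state=True`` the 4th column is interpreted as a chromatin-state
    label and a :class:`ChromStateAnnotation` is returned; otherwise a list
    of :class:`FeatureAnnotation` (4th column = name, optional 6th =
    strand).
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 else "."
            records.append((chrom, start, end, name, strand, lineno))

    records.sort(key=lambda r: (r[0], r[1], r[2]))
    if state:
        df = pd.DataFrame(
            [(c, s, e, n) for c, s, e, n, _, _ in records],
            columns=["chrom", "start", "end", "state"],
        )
        return ChromStateAnnotation(intervals=df)
    return [
        FeatureAnnotation(feature_id=n, chrom=c, start=s, end=e,
                          strand=st, kind=kind)
        for c, s, e, n, st, _ in records
    ]


def write_bed(features: Iterable[FeatureAnnotation] | ChromStateAnnotation,
              path: str | Path) -> None:
    with open(path, "w") as fh:
        if isinstance(features, ChromStateAnnotation):
            for row in features.intervals.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.state}\n")
        else:
            for f in sorted(features, key=lambda f: (f.chrom, f.start, f.end)):
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n"
                )


def annotations_to_frame(features: Iterable[FeatureAnnotation]) -> pd.DataFrame:
    """Tabular view of feature annotations, indexed by feature_id."""
    rows = [
        (f.feature_id, f.chrom, f.start, f.end, f.strand, f.kind,
         f.gene_length, f.snv_count)
        for f in features
    ]
    df = pd.DataFrame(
        rows,
        columns=["feature_id", "chrom", "start", "end", "strand", "kind",
                 "gene_length", "snv_count"],
    ).set_index("feature_id")
    if not df.index.is_unique:
        raise ValueError("duplicate feature ids in annotation")
    return df


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line (name, description, members...).

    Duplicate members within a line are de-duplicated with a warning;
    duplicate set names are an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one member"
                )
            name, members = fields[0], [m for m in fields[2:] if m]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            uniq = frozenset(members)
            if len(uniq) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} has duplicate members; "
                    "de-duplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, members=uniq))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\tna\t{members}\n")
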