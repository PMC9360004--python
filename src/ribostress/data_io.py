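"""Tabular input/output with strict validation.

All on-disk formats are plain text: tab-separated tables with a header line
(optionally preceded by ``# key=value`` provenance comments) for counts,
sample metadata and gene models, and the standard GMT dialect for gene sets.

Coordinate convention: transcript-local, 0-based, half-open
``[cds_start, cds_end)``.  Gene and transcript identifiers are
case-sensitive; counts are non-negative integers (fractional multi-mapper
weighting is rejected by design — read weighting belongs upstream of this
pipeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "SampleMeta",
    "CountTable",
    "GeneSetCollection",
    "DataValidationError",
    "read_gene_model",
    "write_gene_model",
    "read_count_table",
    "write_count_table",
    "read_gmt",
    "write_gmt",
    "write_tsv",
]

ASSAYS = ("mrna", "ribo")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: which assay, condition and replicate it is."""

    sample_id: str
    assay: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise DataValidationError(
                f"sample {self.sample_id!r}: assay must be one of {ASSAYS}, "
                f"got {self.assay!r}"
            )
        if self.replicate < 1:
            raise DataValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


@dataclass
class GeneModel:
    """Transcript lengths, gene mapping and CDS intervals.

    ``table`` is indexed by ``transcript_id`` with columns ``gene_id``,
    ``length``, ``cds_start``, ``cds_end``.  This object is the coordinate
    authority for frame QC and normalization.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "length", "cds_start", "cds_end"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"gene model missing columns: {missing}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate transcript_id: {dups}")
        t = self.table
        bad = t[
            (t["cds_start"] < 0)
            | (t["cds_start"] >= t["cds_end"])
            | (t["cds_end"] > t["length"])
        ]
        if len(bad):
            raise DataValidationError(
                "CDS outside transcript bounds for rows: "
                + ", ".join(map(str, bad.index.tolist()[:10]))
            )
        frame_off = t[(t["cds_end"] - t["cds_start"]) % 3 != 0]
        if len(frame_off):
            warnings.warn(
                f"{len(frame_off)} transcript(s) with CDS length not divisible "
                f"by 3 (e.g. {frame_off.index[0]!r}); rows retained",
                stacklevel=2,
            )

    @property
    def transcript_ids(self) -> pd.Index:
        return self.table.index

    @property
    def lengths(self) -> pd.Series:
        return self.table["length"]

    @property
    def gene_of(self) -> pd.Series:
        """transcript_id -> gene_id mapping."""
        return self.table["gene_id"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountTable:
    """Raw read counts (transcripts x samples) plus sample metadata.

    ``counts`` is indexed by transcript_id with one column per sample_id, in
    the order the samples were declared.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if list(self.counts.columns) != [s.sample_id for s in self.samples]:
            raise DataValidationError("count columns do not match sample metadata order")
        if self.counts.index.has_duplicates:
            raise DataValidationError("duplicate transcript rows in count table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise DataValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise DataValidationError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def meta(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "assay": [s.assay for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def subset_assay(self, assay: str) -> "CountTable":
        keep = [s for s in self.samples if s.assay == assay]
        return CountTable(self.counts[[s.sample_id for s in keep]], keep)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> frozenset of gene ids."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataValidationError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_gene_model(path) -> GeneModel:
    """Read a gene-model TSV (transcript_id, gene_id, length, cds_start, cds_end).

    Duplicate transcript ids and CDS intervals outside the transcript are hard
    errors; a CDS length not divisible by 3 is a warning and the row is kept.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str, "gene_id": str})
    required = ["transcript_id", "gene_id", "length", "cds_start", "cds_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"gene model {path}: missing columns {missing}")
    df = df.set_index("transcript_id")
    return GeneModel(df[["gene_id", "length", "cds_start", "cds_end"]])


def write_gene_model(model: GeneModel, path, provenance: dict | None = None) -> None:
    write_tsv(model.table.reset_index(), path, provenance)


def read_count_table(path, meta_path) -> CountTable:
    """Read a count matrix and join its columns to sample metadata.

    The counts TSV has ``transcript_id`` first, one column per sample.  The
    metadata TSV is keyed by ``sample_id`` with ``assay``, ``condition`` and
    ``replicate`` columns.  Every count column must have metadata; metadata
    rows for samples absent from the counts are ignored with a warning.
    """
    counts = pd.read_csv(path, sep="\t", comment="#")
    if counts.columns[0] != "transcript_id":
        raise DataValidationError(f"{path}: first column must be transcript_id")
    counts = counts.set_index("transcript_id")

    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype={"sample_id": str})
    if meta["sample_id"].duplicated().any():
        raise DataValidationError(f"{meta_path}: duplicate sample_id")
    meta = meta.set_index("sample_id")

    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise DataValidationError(f"samples missing from metadata: {missing}")
    unused = [s for s in meta.index if s not in counts.columns]
    if unused:
        warnings.warn(f"metadata rows for unused samples ignored: {unused}", stacklevel=2)

    samples = [
        SampleMeta(
            sample_id=sid,
            assay=str(meta.at[sid, "assay"]),
            condition=str(meta.at[sid, "condition"]),
            replicate=int(meta.at[sid, "replicate"]),
        )
        for sid in counts.columns
    ]
    return CountTable(counts, samples)


def write_count_table(table: CountTable, counts_path, meta_path, provenance: dict | None = None) -> None:
    write_tsv(table.counts.reset_index(), counts_path, provenance)
    write_tsv(table.meta.reset_index(), meta_path, provenance)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member ids.

    Duplicate members within a line are deduplicated; a duplicate set name or
    a line with fewer than three fields is a hard error.
    """
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *members = fields
            if name in sets:
                raise DataValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a DataFrame as TSV with an optional ``# key=value`` comment header."""
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)
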