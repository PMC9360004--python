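"""RPKM normalization, detection filtering and ribosome occupancy.

Expression is quantified as RPKM (reads per kilobase of transcript per
million total aligned reads).  Per-sample totals are always computed on the
input count table as given — never after any filtering — so RPKM is exactly
linear in counts within a sample.

Ribosome occupancy of a transcript in a condition is the ratio of the mean
Ribo-seq signal to the mean mRNA-seq signal across replicates, a per-
transcript proxy for translation efficiency.  Occupancy is computed on RPKM
by default ("normalized values"); ``basis='raw'`` preserves the literal
raw-count reading (the two differ only by the per-sample library/length
factors, which cancel within a transcript only for matched totals).

No pseudocounts are used anywhere: zeros are removed by the detection
filter, which keeps a transcript only if it has signal in every replicate of
every condition in BOTH assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CountTable, DataValidationError, GeneModel, SampleMeta

__all__ = [
    "ExpressionTable",
    "OccupancyTable",
    "compute_rpkm",
    "apply_detection_filter",
    "compute_occupancy",
    "condition_means",
    "gene_representatives",
]


@dataclass
class ExpressionTable:
    """RPKM values (transcripts x samples) with the source sample metadata."""

    rpkm: pd.DataFrame
    samples: list[SampleMeta]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen


@dataclass
class OccupancyTable:
    """Per-condition occupancy with the two source means kept for audit.

    ``occupancy[t, c] = mean(ribo RPKM over replicates) / mean(mrna RPKM)``,
    defined only for detected transcripts (mRNA mean strictly positive).
    """

    occupancy: pd.DataFrame
    ribo_means: pd.DataFrame
    mrna_means: pd.DataFrame


def compute_rpkm(counts: CountTable, model: GeneModel) -> ExpressionTable:
    """RPKM: ``count / (length_kb) / (total_aligned_reads_millions)``.

    Every transcript must be present in the gene model; a sample with zero
    total reads is a hard error (its RPKM would be undefined).
    """
    missing = counts.counts.index.difference(model.transcript_ids)
    if len(missing):
        raise DataValidationError(
            f"{len(missing)} transcript(s) absent from gene model, e.g. {missing[0]!r}"
        )
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DataValidationError(f"sample(s) with zero total reads: {zero.index.tolist()}")
    lengths_kb = model.lengths.reindex(counts.counts.index) / 1000.0
    rpkm = counts.counts.div(totals / 1e6, axis=1).div(lengths_kb, axis=0)
    return ExpressionTable(rpkm, list(counts.samples))


def apply_detection_filter(mrna: ExpressionTable, ribo: ExpressionTable) -> set[str]:
    """Transcripts with signal in all replicates of all conditions, both assays.

    The rule is strict: a single zero in any of the libraries excludes the
    transcript.  Returns the detected transcript ids as a set.
    """
    shared = mrna.rpkm.index.intersection(ribo.rpkm.index)
    ok_mrna = (mrna.rpkm.loc[shared] > 0).all(axis=1)
    ok_ribo = (ribo.rpkm.loc[shared] > 0).all(axis=1)
    return set(shared[ok_mrna & ok_ribo])


def condition_means(expr: ExpressionTable, transcripts=None) -> pd.DataFrame:
    """Mean RPKM per condition across replicates (transcripts x conditions)."""
    conditions = expr.conditions()
    rpkm = expr.rpkm if transcripts is None else expr.rpkm.loc[list(transcripts)]
    out = {}
    for cond in conditions:
        cols = [s.sample_id for s in expr.samples if s.condition == cond]
        out[cond] = rpkm[cols].mean(axis=1)
    return pd.DataFrame(out)


def compute_occupancy(
    mrna: ExpressionTable,
    ribo: ExpressionTable,
    detected: set[str],
    basis: str = "rpkm",
    mrna_counts: CountTable | None = None,
    ribo_counts: CountTable | None = None,
) -> OccupancyTable:
    """Ribosome occupancy per condition, restricted to detected transcripts.

    ``basis='rpkm'`` (default) takes means of RPKM; ``basis='raw'`` takes
    means of raw counts and requires the two count tables.
    """
    order = [t for t in mrna.rpkm.index if t in detected]
    if basis == "rpkm":
        mrna_means = condition_means(mrna, order)
        ribo_means = condition_means(ribo, order)
    elif basis == "raw":
        if mrna_counts is None or ribo_counts is None:
            raise ValueError("basis='raw' requires the raw count tables")
        mrna_means = condition_means(
            ExpressionTable(mrna_counts.counts.astype(float), list(mrna_counts.samples)), order
        )
        ribo_means = condition_means(
            ExpressionTable(ribo_counts.counts.astype(float), list(ribo_counts.samples)), order
        )
    else:
        raise ValueError(f"unknown occupancy basis {basis!r}")

    if (mrna_means.to_numpy() <= 0).any():
        bad = mrna_means.index[(mrna_means <= 0).any(axis=1)].tolist()
        raise DataValidationError(
            f"mRNA mean is zero for requested transcript(s): {bad[:5]} — "
            "occupancy requires the detection filter"
        )
    occupancy = ribo_means / mrna_means
    return OccupancyTable(occupancy, ribo_means, mrna_means)


def gene_representatives(
    mrna: ExpressionTable, model: GeneModel, detected: set[str], control: str
) -> pd.Series:
    """gene_id -> representative transcript_id.

    Classification is transcript-level; gene-level summaries use the
    transcript with the highest mean mRNA RPKM in the control condition as
    the gene's representative.  This aggregation rule is a package policy.
    """
    order = [t for t in mrna.rpkm.index if t in detected]
    cols = [s.sample_id for s in mrna.samples if s.condition == control]
    means = mrna.rpkm.loc[order, cols].mean(axis=1)
    genes = model.gene_of.reindex(order)
    df = pd.DataFrame({"gene_id": genes, "mean": means, "transcript_id": order})
    idx = df.groupby("gene_id")["mean"].idxmax()
    reps = df.loc[idx].set_index("gene_id")["transcript_id"]
    return reps
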