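"""Footprint quality control: reading-frame periodicity and CDS enrichment.

Ribosome footprints from a 3-nt-stepping ribosome show a characteristic
periodicity: after shifting each read's 5' end to the ribosomal P site
(default offset +12 nt, the standard value for ~28-nt footprints), the
P sites of genuine footprints fall predominantly in frame 0 of the coding
sequence.  mRNA-seq fragments show no such bias and distribute across the
whole transcript, so the ratio of in-CDS fractions between the two assays
(CDS enrichment) is a second library-quality readout.

Footprint records are transcript-coordinate tuples
(transcript_id, five_prime_pos, length), read from a 3-column TSV; the
upstream conversion from transcriptome-aligned reads to this table is out of
scope (see :func:`footprints_from_alignments`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DataValidationError, GeneModel

__all__ = [
    "FrameDistribution",
    "read_footprints",
    "write_footprints",
    "frame_distribution",
    "cds_enrichment",
    "footprints_from_alignments",
]

DEFAULT_P_SITE_OFFSET = 12
DEFAULT_LENGTH_BOUNDS = (20, 40)  # size-selection window of the library prep

FOOTPRINT_COLUMNS = ["transcript_id", "five_prime_pos", "length"]


@dataclass
class FrameDistribution:
    """Fractions of P sites in frames 0/1/2 over ``n_reads`` counted reads.

    When no read survives filtering the fractions are NaN and ``defined``
    is False; this is a flagged empty result, not an error.
    """

    f0: float
    f1: float
    f2: float
    n_reads: int
    n_excluded: int = 0

    @property
    def defined(self) -> bool:
        return self.n_reads > 0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)


def read_footprints(
    path, model: GeneModel | None = None, length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS
) -> pd.DataFrame:
    """Read footprint records; validate coordinates against a gene model if given."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str})
    missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    lo, hi = length_bounds
    bad_len = df[(df["length"] < lo) | (df["length"] > hi)]
    if len(bad_len):
        raise DataValidationError(
            f"{len(bad_len)} read(s) outside length bounds [{lo}, {hi}]"
        )
    if (df["five_prime_pos"] < 0).any():
        raise DataValidationError("negative five_prime_pos")
    if model is not None:
        tx_len = model.lengths.reindex(df["transcript_id"]).to_numpy()
        if np.isnan(tx_len).any():
            unknown = df.loc[np.isnan(tx_len), "transcript_id"].unique().tolist()
            raise DataValidationError(f"reads on unknown transcripts: {unknown[:5]}")
        if ((df["five_prime_pos"] + df["length"]).to_numpy() > tx_len).any():
            raise DataValidationError("read extends past transcript end")
    return df[FOOTPRINT_COLUMNS]


def write_footprints(reads: pd.DataFrame, path, provenance: dict | None = None) -> None:
    from .data_io import write_tsv

    write_tsv(reads[FOOTPRINT_COLUMNS], path, provenance)


def frame_distribution(
    reads: pd.DataFrame,
    model: GeneModel,
    p_site_offset: int = DEFAULT_P_SITE_OFFSET,
) -> FrameDistribution:
    """Distribution of P-site reading frames over CDS-internal footprints.

    Only reads whose P site (5' end + offset) lies inside the annotated CDS
    are counted; frame = (p_site - cds_start) mod 3.  Reads on transcripts
    without a usable CDS annotation, or with the P site outside the CDS, are
    excluded and tallied in ``n_excluded``.
    """
    tx = reads["transcript_id"]
    known = tx.isin(model.transcript_ids)
    sub = reads[known]
    cds_start = model.table["cds_start"].reindex(sub["transcript_id"]).to_numpy()
    cds_end = model.table["cds_end"].reindex(sub["transcript_id"]).to_numpy()
    p_site = sub["five_prime_pos"].to_numpy() + p_site_offset
    in_cds = (p_site >= cds_start) & (p_site < cds_end)
    frames = np.mod(p_site[in_cds] - cds_start[in_cds], 3)
    n = int(in_cds.sum())
    n_excluded = len(reads) - n
    if n == 0:
        return FrameDistribution(np.nan, np.nan, np.nan, 0, n_excluded)
    counts = np.bincount(frames.astype(int), minlength=3)
    f0, f1, f2 = (counts / n).tolist()
    return FrameDistribution(f0, f1, f2, n, n_excluded)


def cds_enrichment(
    ribo_reads: pd.DataFrame,
    mrna_reads: pd.DataFrame,
    model: GeneModel,
    transcript_id: str,
    p_site_offset: int = DEFAULT_P_SITE_OFFSET,
) -> tuple[float, float, float]:
    """(ribo CDS fraction, mrna CDS fraction, ratio) for one transcript.

    Ribo-seq reads are located by their P site, mRNA-seq reads by their raw
    5' end (mRNA fragments have no ribosome geometry).  A zero mRNA CDS
    fraction leaves the ratio NaN (flagged undefined).
    """
    if transcript_id not in model.transcript_ids:
        raise DataValidationError(f"unknown transcript {transcript_id!r}")
    cds_start = int(model.table.at[transcript_id, "cds_start"])
    cds_end = int(model.table.at[transcript_id, "cds_end"])

    ribo = ribo_reads[ribo_reads["transcript_id"] == transcript_id]
    mrna = mrna_reads[mrna_reads["transcript_id"] == transcript_id]
    if len(ribo) == 0 or len(mrna) == 0:
        raise DataValidationError(
            f"no reads on {transcript_id!r} in one of the assays"
        )
    p_site = ribo["five_prime_pos"].to_numpy() + p_site_offset
    ribo_frac = float(((p_site >= cds_start) & (p_site < cds_end)).mean())
    five = mrna["five_prime_pos"].to_numpy()
    mrna_frac = float(((five >= cds_start) & (five < cds_end)).mean())
    ratio = ribo_frac / mrna_frac if mrna_frac > 0 else float("nan")
    return ribo_frac, mrna_frac, ratio


def footprints_from_alignments(*args, **kwargs):
    """Converter stub: transcriptome alignments -> footprint TSV.

    Producing the 3-column footprint table from aligned reads amounts to
    taking, for each transcriptome-aligned read, the transcript id, the
    0-based position of its 5'-most aligned base in transcript coordinates,
    and its aligned length, then writing the triples with
    :func:`write_footprints`.  Alignment itself (and BAM parsing) is
    deliberately outside this package; perform it upstream and export the
    triples as TSV.
    """
    raise NotImplementedError(
        "alignment-to-footprint conversion is upstream of this package; "
        "export (transcript_id, five_prime_pos, length) as TSV instead"
    )
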