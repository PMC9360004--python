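"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the structure of the study's deposited data: on the
order of 10^4 transcripts measured by two assays (mRNA-seq and Ribo-seq)
across three conditions (CON, CPA1, CPA18) with three replicates each,
negative-binomial counts, planted temporal regulation classes, and footprint
records carrying 3-nt periodicity.

Expected expression follows the multiplicative model

    E[mRNA RPKM | condition] = baseline * 2**(cumulative abundance L2DE)
    E[ribo RPKM | condition] = E[mRNA RPKM] * occupancy
                               * 2**(cumulative occupancy L2DE)

so the footprint L2DE equals abundance L2DE + occupancy L2DE by
construction.  Counts are negative binomial with variance mu + alpha*mu^2
(alpha = 0 reproduces the rounded means exactly).  Planted effect sizes are
either 0 or at least cutoff + margin (default margin 0.3 above the 0.32
grouping cutoff) so that noise-free classification is unambiguous.

All randomness flows from one integer seed through ``SeedSequence`` spawning
so the per-purpose streams are independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CountTable,
    GeneModel,
    GeneSetCollection,
    SampleMeta,
    write_count_table,
    write_gene_model,
    write_gmt,
    write_tsv,
)
from .riboqc import DEFAULT_P_SITE_OFFSET, FOOTPRINT_COLUMNS

__all__ = [
    "SyntheticTruth",
    "generate_gene_model",
    "generate_truth",
    "generate_counts",
    "generate_footprints",
    "generate_cohort_expression",
    "write_fixture",
    "DEFAULT_CONDITIONS",
]

DEFAULT_CONDITIONS = ("CON", "CPA1", "CPA18")
DEFAULT_MARGIN = 0.3

# trend geometry per planted class: (acute sign, chronic sign); 0 = no change
_CLASS_SIGNS = {
    "up/up": (1, 1),
    "up/down": (1, -1),
    "none/up": (0, 1),
    "down/down": (-1, -1),
    "down/up": (-1, 1),
    "none/down": (0, -1),
}
ABUNDANCE_CLASSES = {
    "G1": "up/up", "G2": "up/down", "G3": "none/up",
    "G4": "down/down", "G5": "down/up", "G6": "none/down",
}
OCCUPANCY_CLASSES = {
    "G7": "up/up", "G8": "up/down", "G9": "none/up",
    "G10": "none/down", "G11": "down/up", "G12": "down/down",
}


def _spawn(seed: int, stream: int) -> np.random.Generator:
    """One independent generator per (seed, purpose-stream) pair."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SyntheticTruth:
    """Planted per-transcript ground truth plus global simulation settings.

    ``table`` (indexed by transcript_id): baseline_rpkm, baseline_occupancy,
    abundance_group, occupancy_group and the four planted effect sizes
    (ab_acute, ab_chronic, occ_acute, occ_chronic, as L2DE).
    """

    table: pd.DataFrame
    dispersion: dict = field(default_factory=lambda: {"mrna": 0.05, "ribo": 0.05})
    library_size: dict = field(default_factory=lambda: {"mrna": 20_000_000, "ribo": 20_000_000})
    conditions: tuple = DEFAULT_CONDITIONS
    n_replicates: int = 3
    seed: int = 0

    def expected_rpkm(self, assay: str) -> pd.DataFrame:
        """Expected RPKM (transcripts x conditions) under the planted model."""
        t = self.table
        cum_ab = {
            self.conditions[0]: 0.0,
            self.conditions[1]: t["ab_acute"],
            self.conditions[2]: t["ab_acute"] + t["ab_chronic"],
        }
        cum_occ = {
            self.conditions[0]: 0.0,
            self.conditions[1]: t["occ_acute"],
            self.conditions[2]: t["occ_acute"] + t["occ_chronic"],
        }
        out = {}
        for cond in self.conditions:
            mrna = t["baseline_rpkm"] * 2.0 ** cum_ab[cond]
            if assay == "mrna":
                out[cond] = mrna
            else:
                out[cond] = mrna * t["baseline_occupancy"] * 2.0 ** cum_occ[cond]
        return pd.DataFrame(out)

    def expected_realized_rpkm(self, model, assay: str) -> pd.DataFrame:
        """Expected RPKM after per-library total normalization.

        RPKM is compositional: when the planted effects change a condition's
        total expression mass, every transcript's realized RPKM shifts by the
        condition's common normalization factor.  This returns the planted
        values on that realized (per-million) scale; contrasts of these
        values are what the pipeline recovers at zero dispersion.
        """
        expected = self.expected_rpkm(assay)
        lengths_kb = model.lengths.reindex(self.table.index) / 1000.0
        mass = expected.mul(lengths_kb, axis=0).sum(axis=0)  # per-condition count mass
        return expected.div(mass / 1e6, axis=1)

    def composition_shift(self, model, assay: str) -> pd.Series:
        """Common log2 shift of realized vs planted contrasts, per condition.

        The shift for condition c is -log2(mass_c / mass_control); it is the
        constant added to every transcript's realized L2DE against control.
        Small values (well below the grouping cutoff) mean the planted
        labels remain the unambiguous noise-free classification.
        """
        expected = self.expected_rpkm(assay)
        lengths_kb = model.lengths.reindex(self.table.index) / 1000.0
        mass = expected.mul(lengths_kb, axis=0).sum(axis=0)
        return -np.log2(mass / mass[self.conditions[0]])


def generate_gene_model(
    n_genes: int,
    transcripts_per_gene: int | tuple[int, int] = 1,
    seed: int = 0,
) -> GeneModel:
    """Random gene model: lengths 500-5000 nt, CDS a 3-multiple over 40-90%.

    ``transcripts_per_gene`` is either a constant or an inclusive (lo, hi)
    range sampled uniformly per gene.  Deterministic under ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _spawn(seed, 0)
    rows = []
    for gi in range(n_genes):
        gene = f"g{gi + 1:05d}"
        if isinstance(transcripts_per_gene, tuple):
            k = int(rng.integers(transcripts_per_gene[0], transcripts_per_gene[1] + 1))
        else:
            k = int(transcripts_per_gene)
        for ti in range(k):
            length = int(rng.integers(500, 5001))
            frac = rng.uniform(0.4, 0.9)
            cds_len = max(3, int(length * frac) // 3 * 3)
            cds_start = int(rng.integers(0, length - cds_len + 1))
            rows.append(
                {
                    "transcript_id": f"{gene}.t{ti + 1}",
                    "gene_id": gene,
                    "length": length,
                    "cds_start": cds_start,
                    "cds_end": cds_start + cds_len,
                }
            )
    df = pd.DataFrame(rows).set_index("transcript_id")
    return GeneModel(df)


def generate_truth(
    model: GeneModel,
    seed: int = 0,
    class_fraction: float = 0.24,
    margin: float = DEFAULT_MARGIN,
    group_cutoff: float = 0.32,
    dispersion: dict | None = None,
    library_size: dict | None = None,
    conditions: tuple = DEFAULT_CONDITIONS,
    n_replicates: int = 3,
) -> SyntheticTruth:
    """Plant regulation classes and baselines for every transcript.

    ``class_fraction`` of transcripts receive a temporal class (spread
    uniformly over the six classes) independently for the abundance and the
    occupancy channel; effect magnitudes are uniform in
    [cutoff + margin, cutoff + margin + 1].
    """
    rng = _spawn(seed, 1)
    n = len(model)
    ids = model.transcript_ids
    baseline_rpkm = np.exp(rng.normal(np.log(50.0), 1.0, size=n)).clip(min=2.0)
    baseline_occupancy = np.exp(rng.normal(0.0, 0.3, size=n))
    # expected count mass per transcript at baseline, for pairing (below)
    mass = baseline_rpkm * model.lengths.to_numpy() / 1000.0

    # A small set of dominant secretory-like transcripts carries ~half the
    # expression mass (as Ins mRNAs do in beta cells) and, below, absorbs the
    # planted mass imbalance so that realized RPKM contrasts equal the
    # planted effects exactly (RPKM is compositional; without a mass sink
    # every planting would shift all realized values by a common
    # per-condition constant).  Spreading the sink over several transcripts
    # keeps the per-library normalization total low-variance under
    # negative-binomial noise, which a single 50%-mass transcript would not.
    dominant_fraction = 0.5
    n_dominant = max(1, min(20, n // 10))
    dom = np.argsort(-mass, kind="stable")[:n_dominant]
    other_mass = mass.sum() - mass[dom].sum()
    scale = dominant_fraction / (1 - dominant_fraction) * other_mass / mass[dom].sum()
    baseline_rpkm[dom] *= scale
    mass[dom] *= scale

    # RPKM is compositional, so a mass-imbalanced planting would shift every
    # realized L2DE by a common per-condition constant and could push null
    # transcripts over the cutoff.  Classes are therefore planted in mirror
    # pairs (up/up with down/down etc.) with matched effect magnitudes on
    # mass-adjacent transcripts: the linear mass terms cancel within a pair,
    # leaving only the small convexity term (~0.1 log2 units at defaults).
    _MIRROR = {
        "up/up": "down/down", "down/down": "up/up",
        "up/down": "down/up", "down/up": "up/down",
        "none/up": "none/down", "none/down": "none/up",
    }

    def plant(class_map: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        labels = np.full(n, "none", dtype=object)
        acute = np.zeros(n)
        chronic = np.zeros(n)
        classed = np.nonzero(rng.random(n) < class_fraction)[0]
        classed = classed[~np.isin(classed, dom)]  # dominant transcripts are the mass sink
        classed = classed[np.argsort(-mass[classed], kind="stable")]
        trend_of = {v: k for k, v in class_map.items()}  # trend -> group label
        trends = list(class_map.values())
        lo = group_cutoff + margin
        for k in range(0, len(classed) - 1, 2):
            i, j = classed[k], classed[k + 1]
            trend = trends[int(rng.integers(0, len(trends)))]
            e_a, e_c = rng.uniform(lo, lo + 1.0, size=2)
            for idx, tr in ((i, trend), (j, _MIRROR[trend])):
                sa, sc = _CLASS_SIGNS[tr]
                labels[idx] = trend_of[tr]
                acute[idx] = sa * e_a
                chronic[idx] = sc * e_c
        if len(classed) % 2:  # leftover transcript has the smallest mass
            i = classed[-1]
            trend = trends[int(rng.integers(0, len(trends)))]
            sa, sc = _CLASS_SIGNS[trend]
            labels[i] = trend_of[trend]
            acute[i] = sa * rng.uniform(lo, lo + 1.0)
            chronic[i] = sc * rng.uniform(lo, lo + 1.0)
        return labels, acute, chronic

    ab_labels, ab_acute, ab_chronic = plant(ABUNDANCE_CLASSES)
    occ_labels, occ_acute, occ_chronic = plant(OCCUPANCY_CLASSES)

    # The mirror pairing cancels the linear mass terms but not the convexity
    # excess (2**e + 2**-e - 2 > 0), which still accumulates across planted
    # pairs.  The dominant transcripts absorb the exact residual: a shared
    # effect is solved per condition so each assay's total expected count
    # mass is constant, making realized RPKM contrasts equal the planted
    # effects for every other transcript.  Their truth labels then follow
    # from the solved effects under the same trend rules the classifier
    # applies.
    from .classification import _ABUNDANCE_MAP, _OCCUPANCY_MAP, _temporal_trend

    cum_ab = {0: np.zeros(n), 1: ab_acute, 2: ab_acute + ab_chronic}
    cum_occ = {0: np.zeros(n), 1: occ_acute, 2: occ_acute + occ_chronic}
    others = ~np.isin(np.arange(n), dom)
    dom_mrna = mass[dom].sum()
    dom_ribo = (mass * baseline_occupancy)[dom].sum()
    dom_ab = {0: 0.0}
    dom_occ = {0: 0.0}
    for c in (1, 2):
        m_mrna = mass * 2.0 ** cum_ab[c]
        m_ribo = m_mrna * baseline_occupancy * 2.0 ** cum_occ[c]
        target_mrna = mass[others].sum() + dom_mrna - m_mrna[others].sum()
        target_ribo = (
            (mass * baseline_occupancy)[others].sum() + dom_ribo - m_ribo[others].sum()
        )
        if target_mrna <= 0 or target_ribo <= 0:
            raise ValueError(
                "planted mass imbalance exceeds the dominant transcripts' "
                "capacity to absorb it; lower class_fraction or margin"
            )
        dom_ab[c] = float(np.log2(target_mrna / dom_mrna))
        dom_occ[c] = float(np.log2(target_ribo / dom_ribo) - dom_ab[c])
    ab_acute[dom], ab_chronic[dom] = dom_ab[1], dom_ab[2] - dom_ab[1]
    occ_acute[dom], occ_chronic[dom] = dom_occ[1], dom_occ[2] - dom_occ[1]
    for eff_acute, eff_overall, labels, trend_map in (
        (dom_ab[1], dom_ab[2], ab_labels, _ABUNDANCE_MAP),
        (dom_occ[1], dom_occ[2], occ_labels, _OCCUPANCY_MAP),
    ):
        trend = _temporal_trend(
            eff_acute, eff_overall - eff_acute, eff_overall, group_cutoff
        )
        labels[dom] = trend_map[trend] if trend is not None else "none"
        if min(
            abs(abs(v) - group_cutoff)
            for v in (eff_acute, eff_overall - eff_acute, eff_overall)
        ) < 0.02:
            import warnings

            warnings.warn(
                "dominant transcript's absorbed effect sits near the grouping "
                "cutoff; its truth label may be ambiguous under count rounding",
                stacklevel=2,
            )

    table = pd.DataFrame(
        {
            "baseline_rpkm": baseline_rpkm,
            "baseline_occupancy": baseline_occupancy,
            "abundance_group": ab_labels,
            "occupancy_group": occ_labels,
            "ab_acute": ab_acute,
            "ab_chronic": ab_chronic,
            "occ_acute": occ_acute,
            "occ_chronic": occ_chronic,
        },
        index=ids,
    )
    truth = SyntheticTruth(
        table=table,
        dispersion=dispersion or {"mrna": 0.05, "ribo": 0.05},
        library_size=library_size or {"mrna": 20_000_000, "ribo": 20_000_000},
        conditions=conditions,
        n_replicates=n_replicates,
        seed=seed,
    )
    import warnings

    for assay in ("mrna", "ribo"):
        shift = truth.composition_shift(model, assay)
        if shift.abs().max() > group_cutoff - 0.05:
            warnings.warn(
                f"{assay}: compositional shift {shift.abs().max():.3f} log2 "
                "approaches the grouping cutoff; planted labels may be "
                "ambiguous on the realized scale",
                stacklevel=2,
            )
    return truth


def generate_counts(truth: SyntheticTruth, model: GeneModel) -> tuple[CountTable, CountTable]:
    """Negative-binomial count tables (mRNA, ribo) under the planted model.

    Mean count = expected RPKM * (length/1000) * (library_size/10^6);
    dispersion alpha gives variance mu + alpha*mu^2; alpha = 0 yields the
    rounded means exactly.  Warns when the library is too shallow to
    represent the baselines (expected count < 1 for most transcripts).
    """
    import warnings

    lengths_kb = model.lengths.reindex(truth.table.index).to_numpy() / 1000.0
    tables = []
    for stream, assay in enumerate(("mrna", "ribo"), start=2):
        rng = _spawn(truth.seed, stream)
        expected = truth.expected_rpkm(assay)
        lib = truth.library_size[assay]
        alpha = truth.dispersion[assay]
        cols, metas = {}, []
        for cond in truth.conditions:
            mu = expected[cond].to_numpy() * lengths_kb * (lib / 1e6)
            # RPKM is compositional: realized values equal the planted ones
            # only if each library's mean counts sum to the library size, so
            # rescale the condition's mean vector to that total
            mu = mu * (lib / mu.sum())
            if (mu < 1).mean() > 0.5:
                warnings.warn(
                    f"{assay}/{cond}: library too shallow — expected count < 1 "
                    f"for {100 * (mu < 1).mean():.0f}% of transcripts",
                    stacklevel=2,
                )
            for rep in range(1, truth.n_replicates + 1):
                sid = f"{assay}_{cond}_{rep}"
                if alpha == 0:
                    counts = np.rint(mu).astype(np.int64)
                else:
                    counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
                cols[sid] = counts
                metas.append(SampleMeta(sid, assay, cond, rep))
        df = pd.DataFrame(cols, index=truth.table.index)
        df.index.name = "transcript_id"
        tables.append(CountTable(df, metas))
    return tables[0], tables[1]


def generate_footprints(
    model: GeneModel,
    n_reads: int,
    frame0_fraction: float,
    p_site_offset: int = DEFAULT_P_SITE_OFFSET,
    seed: int = 0,
    length_range: tuple[int, int] = (26, 32),
) -> pd.DataFrame:
    """Footprint records whose P sites hit frame 0 with the given probability.

    Reads land inside the CDS of eligible transcripts (those whose CDS leaves
    room for the 5' overhang and read length); the remaining probability mass
    is split equally between frames 1 and 2.  Deterministic under ``seed``.
    """
    if not 0 <= frame0_fraction <= 1:
        raise ValueError("frame0_fraction must be in [0, 1]")
    rng = _spawn(seed, 4)
    lo_len, hi_len = length_range
    t = model.table
    eligible = t[
        (t["cds_start"] >= p_site_offset)
        & (t["cds_end"] - t["cds_start"] >= 9)
        & (t["length"] - t["cds_end"] >= hi_len - p_site_offset)
    ]
    if eligible.empty:
        raise ValueError("no transcript can host footprints with these settings")
    pick = rng.integers(0, len(eligible), size=n_reads)
    cds_start = eligible["cds_start"].to_numpy()[pick]
    cds_end = eligible["cds_end"].to_numpy()[pick]
    n_codons = (cds_end - cds_start) // 3
    # frame-0 codon anchor, excluding the last codon so +2 stays inside
    codon = (rng.random(n_reads) * (n_codons - 1)).astype(np.int64)
    frame = np.where(
        rng.random(n_reads) < frame0_fraction,
        0,
        rng.integers(1, 3, size=n_reads),
    )
    p_site = cds_start + 3 * codon + frame
    lengths = rng.integers(lo_len, hi_len + 1, size=n_reads)
    return pd.DataFrame(
        {
            "transcript_id": eligible.index.to_numpy()[pick],
            "five_prime_pos": p_site - p_site_offset,
            "length": lengths,
        },
        columns=FOOTPRINT_COLUMNS,
    )


def generate_cohort_expression(
    n_genes: int,
    n_samples_per_group: int,
    shifted_genes: set,
    log2_shift: float,
    seed: int = 0,
    noise_sd: float = 0.5,
    group_labels: tuple[str, str] = ("CON", "T1D"),
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Log-normal two-group expression matrix with planted shifted genes.

    Genes in ``shifted_genes`` differ by ``log2_shift`` (log2 units, group 2
    relative to group 1).  Returns (genes x samples matrix, sample -> label
    series, per-gene truth table).
    """
    rng = _spawn(seed, 5)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    unknown = set(shifted_genes) - set(genes)
    if unknown:
        raise ValueError(f"shifted genes outside the generated namespace: {sorted(unknown)[:5]}")
    base = rng.uniform(3.0, 10.0, size=n_genes)  # log2 baseline per gene
    shift = np.array([log2_shift if g in shifted_genes else 0.0 for g in genes])
    cols, labels = {}, {}
    for gi, glabel in enumerate(group_labels):
        for si in range(1, n_samples_per_group + 1):
            sid = f"{glabel}_{si}"
            log2_expr = base + gi * shift + rng.normal(0.0, noise_sd, size=n_genes)
            cols[sid] = 2.0 ** log2_expr
            labels[sid] = glabel
    expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    truth = pd.DataFrame(
        {"shifted": [g in shifted_genes for g in genes], "log2_shift": shift},
        index=expr.index,
    )
    return expr, pd.Series(labels), truth


def _pathway_collection(truth: SyntheticTruth, model: GeneModel, seed: int) -> GeneSetCollection:
    """Stand-in pathway sets: one enriched for planted-up genes, one random."""
    rng = _spawn(seed, 6)
    gene_of = model.gene_of
    up = sorted(
        {
            gene_of[t]
            for t, row in truth.table.iterrows()
            if row["abundance_group"] in ("G1", "G3") or row["occupancy_group"] in ("G7", "G9")
        }
    )
    all_genes = sorted(set(gene_of))
    n_up = min(len(up), 40)
    n_bg = min(len(all_genes), 30)
    er_set = set(rng.choice(up, size=n_up, replace=False)) if n_up else set()
    er_set |= set(rng.choice(all_genes, size=n_bg, replace=False))
    random_set = set(rng.choice(all_genes, size=min(len(all_genes), 50), replace=False))
    return GeneSetCollection(
        {
            "ER_PROTEIN_PROCESSING_SYNTHETIC": frozenset(er_set),
            "RANDOM_SET_SYNTHETIC": frozenset(random_set),
        },
        {
            "ER_PROTEIN_PROCESSING_SYNTHETIC": "synthetic stand-in, enriched for planted-up genes",
            "RANDOM_SET_SYNTHETIC": "synthetic random background set",
        },
    )


def write_fixture(
    outdir,
    n_genes: int = 2000,
    seed: int = 0,
    dispersion: float = 0.05,
    n_footprints: int = 10_000,
    frame0_fraction: float = 0.85,
) -> Path:
    """Write a complete fixture directory: counts, metadata, gene model, GMT,
    footprints and the truth table.  Everything is derived from ``seed``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = generate_gene_model(n_genes, seed=seed)
    truth = generate_truth(
        model, seed=seed, dispersion={"mrna": dispersion, "ribo": dispersion}
    )
    mrna, ribo = generate_counts(truth, model)
    reads = generate_footprints(model, n_footprints, frame0_fraction, seed=seed)
    pathways = _pathway_collection(truth, model, seed)

    prov = {"generator": "ribostress.synthetic", "seed": seed}
    write_gene_model(model, outdir / "gene_model.tsv", prov)
    write_count_table(mrna, outdir / "mrna_counts.tsv", outdir / "mrna_meta.tsv", prov)
    write_count_table(ribo, outdir / "ribo_counts.tsv", outdir / "ribo_meta.tsv", prov)
    write_tsv(reads, outdir / "footprints.tsv", prov)
    write_gmt(pathways, outdir / "pathways.gmt")
    write_tsv(truth.table.reset_index().rename(columns={"index": "transcript_id"}),
              outdir / "truth.tsv", prov)
    return outdir
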