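"""Pipeline orchestration behind a declarative YAML configuration.

Every analysis threshold surfaces as a named config key with the study value
as its default: grouping cutoff 0.32, regulation-mode cutoff 0.6, FDR
cutoff 1e-3, footprint length window 20-40 nt, P-site offset 12 nt.  A run
writes expression, occupancy, L2DE, assignment, summary, gene-set,
enrichment and QC tables plus a provenance log (config hash, package
version, seed), and is idempotent: rerunning the same config reproduces
byte-identical outputs.  Logging is at stage granularity with record counts
in and out of every filter, so marginal group sizes are always auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classification import classify_dataset
from .data_io import read_count_table, read_gene_model, read_gmt, write_tsv
from .genesets import (
    GeneChange,
    changes_from_l2de,
    derive_adaptome,
    derive_cell_specific_set,
    hypergeometric_enrichment,
)
from .normalization import (
    apply_detection_filter,
    compute_occupancy,
    compute_rpkm,
    gene_representatives,
)
from .riboqc import frame_distribution, read_footprints

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("ribostress")


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see module docstring for defaults."""

    mrna_counts: str
    mrna_meta: str
    ribo_counts: str
    ribo_meta: str
    gene_model: str
    outdir: str
    footprints: str | None = None
    pathways: str | None = None
    reference_changes: str | None = None
    conditions: dict = field(
        default_factory=lambda: {"control": "CON", "acute": "CPA1", "chronic": "CPA18"}
    )
    group_cutoff: float = 0.32
    mode_cutoff: float = 0.6
    change_cutoff: float = 0.6
    fdr_cutoff: float = 1e-3
    occupancy_basis: str = "rpkm"
    mode_y: str = "footprints"
    p_site_offset: int = 12
    footprint_length_bounds: tuple = (20, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        for key in ("group_cutoff", "mode_cutoff", "change_cutoff", "fdr_cutoff"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be > 0")
        for role in ("control", "acute", "chronic"):
            if role not in self.conditions:
                raise ValueError(f"conditions must define {role!r}")
        self.footprint_length_bounds = tuple(self.footprint_length_bounds)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def condition_triple(self) -> tuple[str, str, str]:
        return (
            self.conditions["control"],
            self.conditions["acute"],
            self.conditions["chronic"],
        )


def _validate_conditions(config: PipelineConfig, table) -> None:
    declared = set(table.conditions())
    wanted = set(config.condition_triple())
    missing = wanted - declared
    if missing:
        raise ValueError(
            f"contrast references condition(s) absent from metadata: {sorted(missing)}"
        )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages and write the report directory; returns its path."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {
        "package": "ribostress",
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
    }

    # --- stage: load -------------------------------------------------------
    logger.info("stage load: reading inputs")
    model = read_gene_model(config.gene_model)
    mrna_counts = read_count_table(config.mrna_counts, config.mrna_meta)
    ribo_counts = read_count_table(config.ribo_counts, config.ribo_meta)
    _validate_conditions(config, mrna_counts)
    _validate_conditions(config, ribo_counts)
    logger.info(
        "stage load: %d transcripts, %d mrna samples, %d ribo samples",
        len(mrna_counts.counts), len(mrna_counts.samples), len(ribo_counts.samples),
    )

    # --- stage: normalize --------------------------------------------------
    mrna = compute_rpkm(mrna_counts, model)
    ribo = compute_rpkm(ribo_counts, model)
    detected = apply_detection_filter(mrna, ribo)
    logger.info(
        "stage normalize: detection filter kept %d / %d transcripts",
        len(detected), len(mrna.rpkm),
    )
    occ = compute_occupancy(
        mrna, ribo, detected, basis=config.occupancy_basis,
        mrna_counts=mrna_counts, ribo_counts=ribo_counts,
    )
    write_tsv(mrna.rpkm.reset_index(), outdir / "mrna_rpkm.tsv", prov)
    write_tsv(ribo.rpkm.reset_index(), outdir / "ribo_rpkm.tsv", prov)
    occ_out = occ.occupancy.copy()
    for cond in occ_out.columns:
        occ_out[f"ribo_mean_{cond}"] = occ.ribo_means[cond]
        occ_out[f"mrna_mean_{cond}"] = occ.mrna_means[cond]
    write_tsv(occ_out.reset_index(), outdir / "occupancy.tsv", prov)

    # --- stage: classify ---------------------------------------------------
    result = classify_dataset(
        mrna, ribo, occ,
        conditions=config.condition_triple(),
        group_cutoff=config.group_cutoff,
        mode_cutoff=config.mode_cutoff,
        mode_y=config.mode_y,
    )
    write_tsv(result.l2de, outdir / "l2de.tsv", prov)
    write_tsv(result.assignments, outdir / "assignments.tsv", prov)
    write_tsv(result.modes, outdir / "modes.tsv", prov)
    write_tsv(result.summary, outdir / "summary.tsv", prov)
    logger.info(
        "stage classify: %d transcripts classified across %d contrasts",
        len(result.assignments), result.l2de["contrast"].nunique(),
    )

    # --- stage: genesets ---------------------------------------------------
    control = config.conditions["control"]
    reps = gene_representatives(mrna, model, detected, control)
    rep_tx = reps.to_numpy()
    overall = result.l2de[result.l2de["contrast"] == "overall"].set_index("transcript_id")
    gene_x = pd.Series(overall.loc[rep_tx, "x"].to_numpy(), index=reps.index)
    gene_occ = pd.Series(overall.loc[rep_tx, "occ_l2de"].to_numpy(), index=reps.index)
    changes = changes_from_l2de(gene_x, "abundance", "overall", config.change_cutoff)
    changes += changes_from_l2de(gene_occ, "occupancy", "overall", config.change_cutoff)

    if config.reference_changes:
        ref_df = pd.read_csv(config.reference_changes, sep="\t", comment="#")
        reference = [
            GeneChange(r.gene_id, r.direction, r.channel, r.contrast)
            for r in ref_df.itertuples()
        ]
    else:
        reference = []
    regulome = derive_cell_specific_set(changes, reference, name="regulome")
    write_tsv(regulome.to_frame(), outdir / "regulome.tsv", prov)
    logger.info(
        "stage genesets: %d changed genes -> regulome of %d after reference filter",
        len({c.gene_id for c in changes}), len(regulome),
    )

    if config.pathways:
        pathways = read_gmt(config.pathways)
        universe = set(reps.index)
        up_ab = {g for g, v in gene_x.items() if v >= config.change_cutoff}
        up_occ = {g for g, v in gene_occ.items() if v >= config.change_cutoff}
        ref_genes = {c.gene_id for c in reference}
        enr_rows = []
        gene_group = pd.Series(
            result.assignments.set_index("transcript_id")
            .loc[rep_tx, "abundance_group"].to_numpy(),
            index=reps.index,
        )
        for pname, members in pathways.sets.items():
            for group in sorted(gene_group.unique()):
                hits = set(gene_group.index[gene_group == group])
                k, p = hypergeometric_enrichment(hits, universe, set(members))
                enr_rows.append(
                    {"pathway": pname, "group": group, "overlap": k,
                     "n_hits": len(hits), "p_value": p}
                )
        write_tsv(pd.DataFrame(enr_rows), outdir / "enrichment.tsv", prov)

        first = next(iter(pathways.sets))
        adaptome = derive_adaptome(
            up_ab, up_occ, set(pathways.sets[first]), ref_genes, name="adaptome"
        )
        write_tsv(adaptome.to_frame(), outdir / "adaptome.tsv", prov)
        logger.info("stage genesets: adaptome of %d genes from pathway %r", len(adaptome), first)

    # --- stage: qc ---------------------------------------------------------
    if config.footprints:
        reads = read_footprints(
            config.footprints, model, length_bounds=config.footprint_length_bounds
        )
        dist = frame_distribution(reads, model, p_site_offset=config.p_site_offset)
        qc = pd.DataFrame(
            [
                {
                    "metric": "frame0_fraction", "value": dist.f0,
                    "n_reads": dist.n_reads, "n_excluded": dist.n_excluded,
                },
                {"metric": "frame1_fraction", "value": dist.f1,
                 "n_reads": dist.n_reads, "n_excluded": dist.n_excluded},
                {"metric": "frame2_fraction", "value": dist.f2,
                 "n_reads": dist.n_reads, "n_excluded": dist.n_excluded},
            ]
        )
        write_tsv(qc, outdir / "qc_frames.tsv", prov)
        logger.info(
            "stage qc: %d reads counted, frame0 fraction %.3f", dist.n_reads, dist.f0
        )

    # --- provenance --------------------------------------------------------
    with open(outdir / "provenance.json", "w") as fh:
        json.dump({**prov, "config": asdict(config)}, fh, indent=2, sort_keys=True, default=str)
    return outdir
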