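import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from ribostress import (
    CountTable,
    GeneModel,
    SampleMeta,
    apply_detection_filter,
    compute_occupancy,
    compute_rpkm,
    generate_counts,
    generate_gene_model,
    generate_truth,
)


@pytest.fixture
def tiny_model():
    """Three transcripts over two genes with simple CDS intervals."""
    df = pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g2"],
            "length": [2000, 1000, 3000],
            "cds_start": [100, 30, 600],
            "cds_end": [1600, 930, 2400],
        },
        index=pd.Index(["tx1", "tx2", "tx3"], name="transcript_id"),
    )
    return GeneModel(df)


def make_count_table(counts: dict, assay: str, conditions, n_reps: int, index):
    """Build a CountTable from a dict of sample_id -> column values."""
    samples = []
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            samples.append(SampleMeta(f"{assay}_{cond}_{rep}", assay, cond, rep))
    df = pd.DataFrame(counts, index=index)
    df = df[[s.sample_id for s in samples]]
    df.index.name = "transcript_id"
    return CountTable(df, samples)


@pytest.fixture
def noise_free_run():
    """Small planted dataset at zero dispersion, fully normalized/classified."""
    model = generate_gene_model(300, seed=11)
    truth = generate_truth(model, seed=11, dispersion={"mrna": 0.0, "ribo": 0.0})
    mrna_c, ribo_c = generate_counts(truth, model)
    mrna = compute_rpkm(mrna_c, model)
    ribo = compute_rpkm(ribo_c, model)
    detected = apply_detection_filter(mrna, ribo)
    occ = compute_occupancy(mrna, ribo, detected)
    return model, truth, mrna, ribo, detected, occ
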