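"""Derivation of cell-type-specific stress gene sets and set statistics.

Two derived sets are central.  The *regulome* collects genes affected in the
target cell type during the chronic adaptive state, minus genes behaving the
same way (same direction, either channel) in a reference cell type — a
cell-type-specific chronic-stress signature.  The *adaptome* is the subset
of an ER-protein-processing pathway that is upregulated in abundance or in
translation during chronic adaptation, split into the part shared with the
reference cell type and the cell-type-specific remainder.

Over-representation uses the one-sided hypergeometric tail (the generic
replacement for an annotation service); cross-cohort expression comparison
uses a per-gene two-sided Wilcoxon-Mann-Whitney test with Benjamini-
Hochberg adjustment across the tested gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneChange",
    "DerivedGeneSet",
    "derive_cell_specific_set",
    "derive_adaptome",
    "changes_from_l2de",
    "hypergeometric_enrichment",
    "compare_geneset_expression",
    "intersect_platforms",
    "percent_of_universe",
]


@dataclass(frozen=True)
class GeneChange:
    """One directional change call for a gene in one channel and contrast."""

    gene_id: str
    direction: str  # "up" | "down"
    channel: str  # "abundance" | "occupancy"
    contrast: str

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if self.channel not in ("abundance", "occupancy"):
            raise ValueError(f"channel must be abundance/occupancy, got {self.channel!r}")


@dataclass
class DerivedGeneSet:
    """A derived gene set with its provenance and reference-overlap split."""

    name: str
    members: frozenset
    provenance: dict = field(default_factory=dict)
    reference_overlap: frozenset = frozenset()
    specific: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.reference_overlap | self.specific != self.members or (
            self.reference_overlap & self.specific
        ):
            raise ValueError("reference_overlap and specific must partition members")

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "set_name": self.name,
                "in_reference": g in self.reference_overlap,
            }
            for g in sorted(self.members)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "set_name", "in_reference"])


def changes_from_l2de(
    values: pd.Series, channel: str, contrast: str, cutoff: float = 0.6
) -> list[GeneChange]:
    """Directional change calls from per-gene L2DE values at |L2DE| >= cutoff."""
    out = []
    for gene, v in values.items():
        if v >= cutoff:
            out.append(GeneChange(gene, "up", channel, contrast))
        elif v <= -cutoff:
            out.append(GeneChange(gene, "down", channel, contrast))
    return out


def derive_cell_specific_set(
    changes_target: list[GeneChange],
    changes_reference: list[GeneChange],
    name: str = "regulome",
) -> DerivedGeneSet:
    """Target-cell changed genes minus same-direction changes in the reference.

    A target gene is excluded only if the reference shows a change in the
    SAME direction (in any channel); an opposite-direction change in the
    reference does not count as similar behavior and the gene is retained.
    """
    if not changes_target:
        warnings.warn("empty target change list; derived set is empty", stacklevel=2)
    target_dirs: dict[str, set] = {}
    for c in changes_target:
        target_dirs.setdefault(c.gene_id, set()).add(c.direction)
    ref_dirs: dict[str, set] = {}
    for c in changes_reference:
        ref_dirs.setdefault(c.gene_id, set()).add(c.direction)

    excluded = {
        g for g, dirs in target_dirs.items() if dirs & ref_dirs.get(g, set())
    }
    members = frozenset(target_dirs) - excluded
    return DerivedGeneSet(
        name=name,
        members=members,
        provenance={
            "n_target_changed": len(target_dirs),
            "n_reference_changed": len(ref_dirs),
            "excluded_same_direction": sorted(excluded),
        },
        reference_overlap=frozenset(),
        specific=members,
    )


def derive_adaptome(
    up_abundance: set,
    up_occupancy: set,
    pathway: set,
    reference_regulated: set,
    name: str = "adaptome",
) -> DerivedGeneSet:
    """Pathway genes upregulated in abundance or translation, split by reference.

    ``members = (up_abundance | up_occupancy) & pathway``;
    ``reference_overlap = members & reference_regulated``; ``specific`` is
    the remainder (the cell-type-specific part of the adaptive program).
    """
    members = frozenset((set(up_abundance) | set(up_occupancy)) & set(pathway))
    overlap = frozenset(members & set(reference_regulated))
    return DerivedGeneSet(
        name=name,
        members=members,
        provenance={
            "n_up_abundance_in_pathway": len(set(up_abundance) & set(pathway)),
            "n_up_occupancy_in_pathway": len(set(up_occupancy) & set(pathway)),
            "n_pathway": len(set(pathway)),
        },
        reference_overlap=overlap,
        specific=members - overlap,
    )


def hypergeometric_enrichment(hits: set, universe: set, pathway: set) -> tuple[int, float]:
    """Over-representation of ``pathway`` among ``hits`` within ``universe``.

    Returns (overlap count, one-sided p = P(X >= overlap)) under the
    hypergeometric null with N=|universe|, K=|pathway & universe|, n=|hits|.
    """
    hits, universe = set(hits), set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    K = len(set(pathway) & universe)
    N, n = len(universe), len(hits)
    k = len(hits & set(pathway))
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


def compare_geneset_expression(
    expr: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    genes: set,
    fdr_cutoff: float = 1e-3,
) -> tuple[pd.DataFrame, set]:
    """Per-gene two-group rank-sum comparison with BH adjustment.

    ``expr`` is genes x samples; ``groups`` maps each sample to one of
    exactly two labels, each with at least 2 samples.  Genes absent from
    ``expr`` are reported as untested.  Returns the per-gene table (group
    means, U statistic, two-sided p, BH FDR, direction) and the set of genes
    with FDR <= ``fdr_cutoff``.

    The test is exact when both groups have <= 20 samples and the pooled
    values are tie-free, otherwise the normal approximation with tie
    correction is used.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    g1 = [s for s in expr.columns if s in groups.index and groups[s] == labels[0]]
    g2 = [s for s in expr.columns if s in groups.index and groups[s] == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")

    rows = []
    for gene in sorted(genes):
        if gene not in expr.index:
            rows.append(
                {
                    "gene_id": gene, "tested": False,
                    f"mean_{labels[0]}": np.nan, f"mean_{labels[1]}": np.nan,
                    "statistic": np.nan, "p_value": np.nan, "direction": "na",
                }
            )
            continue
        a = expr.loc[gene, g1].to_numpy(dtype=float)
        b = expr.loc[gene, g2].to_numpy(dtype=float)
        pooled = np.concatenate([a, b])
        exact = max(len(a), len(b)) <= 20 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        rows.append(
            {
                "gene_id": gene, "tested": True,
                f"mean_{labels[0]}": a.mean(), f"mean_{labels[1]}": b.mean(),
                "statistic": float(res.statistic), "p_value": float(res.pvalue),
                "direction": "down" if b.mean() < a.mean() else "up",
            }
        )
    table = pd.DataFrame(rows)

    tested = table["tested"].to_numpy()
    fdr = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    if tested.any():
        reject, adj, _, _ = multipletests(
            table.loc[tested, "p_value"].to_numpy(), alpha=fdr_cutoff, method="fdr_bh"
        )
        fdr[tested] = adj
        sig[tested] = reject
    table["fdr"] = fdr
    table["significant"] = sig
    significant = set(table.loc[table["significant"], "gene_id"])
    return table, significant


def intersect_platforms(sets: dict[str, set]) -> pd.DataFrame:
    """Venn partition of >= 2 named gene sets.

    One row per non-trivial region: which sets the region belongs to, its
    size, and its members.  The row whose ``in_sets`` names every input set
    is the cross-platform common core.
    """
    if len(sets) < 2:
        raise ValueError("at least two named sets required")
    names = list(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for inc in combinations(names, r):
            exc = [n for n in names if n not in inc]
            region = set.intersection(*(set(sets[n]) for n in inc))
            for n in exc:
                region -= set(sets[n])
            rows.append(
                {
                    "in_sets": "&".join(inc),
                    "n_sets": r,
                    "count": len(region),
                    "members": ",".join(sorted(region)),
                }
            )
    return pd.DataFrame(rows)


def percent_of_universe(count: int, universe_size: int) -> float:
    """Share of the detected gene universe, in percent."""
    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    return 100.0 * count / universe_size
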