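"""L2DE contrasts, temporal groups G1-G12, and regulation modes.

The analysis compares three conditions — untreated control (CON), acute
stress (CPA1) and chronic stress (CPA18) — through three log2 differential
expression (L2DE) contrasts: acute (CPA1/CON), chronic (CPA18/CPA1) and
overall (CPA18/CON).  L2DE is log2 of the ratio of replicate-mean RPKM;
a value of 0.6 corresponds to at least a 50% difference (2**0.6 ~ 1.52).

Temporal classification (cutoff 0.32, inclusive for up/down, strict for
"no change"):

    up/up -> G1; up/down -> G2; none/up with overall up -> G3;
    down/down -> G4; down/up -> G5; none/down with overall down -> G6

applied to mRNA abundance L2DE.  The same rule geometry, applied to the
occupancy L2DE, maps to G7-G12 in the order: G7 up/up, G8 up/down, G9
none/up overall-up, G10 none/down overall-down, G11 down/up, G12 down/down.

Regulation modes combine x (the transcriptome L2DE) and y (the ribosome-
footprint L2DE) with cutoff 0.6:

    up_both       -0.6 <= x-y < 0.6, x >= 0.6,  y >= 0.6
    up_occ_only    x-y < -0.6,                  y > 0.6
    down_both     -0.6 <= x-y < 0.6, x <= -0.6, y <= -0.6
    down_occ_only  x-y > 0.6,                   y < -0.6

The boundary semantics (inclusive -0.6, strict 0.6 on x-y; strict y on the
occupancy-only modes) follow the inequalities exactly as stated.  The scheme
is purely threshold-based; no significance test enters group membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import ExpressionTable, OccupancyTable, condition_means

__all__ = [
    "l2de",
    "fold_change",
    "classify_temporal_abundance",
    "classify_temporal_occupancy",
    "classify_regulation_mode",
    "classify_dataset",
    "ClassificationResult",
    "ABUNDANCE_GROUPS",
    "OCCUPANCY_GROUPS",
    "REGULATION_MODES",
    "DEFAULT_GROUP_CUTOFF",
    "DEFAULT_MODE_CUTOFF",
]

DEFAULT_GROUP_CUTOFF = 0.32
DEFAULT_MODE_CUTOFF = 0.6

ABUNDANCE_GROUPS = ("G1", "G2", "G3", "G4", "G5", "G6")
OCCUPANCY_GROUPS = ("G7", "G8", "G9", "G10", "G11", "G12")
REGULATION_MODES = ("up_both", "up_occ_only", "down_both", "down_occ_only")

# shared trend geometry -> group label, per channel
_ABUNDANCE_MAP = {
    "up/up": "G1",
    "up/down": "G2",
    "none/up": "G3",
    "down/down": "G4",
    "down/up": "G5",
    "none/down": "G6",
}
_OCCUPANCY_MAP = {
    "up/up": "G7",
    "up/down": "G8",
    "none/up": "G9",
    "none/down": "G10",
    "down/up": "G11",
    "down/down": "G12",
}


def l2de(value_num: float, value_den: float) -> float:
    """log2 differential expression between two positive expression values."""
    if value_num <= 0 or value_den <= 0:
        raise ValueError(f"l2de requires positive inputs, got ({value_num}, {value_den})")
    return math.log2(value_num / value_den)


def fold_change(l2de_value: float) -> float:
    """Linear fold change implied by an L2DE value (2**l2de)."""
    return 2.0 ** l2de_value


def _temporal_trend(acute: float, chronic: float, overall: float, cutoff: float) -> str | None:
    """Evaluate the trend rules; returns 'up/up' etc. or None."""
    for v in (acute, chronic, overall):
        if not math.isfinite(v):
            raise ValueError(f"non-finite L2DE input: {(acute, chronic, overall)}")
    up_a, down_a = acute >= cutoff, acute <= -cutoff
    none_a = abs(acute) < cutoff
    up_c, down_c = chronic >= cutoff, chronic <= -cutoff
    if up_a and up_c:
        return "up/up"
    if up_a and down_c:
        return "up/down"
    if none_a and up_c and overall >= cutoff:
        return "none/up"
    if down_a and down_c:
        return "down/down"
    if down_a and up_c:
        return "down/up"
    if none_a and down_c and overall <= -cutoff:
        return "none/down"
    return None


def classify_temporal_abundance(
    acute: float, chronic: float, overall: float, cutoff: float = DEFAULT_GROUP_CUTOFF
) -> str:
    """Assign G1-G6 (or 'none') from the three abundance L2DE values."""
    trend = _temporal_trend(acute, chronic, overall, cutoff)
    return _ABUNDANCE_MAP[trend] if trend else "none"


def classify_temporal_occupancy(
    acute_occ: float, chronic_occ: float, overall_occ: float, cutoff: float = DEFAULT_GROUP_CUTOFF
) -> str:
    """Assign G7-G12 (or 'none') from the three occupancy L2DE values."""
    trend = _temporal_trend(acute_occ, chronic_occ, overall_occ, cutoff)
    return _OCCUPANCY_MAP[trend] if trend else "none"


def classify_regulation_mode(x: float, y: float, cutoff: float = DEFAULT_MODE_CUTOFF) -> str:
    """Four-way regulation mode from joint (x, y) L2DE, rules in printed order."""
    d = x - y
    if -cutoff <= d < cutoff and x >= cutoff and y >= cutoff:
        return "up_both"
    if d < -cutoff and y > cutoff:
        return "up_occ_only"
    if -cutoff <= d < cutoff and x <= -cutoff and y <= -cutoff:
        return "down_both"
    if d > cutoff and y < -cutoff:
        return "down_occ_only"
    return "none"


# ---------------------------------------------------------------------------
# vectorized dataset classification
# ---------------------------------------------------------------------------


def _trend_vec(acute: np.ndarray, chronic: np.ndarray, overall: np.ndarray, cutoff: float, mapping: dict) -> np.ndarray:
    if not (np.isfinite(acute).all() and np.isfinite(chronic).all() and np.isfinite(overall).all()):
        raise ValueError("non-finite L2DE values in temporal classification")
    up_a, down_a = acute >= cutoff, acute <= -cutoff
    none_a = np.abs(acute) < cutoff
    up_c, down_c = chronic >= cutoff, chronic <= -cutoff
    out = np.full(acute.shape, "none", dtype=object)
    out[none_a & down_c & (overall <= -cutoff)] = mapping["none/down"]
    out[down_a & up_c] = mapping["down/up"]
    out[down_a & down_c] = mapping["down/down"]
    out[none_a & up_c & (overall >= cutoff)] = mapping["none/up"]
    out[up_a & down_c] = mapping["up/down"]
    out[up_a & up_c] = mapping["up/up"]
    return out


def _mode_vec(x: np.ndarray, y: np.ndarray, cutoff: float) -> np.ndarray:
    d = x - y
    band = (-cutoff <= d) & (d < cutoff)
    out = np.full(x.shape, "none", dtype=object)
    out[(d > cutoff) & (y < -cutoff)] = "down_occ_only"
    out[band & (x <= -cutoff) & (y <= -cutoff)] = "down_both"
    out[(d < -cutoff) & (y > cutoff)] = "up_occ_only"
    out[band & (x >= cutoff) & (y >= cutoff)] = "up_both"
    return out


@dataclass
class ClassificationResult:
    """Outputs of :func:`classify_dataset`.

    ``l2de``: long table, one row per (transcript, contrast) with columns
    x (abundance), y (footprints), occ_l2de.
    ``assignments``: per transcript, abundance_group and occupancy_group.
    ``modes``: per (transcript, contrast), the regulation mode.
    ``summary``: per-group and per-mode transcript counts (the marginal
    "n =" bookkeeping).
    """

    l2de: pd.DataFrame
    assignments: pd.DataFrame
    modes: pd.DataFrame
    summary: pd.DataFrame


def classify_dataset(
    mrna: ExpressionTable,
    ribo: ExpressionTable,
    occ: OccupancyTable,
    conditions: tuple[str, str, str] = ("CON", "CPA1", "CPA18"),
    group_cutoff: float = DEFAULT_GROUP_CUTOFF,
    mode_cutoff: float = DEFAULT_MODE_CUTOFF,
    mode_y: str = "footprints",
) -> ClassificationResult:
    """Classify every detected transcript over the three canonical contrasts.

    ``conditions`` is (control, acute, chronic); the contrasts evaluated are
    acute/control, chronic/acute and chronic/control.  ``mode_y`` selects
    what feeds y in the regulation-mode rules: the footprint L2DE
    (``'footprints'``, the symbol definitions' reading) or the occupancy
    L2DE (``'occupancy'``, for sensitivity analysis).

    The detection filter must already have been applied: all replicate means
    entering the ratios must be strictly positive.
    """
    control, acute_cond, chronic_cond = conditions
    for cond in conditions:
        if cond not in mrna.conditions() or cond not in ribo.conditions():
            raise ValueError(f"condition {cond!r} absent from sample metadata")
    if mode_y not in ("footprints", "occupancy"):
        raise ValueError(f"mode_y must be 'footprints' or 'occupancy', got {mode_y!r}")

    transcripts = occ.occupancy.index
    m_means = condition_means(mrna, transcripts)
    r_means = condition_means(ribo, transcripts)
    if (m_means[list(conditions)].to_numpy() <= 0).any() or (
        r_means[list(conditions)].to_numpy() <= 0
    ).any():
        raise ValueError("zero replicate mean encountered; apply the detection filter first")

    contrasts = {
        "acute": (acute_cond, control),
        "chronic": (chronic_cond, acute_cond),
        "overall": (chronic_cond, control),
    }
    x, y, o = {}, {}, {}
    for name, (num, den) in contrasts.items():
        x[name] = np.log2(m_means[num].to_numpy() / m_means[den].to_numpy())
        y[name] = np.log2(r_means[num].to_numpy() / r_means[den].to_numpy())
        o[name] = np.log2(
            occ.occupancy[num].to_numpy() / occ.occupancy[den].to_numpy()
        )

    l2de_rows = []
    for name, (num, den) in contrasts.items():
        l2de_rows.append(
            pd.DataFrame(
                {
                    "transcript_id": transcripts,
                    "contrast": name,
                    "numerator": num,
                    "denominator": den,
                    "x": x[name],
                    "y": y[name],
                    "occ_l2de": o[name],
                }
            )
        )
    l2de_df = pd.concat(l2de_rows, ignore_index=True)

    abundance_group = _trend_vec(x["acute"], x["chronic"], x["overall"], group_cutoff, _ABUNDANCE_MAP)
    occupancy_group = _trend_vec(o["acute"], o["chronic"], o["overall"], group_cutoff, _OCCUPANCY_MAP)
    assignments = pd.DataFrame(
        {
            "transcript_id": transcripts,
            "abundance_group": abundance_group,
            "occupancy_group": occupancy_group,
        }
    )

    mode_rows = []
    for name in contrasts:
        yy = y[name] if mode_y == "footprints" else o[name]
        mode_rows.append(
            pd.DataFrame(
                {
                    "transcript_id": transcripts,
                    "contrast": name,
                    "mode": _mode_vec(x[name], yy, mode_cutoff),
                }
            )
        )
    modes_df = pd.concat(mode_rows, ignore_index=True)

    summary_rows = []
    for g in ABUNDANCE_GROUPS:
        summary_rows.append(("abundance_group", g, int((abundance_group == g).sum())))
    for g in OCCUPANCY_GROUPS:
        summary_rows.append(("occupancy_group", g, int((occupancy_group == g).sum())))
    for name in contrasts:
        sub = modes_df[modes_df["contrast"] == name]
        for m in REGULATION_MODES:
            summary_rows.append((f"mode[{name}]", m, int((sub["mode"] == m).sum())))
    summary = pd.DataFrame(summary_rows, columns=["channel", "label", "n"])

    return ClassificationResult(l2de_df, assignments, modes_df, summary)
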