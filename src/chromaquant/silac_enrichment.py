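"""SILAC forward/reverse nucleosome-pulldown enrichment calls.

In the forward experiment the heavy-labelled extract is incubated with the
H3K36me3-modified nucleosomes and the light extract with the unmodified
ones; in the reverse experiment the labels are swapped.  Orienting both
heavy/light ratios onto a common log2 me3/unmod scale therefore means
taking ``log2(H/L)`` of the forward experiment and ``-log2(H/L)`` of the
reverse.  A protein reproducibly enriched on methylated nucleosomes has
both oriented ratios above the threshold tau (default 1, i.e. 2-fold) —
the quadrant where both axes are positive in a forward-vs-reverse scatter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SilacRecord",
    "orient_ratios",
    "classify_protein",
    "classify_table",
    "enriched_set",
    "read_silac_table",
]

Call = Literal["enriched", "depleted", "inconsistent", "unchanged", "invalid"]

DEFAULT_TAU = 1.0


@dataclass(frozen=True)
class SilacRecord:
    protein_id: str
    ratio_forward_HL: float
    ratio_reverse_HL: float
    oriented_forward: float | None
    oriented_reverse: float | None
    call: Call


def orient_ratios(
    raw_forward_HL: float, raw_reverse_HL: float
) -> tuple[float, float]:
    """Map raw heavy/light ratios onto the common log2 me3/unmod scale.

    Forward: heavy extract met the methylated bait, so the oriented ratio
    is ``log2(H/L)``.  Reverse: labels swapped, so the sign flips:
    ``-log2(H/L)``.  Non-positive or non-finite ratios are a ValueError;
    table-level processing flags such records instead.
    """
    for name, value in [
        ("forward", raw_forward_HL), ("reverse", raw_reverse_HL)
    ]:
        if not (isinstance(value, (int, float)) and math.isfinite(value)
                and value > 0):
            raise ValueError(
                f"{name} H/L ratio must be a positive finite number, "
                f"got {value!r}"
            )
    return math.log2(raw_forward_HL), -math.log2(raw_reverse_HL)


def classify_protein(
    oriented_forward: float,
    oriented_reverse: float,
    tau: float = DEFAULT_TAU,
) -> Call:
    """Quadrant call on oriented log2 ratios.

    ``enriched``: both > tau; ``depleted``: both < -tau; ``inconsistent``:
    the two exceed tau in opposite directions; ``unchanged`` otherwise.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    f, r = oriented_forward, oriented_reverse
    if f > tau and r > tau:
        return "enriched"
    if f < -tau and r < -tau:
        return "depleted"
    if (f > tau and r < -tau) or (f < -tau and r > tau):
        return "inconsistent"
    return "unchanged"


def _valid_ratio(value) -> bool:
    try:
        return math.isfinite(float(value)) and float(value) > 0
    except (TypeError, ValueError):
        return False


def classify_table(
    table: pd.DataFrame, tau: float = DEFAULT_TAU
) -> pd.DataFrame:
    """Orient and classify a protein ratio table.

    Expects columns ``protein_id``, ``ratio_forward_HL``,
    ``ratio_reverse_HL``.  Records with missing or non-positive raw ratios
    are kept but flagged ``invalid`` and excluded from calls.  Returns the
    input columns plus ``oriented_forward``, ``oriented_reverse``, ``call``.
    """
    if table.empty:
        raise ValueError("SILAC table is empty")
    oriented_f = np.full(len(table), np.nan)
    oriented_r = np.full(len(table), np.nan)
    calls: list[Call] = []
    fwd = table["ratio_forward_HL"].to_numpy()
    rev = table["ratio_reverse_HL"].to_numpy()
    for i in range(len(table)):
        if not (_valid_ratio(fwd[i]) and _valid_ratio(rev[i])):
            calls.append("invalid")
            continue
        f, r = orient_ratios(float(fwd[i]), float(rev[i]))
        oriented_f[i], oriented_r[i] = f, r
        calls.append(classify_protein(f, r, tau))
    out = table.copy()
    out["oriented_forward"] = oriented_f
    out["oriented_reverse"] = oriented_r
    out["call"] = calls
    return out


def enriched_set(
    table: pd.DataFrame, tau: float = DEFAULT_TAU
) -> tuple[list[str], pd.DataFrame]:
    """Enriched proteins plus the full scatter-coordinate table.

    Returns the enriched-call protein ids sorted by
    ``min(oriented_forward, oriented_reverse)`` descending (most
    confidently enriched first), and the per-protein coordinate table
    (protein_id, oriented_forward, oriented_reverse, call) for plotting.
    """
    classified = (
        table
        if "call" in table.columns
        else classify_table(table, tau)
    )
    coords = classified[
        ["protein_id", "oriented_forward", "oriented_reverse", "call"]
    ].copy()
    hits = classified[classified["call"] == "enriched"].copy()
    hits["rank_key"] = np.minimum(
        hits["oriented_forward"], hits["oriented_reverse"]
    )
    hits = hits.sort_values(
        ["rank_key", "protein_id"], ascending=[False, True], kind="stable"
    )
    return hits["protein_id"].tolist(), coords


def read_silac_table(path) -> pd.DataFrame:
    """Read a protein ratio TSV with columns protein_id,
    ratio_forward_HL, ratio_reverse_HL (extra columns pass through)."""
    table = pd.read_csv(path, sep="\t")
    required = {"protein_id", "ratio_forward_HL", "ratio_reverse_HL"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"SILAC table missing columns: {sorted(missing)}")
    return table
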