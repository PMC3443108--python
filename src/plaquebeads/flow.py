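"""Labeling-verification gating of flow-cytometry event tables.

Mirrors the sequential strategy used to verify bead labeling of blood
monocytes: a rectangular live-cell gate in (FSC, SSC), a CD115-high gate
selecting monocytes among live leukocytes, a Gr1 split into classical
(Gr1-high) and non-classical (Gr1-low) monocytes, and a FITC gate marking
bead-positive events.  All gates are pure row filters on the event table.
"""

from __future__ import annotations

from typing import Tuple

import pandas as pd

from .config import GateParams

__all__ = [
    "gate_live",
    "gate_monocytes",
    "monocyte_fraction",
    "split_gr1",
    "bead_positive_fraction",
    "gating_report",
]


def gate_live(events: pd.DataFrame, params: GateParams) -> pd.DataFrame:
    """Events inside the rectangular live gate in (FSC, SSC)."""
    if events.empty:
        raise ValueError("event table is empty")
    fsc_lo, fsc_hi = params.fsc_range
    ssc_lo, ssc_hi = params.ssc_range
    keep = (
        events["fsc"].between(fsc_lo, fsc_hi)
        & events["ssc"].between(ssc_lo, ssc_hi)
    )
    return events[keep]


def gate_monocytes(live_events: pd.DataFrame, params: GateParams) -> pd.DataFrame:
    """CD115-high events among the live gate."""
    return live_events[live_events["cd115"] > params.cd115_threshold]


def monocyte_fraction(live_events: pd.DataFrame, params: GateParams) -> float:
    """Percentage of live leukocyte events that are CD115-high monocytes."""
    if live_events.empty:
        raise ValueError("live gate is empty")
    return 100.0 * len(gate_monocytes(live_events, params)) / len(live_events)


def split_gr1(monocyte_events: pd.DataFrame,
              params: GateParams) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition monocytes into (Gr1-high, Gr1-low) at the Gr1 threshold.

    The subsets are disjoint and their union is the input.
    """
    hi = monocyte_events["gr1"] > params.gr1_threshold
    return monocyte_events[hi], monocyte_events[~hi]


def bead_positive_fraction(
    monocyte_events: pd.DataFrame,
    params: GateParams,
    denominator: str = "all_monocytes",
) -> float:
    """Percentage of bead-positive Gr1-low monocytes.

    ``denominator`` chooses the reference population: ``"all_monocytes"``
    (the convention used when quoting bead-positive Gr1-low cells as a
    share of total blood monocytes) or ``"gr1lo"``.
    """
    if denominator not in ("all_monocytes", "gr1lo"):
        raise ValueError("denominator must be 'all_monocytes' or 'gr1lo'")
    _, gr1lo = split_gr1(monocyte_events, params)
    denom = monocyte_events if denominator == "all_monocytes" else gr1lo
    if denom.empty:
        raise ZeroDivisionError("denominator population is empty")
    beadpos = gr1lo[gr1lo["fitc"] > params.fitc_threshold]
    return 100.0 * len(beadpos) / len(denom)


def gating_report(events: pd.DataFrame, params: GateParams) -> dict:
    """Run the full gate chain and return the headline fractions."""
    live = gate_live(events, params)
    monocytes = gate_monocytes(live, params)
    gr1hi, gr1lo = split_gr1(monocytes, params)
    report = {
        "n_events": int(len(events)),
        "n_live": int(len(live)),
        "n_monocytes": int(len(monocytes)),
        "n_gr1hi": int(len(gr1hi)),
        "n_gr1lo": int(len(gr1lo)),
        "monocyte_percent_of_live": monocyte_fraction(live, params),
    }
    if len(monocytes):
        report["beadpos_gr1lo_percent_of_monocytes"] = bead_positive_fraction(
            monocytes, params, denominator="all_monocytes")
    return report
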