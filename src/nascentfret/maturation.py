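"""CFTR maturation from immunoblot band intensities.

CFTR appears on a blot as the core-glycosylated ER form (band B) and the
maturely glycosylated post-Golgi form (band C); the amount of band C
indexes trafficking through the secretory pathway.  Inputs are numeric
band intensities (densitometry happens upstream).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .types import BlotLane, MaturationResult

__all__ = ["maturation_efficiency", "relative_trafficking", "lanes_from_table"]


def maturation_efficiency(lane: BlotLane) -> float:
    """Percent of CFTR in the mature form: 100 * C / (B + C)."""
    total = lane.band_b + lane.band_c
    if total <= 0:
        raise ValueError("band B + band C must be positive")
    return 100.0 * lane.band_c / total


def lanes_from_table(table: pd.DataFrame, construct: str) -> list[BlotLane]:
    """Extract one construct's replicate lanes from a tidy blot table."""
    sub = table[table["construct"] == construct]
    if sub.empty:
        raise ValueError(f"no lanes for construct {construct!r}")
    return [
        BlotLane(
            construct_label=construct,
            band_b=row["band_B"],
            band_c=row["band_C"],
            loading_control=row["loading_control"],
        )
        for _, row in sub.iterrows()
    ]


def relative_trafficking(
    mutant_lanes: Sequence[BlotLane],
    wt_lanes: Sequence[BlotLane],
) -> MaturationResult:
    """Loading-normalized band-C level of a mutant relative to wild type.

    Each mutant lane's band C / loading-control ratio is expressed as a
    percentage of the mean wild-type ratio; the result is the mean +/-
    SEM over mutant replicates.  Normalizing band C to the loading
    control (rather than to band B + C) makes the readout proportional
    to the absolute amount of mature protein per cell equivalent.
    """
    if not mutant_lanes or not wt_lanes:
        raise ValueError("need at least one replicate lane per group")
    wt_ratios = np.array(
        [lane.band_c / lane.loading_control for lane in wt_lanes]
    )
    if np.all(wt_ratios == 0):
        raise ValueError("wild-type band C is zero in all replicates")
    wt_ref = wt_ratios.mean()
    values = np.array(
        [100.0 * (lane.band_c / lane.loading_control) / wt_ref for lane in mutant_lanes]
    )
    n = values.size
    sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return MaturationResult(
        construct_label=mutant_lanes[0].construct_label,
        relative_to_wt=float(values.mean()),
        sem=sem,
        n=int(n),
        replicate_values=tuple(float(v) for v in values),
    )
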