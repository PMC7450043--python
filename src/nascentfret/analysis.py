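"""Replicate aggregation and condition comparisons.

Turns per-experiment FRET results into condition profiles (mean +/- SEM
over independent replicates, QC-failed quadruples excluded) and
implements the study's comparison repertoire: per-truncation wild-type
vs mutant contrasts, detection of the folding window in which a mutation
significantly de-compacts the nascent chain, bound-vs-released contrasts
with an exit-tunnel exposure-equivalence check, thermal profiles, and
wild-type-minus-mutant difference curves.

Statistical conventions: two-sample pooled-variance Student's t test
(Welch available but off by default), alpha = 0.05, no multiple-testing
correction across truncations or temperatures; one-tailed tests are
directional for wild type > mutant.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError
from .types import (
    ComparisonResult,
    ConditionKey,
    ConditionProfile,
    DeltaCurve,
    ExposedLength,
    FoldingWindow,
    FretResult,
)

__all__ = [
    "aggregate_profile",
    "compare_conditions",
    "length_scan",
    "detect_folding_window",
    "release_comparison",
    "thermal_curve",
    "delta_fret",
    "DEFAULT_ALPHA",
    "DEFAULT_TUNNEL_OFFSET",
    "TUNNEL_OFFSET_BAND",
]

DEFAULT_ALPHA = 0.05

#: Default exit-tunnel offset (residues sequestered in the ribosome);
#: midpoint of the 30-40 residue band.
DEFAULT_TUNNEL_OFFSET = 35
#: Accepted range of implied offsets for bound/released pairings.
TUNNEL_OFFSET_BAND = (30, 40)


def aggregate_profile(
    results: Sequence[FretResult],
    include_qc_failed: bool = False,
) -> ConditionProfile:
    """Mean +/- SEM of replicate FRET efficiencies for one condition.

    QC-failed replicates are excluded (and counted) unless
    ``include_qc_failed``.  SEM uses the n-1 sample standard deviation;
    a single usable replicate yields SEM = 0 with the ``low_n`` flag set.
    """
    if not results:
        raise ValueError("no replicates supplied")
    conditions = {r.condition for r in results}
    if len(conditions) != 1:
        raise ValueError("replicates must share one condition")
    usable = [r for r in results if include_qc_failed or r.qc_pass]
    n_excluded = len(results) - len(usable)
    if not usable:
        raise ValueError(
            f"no usable replicates ({n_excluded} excluded by readthrough QC)"
        )
    e = np.array([r.e_fret for r in usable], dtype=float)
    n = e.size
    if n > 1:
        sem = float(np.std(e, ddof=1) / math.sqrt(n))
    else:
        sem = 0.0
    return ConditionProfile(
        condition=next(iter(conditions)),
        replicate_e=tuple(float(x) for x in e),
        mean=float(e.mean()),
        sem=sem,
        n=int(n),
        n_excluded=int(n_excluded),
        low_n=n < 2,
    )


def compare_conditions(
    a: ConditionProfile,
    b: ConditionProfile,
    tail: str = "two",
    paired: bool = False,
    welch: bool = False,
) -> ComparisonResult:
    """Student's t comparison of two condition profiles (a minus b).

    Pooled-variance two-sample t by default; ``welch=True`` drops the
    equal-variance assumption; ``paired=True`` tests the replicate-wise
    differences (replicate order defines the pairing).  ``tail`` is
    ``"two"`` or ``"one"``; the one-tailed alternative is a > b.
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    xa = np.asarray(a.replicate_e, dtype=float)
    xb = np.asarray(b.replicate_e, dtype=float)
    na, nb = xa.size, xb.size
    if paired:
        if na != nb:
            raise ValueError("paired comparison needs equal replicate counts")
        if na < 2:
            raise ValueError("paired comparison needs at least two pairs")
        d = xa - xb
        sd = d.std(ddof=1)
        df = float(na - 1)
        t = float(d.mean() / (sd / math.sqrt(na))) if sd > 0 else (
            0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
        )
    else:
        if na < 2 or nb < 2:
            raise ValueError("each group needs at least two replicates")
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        diff = xa.mean() - xb.mean()
        if welch:
            se2 = va / na + vb / nb
            df = (
                se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
                if se2 > 0
                else float(na + nb - 2)
            )
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = sp2 * (1 / na + 1 / nb)
            df = float(na + nb - 2)
        t = float(diff / math.sqrt(se2)) if se2 > 0 else (
            0.0 if diff == 0 else math.copysign(math.inf, diff)
        )
    if tail == "two":
        p = float(2 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    else:
        p = float(stats.t.sf(t, df)) if math.isfinite(t) else (
            0.0 if t > 0 else 1.0
        )
    p = min(p, 1.0)
    return ComparisonResult(
        difference_of_means=float(xa.mean() - xb.mean()),
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        tail=tail,
        group_ns=(int(na), int(nb)),
        paired=paired,
        welch=welch,
    )


def length_scan(
    wt_profiles: Mapping[int, ConditionProfile],
    mut_profiles: Mapping[int, ConditionProfile],
    tail: str = "two",
    paired: bool = False,
) -> pd.DataFrame:
    """Per-truncation wild-type vs mutant contrast, ordered by length.

    Returns a tidy frame with columns truncation, wt_mean, wt_sem, wt_n,
    mut_mean, mut_sem, mut_n, difference (WT minus mutant), t, df,
    p_value.  The two series must cover the same truncation grid.
    """
    wt_grid = sorted(wt_profiles)
    mut_grid = sorted(mut_profiles)
    if wt_grid != mut_grid:
        raise ValueError(
            f"mismatched truncation grids: WT {wt_grid} vs mutant {mut_grid}"
        )
    rows = []
    for trunc in wt_grid:
        cmp_ = compare_conditions(
            wt_profiles[trunc], mut_profiles[trunc], tail=tail, paired=paired
        )
        rows.append(
            {
                "truncation": trunc,
                "wt_mean": wt_profiles[trunc].mean,
                "wt_sem": wt_profiles[trunc].sem,
                "wt_n": wt_profiles[trunc].n,
                "mut_mean": mut_profiles[trunc].mean,
                "mut_sem": mut_profiles[trunc].sem,
                "mut_n": mut_profiles[trunc].n,
                "difference": cmp_.difference_of_means,
                "t": cmp_.t_statistic,
                "df": cmp_.degrees_of_freedom,
                "p_value": cmp_.p_value,
            }
        )
    return pd.DataFrame(rows)


def detect_folding_window(
    scan: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    probe_site: Optional[int] = None,
) -> FoldingWindow:
    """Maximal contiguous run of significant mutant de-compaction.

    A truncation belongs to the window when its contrast is significant
    (p < alpha) *and* the mutant mean lies below the wild type
    (difference = WT - mutant > 0).  Among contiguous runs the longest
    wins (earliest on ties); no significant truncation yields an empty
    window.
    """
    df = scan.sort_values("truncation").reset_index(drop=True)
    sig = ((df["p_value"] < alpha) & (df["difference"] > 0)).to_numpy()
    best: Tuple[int, int] = (0, 0)  # (start index, length)
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j < len(sig) and sig[j]:
                j += 1
            if j - i > best[1]:
                best = (i, j - i)
            i = j
        else:
            i += 1
    if best[1] == 0:
        return FoldingWindow(
            probe_site=probe_site, start_truncation=None,
            end_truncation=None, truncations=(),
        )
    run = df["truncation"].iloc[best[0] : best[0] + best[1]].tolist()
    return FoldingWindow(
        probe_site=probe_site,
        start_truncation=int(run[0]),
        end_truncation=int(run[-1]),
        truncations=tuple(int(t) for t in run),
    )


def release_comparison(
    bound: ConditionProfile,
    released: ConditionProfile,
    tunnel_band: Tuple[int, int] = TUNNEL_OFFSET_BAND,
    tail: str = "two",
) -> Tuple[ComparisonResult, ExposedLength]:
    """Bound-vs-released contrast with exposure-equivalence checking.

    A ribosome-bound chain truncated at L exposes residues only up to
    L minus the exit-tunnel offset, so a fair comparison pairs a bound
    truncation with a released truncation shorter by one tunnel offset
    (e.g. bound 604 vs released 568, bound 704 vs released 664).  The
    implied offset must fall inside ``tunnel_band``; otherwise a
    :class:`~nascentfret.errors.PairingError` names both exposed ranges.

    Returns the comparison (bound minus released) and the bound chain's
    :class:`~nascentfret.types.ExposedLength` annotation documenting the
    offset that made the pairing valid.
    """
    if bound.condition.ribosome_state != "bound":
        raise PairingError("first profile must be ribosome-bound")
    if released.condition.ribosome_state != "released":
        raise PairingError("second profile must be ribosome-released")
    offset = bound.condition.truncation - released.condition.truncation
    lo, hi = tunnel_band
    if not lo <= offset <= hi:
        b_exposed = (
            f"bound truncation {bound.condition.truncation} exposes up to "
            f"residue {bound.condition.truncation - lo}..."
            f"{bound.condition.truncation - hi}"
        )
        r_exposed = (
            f"released truncation {released.condition.truncation} exposes up "
            f"to residue {released.condition.truncation}"
        )
        raise PairingError(
            f"non-equivalent exposure pairing (implied tunnel offset {offset} "
            f"outside [{lo}, {hi}]): {b_exposed}; {r_exposed}"
        )
    annotation = ExposedLength(
        truncation=bound.condition.truncation,
        ribosome_state="bound",
        tunnel_offset=offset,
    )
    return compare_conditions(bound, released, tail=tail), annotation


def thermal_curve(
    results_by_temperature: Mapping[float, Sequence[FretResult]],
    include_qc_failed: bool = False,
) -> List[ConditionProfile]:
    """Per-temperature condition profiles, sorted by temperature.

    Replicate counts may differ between temperatures.  Monotonicity of
    the mean curve is diagnosed by the caller if needed; it is reported,
    never enforced.
    """
    return [
        aggregate_profile(results_by_temperature[t], include_qc_failed)
        for t in sorted(results_by_temperature)
    ]


def delta_fret(
    wt_series: Sequence[ConditionProfile],
    mut_series: Sequence[ConditionProfile],
) -> DeltaCurve:
    """Wild-type-minus-mutant difference curve over temperature.

    Per temperature: difference of means, propagated SEM
    sqrt(SEM_WT^2 + SEM_mut^2), and a one-tailed p value for the
    directional hypothesis wild type > mutant.
    """
    wt_temps = [p.condition.temperature for p in wt_series]
    mut_temps = [p.condition.temperature for p in mut_series]
    if wt_temps != mut_temps:
        raise ValueError(
            f"temperature grids differ: WT {wt_temps} vs mutant {mut_temps}"
        )
    deltas, sems, ps = [], [], []
    for wt, mut in zip(wt_series, mut_series):
        deltas.append(wt.mean - mut.mean)
        sems.append(math.sqrt(wt.sem**2 + mut.sem**2))
        if wt.n < 2 or mut.n < 2:
            # low-n profiles are excluded from significance testing
            ps.append(float("nan"))
        else:
            ps.append(compare_conditions(wt, mut, tail="one").p_value)
    return DeltaCurve(
        temperatures=tuple(wt_temps),
        delta_mean=tuple(deltas),
        delta_sem=tuple(sems),
        p_one_tailed=tuple(ps),
    )
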