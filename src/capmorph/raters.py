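"""Two-rater measurement protocol: compare, flag, and average.

Two raters independently measure a subset of the per-profile indices.  For
each pair of readings the relative deviation |v1 − v2| / mean(v1, v2) is
computed; pairs deviating by more than the tolerance (default 10 %) are
flagged for repetition, otherwise the mean of the two readings is accepted.
The mean is used as the deviation denominator because either single reading
would make the rule asymmetric in the raters.

Indices measured by both raters: lumen radius, EC thickness, EC nucleus area
density, and intraluminal surface enlargement.  BM thickness and pericyte
coverage vary only negligibly between trained raters and are taken from a
single rater.  Socket counts are compared with the same 10 % rule, except
that small-count pairs differing by at most one are accepted outright
(percentage rules degenerate at tiny counts).

Software cannot re-measure: unresolved flagged readings are reported in a
discrepancy table and the merged value is left missing, to be filled by a
third reading if one is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

RATER_TOLERANCE = 0.10

#: Indices measured independently by both raters and merged by averaging.
DUAL_MEASURED = [
    "lumen_radius_nm",
    "ec_thickness_nm",
    "nucleus_area_density_pct",
    "luminal_enlargement_pct",
]

#: Indices copied from the first rater.
SINGLE_RATER = ["bm_thickness_nm", "pc_coverage"]

COUNT_COLUMNS = [
    "ec_sockets_n", "ec_sockets_empty_n", "pc_sockets_n", "pc_sockets_empty_n",
]

DISCREPANCY_COLUMNS = ["micrograph_id", "metric", "value_rater1", "value_rater2",
                       "relative_deviation", "status"]


@dataclass
class RaterPair:
    metric_name: str
    value_rater1: float
    value_rater2: float
    relative_deviation: float
    status: str  # "accepted" | "repeat_required"
    merged_value: float | None


def reconcile(
    v1: float, v2: float, tolerance: float = RATER_TOLERANCE,
    metric_name: str = "",
) -> RaterPair:
    """Compare two readings of one metric under the relative-deviation rule."""
    if v1 < 0 or v2 < 0:
        raise ValueError("rater readings must be non-negative")
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    mean = 0.5 * (v1 + v2)
    deviation = 0.0 if mean == 0 else abs(v1 - v2) / mean
    accepted = deviation <= tolerance
    return RaterPair(
        metric_name=metric_name,
        value_rater1=float(v1),
        value_rater2=float(v2),
        relative_deviation=float(deviation),
        status="accepted" if accepted else "repeat_required",
        merged_value=float(mean) if accepted else None,
    )


def reconcile_counts(
    c1: int, c2: int, tolerance: float = RATER_TOLERANCE,
    metric_name: str = "",
) -> RaterPair:
    """Count variant: pairs differing by at most one are accepted outright."""
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be non-negative")
    if abs(c1 - c2) <= 1:
        mean = 0.5 * (c1 + c2)
        deviation = 0.0 if mean == 0 else abs(c1 - c2) / mean
        return RaterPair(metric_name, float(c1), float(c2), float(deviation),
                         "accepted", float(mean))
    return reconcile(c1, c2, tolerance, metric_name)


def flag_rate_closed_form(sigma: float, tolerance: float = RATER_TOLERANCE) -> float:
    """Expected flag rate for two independent lognormal readings.

    If both readings carry multiplicative lognormal noise with log-scale SD
    ``sigma`` around a common true value, the log-ratio is N(0, 2 sigma²) and
    |v1 − v2| / mean > tol  ⇔  |log v1 − log v2| > 2 atanh(tol / 2).
    """
    from scipy.stats import norm

    threshold = 2.0 * np.arctanh(tolerance / 2.0)
    return 2.0 * norm.sf(threshold / (sigma * np.sqrt(2.0)))


def reconcile_profiles(
    profiles_r1: pd.DataFrame,
    profiles_r2: pd.DataFrame,
    metrics_to_merge: Sequence[str] = tuple(DUAL_MEASURED),
    tolerance: float = RATER_TOLERANCE,
    extra_readings: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge two raters' profile tables.

    Returns ``(merged, discrepancies)``.  Merged rows use the rater mean for
    the dual-measured indices (missing where a flagged pair is unresolved),
    first-rater values for the single-rater indices, reconciled means for the
    socket counts, the rater average for the disruption flag, and the union
    of exclusion flags.  ``extra_readings``, if given, provides third
    readings indexed by (micrograph_id, metric) with a ``value`` column; a
    flagged pair with a third reading merges to the mean of all three.
    """
    d1 = profiles_r1.set_index("micrograph_id", verify_integrity=True)
    d2 = profiles_r2.set_index("micrograph_id", verify_integrity=True)
    only1 = d1.index.difference(d2.index)
    only2 = d2.index.difference(d1.index)
    if len(only1) or len(only2):
        raise ValueError(
            "rater record sets do not cover the same micrographs; "
            f"only rater 1: {list(only1[:5])}, only rater 2: {list(only2[:5])}"
        )
    d2 = d2.loc[d1.index]
    thirds = {}
    if extra_readings is not None:
        for _, r in extra_readings.iterrows():
            thirds[(r["micrograph_id"], r["metric"])] = float(r["value"])

    merged = d1.copy()
    merged["rater_id"] = d1["rater_id"].astype(str) + "+" + d2["rater_id"].astype(str)
    merged["excluded"] = d1["excluded"].astype(bool) | d2["excluded"].astype(bool)
    merged["exclusion_reason"] = np.where(
        d1["excluded"].astype(bool), d1["exclusion_reason"], d2["exclusion_reason"]
    )
    merged["bm_disrupted"] = 0.5 * (
        d1["bm_disrupted"].astype(float) + d2["bm_disrupted"].astype(float)
    )

    disc_rows = []
    for metric in metrics_to_merge:
        v1 = d1[metric].to_numpy(dtype=float)
        v2 = d2[metric].to_numpy(dtype=float)
        mean = 0.5 * (v1 + v2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dev = np.where(mean == 0, 0.0, np.abs(v1 - v2) / mean)
        flagged = dev > tolerance
        out = mean.copy()
        for idx in np.flatnonzero(flagged):
            mid = d1.index[idx]
            third = thirds.get((mid, metric))
            if third is not None:
                out[idx] = (v1[idx] + v2[idx] + third) / 3.0
                status = "resolved_third_reading"
            else:
                out[idx] = np.nan
                status = "repeat_required"
            disc_rows.append({
                "micrograph_id": mid, "metric": metric,
                "value_rater1": v1[idx], "value_rater2": v2[idx],
                "relative_deviation": dev[idx], "status": status,
            })
        merged[metric] = out

    for metric in COUNT_COLUMNS:
        c1 = d1[metric].to_numpy(dtype=float)
        c2 = d2[metric].to_numpy(dtype=float)
        out = 0.5 * (c1 + c2)
        small = np.abs(c1 - c2) <= 1
        mean = 0.5 * (c1 + c2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dev = np.where(mean == 0, 0.0, np.abs(c1 - c2) / mean)
        flagged = (~small) & (dev > tolerance)
        for idx in np.flatnonzero(flagged):
            out[idx] = np.nan
            disc_rows.append({
                "micrograph_id": d1.index[idx], "metric": metric,
                "value_rater1": c1[idx], "value_rater2": c2[idx],
                "relative_deviation": dev[idx], "status": "repeat_required",
            })
        merged[metric] = out

    discrepancies = pd.DataFrame(disc_rows, columns=DISCREPANCY_COLUMNS)
    return merged.reset_index(), discrepancies


def write_discrepancy_table(discrepancies: pd.DataFrame, path) -> None:
    out = discrepancies.reindex(columns=DISCREPANCY_COLUMNS)
    out.to_csv(path, index=False, encoding="utf-8", float_format="%.6g")
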