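"""Per-subject summaries and per-group tables.

The subject (biopsy) is the unit of statistical analysis: per-profile indices
are averaged over the included (non-oblique, geometrically valid) profiles of
each biopsy, and peg-socket-junction / BM-disruption observations become
per-subject frequencies — the percentage of included capillary profiles on
which the structure was seen.  Group tables report mean ± sample SD across
the subjects of each study group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation_io import SUBJECT_COLUMNS

#: Metric columns averaged per subject (NaN entries — e.g. unresolved rater
#: discrepancies — are ignored by the mean).
METRIC_COLUMNS = [
    "lumen_radius_nm",
    "ec_thickness_nm",
    "bm_thickness_nm",
    "pc_coverage",
    "nucleus_area_density_pct",
    "luminal_enlargement_pct",
]

FREQUENCY_COLUMNS = [
    "pct_capillaries_with_ec_sockets",
    "pct_capillaries_with_empty_ec_sockets",
    "pct_capillaries_with_pc_sockets",
    "pct_capillaries_with_empty_pc_sockets",
    "pct_capillaries_bm_disrupted",
]

SUMMARY_VALUE_COLUMNS = METRIC_COLUMNS + FREQUENCY_COLUMNS


class EmptySubjectError(ValueError):
    """Raised when a subject has no included capillary profiles."""


def summarize_subject(profiles: pd.DataFrame, age_years: float | None = None) -> dict:
    """Summarize one subject's merged profile records into a summary row.

    ``profiles`` must contain the rows of exactly one (subject_id, biopsy_id).
    Index means and frequencies use included profiles only; excluded
    (obliquely sectioned or geometrically invalid) profiles are omitted from
    frequency denominators as well.
    """
    subjects = profiles["subject_id"].unique()
    biopsies = profiles["biopsy_id"].unique()
    if len(subjects) != 1 or len(biopsies) != 1:
        raise ValueError("summarize_subject expects rows of a single biopsy")
    if profiles.duplicated(subset=["micrograph_id"]).any():
        raise ValueError(f"duplicate micrograph_ids for subject {subjects[0]!r}")
    included = profiles.loc[~profiles["excluded"].astype(bool)]
    n_inc = len(included)
    if n_inc == 0:
        raise EmptySubjectError(
            f"subject {subjects[0]!r} biopsy {biopsies[0]!r} has no included profiles"
        )
    row: dict = {
        "subject_id": subjects[0],
        "biopsy_id": biopsies[0],
        "group": profiles["group"].iloc[0],
        "age_years": age_years if age_years is not None else np.nan,
        "n_profiles_annotated": len(profiles),
        "n_profiles_included": n_inc,
    }
    for col in METRIC_COLUMNS:
        row[col] = float(included[col].mean())
    pct = lambda mask: 100.0 * float(np.asarray(mask, dtype=float).mean())
    row["pct_capillaries_with_ec_sockets"] = pct(included["ec_sockets_n"] > 0)
    row["pct_capillaries_with_empty_ec_sockets"] = pct(included["ec_sockets_empty_n"] > 0)
    row["pct_capillaries_with_pc_sockets"] = pct(included["pc_sockets_n"] > 0)
    row["pct_capillaries_with_empty_pc_sockets"] = pct(included["pc_sockets_empty_n"] > 0)
    # bm_disrupted may be fractional after two-rater averaging: the subject
    # frequency is then the mean of the two raters' per-subject frequencies.
    row["pct_capillaries_bm_disrupted"] = 100.0 * float(included["bm_disrupted"].mean())
    return row


def subject_table(
    profiles: pd.DataFrame, ages: dict[str, float] | None = None
) -> pd.DataFrame:
    """Summarize merged profile records into one row per biopsy."""
    rows = []
    for (_, biopsy), grp in profiles.groupby(["subject_id", "biopsy_id"], sort=True):
        age = (ages or {}).get(biopsy)
        if age is None and ages is not None:
            age = ages.get(grp["subject_id"].iloc[0])
        rows.append(summarize_subject(grp, age_years=age))
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def group_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean ± sample SD of every subject-summary field.

    Groups with fewer than two subjects get an undefined (NaN) SD and are
    flagged in the ``sd_defined`` column rather than dropped.
    """
    rows = []
    for group, grp in summaries.groupby("group", sort=False):
        row = {"group": group, "n_subjects": len(grp)}
        row["sd_defined"] = len(grp) >= 2
        for col in SUMMARY_VALUE_COLUMNS:
            row[f"{col}_mean"] = float(grp[col].mean())
            row[f"{col}_sd"] = float(grp[col].std(ddof=1)) if len(grp) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_group_table(groups: pd.DataFrame, path) -> None:
    groups.to_csv(path, index=False, encoding="utf-8", float_format="%.6g")
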