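"""End-to-end pipeline: measure -> reconcile -> summarize -> test -> report.

Also houses the contrasts derivable directly from the published group table
(packaged as ``data/published_group_table.csv``): the relative reduction of the
intraluminal surface-enlargement index in untrained diabetics against every
other study group, and the relative pre- to post-training increase of the
BM-disruption frequency in the diabetes study.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (
    CapillaryAnnotation,
    write_profile_table,
    write_subject_table,
)
from .morphometry import MorphometryConfig, profile_table
from .raters import (
    DUAL_MEASURED,
    RATER_TOLERANCE,
    reconcile_profiles,
    write_discrepancy_table,
)
from .stats import ALPHA_LEVELS, StatConfig, run_full_stat_battery
from .summaries import (
    SUMMARY_VALUE_COLUMNS,
    group_table,
    subject_table,
    write_group_table,
)
from .synthetic import reference_group_table

logger = logging.getLogger("capmorph")


@dataclass
class PipelineConfig:
    mode: str = "consistent"
    aspect_ratio_cutoff: float = 1.2
    rater_tolerance: float = RATER_TOLERANCE
    alphas: tuple[float, ...] = ALPHA_LEVELS
    paired: bool = True
    master_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.aspect_ratio_cutoff > 1:
            raise ValueError("aspect_ratio_cutoff must be > 1")
        if not 0 < self.rater_tolerance < 1:
            raise ValueError("rater_tolerance must be in (0, 1)")
        if list(self.alphas) != sorted(self.alphas, reverse=True):
            raise ValueError("alpha levels must be strictly decreasing")

    def morphometry(self) -> MorphometryConfig:
        return MorphometryConfig(mode=self.mode,
                                 aspect_ratio_cutoff=self.aspect_ratio_cutoff)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "aspect_ratio_cutoff": self.aspect_ratio_cutoff,
            "rater_tolerance": self.rater_tolerance,
            "alphas": list(self.alphas),
            "paired": self.paired,
            "master_seed": self.master_seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config field(s): {sorted(unknown)}")
        kwargs = dict(d)
        if "alphas" in kwargs:
            kwargs["alphas"] = tuple(kwargs["alphas"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    profiles: dict[str, pd.DataFrame]      # per-rater measured tables
    merged: pd.DataFrame                   # reconciled profile records
    discrepancies: pd.DataFrame
    subjects: pd.DataFrame
    groups: pd.DataFrame
    stats: pd.DataFrame
    comparisons: list = field(default_factory=list)
    report: str = ""
    config_hash: str = ""


def run_pipeline(
    annotations: Mapping[str, Sequence[CapillaryAnnotation]]
    | Sequence[CapillaryAnnotation],
    config: PipelineConfig | None = None,
    ages: Mapping[str, float] | None = None,
    run_stats: bool = True,
) -> PipelineResult:
    """Run the full analysis on one or two raters' annotation sets.

    ``annotations`` is either a mapping rater id -> annotation list (two-rater
    protocol, reconciled) or a flat list (single-rater, used as-is).
    """
    cfg = config or PipelineConfig()
    mcfg = cfg.morphometry()

    if isinstance(annotations, Mapping):
        raters = list(annotations)
        if len(raters) != 2:
            raise ValueError("two-rater pipeline expects exactly 2 raters")
        logger.info("measuring %d + %d profiles",
                    len(annotations[raters[0]]), len(annotations[raters[1]]))
        profiles = {r: profile_table(annotations[r], mcfg) for r in raters}
        merged, discrepancies = reconcile_profiles(
            profiles[raters[0]], profiles[raters[1]],
            metrics_to_merge=DUAL_MEASURED, tolerance=cfg.rater_tolerance,
        )
        if len(discrepancies):
            logger.warning("%d rater discrepancies flagged for repetition",
                           len(discrepancies))
    else:
        profiles = {"single": profile_table(annotations, mcfg)}
        merged = profiles["single"].copy()
        merged["bm_disrupted"] = merged["bm_disrupted"].astype(float)
        discrepancies = pd.DataFrame(
            columns=["micrograph_id", "metric", "value_rater1", "value_rater2",
                     "relative_deviation", "status"])

    n_excluded = int(merged["excluded"].astype(bool).sum())
    if n_excluded:
        logger.info("%d of %d profiles excluded (oblique or invalid geometry)",
                    n_excluded, len(merged))
    subjects = subject_table(merged, ages=dict(ages) if ages else None)
    groups = group_table(subjects)

    comparisons: list = []
    stats_df = pd.DataFrame()
    if run_stats:
        comparisons, stats_df = run_full_stat_battery(
            subjects, StatConfig(paired=cfg.paired, alphas=cfg.alphas))

    result = PipelineResult(
        profiles=profiles, merged=merged, discrepancies=discrepancies,
        subjects=subjects, groups=groups, stats=stats_df,
        comparisons=comparisons, config_hash=cfg.hash(),
    )
    result.report = render_report(result, cfg)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path,
                  config: PipelineConfig | None = None) -> dict:
    """Write every pipeline product as CSV/text under ``outdir``."""
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    all_profiles = pd.concat(result.profiles.values(), ignore_index=True)
    write_profile_table(all_profiles, outdir / "profiles.csv")
    paths["profiles"] = str(outdir / "profiles.csv")
    write_profile_table(result.merged, outdir / "profiles_merged.csv")
    paths["profiles_merged"] = str(outdir / "profiles_merged.csv")
    write_subject_table(result.subjects, outdir / "subjects.csv")
    paths["subjects"] = str(outdir / "subjects.csv")
    write_group_table(result.groups, outdir / "groups.csv")
    paths["groups"] = str(outdir / "groups.csv")
    write_discrepancy_table(result.discrepancies, outdir / "discrepancies.csv")
    paths["discrepancies"] = str(outdir / "discrepancies.csv")
    result.stats.to_csv(outdir / "stats_results.csv", index=False,
                        encoding="utf-8", float_format="%.6g")
    paths["stats"] = str(outdir / "stats_results.csv")
    (outdir / "report.txt").write_text(result.report, encoding="utf-8")
    paths["report"] = str(outdir / "report.txt")
    meta = {"config": cfg.to_dict(), "config_hash": cfg.hash(),
            "n_profiles": int(len(result.merged)),
            "n_subjects": int(len(result.subjects))}
    (outdir / "run_manifest.json").write_text(
        json.dumps(meta, sort_keys=True, indent=2) + "\n", encoding="utf-8")
    paths["run_manifest"] = str(outdir / "run_manifest.json")
    return paths


def render_report(result: PipelineResult, config: PipelineConfig) -> str:
    """Plain-text report: group table layout plus the significance battery."""
    lines = [
        "capillary morphometry report",
        f"config hash: {config.hash()}   mode: {config.mode}   "
        f"aspect-ratio cutoff: {config.aspect_ratio_cutoff}",
        "",
        f"profiles: {len(result.merged)} "
        f"({int(result.merged['excluded'].astype(bool).sum())} excluded), "
        f"subjects: {len(result.subjects)}, groups: {len(result.groups)}",
        "",
        "group means +/- SD (subjects as analysis units)",
    ]
    for _, row in result.groups.iterrows():
        cells = [f"{row['group']:<18} n={row['n_subjects']:>2}"]
        for col in SUMMARY_VALUE_COLUMNS:
            m, s = row[f"{col}_mean"], row[f"{col}_sd"]
            cells.append(f"{col}={m:.3g}±{s:.2g}" if np.isfinite(s)
                         else f"{col}={m:.3g}±NA")
        lines.append("  " + " ".join(cells))
    if len(result.stats):
        lines += ["", "statistical battery (stars: " +
                  ", ".join(f"{'*' * (i + 1)} p<{a}" for i, a in
                            enumerate(config.alphas)) + ")"]
        for _, r in result.stats.iterrows():
            if r["note"]:
                lines.append(f"  {r['design']:<28} {r['index']:<28} {r['note']}")
            else:
                lines.append(
                    f"  {r['design']:<28} {r['index']:<28} "
                    f"stat={r['statistic']:+.3g} p={r['p_value']:.4g} {r['stars']}")
    if len(result.discrepancies):
        lines += ["", f"rater discrepancies requiring repetition: "
                  f"{len(result.discrepancies)} (see discrepancies.csv)"]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Contrasts derived from the published group table
# ---------------------------------------------------------------------------

def published_group_contrasts(reference: pd.DataFrame | None = None) -> dict:
    """Arithmetic contrasts on the published per-group means.

    * minimum and maximum relative reduction (%) of the intraluminal
      surface-enlargement index in untrained diabetics vs every other group;
    * relative increase (%) of the BM-disruption frequency from the pre- to
      the post-training biopsy of the diabetes study.

    Negative reductions (diabetics higher than a comparison group) are
    reported as such.
    """
    ref = (reference if reference is not None else reference_group_table())
    ref = ref.set_index("group")
    t2dm = float(ref.loc["diabetic_pre", "luminal_enlargement_mean"])
    others = ref.drop(index="diabetic_pre")["luminal_enlargement_mean"].astype(float)
    reductions = 100.0 * (others - t2dm) / others
    pre = float(ref.loc["diabetic_pre", "disrupted_bm_mean"])
    post = float(ref.loc["diabetic_post", "disrupted_bm_mean"])
    return {
        "enlargement_reduction_min_pct": float(reductions.min()),
        "enlargement_reduction_max_pct": float(reductions.max()),
        "enlargement_reduction_vs_group": {
            g: float(v) for g, v in reductions.items()
        },
        "disrupted_bm_training_increase_pct": 100.0 * (post - pre) / pre,
    }
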