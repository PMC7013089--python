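# capmorph

Morphometry of skeletal-muscle capillary cross-sections from hand-traced
transmission-electron-micrograph contours.

Structural microangiopathy — remodeling of the capillary wall in systemic
vascular disease — is quantified by tracing compartment boundaries on
transverse capillary profiles and deriving geometric indices from the traced
areas *A* and boundary lengths *C*:

* lumen radius `R = 2·A_lumen / C_lumen`
* endothelial (EC) layer thickness `2·(A_abluminal − A_lumen) / (C_abluminal + C_lumen)`
* basement-membrane (BM) thickness `2·(A_BM − A_abluminal − ΣA_pericyte) / (C_BM + C_abluminal)`
* pericyte coverage (fraction of the abluminal arc subtended by pericytes),
  EC nucleus area density (% of the EC ring), and intraluminal surface
  enlargement by projections (% of the luminal perimeter)
* per-subject frequencies of peg–socket junctions (pericyte "pegs" in
  endothelial or pericyte "sockets", empty or filled) and of disrupted BM

Profiles with a max/min Feret-diameter ratio above 1.2 are treated as
obliquely sectioned and excluded. Four indices are measured by two raters
and merged under a 10 % mean-relative-deviation rule. Subjects (biopsies)
are the statistical unit; the battery covers paired/unpaired t-tests within
studies, 2×2 two-way ANOVA (phenotype × training) with Tukey HSD, a
cross-study one-way ANOVA of untrained hypertensive, type-2-diabetic and
claudicant patients against 42 pooled healthy participants, Spearman
correlations with age, and Lilliefors/Shapiro–Wilk normality screening.

The package is aimed at quantitative microscopists and exercise/vascular
physiologists who have traced capillary profiles (in ImageJ or any tool that
can export the JSON schema) and want a reproducible path from tracings to
the published table-and-stars analysis — plus a synthetic-cohort generator
with known ground truth for validating every stage without biopsy data.

## Worked example

Simulate two study groups (untrained and trained diabetics, 4 subjects × 20
profiles each) and run the full pipeline — measurement, two-rater
reconciliation, subject/group aggregation, statistics:

```python
import dataclasses
from capmorph import (CohortConfig, PipelineConfig, default_study_config,
                      generate_cohort, run_pipeline)

groups = {g: dataclasses.replace(default_study_config()[g],
                                 n_subjects=4, n_capillaries=20)
          for g in ("diabetic_pre", "diabetic_post")}
cohort = generate_cohort(CohortConfig(groups=groups), master_seed=7)
result = run_pipeline(cohort.annotations, PipelineConfig(), ages=cohort.ages)

cols = ["group", "n_subjects",
        "luminal_enlargement_pct_mean", "luminal_enlargement_pct_sd",
        "pct_capillaries_bm_disrupted_mean", "pct_capillaries_bm_disrupted_sd"]
print(result.groups[cols].round(1).to_string(index=False))
```

```
        group  n_subjects  luminal_enlargement_pct_mean  luminal_enlargement_pct_sd  pct_capillaries_bm_disrupted_mean  pct_capillaries_bm_disrupted_sd
diabetic_post           4                          13.5                         0.9                               34.2                             15.0
 diabetic_pre           4                          10.0                         1.3                               30.5                              8.1
```

The generator drew these groups at the published means (enlargement
10.2 ± 3.1 % vs 13.7 ± 1.9 %; disruption 34.9 ± 8.5 % vs 45.7 ± 9.9 %), and
the pipeline recovers the enlargement means at 4-subject precision; the
disruption frequencies are noisier because 20 binary observations per biopsy
carry ~10 points of binomial SD. The paired t-test detects the training
effect on the surface-enlargement index:

```
  design                   index  statistic  p_value stars
paired_t luminal_enlargement_pct    16.0251   0.0005   ***
```

The same stages are available from the shell:

```bash
capmorph simulate -c cohort.yaml -o sim/        # cohort + truth archive
capmorph run -a sim/annotations_rater_A.json \
             -b sim/annotations_rater_B.json -o out/
capmorph validate sim/annotations_rater_A.json
capmorph targets
```

`capmorph targets` evaluates the contrasts derivable from the packaged
published group table:

```
contrasts on the packaged published group means:
  enlargement, untrained diabetics vs other groups: 17.7% to 39.6% lower
  BM disruption, diabetes study pre -> post training: 30.9% increase
```

`capmorph run` writes `profiles.csv`, `subjects.csv`, `groups.csv`,
`discrepancies.csv`, `stats_results.csv` and a plain-text report; units are
fixed per column (nm, %, fractions) and documented in the headers module.

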