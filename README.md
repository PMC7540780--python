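# petrelniche

Niche-segregation analysis for sympatric central-place foragers, built
around the question of how two sibling seabird species — northern and
southern giant petrels (*Macronectes halli* / *M. giganteus*, NGP / SGP)
breeding side by side on a sub-Antarctic island — partition space, habitat
and diet. The package is aimed at movement ecologists and stable-isotope
ecologists who have (i) GPS tracks of nest-bound foragers, (ii) per-
individual blood δ13C/δ15N values, and (iii) gridded environmental fields,
and who want the full chain from raw fixes to segregation tests as tested,
reusable code rather than a one-off script.

## What it computes

**Space.** Tracks are speed-filtered (30 m/s), cut into foraging trips
(≥3 h further than 200 m from the nest), and individuals are classified
into *nearby* versus *distant* movement strategies by exact Fisher–Jenks
natural breaks on log trip distance. Group space use is a kernel
utilization distribution (UD) — an isotropic Gaussian KDE in lon/lat with
bandwidth *h* (default 0.8°), averaged with equal weight per individual —
summarized by 95% ("foraging range") and 50% ("core area") volume
contours. Overlap between groups is Bhattacharyya's affinity

    BA = Σ_cells √(p_i · q_i) ∈ [0, 1],

tested against a null of no segregation by permuting individual labels
within year (1000×) and counting how often the observed BA exceeds the
permuted one (small p ⇒ segregation).

**Isotopes.** Each group's (δ13C, δ15N) sample is summarized by the
standard ellipse area, SEA = π√(det Σ), with small-sample correction
SEAc = SEA·(n−1)/(n−2). Niche overlap between groups is the SEAc
intersection as a proportion of the summed non-overlapping areas, with the
same year-constrained permutation null; group location differences use
Wilks' Λ MANOVA, normality screening uses Mardia's coefficients, and
relative trophic position is the externally studentized residual of δ15N
regressed on δ13C (removing the baseline isoscape gradient that δ13C
carries).

**Habitat.** At-sea fixes are annotated with seven environmental
covariates (daily variables matched by date, chlorophyll by month, depth
statically), screened for |Spearman| > 0.70 collinearity, and classified
to species × sex by a 1000-tree random forest reported with out-of-bag
errors and Gini importances.

**Synthetic study.** A seeded generator produces tracks, isotopes, fields
and a land mask with the statistical structure the analysis assumes
(two movement strategies, species-specific directional bias, a latitudinal
δ13C isoscape with group trophic offsets), so the entire pipeline runs and
is tested end to end without any data download. See `docs/methods.md` for
models, assumptions and limitations.

## Worked example

```python
import petrelniche as pn
from petrelniche import PipelineConfig, run_pipeline

sim = pn.default_config(n_individuals_per_group=8, seed=7,
                        window_start="2016-10-01", window_end="2016-10-08")
cfg = PipelineConfig(sim=sim, n_perm=199, seed=7, stages=("spatial",))
res = run_pipeline(cfg)
print(res.spatial_report[res.spatial_report.contour_level == 95]
      [["comparison", "observed_overlap", "permuted_mean", "p_value"]]
      .round(3).to_string(index=False))
```

prints

```
              comparison  observed_overlap  permuted_mean  p_value
    NGP_male vs SGP_male             0.936          0.935    0.985
NGP_female vs SGP_female             0.017          0.428    0.000
  NGP_male vs NGP_female             0.057          0.686    0.000
  SGP_male vs SGP_female             0.020          0.650    0.000
```

Read: males of the two species share the island's surroundings (BA 0.94,
indistinguishable from the permutation null, p = 0.985), while the two
species' females — which forage at sea in opposite directions — barely
overlap (BA 0.02 versus ~0.43 expected under label exchange, p = 0), and
within each species males and females are segregated. That is the
qualitative pattern this analysis is designed to detect: sexual
segregation within species, spatial segregation between the pelagic
females, and no spatial segregation between males. The same `run_pipeline`
call with `stages=("spatial", "isotopes", "habitat")` adds the
SEAc/MANOVA/overlap tables and the habitat classification report, written
as CSV/JSON to `outdir` with a run manifest.

A command-line interface wraps the same calls:

```bash
petrelniche simulate --seed 1 --n-per-group 10 --outdir data/
petrelniche validate --tracks data/tracks.csv
petrelniche run --seed 1 --outdir results/
```

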