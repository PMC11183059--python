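# dugongrisk

Presence-only habitat suitability modelling, fishing-pressure risk mapping
and Critical Dugong Habitat (CDH) accounting for coastal seascapes.

Dugongs (*Dugong dugon*) persist in disjunct pockets of seagrass habitat
where systematic occurrence data are rare: most records come from fisher
interviews, volunteer networks and opportunistic sightings. This package
implements the full spatial prioritization workflow used for such data: a
two-stage maximum-entropy suitability model (seagrass first, dugong second,
with the modelled seagrass surface as a biotic predictor), seasonal model
stratification, niche-similarity statistics, a suitability-by-pressure risk
surface, Critical Habitat extraction, marine-protected-area (MPA) gap
accounting, and a boat-survey cross-check via inverse-distance-weighted
(IDW) threat interpolation. A synthetic-seascape generator with known
ground truth makes every stage testable end to end without any external
data.

## The model

The suitability model is the Gibbs distribution over background cells
*x* of the study region,

    p(x) = exp(λ·f(x)) / Z(λ),

where *f(x)* are features (linear, quadratic, product, hinge, threshold
expansions of the environmental predictors, min–max scaled over the
background) and *Z* normalizes over the background sample. The
coefficients maximize the L1-penalized presence log-likelihood

    (1/m) Σ_presence λ·f(x) − log Z(λ) − Σ_j β_j |λ_j|,

with per-feature penalties β_j following the published per-class
regularization tables scaled by a single multiplier. Maps are reported on
the logistic scale `e^H r/(1+e^H r)`, with `r` the normalized raw output
and `H` its entropy over the background, so a "typical" presence cell
scores 0.5. Settings (feature classes × regularization multiplier) are
chosen by the smallest AICc, with test AUC from random 5-fold partitions
(more than 50 occurrences) or leave-one-out jackknife (50 or fewer).

Downstream, seasonal suitability maps are averaged, multiplied by the
min–max-normalized fishing-pressure layer, and classified on the
percent-of-range scale (low 0–25, moderate 25–50, high 50–100). Cells in
the high risk class whose combined suitability exceeds 0.75 are Critical
Dugong Habitat. The gap report states how much high-risk area falls inside
and outside the MPA polygons, in km² and percent. Niche similarity between
seasons uses Warren's *I* (1 − ½·squared Hellinger distance) and
Schoener's *D* (1 − ½·L1 distance) on sum-normalized surfaces.

## Worked example

Run the whole pipeline on the default synthetic seascape (a 100×100 grid
of 1-km cells, three monsoon seasons, 60 presences per season):

```python
from dugongrisk.maxent import FeatureExpansion
from dugongrisk.pipeline import PipelineConfig, run_all
from dugongrisk.synthetic import ScenarioConfig

out = run_all(PipelineConfig(
    seed=1, scenario=ScenarioConfig(seed=1), use_bias=False,
    select_settings=False,
    candidates=[(FeatureExpansion(("linear", "quadratic", "hinge")), 1.0)],
))
print(out["report"].to_text())
print(f"Model-vs-survey Cohen's kappa: {out['kappa']:.4f}")
```

prints

```
High-risk area:            466.00 km2
  protected (inside MPA):  148.00 km2
  outside MPA network:     318.00 km2
  protected share:         31.8%
  outside share:           about 68%
Critical Dugong Habitat:   106.00 km2
Model-vs-survey Cohen's kappa: 0.0927
```

466 km² of the synthetic sea ends up in the high risk class; 31.8% of it
overlaps the scenario's MPA rectangles, so about 68% of high-risk habitat
is unprotected, and 106 km² qualifies as Critical Dugong Habitat. The
positive kappa says the boat-survey threat classes agree with the modelled
risk classes beyond chance. Per-season models also report the usual
`AUC ± SD` line (for this run, e.g. `0.847 ± 0.060` pre-monsoon).

The same workflow is scriptable from the shell:

```bash
dugongrisk simulate --seed 1 --out scenario/
dugongrisk run-all --seed 1 --out results/
```

with further subcommands (`prep`, `fit-seagrass`, `fit-dugong`, `select`,
`overlap`, `risk`, `validate`, `report`) to run any stage in isolation on
the files a previous stage wrote.

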