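# mfdiv — marine-reference sensitivity of freshwater divergence estimates

Studies of rapid freshwater adaptation in threespine stickleback
(*Gasterosteus aculeatus*) routinely use a contemporary marine population as
a proxy for the ancestral state.  That shortcut assumes marine fish are
phenotypically homogeneous across sampling sites.  `mfdiv` implements the
full analysis needed to test that assumption and to quantify its
consequences: if marine sites differ morphologically, how much do estimates
of freshwater **divergence** (how far a lake population has moved) and
**parallelism** (how similar the trajectories of different lakes are) depend
on which marine site you happened to sample?

It is aimed at evolutionary ecologists working with population-level
morphometric surveys, and ships with a synthetic survey generator (10 marine
+ 6 freshwater sites, 20–60 fish each, 8 linear traits + 2 counted traits)
so the whole pipeline runs end to end with known ground truth.

## The quantities at the core

* **Allometric size correction** — each trait is adjusted to a common body
  size: `γᵢ = χᵢ − β(Lᵢ − L̄)`, with `β` the per-population OLS slope of the
  raw trait on standard length `Lᵢ` and `L̄` the grand mean standard length.
  Gill raker number is never corrected; lateral plate number is corrected in
  freshwater fish only.
* **Morphospace** — one correlation-matrix PCA over all size-corrected
  specimens; site centroids are per-site mean scores.
* **Divergence** — for a marine reference *m* and lake *f*, either the
  absolute PC1 centroid difference `|c_f − c_m|` or the length
  `L = ‖c_f − c_m‖₂` of the multivariate divergence vector.
* **Parallelism (theta)** — for two lakes sharing a reference, the angle
  `θ = arccos( v₁·v₂ / ‖v₁‖‖v₂‖ )` between their divergence vectors; θ well
  below the 90° null indicates parallel evolution.
* **Reference effect** — divergence (or θ) ~ marine reference (fixed) +
  (1 | freshwater site), a balanced two-way mixed ANOVA reporting the marine
  sum of squares, `F` with `n_ref − 1` numerator df, and the
  random-intercept variance; plus the per-lake percent change
  `100 × (max − min)/max` across references.
* **Distance decay** — divergence regressed on shortest *through-water*
  distance (8-connected Dijkstra over a water raster, √2 diagonal cost) and
  on climatic difference (site-level PCA of the non-collinear bioclim
  variables), with the lake as a random intercept.

## Worked example

The numbered drivers under `analysis/` run the study on a synthetic survey
and narrate their findings (all tables land under `results/`):

```sh
python analysis/01_simulate_survey.py --seed 1
python analysis/02_size_correction.py
python analysis/03_morphospace.py
python analysis/04_divergence_parallelism.py
python analysis/05_distance_decay.py
```

which prints, among other things:

```
simulated 524 fish across 16 sites (seed 1)
  mean standard length: 50.61 mm
morphospace over 524 fish, 10 traits
  PC1 38.7%  PC2 12.6%  PC3 9.9% of variance
  strongest PC1 loadings: lateral_plate_number, pelvic_spine_length, pelvic_girdle_length, body_depth
divergence (PC1) per-reference means: 3.51-4.18
reference substitution changes divergence by 14%-22% depending on the lake
vector length depends on reference: SS = 1.06, F_9 = 4.5, p = 0.00028
theta: mean 33 deg (range 17-48); per-reference means 31-35 deg
theta depends on reference: SS = 174.7, F_9 = 12.4, p = 6.6e-14
```

Reading this: the armour/spine traits dominate PC1 (the marine–freshwater
axis); swapping the marine reference moves a lake's divergence estimate by
up to ~22% on this synthetic survey; mean θ ≈ 33° is far below the 90°
null, i.e. the lakes evolved in parallel, but the strength of that
inference too depends significantly on the reference (F₉ = 12.4).  The
distance-decay slopes are null here because the generator draws site means
without spatial autocorrelation — see `docs/methods.md`.

The same computation is available as a single call:

```python
from mfdiv import RunConfig, run_pipeline
results = run_pipeline(RunConfig(outdir="results/run", seed=1))
```

## Layout

```
src/mfdiv/        simulate, preprocess, morphospace, vectors, models,
                  geo_env, pipeline
analysis/         numbered narrative drivers (see worked example)
scripts/          acceptance.py
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   models, assumptions, parameter choices, limitations
```
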