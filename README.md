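# condclim

Climate-window analysis of avian body-condition responses, from raw
constant-effort-site (CES) ringing records to future projections and the
"species signal" — with a synthetic-data generator that plants a known
truth so every stage can be validated end to end.

## The problem

Mist-netting schemes capture the same bird populations year after year
under a fixed protocol, recording body mass and wing length. Body
condition — mass corrected for structural size, here the residual of a
per-species OLS regression of mass (g) on wing length (mm) — tracks fat
and protein reserves and responds to weather. Three questions drive the
pipeline:

1. **Which climate variables affect condition, and over which days?**
   For each species × variable (mean temperature, precipitation, wind,
   relative humidity, sunshine duration, daily temperature range), every
   consecutive-day window in the 365 days before the season's end
   (15 August) is a candidate. The daily series is averaged over the
   window per site-year, grand-mean centred, and added — linearly or
   quadratically — to a baseline model of condition (age, sex, time of
   day, day of season, individual identity). The (window, shape) pair
   minimising AICc wins, and a year-permutation randomization test guards
   against the winner being an artefact of trying tens of thousands of
   models: the year→climate mapping is permuted, the full scan re-run,
   and `p = (1 + #{permuted ΔAICc ≥ observed}) / (n_rand + 1)`.

2. **How sensitive is condition, and what does that imply for 2050?**
   Signal-bearing variables are combined by all-subsets AICc selection
   (collinear variables, |r| > 0.6, move as one group; "hitchhiker"
   variables are pruned) and full model averaging. Sensitivity is the
   tangent of the fitted curve at mean climate, `s = β₁ + 2β₂C̄`, with
   delta-method SE, expressed in % of species mean mass per climate
   unit. The projection to 2050 is `dB/dT = Σᵢ sᵢ·eᵢ`, where `eᵢ` is the
   season-matched projected change ("exposure") of variable *i*.

3. **Is there a species signal?** Site-level sensitivities are decomposed
   by a weighted random-intercept model (weights = 1/SE, species as the
   grouping factor) into among-species and among-population variance; the
   ratio `σ²ₛₚ/(σ²ₛₚ+σ²ₚₒₚ)` is an intraclass correlation. Near 1,
   populations of a species respond alike; near 0, a single species-level
   value is meaningless. Trait models (body size, migration, habitat,
   life-expectancy; site habitat) and phylogenetic/geographic
   distance–dissimilarity regressions ask what, if anything, predicts the
   variation.

## Worked example

```python
import condclim as cc

design = cc.default_design(n_species=1, n_sites=6, n_years=15, seed=2)
truth = cc.default_truth(
    design,
    effects=[cc.ClimateEffect(variable="temp", window=(100, 40), beta1=-0.5)],
    recapture_prob=0.0,
)
climate = cc.gen_climate(design, seed=2)
captures = cc.gen_captures(design, climate, truth, seed=2, captures_per_visit=1.5)
cond = cc.compute_condition(captures)
res = cc.randomization_test(
    cond, climate, variable="temp",
    site_to_station=dict(zip(design.sites["site"], design.sites["station"])),
    stride=5, n_rand=20, seed=3,
)
print(res.window, res.shape, round(res.beta1, 3), round(res.p_value, 3))
```

prints

```
(100, 40) linear -0.502 0.048
```

— the planted 100→40-day temperature window is recovered exactly, the
linear shape is preferred, the fitted slope −0.502 g/°C matches the
planted −0.5, and the signal beats all 20 permutations (p = 1/21 ≈ 0.048).

The same chain runs from the shell:

```bash
condclim simulate --out data/ --n-species 5 --seed 1
condclim run --data data/ --out results/ --stride 5 --n-rand 20 --seed 1
```

which writes `windows.csv` (best window, shape, ΔAICc and randomization p
per species × variable), `sensitivities.csv` (gram- and percent-scale
tangents at species and site level), `projections.csv` (per-variable
contributions and totals for 2050), `variance_ratios.csv` (the species
signal), `traits.csv`, `distance_slopes.csv` and `summary.json`, each
stamped with the config hash and seed.

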