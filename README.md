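# nh3ineq

Satellite observations of ammonia (NH₃) vertical column densities are one of
the few spatially complete records of air quality around concentrated animal
feeding operations (CAFOs), where ground monitoring is sparse and contested.
`nh3ineq` implements the analysis chain that turns coarse Level-2-like
satellite soundings into block-group-scale, population-weighted exposure
inequality metrics between demographic groups, together with the
meteorological stratifications and source-distance analyses used to attribute
the signal to facility emissions. It is aimed at researchers in environmental
epidemiology and environmental justice who want a tested, reusable, fully
synthetic-testable implementation of these methods.

## What it computes

**Oversampling.** Each sounding `i` (column `C_i`, 1σ uncertainty `σ_i`,
elliptical footprint with semi-axes `a, b` and orientation θ) contributes to
grid cell `j` of a regular 0.01° grid with weight `S_ij σ_i⁻²`, where

    S = exp(−ln2 · (|u/a|^k + |v/b|^k))

is the generalized-Gaussian spatial response at the cell's offset `(u, v)` in
the footprint's rotated frame — 1 at the footprint centre and exactly ½ at
its edge. `k = 2` is the smooth Gaussian commonly used for this instrument;
`k ≈ 18` approximates the sharp-edged physical pixel. The long-term cell
value is `Σ S_ij σ_i⁻² C_i / Σ S_ij σ_i⁻²` after a cloud/sensitivity
postfilter.

**Enhancements.** The exposure signal is ΔNH₃ = column − background, with the
background an empirically selected low percentile (default the 10th) of the
valid-cell column distribution for the period; cells at or below it are
flagged, not clipped. The percentile is chosen as the highest decile at which
absolute inequalities from raw columns and from enhancements are
statistically equivalent (`select_background_decile`).

**Inequalities.** Enhancements are aggregated to block-group polygons by
exact polygon–cell intersection (area weighting), then summarized per group
as population-weighted means over that group's *eligible* block groups
(group population share at or above the regional mean share):

    x̄_w = Σ p_i x_i / Σ p_i,   SEM = sqrt( Σ w_i² (x_i − x̄_w)² ),  w_i = p_i/Σp

Inequality versus the reference group is reported absolutely (`x̄_g − x̄_ref`)
and relatively (percent of the reference mean), with combined standard mean
errors.

**Stratification and distance decay.** Days are median-split by morning
(8 am–12 pm LT) wind speed and temperature; each stratum is re-oversampled
and enhanced against the all-days background. Block-group enhancements are
profiled against haversine distance to the nearest permitted swine facility;
the profile's spatial extent is where the binned mean last stays at or above
twice a far-field noise level (2× the 2σ spread at 15–20 km, shared across
strata).

**Synthetic scenes.** `nh3ineq.synthetic` generates fully self-contained
scenes — clustered exponential-decay point sources on a uniform background,
block groups whose demographic composition follows a logistic link on
facility proximity, lognormal/normal meteorology, and noisy elliptical
soundings — with a `designed_inequality` oracle computed by pushing the
noise-free truth field through the observation operator, so every downstream
stage is testable without external data.

## Worked example

```python
from nh3ineq import RunConfig, SceneConfig, run_all

config = RunConfig(
    scene=SceneConfig(seed=7, hot_source_multiplier=1.0, calm_decay_multiplier=1.0),
    n_days=60, pixels_per_day=120, noise_cv=0.15, stratify=False, seed=7,
)
report = run_all(config)
print(report.inequality[["group", "relative", "absolute", "sem_abs"]])
```

prints (see `examples/inequality_analysis.py`):

```
pixels used: 4856 of 7200 simulated
10th-percentile background: 4.64e+15 molecules/cm^2

           group  recovered %  designed %  abs (cm^-2)
           black       223.5       246.9     3.46e+15
        hispanic       223.5       246.9     3.46e+15
 american_indian       223.5       246.9     3.46e+15
```

The recovered relative inequality (223.5%: the population-weighted mean
enhancement for the group is 3.2× the reference group's) matches the scene's
designed value (246.9%) within the combined standard mean errors. All
non-reference groups coincide because the generator ties their population
shares to facility proximity through one shared link. The synthetic gaps are
deliberately larger than those a real regional record produces; they are a
designed recovery target, not an empirical estimate.

Other capabilities are demonstrated one per script under `examples/`:
oversampling (`oversample_scene.py`), stratified met analysis
(`stratified_met_analysis.py`), distance-decay profiles and
population-weighted distances (`distance_decay_profile.py`), the census
vintage swap (`census_vintage_swap.py`), and the passive-sampler bias
calculator (`passive_sampler_bias.py`).

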