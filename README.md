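# ecoira

Integrated Resilience Assessment (IRA) for yearly community time series:
a Python toolkit for detecting and quantifying climate-driven regime
shifts in multispecies survey data, built for quantitative community
ecologists working with bottom-trawl (or comparable) monitoring series.

Given a species × year biomass matrix (kg/km²), a species trait table and
candidate environmental stressor series (e.g. seasonal chlorophyll-*a*,
SST, a hydroclimatic index), the package

1. **ordinates** the community: correlation-matrix PCA of log-transformed
   biomasses over a grid of species-inclusion thresholds, keeping the most
   parsimonious PCA whose leading score series still track the most
   inclusive one;
2. **detects regime shifts** in the PC scores with the sequential t-test
   (STARS): a candidate year whose value departs from the running regime
   mean by more than `diff = t_{α/2, 2l−2} · sqrt(2σ²_l / l)` is confirmed
   or rejected by the Regime Shift Index, a cumulative sum of normalized
   anomalies over the next `l` years, with AR(1) prewhitening against red
   noise;
3. **discriminates continuous from discontinuous responses**: for each
   stressor × season × lag (0–2 yr) cell it fits a GAM
   `PC_y = s(x_{y−lag}) + ε` and a threshold GAM (TGAM) with separate
   smooths before and after a threshold year, and compares them by
   *genuine* cross-validation — for every left-out year the whole
   estimation (threshold-year search and smoothing-parameter selection
   included) is re-run, so GAM and TGAM errors are directly comparable;
4. **quantifies resilience** on the fold: the optimal TGAM's branches are
   the attractors on standardized (driver *x*, state *z*) axes,
   `Res_y = h_y − v_y` with `v_y = |z_y − attractor(x_y)|` and
   `h_y = |x_y − x_F|`, the tipping point `x_F` of each regime calibrated
   so the lowest within-regime `Res_y` is exactly zero; relative
   resilience `rRes_y = Res_y / max Res_y` is interpolated onto a 100×100
   stability landscape;
5. **tracks who wins and loses**: community-weighted mean temperature
   `CWMT_i = Σ_s Tpref_s · W_{s,i} / Σ_s W_{s,i}` with
   `W = log(biomass+1)`, life-history strategy contributions
   (opportunistic / periodic / equilibrium proportions, weighted the same
   way), equal-weight functional-group biomass series, and AR(1)-GLS
   (corAR1) trend tests.

A synthetic fold-bifurcation generator (`ecoira.synthetic`) produces
stressors, a latent two-attractor community state with hysteresis, species
matrices with sporadic catches, and trait tables with known ground truth,
so the entire chain is testable without any survey download.

## Worked example

```python
import ecoira as e
from ecoira.pipeline import RunConfig, run_ira

ds = e.simulate_dataset(seed=1)          # 26 years, 100 species, shift at 2009
bundle = run_ira(RunConfig(area="synthetic", seed=1),
                 biomass=ds.biomass, traits=ds.traits, stressors=ds.stressors)
print(bundle.model_selection.summary())
print(bundle.resilience.summary())
```

prints

```
optimal model per response (by genuine CV):
  PC1: TGAM chl_winter lag=1  gCV=0.244  var.expl=88.6%, threshold=2009.0
  PC2: GAM chl_winter lag=1  gCV=0.938  var.expl=12.8%, threshold=nan
  PC3: GAM sst_winter lag=1  gCV=0.884  var.expl=20.3%, threshold=nan
retained system PC: PC1
resilience assessment (standardized axes):
  regime 0: tipping x_F = +1.502 (high_x)
  regime 1: tipping x_F = -1.161 (low_x)
  max Res_y = 3.742 (rRes max = 1.000)
```

Reading this: across the 36-model grid the lowest genuine-CV error goes to
a discontinuous (TGAM) response of PC1 to winter chlorophyll at a 1-year
lag — exactly the mechanism the generator simulated — and the estimated
threshold year 2009 matches the ground truth. A unit-variance response
makes gCV ≈ 1.04 the skill of an intercept-only model, so 0.244 is a
strong fit (88.6% variance explained), while PC2/PC3 carry no signal. The
resilience stage then reports each regime's calibrated tipping point on
the standardized driver axis and the yearly resilience series whose
maximum defines `rRes = 1`.

The same run is available from a shell:

```
ecoira simulate --seed 1 --out data/
ecoira run-all --config config.yaml
```

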