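# fireregimes

Comparative fire-regime analysis for gridded burned-area data: define a
region's fire regimes from satellite-style monthly fire records, project
them onto a larger tropical domain, quantify how much of the tropics they
cover, measure burned-area trends that cannot be explained by rainfall,
and relate regimes to vegetation classes and tree-loss anomalies.

The package is aimed at landscape fire ecologists asking whether a focal
region's fire is globally unusual or a microcosm of wider tropical fire —
and whether its landscape degradation tracks landscape-scale fire at all.

## The method

Every grid cell with a multi-year monthly record of burned area, fire
count and mean fire size is described by **12 fire characteristics**:
monthly and yearly mean and coefficient of variation (CV) of each of the
three fields.  Monthly statistics are computed on the 12-value
climatological cycle (seasonality); yearly statistics on annual aggregates
(interannual variability).  Cells with no landscape-scale fire over the
span — no individual fire ≥ 0.21 km² (~21 ha, the detection floor of
500 m burned-area products) — form the **NLSF** class and are set aside.

The pipeline then:

1. **defines regimes** by agglomerative complete-linkage clustering
   (Euclidean distance on min–max-normalised characteristics), cut at a
   chosen K; labels ascend with cluster-mean burned area, so regime K is
   always the highest-fire regime;
2. **projects regimes** onto the full domain with the multivariate
   environmental similarity surface (MESS).  For a probe value *p* and a
   reference sample with fraction *f*% strictly below *p*:
   `f = 0 → 100·(p − min)/(max − min)`, `0 < f ≤ 50 → 2f`,
   `50 < f < 100 → 2(100 − f)`, `f = 100 → 100·(max − p)/(max − min)`;
   a cell's MESS is the minimum over the 12 characteristics.  Cells
   positive for some regime are *similar*, cells non-positive everywhere
   are *dissimilar*, and cells above 24 for exactly one regime form the
   mutually *exclusive* subset;
3. **quantifies niche overlap** between regions per regime with
   Schoener's `D = 1 − ½ Σ |w_a − w_b|` over binary occupancy grids in
   PCA-reduced fire / vegetation / climate spaces (two axes, fit on the
   pooled tropics);
4. **measures trends**: regime-wide ordinary least squares on annual
   burned area, and pixel-wise *rainfall-decoupled* trends — burned area
   regressed on the year index plus antecedent 6-month (drought) and
   24-month (fuel build-up) precipitation sums, the year coefficient
   read as the anthropogenic component;
5. **summarises degradation**: vegetation classed from normalised NDVI
   statistics (forest: mean > 0.80 and annual CV < 0.08; grassy:
   0.06 ≤ mean < 0.80 and monthly CV > 0.08), then tree-loss fractions
   and anomaly ratios (stratum ÷ all-tropics, > 1 = anomalous) per
   regime × region × vegetation class.

Real satellite archives are out of scope; the package ships a fully
parameterised **synthetic tropics** (three labelled regions, planted
regime archetypes, precipitation-coupled burned area, planted trends and
anomaly ratios, a truth record) so every stage is testable by parameter
recovery.

## Worked example

```bash
python examples/02_define_regimes.py
```

```
clustered 306 burned cells into 5 regimes
adjusted Rand index vs planted labels: 1.000

cut-height diagnostics (relative height of each K-cluster cut):
   K  cut_height  relative_height  flagged
0  2       3.113            1.000     True
1  3       1.946            0.625     True
2  4       1.364            0.438    False
3  5       0.979            0.315    False
...
```

The adjusted Rand index of 1.0 says the five planted regime archetypes
were recovered exactly from ~300 burned cells; the cut heights collapse
sharply beyond K = 5, the planted number of regimes.  Likewise,

```bash
python examples/04_trends_and_degradation.py
```

```
type-I error of the anthropogenic-trend flag: 0.066 (nominal 0.05, n=500)
planted -1 km^2/yr trend: recovered year coefficient -0.94, t < -2 in 91% of pixels

planted vs recovered tree-loss anomaly ratios:
  regime 1: planted 1.0, recovered 0.99
  regime 2: planted 2.0, recovered 2.00
  regime 3: planted 4.0, recovered 4.05
all-tropics baseline ratio: 1.0 (exact by construction)
```

— the rainfall-decoupling regression is calibrated (false-positive rate
at the nominal 5%), recovers a planted decoupled trend, and the
degradation summary returns the planted tree-loss anomaly ratios.

The other examples cover simulation/characterisation
(`01_simulate_and_characterise.py`) and the tropics-wide MESS projection
(`03_project_tropics.py`).  A thin CLI wraps the staged pipeline:
`fireregimes report --seed 42 --out out/` runs simulate → characterise →
cluster → project → overlap → trends → degrade and writes every stage's
table.

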