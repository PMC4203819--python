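# furrow

Quantitative analysis of contractile-ring closure during epithelial
cytokinesis, built around the kind of sparse annotation data produced by
live imaging of *C. elegans* vulval precursor cells (VPCs): three points
clicked on the cell outline and three on the ring outline per time point.

During cytokinesis an actomyosin ring constricts the cell equator. In
small epithelial cells the ring closes asymmetrically — it migrates
toward the apical surface as it shrinks — and closure speed scales with
cell size. `furrow` turns point annotations into ring-closure kinetics,
furrow-asymmetry measurements and size-scaling regressions, and ships a
synthetic-data generator with exact ground truth for validating the
whole chain.

## Measurements

From three cell-outline points and three ring points per frame, circles
are fit exactly (a circle is determined by three points), giving cell
radius `R`, ring radius `r` and the center-to-center distance `D`:

- **Ring closure** `= 100 · (1 − r/R)` — 0% at furrow onset, 100% when
  the ring has fully constricted.
- **Furrow asymmetry** `= 100 · D/R` — 0% for concentric closure; under
  apically directed furrowing it grows in proportion to closure.
- **Apical displacement** — the signed projection of the ring-center
  offset onto the annotated apical axis, in µm.

Per-trace kinetics follow the field conventions: traces are aligned at
their 50%-closure crossing (`t_mid`), speeds are the time derivative of
lightly smoothed closure, the average 20–80% speed is the least-squares
slope over that window, and population curves report mean ± SEM on
common time and closure grids. Morphometrics cover box-model cell
volumes from z-stacks, myosin-domain (furrow) breadth from intensity
profiles, division-plane perimeters (Ramanujan ellipse approximation)
and linear scaling fits. Group comparisons use unpaired t-tests
(pooled or Welch) and one-way ANOVA.

## Worked example

Simulate a cohort of 20 annotated cells under realistic conditions
(logistic closure with rate `k = 0.72 /min` and midpoint `t0 = 5 min`,
cell radius 2.5 µm, apical drift fraction `α = 0.4`, 0.05 µm annotation
jitter), then quantify and summarize them:

```python
from furrow.models import ClosureKinetics
from furrow.simulate import ClosureModel

models = [ClosureModel(k=0.72, t0=5.0, R0=2.5, alpha=0.4,
                       jitter_sigma_um=0.05, seed=i) for i in range(20)]
results = ClosureKinetics.simulate(models).fit()
print(results.summary())
```

Output (one trace fails the monotone-closure guard at this noise level
and is dropped with a log message, leaving 19):

```
dropping trace sim_013: trace sim_013: smoothed closure drops 21.2 points; not a monotone closure trace
Ring closure kinetics
=====================================================
traces: 19
t_mid (min):               4.990 ± 0.013 (SEM)
speed 20-80% (%/min):     16.014 ± 0.139
peak speed (%/min):       17.810 ± 0.121
closure at peak (%):      49.138 ± 1.722
duration 10-90% (min):     6.247 ± 0.071
logistic k (1/min):        0.718 ± 0.004
asymmetry/closure slope:   0.394 ± 0.004
```

The estimates recover the generating parameters: midpoint 4.99 vs 5 min,
peak speed 17.8 vs the analytic 25·k = 18 %/min, logistic rate 0.718 vs
0.72 /min, and asymmetry slope 0.394 vs α = 0.4. `results.summary_frame`
gives the per-trace table as a DataFrame, `results.curves` the aligned
population mean ± SEM curves, and `results.plot("closure")` a quick
figure.

The same pipeline runs from the command line on annotation CSVs:

```
furrow simulate --out sim/ --n-traces 20 --seed 0
furrow quantify --annotations sim/annotations.csv --out quant/
furrow summarize --traces quant/traces.csv --out summary/
```

or in one step with `furrow run-pipeline --config config.yaml`.

## Layout

- `src/furrow/geometry.py` — circle fits, closure / asymmetry / apical metrics
- `src/furrow/kinetics.py` — alignment, speeds, population averaging
- `src/furrow/morphometrics.py` — volumes, breadths, perimeters, scaling fits
- `src/furrow/stats.py` — t-tests, ANOVA, mean ± SEM
- `src/furrow/simulate.py` — trace, population and image generators
- `src/furrow/models.py` — `ClosureKinetics` / `ScalingRegression` model objects
- `src/furrow/io.py`, `src/furrow/cli.py` — CSV/YAML/TIFF I/O and the `furrow` CLI
- `docs/methods.md` — methods note: models, parameters, numerical choices
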