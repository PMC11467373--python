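# gridloc

Localisation workflows for automated radio telemetry systems (ARTS):
grids of fixed receiver nodes that continuously log the radio-signal
strength (RSS, in dB) of animal-borne tags.  `gridloc` goes from raw node
detections to estimated positions and quantifies how every
analytical decision along the way changes localisation error — the
workflow a movement ecologist needs when calibrating a node grid with
drone or walking trials before tracking animals (here: high-Andean
hummingbirds over a paramo valley, but nothing is species-specific).

## The pipeline

1. **Signal preparation** — detections are matched to ground-truth
   relocations by nearest timestamp (≤ 10 s gap); per relocation × node the
   maximum and the outlier-trimmed average RSS are computed (reads ≥ 4.33 dB
   from the mean are discarded once, then the survivors re-averaged).
2. **Signal smoothing** (optional) — per trial × node RSS series, either a
   cubic smoothing spline with GCV-chosen penalty or a local-level
   state-space model (random-walk level + white observation noise, variances
   by maximum likelihood, fixed-interval Kalman smoother).
3. **Decay calibration** — nonlinear least squares of

   `RSS(d) = a · exp(−S · d) + K`

   with intercept `a` (dB), decay factor `S` (1/m) and horizontal asymptote
   `K` (dB), fitted to the pooled data and then re-fitted per node or per
   tag starting from the general estimates (small or failing groups fall
   back).  Uncertainty by case-resampling bootstrap.
4. **Localisation** — invert the decay model to per-node distance estimates
   (`d = −ln((RSS − K)/a)/S`; reads ≤ K are excluded, negative distances
   clamped to 0 m) and solve for position by one of four methods:
   multilateration over **all nodes**, trilateration with the
   **strongest 3** or the **nearest 3** (in estimated distance) nodes, or a
   **grouped k-means** consensus: multilaterate every ≥3-node subset of the
   ≤7 strongest nodes (≤ 99 candidates), cluster the candidates and return
   the largest cluster's centroid.
5. **Track post-processing** — optional coordinate smoothing (same two
   smoothers) and an iterative speed filter (95% quantile or a hard
   biological cap, e.g. 25 m/s for hummingbirds).
6. **Evaluation** — error = planar distance (m) to ground truth, tabulated
   over the full 2 × 3 × 3 × 4 × 3 = 216-workflow factorial as a
   mixed-model-ready long table; step-resampling random-track nulls with a
   paired signed-rank test; terrain/vegetation/grid-membership covariates
   per relocation.
7. **Synthetic scenes** — a generator emulating a 46-node, 150 m grid with
   drone/walking trials at field-realistic speeds and RSS following a known
   decay law plus node offsets, vegetation attenuation, AR(1) noise and a
   detection floor, so the whole pipeline is testable without field data.

All geometry runs in an automatically selected UTM zone; inputs are plain
CSV, GPX 1.1, GeoTIFF (DEM) and GeoJSON (vegetation polygons).

## Worked example

```python
from gridloc import SceneConfig, TrialSpec, TagSpec, WorkflowConfig, make_scene
from gridloc.workflow import WorkflowRunner

cfg = SceneConfig(n_rows=5, n_cols=5, drop_nodes=(), noise_sd=2.0,
                  node_offset_sd=3.0, noise_ar1=0.6, seed=42)
trials = [
    TrialSpec("drone1", "high_flight", duration=120.0, tag=TagSpec("tag01")),
    TrialSpec("walk1", "ground", duration=120.0, tag=TagSpec("tag01"), t_offset=3600.0),
]
scene = make_scene(cfg, trials, with_landscape=False)

runner = WorkflowRunner.from_scene(scene, seed=1)
model = runner.model_set("max", "spline").general
wf = WorkflowConfig("max", "spline", "node", "strongest3", "none")
err = runner.errors(wf)
```

prints (via the obvious f-strings):

```
25 nodes, 3000 raw detections
general decay fit: a=74.5 dB, S=0.0109 /m, K=-105.0 dB (resid SE 3.49 dB, n=3000)
workflow max/spline/node/strongest3/none: 120 relocations localised, median error 6.7 m (90th percentile 12.4 m)
```

The decay fit recovers the scene's ground-truth law (a=68, S=0.01, K=−105)
up to the per-node offsets folded into `a`; the chosen workflow (maximum
RSS, spline-smoothed signals, node-scope models, strongest-three
trilateration) localises the 120 trial relocations with a median error of
a few metres under 2 dB AR(1) noise.  `runner.error_table()` produces the
same numbers for all 216 workflows at once.

The same run is available from a shell:

```sh
gridloc simulate --out scene/ --seed 42 --rows 5 --cols 5
gridloc localise --scene scene/ --rss max --smoother spline --scope node \
    --method strongest3 --out errors.csv
gridloc evaluate --scene scene/ --nulls 99 --seed 7 --out results/
```

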