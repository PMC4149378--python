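# stainkinetics

Quantifies how an iodine potassium iodide (I₂KI, Lugol's iodine) contrast
agent penetrates cardiac tissue during incubation, from a time series of
X-ray computed-tomography (micro-CT) slice images, and turns the result
into a practical staining-time calculator.

I₂KI is a standard high-density contrast agent for soft-tissue micro-CT:
under-stained tissue keeps its low native contrast and defeats automated
segmentation, while over-staining causes tissue shrinkage. The package is
for imaging scientists who need to choose the minimum incubation time
that fully stains a sample of a given thickness.

## The model

Along a transmural line profile, the image intensity of a tissue element
at depth *d* (mm from the epicardial edge) saturates exponentially over
staining time *t* (hours):

    I(d, t) = Imax(d) − (Imax(d) − I₀) · exp(−t / τ(d))

where *I₀* is the unstained intensity, *Imax(d)* the saturated ceiling at
that depth (depth-dependent because of beam hardening) and *τ(d)* the
local time constant. The time for the saturation ratio *I/Imax* to reach
a target level *s* (90, 95 or 99 %) follows in closed form, and — because
the stain advances by diffusion — it grows exponentially with depth:

    T(d) = A · exp(B · d)

with *A* (hours, the surface staining time) and *B* (per mm) fitted per
saturation level by ordinary least squares on the semi-log scale.
Reference coefficients for mouse ventricular wall ship with the package:

| level | A (h) | B (/mm) |
|-------|-------|---------|
| 90 %  | 5.72  | 1.04    |
| 95 %  | 7.17  | 1.12    |
| 99 %  | 11.3  | 1.16    |

The pipeline stages are: width-averaged line-profile extraction from the
slice images → three-step epicardial edge detection (Gaussian smoothing,
maximal-gradient search, gradient-decay criterion) → discretization into
twenty 0.1 mm depth segments → per-depth saturation-curve fit
(derivative-free simplex) → per-level depth–time model. A synthetic
phantom generator (annular wall, exponential-in-depth time constants,
beam-hardening ceiling gradient, seeded Gaussian noise) provides exact
ground truth for every stage.

## Worked example

Recommend a staining time for a 2 mm-thick sample using the packaged
mouse-heart coefficients:

```sh
$ stainkinetics calc --level 0.90 --thickness-mm 2
2 mm sample, single-sided, target 90% saturation: effective depth 2 mm -> recommended staining time 45.79 h

$ stainkinetics calc --level 0.99 --thickness-mm 2 --dual-sided
2 mm sample, dual-sided, target 99% saturation: effective depth 1 mm -> recommended staining time 36.05 h
```

The first number is A·exp(B·2) = 5.72·e^2.08 for single-sided exposure,
where the stain must cross the full 2 mm. Staining from both surfaces
halves the diffusion distance, so the 99 % target needs only
11.3·e^1.16 ≈ 36 h instead of ≈ 115 h.

Run the whole pipeline on a simulated phantom and fit its coefficient
table:

```sh
$ stainkinetics run --config examples/simulate.yaml --out-dir runs/demo
level  A_hours  B_per_mm  r2_log
 0.90   10.173    0.9768  0.99998
 0.95   13.890    0.9827  0.99998
 0.99   22.520    0.9888  0.99998
artifacts written to runs/demo
```

Here the phantom's time constant grows with depth at β = 1.0 /mm, and
the fitted B per level recovers it to within a few per cent; the run
also writes `profile.csv`, `grid.csv`, `fits.csv`,
`saturation_times.csv`, `coefficients.csv` and `report.json` (with the
config hash for provenance). The same stages are available as library
functions (`stainkinetics.run_pipeline`, `fit_saturation_curve`,
`fit_staining_time_model`, …) and as the finer-grained subcommands
`simulate`, `extract`, `fit` and `model`.

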