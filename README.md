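# myoatlas

Pixel-wise analysis of myocardial injury from segmented cardiac MRI.

After an ST-elevation myocardial infarction (STEMI), late and early
gadolinium enhancement (LGE/EGE) imaging reveals the infarcted myocardium
and microvascular-obstruction (MVO) cores inside it. Trials routinely
summarize these lesions with a handful of global numbers (infarct size,
transmurality), which discards *where* the injury sits in the wall.
`myoatlas` implements the alternative: map every patient's myocardium onto
one common geometry so lesions can be averaged and statistically compared
at **every myocardial location**, across treatment arms and culprit-vessel
territories.

It is aimed at imaging researchers who already have segmentations
(endocardium, epicardium, infarct, early/late MVO — e.g. exported from
CVI42 as `.cvi42wsx`) and want population-level lesion pattern statistics.

## Method

1. **Coordinates.** Each myocardial pixel gets normalized coordinates
   (*r*, *c*, *z*) ∈ [0,1]³: radial *r* = d_endo/(d_endo+d_epi) from
   endocardium (0) to epicardium (1); circumferential *c* anticlockwise
   from the LV–RV junction landmark; long-axis *z* linear from the
   endocardial apex to the mitral level (both possibly extrapolated beyond
   the acquired stack). Fields are estimated on 4× oversampled images;
   slices beyond apex/base and the LV outflow tract are excluded.
2. **Standardization.** A common semi-ellipsoidal reference LV (maximal
   endo/epi radii 30/50 px, 21 slices of 80×80) carries its own coordinate
   map. Each lesion channel is transported by matching coordinates:
   scattered linear interpolation of the subject's samples at every
   reference myocardial pixel, with circumferential wrap-around and **no
   extrapolation** beyond the acquired *z*-range. Binary masks become soft
   occupancy values in [0,1].
3. **Pixel-wise statistics.** Patterns are averaged per territory and arm
   on a 24 (segments) × 21 (slices) × 20 (radial bins) lattice. Per
   location (*c*, *z*): *location* = max over *r*, *transmurality* = mean
   over *r*, *variability* = across-subject SD, and a two-sample
   **Hotelling T²** test on the radial-profile vector, F-transformed with
   rank-adjusted degrees of freedom; raw p-values are shown on a Bull's eye
   (21 rings × 24 segments, log color scale) and summarized as the
   percentage of locations with p < α.
4. **Global descriptors.** Infarct/early-MVO/late-MVO area (% of
   myocardium), transmurality over the infarcted wall only, and endocardial
   surface area — before and after standardization — compared across arms
   with Mann–Whitney U (continuous) and Fisher exact (categorical) tests.
5. **Population embedding.** Infarct patterns are rotated so each
   territory's mean infarct center matches the LAD territory, then embedded
   in 2D with t-SNE (perplexity 10, PCA initialization) and colored by
   clinical covariates.

Because real trial data of this kind are not shareable, the package ships a
first-class synthetic cohort generator (`myoatlas.synthetic`): annular
anatomies with apex-to-base taper and contour jitter, territory-specific
wedge lesions with controllable center/extent/depth/span, nested MVO cores,
and injectable treatment-arm effects with known ground truth.

## Worked example

Simulate a single-territory two-arm cohort in which the delayed arm carries
+0.25 extra transmural depth, run the full pipeline on a miniature
reference geometry, and read off the results:

```python
from myoatlas import CohortSpec, RunConfig, generate_cohort, run_pipeline
from myoatlas.synthetic import AnatomyPrior, ArmEffect

anatomy = AnatomyPrior(grid_size=48, endo_radius_mean=10, wall_mean=5,
                       n_slices_mean=9, n_slices_sd=1, n_slices_range=(8, 10))
spec = CohortSpec(n_arm_a=12, n_arm_b=12, anatomy=anatomy,
                  territory_mix={"RCA": 1.0},
                  arm_effect=ArmEffect(depth_delta=0.25), seed=42)
cohort = generate_cohort(spec)

config = RunConfig(output_dir="demo-run", ref_endo_radius=12,
                   ref_epi_radius=19, ref_n_slices=11, ref_grid_size=44,
                   oversample=2, n_r=6, perplexity=5, seed=0)
run_dir = run_pipeline(config, studies=cohort.studies)
```

Printing the key numbers from `demo-run/manifest.json` and
`demo-run/descriptor_table.csv` gives:

```
included subjects: 24
RCA significant locations (%): 15.7
native transmurality, immediate: 45.3 (42.6-51.3)
native transmurality, delayed:   70.7 (63.6-75.7)
Mann-Whitney p: 0.0006
```

The injected transmurality difference is recovered both globally (median
45% vs 71%, p < 0.001) and spatially: 15.7% of myocardial locations reach
p < 0.05, clustered over the injected wedge (see
`demo-run/bullseye/RCA_pvalue.png`). The run directory also contains
location/transmurality/variability Bull's eyes (CSV + PNG), per-subject
descriptors before/after standardization, the t-SNE embedding coordinates,
and a manifest with the full configuration and per-subject inclusion log.

A shell interface mirrors the library
(`myoatlas simulate|run|standardize|analyze-group|globals|embed|reproducibility`).

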