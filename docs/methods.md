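# Methods

## Problem setting

Half-mask respirators fail fit tests at high rates, most often at the
nose, because a small number of mass-produced geometries cannot follow
the variety of human nasal profiles. `maskfit` implements a scan-to-size
workflow: a 3D facial scan is reduced to three numbers — the eye-to-chin
distance and the peak height *A* and spread *σ* of a Gaussian fitted to
the nasal cross-section — and those numbers select one of nine
semi-customised designs (three hard-shell sizes × three nasal profiles)
or flag the user for a fully-customised seal. A companion
flow-visualisation analysis grades how well a candidate seal performs on
a model face.

## Canonical anatomical frame

All measurements are made in a frame fixed by five user-supplied
landmarks (outer eye corners, chin, nose tip, nose bridge): origin at the
inter-ocular midpoint, x along the eye-to-eye direction, y vertical with
the chin at negative y, z anterior. No convention for this frame is
standard, so the package fixes one and applies it everywhere; the
orientation transform is a proper rigid motion (det +1, checked to
1e-9), and orienting twice is the identity. Landmarks are supplied as
coordinates in a JSON sidecar — interactive picking is out of scope.

STL files store every triangle independently; vertices closer than
1e-6 mm are merged on read so that plane sections and nearest-point
queries see a connected surface.

## Facial parameters

* **Eye-to-chin** is the straight-line distance from the origin to the
  chin landmark projected into the midsagittal (x = 0) plane. The
  projection makes the measure insensitive to lateral chin asymmetry. A
  surface-geodesic alternative was considered and rejected: the straight
  line is what a rigid shell spans.
* **Nasal profile**: the mesh is cut by a plane perpendicular to the
  bridge→tip ridge line, by default at the midpoint of that segment
  (`station_fraction = 0.5`, configurable; nothing in the workflow pins
  the station, and mid-ridge is the most stable place to cut). The
  intersection curve is projected onto in-plane (lateral, height) axes,
  trimmed to a lateral half-width of **40 mm**, the chord joining the
  two endpoints is subtracted (the Gaussian model has no offset term, so
  the baseline must be removed upstream), the apex is shifted to x = 0,
  and the curve is resampled at ≤ 0.5 mm spacing. The half-width
  matters: with a chord baseline, a window of half-width R biases the
  fitted peak by a factor ≈ exp(−R²/2σ²). At R = 30 mm and the largest
  catalogue σ (11.2 mm) that bias is ~2.8 % — above the 1 % recovery
  target — while at R = 40 mm it is 0.17 %. Hence the 40 mm default.
  Sections with peak relief below 0.5 mm are rejected as "no ridge"
  rather than fitted.
* **Gaussian fit**: h = A·exp(−(x−c)²/2σ²) by Levenberg–Marquardt least
  squares, initialised at A₀ = max h, c₀ = argmax, σ₀ = HWHM/√(2 ln 2),
  xtol 1e-8. σ is reported as |σ| (the model is even in σ). Failure to
  converge or a non-positive peak sets `converged = False` with the
  solver message; it is never silently returned as a parameter set.
* **Ridge angle**: the angle between the bridge→tip line and the facial
  x–y plane, in [0, 90°); 90° (a ridge perpendicular to the face) is
  rejected as degenerate.

## Sizing table and assignment

`fit_normal` is a moment fit (mean, n−1 sd); the "maximum" of the fitted
normal is its mean, and FWHM = 2σ√(2 ln 2). Three brackets are centred
at μ − FWHM/2, μ, μ + FWHM/2, each spanning centre ± half-width. The
half-widths are **not derivable from the method** — they are design
choices of the catalogue — so they are explicit configuration:
defaults 4.5 mm (eye-to-chin) and 0.5 (σ), calibrated so that the
bundled reference catalogue's printed ranges (e.g. Small 92.8–101.8 mm,
midpoint 97.3) are reproduced. Adjacent brackets then overlap by
2·hw − FWHM/2; non-adjacent brackets must not overlap (enforced).

Per shell, members are selected by eye-to-chin range — members of an
overlap contribute to **both** adjacent shells' σ distributions, which
is what gives borderline users flexibility at assignment time — and the
σ brackets and per-cell mean A are computed from those members.

Assignment: collect the shells whose range contains the user's
eye-to-chin (none → fully-custom). With one shell, pick the containing
σ profile (none → fully-custom). In an overlap of two shells, a shell
with a containing profile beats one without; if both contain, the
smaller σ-midpoint distance wins, with deterministic tie-breaks (closer
shell midpoint, then the smaller shell). Out-of-range users are a
*flag*, not an error: identifying them is half the point of the
workflow.

`coverage` is reported two ways, because "fraction of users served" can
mean eye-to-chin range only (`mode="shell"`) or full assignability
(`mode="joint"`); `assign` implements the joint reading and the
acceptance script reports it. On the default synthetic cohort the joint
coverage comes out near 88 %, consistent with the ~87.5 % published for
the original 200-participant cohort.

`mesh_deviation` (used to compare two scanning systems) is the unsigned
distance from each query vertex to the nearest point of the reference
surface. Unsigned was chosen over signed for symmetry of
interpretation. The query is exact: per-vertex nearest-point-on-triangle
with a KD-tree candidate prune whose search radius is expanded by the
largest triangle circumradius, so no closer triangle can be missed.
`compare_param_sets` reports the mean absolute difference, that as a
percentage of the first set's mean, the sd of the signed differences,
and the signed mean (which recovers a systematic offset).

## Flow visualisation

Frames are greyscale in [0, 255] at a known frame rate (250 fps in the
reference setup). Defaults follow the reference protocol: background =
mean of the first 5 frames; analysis windows of 10 frames every 25
frames (0.1 s at 250 fps); absolute deviations < 3 greyscale units are
treated as no deviation. Choices the protocol leaves open are fixed as:

* **Despeckle** = 3×3 median filter on the thresholded deviation
  magnitude (configurable size). Note a consequence checked in the
  tests: an isolated hot pixel vanishes, and a 5×5 hot block keeps 21 of
  its 25 pixels (the corners have fewer than five hot neighbours).
* **Brightness scaling** = 1 + (scale_max − 1)·b/b_max with b the local
  background value, i.e. a factor in [1, 2] by default. Scaling is
  applied after thresholding and is ≥ 1, so it cannot change mask
  membership: the pixel **count** — the quantitative output — is
  scaling-independent, and the threshold applies to raw greyscale
  deviations.
* **Counts** use the binary mask (a pixel is vapour or not).
* **Transient rule**: the filling transient ends the first time the
  count reaches 90 % of the series maximum. This detects the knee of a
  fill-then-plateau (sealed) recording; for a continuously growing leak
  there is no knee, so `transient_time` can fix the boundary at a known
  moment after injection (the injection instant is marked manually in
  the reference experiments). The leak grade is the ordinary
  least-squares slope of counts vs time strictly after the transient
  (≥ 5 points required), plus the post-transient mean as the plateau
  estimate.

## Synthetic data

The scans and videos behind the original catalogue are not
redistributable, so the generators are first-class, tested code and
define the study conditions used throughout the tests.

* `synth_face`: base surface is a shallow cap (radius 420 mm, curved
  along the vertical axis only) standing in for the facial plane. The
  nose is added by displacing base vertices along the height axis of the
  ridge-perpendicular section by A·exp(−x²/2σ²) times a smooth envelope
  that equals 1 exactly at mid-ridge. Because the displacement direction
  is perpendicular to the ridge axis, a section cut at station 0.5
  recovers the Gaussian exactly, and because the base is laterally
  straight its contribution to the section is removed exactly by the
  chord baseline — noiseless recovery error is limited only by mesh
  resolution (~0.3 % at the 1 mm default). The ridge axis is inclined
  at the requested angle *to the landmark-defined canonical frame*, so
  the ground-truth ridge angle is exact by construction. Landmarks are
  exact regardless of vertex noise; noise is applied along vertex
  normals. What this face does **not** emulate: lateral facial
  curvature, cheeks, lips, scanner artefacts, or landmark-placement
  error — passing recovery tests shows the extraction pipeline is
  correct, not that real scans are this clean.
* `synth_cohort`: independent normal draws per parameter, clipped at
  ±3 sd. Defaults (eye-to-chin μ 104.85, σ 6.37 mm; nasal σ μ 10.1,
  sd 0.72; A μ 23.3, sd 1.2 mm) are back-derived from the reference
  catalogue's bracket midpoints and per-cell means, so the default
  cohort rebuilds a catalogue-like table. Real cohorts correlate facial
  height with nasal size; the independence assumption is a documented
  simplification.
* `synth_leak_video`: a static background with a mild horizontal
  brightness gradient (so the brightness-scaling path is exercised) and
  a bright disc (+40 grey levels) whose pixel area grows at a set rate
  after injection, optionally saturating at a plateau area (the sealed
  scenario). The ground truth is the per-frame count of actually drawn
  disc pixels, not the nominal area, so comparisons are free of
  rasterisation bias.

## Problem sizes and tolerances

Default test/acceptance sizes: 10 000-record cohorts for table
construction (bracket midpoints within 0.3 mm of the population
values), 100 000 for the coverage-vs-CDF check (0.5 percentage-point
band), 10 000 for agreement recovery (5 % band), 50-face sweeps for
parameter recovery (< 1 % max noiseless, < 3 % median at 0.2 mm vertex
noise), and 6 s / 250 fps / 160×120 px videos for leak grading. These
sizes make the statistical bands comfortable while keeping the full
suite around half a minute.

## Known limitations

* Landmarks must be supplied; there is no automatic detection, and
  landmark error propagates directly into the eye-to-chin distance and
  the section placement.
* The Gaussian nasal model is the point of the workflow, not a claim
  about anatomy; strongly non-Gaussian profiles show up as a large
  `fit_rmse` and should be routed to full customisation by the caller.
* Pixel counts are a semi-quantitative leak measure; no conversion to
  volumetric leak rate is attempted.
* CAD generation, moulding, physical capture hardware, and human fit
  testing are outside the package's scope.
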