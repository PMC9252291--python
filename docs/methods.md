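# Methods

`numsense` implements an untrained two-layer neural-network model of the
visual number sense, the four controlled dot-array stimulus sets used to
probe it, and the tuning-curve analysis that quantifies numerosity
selectivity. This note documents the model, the stimulus generators, the
analysis pipeline, the numerical choices, and the known limitations.

## Model

**Architecture.** A 64×64 input layer (one unit per image pixel) is fully
connected to a 20×20 output layer. Connection weights are drawn i.i.d. from
N(μ = 0.5, σ² = 0.1) and never adjusted: the model is untrained, and every
result is a property of random connectivity plus lateral inhibition.

**Lateral inhibition.** Each layer performs a single, simultaneous pass of
subtractive lateral inhibition. Unit (x₀, y₀) with pre-inhibition activity
a receives

    a_inh(x₀,y₀) = a(x₀,y₀) − Σ_{(x,y)≠(x₀,y₀)} g · a(x,y)² · exp(−R² / (2 σ(x,y)²))

where R is the Euclidean distance between the two units in the layer's own
grid coordinates, σ(x,y) is the *source* unit's inhibition range, and the
gain is g = 2 (a unit inhibits its surround twice as strongly as its own
drive, which keeps the network from over-excitation). Three features matter:

* *Single pass.* All units inhibit one another using pre-inhibition
  activities; there is no recurrent settling. One pass stands in for the
  cumulative effect of inhibition at successive stages of the visual
  pathway.
* *Quadratic source term.* Inhibition scales with the square of the source
  activity while the feedforward drive is linear. Inhibition therefore
  overtakes excitation as stimulus intensity grows — the property that makes
  the output layer collapse toward zero under strong unattenuated input, and
  the reason ablating input-layer inhibition destroys the number sense
  rather than merely rescaling responses (a purely linear inhibition would
  leave preferences scale-invariant and ablation would change nothing
  qualitatively). For binary images the input layer is insensitive to the
  square.
* *Heterogeneous ranges.* Each unit draws its own σ once per network from a
  Gaussian truncated to positive values: input layer N(0.67, 0.40²), output
  layer N(0.26, 0.22²), both in units of the layer's own grid spacing.
  Draws are redrawn until positive (rather than absolute-valued) so the
  mode stays at the mean. The two sweep grids used in the ablation
  experiments (output 0.10–0.40, input 0.55–0.80) bracket these defaults.

Post-inhibition activities are rectified at zero (firing-rate reading);
`rectify=False` exposes the raw values. Rectification is essential: the mean
over repeats of a rectified noisy response is what turns the underlying
drive-versus-suppression competition into unimodal, interior-peaked tuning
curves.

**Why tuning emerges.** With input inhibition on, the total surviving input
activity T grows roughly linearly with the number of items n, independently
of item size and shape. An output unit's drive is ≈ 0.5·T while its
inhibition is ≈ L·(0.5·T)², where L sums the kernels of its neighbours. The
rectified response c₁T − c₂T² is a parabola in T: it peaks at an
intermediate numerosity set by the unit's inhibition load L, which varies
across units through the heterogeneous σ field and the unit's position
(edge units are inhibited least). A parabola peaking at n* has half-width
proportional to n*, which predicts a tuning-width-versus-preference slope of
about 0.5 on the linear scale — the size effect — and a nearly flat width on
compressed scales.

**Ablations.** Input-layer and output-layer inhibition can be switched off
independently (`no_input_li`, `no_output_li`, `no_li`). Without input
inhibition the output layer receives raw totals (e.g. 21·n active pixels for
control set 1); the quadratic inhibition then crushes responses at all but
the smallest numerosities, so the preference distribution collapses onto
numerosity 1 for the sets whose drive varies with n, and is flat for control
set 2, whose total drive (total area 600) does not depend on n at all.
Without output inhibition responses grow monotonically with drive and units
prefer the extremes.

## Stimuli

All images are 64×64 with binary intensities (1 on items, 0 elsewhere); a
control set holds one image per numerosity n = 1…30. Items are always
separated by at least one background pixel, so numerosity equals the number
of 4-connected foreground components. "Perimeter" is the digital
boundary-pixel count: item pixels with at least one 4-neighbour outside the
item. Under this convention the 5×5 square minus its four corners has
exactly area 21 and perimeter 12; continuous geometry admits no such shape,
which is why the digital convention is the right reading of those numbers.

* **Set 1 (fixed item area and perimeter).** Every item is the canonical
  21-pixel blob above. Placement is uniform over the frame with bounding
  boxes kept ≥ 1 background pixel apart (rejection sampling, 10,000 attempt
  budget).
* **Set 2 (fixed total area = 600).** Per-item areas are integers summing
  exactly to 600 (600 div n, remainder spread one pixel each to the first
  items). Each item is the disc-like blob of its exact area: the k lattice
  pixels nearest the item centre, which are always 4-connected.
* **Set 3 (fixed total perimeter = 180).** Per-item boundary budgets sum
  exactly to 180. Even budgets ≥ 4 become solid near-square rectangles
  (an h×w rectangle has 2h+2w−4 boundary pixels); budgets 1–3 are pixel
  lines; odd budgets add a single nub pixel outside a corner, which adds
  exactly one boundary pixel. Solid (not hollow) pieces are used so that
  surviving post-inhibition activity does not scale with ring length; with
  solid pieces the input layer's total response grows with n as required.
* **Set 4 (pentagonal convex hull, varied shapes).** Items are small
  (≤ 5×5) polyomino versions of a cross, rectangle, circle, triangle,
  square and diamond, drawn at random per item. The first five items sit on
  the vertices of the regular pentagon inscribed in a circle of diameter 60
  centred on the frame; remaining items are scattered inside the pentagon
  (shrunk by 0.82 toward the centre so the centroid hull keeps exactly five
  vertices). The pentagon is rotated 9° off the axes so vertex items fit the
  frame after rounding; vertex centroids land within about one pixel of the
  exact vertices. For n < 5 a pentagonal hull is unsatisfiable; items are
  placed on the first n vertices and a warning is issued. Set 4 uses
  dilated-mask disjointness rather than bounding-box separation (bounding
  boxes cannot pack 30 items into the pentagon); the ≥ 1 pixel background
  separation is preserved.

`audit_features` measures per-item areas and boundary perimeters and the
convex hull of item centroids, and the test suite verifies every constraint
exactly (sets 2 and 3 meet their totals with zero slack).

## Analysis

Responses of the 400 output units to the 30 numerosities are collected over
repeated runs (default 30), regenerating stimuli, weights and σ fields each
run. Per unit, the raw mean tuning curve over runs is computed and its
preferred numerosity is the argmax (ties break to the smallest numerosity).
Alongside, the *normalized* average curve divides each run's curve by its
own peak before averaging ("average response after normalization"), skipping
runs in which the unit was silent; this weighs weak and strong runs equally
and carries the run-to-run variability into the curve shape. The preference
distribution is the per-run histogram of preferences (fraction of the 400
units), averaged over runs.

Tuning curves are examined on four abscissae: f(x) = x, √x, ∛x, log₂x.
Gaussian functions A·exp(−(f(n)−μ)²/2σ²) are least-squares fitted:

* **Per unit** (the quantitative route): each responsive unit's normalized
  average curve is fitted on each scale; units with constant (all-zero)
  curves carry no signal and are skipped. Goodness of fit is the regression
  sum of squares over the total sum of squares, clipped to [0, 1]. Summary
  r² averages unit fits within each preferred numerosity first, then across
  preferences, then across control sets, so rarely-preferred numerosities
  are not swamped by popular ones. The size-effect slope is the OLS slope
  of fitted σ (in the scale's transformed units) against the fitted curve's
  own preferred numerosity — the Gaussian center mapped back to raw
  numerosity units — across a set's unit fits, averaged across sets. Width
  and position then come from the same fit; on compressed scales this
  pairing makes the slope nearly zero whenever widths are constant in
  transformed units, which is exactly the Weber–Fechner signature the
  comparison is after. (The discrete argmax preference class is available
  as an alternative abscissa.)
* **Pooled** (the display route): the normalized average curves of units
  sharing a preference on the grid n = 1, 2, 4, …, 28, 30 are averaged and
  min–max normalized to [0, 1] (max-only normalization is available as an
  option); a preference that attracts no units yields an absent pool rather
  than an error. Pooled curves drive the tuning-curve panels and are also
  fitted for reference.

Fit initialization: A₀ = 1 (curve peak), μ₀ = f(preferred numerosity),
σ₀ = (f(30)−f(1))/4; bounds σ ∈ (0, 10·(f(30)−f(1))], μ within two spans of
the data window; tolerances 1e-8, at most 5,000 evaluations
(`scipy.optimize.curve_fit`). Non-converged fits are flagged and excluded
from averages.

## Experiments and reproducibility

`run_experiment` orchestrates the four conditions over any subset of the
control sets. Each (condition, set, repeat) cell derives its own seed from
the master seed through `numpy.random.SeedSequence`, split further into a
stimulus stream and a network stream; everything downstream is bit
deterministic given the master seed. By default different conditions use
different streams (everything regenerated per condition, as in the original
protocol); `share_streams=True` drops the condition from the derivation so
ablation contrasts can be run on identical stimuli and weights.

A σ sweep replaces the *mean* of one layer's inhibition-range distribution
with each value from a list while retaining the per-unit spread
(`sweep_mode="constant"` uses a homogeneous field instead) and records one
preference distribution per value.

Default problem sizes: 30 repeats per set for reported quantities; the test
suite's end-to-end checks run 12 repeats per set, which leaves all reported
tolerance bands unchanged.

## Numerical notes

* The inhibition pass is a dense (N² ) kernel matrix per layer per network
  (4096×4096 for the input layer), built once per repeat and applied as a
  mat-vec against squared activities; squared grid distances are cached per
  layer shape.
* A flat curve has zero total sum of squares; its r² is defined as 0.
* The SS_reg/SS_tot ratio can exceed 1 for non-linear fits (the regression
  identity does not hold); values are clipped to [0, 1].
* Placement uses rejection sampling with a 10,000-attempt budget per image
  and restarts on dead ends; infeasible requests raise a packing error that
  names the set and numerosity.

## Limitations

* The stimulus generator covers the four controlled regimes only: binary
  intensities, non-overlapping items, no natural scenes, colour, or symbolic
  digits. Conclusions from passing tests concern this stimulus family, not
  natural images.
* The output-layer inhibition-range parameters (mean 0.26, sd 0.22 grid
  spacings) are the values consistent with the output-layer sweep grid
  0.10–0.40; inhibition ranges far above the grid spacing silence the layer
  entirely.
* Quantities derived from stochastic runs (goodness of fit, slopes,
  preference proportions) vary by a few percent between master seeds at 30
  repeats; tolerances in the tests reflect that spread.
* For n < 5 in set 4 the pentagonal hull constraint is relaxed (items on
  the first n vertices) — these images satisfy the shape-variation control
  but not the hull control.
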