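# Methods

This note records the model, the conventions and the genuinely open design
choices in `hedgelines`, in the package's own words. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and assumptions

The model is a threshold classification of canopy height statistics along a
linear boundary framework. Its assumptions are:

* **Height is sufficient.** Woody boundary features are distinguishable
  from walls, fences, banks and water purely by the vertical structure of
  the surface model along the boundary. Nothing spectral or contextual is
  used.
* **The framework is right.** Boundaries are where the polygon mosaic says
  they are; the model classifies given segments, it does not find new ones.
* **Screening is conservative.** Built-up, woodland, littoral and
  sub-littoral areas and high ground are zeroed rather than dropped, so a
  boundary passing through them reads "no canopy" instead of "no data".
  Genuine voids in the input grids stay `nodata` and are excluded from
  segment statistics — missing data and masked data are deliberately
  distinct states.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `min_h_floor` | −0.13 | m | lowest sampled height a woody boundary may show; absorbs a ditch hugging the hedge |
| `mean_h_floor` | 0.58 | m | mean height over the whole segment; low because hedges are gappy |
| `max_h_ceiling` | 58 | m | tallest credible tree in Great Britain; higher values are artefacts |
| altitude cutoff | 300 | m | ground altitude above which woody boundary features are not expected |
| sample step | CHM cell (5) | m | spacing of height samples along a segment; both endpoints always sampled |
| buffer radius | 5 | m | tolerance for linework mismatch between two frameworks |
| point interval | 5 | m | spacing of validation points along each network |
| match radius | 10 | m | nearest-neighbour cap, 2 × buffer radius: points further apart cannot describe the same boundary |

The source material gives the altitude cutoff as 350 m in one place and
300 m in two others; the operative screening description says 300 m, so
300 m is the default and the value is configurable.

## Conventions and numerical choices

* **Raster georeferencing.** Origin at the top-left corner, rows increase
  southwards; cell `(r, c)` covers the half-open square
  `[x0+c·s, x0+(c+1)·s) × (y0−(r+1)·s, y0−r·s]`, so a point on a shared
  edge belongs to the cell to its east/south. The far south/east edges of
  the whole extent are closed, so a boundary lying exactly on the extent
  border still samples the last row/column.
* **Coarser altitude screen.** A terrain grid coarser than the CHM (e.g.
  50-m against 5-m) is resampled nearest-neighbour: each CHM cell centre
  looks up the terrain cell containing it.
* **Network segments.** The dissolved mosaic is reduced to the primitive
  noded edges of the arrangement, with canonical vertex order and ids
  assigned by sorted (min-endpoint, max-endpoint), so output is independent
  of input polygon order. An isolated ring with no junctions stays one
  closed segment. `merge_chains=True` instead merges degree-2 runs so
  segment endpoints are exactly the junctions; both satisfy the noding
  invariant, and the primitive form is the default because it makes the
  segment count of a mosaic equal to its arrangement-edge count, which is
  directly checkable by enumeration.
* **Generalization** is plain Douglas–Peucker (`tolerance` = maximum
  perpendicular offset); tolerance 0 is the default and a strict identity.
  Generalization runs before splitting at intersections, mirroring the
  order in which a cartographic framework is simplified before noding;
  both orders are executable.
* **Classification comparisons are inclusive**, so a segment sitting
  exactly on all three thresholds is woody.
* **Square membership.** Segments crossing 1-km square borders are clipped
  at the border, which conserves total length across squares exactly.
* **Calibration.** The estimator objective |total − target| is piecewise
  constant in each threshold: between two consecutive attributed-segment
  statistics nothing changes. A greedy single-step hill climb therefore
  cannot move at 0.01-m resolution, so the search varies each parameter
  *sequentially over its whole range* in 0.01-m increments (fixed order:
  min floor, mean floor, max ceiling) and moves to the minimiser. Ties
  keep the incumbent; among tying new candidates the one closest to the
  incumbent wins, then the smaller value. Sweeps repeat until a full sweep
  changes nothing. The search is deterministic, never returns a worse
  objective than its start, and returns the start unchanged when the start
  already meets the target. A full grid search is available for small
  ranges. The per-stratum fit is reported but only the national total is
  optimised, because no multi-stratum loss is defined for this problem.
* **Weighted vs unweighted totals.** The stratified expansion
  (population × sample mean) is the primary estimator; an unweighted
  plain sum of sampled squares is available as an option.
* **Validation matching** is truth→model directional by default with ties
  broken by the smaller point index (the reverse direction is a flag);
  buffers use round caps and joins. Report percentages round half-up to
  integers; unrounded values are retained. Kappa of a degenerate matrix
  with chance agreement p_e = 1 is defined as 1 when observed agreement is
  also 1, else 0. Landis–Koch verbal bands are report annotations only.

## The synthetic generator

`generate_landscape` emulates the data regime the pipeline consumes: a
perturbed-grid field mosaic (mean field edge 200 m), a smooth two-harmonic
terrain surface (relief 60 m), hedge canopies of 1–4 m painted onto cells
whose centres lie within half a hedge width (2.5 m) of a designated
boundary, gap cells (default 15 % of hedge cells), occasional emergent
trees (2 % of hedge cells, up to 25 m), shallow ditch depressions beside
hedges (−0.10 m, 10 % of the adjacent band — kept shallower than the
0.13 m the minimum threshold tolerates, so a ditch alone cannot flip a true
hedge), woodland (8 %) and built-up (4 %) patches with their own canopy
structure, white surface noise (0.05 m), and north–south stratum bands over
the 1-km squares with hedge probability falling from 0.6 to 0.3. All draws
come from one seeded stream in a fixed order, so identical parameters give
bit-identical landscapes and varying a late parameter (e.g. the gap
fraction) leaves everything drawn earlier unchanged — that coupling is what
makes the gap-ladder monotonicity property exactly testable.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: spatially correlated surface error (radar
height error correlates over tens of metres; the generator's white noise is
the *worst* case for the minimum statistic, which is why the default noise
is small), double boundaries and boundary complexes, curved linework,
real land-class definitions, and any sensor physics. Synthetic validation
kappas near 1 say the machinery is correct, not that the method achieves
such agreement against field data — against real survey data the published
point-match table gives kappa ≈ 0.22.

## Problem sizes

Tests and the acceptance script use 1–3-km landscapes for unit and
end-to-end properties, a 5-km landscape (~1,300 boundary segments, 10⁶
raster cells) for calibration recovery, a 6-km landscape for the 200-sample
Monte-Carlo estimator check, and 200-point instances for the brute-force
nearest-neighbour oracle — sizes at which every independent oracle
(arrangement enumeration, O(n²) matching, raster area integration,
hand-enumerated point sampling) is exact and fast.

## Known limitations

* No reprojection: all coordinates are planar metres; geographic inputs
  must be projected first.
* The classifier is binary woody/other; walls, fences, banks and water are
  not discriminated from one another.
* No standard errors on the stratified total: the survey's variance
  estimator is not part of the model description, and a spatial bootstrap
  is out of scope.
* Whether height statistics should be computed over all cells a line
  touches rather than points sampled along it is unknowable from the model
  description; point sampling at the cell scale is used because it is
  oracle-checkable and converges to cell-traversal statistics as the step
  shrinks.
* Disambiguation of validation points falling in overlapping buffers of
  two distinct boundaries is resolved implicitly by nearest-neighbour
  matching; other conventions are defensible.
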