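# Methods

## Model structure

The habitat model is a Mamdani fuzzy-inference system with four inputs —
bed grain size *d* (m), water temperature *T* (°C), depth-averaged flow
velocity *U* (m/s) and water depth *h* (m) — and one output, the habitat
suitability index HSI ∈ [0, 1].  Each variable carries five normal,
piecewise-linear fuzzy sets (VL, L, M, H, VH) that overlap pairwise and
jointly cover the universe, so every input has a defined response.  Rule
strength is the min over factors of the max membership across the rule's
allowed grades; the `AC` wildcard contributes the factor's maximal
membership (which dips to 0.5 exactly at crossover points — a property of
the wildcard-as-maximum convention, not a coverage gap).  Each rule clips
its consequent set at the rule strength; clipped sets aggregate pointwise
by max; the centroid of the aggregate, by trapezoidal quadrature on a
0.001 grid over [0, 1], is the crisp HSI.  A zero aggregate cannot occur
with the complete default rule base; if a custom configuration produces
one, the defuzzifier returns a configurable fallback (default 0) and logs
a warning.

## Membership breakpoints

Only the grade *thresholds* are published, not curve shapes, so all
transitions are linear ramps centred on the stated thresholds and the
crossover memberships are exactly 0.5:

| factor | crossovers (VL/L, L/M, M/H, H/VH) | transition widths |
|---|---|---|
| temperature (°C) | 18, 20, 25, 27 | 2, 2, 2, 2 |
| velocity (m/s) | 0.1, 0.2, 1.3, 1.5 | 0.1, 0.1, 0.2, 0.2 |
| depth (m) | 0.6, 1.2, 11.5, 15 | 0.4, 0.4, 2, 2 |
| grain size (m) | 0.002, 0.02, 0.25, 0.40 | 0.002, 0.02, 0.1, 0.1 |

The temperature widths are pinned by the worked example (17 °C fully VL,
18 °C half VL / half L).  For velocity, a 0.2 m/s wide transition at the
0.2 m/s crossover would geometrically overlap the 0.1 m/s crossover and
leave no normal L set, so both low-end transitions use width 0.1; the
upper transitions keep width 0.2 and the VH shoulder starts at 1.6 m/s.
Depth and grain-size widths are chosen proportionate to their thresholds
with the VH shoulders at 16 m and 0.45 m.  All breakpoints are
configurable through the variable file.

The output sets are five triangles on [0, 1]: VL (0, 0, 0.2),
L (0, 0.2, 0.4), M (0.3, 0.5, 0.7), H (0.6, 0.8, 1), VH (0.8, 1, 1).  The
L set is symmetric about 0.2, so a fully blocked cell (only L-consequent
rules firing, at any strength) defuzzifies to exactly 0.2 and lands in the
low-suitability class.  With this geometry a fully blocked *reach* has
OSI = 0.2; the study's reported blocked-period OSI of 0.06 implies an
output-set geometry that is not recoverable from the publication, so no
attempt is made to match it and the sets remain configurable.

## Rule base

The packaged four-factor rule file carries the thirteen published rows
plus two documented additions:

* `VH AC AC AC -> L` — boulder-dominated beds (d > 0.40 m) depress
  suitability, mirroring the printed sand-blocking row `VL AC AC AC -> L`;
  without it the substrate-VH grade matches no rule.
* `L/M/H L/H L/H L/H -> L` — a completion row: the published table covers
  no combination with temperature, velocity and depth all merely marginal
  (L or H).  All-marginal conditions are graded low, consistent with the
  published row `L/H L/H L/H M -> L`.  This keeps the rule base complete
  (every 5⁴ grade combination matches exactly one expanded rule, verified
  by enumeration) and the HSI surface continuous.

`/` alternatives expand by cartesian product at load time; duplicate
expansions deduplicate; equal antecedents with different consequents are a
configuration error.

## Three-factor baseline

The predecessor model uses temperature, velocity and depth only.  It is
reconstructed from the four-factor base by widening every substrate
antecedent to `AC` and dropping the two substrate-only blocking rows.
Where the deletion makes expanded rules disagree (e.g. substrate M gave H
while substrate L/H gave M), the baseline keeps the **lower** consequent:
a model with no substrate knowledge cannot credit the compensation a
favourable bed provides, and the lift above that conservative baseline is
precisely the substrate effect the comparison quantifies.  With the upper
consequent the baseline would dominate the four-factor model everywhere
and the substrate effect could never be positive, contradicting the
reported May increases.

## Substrate inversion

The threshold-velocity formula is U-shaped in *d* (gravity term rising,
cohesion term ~ d^−0.72 falling), with its minimum located by
golden-section search (relative tolerance 1e-8 on a [1e-6, 2] m bracket).
Inversion solves the coarse (rising) branch by bisection to 1e-6 relative;
velocities below the attainable minimum clamp to the branch point and
velocities demanding grains coarser than 2 m clamp to the bracket, both
flagged.  Densities enter only through (ρ_s − ρ)/ρ = 1.65, so the g/cm³
values are used without conversion; all lengths and velocities are SI.

By default the pipeline inverts grain size from the **formative** velocity
field — the schedule's peak-discharge period — and joins it to every
period by cell id.  Rationale: bed-surface texture is set by the most
competent flow a reach experiences; inverting from each period's own
low-flow field (mean 0.4–0.6 m/s) would predict sub-millimetre sand over
essentially the whole reach, contradicting the gravel/cobble beds reported
for the study area, and sand blocks the four-factor model everywhere.
`substrate_mode="per-period"` re-inverts from each period's field (the bed
then coarsens with the rising seasonal discharge), and
`substrate_mode="supplied"` uses a `grain_d_m` column as-is, which is also
how measured substrate maps would enter.

## Reach metrics

WUA, OSI and the class proportions are computed over wetted cells only;
cells with missing or non-positive depth are excluded with a logged count.
Class bins follow the half-open convention (ISP: HSI ≥ 0.7;
MSP: 0.3 ≤ HSI < 0.7; LSP: HSI < 0.3), so the three proportions sum to
100 % exactly before display rounding (2 decimals; WUA is reported both in
m² at full precision and in 10⁵ m² at 2 decimals).

## Synthetic reach

The generator replaces the unavailable bathymetry and 2-D hydrodynamics
with steady uniform Manning flow on a parabolic channel (6 000 m long,
cells 20 m in the channel and 50 m on the bench) flanked by benches one
metre above bank level.  Per cross-section the stage is solved so
conveyance √S/n · Σ h^(5/3) w matches the period discharge with the
period's Manning n; local velocity is √S/n · h^(2/3).  Mean-one lognormal
multipliers (σ = 0.15) perturb depth and velocity, after which velocities
are rescaled within each section so the section discharge is conserved
exactly.  A small sinusoidal along-reach variation of the bankfull depth
(±4 %, wavelength 1.5 km) breaks longitudinal uniformity.  All randomness
derives from a single seed; geometry and cell areas are seed-independent.

Channel width (200 m) and slope (4.0e-4) are the output of a deterministic,
noise-free grid search (`calibrate_defaults`) targeting the reported
regime: at 1 840.67 m³/s (n = 0.1704) mean depth ∈ [9, 10] m and mean
velocity ∈ [0.4, 0.6] m/s; at 9 596.25 m³/s (n = 0.0883) over half the
wetted area faster than 1.5 m/s (measured: 9.49 m, 0.498 m/s, 53–54 %,
with 62 % of flood area deeper than 15 m).  The generator emulates these
marginal summary bands and the bank-to-thalweg ordering only; it does not
reproduce the real reach's planform, backwater profiles, secondary
currents or the joint depth–velocity structure of an unsteady flood wave.
Passing tests therefore validate the method's behaviour under realistic
magnitudes, not site-specific predictions.

## Problem sizes and numerical choices

Default runs use ~3 600 wetted cells per period (300 cross-sections × 12
cells) over ten semi-monthly periods, a size at which a full two-model
schedule comparison completes in well under a minute.  Defuzzification
uses a 0.001 grid (the centroid agrees with a 1e-5-step quadrature oracle
to better than 1e-3); inputs outside a variable's universe are clamped to
its bounds with a logged count; stage solving uses Brent's method with a
200 m stage cap, and an unreachable discharge raises an error naming the
bound.

## Known limitations

* The Manning stand-in ties velocity to local depth monotonically within a
  section; with the schedule's per-period roughness values this makes
  early July hydraulically similar to early June, so the seasonal WUA
  maximum falls in early July (10.8 × 10⁵ m²) marginally above early June
  (9.9 × 10⁵ m²), one half-month later than the study's June peak.  The
  field pattern that produces the July decline (backwater-driven stage and
  velocity structure during the flood) requires the hydrodynamic models
  that are deliberately out of scope here.
* With the default output sets a fully blocked reach has OSI 0.2, not the
  reported 0.06 (see above); absolute WUA/OSI magnitudes are therefore not
  comparable to the published table, while the qualitative structure
  (blocked cold months, May onset, flood collapse, positive May substrate
  effect) is.
* The reconstructed three-factor baseline is an explicit derivation from
  the four-factor table, not a citation-verified copy of the predecessor
  model's own rule base.
* Grain-size inversion treats the bed as a static response to a single
  formative flow; no armoring dynamics, supply limitation or bed evolution.
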