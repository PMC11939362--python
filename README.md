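# spawnhab

Substrate-inclusive fuzzy-logic assessment of river spawning habitat for
*Coreius guichenoti*, an endemic drifting-egg cyprinid of the upper Yangtze
whose spawning grounds in the lower Jinsha River are being reshaped by
cascade-reservoir operation.  The package is written for ecohydraulic
modellers who need a reproducible, testable implementation of the method:
per-cell habitat suitability from water temperature, flow velocity, water
depth **and bed grain size**, reach-level habitat indices per semi-monthly
period, and a quantified comparison against the traditional three-factor
(no-substrate) model.

## The model

Each factor is graded on five linguistic levels (VL, L, M, H, VH) by
piecewise-linear membership functions anchored to the species' published
tolerance bands (e.g. spawning is blocked below 18 °C or above 27 °C and
optimal at 20–25 °C, so a temperature of 18 °C is half VL, half L).  A rule
base maps factor-grade combinations to a suitability grade; Mamdani
inference (min AND, clip implication, max aggregation) and centroid
defuzzification

    HSI = ∫ Z μ_c(Z) dZ / ∫ μ_c(Z) dZ,   Z ∈ [0, 1]

yield a crisp habitat suitability index per grid cell.  Bed grain size *d*
is not observed but inverted from the threshold (incipient-motion) velocity

    U_e = (h/d)^0.14 [ 17.6 ((ρ_s − ρ)/ρ) d + 0.000000605 (10 + h) / d^0.72 ]^0.5

on its coarse (rising) branch: the local flow determines the finest grain
it cannot winnow away.  Reach quality per period is summarized by the
weighted usable area WUA = Σ A_i·HSI_i, the overall suitability index
OSI = WUA / Σ A_i, and the area fractions ISP (HSI ≥ 0.7),
MSP (0.3 ≤ HSI < 0.7) and LSP (HSI < 0.3).

Because the study's bathymetry and 2-D hydrodynamic fields are not
published, the package ships a calibrated synthetic reach (Manning
uniform-flow stand-in, parabolic channel plus benches) that reproduces the
reported hydraulic regime of the 6 km study reach: mean depth 9–10 m and
mean velocity 0.4–0.6 m/s at ~1 840 m³/s, and >50 % of the area faster
than 1.5 m/s at the 9 596 m³/s flood.

## Worked example

```
$ spawnhab substrate --depth 10 --velocity 4.516
grain diameter d = 0.25 m
```

A 4.5 m/s flow over 10 m of water keeps a 25 cm cobble bed immobile — the
coarse-branch inversion of the threshold-velocity formula.

Running the analysis drivers end to end (seed 42):

```
$ python analysis/01_calibrate_reach.py
calibrated reach: channel width 200 m, slope 4.00e-04
  low_mean_depth: 9.488
  low_mean_velocity: 0.4981
  ...
$ python analysis/03_evaluate_habitat.py
              Period       WUA_m2  WUA_1e5_m2  OSI   ISP   MSP    LSP
 First half of March 3.600000e+05        3.60 0.20  0.00  0.00 100.00
   First half of May 6.649386e+05        6.65 0.37  0.00 71.68  28.32
  First half of June 9.872794e+05        9.87 0.55 56.48 13.37  30.16
 Second half of July 7.037350e+05        7.04 0.39 22.90 13.78  63.32
  (abridged)
```

March and April are fully blocked by the 13.4–16.1 °C water temperatures
(every cell HSI = 0.2, LSP = 100 %); suitability rises once temperature
crosses the 18 °C threshold in May and collapses again in the late-July
flood when most of the section runs faster than 1.5 m/s.

```
$ python analysis/04_compare_models.py
              Period   WUA   OSI   ISP   MSP   LSP
 First half of March  0.00  0.00  0.00  0.00  0.00
   First half of May  3.84  3.84  0.00  0.12 -0.31
  Second half of May  1.29  1.29  0.00 -0.22  0.34
  (abridged)
```

Relative changes (%) after adding the substrate factor: nothing in the
cold months (both models blocked identically), a positive WUA lift in May
where gravel/cobble beds partly compensate the still-marginal 18.7 °C
water, and small negative corrections in June–July.

The same stages are available as a CLI (`spawnhab simulate | substrate |
evaluate | compare | summarize`) and as library calls
(`spawnhab.run_schedule`, `spawnhab.compare_models`, ...).

## Layout

* `src/spawnhab/` — library: `fuzzy` (sets, rules, Mamdani inference),
  `substrate` (threshold-velocity formula and inversion), `metrics`
  (WUA/OSI/ISP/MSP/LSP), `pipeline` (per-period runs, baseline, model
  comparison), `synthetic` (reach generator and calibration), `io`, `cli`.
* `src/spawnhab/data/` — default fuzzy variables, rule file and the
  semi-monthly operating schedule (discharge, water level, Manning n,
  temperature).
* `analysis/` — numbered drivers reproducing the study sequence.
* `docs/methods.md` — model assumptions, parameter choices, limitations.
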