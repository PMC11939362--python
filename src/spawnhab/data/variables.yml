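# Default fuzzy variables for the Coreius guichenoti spawning-habitat model.
#
# Each set is a list of [x, mu] breakpoints; membership is piecewise linear
# between them and extends flat at the terminal mu outside the listed range.
# Crossover points (adjacent grades at mu = 0.5) sit on the species' stated
# suitability thresholds: temperature 18/20/25/27 degC, velocity
# 0.1/0.2/1.3/1.5 m/s, depth 0.6/1.2/11.5/15 m, grain size 2/20/250/400 mm.
substrate:
  units: m
  universe: [0.0, 2.0]
  sets:
    VL: [[0.001, 1.0], [0.003, 0.0]]
    L:  [[0.001, 0.0], [0.003, 1.0], [0.010, 1.0], [0.030, 0.0]]
    M:  [[0.010, 0.0], [0.030, 1.0], [0.200, 1.0], [0.300, 0.0]]
    H:  [[0.200, 0.0], [0.300, 1.0], [0.350, 1.0], [0.450, 0.0]]
    VH: [[0.350, 0.0], [0.450, 1.0]]
temperature:
  units: degC
  universe: [0.0, 40.0]
  sets:
    VL: [[17.0, 1.0], [19.0, 0.0]]
    L:  [[17.0, 0.0], [19.0, 1.0], [21.0, 0.0]]
    M:  [[19.0, 0.0], [21.0, 1.0], [24.0, 1.0], [26.0, 0.0]]
    H:  [[24.0, 0.0], [26.0, 1.0], [28.0, 0.0]]
    VH: [[26.0, 0.0], [28.0, 1.0]]
velocity:
  units: m/s
  universe: [0.0, 6.0]
  sets:
    VL: [[0.05, 1.0], [0.15, 0.0]]
    L:  [[0.05, 0.0], [0.15, 1.0], [0.25, 0.0]]
    M:  [[0.15, 0.0], [0.25, 1.0], [1.20, 1.0], [1.40, 0.0]]
    H:  [[1.20, 0.0], [1.40, 1.0], [1.60, 0.0]]
    VH: [[1.40, 0.0], [1.60, 1.0]]
depth:
  units: m
  universe: [0.0, 50.0]
  sets:
    VL: [[0.4, 1.0], [0.8, 0.0]]
    L:  [[0.4, 0.0], [0.8, 1.0], [1.0, 1.0], [1.4, 0.0]]
    M:  [[1.0, 0.0], [1.4, 1.0], [10.5, 1.0], [12.5, 0.0]]
    H:  [[10.5, 0.0], [12.5, 1.0], [14.0, 1.0], [16.0, 0.0]]
    VH: [[14.0, 0.0], [16.0, 1.0]]
# Output suitability sets: five triangles on [0, 1].  The L centroid (0.2)
# sits below the 0.3 low-suitability cutoff so that fully blocked cells land
# in the low-suitability class.
hsi:
  units: dimensionless
  universe: [0.0, 1.0]
  sets:
    VL: [[0.0, 1.0], [0.2, 0.0]]
    L:  [[0.0, 0.0], [0.2, 1.0], [0.4, 0.0]]
    M:  [[0.3, 0.0], [0.5, 1.0], [0.7, 0.0]]
    H:  [[0.6, 0.0], [0.8, 1.0], [1.0, 0.0]]
    VH: [[0.8, 0.0], [1.0, 1.0]]
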