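"""Fuzzy sets, rule base and Mamdani inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spawnhab.fuzzy as fz
from spawnhab.fuzzy import (
    AC,
    GRADES,
    ConfigurationError,
    DefuzzifySpec,
    FuzzyRule,
    FuzzySet,
    RuleBase,
    defuzzify_centroid,
    evaluate_hsi,
    evaluate_hsi_field,
    fuzzify,
    infer,
    membership,
    rule_strength,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

FINE = np.linspace(0.0, 1.0, 100_001)  # 1e-5-step quadrature grid


def centroid_oracle(curve):
    """Fine-grid trapezoid centroid, independent of DefuzzifySpec."""
    den = np.trapezoid(curve, FINE)
    return np.trapezoid(curve * FINE, FINE) / den


def mamdani_oracle(rb, variables, inputs):
    """Scalar brute-force Mamdani evaluation on the fine grid."""
    mus = {
        f: variables[f].fuzzify(float(np.clip(x, *variables[f].universe)))
        for f, x in zip(fz.INPUT_FACTORS, inputs)
    }
    agg = np.zeros_like(FINE)
    for rule in rb.rules:
        s = min(max(mus[f][g] for g in grades) for f, grades in rule.antecedent)
        agg = np.maximum(agg, np.minimum(s, variables["hsi"].sets[rule.consequent](FINE)))
    return centroid_oracle(agg)


# ---------------------------------------------------------------------------
# membership and fuzzification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "temp, expected",
    [(17.0, 1.0), (18.0, 0.5), (19.0, 0.0), (13.4, 1.0)],
)
def test_temperature_vl_membership(variables, temp, expected):
    """The 17/18 degC worked example: full, half and zero VL membership."""
    assert membership(variables["temperature"], "VL", temp) == pytest.approx(expected)


def test_fuzzify_splits_between_adjacent_sets(variables):
    assert fuzzify(variables["temperature"], 18.0) == pytest.approx(
        {"VL": 0.5, "L": 0.5, "M": 0.0, "H": 0.0, "VH": 0.0}
    )
    assert fuzzify(variables["temperature"], 13.4) == pytest.approx(
        {"VL": 1.0, "L": 0.0, "M": 0.0, "H": 0.0, "VH": 0.0}
    )
    assert fuzzify(variables["temperature"], 22.0) == pytest.approx(
        {"VL": 0.0, "L": 0.0, "M": 1.0, "H": 0.0, "VH": 0.0}
    )


CROSSOVERS = {
    "temperature": [(18.0, "VL", "L"), (20.0, "L", "M"), (25.0, "M", "H"),
                    (27.0, "H", "VH")],
    "velocity": [(0.1, "VL", "L"), (0.2, "L", "M"), (1.3, "M", "H"),
                 (1.5, "H", "VH")],
    "depth": [(0.6, "VL", "L"), (1.2, "L", "M"), (11.5, "M", "H"),
              (15.0, "H", "VH")],
    "substrate": [(0.002, "VL", "L"), (0.02, "L", "M"), (0.25, "M", "H"),
                  (0.40, "H", "VH")],
}


@pytest.mark.parametrize("name", sorted(CROSSOVERS))
def test_crossover_partition(variables, name):
    """At every suitability threshold the two adjacent grades split 50/50."""
    var = variables[name]
    for x, a, b in CROSSOVERS[name]:
        assert var.membership(a, x) == pytest.approx(0.5), (name, x)
        assert var.membership(b, x) == pytest.approx(0.5), (name, x)


def test_invalid_sets_rejected():
    with pytest.raises(ConfigurationError):
        FuzzySet("L", (1.0, 1.0, 2.0), (0.0, 1.0, 0.0))  # non-increasing x
    with pytest.raises(ConfigurationError):
        FuzzySet("L", (0.0, 1.0), (0.0, 0.5))  # not normal
    with pytest.raises(ConfigurationError):
        FuzzySet("XX", (0.0, 1.0), (0.0, 1.0))  # unknown grade


def test_unknown_grade_query_is_configuration_error(variables):
    with pytest.raises(ConfigurationError):
        variables["temperature"].membership("XL", 20.0)


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


def test_rule_file_parsing_matches_token_semantics():
    rb = RuleBase.from_text("L/M/H  M  L/H  L/H  M  # a table row\nVL AC AC AC L\n")
    r0 = rb.rules[0].antecedent_map
    assert r0["substrate"] == frozenset({"L", "M", "H"})
    assert r0["temperature"] == frozenset({"M"})
    assert r0["velocity"] == frozenset({"L", "H"})
    assert rb.rules[0].consequent == "M"
    assert rb.rules[1].antecedent_map["temperature"] == AC


def test_rule_file_errors():
    with pytest.raises(ConfigurationError, match="consequent"):
        RuleBase.from_text("M M M M M/H\n")
    with pytest.raises(ConfigurationError, match="unknown grade"):
        RuleBase.from_text("M M XX M H\n")
    with pytest.raises(ConfigurationError, match="conflicting"):
        RuleBase.from_text("M M M M H\nM M M M L\n")
    with pytest.raises(ConfigurationError, match="empty"):
        RuleBase(())


def test_rule_strength_min_of_factor_maxima(variables):
    ones = {g: 1.0 for g in GRADES}
    mus = {f: dict(ones) for f in fz.INPUT_FACTORS}
    all_m = FuzzyRule.build({f: frozenset({"M"}) for f in fz.INPUT_FACTORS}, "VH")
    assert rule_strength(all_m, mus) == 1.0
    # AC contributes the factor's maximal membership
    blocking = FuzzyRule.build(
        {"substrate": AC, "temperature": frozenset({"VL"}), "velocity": AC,
         "depth": AC}, "L")
    mus2 = {f: {g: 0.0 for g in GRADES} for f in fz.INPUT_FACTORS}
    for f in fz.INPUT_FACTORS:
        mus2[f]["M"] = 1.0
    mus2["temperature"] = {"VL": 1.0, "L": 0.0, "M": 0.0, "H": 0.0, "VH": 0.0}
    assert rule_strength(blocking, mus2) == 1.0
    # the weakest factor limits the rule
    mus3 = {f: dict(ones) for f in fz.INPUT_FACTORS}
    mus3["temperature"] = {"VL": 0.0, "L": 0.0, "M": 0.5, "H": 0.0, "VH": 0.0}
    assert rule_strength(all_m, mus3) == 0.5
    with pytest.raises(ValueError, match="missing"):
        rule_strength(all_m, {"substrate": ones})


def test_rule_base_completeness(rb4):
    """Every 5^4 grade combination matches at least one expanded rule."""
    assert rb4.missing_combinations() == []


# ---------------------------------------------------------------------------
# inference and defuzzification
# ---------------------------------------------------------------------------


def test_blocked_temperature_fires_only_low_rules(rb4, variables):
    """At 13.4 degC only consequent-L rules fire: aggregate is the L set."""
    grid, agg = infer(rb4, variables, (0.1, 13.4, 0.5, 5.0))
    expected = variables["hsi"].sets["L"](grid)
    assert np.allclose(agg, expected)
    # enumeration: every rule containing temperature VL has consequent L
    for rule in rb4.rules:
        if "VL" in rule.antecedent_map["temperature"]:
            assert rule.consequent == "L"


def test_all_optimal_fires_full_vh(rb4, variables):
    grid, agg = infer(rb4, variables, (0.1, 22.5, 0.7, 5.0))
    assert np.allclose(agg, variables["hsi"].sets["VH"](grid))


def test_centroid_closed_forms():
    grid = np.linspace(0.0, 1.0, 1001)
    tri = np.interp(grid, [0.3, 0.5, 0.7], [0.0, 1.0, 0.0])
    assert defuzzify_centroid(grid, tri) == pytest.approx(0.5, abs=1e-9)
    assert defuzzify_centroid(grid, np.ones_like(grid)) == pytest.approx(0.5)


def test_centroid_of_full_l_set_matches_fine_grid_oracle(variables):
    l_set = variables["hsi"].sets["L"]
    grid = DefuzzifySpec().grid()
    got = defuzzify_centroid(grid, l_set(grid))
    assert got == pytest.approx(centroid_oracle(l_set(FINE)), abs=1e-3)
    assert got == pytest.approx(0.2, abs=1e-6)


def test_zero_aggregate_uses_fallback():
    grid = np.linspace(0.0, 1.0, 101)
    spec = DefuzzifySpec(fallback=0.25)
    assert defuzzify_centroid(grid, np.zeros_like(grid), spec) == 0.25


@pytest.mark.parametrize(
    "inputs",
    [
        (0.1, 13.4, 0.5, 5.0),    # temperature-blocked
        (0.1, 22.5, 0.7, 5.0),    # all optimal
        (0.1, 22.5, 0.7, 0.9),    # depth on the L plateau
        (0.05, 19.0, 0.7, 5.0),   # temperature L peak, substrate M
        (0.0004, 18.7, 0.5, 9.5), # sandy bed at the May temperature
        (0.25, 20.0, 1.3, 11.5),  # every factor at a crossover
    ],
)
def test_evaluate_hsi_matches_brute_force_oracle(rb4, variables, inputs):
    """The vectorized pipeline equals an independent fine-grid evaluation."""
    expected = mamdani_oracle(rb4, variables, inputs)
    assert evaluate_hsi(rb4, variables, inputs) == pytest.approx(expected, abs=1e-3)
    got = evaluate_hsi_field(
        rb4, variables,
        np.array([inputs[0]]), inputs[1], np.array([inputs[2]]),
        np.array([inputs[3]]),
    )
    assert got[0] == pytest.approx(expected, abs=1e-3)


def test_blocked_hsi_sits_in_low_class(rb4, variables):
    assert evaluate_hsi(rb4, variables, (0.1, 13.4, 0.5, 5.0)) == pytest.approx(0.2, abs=1e-6)
    assert evaluate_hsi(rb4, variables, (0.1, 13.4, 0.5, 5.0)) < 0.3


def test_temperature_blocking_is_independent_of_other_factors(rb4, variables):
    """Fully cold or hot water fixes HSI no matter the hydraulics or bed."""
    for temp in (13.4, 29.0):
        vals = [
            evaluate_hsi(rb4, variables, (d, temp, u, h))
            for d in (0.0005, 0.05, 0.5)
            for u in (0.1, 0.7, 2.0)
            for h in (0.5, 5.0, 18.0)
        ]
        assert np.ptp(vals) < 1e-9


def test_hsi_continuous_along_sweeps(rb4, variables):
    """Piecewise-linear memberships + max/min + centroid give no jumps."""
    hsi = np.array([evaluate_hsi(rb4, variables, (0.1, t, 0.7, 5.0))
                    for t in np.arange(12.0, 30.0, 0.05)])
    assert np.abs(np.diff(hsi)).max() < 0.05
    # velocity transitions are as narrow as 0.1 m/s (max slope ~6 per m/s),
    # so a 0.002 m/s sweep step bounds increments well below any jump
    vels = np.arange(0.0, 2.5, 0.002)
    hsi_v = evaluate_hsi_field(
        rb4, variables, np.full(vels.size, 0.1), 22.5, vels,
        np.full(vels.size, 5.0))
    assert np.abs(np.diff(hsi_v)).max() < 0.05


def test_warming_into_optimum_never_decreases_hsi(rb4, variables):
    temps = np.arange(19.0, 22.6, 0.1)
    hsi = [evaluate_hsi(rb4, variables, (0.1, t, 0.7, 5.0)) for t in temps]
    assert np.all(np.diff(hsi) >= -1e-9)


# hypothesis draws cannot mix with pytest fixtures here; module-level singletons
_RB4 = None
_VARS = None


def _defaults():
    global _RB4, _VARS
    if _RB4 is None:
        import spawnhab as sh

        _RB4, _VARS = sh.load_rules(), sh.load_variables()
    return _RB4, _VARS


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    d=st.floats(1e-5, 2.0),
    t=st.floats(0.0, 40.0),
    u=st.floats(0.0, 6.0),
    h=st.floats(0.01, 50.0),
)
def test_hsi_always_within_unit_interval(d, t, u, h):
    rb, variables = _defaults()
    hsi = evaluate_hsi(rb, variables, (d, t, u, h))
    assert 0.0 <= hsi <= 1.0
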