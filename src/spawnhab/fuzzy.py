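"""Mamdani fuzzy inference for spawning-habitat suitability.

Four habitat factors -- bed grain size (``substrate``), water
``temperature``, depth-averaged ``velocity`` and water ``depth`` -- are
graded on five linguistic levels (VL, L, M, H, VH) by piecewise-linear
membership functions.  A rule base maps graded factor combinations to a
suitability grade; min-AND rule strengths clip the consequent sets, the
clipped sets are aggregated pointwise by max, and the centroid of the
aggregate is the crisp habitat suitability index (HSI) on [0, 1].

The numeric breakpoints of the default sets are anchored to the species'
published tolerance and optimum bands (temperature unsuitable below 18 or
above 27 degC, optimal 20-25 degC; velocity optimal 0.2-1.3 m/s, unsuitable
above 1.5; depth optimal 1.2-11.5 m, unsuitable above 15; gravel/cobble beds
2-25 cm suitable, boulders above 40 cm unsuitable) and are configurable
through the variable file (see :mod:`spawnhab.io`).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRADES",
    "INPUT_FACTORS",
    "AC",
    "ConfigurationError",
    "FuzzySet",
    "FuzzyVariable",
    "FuzzyRule",
    "RuleBase",
    "DefuzzifySpec",
    "membership",
    "fuzzify",
    "rule_strength",
    "infer",
    "defuzzify_centroid",
    "evaluate_hsi",
    "evaluate_hsi_field",
]

log = logging.getLogger(__name__)

#: Linguistic grades, ordered from very low to very high.
GRADES = ("VL", "L", "M", "H", "VH")
GRADE_RANK = {g: i for i, g in enumerate(GRADES)}

#: Input factors of the four-factor spawning model, in rule-file column order.
INPUT_FACTORS = ("substrate", "temperature", "velocity", "depth")

#: Wildcard antecedent: the entire fuzzy set of a factor.
AC = frozenset(GRADES)


class ConfigurationError(ValueError):
    """Raised for malformed rule bases or fuzzy-variable definitions."""


# ---------------------------------------------------------------------------
# fuzzy sets and variables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzySet:
    """One linguistic grade of a factor as a piecewise-linear membership.

    Membership is linearly interpolated between ``breakpoints`` (x, mu)
    and extends flat at the terminal mu outside the listed x-range.
    """

    label: str
    xs: tuple[float, ...]
    mus: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.label not in GRADES:
            raise ConfigurationError(f"unknown grade label {self.label!r}")
        xs = np.asarray(self.xs, dtype=float)
        mus = np.asarray(self.mus, dtype=float)
        if xs.size != mus.size or xs.size < 2:
            raise ConfigurationError(
                f"{self.label}: need >= 2 (x, mu) breakpoints, got {xs.size}"
            )
        if not np.all(np.diff(xs) > 0):
            raise ConfigurationError(f"{self.label}: breakpoint x must strictly increase")
        if np.any(mus < 0) or np.any(mus > 1):
            raise ConfigurationError(f"{self.label}: membership must lie in [0, 1]")
        if not np.any(np.isclose(mus, 1.0)):
            raise ConfigurationError(f"{self.label}: set is not normal (no mu = 1)")

    @classmethod
    def from_breakpoints(cls, label: str, breakpoints) -> "FuzzySet":
        xs, mus = zip(*breakpoints)
        return cls(label, tuple(float(x) for x in xs), tuple(float(m) for m in mus))

    def __call__(self, x):
        """Membership degree at ``x`` (scalar or array)."""
        return np.interp(x, self.xs, self.mus)


@dataclass(frozen=True)
class FuzzyVariable:
    """A factor with five overlapping linguistic sets on a universe."""

    name: str
    units: str
    universe: tuple[float, float]
    sets: dict[str, FuzzySet] = field(compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ConfigurationError(f"{self.name}: empty universe {self.universe}")
        if tuple(sorted(self.sets)) != tuple(sorted(GRADES)):
            raise ConfigurationError(
                f"{self.name}: expected exactly the five grades {GRADES}, "
                f"got {sorted(self.sets)}"
            )
        self._check_coverage_and_overlap()

    def _check_coverage_and_overlap(self, n: int = 2001) -> None:
        grid = np.linspace(*self.universe, n)
        mm = self.memberships(grid)  # (n, 5)
        if np.any(mm.sum(axis=1) <= 0):
            x_bad = grid[mm.sum(axis=1) <= 0][0]
            raise ConfigurationError(
                f"{self.name}: no set covers universe point x={x_bad:g}"
            )
        for a, b in zip(GRADES[:-1], GRADES[1:]):
            both = (mm[:, GRADE_RANK[a]] > 0) & (mm[:, GRADE_RANK[b]] > 0)
            if not both.any():
                raise ConfigurationError(
                    f"{self.name}: adjacent sets {a} and {b} do not overlap"
                )

    def membership(self, grade: str, x):
        if grade not in self.sets:
            raise ConfigurationError(f"{self.name}: unknown grade {grade!r}")
        return self.sets[grade](x)

    def memberships(self, x) -> np.ndarray:
        """Memberships of all five grades at ``x``; shape ``x.shape + (5,)``."""
        return np.stack([self.sets[g](x) for g in GRADES], axis=-1)

    def fuzzify(self, x: float) -> dict[str, float]:
        return {g: float(self.sets[g](x)) for g in GRADES}

    def clamp(self, x):
        """Clamp values to the universe (flat-shoulder semantics)."""
        lo, hi = self.universe
        x = np.asarray(x, dtype=float)
        n_out = int(np.count_nonzero((x < lo) | (x > hi)))
        if n_out:
            log.debug("%s: clamped %d value(s) to universe [%g, %g]",
                      self.name, n_out, lo, hi)
        return np.clip(x, lo, hi)


def membership(var: FuzzyVariable, grade: str, x: float) -> float:
    """Degree to which factor value ``x`` belongs to ``grade`` of ``var``."""
    if not np.isfinite(x):
        raise ValueError(f"{var.name}: non-finite input {x!r}")
    return float(var.membership(grade, x))


def fuzzify(var: FuzzyVariable, x: float) -> dict[str, float]:
    """Memberships of ``x`` in all five grades of ``var``."""
    if not np.isfinite(x):
        raise ValueError(f"{var.name}: non-finite input {x!r}")
    return var.fuzzify(x)


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzyRule:
    """Antecedent grade-sets per factor and a single consequent grade.

    ``AC`` (the full grade set) acts as a wildcard; in the rule file the
    ``/`` token separates alternative grades.
    """

    antecedent: tuple[tuple[str, frozenset[str]], ...]
    consequent: str

    def __post_init__(self) -> None:
        factors = tuple(f for f, _ in self.antecedent)
        if factors != INPUT_FACTORS:
            raise ConfigurationError(
                f"rule antecedent must cover {INPUT_FACTORS}, got {factors}"
            )
        for f, grades in self.antecedent:
            if not grades or not grades <= AC:
                raise ConfigurationError(f"rule: bad grade set {grades} for {f}")
        if self.consequent not in GRADES:
            raise ConfigurationError(f"rule: bad consequent {self.consequent!r}")

    @classmethod
    def build(cls, antecedent: dict[str, frozenset[str]], consequent: str) -> "FuzzyRule":
        return cls(tuple((f, frozenset(antecedent[f])) for f in INPUT_FACTORS), consequent)

    @property
    def antecedent_map(self) -> dict[str, frozenset[str]]:
        return dict(self.antecedent)

    def matches(self, combo: dict[str, str]) -> bool:
        return all(combo[f] in grades for f, grades in self.antecedent)

    def expand(self):
        """Yield every fully-ground grade combination this rule covers."""
        sets = [sorted(grades, key=GRADE_RANK.get) for _, grades in self.antecedent]
        for combo in itertools.product(*sets):
            yield combo


def _parse_token(tok: str) -> frozenset[str]:
    if tok == "AC":
        return AC
    grades = frozenset(tok.split("/"))
    if not grades <= AC:
        bad = sorted(grades - AC)
        raise ConfigurationError(f"unknown grade token(s) {bad} in {tok!r}")
    return grades


@dataclass(frozen=True)
class RuleBase:
    """An ordered list of fuzzy rules plus a provenance tag."""

    rules: tuple[FuzzyRule, ...]
    tag: str = "4-factor"

    def __post_init__(self) -> None:
        if not self.rules:
            raise ConfigurationError("empty rule base")
        self._check_conflicts()

    def _check_conflicts(self) -> None:
        seen: dict[tuple[str, ...], str] = {}
        for rule in self.rules:
            for combo in rule.expand():
                prev = seen.get(combo)
                if prev is not None and prev != rule.consequent:
                    raise ConfigurationError(
                        f"conflicting rules for combination {combo}: "
                        f"{prev} vs {rule.consequent}"
                    )
                seen[combo] = rule.consequent

    @classmethod
    def from_text(cls, text: str, tag: str = "4-factor") -> "RuleBase":
        """Parse a rule file: four antecedent tokens + consequent per line.

        Tokens come from {VL, L, M, H, VH, AC} with ``/`` for alternatives;
        ``#`` starts a comment.
        """
        rules = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != 5:
                raise ConfigurationError(
                    f"rule line {lineno}: expected 4 antecedent tokens + "
                    f"consequent, got {len(toks)}: {raw!r}"
                )
            antecedent = {f: _parse_token(t) for f, t in zip(INPUT_FACTORS, toks[:4])}
            if toks[4] not in GRADES:
                raise ConfigurationError(
                    f"rule line {lineno}: consequent must be a single grade, "
                    f"got {toks[4]!r}"
                )
            rules.append(FuzzyRule.build(antecedent, toks[4]))
        return cls(tuple(rules), tag=tag)

    def missing_combinations(self, factors=INPUT_FACTORS) -> list[dict[str, str]]:
        """Grade combinations over ``factors`` matched by no rule."""
        missing = []
        for grades in itertools.product(GRADES, repeat=len(factors)):
            combo = dict(zip(factors, grades))
            full = {f: combo.get(f, GRADES[0]) for f in INPUT_FACTORS}
            # factors absent from `combo` must be matched regardless of grade
            ok = any(
                all(
                    (f not in combo) and rule.antecedent_map[f] == AC
                    or (f in combo and combo[f] in rule.antecedent_map[f])
                    for f in INPUT_FACTORS
                )
                for rule in self.rules
            ) if len(factors) < len(INPUT_FACTORS) else any(
                rule.matches(full) for rule in self.rules
            )
            if not ok:
                missing.append(combo)
        return missing

    def is_complete(self, factors=INPUT_FACTORS) -> bool:
        return not self.missing_combinations(factors)


def rule_strength(rule: FuzzyRule, memberships: dict[str, dict[str, float]]) -> float:
    """Min over factors of the max membership across the rule's allowed grades.

    ``AC`` contributes the factor's maximal membership.
    """
    terms = []
    for f, grades in rule.antecedent:
        if f not in memberships:
            raise ValueError(f"factor {f!r} missing from memberships")
        mu = memberships[f]
        terms.append(max(mu[g] for g in grades))
    return float(min(terms))


# ---------------------------------------------------------------------------
# inference and defuzzification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DefuzzifySpec:
    """Discretization of the HSI universe for centroid defuzzification."""

    step: float = 1e-3
    fallback: float = 0.0

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ConfigurationError("defuzzification step must be > 0")
        if not 0.0 <= self.fallback <= 1.0:
            raise ConfigurationError("fallback HSI must lie in [0, 1]")

    def grid(self, universe: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
        lo, hi = universe
        n = int(round((hi - lo) / self.step)) + 1
        return np.linspace(lo, hi, n)


def _strength_matrix(rb: RuleBase, mm: dict[str, np.ndarray]) -> np.ndarray:
    """Rule strengths for vectorized inputs: shape (n_rules, N)."""
    out = np.empty((len(rb.rules), next(iter(mm.values())).shape[0]))
    for i, rule in enumerate(rb.rules):
        terms = [
            mm[f][:, [GRADE_RANK[g] for g in grades]].max(axis=1)
            for f, grades in rule.antecedent
        ]
        out[i] = np.minimum.reduce(terms)
    return out


def _output_matrix(hsi_var: FuzzyVariable, grid: np.ndarray) -> np.ndarray:
    """Consequent sets sampled on the HSI grid: shape (5, len(grid))."""
    return np.stack([hsi_var.sets[g](grid) for g in GRADES])


def infer(
    rb: RuleBase,
    variables: dict[str, FuzzyVariable],
    inputs: tuple[float, float, float, float],
    spec: DefuzzifySpec = DefuzzifySpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated output membership for one (d, T, U, h) input.

    Returns ``(grid, aggregate)`` sampled on the HSI universe.  Each rule
    clips its consequent set at the rule strength (min implication); the
    clipped sets are combined pointwise by max.
    """
    hsi_var = variables["hsi"]
    grid = spec.grid(hsi_var.universe)
    mm = {
        f: variables[f].memberships(variables[f].clamp([x]))
        for f, x in zip(INPUT_FACTORS, inputs)
    }
    strengths = _strength_matrix(rb, mm)[:, 0]
    outmat = _output_matrix(hsi_var, grid)
    agg = np.zeros_like(grid)
    for rule, s in zip(rb.rules, strengths):
        np.maximum(agg, np.minimum(s, outmat[GRADE_RANK[rule.consequent]]), out=agg)
    return grid, agg


def defuzzify_centroid(
    grid: np.ndarray, agg: np.ndarray, spec: DefuzzifySpec = DefuzzifySpec()
) -> np.ndarray | float:
    """Centroid (center of mass) of the aggregated membership.

    ``agg`` may be 1-D or batched (..., len(grid)); trapezoidal quadrature.
    Returns the spec fallback where the aggregate is identically zero.
    """
    num = np.trapezoid(agg * grid, grid, axis=-1)
    den = np.trapezoid(agg, grid, axis=-1)
    scalar = np.ndim(den) == 0
    num, den = np.atleast_1d(num), np.atleast_1d(den)
    out = np.full(den.shape, spec.fallback, dtype=float)
    ok = den > 0
    if not ok.all():
        log.warning("defuzzify: %d aggregate(s) identically zero; using fallback %g",
                    int((~ok).sum()), spec.fallback)
    out[ok] = num[ok] / den[ok]
    return float(out[0]) if scalar else out


def evaluate_hsi(
    rb: RuleBase,
    variables: dict[str, FuzzyVariable],
    inputs: tuple[float, float, float, float],
    spec: DefuzzifySpec = DefuzzifySpec(),
) -> float:
    """Crisp HSI for one (grain size d, temperature T, velocity U, depth h)."""
    grid, agg = infer(rb, variables, inputs, spec)
    return float(defuzzify_centroid(grid, agg, spec))


def evaluate_hsi_field(
    rb: RuleBase,
    variables: dict[str, FuzzyVariable],
    substrate: np.ndarray,
    temperature,
    velocity: np.ndarray,
    depth: np.ndarray,
    spec: DefuzzifySpec = DefuzzifySpec(),
    chunk: int = 4096,
) -> np.ndarray:
    """Vectorized :func:`evaluate_hsi` over per-cell fields.

    ``temperature`` may be a scalar (one value per period) or an array.
    """
    sub = np.asarray(substrate, dtype=float)
    vel = np.asarray(velocity, dtype=float)
    dep = np.asarray(depth, dtype=float)
    n = sub.shape[0]
    tem = np.broadcast_to(np.asarray(temperature, dtype=float), (n,))
    values = {"substrate": sub, "temperature": tem, "velocity": vel, "depth": dep}

    hsi_var = variables["hsi"]
    grid = spec.grid(hsi_var.universe)
    outmat = _output_matrix(hsi_var, grid)
    conseq_idx = np.array([GRADE_RANK[r.consequent] for r in rb.rules])

    out = np.empty(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        mm = {
            f: variables[f].memberships(variables[f].clamp(values[f][sl]))
            for f in INPUT_FACTORS
        }
        strengths = _strength_matrix(rb, mm)  # (R, m)
        agg = np.zeros((strengths.shape[1], grid.size))
        for i in range(len(rb.rules)):
            np.maximum(
                agg,
                np.minimum(strengths[i][:, None], outmat[conseq_idx[i]][None, :]),
                out=agg,
            )
        out[sl] = defuzzify_centroid(grid, agg, spec)
    return out
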