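"""A small Mamdani fuzzy-inference engine.

Piecewise-linear (trapezoidal/triangular) membership functions, min
activation for rule antecedents, max aggregation of clipped consequents and
centroid defuzzification on a discretized output universe.  This is the
classic fuzzify → infer → defuzzify pipeline used by rule-based process
controllers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["FuzzySet", "Rule", "MamdaniSystem", "FuzzyCoverageError"]


class FuzzyCoverageError(ValueError):
    """A crisp input falls outside the support of every input set."""


@dataclass(frozen=True)
class FuzzySet:
    """Trapezoidal membership function with knots a ≤ b ≤ c ≤ d.

    Membership rises linearly on [a, b], is 1 on [b, c] and falls on [c, d].
    Set b == c for a triangle; a == b (or c == d) makes a crisp shoulder.
    """

    name: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"set '{self.name}': knots must satisfy a ≤ b ≤ c ≤ d")

    def membership(self, x: float | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.b > self.a:
            rise = (x - self.a) / (self.b - self.a)
            out = np.where((x > self.a) & (x < self.b), rise, out)
        out = np.where((x >= self.b) & (x <= self.c), 1.0, out)
        if self.d > self.c:
            fall = (self.d - x) / (self.d - self.c)
            out = np.where((x > self.c) & (x < self.d), fall, out)
        return out


@dataclass(frozen=True)
class Rule:
    """IF all antecedents hold THEN the output term holds.

    ``antecedents`` maps input-variable name → set name; activation is the
    minimum of the antecedent memberships (AND semantics).
    """

    antecedents: Mapping[str, str]
    consequent: str


@dataclass
class MamdaniSystem:
    """Inputs, output terms and rules for one crisp output variable.

    Parameters
    ----------
    inputs
        variable name → sequence of FuzzySet over that variable's universe.
    output_sets
        FuzzySets over the output universe.
    rules
        The rule base (must be non-empty).
    output_range
        (lo, hi) of the output universe.
    resolution
        Number of sample points for centroid integration.
    """

    inputs: dict[str, Sequence[FuzzySet]]
    output_sets: Sequence[FuzzySet]
    rules: Sequence[Rule]
    output_range: tuple[float, float]
    resolution: int = 641
    _grid: np.ndarray = field(init=False, repr=False)
    _out_mu: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rule base must be non-empty")
        names = {s.name for s in self.output_sets}
        for r in self.rules:
            if r.consequent not in names:
                raise ValueError(f"rule consequent '{r.consequent}' is not an output set")
            for var, term in r.antecedents.items():
                if var not in self.inputs:
                    raise ValueError(f"rule references unknown input '{var}'")
                if term not in {s.name for s in self.inputs[var]}:
                    raise ValueError(f"input '{var}' has no set '{term}'")
        lo, hi = self.output_range
        self._grid = np.linspace(lo, hi, self.resolution)
        self._out_mu = {s.name: s.membership(self._grid) for s in self.output_sets}

    def fuzzify(self, crisp: Mapping[str, float]) -> dict[str, dict[str, float]]:
        """Membership degree of each crisp input in each of its sets."""
        degrees: dict[str, dict[str, float]] = {}
        for var, sets in self.inputs.items():
            if var not in crisp:
                continue
            d = {s.name: float(s.membership(crisp[var])) for s in sets}
            if max(d.values()) <= 0.0:
                raise FuzzyCoverageError(
                    f"input {var}={crisp[var]} not covered by any fuzzy set")
            degrees[var] = d
        return degrees

    def infer(self, crisp: Mapping[str, float]) -> np.ndarray:
        """Aggregated output membership over the discretized universe."""
        degrees = self.fuzzify(crisp)
        agg = np.zeros_like(self._grid)
        for rule in self.rules:
            acts = [degrees[var][term] for var, term in rule.antecedents.items()
                    if var in degrees]
            if not acts:
                continue
            alpha = min(acts)
            if alpha > 0:
                np.maximum(agg, np.minimum(alpha, self._out_mu[rule.consequent]),
                           out=agg)
        return agg

    def defuzzify(self, crisp: Mapping[str, float]) -> float:
        """Centroid of the aggregated output set.

        If no rule fires (all activations zero) the output defaults to the
        low end of the output range.
        """
        agg = self.infer(crisp)
        area = np.trapezoid(agg, self._grid)
        if area <= 0:
            return float(self.output_range[0])
        return float(np.trapezoid(agg * self._grid, self._grid) / area)
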