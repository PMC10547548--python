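"""Neighbour-modulated (Taylor–Frank) cross-check.

An inclusive-fitness model and its neighbour-modulated twin must agree:
the selection gradient obtained by differentiating a recipient-centred
fitness function,

    S(t) = Σ_classes  weight × [ ∂w/∂x + r ∂w/∂y ]  at x = y = z = t,

has the same sign as the inclusive-fitness effect at every resident trait
value, and the two approaches locate the same optimized trait value (ESS).
A disagreement means a mistake was made in building one of the two models —
which is exactly what this module is for detecting.

Here ``x`` is the focal individual's trait, ``y`` the local (social
partner / patch) average trait, ``z`` the population resident trait, and
``r`` the relatedness of the focal individual to the partners whose traits
enter through ``y``.  Derivatives are taken numerically (central
differences with one Richardson refinement), so the fitness function can be
any smooth black box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

__all__ = [
    "FitnessComponent",
    "FitnessModel",
    "NumericError",
    "BracketError",
    "marginal_fitness",
    "ess_solve",
    "CrossCheckReport",
    "cross_check",
]


class NumericError(ArithmeticError):
    """Non-finite fitness evaluation or underflowing step."""


class BracketError(ValueError):
    """The supplied bracket does not straddle a sign change."""


@dataclass(frozen=True)
class FitnessComponent:
    """One class's contribution to the selection gradient.

    ``fitness_fn(x, y, z)`` is the expected contribution of a focal
    individual with trait ``x`` whose social partners average ``y`` in a
    resident-``z`` population.  ``weight`` is the class reproductive-value
    weight (``c/u`` based, or 1 for homogeneous models); ``relatedness`` is
    the r applied to the partner derivative ``∂w/∂y``.
    """

    fitness_fn: Callable[[float, float, float], float]
    relatedness: float = 0.0
    weight: float = 1.0
    class_label: str = "X"


@dataclass(frozen=True)
class FitnessModel:
    """A neighbour-modulated fitness model: a sum of weighted components."""

    components: tuple[FitnessComponent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not self.components:
            raise ValueError("fitness model needs at least one component")

    @classmethod
    def single(
        cls,
        fitness_fn: Callable[[float, float, float], float],
        relatedness: float = 0.0,
        weight: float = 1.0,
    ) -> "FitnessModel":
        return cls((FitnessComponent(fitness_fn, relatedness, weight),))


def _central(f: Callable[[float], float], t: float, h: float) -> float:
    hi, lo = f(t + h), f(t - h)
    if not (math.isfinite(hi) and math.isfinite(lo)):
        raise NumericError(f"non-finite fitness evaluation near trait {t} (step {h})")
    return (hi - lo) / (2.0 * h)


def _derivative(f: Callable[[float], float], t: float, h: float) -> float:
    """Central difference with one Richardson extrapolation step (O(h^4))."""
    if h <= 0 or t + h == t:
        raise NumericError(f"step size {h} underflows at trait {t}")
    d_h = _central(f, t, h)
    d_h2 = _central(f, t, h / 2.0)
    return (4.0 * d_h2 - d_h) / 3.0


def marginal_fitness(fm: FitnessModel, trait: float, h: float = 1e-5) -> float:
    """Selection gradient of the neighbour-modulated model at a resident trait.

    Evaluates ``Σ weight × [∂w/∂x + r ∂w/∂y]`` at ``x = y = z = trait``.
    The sign is the direction of selection on a slight trait increase.
    """
    total = 0.0
    for comp in fm.components:
        w = comp.fitness_fn
        d_x = _derivative(lambda x: w(x, trait, trait), trait, h)
        d_y = _derivative(lambda y: w(trait, y, trait), trait, h)
        total += comp.weight * (d_x + comp.relatedness * d_y)
    return total


def ess_solve(
    gradient: Callable[[float], float],
    bracket: tuple[float, float],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Bisection root of a selection gradient: the candidate optimized trait.

    ``gradient(lo)`` and ``gradient(hi)`` must have opposite signs.  Boundary
    optima (gradient of constant sign) must be handled by the caller.
    """
    lo, hi = bracket
    g_lo, g_hi = gradient(lo), gradient(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if math.copysign(1.0, g_lo) == math.copysign(1.0, g_hi):
        raise BracketError(
            f"gradient has the same sign at both bracket ends ({g_lo:+g}, {g_hi:+g}); "
            "no interior ESS in this bracket"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g_mid = gradient(mid)
        if g_mid == 0.0 or (hi - lo) / 2.0 < tol:
            return mid
        if math.copysign(1.0, g_mid) == math.copysign(1.0, g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class CrossCheckReport:
    """Per-grid-point sign comparison plus ESS agreement between the two routes."""

    grid: tuple[float, ...]
    if_effects: tuple[float, ...]
    nm_gradients: tuple[float, ...]
    agreements: tuple[bool, ...]
    ess_if: Optional[float]
    ess_nm: Optional[float]
    ess_difference: Optional[float]
    passed: bool
    band: float

    def to_json_dict(self) -> dict:
        return {
            "passed": self.passed,
            "ess_if": self.ess_if,
            "ess_nm": self.ess_nm,
            "ess_difference": self.ess_difference,
            "band": self.band,
            "points": [
                {"trait": t, "if_effect": e, "nm_gradient": g, "agree": a}
                for t, e, g, a in zip(self.grid, self.if_effects, self.nm_gradients, self.agreements)
            ],
        }

    def __str__(self) -> str:
        lines = [
            f"cross-check: {'PASS' if self.passed else 'FAIL'}",
            f"  ESS (inclusive fitness):      {self.ess_if}",
            f"  ESS (neighbour-modulated):    {self.ess_nm}",
            f"  |ESS difference|:             {self.ess_difference}",
            "  trait        IF effect     NM gradient   agree",
        ]
        for t, e, g, a in zip(self.grid, self.if_effects, self.nm_gradients, self.agreements):
            lines.append(f"  {t:<12.6g} {e:<+13.6g} {g:<+13.6g} {'yes' if a else 'NO'}")
        return "\n".join(lines)


def _first_sign_change(grid: Sequence[float], values: Sequence[float], band: float):
    """Bracket of the first genuine crossing, ignoring within-band (noise) points."""
    last = None  # (trait, sign) of the last point outside the band
    for t, v in zip(grid, values):
        if abs(v) <= band:
            continue
        s = math.copysign(1.0, v)
        if last is not None and s != last[1]:
            return (last[0], t)
        last = (t, s)
    return None


def cross_check(
    if_family: Callable[[float], float],
    fm: FitnessModel,
    grid: Sequence[float],
    band: float = 1e-9,
    ess_tol: float = 1e-6,
) -> CrossCheckReport:
    """Compare an inclusive-fitness effect curve against its NM twin.

    ``if_family`` maps a resident trait value to the inclusive-fitness
    effect of a slight trait increase (use
    ``lambda t: family(t).effect().effect`` for an :class:`~inclufit.core.IFModel`
    family).  PASS requires the signs to agree at every grid point whose
    magnitudes exceed ``band`` on both routes, and — when either curve has an
    interior zero crossing on the grid — the two bisection ESS estimates to
    agree within ``ess_tol``.
    """
    grid = [float(t) for t in grid]
    if_vals = [float(if_family(t)) for t in grid]
    nm_vals = [float(marginal_fitness(fm, t)) for t in grid]
    agreements = []
    for e, g in zip(if_vals, nm_vals):
        if abs(e) <= band or abs(g) <= band:
            agreements.append(True)  # inside the equilibrium band: no sign to compare
        else:
            agreements.append(math.copysign(1.0, e) == math.copysign(1.0, g))
    signs_ok = all(agreements)

    br_if = _first_sign_change(grid, if_vals, band)
    br_nm = _first_sign_change(grid, nm_vals, band)
    ess_if = ess_nm = ess_diff = None
    if br_if is not None and br_nm is not None:
        ess_if = ess_solve(if_family, br_if)
        ess_nm = ess_solve(lambda t: marginal_fitness(fm, t), br_nm)
        ess_diff = abs(ess_if - ess_nm)
        passed = signs_ok and ess_diff < ess_tol
    elif br_if is None and br_nm is None:
        passed = signs_ok  # both curves one-signed: boundary optimum on this grid
    else:
        passed = False  # one route sees an interior ESS the other does not
    return CrossCheckReport(
        grid=tuple(grid),
        if_effects=tuple(if_vals),
        nm_gradients=tuple(nm_vals),
        agreements=tuple(agreements),
        ess_if=ess_if,
        ess_nm=ess_nm,
        ess_difference=ess_diff,
        passed=passed,
        band=band,
    )
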