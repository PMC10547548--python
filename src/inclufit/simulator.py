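"""Individual-based validation of the δ-weak-selection predictions.

The analytic machinery asserts that a slight behavioural deviation invades
exactly when its inclusive-fitness effect is positive.  This module checks
that claim empirically with a haploid Wright–Fisher island model: a finite
population of ``patches × n`` clonally reproducing breeders, social
interactions that perturb fecundity by a small amount ``delta_trait``,
offspring dispersal with probability ``m``, and local density regulation
(``n`` breeders re-sampled per patch in proportion to competitive ability,
which is parental fecundity).  A mutant expressing the deviant trait is
introduced once per replicate and followed to fixation or loss; the
fixation probability is compared against the neutral expectation
``1/(patches × n)`` with a Wilson score interval.

A separate routine demonstrates the geometric argument for why trait
deviations are small in the first place: in Fisher's geometric model, a
mutation of vanishing size has a 50% chance of moving the phenotype toward
the optimum, and larger mutations overshoot increasingly often.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .core import IFModel, inclusive_fitness_effect

__all__ = [
    "SocialParams",
    "SimSpec",
    "SimulationError",
    "FixationResult",
    "wright_fisher_island",
    "InvasionReport",
    "invasion_sign_test",
    "fisher_geometric",
    "fisher_geometric_closed_form",
]


class SimulationError(RuntimeError):
    """Nonviable simulation parameters (e.g. zero or negative fecundity)."""


@dataclass(frozen=True)
class SocialParams:
    """Helping payoffs: the actor pays ``C`` to confer ``B`` on its patch.

    With ``whole_group=True`` the benefit is a patch public good shared by
    all ``n`` patch members including the helper (each receives ``B``
    times the patch mean helping level); with ``False`` it goes to the
    ``n - 1`` others only.
    """

    B: float
    C: float
    whole_group: bool = True


@dataclass(frozen=True)
class SimSpec:
    """Wright–Fisher island run: demography, payoffs, effort and seed."""

    patches: int
    n: int
    m: float
    delta_trait: float
    social: SocialParams
    replicates: int
    seed: int
    max_generations: int = 500_000

    def __post_init__(self) -> None:
        if self.patches < 1 or self.n < 1 or self.replicates < 1:
            raise SimulationError("patches, n and replicates must be positive")
        if not 0.0 <= self.m <= 1.0:
            raise SimulationError("migration probability m must lie in [0, 1]")
        if abs(self.delta_trait) > 0.1:
            warnings.warn(
                "delta_trait exceeds 0.1: the first-order (δ-weak) prediction "
                "may not describe a deviation this large",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def population_size(self) -> int:
        return self.patches * self.n

    @property
    def neutral_fixation(self) -> float:
        return 1.0 / self.population_size


@dataclass(frozen=True)
class FixationResult:
    """Fixation-probability estimate with a 95% Wilson score interval."""

    estimate: float
    ci_lo: float
    ci_hi: float
    replicates: int
    n_fixed: int
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "replicates": self.replicates,
            "n_fixed": self.n_fixed,
            "seed": self.seed,
        }


def _wilson(successes: int, trials: int, confidence: float = 0.95) -> tuple[float, float]:
    from scipy.stats import binomtest

    ci = binomtest(successes, trials).proportion_ci(confidence_level=confidence, method="wilson")
    return float(ci.low), float(ci.high)


def _fecundities(K: np.ndarray, spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Mutant and resident fecundity per patch, given mutant counts ``K``."""
    n = spec.n
    d = spec.delta_trait
    B, C = spec.social.B, spec.social.C
    frac = K / n
    if spec.social.whole_group:
        f_mut = 1.0 + d * (-C + B * frac)
        f_res = 1.0 + d * (B * frac)
    else:
        if n == 1:
            f_mut = 1.0 + d * (-C) * np.ones_like(frac)
            f_res = np.ones_like(frac)
        else:
            f_mut = 1.0 + d * (-C + B * (K - 1) / (n - 1))
            f_res = 1.0 + d * (B * K / (n - 1))
    if np.any(f_mut <= 0) or np.any(f_res <= 0):
        raise SimulationError("social parameters drive fecundity to zero or below")
    return f_mut, f_res


def wright_fisher_island(spec: SimSpec) -> FixationResult:
    """Estimate the fixation probability of a single deviant mutant.

    Life cycle per generation: social interaction sets fecundity; offspring
    disperse with probability ``m`` (migrants land uniformly at random over
    all patches); each patch then samples ``n`` new breeders from the
    offspring competing there, in proportion to parental fecundity.  All
    replicates are advanced in lockstep on per-patch mutant counts (within
    a patch, individuals of the same type are exchangeable), so a run with
    the same seed is bit-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    P, n, m = spec.patches, spec.n, spec.m
    R = spec.replicates
    K = np.zeros((R, P), dtype=np.int64)
    start_patch = rng.integers(0, P, size=R)
    K[np.arange(R), start_patch] = 1

    active = np.ones(R, dtype=bool)
    fixed = np.zeros(R, dtype=bool)
    for _ in range(spec.max_generations):
        if not active.any():
            break
        Ka = K[active]
        f_mut, f_res = _fecundities(Ka, spec)
        mut_w = Ka * f_mut                      # mutant competitive weight per patch
        tot_w = mut_w + (n - Ka) * f_res        # all competitive weight per patch
        mut_in = (1.0 - m) * mut_w + m * mut_w.mean(axis=1, keepdims=True)
        tot_in = (1.0 - m) * tot_w + m * tot_w.mean(axis=1, keepdims=True)
        pi = np.clip(mut_in / tot_in, 0.0, 1.0)
        K_next = rng.binomial(n, pi)
        K[active] = K_next
        counts = K[active].sum(axis=1)
        done_now = (counts == 0) | (counts == n * P)
        idx = np.flatnonzero(active)
        fixed[idx[counts == n * P]] = True
        active[idx[done_now]] = False
    else:
        if active.any():
            raise SimulationError(
                f"{int(active.sum())} replicates unresolved after "
                f"{spec.max_generations} generations"
            )
    n_fixed = int(fixed.sum())
    lo, hi = _wilson(n_fixed, R)
    return FixationResult(
        estimate=n_fixed / R, ci_lo=lo, ci_hi=hi, replicates=R, n_fixed=n_fixed, seed=spec.seed
    )


@dataclass(frozen=True)
class InvasionReport:
    """Agreement between a fixation CI and the analytic effect's sign.

    ``status`` is "pass" when the CI excludes the neutral probability on
    the side the inclusive-fitness effect predicts, "inconclusive" when the
    CI straddles neutrality, and "fail" on a contradiction.
    """

    status: str
    effect: float
    fixation: FixationResult
    neutral: float

    def to_json_dict(self) -> dict:
        return {
            "status": self.status,
            "effect": self.effect,
            "neutral": self.neutral,
            "fixation": self.fixation.to_json_dict(),
        }


def invasion_sign_test(spec: SimSpec, if_model: IFModel, tol: float = 1e-9) -> InvasionReport:
    """Run the simulator and compare fixation against the analytic prediction.

    ``spec`` and ``if_model`` must be built from the same parameters (the
    gallery constructors do this).  An underpowered run whose CI straddles
    the neutral probability is reported as inconclusive, never as failure.
    """
    effect = inclusive_fitness_effect(if_model, tol=tol).effect
    fix = wright_fisher_island(spec)
    p0 = spec.neutral_fixation
    if fix.ci_lo <= p0 <= fix.ci_hi:
        status = "inconclusive" if abs(effect) > tol else "pass"
    elif fix.ci_lo > p0:
        status = "pass" if effect > tol else "fail"
    else:
        status = "pass" if effect < -tol else "fail"
    return InvasionReport(status=status, effect=effect, fixation=fix, neutral=p0)


def fisher_geometric(
    k: int,
    epsilon: float,
    d: float,
    replicates: int,
    seed: int,
    chunk: int = 100_000,
) -> float:
    """Probability that a random mutation of size ``epsilon`` is beneficial.

    A phenotype sits at distance ``d`` from the optimum in ``k``-dimensional
    trait space; mutations step a length ``epsilon`` in a uniformly random
    direction.  Returns the Monte-Carlo fraction of steps that reduce the
    distance to the optimum.  As ``epsilon/d → 0`` this tends to 1/2; a step
    is beneficial iff its component toward the optimum exceeds
    ``epsilon/(2d)``, so large mutations overshoot and the probability falls
    to 0 by ``epsilon = 2d``.
    """
    if k < 1:
        raise ValueError("k (trait-space dimension) must be >= 1")
    if epsilon <= 0 or d <= 0 or replicates < 1:
        raise ValueError("epsilon, d and replicates must be positive")
    threshold = epsilon / (2.0 * d)
    rng = np.random.default_rng(seed)
    hits = 0
    remaining = replicates
    while remaining > 0:
        size = min(chunk, remaining)
        g = rng.standard_normal((size, k))
        # component of the unit step direction along the axis toward the optimum
        u1 = g[:, 0] / np.linalg.norm(g, axis=1)
        hits += int(np.count_nonzero(u1 > threshold))
        remaining -= size
    return hits / replicates


def fisher_geometric_closed_form(k: int, epsilon: float, d: float) -> float:
    """Exact cap-area probability ``P(u_1 > epsilon/(2d))`` for a random unit vector.

    The first coordinate of a uniform point on the (k-1)-sphere satisfies
    ``(1 + u_1)/2 ~ Beta((k-1)/2, (k-1)/2)`` for ``k >= 2``; for ``k = 1``
    the direction is ±1 with equal probability.
    """
    x = epsilon / (2.0 * d)
    if x >= 1.0:
        return 0.0
    if k == 1:
        return 0.5  # the "+1" direction improves whenever epsilon < 2d
    from scipy.stats import beta

    return float(beta.sf((1.0 + x) / 2.0, (k - 1) / 2.0, (k - 1) / 2.0))
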