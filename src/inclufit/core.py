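"""Assembly of the inclusive-fitness effect.

The user declares only the *primary* deviations: the actor changes its own
normal share of reproductive value by a fractional amount ``δw_i/w`` and
changes the shares of named recipients by ``δw_j/w``.  Because the total
reproductive value of the population is fixed, every primary deviation
forces an equal-and-opposite *secondary* (compensatory) deviation on a pool
of competitors in the same class; the toolkit generates those terms
automatically.  Summing primary and secondary changes, each weighted by the
actor's consanguinity to the affected party, gives the net effect

    R_ii (c_X/u_X) δ_i + Σ_j R_ij (c/u)_j δ_j  -  R_ik (c_X/u_X) δ_i
        - Σ_j R_im_j (c/u)_j δ_j

which factors as ``(R_ii - R_ik)`` times the *inclusive-fitness effect*

    (c_X/u_X) δ_i + Σ_j r_j (c/u)_j δ_j,   r_j = (R_ij - R_im_j)/(R_ii - R_ik).

The effect's sign decides selection: positive → the deviation is favoured,
negative → disfavoured, zero → evolutionary equilibrium.  With global
compensation (``R_ik = R_im = 0``) the positivity condition is Hamilton's
rule.  Assembly is strictly first order in the deviations (δ-weak
selection): no products of deltas are ever formed, so the effect is exactly
linear in the declared deltas.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, NamedTuple, Optional, Sequence

from .demography import ClassStructure

__all__ = [
    "ACTOR_ROLE",
    "Deviation",
    "CompensationPool",
    "ConsanguinitySet",
    "IFModel",
    "TermRecord",
    "IFEffectResult",
    "SpecificationError",
    "UndefinedRelatednessError",
    "relatedness",
    "primary_effect",
    "secondary_effect",
    "inclusive_fitness_effect",
    "effect_curve",
    "conservation_table",
]

ACTOR_ROLE = "actor"

#: default half-width of the band within which an effect counts as equilibrium
DEFAULT_TOL = 1e-9


class SpecificationError(ValueError):
    """The declarative model is internally inconsistent (dangling labels etc.)."""


class UndefinedRelatednessError(ZeroDivisionError):
    """R_ii == R_ik: the actor is no more related to itself than to its own
    compensator pool, so relatedness has no defined value."""


def _check_prob(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0):
        raise SpecificationError(f"{name} must be a probability in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class CompensationPool:
    """The competitors who absorb one primary deviation.

    Compensation happens within the class of the deviation it balances, so
    ``class_label`` must match.  ``consanguinity_to_actor`` is the R between
    the actor and the average pool member (build it with
    :func:`inclufit.consanguinity.pool_consanguinity` when the pool mixes
    roles, e.g. a patch pool that includes the actor itself).
    """

    pool_label: str
    class_label: str
    consanguinity_to_actor: float
    membership_note: str = ""

    def __post_init__(self) -> None:
        _check_prob(self.consanguinity_to_actor, f"pool {self.pool_label!r} consanguinity")


@dataclass(frozen=True)
class Deviation:
    """One primary fractional change ``δw/w`` to a participant's competitive ability.

    ``delta`` is the multiplicative factor by which the participant's normal
    share changes (dimensionless).  ``episode`` distinguishes points in time
    when the same class is affected more than once (primed quantities); it is
    an ordinal label and carries no discounting of its own.
    ``class_weight_override`` substitutes for ``c/u`` of the class when a
    later episode uses different (primed) class weights.
    """

    participant_role: str
    class_label: str
    delta: float
    compensation_scope: str
    episode: str = "t0"
    class_weight_override: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta):
            raise SpecificationError(f"delta for {self.participant_role!r} must be finite")
        if self.class_weight_override is not None and self.class_weight_override < 0:
            raise SpecificationError("class weight override must be non-negative")


@dataclass(frozen=True)
class ConsanguinitySet:
    """Actor-centred consanguinity coefficients.

    ``R_ii`` is the actor self-coefficient; ``R_to`` maps each recipient role
    (``j``, ``ℓ``, ``j1`` ...) to the actor's consanguinity with it.  Pool
    coefficients live on the :class:`CompensationPool` objects.
    """

    R_ii: float
    R_to: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_prob(self.R_ii, "R_ii")
        for role, value in self.R_to.items():
            _check_prob(value, f"R_to[{role!r}]")

    def coefficient(self, role: str) -> float:
        if role == ACTOR_ROLE:
            return self.R_ii
        try:
            return self.R_to[role]
        except KeyError:
            raise SpecificationError(
                f"no consanguinity entry for participant {role!r}"
            ) from None


@dataclass(frozen=True)
class IFModel:
    """A full declarative inclusive-fitness model.

    One actor deviation (possibly with ``delta = 0`` — it still anchors the
    actor's compensator pool, which supplies ``R_ik``), any number of
    recipient deviations, the consanguinity coefficients, the class
    structure, and the compensation pools.
    """

    structure: ClassStructure
    actor_class: str
    deviations: tuple[Deviation, ...]
    consanguinity: ConsanguinitySet
    pools: Mapping[str, CompensationPool]

    def __post_init__(self) -> None:
        object.__setattr__(self, "deviations", tuple(self.deviations))
        actors = [d for d in self.deviations if d.participant_role == ACTOR_ROLE]
        if len(actors) != 1:
            raise SpecificationError(
                f"exactly one deviation must belong to the actor, found {len(actors)}"
            )
        if self.actor_class not in self.structure.classes:
            raise SpecificationError(f"actor class {self.actor_class!r} not in structure")
        if actors[0].class_label != self.actor_class:
            raise SpecificationError("the actor's deviation must be in the actor's class")
        for dev in self.deviations:
            if dev.class_label not in self.structure.classes:
                raise SpecificationError(
                    f"deviation for {dev.participant_role!r} references unknown class "
                    f"{dev.class_label!r}"
                )
            pool = self.pools.get(dev.compensation_scope)
            if pool is None:
                raise SpecificationError(
                    f"deviation for {dev.participant_role!r} references undefined "
                    f"compensation pool {dev.compensation_scope!r}"
                )
            if pool.class_label != dev.class_label:
                raise SpecificationError(
                    f"pool {pool.pool_label!r} is in class {pool.class_label!r} but "
                    f"compensates a deviation in class {dev.class_label!r} "
                    "(compensation happens within each class)"
                )
            # fail fast on missing coefficients
            self.consanguinity.coefficient(dev.participant_role)

    @property
    def actor_deviation(self) -> Deviation:
        return next(d for d in self.deviations if d.participant_role == ACTOR_ROLE)

    def scaled(self, alpha: float) -> "IFModel":
        """The same model with every delta multiplied by ``alpha``."""
        return replace(
            self,
            deviations=tuple(replace(d, delta=alpha * d.delta) for d in self.deviations),
        )

    def effect(self, tol: float = DEFAULT_TOL) -> "IFEffectResult":
        """Assemble the inclusive-fitness effect (see module docstring)."""
        return inclusive_fitness_effect(self, tol=tol)

    def _weight(self, dev: Deviation) -> float:
        if dev.class_weight_override is not None:
            return dev.class_weight_override
        return self.structure.weight(dev.class_label)


class TermRecord(NamedTuple):
    participant_role: str
    class_label: str
    episode: str
    delta: float
    relatedness: float
    class_weight: float
    contribution: float


@dataclass(frozen=True)
class IFEffectResult:
    """The inclusive-fitness effect with its per-term decomposition.

    ``effect`` is the bracketed sum; ``leading_factor`` is ``R_ii - R_ik``
    (positive in well-posed models).  ``verdict`` is "favoured" when the
    effect exceeds the equilibrium tolerance, "disfavoured" below its
    negative, and "equilibrium" inside the band.
    """

    effect: float
    leading_factor: float
    terms: tuple[TermRecord, ...]
    verdict: str
    tol: float = DEFAULT_TOL

    def to_frame(self):
        """Term table as a pandas DataFrame (one row per deviation)."""
        import pandas as pd

        return pd.DataFrame(self.terms, columns=TermRecord._fields)

    def to_tsv(self) -> str:
        """Flat TSV term table; the contribution column sums to the effect."""
        lines = ["\t".join(TermRecord._fields)]
        for t in self.terms:
            lines.append(
                f"{t.participant_role}\t{t.class_label}\t{t.episode}\t"
                f"{t.delta:.12g}\t{t.relatedness:.12g}\t{t.class_weight:.12g}\t"
                f"{t.contribution:.12g}"
            )
        return "\n".join(lines) + "\n"

    def to_json_dict(self) -> dict:
        return {
            "effect": self.effect,
            "leading_factor": self.leading_factor,
            "verdict": self.verdict,
            "tol": self.tol,
            "terms": [t._asdict() for t in self.terms],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)

    def summary(self) -> str:
        width = max(len(t.participant_role) for t in self.terms)
        lines = [
            "Inclusive-fitness effect",
            "=" * 48,
            f"effect          {self.effect:+.9g}",
            f"leading factor  {self.leading_factor:+.9g}  (R_ii - R_ik)",
            f"verdict         {self.verdict}",
            "-" * 48,
            f"{'role':<{width}}  class  episode  r        c/u      delta     contrib",
        ]
        for t in self.terms:
            lines.append(
                f"{t.participant_role:<{width}}  {t.class_label:<5}  {t.episode:<7}  "
                f"{t.relatedness:+.4f}  {t.class_weight:.4f}  {t.delta:+.5f}  "
                f"{t.contribution:+.6g}"
            )
        return "\n".join(lines)


def relatedness(R_ij: float, R_im: float, R_ii: float, R_ik: float) -> float:
    """Compensation-adjusted relatedness ``(R_ij - R_im) / (R_ii - R_ik)``.

    ``R_im`` is the actor's consanguinity to the recipient's compensator
    pool and ``R_ik`` to its own.  The value may be negative (which is what
    makes spite possible).  In a homogeneous population with a single
    compensator pool, ``R_im = R_ik``.
    """
    denom = R_ii - R_ik
    if denom == 0.0:
        raise UndefinedRelatednessError(
            "R_ii equals R_ik: the actor is no more related to itself than to "
            "its own compensator pool; relatedness is undefined"
        )
    return (R_ij - R_im) / denom


def primary_effect(model: IFModel) -> tuple[float, list[TermRecord]]:
    """Consanguinity-weighted sum of the declared primary deviations.

    Homogeneous case: ``R_ii δw_i/w + R_ij δw_j/w``; class-structured case
    weights each delta by its class's ``c/u``.
    """
    terms = []
    total = 0.0
    for dev in model.deviations:
        R = model.consanguinity.coefficient(dev.participant_role)
        weight = model._weight(dev)
        contribution = R * weight * dev.delta
        terms.append(
            TermRecord(dev.participant_role, dev.class_label, dev.episode, dev.delta, R, weight, contribution)
        )
        total += contribution
    return total, terms


def secondary_effect(model: IFModel) -> tuple[float, list[TermRecord]]:
    """Compensatory terms generated from the primary deviations.

    Each primary delta is balanced by an equal-and-opposite change spread
    over its compensation pool, weighted by the actor's consanguinity to the
    pool: ``-Σ R_pool (c/u) δ``.  The caller never writes these by hand.
    """
    terms = []
    total = 0.0
    for dev in model.deviations:
        pool = model.pools[dev.compensation_scope]
        R = pool.consanguinity_to_actor
        weight = model._weight(dev)
        contribution = -R * weight * dev.delta
        terms.append(
            TermRecord(pool.pool_label, pool.class_label, dev.episode, -dev.delta, R, weight, contribution)
        )
        total += contribution
    return total, terms


def conservation_table(model: IFModel) -> dict[tuple[str, str], float]:
    """Unweighted primary + compensatory reproductive-value change per (class, episode).

    Every entry is exactly 0: the compensation generated for each deviation
    is its exact negative, in the same class and episode.
    """
    table: dict[tuple[str, str], float] = {}
    _, primary_terms = primary_effect(model)
    _, secondary_terms = secondary_effect(model)
    # each secondary term is generated from the primary term at the same index,
    # so summing the pair first makes the cancellation exact, not just close
    for p, s in zip(primary_terms, secondary_terms):
        key = (p.class_label, p.episode)
        table[key] = table.get(key, 0.0) + (p.delta + s.delta)
    return table


def inclusive_fitness_effect(model: IFModel, tol: float = DEFAULT_TOL) -> IFEffectResult:
    """Assemble the inclusive-fitness effect of the actor's deviation.

    Returns the bracketed effect ``(c_X/u_X) δ_actor + Σ r_j (c/u)_j δ_j``
    with one relatedness per recipient, computed from that recipient's own
    compensator pool.  The actor's own term has relatedness exactly 1.  The
    net (unfactored) effect equals ``leading_factor × effect``.
    """
    R_ii = model.consanguinity.R_ii
    actor_pool = model.pools[model.actor_deviation.compensation_scope]
    R_ik = actor_pool.consanguinity_to_actor
    leading = R_ii - R_ik
    if leading < 0:
        warnings.warn(
            f"leading factor R_ii - R_ik = {leading} is negative; the sign convention "
            "of the bracketed effect is inverted relative to the net effect",
            RuntimeWarning,
            stacklevel=2,
        )
    terms = []
    total = 0.0
    for dev in model.deviations:
        if dev.participant_role == ACTOR_ROLE:
            r = relatedness(R_ii, R_ik, R_ii, R_ik)  # == 1 by construction
        else:
            R_ij = model.consanguinity.coefficient(dev.participant_role)
            R_im = model.pools[dev.compensation_scope].consanguinity_to_actor
            r = relatedness(R_ij, R_im, R_ii, R_ik)
        weight = model._weight(dev)
        contribution = r * weight * dev.delta
        terms.append(
            TermRecord(dev.participant_role, dev.class_label, dev.episode, dev.delta, r, weight, contribution)
        )
        total += contribution
    if total > tol:
        verdict = "favoured"
    elif total < -tol:
        verdict = "disfavoured"
    else:
        verdict = "equilibrium"
    return IFEffectResult(
        effect=total, leading_factor=leading, terms=tuple(terms), verdict=verdict, tol=tol
    )


def effect_curve(
    model_family: Callable[[float], IFModel],
    trait_grid: Sequence[float],
    tol: float = DEFAULT_TOL,
) -> list[tuple[float, float]]:
    """Evaluate the inclusive-fitness effect along a grid of trait values.

    ``model_family`` maps a trait value to a valid :class:`IFModel` (the
    model of a slight deviation *from* that resident trait).  The zero
    crossings of the curve locate candidate optimized trait values (ESS):
    trait values from which slight deviations are disfavoured.
    """
    curve = []
    for x in trait_grid:
        try:
            model = model_family(x)
            result = inclusive_fitness_effect(model, tol=tol)
        except Exception as exc:  # noqa: BLE001 - re-raise with the trait value named
            raise RuntimeError(f"model family failed at trait value {x!r}: {exc}") from exc
        curve.append((float(x), result.effect))
    return curve
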