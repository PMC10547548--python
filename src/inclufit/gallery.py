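"""Worked inclusive-fitness models, each with its neighbour-modulated twin.

Every constructor follows the same three building steps: (1) establish the
demography (class sizes, reproductive values, consanguinities) of the
deviation-free population; (2) declare the primary interaction — who gains
or loses competitive ability, and by how much; (3) identify when and at
what scale the compensating competition occurs, which fixes the
compensator pools and hence relatedness.  The result is a
:class:`GalleryModel` holding a trait-parameterized :class:`~inclufit.core.IFModel`
family and an equivalent :class:`~inclufit.oracle.FitnessModel`, both built
from the same parameter record, so the two routes can be cross-checked.

The trait convention throughout: ``if_family(t)`` is the model of a slight
*increase* of the trait in a resident-``t`` population, so the sign of its
effect is directly comparable with the neighbour-modulated selection
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from . import consanguinity as cons
from .core import (
    ACTOR_ROLE,
    CompensationPool,
    ConsanguinitySet,
    Deviation,
    IFModel,
    inclusive_fitness_effect,
)
from .demography import ClassStructure
from .oracle import CrossCheckReport, FitnessComponent, FitnessModel, cross_check

__all__ = [
    "GalleryModel",
    "help_with_synergy",
    "viscous_help",
    "ageclass_altruism",
    "sex_ratio_lmc",
    "GALLERY",
    "build",
]


@dataclass(frozen=True)
class GalleryModel:
    """A named worked model: IF family + NM twin + construction narrative."""

    name: str
    parameters: Mapping[str, float]
    if_family: Callable[[float], IFModel]
    fitness_model: FitnessModel
    narrative: str
    trait_bracket: tuple[float, float] = (0.01, 0.99)

    def effect_at(self, trait: float) -> float:
        """Inclusive-fitness effect of a slight trait increase at resident ``trait``."""
        return inclusive_fitness_effect(self.if_family(trait)).effect

    def default_grid(self, points: int = 9) -> np.ndarray:
        lo, hi = self.trait_bracket
        return np.linspace(lo, hi, points)

    def run_cross_check(self, grid: Optional[Sequence[float]] = None) -> CrossCheckReport:
        """Sign + ESS agreement between the IF assembly and the NM gradient."""
        if grid is None:
            grid = self.default_grid()
        return cross_check(self.effect_at, self.fitness_model, grid)


def _homogeneous_model(
    delta_actor: float,
    recipients: Sequence[tuple[str, float, float, float]],
    R_ii: float,
    R_ik: float,
) -> IFModel:
    """Single-class model: recipients are (role, delta, R_ij, R_im) tuples."""
    structure = ClassStructure.homogeneous()
    pools = {"k": CompensationPool("k", "X", R_ik, "actor's competitors")}
    deviations = [Deviation(ACTOR_ROLE, "X", delta_actor, "k")]
    R_to = {}
    for role, delta, R_ij, R_im in recipients:
        pool_label = f"m_{role}"
        pools[pool_label] = CompensationPool(pool_label, "X", R_im, f"{role}'s competitors")
        deviations.append(Deviation(role, "X", delta, pool_label))
        R_to[role] = R_ij
    return IFModel(
        structure=structure,
        actor_class="X",
        deviations=tuple(deviations),
        consanguinity=ConsanguinitySet(R_ii=R_ii, R_to=R_to),
        pools=pools,
    )


def help_with_synergy(
    B: float,
    C: float,
    D: float,
    R_ii: float = 0.5,
    R_ij: float = 0.25,
    R_ik: float = 0.0,
    R_im: Optional[float] = None,
) -> GalleryModel:
    """Pairwise helping with a synergistic payoff ``D``.

    The actor pays a fractional cost ``C`` and its partner gains ``B``; an
    extra payoff ``D`` accrues only when *both* interactants deviate.  Under
    δ-weak selection a double deviation is second order, so ``D`` never
    enters the assembled effect: the inclusive-fitness effect is
    ``-C + r B`` for any ``D``.  The NM twin keeps ``D`` in its fitness
    function — written in deviations from the resident, where it vanishes
    upon differentiation at the resident point — as an explicit check.
    """
    if R_im is None:
        R_im = R_ik
    r = (R_ij - R_im) / (R_ii - R_ik)

    def if_family(t: float) -> IFModel:
        return _homogeneous_model(-C, [("j", B, R_ij, R_im)], R_ii, R_ik)

    def fitness(x: float, y: float, z: float) -> float:
        return 1.0 - C * x + B * y + D * (x - z) * (y - z)

    fm = FitnessModel.single(fitness, relatedness=r)
    narrative = (
        "Demography: large well-mixed population; compensation for both the "
        f"cost and the benefit falls on pools with R = {R_ik} and {R_im}. "
        f"Primary interaction: actor pays {C} of its share, partner (R_ij = {R_ij}) "
        f"gains {B}; a synergistic bonus D = {D} requires two simultaneous deviants "
        "and is therefore invisible at first order. "
        f"Resulting effect: -C + rB with r = {r:.6g}, independent of D."
    )
    return GalleryModel(
        name="help_with_synergy",
        parameters={"B": B, "C": C, "D": D, "R_ii": R_ii, "R_ij": R_ij, "R_ik": R_ik, "R_im": R_im},
        if_family=if_family,
        fitness_model=fm,
        narrative=narrative,
    )


def viscous_help(
    B: float,
    C: float,
    n: int,
    m: float,
    elastic: bool,
    whole_group: bool = False,
) -> GalleryModel:
    """Helping among patch-mates under limited dispersal (island model).

    Haploid breeders, ``n`` per patch, offspring dispersing with probability
    ``m``; the patch-mate consanguinity ``F`` comes from the island IBD
    recursion.  The actor pays ``C``; the benefit ``B`` goes to a random
    patch-mate (``whole_group=False``) or is a patch public good shared by
    all ``n`` members including the actor (``whole_group=True``).

    Elasticity decides the compensation scale.  *Elastic*: the patch's
    output can expand, so extra offspring displace random members of the
    population at large (pool R = 0) and the effect is ``-C + rB``.
    *Inelastic*: patch output is capped, so extra offspring displace
    competitors on the patches where the offspring land; a fraction
    ``(1-m)^2`` of that displacement falls back on the natal patch
    (home-born offspring meeting home-born offspring), giving the pool
    ``R = (1-m)^2 [R_ii/n + (1-1/n)F]`` — which equals ``F`` itself, by the
    IBD recursion.  With the benefit going to patch-mates this makes
    relatedness vanish: kin competition exactly cancels kin benefit and the
    effect is ``-C`` for every ``m``, while a whole-group benefit leaves
    only the actor's own share: effect ``-C + B/n``.
    """
    R_ii = 1.0  # haploid
    F = cons.island_model_ibd(cons.IslandModelSpec(n=n, m=m))
    R_patch = cons.pool_consanguinity(
        [("self", R_ii, 1.0 / n), ("patch-mate", F, (n - 1.0) / n)]
    )
    R_j = R_patch if whole_group else F
    if elastic:
        R_comp = 0.0
    else:
        # Displaced competitors are local with probability (1-m)^2, drawn from
        # the patch average (actor included), else from the population at
        # large: R = (1-m)^2 [R_ii/n + (1-1/n)F].  At equilibrium that
        # expression IS the island recursion, so the pool coefficient equals F
        # itself; using the identity keeps the kin-benefit/kin-competition
        # cancellation exact instead of leaving an O(iteration-residual)
        # relatedness, which the m -> 0 corner (1 - F -> 0) would amplify.
        R_comp = F
    r = (R_j - R_comp) / (R_ii - R_comp)

    def if_family(t: float) -> IFModel:
        return _homogeneous_model(-C, [("j", B, R_j, R_comp)], R_ii, R_comp)

    # NM twin: y is the patch mean trait (focal included), relatedness R_patch.
    if whole_group:
        def fecundity(x: float, y: float) -> float:
            return 1.0 - C * x + B * y
    else:
        def fecundity(x: float, y: float) -> float:
            others = (n * y - x) / (n - 1) if n > 1 else 0.0
            return 1.0 - C * x + B * others

    if elastic:
        def fitness(x: float, y: float, z: float) -> float:
            return fecundity(x, y) / fecundity(z, z)
    else:
        def fitness(x: float, y: float, z: float) -> float:
            fbar_patch = fecundity(y, y)
            fbar_pop = fecundity(z, z)
            stay = (1.0 - m) / ((1.0 - m) * fbar_patch + m * fbar_pop)
            leave = m / fbar_pop
            return fecundity(x, y) * (stay + leave)

    fm = FitnessModel.single(fitness, relatedness=R_patch / R_ii)
    narrative = (
        f"Demography: infinite island model, {n} haploid breeders per patch, "
        f"migration {m}; equilibrium patch-mate IBD F = {F:.6g}. "
        f"Primary interaction: actor pays {C}; benefit {B} to "
        + ("the whole patch (public good, actor included)" if whole_group else "a random patch-mate")
        + f" with R_j = {R_j:.6g}. Compensation: "
        + ("global (elastic patch output), pool R = 0."
           if elastic
           else f"local after partial dispersal (inelastic), pool R = {R_comp:.6g} = F.")
        + f" Effective relatedness r = {r:.6g}."
    )
    return GalleryModel(
        name="viscous_help",
        parameters={"B": B, "C": C, "n": n, "m": m, "elastic": float(elastic),
                    "whole_group": float(whole_group), "F": F},
        if_family=if_family,
        fitness_model=fm,
        narrative=narrative,
    )


def ageclass_altruism(
    s: float,
    f1: float,
    f2: float,
    B: float,
    C: float,
    donor_class: str = "young",
    beneficiary_class: str = "old",
    R_ij: float = 0.25,
    R_ii: float = 0.5,
    structure: Optional[ClassStructure] = None,
) -> GalleryModel:
    """Altruism between age classes in a two-age Leslie demography.

    Ages ``young``/``old`` with fecundities ``f1``, ``f2`` and survival
    ``s``; class sizes ``u`` and reproductive values ``c`` come from the
    dominant eigenpair of the Leslie matrix (or from an explicit
    ``structure``, the "open-model" route — needed e.g. for a
    post-reproductive beneficiary class whose ``c`` is 0, which makes the
    matrix non-primitive).  The donor pays ``C`` of its within-class share,
    the beneficiary gains ``B``; each deviation is compensated globally
    within its own age class (pool R = 0), so the effect is
    ``(c_X/u_X)(-C) + (R_ij/R_ii)(c_Y/u_Y) B``.
    """
    if structure is None:
        from .demography import ProjectionMatrix, structure_from_matrix

        A = ProjectionMatrix(labels=("young", "old"), entries=np.array([[f1, f2], [s, 0.0]]))
        structure = structure_from_matrix(A)
    if donor_class not in structure.classes or beneficiary_class not in structure.classes:
        raise ValueError("donor and beneficiary classes must exist in the structure")

    pools = {
        "k": CompensationPool("k", donor_class, 0.0, f"population-wide {donor_class}"),
        "m": CompensationPool("m", beneficiary_class, 0.0, f"population-wide {beneficiary_class}"),
    }

    def if_family(t: float) -> IFModel:
        return IFModel(
            structure=structure,
            actor_class=donor_class,
            deviations=(
                Deviation(ACTOR_ROLE, donor_class, -C, "k"),
                Deviation("j", beneficiary_class, B, "m"),
            ),
            consanguinity=ConsanguinitySet(R_ii=R_ii, R_to={"j": R_ij}),
            pools=pools,
        )

    w_x = structure.weight(donor_class)
    w_y = structure.weight(beneficiary_class)
    fm = FitnessModel(
        (
            FitnessComponent(lambda x, y, z: 1.0 - C * x, relatedness=0.0, weight=w_x,
                             class_label=donor_class),
            FitnessComponent(lambda x, y, z: 1.0 + B * y, relatedness=R_ij / R_ii, weight=w_y,
                             class_label=beneficiary_class),
        )
    )
    narrative = (
        f"Demography: two age classes; Leslie matrix [[{f1}, {f2}], [{s}, 0]] gives "
        f"per-capita class weights c/u = {w_x:.6g} ({donor_class}) and {w_y:.6g} "
        f"({beneficiary_class}). Primary interaction: a {donor_class} donor pays {C} "
        f"of its within-class share so a {beneficiary_class} relative (R_ij = {R_ij}) "
        f"gains {B}. Compensation: within each age class, at the global scale (pool R = 0)."
    )
    return GalleryModel(
        name="ageclass_altruism",
        parameters={"s": s, "f1": f1, "f2": f2, "B": B, "C": C, "R_ij": R_ij, "R_ii": R_ii},
        if_family=if_family,
        fitness_model=fm,
        narrative=narrative,
    )


def sex_ratio_lmc(n_foundresses: int) -> GalleryModel:
    """Sex-ratio evolution under local mate competition (diploid mothers).

    ``n`` once-mated foundresses settle per patch; sons stay and compete for
    matings with the patch's daughters; mated daughters disperse.  The trait
    is the proportion of sons ``x``.  A deviant mother converts a daughter
    into a son (trait increase), which plays out as three deviations:

    * a new son appears (R mother-son = 1/4), displacing competitors in the
      local mating pool — the patch's sons, of whom a fraction ``1/n`` are
      her own (pool R = 1/(4n));
    * a daughter is erased (R = 1/4), compensated globally (pool R = 0)
      since mated daughters disperse and compete population-wide;
    * at mating time the lost daughter's matings are withdrawn from the
      patch's sons (recipient R = 1/(4n), a later episode in the same son
      class), that loss being made up globally (pool R = 0); its size in
      son-share units is ``x/(1-x)``, one daughter's paternity re-expressed
      per son share.

    Sons and daughters each hold half the total reproductive value
    (autosomal inheritance), with per-capita weights ``(1/2)/x`` and
    ``(1/2)/(1-x)``.  The effect curve crosses zero at the classic ESS
    ``x* = (n-1)/(2n)``; for a single foundress the gradient is negative
    throughout (boundary ESS at all-daughters, modulo needing some sons).
    """
    n = int(n_foundresses)
    if n < 1:
        raise ValueError("n_foundresses must be >= 1")
    p = cons.PloidySpec(ploidy="diploid", f=0.0)
    R_ii = cons.self_consanguinity(p)                       # 1/2
    R_off = cons.pedigree_consanguinity("parent-offspring", p)  # 1/4
    R_patch_son = cons.pool_consanguinity(
        [("own son", R_off, 1.0 / n), ("co-foundress son", 0.0, (n - 1.0) / n)]
    )

    def if_family(t: float) -> IFModel:
        if not 0.0 < t < 1.0:
            raise ValueError("resident sex ratio must lie strictly between 0 and 1")
        structure = ClassStructure(
            classes=("mothers", "sons", "daughters"),
            u={"mothers": 1.0, "sons": t, "daughters": 1.0 - t},
            c={"mothers": 0.0, "sons": 0.5, "daughters": 0.5},
        )
        pools = {
            "k": CompensationPool("k", "mothers", 0.0, "other mothers (global)"),
            "patch_sons": CompensationPool(
                "patch_sons", "sons", R_patch_son, "sons bred on the patch"
            ),
            "global_daughters": CompensationPool(
                "global_daughters", "daughters", 0.0, "daughters population-wide"
            ),
            "global_sons": CompensationPool("global_sons", "sons", 0.0, "sons population-wide"),
        }
        return IFModel(
            structure=structure,
            actor_class="mothers",
            deviations=(
                Deviation(ACTOR_ROLE, "mothers", 0.0, "k"),
                Deviation("new_son", "sons", +1.0, "patch_sons", episode="t0"),
                Deviation("lost_daughter", "daughters", -1.0, "global_daughters", episode="t0"),
                Deviation(
                    "patch_sons_matings", "sons", -t / (1.0 - t), "global_sons", episode="t1"
                ),
            ),
            consanguinity=ConsanguinitySet(
                R_ii=R_ii,
                R_to={
                    "new_son": R_off,
                    "lost_daughter": R_off,
                    "patch_sons_matings": R_patch_son,
                },
            ),
            pools=pools,
        )

    # NM twin: a mother's grandoffspring through daughters and through sons'
    # matings; y is the patch mean sex ratio (focal foundress included).
    def fitness(x: float, y: float, z: float) -> float:
        via_daughters = (1.0 - x) / (1.0 - z)
        via_sons = (x * (1.0 - y) / y) / (1.0 - z)
        return 0.5 * via_daughters + 0.5 * via_sons

    fm = FitnessModel.single(fitness, relatedness=1.0 / n)
    narrative = (
        f"Demography: {n} once-mated foundresses per patch; sons mate locally, "
        "mated daughters disperse; sons and daughters each carry half the total "
        "reproductive value. Primary interaction: a mother converts a daughter "
        "into a son. Compensation: the new son displaces patch sons "
        f"(pool R = {R_patch_son:.6g}); the daughter and the withdrawn matings are "
        "compensated at the global scale."
    )
    return GalleryModel(
        name="sex_ratio_lmc",
        parameters={"n_foundresses": float(n)},
        if_family=if_family,
        fitness_model=fm,
        narrative=narrative,
        trait_bracket=(0.02, 0.98),
    )


GALLERY: dict[str, Callable[..., GalleryModel]] = {
    "help_with_synergy": help_with_synergy,
    "viscous_help": viscous_help,
    "ageclass_altruism": ageclass_altruism,
    "sex_ratio_lmc": sex_ratio_lmc,
}


def build(name: str, **params) -> GalleryModel:
    """Build a gallery model by name."""
    try:
        ctor = GALLERY[name]
    except KeyError:
        raise KeyError(f"unknown gallery model {name!r}; available: {sorted(GALLERY)}") from None
    return ctor(**params)
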