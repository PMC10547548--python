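"""Coefficients of consanguinity (identity by descent).

The consanguinity ``R_ij`` between individuals *i* and *j* is the probability
that an allele drawn at random from *i* is identical by descent (IBD) to one
drawn at random from *j* — i.e. both descend from a common ancestral copy
without mutation.  The self-coefficient ``R_ii`` draws twice *with
replacement* from the same individual, so ``R_ii = 1`` for haploids and
``(1 + f)/2`` for diploids with inbreeding coefficient ``f``.

Three sources of coefficients are provided:

* pedigree coefficients, computed by recursing over gene-transmission paths
  in small explicit pedigrees (diploid and haplodiploid);
* equilibrium IBD between patch-mates under the infinite-island model,
  obtained as the fixed point of the standard recursion
  ``F' = (1 - m)^2 [1/n + (1 - 1/n) F]``;
* weighted pool averages, for "average member of some group" recipients and
  compensator pools (the group may or may not include the focal individual —
  that choice is the caller's, encoded in the weights).

All coefficients here are "normal" values: they assume no deviant behaviour
has taken place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "PloidySpec",
    "IslandModelSpec",
    "ConsanguinityError",
    "self_consanguinity",
    "pedigree_consanguinity",
    "island_model_ibd",
    "island_model_ibd_closed_form",
    "pool_consanguinity",
    "SUPPORTED_RELATIONSHIPS",
]


class ConsanguinityError(ValueError):
    """Invalid ploidy/relationship specification or non-convergent recursion."""


@dataclass(frozen=True)
class PloidySpec:
    """Ploidy with inbreeding coefficient ``f`` (and sex, for haplodiploids).

    ``sex`` is only consulted when ``ploidy == "haplodiploid"``: females are
    diploid, males haploid.
    """

    ploidy: str = "diploid"
    f: float = 0.0
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ploidy not in ("haploid", "diploid", "haplodiploid"):
            raise ConsanguinityError(f"unknown ploidy {self.ploidy!r}")
        if not 0.0 <= self.f <= 1.0:
            raise ConsanguinityError("inbreeding coefficient f must lie in [0, 1]")
        if self.ploidy == "haplodiploid" and self.sex not in ("female", "male"):
            raise ConsanguinityError("haplodiploid ploidy requires sex='female' or 'male'")


@dataclass(frozen=True)
class IslandModelSpec:
    """Infinite-island demography: ``n`` breeders per patch, migration ``m``."""

    n: int
    m: float
    ploidy: PloidySpec = field(default_factory=lambda: PloidySpec(ploidy="haploid"))
    generations: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConsanguinityError("n (breeders per patch) must be >= 1")
        if not 0.0 <= self.m <= 1.0:
            raise ConsanguinityError("migration probability m must lie in [0, 1]")


def self_consanguinity(p: PloidySpec) -> float:
    """Self-coefficient ``R_ii``: 1 for haploids, ``(1 + f)/2`` for diploids."""
    if p.ploidy == "haploid":
        return 1.0
    if p.ploidy == "diploid":
        return (1.0 + p.f) / 2.0
    # haplodiploid: males carry one allele, females two
    return 1.0 if p.sex == "male" else (1.0 + p.f) / 2.0


# --- pedigree coefficients -------------------------------------------------
#
# A pedigree node is (name, ploidy_tag, parents, depth); founders have no
# parents.  Kinship phi(a, b) is computed by recursing on the deeper
# individual: a random allele from a diploid is the maternal or paternal
# allele with probability 1/2 each, while a haploid (haplodiploid male)
# transmits a random maternal allele.  Founders are drawn from a base
# population in which the cross-kinship between mates equals the requested
# inbreeding coefficient f (so that offspring of founder pairs have
# inbreeding f) and founder self-kinship is (1 + f)/2 (diploid) or 1
# (haploid).


@dataclass(frozen=True)
class _Node:
    name: str
    haploid: bool
    parents: tuple = ()
    depth: int = 0


def _kinship(a: _Node, b: _Node, base_f: float, memo: dict) -> float:
    key = (a.name, b.name) if a.name <= b.name else (b.name, a.name)
    if key in memo:
        return memo[key]
    if a.name == b.name:
        if a.haploid:
            val = 1.0
        elif not a.parents:
            val = (1.0 + base_f) / 2.0
        else:
            mother, father = a.parents
            val = 0.5 + 0.5 * _kinship(mother, father, base_f, memo)
    else:
        # recurse on the deeper (younger) individual
        if b.depth > a.depth:
            a, b = b, a
        if not a.parents:
            val = base_f  # two distinct founders
        elif a.haploid:
            (mother,) = a.parents
            val = _kinship(mother, b, base_f, memo)
        else:
            mother, father = a.parents
            val = 0.5 * _kinship(mother, b, base_f, memo) + 0.5 * _kinship(father, b, base_f, memo)
    memo[key] = val
    return val


def _build_pedigree(relationship: str, p: PloidySpec) -> tuple[_Node, _Node]:
    """Return the two individuals whose consanguinity is requested."""
    hd = p.ploidy == "haplodiploid"
    haploid_all = p.ploidy == "haploid"

    def founder(name: str, haploid: bool = False) -> _Node:
        return _Node(name, haploid=haploid or haploid_all)

    if relationship == "self":
        ego = founder("ego", haploid=hd and p.sex == "male")
        return ego, ego
    if relationship == "parent-offspring":
        if haploid_all:
            parent = founder("P")
            child = _Node("C", haploid=True, parents=(parent,), depth=1)
            return parent, child
        mother = founder("M")
        father = founder("F", haploid=hd)
        if hd:
            # mother-daughter by default; a haplodiploid son has only a mother
            child = _Node("C", haploid=False, parents=(mother, father), depth=1)
        else:
            child = _Node("C", haploid=False, parents=(mother, father), depth=1)
        return mother, child
    if relationship in ("full-sib", "sister-sister (haplodiploid)"):
        if relationship.startswith("sister") and not hd:
            raise ConsanguinityError(f"{relationship!r} requires haplodiploid ploidy")
        if haploid_all:
            parent = founder("P")
            a = _Node("A", haploid=True, parents=(parent,), depth=1)
            b = _Node("B", haploid=True, parents=(parent,), depth=1)
            return a, b
        mother = founder("M")
        father = founder("F", haploid=hd)
        a = _Node("A", haploid=False, parents=(mother, father), depth=1)
        b = _Node("B", haploid=False, parents=(mother, father), depth=1)
        return a, b
    if relationship == "half-sib":
        if haploid_all:
            raise ConsanguinityError("half-sib is not defined for uniparental haploids")
        mother = founder("M")
        f1 = founder("F1", haploid=hd)
        f2 = founder("F2", haploid=hd)
        a = _Node("A", haploid=False, parents=(mother, f1), depth=1)
        b = _Node("B", haploid=False, parents=(mother, f2), depth=1)
        return a, b
    if relationship == "brother-sister (haplodiploid)":
        if not hd:
            raise ConsanguinityError(f"{relationship!r} requires haplodiploid ploidy")
        mother = founder("M")
        father = founder("F", haploid=True)
        brother = _Node("S", haploid=True, parents=(mother,), depth=1)
        sister = _Node("A", haploid=False, parents=(mother, father), depth=1)
        return brother, sister
    raise ConsanguinityError(f"unsupported relationship {relationship!r}")


SUPPORTED_RELATIONSHIPS = (
    "self",
    "parent-offspring",
    "full-sib",
    "half-sib",
    "sister-sister (haplodiploid)",
    "brother-sister (haplodiploid)",
)


def pedigree_consanguinity(relationship: str, p: PloidySpec) -> float:
    """Consanguinity between two pedigree relatives.

    Computed by recursion over gene-transmission paths in an explicit
    pedigree, with the base population's cross-kinship set to ``p.f``.
    Examples at ``f = 0``: diploid parent-offspring and full sibs 1/4,
    half sibs 1/8, haplodiploid full sisters 3/8, brother-sister 1/4.
    """
    a, b = _build_pedigree(relationship, p)
    return _kinship(a, b, base_f=p.f, memo={})


# --- island model ----------------------------------------------------------


def island_model_ibd(spec: IslandModelSpec, tol: float = 1e-12) -> float:
    """Equilibrium IBD probability between two distinct random patch-mates.

    Fixed point of ``F' = (1 - m)^2 [1/n + (1 - 1/n) F]`` (haploid-gamete
    bookkeeping), iterated from ``F = 0``.  The value lies in ``[0, 1]``;
    it equals 1 only in the closed single-lineage corner ``n = 1, m = 0``.
    """
    F = 0.0
    a = (1.0 - spec.m) ** 2
    n = spec.n
    for _ in range(spec.generations):
        F_new = a * (1.0 / n + (1.0 - 1.0 / n) * F)
        if abs(F_new - F) < tol:
            return F_new
        F = F_new
    raise ConsanguinityError(
        f"island IBD recursion did not converge within {spec.generations} generations; "
        f"last iterate F = {F}"
    )


def island_model_ibd_closed_form(n: int, m: float) -> float:
    """Closed form ``F = (1-m)^2 / (n - (n-1)(1-m)^2)`` of the island recursion."""
    a = (1.0 - m) ** 2
    return a / (n - (n - 1) * a)


def pool_consanguinity(members: Iterable[tuple[str, float, float]]) -> float:
    """Consanguinity to the *average member* of a group.

    ``members`` is an iterable of ``(role, R, weight)``; returns the
    weight-averaged coefficient.  Use this to build recipients or
    compensator pools such as "a random patch member including the focal
    individual": ``[("self", R_ii, 1/n), ("patch-mate", F, (n-1)/n)]``.
    """
    members = list(members)
    if not members:
        raise ConsanguinityError("pool must have at least one member")
    total_w = 0.0
    acc = 0.0
    for role, R, weight in members:
        if weight < 0:
            raise ConsanguinityError(f"negative weight for pool member {role!r}")
        if not 0.0 <= R <= 1.0:
            raise ConsanguinityError(f"coefficient for pool member {role!r} outside [0, 1]")
        total_w += weight
        acc += weight * R
    if total_w <= 0:
        raise ConsanguinityError("pool weights must sum to a positive value")
    return acc / total_w
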