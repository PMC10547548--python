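"""Class structure and reproductive-value accounting.

A class-structured population divides a fixed total of reproductive value
among classes (age, sex, size ...).  Each class ``X`` holds a fraction
``c_X`` of the total and contains ``u_X`` individuals, so ``c_X / u_X`` is
the normal (fair) per-capita share within the class.  Within a class,
individuals receive shares proportional to their competitive ability
relative to the class mean — an individual whose ability exceeds the class
average takes a larger slice, and its within-class competitors necessarily
take smaller ones, because the total is fixed.

For a population whose normal demography is given by a projection matrix
``A`` (entry ``A[d, s]`` = expected per-capita contribution of a class-``s``
individual to class ``d`` over one time step), the stable class proportions
``u`` are the dominant right eigenvector of ``A`` and the per-capita
reproductive values ``v`` are the dominant left eigenvector; the class
totals are ``c_X ∝ u_X v_X``.  ``c_X`` is then the probability that the
ancestor of a random gene in the distant future is in class ``X`` today.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ClassStructure",
    "ProjectionMatrix",
    "DemographyError",
    "stable_class_distribution",
    "class_reproductive_values",
    "structure_from_matrix",
    "allocate_shares",
]


class DemographyError(ValueError):
    """Invalid demographic input (non-square / non-primitive matrix, empty class...)."""


@dataclass(frozen=True)
class ClassStructure:
    """Classes with per-class counts ``u`` and reproductive-value fractions ``c``.

    Parameters
    ----------
    classes : sequence of str
        Ordered class labels.
    u : mapping label -> positive count
        Number (or relative number) of individuals in each class.
    c : mapping label -> fraction, summing to 1
        Fraction of total reproductive value earmarked for each class.
    """

    classes: tuple[str, ...]
    u: Mapping[str, float]
    c: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.classes:
            raise DemographyError("at least one class is required")
        object.__setattr__(self, "classes", tuple(self.classes))
        for label in self.classes:
            if label not in self.u or label not in self.c:
                raise DemographyError(f"class {label!r} missing u or c entry")
            if not np.isfinite(self.u[label]) or self.u[label] <= 0:
                raise DemographyError(f"u[{label!r}] must be positive")
            if not np.isfinite(self.c[label]) or self.c[label] < 0:
                raise DemographyError(f"c[{label!r}] must be non-negative")
        total_c = sum(self.c[label] for label in self.classes)
        if abs(total_c - 1.0) > 1e-9:
            raise DemographyError(f"class reproductive values must sum to 1, got {total_c}")

    @classmethod
    def homogeneous(cls, label: str = "X") -> "ClassStructure":
        """Single-class structure with c = u = 1 (the homogeneous population)."""
        return cls(classes=(label,), u={label: 1.0}, c={label: 1.0})

    def weight(self, label: str) -> float:
        """Per-capita share c_X / u_X — the normal slice for one member of ``label``."""
        if label not in self.c:
            raise DemographyError(f"unknown class label {label!r}")
        return self.c[label] / self.u[label]

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "u": {k: float(self.u[k]) for k in self.classes},
            "c": {k: float(self.c[k]) for k in self.classes},
        }


@dataclass(frozen=True)
class ProjectionMatrix:
    """Square non-negative projection matrix with class labels.

    ``entries[d, s]`` is the expected per-capita contribution of a class-``s``
    individual to class ``d`` over one time step.
    """

    labels: tuple[str, ...]
    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", A)
        object.__setattr__(self, "labels", tuple(self.labels))
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise DemographyError("projection matrix must be square")
        if len(self.labels) != A.shape[0]:
            raise DemographyError("label count must match matrix dimension")
        if not np.all(np.isfinite(A)) or np.any(A < 0):
            raise DemographyError("projection matrix entries must be finite and non-negative")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def is_primitive(self) -> bool:
        """Primitivity check: some power of the boolean pattern is all-positive.

        Wielandt's bound: a primitive n x n matrix satisfies A^(n^2 - 2n + 2) > 0.
        """
        n = self.n
        B = (self.entries > 0).astype(float)
        power = np.linalg.matrix_power(B, max(n * n - 2 * n + 2, 1))
        return bool(np.all(power > 0))

    @classmethod
    def from_csv(cls, path) -> "ProjectionMatrix":
        """Read a labelled matrix from CSV (header row = class labels)."""
        import pandas as pd

        frame = pd.read_csv(path, index_col=0)
        return cls(labels=tuple(str(c) for c in frame.columns), entries=frame.to_numpy(float))


def _dominant_right(A: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000):
    """Dominant eigenpair by deterministic power iteration from the uniform vector."""
    n = A.shape[0]
    x = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        y = A @ x
        lam_new = y.sum()
        if lam_new <= 0:
            raise DemographyError("projection matrix drives the population extinct in one step")
        y /= lam_new
        if np.max(np.abs(y - x)) < tol and abs(lam_new - lam) < tol * max(lam_new, 1.0):
            return y, lam_new
        x, lam = y, lam_new
    raise DemographyError("power iteration failed to converge")


def stable_class_distribution(A: ProjectionMatrix, tol: float = 1e-12) -> np.ndarray:
    """Stable class proportions: dominant right eigenvector of ``A``, summing to 1.

    These are the asymptotic relative class sizes ``u_X`` of the normal
    (deviation-free) demography.
    """
    if not A.is_primitive():
        raise DemographyError("projection matrix must be primitive")
    u, _ = _dominant_right(A.entries, tol=tol)
    return u


def class_reproductive_values(A: ProjectionMatrix, tol: float = 1e-12) -> np.ndarray:
    """Class reproductive-value fractions ``c_X ∝ u_X v_X``, summing to 1.

    ``v`` (dominant left eigenvector of ``A``) is the per-capita reproductive
    value; the class total ``c_X`` equals the probability that the ancestor of
    a random distant-future gene resides in class ``X`` today.
    """
    if not A.is_primitive():
        raise DemographyError("projection matrix must be primitive")
    u, _ = _dominant_right(A.entries, tol=tol)
    v, _ = _dominant_right(A.entries.T, tol=tol)
    c = u * v
    return c / c.sum()


def structure_from_matrix(A: ProjectionMatrix, tol: float = 1e-12) -> ClassStructure:
    """Build a :class:`ClassStructure` (u and c) from a projection matrix."""
    u = stable_class_distribution(A, tol=tol)
    c = class_reproductive_values(A, tol=tol)
    return ClassStructure(
        classes=A.labels,
        u={lab: float(ui) for lab, ui in zip(A.labels, u)},
        c={lab: float(ci) for lab, ci in zip(A.labels, c)},
    )


def allocate_shares(
    w: Sequence[float],
    assignment: Sequence[str],
    structure: ClassStructure,
) -> np.ndarray:
    """Allocate reproductive-value shares by competitive ability within class.

    Individual ``i`` in class ``X`` receives ``(c_X / u_X) * (w_i / wbar_X)``
    where ``wbar_X`` is the mean ability of the individuals assigned to ``X``
    and ``u_X`` is taken as the number of individuals assigned.  Shares within
    each class sum to ``c_X``; all shares sum to 1.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or len(assignment) != w.size:
        raise ValueError("w and assignment must be 1-D and of equal length")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("competitive abilities must be positive and finite")
    labels = np.asarray(assignment, dtype=object)
    for label in structure.classes:
        if not np.any(labels == label):
            raise DemographyError(f"class {label!r} has no individuals assigned")
    unknown = set(labels) - set(structure.classes)
    if unknown:
        raise DemographyError(f"assignment references unknown classes {sorted(unknown)!r}")
    shares = np.empty_like(w)
    for label in structure.classes:
        mask = labels == label
        n_x = int(mask.sum())
        wbar = w[mask].mean()
        shares[mask] = (structure.c[label] / n_x) * (w[mask] / wbar)
    return shares
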