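"""Declarative model files, fixtures and reports.

A model spec is a YAML document whose sections mirror the three
construction steps: ``classes`` (or a ``demography`` matrix from which
``u``/``c`` are derived), the ``actor``, the primary ``deviations``, the
compensation ``pools``, and the ``consanguinity`` block.  Consanguinity
entries may be literal probabilities or directives resolved by the
consanguinity module::

    schema: 1
    classes:
      - {label: X, u: 1, c: 1.0}
    actor: {class: X}
    pools:
      - {label: k, class: X, R: 0.0, note: population at large}
      - {label: m, class: X, R: 0.0}
    consanguinity:
      R_ii: {ploidy: diploid, f: 0.0}     # or a number
      R:
        j: {pedigree: full-sib}           # or a number, or {island: patch-mate}
      island: {n: 10, m: 0.1}             # enables {island: patch-mate}
    deviations:
      - {participant: actor, class: X, delta: -0.01, pool: k}
      - {participant: j, class: X, delta: 0.06, pool: m}

``generate_fixture`` emits random valid specs together with a sidecar
holding the effect computed by :func:`reference_effect` — a deliberately
straight-line evaluator of the net (primary + secondary) sum, kept separate
from the core's per-recipient relatedness route so the two can check each
other.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import consanguinity as cons
from .core import (
    ACTOR_ROLE,
    CompensationPool,
    ConsanguinitySet,
    Deviation,
    IFEffectResult,
    IFModel,
    SpecificationError,
)
from .demography import ClassStructure, ProjectionMatrix, structure_from_matrix

__all__ = [
    "SCHEMA_VERSION",
    "parse_model_spec",
    "model_from_dict",
    "model_to_dict",
    "serialize_model",
    "reference_effect",
    "generate_fixture",
    "write_fixture",
    "write_effect_report",
]

SCHEMA_VERSION = 1


def _require(mapping: dict, key: str, section: str):
    if key not in mapping:
        raise SpecificationError(f"section {section!r}: missing required field {key!r}")
    return mapping[key]


def _resolve_R(value, island_spec: Optional[cons.IslandModelSpec], context: str) -> float:
    """Resolve a consanguinity entry: literal number or directive mapping."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, dict):
        if "ploidy" in value:
            p = cons.PloidySpec(
                ploidy=value["ploidy"], f=float(value.get("f", 0.0)), sex=value.get("sex")
            )
            return cons.self_consanguinity(p)
        if "pedigree" in value:
            p = cons.PloidySpec(
                ploidy=value.get("ploidy", "diploid"),
                f=float(value.get("f", 0.0)),
                sex=value.get("sex"),
            )
            return cons.pedigree_consanguinity(value["pedigree"], p)
        if "island" in value:
            if island_spec is None:
                raise SpecificationError(
                    f"{context}: island directive used but no 'island' block is defined"
                )
            F = cons.island_model_ibd(island_spec)
            kind = value["island"]
            if kind == "patch-mate":
                return F
            if kind == "patch-average":
                n = island_spec.n
                R_ii = cons.self_consanguinity(island_spec.ploidy)
                return cons.pool_consanguinity(
                    [("self", R_ii, 1.0 / n), ("patch-mate", F, (n - 1.0) / n)]
                )
            raise SpecificationError(
                f"{context}: unknown island directive {kind!r} "
                "(expected 'patch-mate' or 'patch-average')"
            )
    raise SpecificationError(f"{context}: cannot resolve consanguinity entry {value!r}")


def model_from_dict(doc: dict, base_dir: Union[str, Path, None] = None) -> IFModel:
    """Build an :class:`IFModel` from a parsed spec document."""
    if not isinstance(doc, dict):
        raise SpecificationError("model spec must be a mapping")
    schema = doc.get("schema")
    if schema != SCHEMA_VERSION:
        raise SpecificationError(
            f"unsupported schema version {schema!r} (this toolkit reads schema {SCHEMA_VERSION})"
        )

    if "demography" in doc:
        dem = doc["demography"]
        if "csv" in dem:
            path = Path(dem["csv"])
            if base_dir is not None and not path.is_absolute():
                path = Path(base_dir) / path
            A = ProjectionMatrix.from_csv(path)
        else:
            A = ProjectionMatrix(
                labels=tuple(_require(dem, "labels", "demography")),
                entries=np.asarray(_require(dem, "matrix", "demography"), dtype=float),
            )
        structure = structure_from_matrix(A)
    else:
        rows = _require(doc, "classes", "top level")
        structure = ClassStructure(
            classes=tuple(str(_require(r, "label", "classes")) for r in rows),
            u={str(r["label"]): float(_require(r, "u", "classes")) for r in rows},
            c={str(r["label"]): float(_require(r, "c", "classes")) for r in rows},
        )

    cons_block = _require(doc, "consanguinity", "top level")
    island_spec = None
    if "island" in cons_block:
        isl = cons_block["island"]
        ploidy = cons.PloidySpec(ploidy=isl.get("ploidy", "haploid"), f=float(isl.get("f", 0.0)),
                                 sex=isl.get("sex"))
        island_spec = cons.IslandModelSpec(n=int(isl["n"]), m=float(isl["m"]), ploidy=ploidy)

    R_ii = _resolve_R(_require(cons_block, "R_ii", "consanguinity"), island_spec, "R_ii")
    R_to = {
        str(role): _resolve_R(value, island_spec, f"R[{role!r}]")
        for role, value in cons_block.get("R", {}).items()
    }

    pools = {}
    for row in _require(doc, "pools", "top level"):
        label = str(_require(row, "label", "pools"))
        pools[label] = CompensationPool(
            pool_label=label,
            class_label=str(_require(row, "class", "pools")),
            consanguinity_to_actor=_resolve_R(
                _require(row, "R", "pools"), island_spec, f"pool {label!r}"
            ),
            membership_note=str(row.get("note", "")),
        )

    deviations = []
    for row in _require(doc, "deviations", "top level"):
        deviations.append(
            Deviation(
                participant_role=str(_require(row, "participant", "deviations")),
                class_label=str(_require(row, "class", "deviations")),
                delta=float(_require(row, "delta", "deviations")),
                compensation_scope=str(_require(row, "pool", "deviations")),
                episode=str(row.get("episode", "t0")),
                class_weight_override=(
                    float(row["class_weight"]) if "class_weight" in row else None
                ),
            )
        )

    actor_class = str(_require(_require(doc, "actor", "top level"), "class", "actor"))
    return IFModel(
        structure=structure,
        actor_class=actor_class,
        deviations=tuple(deviations),
        consanguinity=ConsanguinitySet(R_ii=R_ii, R_to=R_to),
        pools=pools,
    )


def parse_model_spec(path: Union[str, Path]) -> IFModel:
    """Parse a YAML model spec file into a fully resolved :class:`IFModel`."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc, base_dir=path.parent)


def model_to_dict(model: IFModel) -> dict:
    """Serialize a model back to the (fully resolved) spec-document form."""
    return {
        "schema": SCHEMA_VERSION,
        "classes": [
            {"label": lab, "u": float(model.structure.u[lab]), "c": float(model.structure.c[lab])}
            for lab in model.structure.classes
        ],
        "actor": {"class": model.actor_class},
        "consanguinity": {
            "R_ii": model.consanguinity.R_ii,
            "R": {role: float(v) for role, v in model.consanguinity.R_to.items()},
        },
        "pools": [
            {
                "label": p.pool_label,
                "class": p.class_label,
                "R": p.consanguinity_to_actor,
                "note": p.membership_note,
            }
            for p in model.pools.values()
        ],
        "deviations": [
            {
                "participant": d.participant_role,
                "class": d.class_label,
                "delta": d.delta,
                "pool": d.compensation_scope,
                "episode": d.episode,
                **(
                    {"class_weight": d.class_weight_override}
                    if d.class_weight_override is not None
                    else {}
                ),
            }
            for d in model.deviations
        ],
    }


def serialize_model(model: IFModel, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def reference_effect(model: IFModel) -> float:
    """Straight-line net-effect evaluator, independent of the core assembly.

    Sums ``R_participant (c/u) δ  -  R_pool (c/u) δ`` over the deviations and
    divides by the actor's leading factor ``R_ii - R_ik``.  Used as the
    brute-force oracle in property tests and fixture sidecars.
    """
    R_ii = model.consanguinity.R_ii
    R_ik = model.pools[model.actor_deviation.compensation_scope].consanguinity_to_actor
    net = 0.0
    for dev in model.deviations:
        weight = (
            dev.class_weight_override
            if dev.class_weight_override is not None
            else model.structure.c[dev.class_label] / model.structure.u[dev.class_label]
        )
        R_part = (
            R_ii if dev.participant_role == ACTOR_ROLE
            else model.consanguinity.R_to[dev.participant_role]
        )
        R_pool = model.pools[dev.compensation_scope].consanguinity_to_actor
        net += R_part * weight * dev.delta - R_pool * weight * dev.delta
    return net / (R_ii - R_ik)


def generate_fixture(seed: int, max_classes: int = 3, max_recipients: int = 4) -> tuple[dict, dict]:
    """Random valid spec document plus its expected-effect sidecar.

    Coefficients are drawn in valid ranges with the actor's pool kept
    strictly less related than the actor itself (positive leading factor).
    The same seed reproduces the same documents exactly.
    """
    rng = np.random.default_rng(seed)
    n_classes = int(rng.integers(1, max_classes + 1))
    labels = [f"C{i}" for i in range(n_classes)]
    u = rng.uniform(0.2, 5.0, size=n_classes)
    c = rng.dirichlet(np.ones(n_classes))
    classes = [
        {"label": lab, "u": round(float(ui), 6), "c": round(float(ci), 6)}
        for lab, ui, ci in zip(labels, u, c)
    ]
    # renormalize rounded c to sum exactly to 1
    total_c = sum(row["c"] for row in classes)
    classes[-1]["c"] = round(classes[-1]["c"] + (1.0 - total_c), 6)

    R_ii = float(rng.uniform(0.3, 1.0))
    actor_class = labels[int(rng.integers(0, n_classes))]
    R_ik = float(rng.uniform(0.0, R_ii * 0.8))

    pools = [{"label": "k", "class": actor_class, "R": round(R_ik, 6), "note": "actor pool"}]
    deviations = [
        {
            "participant": "actor",
            "class": actor_class,
            "delta": round(float(rng.uniform(-0.5, 0.5)), 6),
            "pool": "k",
        }
    ]
    R = {}
    n_recipients = int(rng.integers(1, max_recipients))
    for idx in range(n_recipients):
        role = f"j{idx}"
        cls = labels[int(rng.integers(0, n_classes))]
        pool_label = f"m{idx}"
        pools.append(
            {
                "label": pool_label,
                "class": cls,
                "R": round(float(rng.uniform(0.0, 1.0)), 6),
                "note": f"pool for {role}",
            }
        )
        deviations.append(
            {
                "participant": role,
                "class": cls,
                "delta": round(float(rng.uniform(-0.5, 0.5)), 6),
                "pool": pool_label,
                "episode": f"t{int(rng.integers(0, 2))}",
            }
        )
        R[role] = round(float(rng.uniform(0.0, 1.0)), 6)

    doc = {
        "schema": SCHEMA_VERSION,
        "classes": classes,
        "actor": {"class": actor_class},
        "consanguinity": {"R_ii": round(R_ii, 6), "R": R},
        "pools": pools,
        "deviations": deviations,
    }
    model = model_from_dict(doc)
    sidecar = {"seed": int(seed), "effect": reference_effect(model)}
    return doc, sidecar


def write_fixture(seed: int, directory: Union[str, Path], stem: str = "fixture") -> tuple[Path, Path]:
    """Write a fixture spec and its sidecar; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc, sidecar = generate_fixture(seed)
    spec_path = directory / f"{stem}_{seed}.yaml"
    sidecar_path = directory / f"{stem}_{seed}.expected.json"
    with open(spec_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return spec_path, sidecar_path


def write_effect_report(
    result: IFEffectResult,
    directory: Union[str, Path],
    stem: str = "effect",
    narrative: str = "",
) -> dict[str, Path]:
    """Write JSON, TSV term table and plain-text narrative for a result."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": directory / f"{stem}.json",
        "tsv": directory / f"{stem}.terms.tsv",
        "txt": directory / f"{stem}.txt",
    }
    paths["json"].write_text(result.to_json(indent=2) + "\n")
    paths["tsv"].write_text(result.to_tsv())
    text = result.summary()
    if narrative:
        text += "\n\n" + narrative
    paths["txt"].write_text(text + "\n")
    return paths
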