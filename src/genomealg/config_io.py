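"""Model configuration files (JSON) and result serialization helpers.

Schema::

    {
      "N": 6,
      "symmetry": "dihedral" | "reflection" | "rotation" | "trivial"
                  | {"generators": ["(1 2 3 4 5 6)", "(1 6)(2 5)(3 4)"]},
      "reversible": true,
      "rearrangements": [{"perm": "(1 2)", "weight": 1},
                         {"perm": "(1 3)", "weight": "1/3"}]
    }

Weights may be numbers or fraction strings; fractions are kept exact.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

from .perm import (
    Permutation,
    SymmetrySubgroup,
    dihedral_group,
    reflection_group,
    rotation_group,
    subgroup_closure,
    trivial_group,
)
from .rearrangement_model import ModelSpec, build_model

__all__ = ["SchemaError", "parse_model_config", "write_model_config", "symmetry_from_spec"]

_NAMED_SYMMETRY = {
    "dihedral": dihedral_group,
    "reflection": reflection_group,
    "rotation": rotation_group,
    "trivial": trivial_group,
}


class SchemaError(ValueError):
    """A model config file violates the documented schema."""


def _parse_weight(value) -> Fraction:
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, bool):
        raise SchemaError("weight must be a number or fraction string")
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(10**12)
    raise SchemaError(f"cannot parse weight {value!r}")


def symmetry_from_spec(spec, n: int) -> SymmetrySubgroup:
    if isinstance(spec, str):
        try:
            return _NAMED_SYMMETRY[spec](n)
        except KeyError:
            raise SchemaError(
                f"unknown symmetry {spec!r}; expected one of "
                f"{sorted(_NAMED_SYMMETRY)} or a generators object"
            ) from None
    if isinstance(spec, dict) and "generators" in spec:
        gens = [Permutation.parse(g, n) for g in spec["generators"]]
        return subgroup_closure(n, gens)
    raise SchemaError(f"malformed symmetry field: {spec!r}")


def parse_model_config(path: str | Path) -> ModelSpec:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc

    for key in ("N", "symmetry", "rearrangements"):
        if key not in raw:
            raise SchemaError(f"{path}: missing required field {key!r}")
    n = raw["N"]
    if not isinstance(n, int) or n < 1:
        raise SchemaError(f"{path}: N must be a positive integer")
    if not isinstance(raw["rearrangements"], list) or not raw["rearrangements"]:
        raise SchemaError(f"{path}: rearrangements must be a non-empty list")

    z = symmetry_from_spec(raw["symmetry"], n)
    base = []
    for i, entry in enumerate(raw["rearrangements"]):
        if not isinstance(entry, dict) or "perm" not in entry or "weight" not in entry:
            raise SchemaError(
                f"{path}: rearrangements[{i}] must have 'perm' and 'weight'"
            )
        base.append((Permutation.parse(entry["perm"], n), _parse_weight(entry["weight"])))
    reversible = bool(raw.get("reversible", True))
    return build_model(n, z, base, enforce_reversibility=reversible)


def write_model_config(ms: ModelSpec, path: str | Path) -> None:
    named = None
    for name, factory in _NAMED_SYMMETRY.items():
        try:
            if factory(ms.n)._element_set == ms.z._element_set:
                named = name
                break
        except ValueError:
            continue
    symmetry = named if named else {"generators": [str(g) for g in ms.z.generators]}
    doc = {
        "N": ms.n,
        "symmetry": symmetry,
        "reversible": ms.reversible,
        "rearrangements": [
            {"perm": str(a), "weight": str(w)} for a, w in ms.base
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
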