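"""Metabolite spin-system constants: chemical shifts and scalar couplings.

A :class:`SpinSystem` is the physical description of one metabolite's
NMR-visible protons — a chemical shift per spin (ppm), a symmetric matrix
of scalar (J) couplings (Hz), and an integer weight per spin for groups of
magnetically equivalent protons that can be collapsed (e.g. the nine
protons of a trimethylamine singlet). The shipped library transcribes
literature constants for the metabolites commonly fitted in brain MRS at
3T and is the single source of truth for all simulation in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SpinSystem",
    "SpinLibrary",
    "load_library",
    "default_library",
    "write_library",
    "get_system",
    "literature_mi_gly_table",
]

PPM_MIN = 0.0
PPM_MAX = 10.0


class LibraryValidationError(ValueError):
    """A spin-system entry violates a structural invariant."""


@dataclass(frozen=True)
class SpinSystem:
    """Chemical shifts, J-couplings and proton multiplicities of one metabolite.

    Parameters
    ----------
    name
        Metabolite label (e.g. ``"mI"``).
    shifts
        Chemical shift per spin, in ppm on the TMS/DSS scale.
    j_matrix
        Symmetric scalar-coupling matrix in Hz, zero diagonal, with the
        same dimension as ``shifts``.
    weights
        Proton multiplicity per spin (>= 1). Equivalent uncoupled protons
        (singlet CH2/CH3 groups) are collapsed to one weighted spin;
        equivalent protons whose couplings matter (lactate CH3) are listed
        as explicit identical-shift spins.
    """

    name: str
    shifts: np.ndarray
    j_matrix: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shifts", np.asarray(self.shifts, dtype=float))
        object.__setattr__(self, "j_matrix", np.asarray(self.j_matrix, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        self.validate()

    @property
    def n_spins(self) -> int:
        return self.shifts.size

    @property
    def total_protons(self) -> float:
        return float(self.weights.sum())

    def validate(self) -> None:
        n = self.n_spins
        if self.j_matrix.shape != (n, n):
            raise LibraryValidationError(
                f"{self.name}: j_matrix shape {self.j_matrix.shape} does not "
                f"match {n} shifts"
            )
        if self.weights.shape != (n,):
            raise LibraryValidationError(
                f"{self.name}: weights length {self.weights.size} does not "
                f"match {n} shifts"
            )
        if not np.allclose(self.j_matrix, self.j_matrix.T, atol=1e-12):
            raise LibraryValidationError(f"{self.name}: j_matrix is not symmetric")
        if not np.allclose(np.diag(self.j_matrix), 0.0, atol=1e-12):
            raise LibraryValidationError(
                f"{self.name}: j_matrix has nonzero diagonal"
            )
        if np.any(self.shifts < PPM_MIN) or np.any(self.shifts > PPM_MAX):
            raise LibraryValidationError(
                f"{self.name}: shifts outside [{PPM_MIN}, {PPM_MAX}] ppm"
            )
        if np.any(self.weights < 1):
            raise LibraryValidationError(f"{self.name}: weights must be >= 1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpinSystem):
            return NotImplemented
        return (
            self.name == other.name
            and np.array_equal(self.shifts, other.shifts)
            and np.array_equal(self.j_matrix, other.j_matrix)
            and np.array_equal(self.weights, other.weights)
        )


@dataclass
class SpinLibrary:
    """A named collection of :class:`SpinSystem` entries with provenance."""

    entries: dict[str, SpinSystem]
    source: str = ""
    notes: str = ""
    omissions: Mapping[str, str] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> SpinSystem:
        return get_system(self, name)

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpinLibrary):
            return NotImplemented
        return (
            self.entries == other.entries
            and self.source == other.source
        )


def _system_from_dict(name: str, d: Mapping) -> SpinSystem:
    try:
        shifts = d["shifts_ppm"]
        j = d["j_hz"]
        weights = d["weights"]
    except KeyError as exc:
        raise LibraryValidationError(f"{name}: missing field {exc}") from exc
    return SpinSystem(name=name, shifts=shifts, j_matrix=j, weights=weights)


def load_library(path: str | Path) -> SpinLibrary:
    """Load and validate a spin library from a JSON file.

    The file layout is ``{"source": str, "metabolites": {name:
    {"shifts_ppm": [...], "j_hz": [[...]], "weights": [...]}}}``; optional
    ``notes`` and ``omissions`` keys carry provenance for compounds left out.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    LibraryValidationError
        If any entry violates a structural invariant (asymmetric J-matrix,
        shift outside 0-10 ppm, mismatched dimensions); the message names
        the offending metabolite and field.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    entries = {
        name: _system_from_dict(name, d) for name, d in raw["metabolites"].items()
    }
    return SpinLibrary(
        entries=entries,
        source=raw.get("source", ""),
        notes=raw.get("notes", ""),
        omissions=raw.get("omissions", {}),
    )


def write_library(lib: SpinLibrary, path: str | Path) -> None:
    """Serialize a library back to the JSON layout read by :func:`load_library`."""
    payload = {
        "source": lib.source,
        "notes": lib.notes,
        "omissions": dict(lib.omissions),
        "metabolites": {
            name: {
                "shifts_ppm": sys.shifts.tolist(),
                "j_hz": sys.j_matrix.tolist(),
                "weights": sys.weights.tolist(),
            }
            for name, sys in lib.entries.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def default_library() -> SpinLibrary:
    """The library of literature constants shipped with the package."""
    with resources.as_file(
        resources.files("spinfit.data").joinpath("spin_library.json")
    ) as p:
        return load_library(p)


def get_system(lib: SpinLibrary, name: str) -> SpinSystem:
    """Look up one metabolite; raises ``KeyError`` listing available names."""
    try:
        return lib.entries[name]
    except KeyError:
        raise KeyError(
            f"unknown metabolite {name!r}; available: {sorted(lib.entries)}"
        ) from None


def literature_mi_gly_table() -> pd.DataFrame:
    """Published brain mI and Gly levels compiled from the MRS literature.

    Columns: tissue (gray/white), reference, year, sequence, te_ms, field,
    mi_mm, mi_tcr, gly_mm, gly_tcr, mi_gly. Missing cells are NaN (a study
    reports either absolute mM values or tCr ratios, rarely both). Column
    means over this table anchor the synthetic in-vivo recipes.
    """
    with resources.as_file(
        resources.files("spinfit.data").joinpath("literature_mi_gly.csv")
    ) as p:
        return pd.read_csv(p)
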