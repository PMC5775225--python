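"""Core molecular containers: atoms, systems, trajectories, selections.

A :class:`MolecularSystem` is an ordered list of :class:`Atom` objects plus
covalent-bond and disulfide annotations.  Coordinates live on the atoms
(Angstrom); array views are built on demand.  A :class:`Trajectory` stores
per-frame coordinate arrays over a fixed reference system, one coordinate
triple per reference atom in every frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import ATOMIC_MASSES, BONDI_RADII, ION_RES_NAMES, WATER_RES_NAMES


def _guess_element(name: str) -> str:
    """Guess the element symbol from a PDB atom name."""
    stripped = name.strip()
    if not stripped:
        return "X"
    # two-letter element names only when the whole atom name is the element
    if stripped.upper() in ("CL", "NA", "MG", "ZN", "CA", "K"):
        return stripped.upper()
    first_alpha = next((c for c in stripped if c.isalpha()), "X")
    return first_alpha.upper()


@dataclass
class Atom:
    """A single atom with optional per-atom force-field annotations.

    ``partial_charge`` is in elementary charges, ``radius`` (PB/SASA radius)
    in Angstrom, ``lj_epsilon`` in kcal/mol and ``lj_rmin_half`` in Angstrom
    (AMBER r_min/2 convention).
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: np.ndarray
    occupancy: float = 1.0
    partial_charge: float | None = None
    radius: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.serial}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if self.radius is not None and self.radius < 0:
            raise ValueError(f"atom {self.serial}: negative radius")
        if not self.element:
            # "CA" is calcium only as a lone ion residue, else an alpha carbon
            if self.name.strip().upper() == "CA" and self.res_name not in ION_RES_NAMES:
                self.element = "C"
            else:
                self.element = _guess_element(self.name)
        self.element = self.element.upper()

    @property
    def label(self) -> str:
        """``resSeq@atomName`` label used in interface reports."""
        return f"{self.res_seq}@{self.name}"

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element, 12.011)

    def is_water(self) -> bool:
        return self.res_name in WATER_RES_NAMES

    def is_ion(self) -> bool:
        return self.res_name in ION_RES_NAMES and self.element != "C"

    def copy(self) -> "Atom":
        return Atom(
            serial=self.serial,
            name=self.name,
            element=self.element,
            res_name=self.res_name,
            res_seq=self.res_seq,
            chain_id=self.chain_id,
            coords=self.coords.copy(),
            occupancy=self.occupancy,
            partial_charge=self.partial_charge,
            radius=self.radius,
            lj_epsilon=self.lj_epsilon,
            lj_rmin_half=self.lj_rmin_half,
        )


class MolecularSystem:
    """Ordered collection of atoms with bond and disulfide annotations.

    ``bonds`` is a list of 0-based atom-index pairs.  Reports use the PDB
    1-based convention; all internal indexing is 0-based.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        bonds: Iterable[tuple[int, int]] = (),
        disulfides: Iterable[tuple] = (),
        meta: str = "",
    ) -> None:
        self.atoms: list[Atom] = list(atoms)
        n = len(self.atoms)
        self.bonds: list[tuple[int, int]] = []
        for i, j in bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j}) for system of {n} atoms")
            self.bonds.append((min(i, j), max(i, j)))
        self.disulfides = list(disulfides)
        self.meta = meta
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_name, a.res_seq, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    # -- array views ---------------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for a, xyz in zip(self.atoms, coords):
            a.coords = xyz.copy()

    def charge_array(self, default: float | None = 0.0) -> np.ndarray:
        out = np.empty(self.n_atoms)
        for i, a in enumerate(self.atoms):
            if a.partial_charge is None:
                if default is None:
                    raise ValueError(f"atom {a.serial} ({a.label}) has no partial charge")
                out[i] = default
            else:
                out[i] = a.partial_charge
        return out

    def radius_array(self, fallback_bondi: bool = True) -> np.ndarray:
        out = np.empty(self.n_atoms)
        for i, a in enumerate(self.atoms):
            if a.radius is not None:
                out[i] = a.radius
            elif fallback_bondi:
                out[i] = BONDI_RADII.get(a.element, 1.7)
            else:
                raise ValueError(f"atom {a.serial} has no radius")
        return out

    def mass_array(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    # -- topology helpers ----------------------------------------------------

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def subset(self, indices: Sequence[int], meta: str | None = None) -> "MolecularSystem":
        """New system containing ``indices`` (order preserved), bonds remapped."""
        indices = list(indices)
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate indices in subset")
        remap = {old: new for new, old in enumerate(indices)}
        atoms = [self.atoms[i].copy() for i in indices]
        bonds = [
            (remap[i], remap[j])
            for i, j in self.bonds
            if i in remap and j in remap
        ]
        return MolecularSystem(atoms, bonds=bonds, meta=meta or self.meta)

    def copy(self) -> "MolecularSystem":
        out = MolecularSystem(
            [a.copy() for a in self.atoms], bonds=list(self.bonds), meta=self.meta
        )
        out.disulfides = list(self.disulfides)
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames over a reference :class:`MolecularSystem`."""

    reference: MolecularSystem
    frames: list[np.ndarray]
    times: list[float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.reference.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k} has shape {f.shape}, expected ({n}, 3)"
                )
        if self.times is not None and len(self.times) != len(self.frames):
            raise ValueError("times length must equal frame count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SelectionSpec:
    """Predicate-based atom selection.

    Each non-``None`` field is a predicate; ``mode`` combines them with
    logical AND (default) or OR.  Resolution is deterministic: ascending
    atom-index order, no duplicates.
    """

    chains: set[str] | None = None
    res_min: int | None = None
    res_max: int | None = None
    names: set[str] | None = None
    mode: str = "and"

    def _predicates(self):
        preds = []
        if self.chains is not None:
            chains = set(self.chains)
            preds.append(lambda a: a.chain_id in chains)
        if self.res_min is not None or self.res_max is not None:
            lo = -math.inf if self.res_min is None else self.res_min
            hi = math.inf if self.res_max is None else self.res_max
            preds.append(lambda a: lo <= a.res_seq <= hi)
        if self.names is not None:
            names = set(self.names)
            preds.append(lambda a: a.name in names)
        return preds

    def resolve(self, system: MolecularSystem) -> list[int]:
        preds = self._predicates()
        if not preds:
            return list(range(system.n_atoms))
        combine = all if self.mode == "and" else any
        return [
            i for i, a in enumerate(system.atoms) if combine(p(a) for p in preds)
        ]


def select(system: MolecularSystem, spec: SelectionSpec) -> list[int]:
    """Resolve ``spec`` on ``system`` to an ordered, duplicate-free index list."""
    return spec.resolve(system)


def select_union(system: MolecularSystem, *specs: SelectionSpec) -> list[int]:
    out: set[int] = set()
    for spec in specs:
        out.update(spec.resolve(system))
    return sorted(out)
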