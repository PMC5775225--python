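"""Reading, preparing and writing molecular structures and trajectories.

PDB parsing is delegated to Biopython's :class:`Bio.PDB.PDBParser` (strict
mode, so malformed records raise with the offending line number).  Writing
uses plain fixed-column ATOM/HETATM formatting; the only trajectory dialect
supported is multi-model PDB.

Preparation follows the workflow used for crystal-structure complexes:
drop unwanted chains, optionally keep crystal waters and Ca2+ ions, and
detect Cys-Cys disulfide bridges geometrically.
"""

from __future__ import annotations

import fnmatch
import io
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .constants import ION_RES_NAMES, WATER_RES_NAMES
from .core import Atom, MolecularSystem, SelectionSpec, Trajectory, select

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "prepare_complex",
    "detect_disulfides",
    "DisulfidePair",
    "read_parameter_table",
    "apply_parameter_table",
    "write_parameter_table",
    "add_polar_hydrogens",
    "write_pqr",
    "select",
    "SelectionSpec",
]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _model_to_system(model, meta: str) -> MolecularSystem:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            for bio_atom in residue:
                # Disordered atoms proxy to the highest-occupancy altloc
                # (tie -> first in file), matching common practice.
                atoms.append(
                    Atom(
                        serial=bio_atom.serial_number,
                        name=bio_atom.get_name(),
                        element=(bio_atom.element or "").strip(),
                        res_name=residue.resname.strip(),
                        res_seq=resseq,
                        chain_id=chain.id if chain.id.strip() else "A",
                        coords=np.asarray(bio_atom.coord, dtype=float),
                        occupancy=(
                            1.0 if bio_atom.occupancy is None else float(bio_atom.occupancy)
                        ),
                    )
                )
    return MolecularSystem(atoms, meta=meta)


def read_pdb(
    source: str | Path | TextIO,
    model_policy: str | int = "first",
) -> MolecularSystem | list[MolecularSystem]:
    """Read a PDB file into one or more :class:`MolecularSystem` objects.

    ``model_policy`` is ``"first"`` (default), ``"all"`` (returns a list,
    one system per MODEL), or a 0-based model index.  Waters and ions are
    retained as their own residues.  Raises ``ValueError`` on empty or
    malformed input; parser errors name the offending line.
    """
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        meta = str(source)
        close = True
    else:
        handle = source
        meta = getattr(source, "name", "<stream>")
        close = False
    try:
        parser = PDBParser(PERMISSIVE=False, QUIET=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            try:
                structure = parser.get_structure("s", handle)
            except PDBConstructionException as exc:
                raise ValueError(f"malformed PDB input ({meta}): {exc}") from exc
    finally:
        if close:
            handle.close()

    models = list(structure)
    if not models or all(len(list(m.get_atoms())) == 0 for m in models):
        raise ValueError(f"no atoms found in PDB input ({meta})")

    if model_policy == "all":
        return [
            _model_to_system(m, meta=f"{meta}#model{k + 1}")
            for k, m in enumerate(models)
        ]
    if model_policy == "first":
        idx = 0
    elif isinstance(model_policy, int):
        idx = model_policy
    else:
        raise ValueError(f"unknown model policy: {model_policy!r}")
    if not (0 <= idx < len(models)):
        raise ValueError(f"model index {idx} out of range (file has {len(models)})")
    return _model_to_system(models[idx], meta=meta)


def _roster(system: MolecularSystem) -> list[tuple]:
    return [(a.chain_id, a.res_name, a.res_seq, a.name) for a in system.atoms]


def read_trajectory(
    source: str | Path | TextIO,
    reference: MolecularSystem | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a :class:`Trajectory`.

    All models must share an identical atom roster; the reference system is
    taken from model 1 when not supplied.
    """
    systems = read_pdb(source, model_policy="all")
    ref = reference if reference is not None else systems[0]
    ref_roster = _roster(ref)
    frames = []
    for k, sys_k in enumerate(systems):
        if _roster(sys_k) != ref_roster:
            raise ValueError(
                f"model {k + 1} atom roster does not match the reference"
            )
        frames.append(sys_k.coords)
    return Trajectory(reference=ref, frames=frames)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_atom_line(atom: Atom, serial: int) -> str:
    hetatm = atom.is_water() or atom.is_ion()
    record = "HETATM" if hetatm else "ATOM  "
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name_field = f" {name:<3}"
    else:
        name_field = f"{name:<4}"
    x, y, z = atom.coords
    return (
        f"{record}{serial:>5} {name_field} {atom.res_name:<3} {atom.chain_id}"
        f"{atom.res_seq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
        f"{0.0:6.2f}          {atom.element:>2}"
    )


def _write_model(fh: TextIO, system: MolecularSystem, coords: np.ndarray | None) -> None:
    prev_chain = None
    serial = 0
    for i, atom in enumerate(system.atoms):
        if prev_chain is not None and atom.chain_id != prev_chain:
            fh.write("TER\n")
        prev_chain = atom.chain_id
        serial += 1
        if coords is not None:
            atom = atom.copy()
            atom.coords = coords[i]
        fh.write(_format_atom_line(atom, serial) + "\n")
    fh.write("TER\n")


def write_pdb(system: MolecularSystem, target: str | Path | TextIO) -> None:
    """Write a single-model PDB (ATOM/HETATM/TER/END)."""
    fh, close = _open_w(target)
    try:
        _write_model(fh, system, None)
        fh.write("END\n")
    finally:
        if close:
            fh.close()


def write_trajectory(trajectory: Trajectory, target: str | Path | TextIO) -> None:
    """Write a multi-model PDB, one MODEL per frame."""
    fh, close = _open_w(target)
    try:
        for k, frame in enumerate(trajectory.frames):
            fh.write(f"MODEL {k + 1:>8}\n")
            _write_model(fh, trajectory.reference, frame)
            fh.write("ENDMDL\n")
        fh.write("END\n")
    finally:
        if close:
            fh.close()


def _open_w(target):
    if isinstance(target, (str, Path)):
        return open(target, "w"), True
    return target, False


def write_pqr(
    system: MolecularSystem,
    target: str | Path | TextIO,
    charges: np.ndarray | None = None,
) -> None:
    """PQR-style dump: PDB columns with charge and radius in place of occupancy/B."""
    q = system.charge_array() if charges is None else np.asarray(charges, float)
    r = system.radius_array()
    fh, close = _open_w(target)
    try:
        for i, atom in enumerate(system.atoms):
            x, y, z = atom.coords
            fh.write(
                f"ATOM  {i + 1:>5} {atom.name:<4} {atom.res_name:<3} {atom.chain_id}"
                f"{atom.res_seq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f" {q[i]:8.4f} {r[i]:7.4f}\n"
            )
        fh.write("END\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

def prepare_complex(
    system: MolecularSystem,
    drop_chains: Iterable[str] = (),
    keep_waters: bool = True,
    keep_ions: bool = True,
) -> MolecularSystem:
    """Apply the structure-preparation rules.

    Removes the listed chains, then drops waters and/or monoatomic ions
    unless the respective flag is set.  Atom ordering and coordinates of
    survivors are untouched.  Raises if nothing survives.
    """
    drop = set(drop_chains)
    unknown = drop - set(system.chains)
    if unknown:
        raise ValueError(f"cannot drop unknown chain(s): {sorted(unknown)}")
    keep_idx = []
    for i, a in enumerate(system.atoms):
        if a.chain_id in drop:
            continue
        if a.is_water() and not keep_waters:
            continue
        if a.is_ion() and not keep_ions:
            continue
        keep_idx.append(i)
    if not keep_idx:
        raise ValueError("preparation removed every atom")
    return system.subset(keep_idx, meta=system.meta + "|prepared")


@dataclass(frozen=True)
class DisulfidePair:
    """A geometric Cys-Cys bridge (atom indices 0-based, residues PDB-numbered)."""

    index_a: int
    index_b: int
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    distance: float


def detect_disulfides(system: MolecularSystem, sg_cutoff: float = 2.5) -> list[DisulfidePair]:
    """Greedy nearest-pair matching of cysteine SG atoms within ``sg_cutoff``.

    Each SG participates in at most one bridge; candidate pairs are taken in
    ascending distance so the result is independent of atom order and
    invariant under rigid-body motion.
    """
    sg = [
        i
        for i, a in enumerate(system.atoms)
        if a.name == "SG" and a.res_name.startswith("CY")
    ]
    candidates = []
    for ii, i in enumerate(sg):
        for j in sg[ii + 1 :]:
            d = float(np.linalg.norm(system.atoms[i].coords - system.atoms[j].coords))
            if d < sg_cutoff:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    pairs: list[DisulfidePair] = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        ai, aj = system.atoms[i], system.atoms[j]
        pairs.append(
            DisulfidePair(i, j, ai.chain_id, ai.res_seq, aj.chain_id, aj.res_seq, d)
        )
    return pairs


# ---------------------------------------------------------------------------
# per-atom parameter tables
# ---------------------------------------------------------------------------

def read_parameter_table(source: str | Path | TextIO) -> list[tuple[str, dict]]:
    """Read a whitespace-delimited per-atom parameter table.

    Format (one header line, ``#`` comments allowed)::

        pattern charge radius lj_epsilon lj_rmin_half

    where ``pattern`` matches ``RESNAME@ATOMNAME`` with shell wildcards.
    Later rows override earlier ones when both match an atom.
    """
    fh, close = (open(source), True) if isinstance(source, (str, Path)) else (source, False)
    rows: list[tuple[str, dict]] = []
    try:
        lines = [ln.strip() for ln in fh]
    finally:
        if close:
            fh.close()
    body = [ln for ln in lines if ln and not ln.startswith("#")]
    if not body:
        raise ValueError("empty parameter table")
    header = body[0].split()
    if header[0].lower() != "pattern":
        raise ValueError("parameter table must start with a 'pattern ...' header line")
    for ln in body[1:]:
        parts = ln.split()
        if len(parts) != 5:
            raise ValueError(f"parameter row needs 5 fields: {ln!r}")
        pattern = parts[0]
        charge, radius, eps, rmin_half = (float(p) for p in parts[1:])
        rows.append(
            (
                pattern,
                {
                    "partial_charge": charge,
                    "radius": radius,
                    "lj_epsilon": eps,
                    "lj_rmin_half": rmin_half,
                },
            )
        )
    return rows


def apply_parameter_table(
    system: MolecularSystem, table: list[tuple[str, dict]]
) -> MolecularSystem:
    """Return a copy of ``system`` with charges/radii/LJ set from ``table``."""
    out = system.copy()
    for atom in out.atoms:
        key = f"{atom.res_name}@{atom.name}"
        for pattern, values in table:
            if fnmatch.fnmatchcase(key, pattern):
                atom.partial_charge = values["partial_charge"]
                atom.radius = values["radius"]
                atom.lj_epsilon = values["lj_epsilon"]
                atom.lj_rmin_half = values["lj_rmin_half"]
    return out


def write_parameter_table(system: MolecularSystem, target: str | Path | TextIO) -> None:
    """Write one exact-match row per distinct (res, name) with parameters set."""
    fh, close = _open_w(target)
    seen: set[str] = set()
    try:
        fh.write("pattern charge radius lj_epsilon lj_rmin_half\n")
        for a in system.atoms:
            key = f"{a.res_name}@{a.name}"
            if key in seen or a.partial_charge is None:
                continue
            seen.add(key)
            fh.write(
                f"{key} {a.partial_charge:.6f} "
                f"{a.radius if a.radius is not None else 1.7:.4f} "
                f"{a.lj_epsilon if a.lj_epsilon is not None else 0.0:.6f} "
                f"{a.lj_rmin_half if a.lj_rmin_half is not None else 1.7:.4f}\n"
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# minimal polar-hydrogen placement
# ---------------------------------------------------------------------------

#: donor heavy atoms eligible for geometric H placement when no H is present
_PLACEABLE = {"N", "OG", "OG1", "OH", "OD1", "OE1", "SG", "NE2", "ND1", "ND2"}

_NH_LENGTH = 1.01
_OH_LENGTH = 0.96


def add_polar_hydrogens(
    system: MolecularSystem, covalent_cutoff: float = 1.8
) -> MolecularSystem:
    """Place idealized hydrogens on bare amide N and hydroxyl/thiol O/S atoms.

    This is deliberately minimal: the H is placed along the direction
    opposite the mean of the unit vectors to the heavy-atom neighbours
    (within ``covalent_cutoff``), at 1.01 A (N-H) or 0.96 A (O-H / S-H).
    It serves hydrogen-bond geometry only, not force-field protonation.
    """
    out = system.copy()
    coords = out.coords
    n = out.n_atoms
    adj = out.adjacency()
    has_bonds = bool(out.bonds)
    new_atoms: list[Atom] = []
    new_bonds: list[tuple[int, int]] = []
    serial = max((a.serial for a in out.atoms), default=0)
    for i, a in enumerate(out.atoms):
        if a.element not in ("N", "O", "S") or a.name not in _PLACEABLE:
            continue
        d = np.linalg.norm(coords - coords[i], axis=1)
        near = [j for j in range(n) if j != i and d[j] < covalent_cutoff]
        if has_bonds:
            near = sorted(set(near) | adj[i])
        if any(out.atoms[j].element == "H" for j in near):
            continue  # already protonated
        heavy = [j for j in near if out.atoms[j].element != "H"]
        if not heavy:
            continue
        direction = -np.sum(
            [(coords[j] - coords[i]) / max(d[j], 1e-9) for j in heavy], axis=0
        )
        nrm = np.linalg.norm(direction)
        if nrm < 1e-6:
            continue  # symmetric environment, no defined direction
        direction /= nrm
        length = _NH_LENGTH if a.element == "N" else _OH_LENGTH
        serial += 1
        h_name = "H" + a.name[1:] if len(a.name) > 1 else "H"
        new_atoms.append(
            Atom(
                serial=serial,
                name=h_name,
                element="H",
                res_name=a.res_name,
                res_seq=a.res_seq,
                chain_id=a.chain_id,
                coords=coords[i] + length * direction,
            )
        )
        new_bonds.append((i, n + len(new_atoms) - 1))
    result = MolecularSystem(
        out.atoms + new_atoms,
        bonds=out.bonds + new_bonds,
        meta=out.meta + "|polarH",
    )
    result.disulfides = list(out.disulfides)
    return result
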