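"""Effective polarizable bond (EPB) fluctuating-charge model.

A designated polar X-H bond responds to its electrostatic environment by
transferring charge dq between its two atoms.  With site potentials Phi_X
and Phi_H, gas-phase reference charges q_X^gas / q_H^gas, bond length d and
polarization force constant k, the energy

    E = E0 + k (dq * d)^2 + (q_X^gas + dq) Phi_X + (q_H^gas - dq) Phi_H

is quadratic in dq and is minimized in closed form by

    dq = (Phi_H - Phi_X) / (2 d^2 k)

The heavy atom gains +dq and the hydrogen loses dq, so the bond's total
charge is conserved exactly.  The induced dipole change is dmu = dq * d.
A fixed-point loop (:func:`iterate_scf`) alternates potential evaluation
and charge update until all dq are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .constants import KE
from .core import MolecularSystem

__all__ = [
    "PolarizableBond",
    "EPBParameterSet",
    "ESPField",
    "ChargeState",
    "compute_esp",
    "solve_delta_q",
    "epb_self_energy",
    "apply_polarization",
    "iterate_scf",
    "assign_polarizable_bonds",
]


@dataclass(frozen=True)
class PolarizableBond:
    """One polarizable X-H bond.

    ``d`` is the bond length (Angstrom) and ``k`` the polarization force
    constant (kcal mol^-1 e^-2 A^-2); both must be positive.
    """

    heavy_index: int
    h_index: int
    q_heavy_gas: float
    q_h_gas: float
    d: float
    k: float

    def __post_init__(self) -> None:
        if self.heavy_index == self.h_index:
            raise ValueError("polarizable bond needs two distinct atoms")
        if self.d <= 0 or self.k <= 0:
            raise ValueError("polarizable bond requires d > 0 and k > 0")


class EPBParameterSet:
    """Map from (res_name, heavy_atom, h_atom) to (k, q_heavy_gas, q_h_gas).

    File format: whitespace table with header
    ``RESNAME HEAVY_ATOM H_ATOM q_heavy_gas q_h_gas k``.
    """

    def __init__(self, entries: Mapping[tuple[str, str, str], tuple[float, float, float]]):
        self.entries = dict(entries)
        for key, (k, qh, qH) in self.entries.items():
            if k <= 0:
                raise ValueError(f"non-positive k for {key}")

    @classmethod
    def from_file(cls, source: str | Path | TextIO) -> "EPBParameterSet":
        fh, close = (open(source), True) if isinstance(source, (str, Path)) else (source, False)
        try:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        finally:
            if close:
                fh.close()
        entries = {}
        for ln in lines:
            parts = ln.split()
            if parts[0].upper() == "RESNAME":
                continue
            if len(parts) != 6:
                raise ValueError(f"EPB parameter row needs 6 fields: {ln!r}")
            res, heavy, h = parts[0], parts[1], parts[2]
            qg_heavy, qg_h, k = (float(p) for p in parts[3:])
            entries[(res, heavy, h)] = (k, qg_heavy, qg_h)
        return cls(entries)

    def to_file(self, target: str | Path | TextIO) -> None:
        fh, close = (open(target, "w"), True) if isinstance(target, (str, Path)) else (target, False)
        try:
            fh.write("RESNAME HEAVY_ATOM H_ATOM q_heavy_gas q_h_gas k\n")
            for (res, heavy, h), (k, qg_heavy, qg_h) in self.entries.items():
                fh.write(f"{res} {heavy} {h} {qg_heavy:.6f} {qg_h:.6f} {k:.6f}\n")
        finally:
            if close:
                fh.close()

    def lookup(self, res_name: str, heavy: str, h: str):
        return self.entries.get((res_name, heavy, h))


class ESPField:
    """Electrostatic potential (kcal mol^-1 e^-1) at a set of atom sites."""

    def __init__(self, values: Mapping[int, float]):
        self.values = dict(values)
        for i, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite potential at site {i}")

    def phi(self, index: int) -> float:
        return self.values[index]

    def __contains__(self, index: int) -> bool:
        return index in self.values


@dataclass
class ChargeState:
    """Polarized per-atom charges plus per-bond dq and dipole change dmu."""

    charges: np.ndarray
    delta_q: dict[tuple[int, int], float]
    delta_mu: dict[tuple[int, int], float]
    converged: bool = True
    iterations: int = 0

    @property
    def total_charge(self) -> float:
        return float(np.sum(self.charges))


def _exclusion_sets(system: MolecularSystem) -> list[set[int]]:
    """Self + 1-2 + 1-3 neighbour exclusion sets from the bond graph."""
    adj = system.adjacency()
    out = []
    for i in range(system.n_atoms):
        excl = {i} | adj[i]
        for j in adj[i]:
            excl |= adj[j]
        out.append(excl)
    return out


def compute_esp(
    system: MolecularSystem,
    charges: np.ndarray,
    sites: Sequence[int],
    exclude_bonded: bool = True,
    cutoff: float | None = None,
    extra_exclusions: Mapping[int, Iterable[int]] | None = None,
) -> ESPField:
    """Coulomb potential at each site from all non-excluded point charges.

    Exclusions per site: the site itself, its 1-2 and 1-3 bonded neighbours
    (when ``exclude_bonded``), and any ``extra_exclusions``.  No periodicity;
    vacuum dielectric (solvent screening is the PB stage's job).
    """
    if len(sites) == 0:
        raise ValueError("no ESP sites given")
    charges = np.asarray(charges, dtype=float)
    coords = system.coords
    if charges.shape[0] != coords.shape[0]:
        raise ValueError("charge array length mismatch")
    excl = _exclusion_sets(system) if exclude_bonded else [{i} for i in range(len(coords))]
    values: dict[int, float] = {}
    for i in sites:
        mask = np.ones(len(coords), dtype=bool)
        banned = set(excl[i])
        if extra_exclusions and i in extra_exclusions:
            banned |= set(extra_exclusions[i])
        mask[list(banned)] = False
        r = np.linalg.norm(coords - coords[i], axis=1)
        if np.any(mask & (r < 1e-9)):
            j = int(np.nonzero(mask & (r < 1e-9))[0][0])
            raise ValueError(f"coincident atoms {i} and {j} in ESP evaluation")
        if cutoff is not None:
            mask &= r < cutoff
        with np.errstate(divide="ignore"):
            contrib = np.where(mask, charges / np.where(r > 0, r, np.inf), 0.0)
        values[i] = KE * float(np.sum(contrib))
    return ESPField(values)


def solve_delta_q(phi_heavy: float, phi_h: float, d: float, k: float) -> float:
    """Closed-form charge transfer minimizing the quadratic bond energy."""
    if d <= 0 or k <= 0:
        raise ValueError("d and k must be positive")
    return (phi_h - phi_heavy) / (2.0 * d * d * k)


def epb_self_energy(dq: float, d: float, k: float) -> float:
    """Polarization self-energy k (dq d)^2 = k (dmu)^2 in kcal/mol."""
    if d <= 0 or k <= 0:
        raise ValueError("d and k must be positive")
    return k * (dq * d) ** 2


def apply_polarization(
    system: MolecularSystem,
    bonds: Sequence[PolarizableBond],
    esp: ESPField,
    base_charges: np.ndarray | None = None,
    allow_shared_heavy: bool = False,
) -> ChargeState:
    """Update charges from site potentials: heavy +dq, hydrogen -dq.

    Atoms outside any polarizable bond keep their ``base_charges`` (the
    system's fixed charges when omitted).  A heavy atom shared by several
    bonds is a configuration error unless ``allow_shared_heavy`` (the split
    -NH2 representation, where each bond carries its share of the gas
    charge).  A hydrogen may belong to one bond only, always.
    """
    if base_charges is None:
        charges = system.charge_array(default=0.0)
    else:
        charges = np.asarray(base_charges, dtype=float).copy()
    heavy_seen: dict[int, int] = {}
    h_seen: set[int] = set()
    for b in bonds:
        heavy_seen[b.heavy_index] = heavy_seen.get(b.heavy_index, 0) + 1
        if b.h_index in h_seen:
            raise ValueError(f"hydrogen atom {b.h_index} in two polarizable bonds")
        h_seen.add(b.h_index)
    if not allow_shared_heavy and any(cnt > 1 for cnt in heavy_seen.values()):
        shared = [i for i, cnt in heavy_seen.items() if cnt > 1]
        raise ValueError(f"atom(s) {shared} belong to multiple polarizable bonds")

    delta_q: dict[tuple[int, int], float] = {}
    delta_mu: dict[tuple[int, int], float] = {}
    # reset bond atoms to their gas-phase reference before adding transfers
    for b in bonds:
        charges[b.heavy_index] = 0.0
    for b in bonds:
        charges[b.heavy_index] += b.q_heavy_gas
        charges[b.h_index] = b.q_h_gas
    for b in bonds:
        if b.heavy_index not in esp or b.h_index not in esp:
            raise ValueError(
                f"ESP missing at polarizable bond ({b.heavy_index}, {b.h_index})"
            )
        dq = solve_delta_q(esp.phi(b.heavy_index), esp.phi(b.h_index), b.d, b.k)
        charges[b.heavy_index] += dq
        charges[b.h_index] -= dq
        key = (b.heavy_index, b.h_index)
        delta_q[key] = dq
        delta_mu[key] = dq * b.d
    return ChargeState(charges=charges, delta_q=delta_q, delta_mu=delta_mu)


def iterate_scf(
    system: MolecularSystem,
    charges0: np.ndarray,
    bonds: Sequence[PolarizableBond],
    tol: float = 1e-6,
    max_iter: int = 50,
    cutoff: float | None = None,
    allow_shared_heavy: bool = False,
) -> ChargeState:
    """Self-consistent fluctuating charges by fixed-point iteration.

    Alternates ESP evaluation (with the current charges) and the closed-form
    charge update until the largest per-bond |dq| change falls below ``tol``
    (elementary charges) or ``max_iter`` is hit.  Non-convergence is flagged
    on the result, not raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    charges = np.asarray(charges0, dtype=float).copy()
    if not bonds:
        return ChargeState(charges=charges, delta_q={}, delta_mu={}, converged=True)
    sites = sorted({b.heavy_index for b in bonds} | {b.h_index for b in bonds})
    prev_dq = {(b.heavy_index, b.h_index): 0.0 for b in bonds}
    state = ChargeState(charges=charges, delta_q=dict(prev_dq), delta_mu={}, converged=False)
    for it in range(1, max_iter + 1):
        esp = compute_esp(system, charges, sites, cutoff=cutoff)
        state = apply_polarization(
            system, bonds, esp, base_charges=charges, allow_shared_heavy=allow_shared_heavy
        )
        charges = state.charges
        change = max(abs(state.delta_q[k] - prev_dq[k]) for k in state.delta_q)
        prev_dq = dict(state.delta_q)
        state.iterations = it
        if change < tol:
            state.converged = True
            break
    return state


def assign_polarizable_bonds(
    system: MolecularSystem,
    params: EPBParameterSet,
    split_shared_heavy: bool = True,
) -> list[PolarizableBond]:
    """Match the system's X-H bonds against an EPB parameter table.

    The bond length ``d`` is taken from the reference geometry.  When a
    heavy atom carries several parameterized hydrogens (e.g. an amide
    -NH2), its gas charge is split evenly across the bonds if
    ``split_shared_heavy``; otherwise the clash raises.
    """
    matches: list[tuple[int, int, tuple[float, float, float]]] = []
    for i, j in system.bonds:
        ai, aj = system.atoms[i], system.atoms[j]
        if ai.element == "H" and aj.element != "H":
            heavy, h = j, i
        elif aj.element == "H" and ai.element != "H":
            heavy, h = i, j
        else:
            continue
        ha, hh = system.atoms[heavy], system.atoms[h]
        entry = params.lookup(ha.res_name, ha.name, hh.name)
        if entry is not None:
            matches.append((heavy, h, entry))
    counts: dict[int, int] = {}
    for heavy, _, _ in matches:
        counts[heavy] = counts.get(heavy, 0) + 1
    bonds = []
    for heavy, h, (k, qg_heavy, qg_h) in matches:
        share = counts[heavy]
        if share > 1 and not split_shared_heavy:
            raise ValueError(
                f"heavy atom {heavy} matched by {share} polarizable bonds"
            )
        d = float(
            np.linalg.norm(system.atoms[heavy].coords - system.atoms[h].coords)
        )
        bonds.append(
            PolarizableBond(
                heavy_index=heavy,
                h_index=h,
                q_heavy_gas=qg_heavy / share,
                q_h_gas=qg_h,
                d=d,
                k=k,
            )
        )
    return bonds
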