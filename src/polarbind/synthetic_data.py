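"""Synthetic fixtures: toy two-chain complexes, Markov hydrogen-bond
trajectories, mutant pairs with known interaction-energy offsets, and a
Born-ion system.

The toy complex emulates an antiparallel beta-sheet-like protein-protein
interface: chain A carries amide-style N-H donors, chain B carbonyl-style
C=O acceptors, arranged collinearly at a chosen donor-acceptor distance so
that each intended pair satisfies the default hydrogen-bond criterion in
the reference frame.  Trajectories break and re-form each bond with a
two-state Markov chain (the broken state rigidly displaces the acceptor
unit along the donor-acceptor axis, clearly outside the criterion) and add
small Gaussian thermal jitter.  Mutants scale ligand charges or LJ well
depths so that the cross-term interaction energy changes by an analytically
known offset.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import BONDI_RADII
from .core import Atom, MolecularSystem, Trajectory
from .epb_model import EPBParameterSet
from .mm_energy import ForceFieldParams, interaction_energy
from .tables import reference_tables  # re-exported packaged fixture

__all__ = [
    "ToyComplexSpec",
    "HBondDynamicsSpec",
    "MutantSpec",
    "make_toy_complex",
    "make_hbond_trajectory",
    "make_mutant_pair",
    "born_fixture",
    "toy_epb_parameters",
    "reference_tables",
]

# Per-atom parameters of the toy building blocks: charge (e), LJ epsilon
# (kcal/mol), LJ r_min/2 (A).  Charges are AMBER-like and sum to neutral
# residues; the donor-N / acceptor-O r_min halves are chosen so the default
# 2.9 A hydrogen-bond contact sits at the LJ minimum, giving the interface
# a net attractive van der Waals term.  Illustrative, not a published set.
_TOY_PARAMS = {
    ("DNR", "N"): (-0.52, 0.17, 1.45),
    ("DNR", "H"): (0.31, 0.0157, 0.6),
    ("DNR", "C"): (0.21, 0.1094, 1.908),
    ("DNR", "CB"): (0.0, 0.1094, 1.908),
    ("ACC", "O"): (-0.50, 0.21, 1.45),
    ("ACC", "C"): (0.50, 0.1094, 1.908),
    ("ACC", "CB"): (0.0, 0.1094, 1.908),
}


@dataclass
class ToyComplexSpec:
    """Geometry and parameters of the toy two-chain complex.

    ``d_da`` is the donor-acceptor heavy-atom distance of each intended
    hydrogen bond (collinear N-H...O geometry); ``pair_spacing`` separates
    consecutive pairs so they stay independent; ``n_scaffold`` adds neutral
    carbon atoms per chain to give the interface a van der Waals footprint.
    """

    n_hbond_pairs: int = 5
    d_da: float = 2.9
    pair_spacing: float = 6.0
    n_scaffold: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hbond_pairs < 0:
            raise ValueError("n_hbond_pairs must be >= 0")
        if self.d_da <= 1.2:
            raise ValueError("d_da too small: donor and acceptor would clash")
        if self.pair_spacing < 4.0:
            raise ValueError("pair_spacing < 4 A would couple adjacent pairs")


@dataclass
class HBondDynamicsSpec:
    """Two-state Markov dynamics of the interface hydrogen bonds.

    ``p_on_off`` / ``p_off_on`` are per-frame transition probabilities
    (scalars or one value per bond); the stationary formed probability is
    p_off_on / (p_on_off + p_off_on).  ``broken_da`` is the donor-acceptor
    distance of the broken state (must exceed the 4 A criterion) and
    ``sigma`` the Gaussian thermal jitter applied to every coordinate.
    """

    p_on_off: float | Sequence[float] = 0.05
    p_off_on: float | Sequence[float] = 0.20
    broken_da: float = 5.0
    sigma: float = 0.05
    n_frames: int = 2000
    seed: int = 0

    def rates(self, n_bonds: int) -> tuple[np.ndarray, np.ndarray]:
        on_off = np.broadcast_to(np.asarray(self.p_on_off, float), (n_bonds,)).copy()
        off_on = np.broadcast_to(np.asarray(self.p_off_on, float), (n_bonds,)).copy()
        for arr, name in ((on_off, "p_on_off"), (off_on, "p_off_on")):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(on_off + off_on <= 0):
            raise ValueError("degenerate Markov rates: both probabilities zero")
        return on_off, off_on

    def __post_init__(self) -> None:
        if self.sigma > 0.15:
            raise ValueError("thermal jitter sigma > 0.15 A would break formed bonds")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class MutantSpec:
    """A synthetic mutant with a known injected interaction-energy offset.

    ``mechanism`` is ``"lj"`` (scale ligand LJ well depths; solvation terms
    untouched) or ``"charge"`` (scale ligand charges; changes the PB term
    too).  ``epsilon`` is the target change of the gas-phase cross-term
    interaction energy, kcal/mol.
    """

    epsilon: float = -4.0
    mechanism: str = "lj"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("lj", "charge"):
            raise ValueError("mechanism must be 'lj' or 'charge'")


def _toy_atom(serial, name, element, res_name, res_seq, chain, xyz):
    q, eps, rmh = _TOY_PARAMS[(res_name, name if name in ("N", "H", "O") else
                               ("C" if name == "C" else "CB"))]
    return Atom(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain,
        coords=np.asarray(xyz, float),
        partial_charge=q,
        radius=BONDI_RADII[element],
        lj_epsilon=eps,
        lj_rmin_half=rmh,
    )


def make_toy_complex(spec: ToyComplexSpec | None = None) -> MolecularSystem:
    """Build the deterministic two-chain toy complex.

    Chain A holds one donor residue (C-N-H, amide-like) per intended bond;
    chain B one acceptor residue (C=O).  The donor N, its H and the
    acceptor O of pair *i* are collinear along x at distance ``d_da``,
    stacked along y.  The returned system carries bonds, charges, radii and
    LJ parameters, plus a ``toy_pairs`` attribute listing
    ``(donor_heavy, donor_h, acceptor, acceptor_unit_indices)`` per pair.
    """
    spec = spec or ToyComplexSpec()
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    pairs: list[tuple[int, int, int, list[int]]] = []
    serial = 0

    for i in range(spec.n_hbond_pairs):
        y = i * spec.pair_spacing
        # chain A donor residue: scaffold C - N - H pointing at the acceptor
        c_idx = len(atoms)
        serial += 1
        atoms.append(_toy_atom(serial, "C", "C", "DNR", i + 1, "A", (-1.45, y, 0.0)))
        n_idx = len(atoms)
        serial += 1
        atoms.append(_toy_atom(serial, "N", "N", "DNR", i + 1, "A", (0.0, y, 0.0)))
        h_idx = len(atoms)
        serial += 1
        atoms.append(_toy_atom(serial, "H", "H", "DNR", i + 1, "A", (1.01, y, 0.0)))
        bonds += [(c_idx, n_idx), (n_idx, h_idx)]
        # chain B acceptor residue: carbonyl O = C
        o_idx = len(atoms)
        serial += 1
        atoms.append(
            _toy_atom(serial, "O", "O", "ACC", 101 + i, "B", (spec.d_da, y, 0.0))
        )
        cb_idx = len(atoms)
        serial += 1
        atoms.append(
            _toy_atom(serial, "C", "C", "ACC", 101 + i, "B", (spec.d_da + 1.23, y, 0.0))
        )
        bonds.append((o_idx, cb_idx))
        pairs.append((n_idx, h_idx, o_idx, [o_idx, cb_idx]))

    # neutral scaffold carbons give the interface a vdW footprint
    span = max(spec.n_hbond_pairs - 1, 1) * spec.pair_spacing
    for s in range(spec.n_scaffold):
        y = span * (s + 0.5) / max(spec.n_scaffold, 1)
        serial += 1
        atoms.append(_toy_atom(serial, "CB", "C", "DNR", 50 + s, "A", (-0.5, y, -3.0)))
        serial += 1
        atoms.append(
            _toy_atom(serial, "CB", "C", "ACC", 150 + s, "B", (spec.d_da + 0.5, y, -3.0))
        )

    # chain-A atoms first, preserving construction order within each chain
    order = [k for k, a in enumerate(atoms) if a.chain_id == "A"] + [
        k for k, a in enumerate(atoms) if a.chain_id == "B"
    ]
    remap = {old: new for new, old in enumerate(order)}
    atoms = [atoms[k] for k in order]
    bonds = [(remap[i], remap[j]) for i, j in bonds]
    pairs = [
        (remap[n], remap[h], remap[o], [remap[u] for u in unit])
        for n, h, o, unit in pairs
    ]
    for new_serial, a in enumerate(atoms, start=1):
        a.serial = new_serial

    system = MolecularSystem(atoms, bonds=bonds, meta=f"toy-complex|seed={spec.seed}")
    coords = system.coords
    if len(coords) > 1:
        from scipy.spatial.distance import pdist

        if float(np.min(pdist(coords))) < 0.7:
            raise ValueError("toy-complex spec places atoms on top of each other")
    system.toy_pairs = pairs  # type: ignore[attr-defined]
    return system


def make_hbond_trajectory(
    complex_system: MolecularSystem, dyn: HBondDynamicsSpec | None = None
) -> Trajectory:
    """Markov hydrogen-bond trajectory over a toy complex.

    Each bond's acceptor unit is rigidly displaced along the donor-acceptor
    axis to ``broken_da`` while the bond is in the broken state; Gaussian
    jitter of width ``sigma`` is added to every coordinate of every frame.
    Initial states are drawn from the stationary distribution.  The RNG
    seed is recorded in the trajectory metadata.
    """
    dyn = dyn or HBondDynamicsSpec()
    pairs = getattr(complex_system, "toy_pairs", None)
    if pairs is None:
        raise ValueError("make_hbond_trajectory needs a complex from make_toy_complex")
    rng = np.random.default_rng(dyn.seed)
    base = complex_system.coords
    n_bonds = len(pairs)
    on_off, off_on = dyn.rates(max(n_bonds, 1))

    if n_bonds:
        p_stat = off_on / (on_off + off_on)
        state = rng.random(n_bonds) < p_stat
    else:
        state = np.zeros(0, dtype=bool)

    # displacement vector per bond: stretch the D-A axis to broken_da
    shifts = []
    for (n_idx, _h, o_idx, _unit), _ in zip(pairs, range(n_bonds)):
        axis = base[o_idx] - base[n_idx]
        d0 = float(np.linalg.norm(axis))
        shifts.append(axis / d0 * (dyn.broken_da - d0))

    frames = []
    for _f in range(dyn.n_frames):
        coords = base.copy()
        for b, (n_idx, _h, _o, unit) in enumerate(pairs):
            if not state[b]:
                coords[unit] += shifts[b]
        if dyn.sigma > 0:
            coords = coords + rng.normal(0.0, dyn.sigma, coords.shape)
        frames.append(coords)
        if n_bonds:
            u = rng.random(n_bonds)
            next_state = np.where(state, u >= on_off, u < off_on)
            state = next_state
    return Trajectory(
        reference=complex_system,
        frames=frames,
        times=list(np.arange(dyn.n_frames, dtype=float)),
        meta={"seed": dyn.seed, "generator": "markov-hbond"},
    )


def make_mutant_pair(
    complex_system: MolecularSystem,
    spec: MutantSpec | None = None,
) -> tuple[MolecularSystem, MolecularSystem, float]:
    """Parent/mutant pair differing by a known cross-term energy offset.

    Returns ``(parent, mutant, epsilon_actual)`` where ``epsilon_actual``
    is the exact mutant-minus-parent interaction-energy difference in the
    reference frame (direct evaluation, not the requested target).
    """
    spec = spec or MutantSpec()
    parent = complex_system.copy()
    parent.toy_pairs = getattr(complex_system, "toy_pairs", None)  # type: ignore[attr-defined]
    sel_a = [i for i, a in enumerate(parent.atoms) if a.chain_id == "A"]
    sel_b = [i for i, a in enumerate(parent.atoms) if a.chain_id == "B"]
    params = ForceFieldParams.from_system(parent)
    coords = parent.coords
    charges = parent.charge_array()
    base = interaction_energy(coords, charges, params, sel_a, sel_b)

    mutant = parent.copy()
    mutant.toy_pairs = parent.toy_pairs  # type: ignore[attr-defined]
    if spec.mechanism == "charge":
        if abs(base.E_es) < 1e-6:
            raise ValueError("zero electrostatic cross term: charge scaling cannot reach epsilon")
        s = 1.0 + spec.epsilon / base.E_es
        for i in sel_b:
            mutant.atoms[i].partial_charge = parent.atoms[i].partial_charge * s
    else:
        if abs(base.E_vdW) < 1e-6:
            raise ValueError("zero vdW cross term: LJ scaling cannot reach epsilon")
        s = 1.0 + spec.epsilon / base.E_vdW
        if s <= 0:
            raise ValueError(
                f"target epsilon {spec.epsilon} unreachable by LJ scaling (scale {s:.3f} <= 0)"
            )
        for i in sel_b:
            mutant.atoms[i].lj_epsilon = parent.atoms[i].lj_epsilon * s**2
    mut_params = ForceFieldParams.from_system(mutant)
    mut_e = interaction_energy(coords, mutant.charge_array(), mut_params, sel_a, sel_b)
    eps_actual = (mut_e.E_es + mut_e.E_vdW) - (base.E_es + base.E_vdW)
    return parent, mutant, float(eps_actual)


def born_fixture(q: float = 1.0, radius: float = 2.0) -> MolecularSystem:
    """Single-ion system for validating the PB solver against the Born formula."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    atom = Atom(
        serial=1,
        name="ION",
        element="X",
        res_name="ION",
        res_seq=1,
        chain_id="A",
        coords=np.zeros(3),
        partial_charge=q,
        radius=radius,
    )
    return MolecularSystem([atom], meta=f"born-ion q={q} a={radius}")


def toy_epb_parameters(k: float = 100.0) -> EPBParameterSet:
    """Illustrative polarizable-bond parameters for the toy donor N-H groups.

    ``k`` defaults to 100 kcal mol^-1 e^-2 A^-2, which maps the ~10 kcal/mol/e
    potential differences across an interface N-H bond onto charge transfers
    of a few hundredths of an elementary charge (a physically sensible
    polarization response with a contractive self-consistent loop; much
    softer k makes |dq| exceed 1 e and the fixed point diverge).  Gas
    charges match the toy fixed-charge table.  These are NOT published
    values -- real parameter sets are user-supplied.
    """
    return EPBParameterSet(
        {
            ("DNR", "N", "H"): (k, _TOY_PARAMS[("DNR", "N")][0], _TOY_PARAMS[("DNR", "H")][0]),
        }
    )
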