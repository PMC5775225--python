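"""Single-trajectory MM/PBSA aggregation.

Per snapshot, the complex, receptor and ligand (the latter two clipped from
the complex frame) each get a gas-phase electrostatic and van der Waals
energy plus polar (PB) and nonpolar (SASA) solvation terms:

    G = E_es + G_PB + E_vdW + G_np - T S_solute

Binding free energy is the complex-minus-parts difference averaged over
snapshots, with the solute-entropy term from normal-mode analysis on a
small snapshot subset:

    dG_bind = dG_PBSA - T dS_solute

Relative binding free energies difference every component against a
reference (wild-type) system:  ddG = dG_bind(mutant) - dG_bind(WT).

In the fluctuating-charge mode, charges are re-polarized per frame and per
species before the electrostatic and PB stages; with the fixed-charge mode
the annotated charges are used throughout.  Waters and ions retained in
the structure should be excluded from the solute selections (implicit
solvent already accounts for them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MolecularSystem, Trajectory
from .epb_model import EPBParameterSet, assign_polarizable_bonds, iterate_scf
from .mm_energy import (
    ForceFieldParams,
    coulomb_energy,
    lj_energy,
    make_energy_fn,
    minimize_steepest_descent,
    normal_mode_entropy,
    numerical_hessian,
)
from .solvation import GridSpec, compute_sasa, nonpolar_energy, solve_pb
from .tables import RELATIVE_ENERGY_ROWS

__all__ = [
    "SnapshotSet",
    "SolvationConfig",
    "EnergyTable",
    "EntropyTerm",
    "BindingResult",
    "RelativeBindingTable",
    "extract_snapshots",
    "snapshot_energies",
    "entropy_term",
    "binding_free_energy",
    "relative_binding",
    "convergence_series",
]

_SPECIES = ("complex", "receptor", "ligand")
_COMPONENTS = ("E_es", "E_vdW", "G_PB", "G_np")


@dataclass(frozen=True)
class SnapshotSet:
    """Deterministic, strictly increasing frame indices chosen for analysis."""

    trajectory_id: str
    indices: tuple[int, ...]
    policy: str

    def __post_init__(self) -> None:
        idx = self.indices
        if len(idx) == 0:
            raise ValueError("empty snapshot set")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("snapshot indices must be strictly increasing")


@dataclass
class SolvationConfig:
    """PB grid plus nonpolar-model settings used by the pipeline."""

    grid: GridSpec = field(default_factory=GridSpec)
    gamma: float = 0.00542
    beta: float = 0.92
    probe: float = 1.4
    sasa_points: int = 960


@dataclass
class EnergyTable:
    """Per-snapshot, per-species MM/PBSA components (kcal/mol)."""

    data: pd.DataFrame  # columns: snapshot, species, E_es, E_vdW, G_PB, G_np, pb_converged
    charge_model: str
    pb_failures: int = 0


@dataclass
class EntropyTerm:
    """Normal-mode -T dS term (kcal/mol) averaged over an entropy subset."""

    minus_t_delta_s: float
    per_snapshot: list[float]
    T: float
    n_skipped: int = 0


@dataclass
class BindingResult:
    """Averaged binding free-energy decomposition for one system."""

    dE_es: float
    dE_vdW: float
    dG_PB: float
    dG_np: float
    minus_t_delta_s: float
    T: float
    n_snapshots: int
    n_entropy_snapshots: int
    sem: dict[str, float] = field(default_factory=dict)

    @property
    def dG_PBSA(self) -> float:
        return self.dE_es + self.dG_PB + self.dE_vdW + self.dG_np

    @property
    def dG_bind(self) -> float:
        return self.dG_PBSA + self.minus_t_delta_s


@dataclass
class RelativeBindingTable:
    """Component-wise differences against a reference system."""

    reference: str
    table: pd.DataFrame  # index RELATIVE_ENERGY_ROWS, one column per system

    def to_tsv(self, target) -> None:
        self.table.to_csv(target, sep="\t", float_format="%.4f")


def extract_snapshots(
    trajectory: Trajectory,
    n: int = 50,
    window: float | tuple[int, int] = 0.5,
) -> SnapshotSet:
    """Evenly strided snapshots from a trailing window of the trajectory.

    ``window`` is either a trailing fraction (e.g. 0.5 = last half) or an
    explicit ``(start, stop)`` frame range (stop exclusive).  Selection is
    deterministic: stride ``floor(window_size / n)`` starting at the first
    window frame.
    """
    n_frames = trajectory.n_frames
    if isinstance(window, tuple):
        start, stop = window
    else:
        if not (0.0 < window <= 1.0):
            raise ValueError("trailing fraction must be in (0, 1]")
        start = n_frames - max(int(round(window * n_frames)), 1)
        stop = n_frames
    if not (0 <= start < stop <= n_frames):
        raise ValueError(f"window [{start}, {stop}) invalid for {n_frames} frames")
    size = stop - start
    if n > size:
        raise ValueError(f"cannot take {n} snapshots from a {size}-frame window")
    stride = size // n
    indices = tuple(start + stride * k for k in range(n))
    return SnapshotSet(
        trajectory_id=str(trajectory.meta.get("seed", "trajectory")),
        indices=indices,
        policy=f"window={window!r},n={n}",
    )


def _species_systems(
    system: MolecularSystem,
    receptor_sel: Sequence[int],
    ligand_sel: Sequence[int],
) -> dict[str, tuple[MolecularSystem, list[int]]]:
    receptor_sel = list(receptor_sel)
    ligand_sel = list(ligand_sel)
    if set(receptor_sel) & set(ligand_sel):
        raise ValueError("receptor and ligand selections overlap")
    complex_sel = sorted(receptor_sel + ligand_sel)
    return {
        "complex": (system.subset(complex_sel), complex_sel),
        "receptor": (system.subset(receptor_sel), sorted(receptor_sel)),
        "ligand": (system.subset(ligand_sel), sorted(ligand_sel)),
    }


def snapshot_energies(
    trajectory: Trajectory,
    snapshots: SnapshotSet,
    receptor_sel: Sequence[int],
    ligand_sel: Sequence[int],
    charge_model: str = "fixed",
    solvation: SolvationConfig | None = None,
    epb_params: EPBParameterSet | None = None,
    max_pb_failure_fraction: float = 0.2,
) -> EnergyTable:
    """MM/PBSA components for every snapshot and species.

    ``charge_model="EPB"`` re-solves the fluctuating charges per frame and
    species (requires ``epb_params``); ``"fixed"`` uses the annotated
    charges.  PB non-convergence is recorded per snapshot; more than
    ``max_pb_failure_fraction`` of failing solves aborts the pipeline.
    """
    if charge_model not in ("fixed", "EPB"):
        raise ValueError("charge_model must be 'fixed' or 'EPB'")
    if charge_model == "EPB" and epb_params is None:
        raise ValueError("EPB mode needs an EPBParameterSet")
    solvation = solvation or SolvationConfig()
    species = _species_systems(trajectory.reference, receptor_sel, ligand_sel)
    cache = {}
    for name, (subsystem, sel) in species.items():
        params = ForceFieldParams.from_system(subsystem)
        bonds = (
            assign_polarizable_bonds(subsystem, epb_params)
            if charge_model == "EPB"
            else []
        )
        cache[name] = (subsystem, np.asarray(sel, dtype=int), params, bonds)

    rows = []
    n_solves = 0
    n_failed = 0
    for snap in snapshots.indices:
        frame = trajectory.frames[snap]
        for name in _SPECIES:
            subsystem, sel, params, bonds = cache[name]
            coords = frame[sel]
            charges = subsystem.charge_array()
            if charge_model == "EPB" and bonds:
                subsystem.set_coords(coords)
                state = iterate_scf(subsystem, charges, bonds)
                charges = state.charges
            e_es = coulomb_energy(coords, charges, params)
            e_vdw = lj_energy(coords, params)
            radii = subsystem.radius_array()
            pb = solve_pb(coords, charges, radii, solvation.grid)
            n_solves += 1
            if not pb.converged:
                n_failed += 1
            sasa = compute_sasa(coords, radii, solvation.probe, solvation.sasa_points)
            g_np = nonpolar_energy(sasa.total, solvation.gamma, solvation.beta)
            rows.append(
                {
                    "snapshot": snap,
                    "species": name,
                    "E_es": e_es,
                    "E_vdW": e_vdw,
                    "G_PB": pb.G_PB,
                    "G_np": g_np,
                    "pb_converged": pb.converged,
                }
            )
    if n_failed > max_pb_failure_fraction * n_solves:
        raise RuntimeError(
            f"PB solver failed on {n_failed}/{n_solves} species-snapshots"
        )
    return EnergyTable(
        data=pd.DataFrame(rows), charge_model=charge_model, pb_failures=n_failed
    )


def entropy_term(
    trajectory: Trajectory,
    snapshots: SnapshotSet,
    receptor_sel: Sequence[int],
    ligand_sel: Sequence[int],
    subset_n: int = 5,
    T: float = 300.0,
    minimize: bool = True,
    n_drop: int = 6,
) -> EntropyTerm:
    """-T dS_solute from normal-mode analysis on an entropy subset.

    ``subset_n`` snapshots are taken from the snapshot set by even stride.
    Per snapshot, dS = S(complex) - S(receptor) - S(ligand) from harmonic
    frequencies after a toy-scale steepest-descent minimization.  Failing
    snapshots are skipped with a count; all failing raises.
    """
    if subset_n < 1:
        raise ValueError("subset_n must be >= 1")
    if subset_n > len(snapshots.indices):
        raise ValueError("subset_n exceeds the snapshot count")
    stride = len(snapshots.indices) // subset_n
    chosen = [snapshots.indices[stride * k] for k in range(subset_n)]
    species = _species_systems(trajectory.reference, receptor_sel, ligand_sel)

    values = []
    skipped = 0
    for snap in chosen:
        frame = trajectory.frames[snap]
        try:
            s_parts = {}
            for name, (subsystem, sel) in species.items():
                coords = frame[np.asarray(sel, dtype=int)]
                # stiff harmonic terms on covalent bonds keep each species
                # internally bound during minimization / NMA
                params = ForceFieldParams.from_system(
                    subsystem, harmonic_from_topology=True
                )
                charges = subsystem.charge_array()
                fn = make_energy_fn(subsystem, charges, params)
                if minimize:
                    coords = minimize_steepest_descent(coords, fn)
                hess = numerical_hessian(coords, fn)
                res = normal_mode_entropy(
                    hess, subsystem.mass_array(), T=T, n_drop=n_drop
                )
                s_parts[name] = res.TS_solute / T
            ds = s_parts["complex"] - s_parts["receptor"] - s_parts["ligand"]
            values.append(-T * ds)
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
    if not values:
        raise RuntimeError("normal-mode entropy failed on every snapshot")
    return EntropyTerm(
        minus_t_delta_s=float(np.mean(values)),
        per_snapshot=values,
        T=T,
        n_skipped=skipped,
    )


def _delta_frame(table: EnergyTable) -> pd.DataFrame:
    """Per-snapshot complex-minus-parts differences of each component."""
    pivot = table.data.pivot_table(
        index="snapshot", columns="species", values=list(_COMPONENTS), sort=True
    )
    out = {}
    for comp in _COMPONENTS:
        out[comp] = (
            pivot[(comp, "complex")]
            - pivot[(comp, "receptor")]
            - pivot[(comp, "ligand")]
        )
    return pd.DataFrame(out)


def binding_free_energy(
    table: EnergyTable,
    entropy: EntropyTerm | float = 0.0,
    T: float = 300.0,
) -> BindingResult:
    """Average the per-snapshot differences into a :class:`BindingResult`.

    ``entropy`` is an :class:`EntropyTerm` or a plain -T dS value (0 when
    the entropy stage is skipped, e.g. for rigid synthetic systems).
    """
    deltas = _delta_frame(table)
    missing = [s for s in _SPECIES if s not in set(table.data["species"])]
    if missing:
        raise ValueError(f"energy table missing species: {missing}")
    n = len(deltas)
    means = deltas.mean()
    sem = (deltas.std(ddof=1) / np.sqrt(n)).fillna(0.0) if n > 1 else deltas.mean() * 0.0
    if isinstance(entropy, EntropyTerm):
        minus_tds = entropy.minus_t_delta_s
        n_ent = len(entropy.per_snapshot)
        T = entropy.T
    else:
        minus_tds = float(entropy)
        n_ent = 0
    return BindingResult(
        dE_es=float(means["E_es"]),
        dE_vdW=float(means["E_vdW"]),
        dG_PB=float(means["G_PB"]),
        dG_np=float(means["G_np"]),
        minus_t_delta_s=minus_tds,
        T=T,
        n_snapshots=n,
        n_entropy_snapshots=n_ent,
        sem={k: float(v) for k, v in sem.items()},
    )


def relative_binding(
    results: Mapping[str, BindingResult],
    reference: str,
) -> RelativeBindingTable:
    """Difference every component against the reference system.

    Output rows follow the standard report layout: electrostatics+PB,
    vdW+nonpolar, their sum, the entropy difference and the total.  The
    reference column is identically zero.
    """
    if reference not in results:
        raise ValueError(f"reference system {reference!r} not in results")
    ref = results[reference]
    cols = {}
    for name, res in results.items():
        es_pb = (res.dE_es + res.dG_PB) - (ref.dE_es + ref.dG_PB)
        vdw_np = (res.dE_vdW + res.dG_np) - (ref.dE_vdW + ref.dG_np)
        d_tds = res.minus_t_delta_s - ref.minus_t_delta_s
        cols[name] = [es_pb, vdw_np, es_pb + vdw_np, d_tds, es_pb + vdw_np + d_tds]
    table = pd.DataFrame(cols, index=RELATIVE_ENERGY_ROWS)
    return RelativeBindingTable(reference=reference, table=table)


def convergence_series(table: EnergyTable, step: int = 1) -> pd.DataFrame:
    """Running (cumulative-mean) dG_PBSA versus snapshot index.

    The final point equals the full-set mean by construction; a drifting
    trajectory shows up as a sloped tail.  Returns a plot-ready frame with
    columns ``snapshot`` and ``dG_PBSA_running``.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    deltas = _delta_frame(table)
    g = deltas.sum(axis=1)  # dG_PBSA per snapshot
    running = g.expanding().mean()
    picked = list(range(step - 1, len(g), step))
    if picked[-1] != len(g) - 1:
        picked.append(len(g) - 1)
    return pd.DataFrame(
        {
            "snapshot": g.index[picked],
            "dG_PBSA_running": running.iloc[picked].to_numpy(),
        }
    ).reset_index(drop=True)
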