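"""MM/PBSA aggregation: snapshots, component tables, ddG arithmetic."""

import numpy as np
import pandas as pd
import pytest

from polarbind.core import Trajectory
from polarbind.binding_pipeline import (
    BindingResult,
    EnergyTable,
    SolvationConfig,
    binding_free_energy,
    convergence_series,
    entropy_term,
    extract_snapshots,
    relative_binding,
    snapshot_energies,
)
from polarbind.mm_energy import ForceFieldParams, interaction_energy
from polarbind.solvation import GridSpec
from polarbind.synthetic_data import (
    HBondDynamicsSpec,
    ToyComplexSpec,
    make_hbond_trajectory,
    make_toy_complex,
    toy_epb_parameters,
)
from polarbind.tables import RELATIVE_ENERGY_ROWS

FAST_SOLV = SolvationConfig(
    grid=GridSpec(spacing=0.7, padding=5.0, tolerance=1e-5), sasa_points=480
)


def _chain_selections(system):
    sel_a = [i for i, a in enumerate(system.atoms) if a.chain_id == "A"]
    sel_b = [i for i, a in enumerate(system.atoms) if a.chain_id == "B"]
    return sel_a, sel_b


def _static_trajectory(system, n_frames=10):
    return Trajectory(reference=system, frames=[system.coords] * n_frames)


class TestExtractSnapshots:
    def _traj(self, n):
        system = make_toy_complex(ToyComplexSpec(n_hbond_pairs=1))
        return Trajectory(reference=system, frames=[system.coords] * n)

    def test_last_half_all_frames(self):
        snaps = extract_snapshots(self._traj(100), n=50, window=0.5)
        assert snaps.indices == tuple(range(50, 100))

    def test_stride_arithmetic(self):
        snaps = extract_snapshots(self._traj(50), n=5, window=1.0)
        assert snaps.indices == (0, 10, 20, 30, 40)

    def test_idempotence(self):
        traj = self._traj(60)
        a = extract_snapshots(traj, n=6, window=0.5)
        b = extract_snapshots(traj, n=6, window=0.5)
        assert a.indices == b.indices

    def test_explicit_range(self):
        snaps = extract_snapshots(self._traj(30), n=3, window=(10, 22))
        assert snaps.indices == (10, 14, 18)

    def test_oversized_request_errors(self):
        with pytest.raises(ValueError, match="snapshots"):
            extract_snapshots(self._traj(10), n=20, window=1.0)


class TestSnapshotEnergies:
    def test_gas_phase_cross_term_identity(self, small_complex):
        # single-trajectory protocol: dE_es / dE_vdW equal the A x B
        # interaction energies exactly (intra-species terms cancel)
        traj = _static_trajectory(small_complex, 2)
        sel_a, sel_b = _chain_selections(small_complex)
        snaps = extract_snapshots(traj, n=1, window=1.0)
        table = snapshot_energies(
            traj, snaps, sel_a, sel_b, solvation=FAST_SOLV
        )
        res = binding_free_energy(table)
        cross = interaction_energy(
            small_complex.coords,
            small_complex.charge_array(),
            ForceFieldParams.from_system(small_complex),
            sel_a,
            sel_b,
        )
        assert res.dE_es == pytest.approx(cross.E_es, abs=1e-9)
        assert res.dE_vdW == pytest.approx(cross.E_vdW, abs=1e-9)

    def test_zero_charges_zero_polar_terms(self, small_complex):
        system = small_complex.copy()
        for a in system.atoms:
            a.partial_charge = 0.0
        traj = _static_trajectory(system, 2)
        sel_a, sel_b = _chain_selections(system)
        snaps = extract_snapshots(traj, n=2, window=1.0)
        table = snapshot_energies(traj, snaps, sel_a, sel_b, solvation=FAST_SOLV)
        assert (table.data["E_es"] == 0.0).all()
        assert (table.data["G_PB"] == 0.0).all()

    def test_epb_reduces_to_fixed_in_zero_field(self):
        # single donor pair; all non-bond charges zeroed -> the bond's ESP
        # sites see no field, dq = 0, and both charge models coincide
        base = make_toy_complex(ToyComplexSpec(n_hbond_pairs=1))
        system = base.copy()
        pairs = base.toy_pairs
        keep = {pairs[0][0], pairs[0][1]}  # N and H keep their gas charges
        for i, a in enumerate(system.atoms):
            if i not in keep:
                a.partial_charge = 0.0
        system.toy_pairs = pairs
        traj = _static_trajectory(system, 1)
        sel_a, sel_b = _chain_selections(system)
        snaps = extract_snapshots(traj, n=1, window=1.0)
        fixed = snapshot_energies(traj, snaps, sel_a, sel_b, charge_model="fixed",
                                  solvation=FAST_SOLV)
        epb = snapshot_energies(traj, snaps, sel_a, sel_b, charge_model="EPB",
                                solvation=FAST_SOLV, epb_params=toy_epb_parameters())
        for col in ("E_es", "E_vdW", "G_PB", "G_np"):
            assert np.allclose(fixed.data[col], epb.data[col], atol=1e-9), col

    def test_overlapping_selections_error(self, small_complex):
        traj = _static_trajectory(small_complex, 1)
        snaps = extract_snapshots(traj, n=1, window=1.0)
        with pytest.raises(ValueError, match="overlap"):
            snapshot_energies(traj, snaps, [0, 1], [1, 2], solvation=FAST_SOLV)


def _result(**kw):
    base = dict(
        dE_es=0.0, dE_vdW=0.0, dG_PB=0.0, dG_np=0.0,
        minus_t_delta_s=0.0, T=300.0, n_snapshots=2, n_entropy_snapshots=0,
    )
    base.update(kw)
    return BindingResult(**base)


def _table_from(components_by_snapshot):
    """Build an EnergyTable where receptor/ligand are zero and the complex
    carries the requested per-snapshot component values."""
    rows = []
    for snap, comps in enumerate(components_by_snapshot):
        for species in ("complex", "receptor", "ligand"):
            vals = comps if species == "complex" else dict.fromkeys(comps, 0.0)
            rows.append({"snapshot": snap, "species": species,
                         "pb_converged": True, **vals})
    return EnergyTable(data=pd.DataFrame(rows), charge_model="fixed")


class TestBindingFreeEnergy:
    def test_hand_built_means_exact(self):
        table = _table_from([
            {"E_es": -10.0, "E_vdW": -2.0, "G_PB": 5.0, "G_np": 0.5},
            {"E_es": -12.0, "E_vdW": -4.0, "G_PB": 7.0, "G_np": 1.5},
        ])
        res = binding_free_energy(table, entropy=2.0)
        assert res.dE_es == pytest.approx(-11.0)
        assert res.dE_vdW == pytest.approx(-3.0)
        assert res.dG_PB == pytest.approx(6.0)
        assert res.dG_np == pytest.approx(1.0)
        assert res.dG_PBSA == pytest.approx(-7.0, abs=1e-6)
        assert res.dG_bind == pytest.approx(-5.0, abs=1e-6)

    def test_complex_equals_parts_gives_entropy_only(self, small_complex):
        # complex energies equal to receptor + ligand -> all deltas vanish
        rows = []
        for snap in range(2):
            for species, scale in (("complex", 2.0), ("receptor", 1.0), ("ligand", 1.0)):
                rows.append({
                    "snapshot": snap, "species": species, "pb_converged": True,
                    "E_es": -3.0 * scale, "E_vdW": -1.0 * scale,
                    "G_PB": 2.0 * scale, "G_np": 0.4 * scale,
                })
        table = EnergyTable(data=pd.DataFrame(rows), charge_model="fixed")
        res = binding_free_energy(table, entropy=3.3)
        assert res.dG_PBSA == pytest.approx(0.0, abs=1e-12)
        assert res.dG_bind == pytest.approx(3.3, abs=1e-12)

    def test_invariant_sums(self):
        res = _result(dE_es=-8.0, dE_vdW=-3.0, dG_PB=6.5, dG_np=0.8,
                      minus_t_delta_s=4.0)
        assert res.dG_PBSA == pytest.approx(-3.7, abs=1e-6)
        assert res.dG_bind == pytest.approx(res.dG_PBSA + 4.0, abs=1e-6)


class TestRelativeBinding:
    def test_identical_mutant_all_zero(self):
        wt = _result(dE_es=-5.0, dG_PB=2.0, minus_t_delta_s=1.0)
        table = relative_binding({"WT": wt, "MUT": wt}, "WT")
        assert np.allclose(table.table["MUT"], 0.0)
        assert np.allclose(table.table["WT"], 0.0)

    def test_printed_component_arithmetic_d374a(self):
        # components chosen to reproduce the published EPB/D374A column
        wt = _result()
        mut = _result(dE_es=-9.7, dE_vdW=5.7, minus_t_delta_s=-2.3)
        table = relative_binding({"WT": wt, "D374A": mut}, "WT")
        col = table.table["D374A"]
        assert col["d(dEes + dGPB)"] == pytest.approx(-9.7)
        assert col["d(dEvdW + dGnp)"] == pytest.approx(5.7)
        assert col["ddG_PBSA"] == pytest.approx(-4.0)
        assert col["ddG_bind"] == pytest.approx(-6.3)

    def test_printed_component_arithmetic_h306y(self):
        wt = _result()
        mut = _result(dE_es=-11.0, dE_vdW=10.2, minus_t_delta_s=-2.9)
        table = relative_binding({"WT": wt, "H306Y": mut}, "WT")
        col = table.table["H306Y"]
        assert col["ddG_PBSA"] == pytest.approx(-0.8, abs=1e-12)
        assert col["ddG_bind"] == pytest.approx(-3.7, abs=1e-12)

    def test_row_order_matches_report_layout(self):
        table = relative_binding({"WT": _result()}, "WT")
        assert list(table.table.index) == RELATIVE_ENERGY_ROWS

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            relative_binding({"A": _result()}, "B")


class TestConvergenceSeries:
    def test_constant_series_flat(self):
        table = _table_from([{"E_es": -5.0, "E_vdW": 0.0, "G_PB": 1.0, "G_np": 0.0}] * 6)
        series = convergence_series(table)
        assert np.allclose(series["dG_PBSA_running"], -4.0)

    def test_final_point_is_full_mean(self):
        comps = [
            {"E_es": e, "E_vdW": 0.0, "G_PB": 0.0, "G_np": 0.0}
            for e in (-2.0, -4.0, -9.0, -1.0)
        ]
        table = _table_from(comps)
        series = convergence_series(table, step=2)
        assert series["dG_PBSA_running"].iloc[-1] == pytest.approx(-4.0)

    def test_trend_recovery(self):
        # linear drift in E_es -> running mean strictly decreasing
        comps = [
            {"E_es": -1.0 * k, "E_vdW": 0.0, "G_PB": 0.0, "G_np": 0.0}
            for k in range(8)
        ]
        series = convergence_series(_table_from(comps))
        diffs = np.diff(series["dG_PBSA_running"])
        assert np.all(diffs < 0)


class TestEntropyTerm:
    def test_subset_stride(self, small_complex):
        traj = _static_trajectory(small_complex, 50)
        sel_a, sel_b = _chain_selections(small_complex)
        snaps = extract_snapshots(traj, n=50, window=1.0)
        term = entropy_term(traj, snaps, sel_a, sel_b, subset_n=5, minimize=False)
        # 5 evenly strided snapshots of the 50-snapshot set
        assert len(term.per_snapshot) + term.n_skipped == 5

    def test_separated_halves_cancel(self):
        # two bonded triatomic units 40 A apart with no charges or LJ: the
        # complex Hessian is exactly block diagonal, its modes are the union
        # of the part modes, so dS = 0 and the -T dS term vanishes
        from conftest import make_system

        def unit(chain, res, x0):
            return [
                ("C1", "C", "UNK", res, chain, (x0, 0.0, 0.0)),
                ("O1", "O", "UNK", res, chain, (x0 + 1.3, 0.0, 0.0)),
                ("N1", "N", "UNK", res, chain, (x0, 1.4, 0.0)),
            ]

        system = make_system(
            unit("A", 1, 0.0) + unit("B", 2, 40.0),
            bonds=[(0, 1), (0, 2), (3, 4), (3, 5)],
        )
        traj = _static_trajectory(system, 2)
        snaps = extract_snapshots(traj, n=2, window=1.0)
        term = entropy_term(traj, snaps, [0, 1, 2], [3, 4, 5], subset_n=1,
                            minimize=False)
        assert term.minus_t_delta_s == pytest.approx(0.0, abs=1e-6)
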