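"""Fluctuating-charge (polarizable bond) model: closed form vs oracles."""

import io

import numpy as np
import pytest

from polarbind.constants import KE
from polarbind.core import MolecularSystem
from polarbind.epb_model import (
    ChargeState,
    EPBParameterSet,
    ESPField,
    PolarizableBond,
    apply_polarization,
    assign_polarizable_bonds,
    compute_esp,
    epb_self_energy,
    iterate_scf,
    solve_delta_q,
)
from polarbind.mm_energy import coulomb_energy

from conftest import make_system


def eq5_energy(dq, phi_s, phi_h, qs_gas, qh_gas, d, k):
    """Independent oracle: the quadratic bond energy (reference E0 dropped)."""
    return k * (dq * d) ** 2 + (qs_gas + dq) * phi_s + (qh_gas - dq) * phi_h


class TestComputeEsp:
    def test_unit_charge_at_one_angstrom(self):
        system = make_system(
            [
                ("X1", "C", "TST", 1, "A", (0.0, 0.0, 0.0), {"partial_charge": 0.0}),
                ("X2", "C", "TST", 2, "A", (1.0, 0.0, 0.0), {"partial_charge": 1.0}),
            ]
        )
        esp = compute_esp(system, system.charge_array(), sites=[0])
        assert esp.phi(0) == pytest.approx(KE)

    def test_no_sources_in_cutoff(self):
        system = make_system(
            [
                ("X1", "C", "TST", 1, "A", (0.0, 0.0, 0.0), {"partial_charge": 0.0}),
                ("X2", "C", "TST", 2, "A", (50.0, 0.0, 0.0), {"partial_charge": 1.0}),
            ]
        )
        esp = compute_esp(system, system.charge_array(), sites=[0], cutoff=12.0)
        assert esp.phi(0) == 0.0

    def test_against_double_loop_oracle(self, rng):
        n = 10
        coords = rng.uniform(-5, 5, size=(n, 3))
        charges = rng.uniform(-1, 1, size=n)
        atoms = [
            ("A%d" % i, "C", "TST", i + 1, "A", coords[i], {"partial_charge": charges[i]})
            for i in range(n)
        ]
        system = make_system(atoms)
        esp = compute_esp(system, charges, sites=list(range(n)))
        for i in range(n):
            expected = sum(
                KE * charges[j] / np.linalg.norm(coords[j] - coords[i])
                for j in range(n)
                if j != i
            )
            assert esp.phi(i) == pytest.approx(expected, rel=1e-8)

    def test_bonded_neighbors_excluded(self):
        # chain 0-1-2: site 0 must not see atoms 1 (1-2) or 2 (1-3), only 3
        system = make_system(
            [
                ("A0", "C", "TST", 1, "A", (0.0, 0.0, 0.0), {"partial_charge": 0.0}),
                ("A1", "C", "TST", 2, "A", (1.5, 0.0, 0.0), {"partial_charge": 1.0}),
                ("A2", "C", "TST", 3, "A", (3.0, 0.0, 0.0), {"partial_charge": 1.0}),
                ("A3", "C", "TST", 4, "A", (5.0, 0.0, 0.0), {"partial_charge": 1.0}),
            ],
            bonds=[(0, 1), (1, 2), (2, 3)],
        )
        esp = compute_esp(system, system.charge_array(), sites=[0])
        assert esp.phi(0) == pytest.approx(KE / 5.0)

    def test_coincident_atoms_error(self):
        system = make_system(
            [
                ("A0", "C", "TST", 1, "A", (0.0, 0.0, 0.0), {"partial_charge": 1.0}),
                ("A1", "C", "TST", 2, "A", (0.0, 0.0, 0.0), {"partial_charge": 1.0}),
            ]
        )
        with pytest.raises(ValueError, match="coincident"):
            compute_esp(system, system.charge_array(), sites=[0])


class TestSolveDeltaQ:
    def test_symmetric_field_gives_zero(self):
        assert solve_delta_q(3.3, 3.3, 1.0, 0.7) == 0.0

    def test_unit_case_matches_scan_oracle(self):
        dq = solve_delta_q(0.0, 2.0, 1.0, 1.0)
        assert dq == pytest.approx(1.0)
        grid = np.arange(-2.0, 2.0, 1e-4)
        energies = [eq5_energy(g, 0.0, 2.0, -0.3, 0.3, 1.0, 1.0) for g in grid]
        assert grid[int(np.argmin(energies))] == pytest.approx(dq, abs=1e-4)

    def test_random_draws_match_minimization(self, rng):
        for _ in range(100):
            phi_s, phi_h = rng.uniform(-5, 5, size=2)
            d = rng.uniform(0.8, 1.5)
            k = rng.uniform(0.3, 2.0)
            qs, qh = rng.uniform(-0.6, 0.6, size=2)
            dq = solve_delta_q(phi_s, phi_h, d, k)
            grid = dq + np.arange(-0.05, 0.05, 1e-4)
            energies = eq5_energy(grid, phi_s, phi_h, qs, qh, d, k)
            best = grid[int(np.argmin(energies))]
            assert abs(best - dq) <= 1e-4

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            solve_delta_q(0.0, 1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            solve_delta_q(0.0, 1.0, 1.0, 0.0)


class TestSelfEnergy:
    def test_zero_transfer(self):
        assert epb_self_energy(0.0, 1.0, 1.0) == 0.0

    def test_unit_case(self):
        assert epb_self_energy(1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_optimum_energy_and_optimality(self):
        # phi_s=0, phi_h=1, gas charges -/+0.3, d=k=1: optimum dq=0.5, E=0.05
        dq = solve_delta_q(0.0, 1.0, 1.0, 1.0)
        assert dq == pytest.approx(0.5)
        e_opt = eq5_energy(dq, 0.0, 1.0, -0.3, 0.3, 1.0, 1.0)
        assert e_opt == pytest.approx(0.05)
        scan = np.arange(-2.0, 2.0, 1e-3)
        assert np.all(e_opt <= eq5_energy(scan, 0.0, 1.0, -0.3, 0.3, 1.0, 1.0) + 1e-12)

    def test_optimality_random_draws(self, rng):
        for _ in range(20):
            phi_s, phi_h = rng.uniform(-5, 5, size=2)
            d = rng.uniform(0.8, 1.5)
            k = rng.uniform(0.3, 2.0)
            qs, qh = rng.uniform(-0.6, 0.6, size=2)
            dq = solve_delta_q(phi_s, phi_h, d, k)
            e_opt = eq5_energy(dq, phi_s, phi_h, qs, qh, d, k)
            perturbed = dq + rng.uniform(-1, 1, size=1000)
            assert np.all(
                e_opt <= eq5_energy(perturbed, phi_s, phi_h, qs, qh, d, k) + 1e-12
            )


def _single_bond_system(extra_atoms=(), extra_bonds=()):
    specs = [
        ("N", "N", "DNR", 1, "A", (0.0, 0.0, 0.0), {"partial_charge": -0.3}),
        ("H", "H", "DNR", 1, "A", (1.0, 0.0, 0.0), {"partial_charge": 0.3}),
    ] + list(extra_atoms)
    return make_system(specs, bonds=[(0, 1)] + list(extra_bonds))


class TestApplyPolarization:
    def test_zero_field_keeps_gas_charges(self):
        system = _single_bond_system()
        bond = PolarizableBond(0, 1, -0.3, 0.3, 1.0, 0.5)
        esp = ESPField({0: 0.0, 1: 0.0})
        state = apply_polarization(system, [bond], esp)
        assert state.charges[0] == pytest.approx(-0.3)
        assert state.charges[1] == pytest.approx(0.3)
        assert state.delta_q[(0, 1)] == 0.0

    def test_transfer_arithmetic(self):
        system = _single_bond_system()
        bond = PolarizableBond(0, 1, -0.3, 0.3, 1.0, 0.5)
        # dq = (phi_h - phi_s) / (2 d^2 k) = 0.2 for phi_h - phi_s = 0.2
        esp = ESPField({0: 0.0, 1: 0.2})
        state = apply_polarization(system, [bond], esp)
        assert state.delta_q[(0, 1)] == pytest.approx(0.2)
        assert state.charges[0] == pytest.approx(-0.1)
        assert state.charges[1] == pytest.approx(0.1)
        assert state.delta_mu[(0, 1)] == pytest.approx(0.2)

    def test_charge_conservation_random_fields(self, rng):
        system = _single_bond_system(
            extra_atoms=[
                ("O", "O", "ACC", 2, "B", (4.0, 1.0, 0.0), {"partial_charge": -0.5}),
            ]
        )
        bond = PolarizableBond(0, 1, -0.3, 0.3, 1.0, 0.5)
        total_before = float(np.sum(system.charge_array()))
        for _ in range(50):
            esp = ESPField({0: rng.uniform(-10, 10), 1: rng.uniform(-10, 10)})
            state = apply_polarization(system, [bond], esp)
            assert state.total_charge == pytest.approx(total_before, abs=1e-12)

    def test_shared_atom_rejected(self):
        system = _single_bond_system(
            extra_atoms=[("H2", "H", "DNR", 1, "A", (0.0, 1.0, 0.0),
                          {"partial_charge": 0.3})],
            extra_bonds=[(0, 2)],
        )
        bonds = [
            PolarizableBond(0, 1, -0.3, 0.3, 1.0, 0.5),
            PolarizableBond(0, 2, -0.3, 0.3, 1.0, 0.5),
        ]
        esp = ESPField({0: 0.0, 1: 0.0, 2: 0.0})
        with pytest.raises(ValueError, match="multiple"):
            apply_polarization(system, bonds, esp)
        # split representation is allowed explicitly
        state = apply_polarization(system, bonds, esp, allow_shared_heavy=True)
        assert isinstance(state, ChargeState)


class TestIterateScf:
    def test_single_bond_converges_immediately(self):
        system = _single_bond_system(
            extra_atoms=[
                ("O", "O", "ACC", 2, "B", (3.0, 0.0, 0.0), {"partial_charge": -0.8}),
            ]
        )
        bond = PolarizableBond(0, 1, -0.3, 0.3, 1.0, 0.5)
        state = iterate_scf(system, system.charge_array(), [bond], tol=1e-8)
        assert state.converged
        assert state.iterations <= 2  # dq fixed after the first update
        # matches the direct closed-form solution from the fixed external field
        esp = compute_esp(system, system.charge_array(), sites=[0, 1])
        expected = solve_delta_q(esp.phi(0), esp.phi(1), 1.0, 0.5)
        assert state.delta_q[(0, 1)] == pytest.approx(expected, abs=1e-8)

    def test_distant_bonds_decouple_under_cutoff(self):
        near = [
            ("O", "O", "ACC", 3, "B", (3.0, 0.0, 0.0), {"partial_charge": -0.8}),
        ]
        far = [
            ("N2", "N", "DNR", 2, "A", (50.0, 0.0, 0.0), {"partial_charge": -0.3}),
            ("H2", "H", "DNR", 2, "A", (51.0, 0.0, 0.0), {"partial_charge": 0.3}),
            ("O2", "O", "ACC", 4, "B", (53.5, 0.0, 0.0), {"partial_charge": -0.6}),
        ]
        combined = make_system(
            [
                ("N", "N", "DNR", 1, "A", (0.0, 0.0, 0.0), {"partial_charge": -0.3}),
                ("H", "H", "DNR", 1, "A", (1.0, 0.0, 0.0), {"partial_charge": 0.3}),
            ] + near + far,
            bonds=[(0, 1), (3, 4)],
        )
        bonds = [
            PolarizableBond(0, 1, -0.3, 0.3, 1.0, 0.5),
            PolarizableBond(3, 4, -0.3, 0.3, 1.0, 0.5),
        ]
        state = iterate_scf(combined, combined.charge_array(), bonds, cutoff=12.0)

        solo_a = _single_bond_system(extra_atoms=near)
        state_a = iterate_scf(
            solo_a, solo_a.charge_array(),
            [PolarizableBond(0, 1, -0.3, 0.3, 1.0, 0.5)], cutoff=12.0,
        )
        assert state.delta_q[(0, 1)] == pytest.approx(
            state_a.delta_q[(0, 1)], abs=1e-10
        )

    def test_four_bond_toy_fixed_point(self, toy_complex):
        from polarbind.synthetic_data import toy_epb_parameters

        params = toy_epb_parameters()
        bonds = assign_polarizable_bonds(toy_complex, params)[:4]
        assert len(bonds) == 4
        state = iterate_scf(
            toy_complex, toy_complex.charge_array(), bonds, tol=1e-6, max_iter=50
        )
        assert state.converged
        assert state.iterations <= 50
        # one extra iteration moves nothing beyond tol
        state2 = iterate_scf(toy_complex, state.charges, bonds, tol=1e-6, max_iter=1)
        for key in state.delta_q:
            assert abs(state2.delta_q[key] - state.delta_q[key]) < 1e-6

    def test_linear_response(self):
        base = _single_bond_system(
            extra_atoms=[
                ("O", "O", "ACC", 2, "B", (3.0, 0.0, 0.0), {"partial_charge": -0.8}),
            ]
        )
        bond = PolarizableBond(0, 1, -0.3, 0.3, 1.0, 0.5)
        dq1 = iterate_scf(base, base.charge_array(), [bond]).delta_q[(0, 1)]
        scaled = base.copy()
        scaled.atoms[2].partial_charge = -0.8 * 2.0
        # the bond's own gas charges stay; only the external source scales
        dq_scaled_external = solve_delta_q(
            *(
                compute_esp(scaled, scaled.charge_array(), sites=[0, 1]).phi(i)
                for i in (0, 1)
            ),
            1.0,
            0.5,
        )
        assert dq_scaled_external == pytest.approx(2.0 * dq1, rel=1e-10)

    def test_zero_field_epb_equals_fixed_coulomb(self, toy_complex):
        # strip all charges except one bond's gas pair -> its ESP sites see
        # nothing (partner and 1-2/1-3 are excluded), so dq = 0 and the EPB
        # electrostatic energy equals the fixed-charge Coulomb energy
        system = toy_complex.copy()
        pairs = toy_complex.toy_pairs
        n_idx, h_idx = pairs[0][0], pairs[0][1]
        for i, a in enumerate(system.atoms):
            if i not in (n_idx, h_idx):
                a.partial_charge = 0.0
        bond = PolarizableBond(n_idx, h_idx, -0.52, 0.31, 1.01, 0.5)
        state = iterate_scf(system, system.charge_array(), [bond])
        assert state.delta_q[(n_idx, h_idx)] == 0.0
        from polarbind.mm_energy import ForceFieldParams

        params = ForceFieldParams.from_system(system)
        e_fixed = coulomb_energy(system.coords, system.charge_array(), params)
        e_epb = coulomb_energy(system.coords, state.charges, params)
        assert e_epb == pytest.approx(e_fixed, abs=1e-12)


class TestAssignAndParams:
    def test_parameter_file_round_trip(self):
        pset = EPBParameterSet({("DNR", "N", "H"): (0.5, -0.52, 0.31)})
        buf = io.StringIO()
        pset.to_file(buf)
        buf.seek(0)
        back = EPBParameterSet.from_file(buf)
        assert back.lookup("DNR", "N", "H") == pytest.approx((0.5, -0.52, 0.31))

    def test_assign_matches_toy_bonds(self, toy_complex):
        from polarbind.synthetic_data import toy_epb_parameters

        bonds = assign_polarizable_bonds(toy_complex, toy_epb_parameters())
        assert len(bonds) == 5  # one N-H per hydrogen-bond pair
        for b in bonds:
            assert toy_complex.atoms[b.heavy_index].name == "N"
            assert toy_complex.atoms[b.h_index].name == "H"
            assert b.d == pytest.approx(1.01, abs=1e-9)

    def test_invalid_bond_parameters(self):
        with pytest.raises(ValueError):
            PolarizableBond(0, 0, -0.3, 0.3, 1.0, 0.5)
        with pytest.raises(ValueError):
            PolarizableBond(0, 1, -0.3, 0.3, 0.0, 0.5)
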