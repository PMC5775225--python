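# polarbind

Analysis toolkit for protein–protein binding with a fluctuating-charge
(effective polarizable bond, EPB) electrostatic model: interface
hydrogen-bond occupancy statistics, MM/PBSA binding free-energy
decomposition with relative ΔΔG between mutants and a wild type, and
buried-surface-area analysis of structures and multi-model PDB
trajectories.

## Why

Fixed-point-charge force fields underpolarize protein–protein interfaces:
in simulations of the PCSK9ΔC–EGFA complex and its gain-of-function
mutants, interface hydrogen bonds that are present in the crystal
structures break, and relative binding affinities come out wrong.
Allowing the partial charges of polar X–H bonds to respond to their
electrostatic environment stabilizes those interactions.  This package
re-implements that analysis chain as a reusable library: it does not run
molecular dynamics itself, but evaluates structures and trajectories
(real or synthetic) with either fixed or fluctuating charges.

## The models

**Effective polarizable bond.**  A polar bond X–H with gas-phase charges
$q_X^{gas}, q_H^{gas}$, length $d$ and polarization force constant $k$
responds to the site potentials $\Phi_X, \Phi_H$ by transferring charge

$$\Delta q = \frac{\Phi_H - \Phi_X}{2 d^2 k},$$

the closed-form minimizer of
$E = k(\Delta q\, d)^2 + (q_X^{gas}+\Delta q)\Phi_X + (q_H^{gas}-\Delta q)\Phi_H$.
Final charges are $q_X = q_X^{gas} + \Delta q$ and $q_H = q_H^{gas} - \Delta q$
(total bond charge conserved exactly); a fixed-point loop iterates
potential evaluation and charge update to self-consistency.

**MM/PBSA.**  Per snapshot and species (complex, receptor, ligand clipped
from the same frame — the single-trajectory protocol),

$$G = E_{es} + G_{PB} + E_{vdW} + G_{np} - T S_{solute},$$

with Coulomb and 12-6 Lennard-Jones gas-phase terms (AMBER conventions),
polar solvation from a finite-difference linearized Poisson–Boltzmann
solver (red–black SOR, analytic Dirichlet boundary, vacuum solve on the
identical grid to cancel grid self-energy), nonpolar solvation
$G_{np} = \gamma \cdot \mathrm{SASA} + \beta$, and a vibrational
normal-mode entropy term.  Binding and relative binding energies are

$$\Delta G_{bind} = G_{complex} - G_{receptor} - G_{ligand}, \qquad
\Delta\Delta G = \Delta G_{bind}(\text{mutant}) - \Delta G_{bind}(\text{WT}).$$

**Hydrogen bonds.**  A donor–acceptor pair counts as bonded in a frame
when the heavy-atom distance is < 4 Å and the D–H···A angle (vertex at H)
exceeds 90°; occupancy is the percentage of frames a bond is present and
the mean inter-protein hydrogen-bond (IPHB) count is the per-frame
average over cross-chain bonds.

## Worked example

```python
from polarbind import (
    ToyComplexSpec, HBondDynamicsSpec, make_toy_complex, make_hbond_trajectory,
    occupancy, mean_iphb,
)

complex_ = make_toy_complex(ToyComplexSpec(n_hbond_pairs=5, seed=0))
traj = make_hbond_trajectory(
    complex_,
    HBondDynamicsSpec(p_on_off=0.05, p_off_on=0.20, n_frames=500, seed=0),
)
for rec in occupancy(traj):
    print(f"{rec.donor:>8} -> {rec.acceptor:<8} {rec.occupancy:5.1f} %")
print(f"mean inter-protein H-bonds per frame: {mean_iphb(traj):.2f}")
```

prints

```
     1@N -> 101@O     86.4 %
     2@N -> 102@O     86.2 %
     5@N -> 105@O     76.2 %
     3@N -> 103@O     75.6 %
     4@N -> 104@O     71.2 %
mean inter-protein H-bonds per frame: 3.96
```

Each interface bond follows a two-state Markov chain with stationary
formed probability 0.2/(0.05+0.2) = 0.8, so occupancies scatter around
80 % and the mean IPHB count around 5 × 0.8 = 4.  The same analyses are
available from the shell:

```sh
polarbind simulate --n-pairs 5 --frames 500 --p-stationary 0.8 --outdir sim
polarbind hbonds sim/trajectory.pdb --outdir hb
polarbind mmpbsa --system WT=sim/trajectory.pdb --params sim/params.tsv \
    --receptor-chains A --ligand-chains B --reference WT --outdir mm
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch — the Born-ion
validation of the PB solver, the self-consistent fluctuating-charge
solve on the synthetic interface, Markov hydrogen-bond occupancy
recovery, and the end-to-end relative binding free energy of a synthetic
mutant pair with a known injected interaction offset — printing each
result, and writes the results JSON to `--out`.

## Layout

| module | contents |
| --- | --- |
| `polarbind.core` | atoms, systems, trajectories, selections |
| `polarbind.structure_io` | PDB/trajectory I/O, preparation rules, disulfides, parameter tables |
| `polarbind.epb_model` | polarizable-bond charges: ESP, closed-form Δq, SCF |
| `polarbind.mm_energy` | Coulomb/LJ/bonded energies, Hessian, normal-mode entropy |
| `polarbind.solvation` | finite-difference PB, Shrake–Rupley SASA, buried surface area |
| `polarbind.interface_analysis` | hydrogen-bond criterion, occupancy, IPHB statistics |
| `polarbind.binding_pipeline` | snapshot extraction, MM/PBSA tables, ΔΔG, convergence series |
| `polarbind.synthetic_data` | toy complexes, Markov trajectories, mutant pairs, packaged reference tables |
| `polarbind.cli` | `polarbind` console entry point |

See `docs/methods.md` for the modelling assumptions, numerical choices
and known limitations.
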