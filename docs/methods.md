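# Methods

This note records the models implemented by `polarbind`, the assumptions
behind them, the defaults that matter, and what the synthetic fixtures do
and do not establish.  Units throughout: Å, kcal/mol, elementary charges
(e), amu, K.  The Coulomb constant is fixed at
k_e = 332.0636 kcal·Å·mol⁻¹·e⁻².

## Fluctuating charges (effective polarizable bond)

A designated polar bond X–H carries gas-phase reference charges
(q_X^gas, q_H^gas), a bond length d taken from the reference geometry,
and a polarization force constant k (kcal·mol⁻¹·e⁻²·Å⁻²).  Writing the
bond energy in an external site potential (Φ_X, Φ_H) as

    E = E0 + k (Δq·d)² + (q_X^gas + Δq) Φ_X + (q_H^gas − Δq) Φ_H

the optimal charge transfer is the closed form
Δq = (Φ_H − Φ_X) / (2 d² k), the induced dipole change is Δμ = Δq·d, and
the polarization self-energy is k(Δμ)².  E0 is an additive constant and
dropped.  Sign convention: the heavy atom gains +Δq, the hydrogen loses
it, so the bond's total charge is conserved identically.

Site potentials are bare Coulomb sums over the other point charges
(vacuum dielectric — solvent screening belongs to the PB stage), with the
site itself, its bonded 1-2 and 1-3 neighbours excluded and 1-4 partners
included unscaled.  No cutoff by default for single structures; a 12 Å
cutoff is a reasonable speed choice for long trajectories and is
configurable.  Self-consistency is a plain fixed-point iteration
(ESP → Δq → charges → ESP …) terminated when no bond's Δq moves by more
than the tolerance (default 10⁻⁶ e); a bond whose sites see only fixed
charges converges in one update.  Non-convergence is flagged on the
result, not raised.

A polar group with several hydrogens on one heavy atom (–NH₂) may be
represented as independent bonds sharing the heavy atom, whose gas charge
is split evenly across them; this representation must be requested
explicitly (`allow_shared_heavy` / `split_shared_heavy`), otherwise a
shared atom is a configuration error.

**On the magnitude of k.**  Interface site-potential differences are of
order 10 kcal·mol⁻¹·e⁻¹, so k of order 100 kcal·mol⁻¹·e⁻²·Å⁻² yields
charge transfers of a few hundredths of an e and a contractive SCF.
Much softer values (k ≲ 1) produce |Δq| > 1 e and a divergent iteration;
the illustrative parameter set shipped for the toy systems therefore
uses k = 100.  These values are placeholders: production parameter sets
fitted to quantum-chemical reference data must be supplied by the user
(text table `RESNAME HEAVY_ATOM H_ATOM q_heavy_gas q_h_gas k`).

## Gas-phase molecular mechanics

Pairwise Coulomb and 12-6 Lennard-Jones in r_min form,
ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶], with Lorentz–Berthelot combining
(ε_ij geometric, r_min,ij = r_min,i/2 + r_min,j/2).  In full-system
scope, 1-2/1-3 pairs are excluded and 1-4 pairs scaled (electrostatics
×1/1.2, LJ ×1/2, AMBER defaults, configurable); cross-scope (A×B)
includes every pair unscaled.  Toy bonded terms are harmonic,
E = k_b(r−r₀)² and k_θ(θ−θ₀)², so a bond's curvature is 2k_b.
Interaction energies are cross-pair sums and satisfy the additivity
identity E(A∪B) = E(A) + E(B) + E_cross term by term.

## Normal-mode entropy

Hessians are central-difference numerical second derivatives (step
10⁻⁴ Å, symmetrized).  After mass weighting, eigenvalues map to
wavenumbers via ν̃ = 108.591·√λ cm⁻¹ (λ in kcal·mol⁻¹·Å⁻²·amu⁻¹).  The
six smallest-|λ| modes are dropped (rigid body, nonlinear case; pass 5
for linear toys).  Each remaining real mode contributes

    S = R [ x/(eˣ−1) − ln(1−e⁻ˣ) ],   x = h c ν̃ / (k_B T)

and the result is T·ΣS at T = 300 K by default.  Two further exclusions
are applied, both counted and flagged: imaginary modes, and near-zero
modes with |ν̃| < 1 cm⁻¹.  The latter matters because the harmonic
entropy diverges as ν̃ → 0: the relative rigid-body modes of a
far-separated complex, or the floppy torsions of toy topologies without
angle terms, would otherwise dominate the sum with unphysical values.
With the near-zero exclusion, a complex of two non-interacting units has
exactly the vibrational entropy of its parts and ΔS = 0.

Entropy is vibrational-only: translational and rotational contributions
are omitted on the grounds that they cancel in mutant-minus-wild-type
comparisons of similar-size complexes.  A consequence worth stating: for
a toy dimer whose only binding effect is one extra soft inter-chain
mode, S_vib *increases* on binding and −TΔS is negative; the familiar
positive −TΔS of rigid-body association comes from the omitted
translational/rotational loss.  ΔΔ comparisons are unaffected.

A minimal backtracking steepest-descent minimizer (RMS gradient
< 10⁻⁴ kcal·mol⁻¹·Å⁻¹) prepares toy structures for NMA; during the
entropy stage every covalent bond also receives a stiff harmonic term
(300 kcal·mol⁻¹·Å⁻², r₀ from the reference geometry) so each species is
internally bound.

## Poisson–Boltzmann solvation

Linearized PB on a cubic grid: ∇·(ε∇φ) − ε_out κ² φ = −4π k_e ρ, solved
twice — once with the dielectric map and optional Debye screening, once
in uniform ε_in — and combined as
G_PB = ½ Σ q_i [φ_solv(r_i) − φ_vac(r_i)], which cancels the grid
self-energy because both solves share the grid, the charge spreading and
the interpolation stencil.

Numerical choices:

- Grid: default spacing 0.5 Å (0.4 Å for validation-grade runs; 0.6–0.7
  for pipeline throughput), padding 8 Å beyond the solute vdW extent
  (must be ≥ 2 spacings).  Charges spread and potentials read back by
  trilinear interpolation.
- Dielectric boundary: the van der Waals surface (ε_in inside any atom
  sphere, default Bondi radii; ε_in = 1, ε_out = 80).  No reentrant /
  molecular surface — a known difference from production PB codes that
  mostly cancels in ΔΔ comparisons.
- Face dielectrics are the harmonic mean of ε sampled at nine points
  along each inter-node segment.  A sharp midpoint assignment leaves
  O(h) boundary error (≈ 4 % on the Born ion at 0.4 Å and non-monotone
  under refinement); harmonic smoothing restores near-quadratic
  convergence (measured Born errors 1.7 % / 0.5 % / 0.2 % at
  0.8 / 0.4 / 0.25 Å).
- Boundary condition: analytic Debye–Hückel (Coulombic at zero ionic
  strength) per face, per solve dielectric.
- Iteration: red–black SOR, ω = 1.8, relative residual < 10⁻⁶ (10⁻⁵ in
  the pipeline), at most 10⁴ sweeps; non-convergence is flagged, and the
  pipeline aborts only if > 20 % of its solves fail.
- Ionic strength default 0 M; κ² follows from the Bjerrum length at the
  solver temperature for a 1:1 salt.

Validation anchor: the Born ion, G = −(k_e/2)(q²/a)(1/ε_in − 1/ε_out),
−81.98 kcal/mol for q = 1 e, a = 2 Å, ε 1→80.

## Surface areas

Shrake–Rupley sampling with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å, Bondi radii).  Buried surface area of
a complex is SASA(A) + SASA(B) − SASA(A∪B) ("total" convention;
"half" divides by two).  Because all three terms use the same point set,
BSA ≥ 0 holds exactly, not just statistically.  Published interface
areas for the wild-type and mutant complexes are packaged as reference
fixtures; whether they follow the total or per-side convention is not
stated in the source, so both conventions are exposed and neither is
asserted.

## Hydrogen bonds and occupancy

Criterion: donor-heavy to acceptor-heavy distance < 4.0 Å (not H···A)
and D–H···A angle with vertex at the hydrogen strictly > 90°.  The
source text's angle phrase is ambiguous; vertex-at-H is the permissive
reading consistent with a 4 Å heavy-atom cutoff, and a vertex-at-donor
variant is available behind a flag.  Donors are N/O/S atoms with a
bonded hydrogen (one donor entry per H; attachment from explicit bonds,
else a 1.25 Å distance rule); acceptors are all O and S atoms plus
nitrogens that carry no hydrogen or appear in a small residue template
(free His ring nitrogens).  A donor hydrogen may bond several acceptors.

Occupancy = 100 × (frames present) / (all frames); the denominator is
always the full frame count, which the trajectory roster invariant makes
safe.  The mean IPHB count equals the sum of occupancies / 100 — the
identity used to interpret fractional published per-trajectory bond
counts (e.g. 5.25 = Σ occ/100 for the wild type).  Crystal-structure
bond counts depend on the protonation source; reports record the
H-placement provenance.  A minimal geometric H placement (N–H 1.01 Å,
O–H 0.96 Å, anti to the heavy-neighbour centroid) is provided for
crystal inputs; it is not a protonation engine.

## MM/PBSA aggregation

Single-trajectory protocol: receptor and ligand coordinates are clipped
from the complex frame, so gas-phase ΔE_es and ΔE_vdW reduce exactly to
cross-term interaction energies (intra-species contributions cancel) in
fixed-charge mode.  In EPB mode the charges are re-solved per frame and
per species before the electrostatic and PB stages, so desolvation and
polarization responses differ between complex and parts — that
difference is the polarization contribution to binding.  Waters and ions
retained during structure preparation are excluded from the solute
selections (the implicit solvent already accounts for them).

Snapshots: n evenly strided frames (stride = floor(window/n)) from a
trailing window (default: 50 from the last half).  The entropy stage
uses an evenly strided subset (default 5 of 50).  Standard errors over
snapshots are reported as SEM.  The convergence diagnostic is the
cumulative-mean ΔG_PBSA per snapshot, whose final point equals the
full-set mean by construction.

## Synthetic data: what it emulates, what it does not

The toy complex is a caricature of an antiparallel β-sheet interface:
chain A carries amide-like C–N–H donors, chain B carbonyl-like C=O
acceptors, collinear at a chosen D–A distance (default 2.9 Å), stacked
6 Å apart, plus neutral scaffold carbons for a vdW footprint.  Charges
are AMBER-like and per-residue neutral; donor-N/acceptor-O r_min/2 are
set to 1.45 Å so the hydrogen-bond contact sits at the LJ minimum and
the interface vdW term is attractive — a prerequisite for injecting
negative LJ-scaled energy offsets.

Bond dynamics are per-bond two-state Markov chains (default
p_on→off = 0.05, p_off→on = 0.20, stationary 0.8, matching the
high-occupancy interface bonds being emulated); the broken state rigidly
displaces the acceptor unit along the D–A axis to 5 Å (clearly outside
the 4 Å criterion), and Gaussian jitter (σ = 0.05 Å, hard-capped at
0.15 Å so formed bonds cannot break spuriously) models thermal noise.
Initial states are drawn from the stationary distribution; one seeded
generator per trajectory, recorded in its metadata.

Mutants scale either all ligand charges (exact gas-phase offset, but the
PB term responds physically) or all ligand LJ well depths (solvation
terms untouched, so the full-pipeline ΔΔG equals the injected offset up
to exactly cancelling PB terms).  End-to-end recovery tests use the LJ
mechanism for that reason; the charge mechanism is verified against its
analytic gas-phase offset directly.

A green synthetic test therefore establishes: geometric bookkeeping,
estimator correctness (occupancy → stationary probability, ΔΔG →
injected offset), conservation laws and solver accuracy on closed-form
anchors.  It does not establish force-field realism, conformational
sampling, or agreement with the published per-complex energies — those
depend on the original explicit-solvent trajectories, which are out of
scope.

## Structure preparation and I/O

PDB reading uses Biopython's strict parser (errors carry line numbers);
altloc duplicates resolve to the highest-occupancy conformer (tie: first
in file).  Multi-model PDB is the only trajectory dialect; every model
must match the reference roster exactly.  Preparation drops named chains
and optionally waters (HOH) and monoatomic ions; survivors keep their
order and coordinates.  Disulfides are detected geometrically: CYS SG
pairs under 2.5 Å, matched greedily by ascending distance so each SG is
used once and the result is invariant under rigid motion.  Atom indices
are 0-based internally and 1-based in reports; labels follow the
`resSeq@atomName` convention of published interface tables.

## Known limitations

- PB dielectric boundary is the vdW surface; absolute G_PB differs from
  molecular-surface codes (relative results are much less sensitive).
- The SOR solver is single-grid; very fine grids (< 0.2 Å) get slow.
- No protonation engine, no CONECT-based bond perception beyond
  disulfides; H-bond donor detection on unprotonated crystal structures
  requires the geometric H placement or pre-protonated input.
- Entropy is harmonic and vibrational-only; see above for the sign
  caveat on soft-mode toys.
- The packaged literature tables are fixtures for arithmetic and layout
  checks, not recomputed results.
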