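"""Fixed-charge molecular-mechanics energies and normal-mode entropy.

Pair terms follow the AMBER conventions: 12-6 Lennard-Jones in r_min form
with Lorentz-Berthelot combining, 1-2/1-3 pairs excluded and 1-4 pairs
scaled (electrostatics x 1/1.2, LJ x 1/2 by default).  Toy bonded terms are
harmonic, E = k_b (r - r0)^2 and E = k_theta (theta - theta0)^2, so the
curvature of a bond is 2 k_b (AMBER force-constant convention).

The vibrational entropy is the harmonic-oscillator expression per mode,

    S = R [ x / (e^x - 1) - ln(1 - e^-x) ],   x = h c nu / (k_B T)

applied to the eigenfrequencies of the mass-weighted Hessian after the six
near-zero rigid-body modes are dropped; imaginary modes are excluded and
counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import HC_OVER_KB, KE, R_KCAL, WAVENUMBER_PER_SQRT_EIG
from .core import MolecularSystem

__all__ = [
    "BondTerm",
    "AngleTerm",
    "ForceFieldParams",
    "EnergyBreakdown",
    "EntropyResult",
    "coulomb_energy",
    "lj_energy",
    "bonded_energy",
    "interaction_energy",
    "total_energy",
    "make_energy_fn",
    "numerical_hessian",
    "normal_mode_entropy",
    "minimize_steepest_descent",
]


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k_b: float  # kcal mol^-1 A^-2 (E = k_b (r - r0)^2)
    r0: float


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int  # vertex
    k: int
    k_theta: float  # kcal mol^-1 rad^-2
    theta0: float  # rad


@dataclass
class ForceFieldParams:
    """Per-atom LJ parameters, exclusions, 1-4 scaling, toy bonded terms."""

    lj_epsilon: np.ndarray
    lj_rmin_half: np.ndarray
    masses: np.ndarray | None = None
    exclusions: set[tuple[int, int]] = field(default_factory=set)  # 1-2 and 1-3
    pairs_14: set[tuple[int, int]] = field(default_factory=set)
    scale_ee_14: float = 1.0 / 1.2
    scale_lj_14: float = 0.5
    bond_terms: list[BondTerm] = field(default_factory=list)
    angle_terms: list[AngleTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, dtype=float)
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be >= 0")
        if np.any(self.lj_rmin_half <= 0):
            raise ValueError("lj_rmin_half must be > 0")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if np.any(self.masses <= 0):
                raise ValueError("masses must be > 0")

    @classmethod
    def from_system(
        cls,
        system: MolecularSystem,
        bond_terms: Sequence[BondTerm] = (),
        angle_terms: Sequence[AngleTerm] = (),
        harmonic_from_topology: bool = False,
        k_b_default: float = 300.0,
        **kwargs,
    ) -> "ForceFieldParams":
        """Build parameters from atom annotations and the system bond graph.

        Atoms with no LJ parameters get epsilon = 0 (no vdW footprint) and a
        placeholder r_min/2.  1-2/1-3 exclusions and 1-4 pairs come from
        bond-graph distances.  ``harmonic_from_topology`` adds a stiff
        harmonic term (``k_b_default`` kcal mol^-1 A^-2, r0 = current
        length) for every covalent bond, keeping toy species internally
        bound during minimization and normal-mode analysis.
        """
        eps = np.array(
            [a.lj_epsilon if a.lj_epsilon is not None else 0.0 for a in system.atoms]
        )
        rmh = np.array(
            [a.lj_rmin_half if a.lj_rmin_half is not None else 1.0 for a in system.atoms]
        )
        adj = system.adjacency()
        exclusions: set[tuple[int, int]] = set()
        pairs_14: set[tuple[int, int]] = set()
        for i in range(system.n_atoms):
            for j in adj[i]:
                if i < j:
                    exclusions.add((i, j))
                for k in adj[j]:
                    if k != i:
                        exclusions.add((min(i, k), max(i, k)))
                        for l in adj[k]:
                            if l not in (i, j):
                                pairs_14.add((min(i, l), max(i, l)))
        pairs_14 -= exclusions
        bond_terms = list(bond_terms)
        if harmonic_from_topology:
            coords = system.coords
            for i, j in system.bonds:
                r0 = float(np.linalg.norm(coords[i] - coords[j]))
                bond_terms.append(BondTerm(i=i, j=j, k_b=k_b_default, r0=r0))
        return cls(
            lj_epsilon=eps,
            lj_rmin_half=rmh,
            masses=system.mass_array(),
            exclusions=exclusions,
            pairs_14=pairs_14,
            bond_terms=bond_terms,
            angle_terms=list(angle_terms),
            **kwargs,
        )


@dataclass
class EnergyBreakdown:
    """Electrostatic / van der Waals / bonded decomposition (kcal/mol)."""

    E_es: float
    E_vdW: float
    E_bonded: float = 0.0

    @property
    def total(self) -> float:
        return self.E_es + self.E_vdW + self.E_bonded


@dataclass
class EntropyResult:
    """Vibrational frequencies (cm^-1) and T*S_vib at temperature T."""

    frequencies: np.ndarray
    TS_solute: float
    T: float
    n_dropped_modes: int
    n_imaginary: int = 0
    n_near_zero: int = 0
    warning: str | None = None


# ---------------------------------------------------------------------------
# pair energies
# ---------------------------------------------------------------------------

def _pair_weights(n: int, params: ForceFieldParams | None, kind: str) -> np.ndarray:
    """Upper-triangle weight matrix applying exclusions and 1-4 scaling."""
    w = np.triu(np.ones((n, n)), k=1)
    if params is not None:
        for i, j in params.exclusions:
            w[min(i, j), max(i, j)] = 0.0
        scale = params.scale_ee_14 if kind == "ee" else params.scale_lj_14
        for i, j in params.pairs_14:
            w[min(i, j), max(i, j)] = scale
    return w


def _cross_weights(n: int, sel_a: Sequence[int], sel_b: Sequence[int]) -> np.ndarray:
    w = np.zeros((n, n))
    ia = np.asarray(sel_a, dtype=int)
    ib = np.asarray(sel_b, dtype=int)
    w[np.ix_(ia, ib)] = 1.0  # each A x B pair exactly once (B x A stays 0)
    return w


def _distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def _resolve_scope(n, params, pair_scope, kind):
    if pair_scope == "all" or pair_scope is None:
        return _pair_weights(n, params, kind)
    sel_a, sel_b = pair_scope
    if set(sel_a) & set(sel_b):
        raise ValueError("cross-scope selections overlap")
    return _cross_weights(n, sel_a, sel_b)


def coulomb_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    params: ForceFieldParams | None = None,
    pair_scope="all",
) -> float:
    """Coulomb sum k_e q_i q_j / r_ij over the included pairs (kcal/mol).

    ``pair_scope`` is ``"all"`` (exclusions and 1-4 scaling applied) or a
    ``(sel_a, sel_b)`` tuple including every A x B pair unscaled.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    n = len(coords)
    w = _resolve_scope(n, params, pair_scope, "ee")
    r = _distances(coords)
    if np.any((w > 0) & (r < 1e-9)):
        raise ValueError("coincident atoms in a non-excluded pair")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(w > 0, w * np.outer(charges, charges) / np.where(r > 0, r, np.inf), 0.0)
    return KE * float(np.sum(e))


def lj_energy(
    coords: np.ndarray,
    params: ForceFieldParams,
    pair_scope="all",
) -> float:
    """12-6 Lennard-Jones energy, eps_ij [(rm/r)^12 - 2 (rm/r)^6] (kcal/mol)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    w = _resolve_scope(n, params, pair_scope, "lj")
    eps = np.sqrt(np.outer(params.lj_epsilon, params.lj_epsilon))
    rmin = params.lj_rmin_half[:, None] + params.lj_rmin_half[None, :]
    r = _distances(coords)
    active = (w > 0) & (eps > 0)
    if np.any(active & (r < 1e-9)):
        raise ValueError("coincident atoms in a non-excluded pair")
    with np.errstate(divide="ignore", invalid="ignore"):
        x6 = np.where(active, (rmin / np.where(r > 0, r, np.inf)) ** 6, 0.0)
    e = np.where(active, w * eps * (x6 * x6 - 2.0 * x6), 0.0)
    return float(np.sum(e))


def bonded_energy(coords: np.ndarray, params: ForceFieldParams) -> float:
    """Harmonic bond + angle energy of the toy bonded terms."""
    coords = np.asarray(coords, dtype=float)
    e = 0.0
    for t in params.bond_terms:
        r = np.linalg.norm(coords[t.i] - coords[t.j])
        e += t.k_b * (r - t.r0) ** 2
    for t in params.angle_terms:
        v1 = coords[t.i] - coords[t.j]
        v2 = coords[t.k] - coords[t.j]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        e += t.k_theta * (theta - t.theta0) ** 2
    return float(e)


def interaction_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    params: ForceFieldParams,
    sel_a: Sequence[int],
    sel_b: Sequence[int],
) -> EnergyBreakdown:
    """Cross-pair (A x B) electrostatic and van der Waals interaction energy."""
    if set(sel_a) & set(sel_b):
        raise ValueError("selections overlap")
    if len(sel_a) == 0 or len(sel_b) == 0:
        return EnergyBreakdown(E_es=0.0, E_vdW=0.0)
    scope = (list(sel_a), list(sel_b))
    return EnergyBreakdown(
        E_es=coulomb_energy(coords, charges, params, pair_scope=scope),
        E_vdW=lj_energy(coords, params, pair_scope=scope),
    )


def total_energy(
    coords: np.ndarray, charges: np.ndarray, params: ForceFieldParams
) -> float:
    """Full MM energy: scoped Coulomb + LJ + bonded terms."""
    return (
        coulomb_energy(coords, charges, params)
        + lj_energy(coords, params)
        + bonded_energy(coords, params)
    )


def make_energy_fn(
    system_or_coords, charges: np.ndarray, params: ForceFieldParams
) -> Callable[[np.ndarray], float]:
    """Energy as a function of a flat 3N coordinate vector."""
    if isinstance(system_or_coords, MolecularSystem):
        n = system_or_coords.n_atoms
    else:
        n = len(np.asarray(system_or_coords))
    charges = np.asarray(charges, dtype=float)

    def fn(flat: np.ndarray) -> float:
        return total_energy(np.asarray(flat, dtype=float).reshape(n, 3), charges, params)

    return fn


# ---------------------------------------------------------------------------
# Hessian, normal modes, entropy
# ---------------------------------------------------------------------------

def numerical_hessian(
    coords: np.ndarray,
    energy_fn: Callable[[np.ndarray], float],
    h: float = 1e-4,
) -> np.ndarray:
    """Central-difference second-derivative matrix, symmetrized.

    ``energy_fn`` takes the flat 3N vector; units kcal mol^-1 A^-2.
    """
    x0 = np.asarray(coords, dtype=float).ravel()
    n = x0.size
    hess = np.empty((n, n))
    e0 = energy_fn(x0)
    for i in range(n):
        xi_p = x0.copy()
        xi_m = x0.copy()
        xi_p[i] += h
        xi_m[i] -= h
        hess[i, i] = (energy_fn(xi_p) - 2.0 * e0 + energy_fn(xi_m)) / h**2
        for j in range(i + 1, n):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            val = (
                energy_fn(xpp) - energy_fn(xpm) - energy_fn(xmp) + energy_fn(xmm)
            ) / (4.0 * h**2)
            hess[i, j] = hess[j, i] = val
    return 0.5 * (hess + hess.T)


def normal_mode_entropy(
    hessian: np.ndarray,
    masses: np.ndarray,
    T: float = 300.0,
    n_drop: int = 6,
    near_zero_cm: float = 1.0,
) -> EntropyResult:
    """Harmonic vibrational entropy from a mass-weighted Hessian.

    Drops the ``n_drop`` smallest-|eigenvalue| modes (6 rigid-body modes for
    a nonlinear molecule; pass 5 for linear toys).  Of the remainder,
    imaginary frequencies and near-zero modes (|nu| < ``near_zero_cm``,
    e.g. floppy torsions of toy topologies or the relative rigid-body modes
    of a far-separated complex, whose harmonic entropy would diverge) are
    excluded from the sum and counted; any such exclusion is recorded as a
    warning on the result.
    """
    masses = np.asarray(masses, dtype=float)
    m3 = np.repeat(masses, 3)
    hmw = hessian / np.sqrt(np.outer(m3, m3))
    eigvals = np.linalg.eigvalsh(hmw)
    order = np.argsort(np.abs(eigvals))
    kept = eigvals[order[n_drop:]]
    freqs = []
    n_imag = 0
    n_near_zero = 0
    for lam in kept:
        nu = WAVENUMBER_PER_SQRT_EIG * np.sqrt(abs(lam))
        if nu < near_zero_cm:
            n_near_zero += 1
        elif lam < 0:
            n_imag += 1
        else:
            freqs.append(nu)
    freqs_arr = np.sort(np.asarray(freqs))
    x = HC_OVER_KB * freqs_arr / T
    s_per_mode = R_KCAL * (x / np.expm1(x) - np.log1p(-np.exp(-x)))
    ts = float(T * np.sum(s_per_mode))
    warning = None
    if n_imag or n_near_zero:
        warning = (
            f"{n_imag} imaginary and {n_near_zero} near-zero mode(s) "
            "excluded from the entropy sum"
        )
    return EntropyResult(
        frequencies=freqs_arr,
        TS_solute=ts,
        T=T,
        n_dropped_modes=n_drop,
        n_imaginary=n_imag,
        n_near_zero=n_near_zero,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# toy minimizer
# ---------------------------------------------------------------------------

def _numerical_gradient(fn, x, h=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2.0 * h)
    return g


def minimize_steepest_descent(
    coords: np.ndarray,
    energy_fn: Callable[[np.ndarray], float],
    rms_tol: float = 1e-4,
    max_steps: int = 2000,
    step0: float = 0.01,
) -> np.ndarray:
    """Backtracking steepest descent on toy systems.

    Stops when the RMS gradient drops below ``rms_tol`` kcal mol^-1 A^-1.
    Intended only to bring normal-mode inputs close to a minimum.
    """
    x = np.asarray(coords, dtype=float).ravel().copy()
    step = step0
    e = energy_fn(x)
    for _ in range(max_steps):
        g = _numerical_gradient(energy_fn, x)
        rms = float(np.sqrt(np.mean(g * g)))
        if rms < rms_tol:
            break
        direction = -g / max(np.linalg.norm(g), 1e-12)
        while step > 1e-10:
            x_new = x + step * direction
            e_new = energy_fn(x_new)
            if e_new < e:
                x, e = x_new, e_new
                step *= 1.2
                break
            step *= 0.5
        else:
            break
    return x.reshape(-1, 3)
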