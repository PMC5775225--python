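"""Hydrogen-bond detection and occupancy statistics over trajectories.

A hydrogen bond is counted when the donor-heavy-atom to acceptor distance
is below ``d_max`` (default 4 A) and the D-H...A angle, with vertex at the
hydrogen, is strictly greater than ``theta_min`` (default 90 degrees).  An
alternative vertex-at-donor angle definition is available behind a flag.

Occupancy of a bond is the percentage of frames in which it satisfies the
criterion; the mean inter-protein hydrogen-bond (IPHB) count is the
per-frame average of cross-chain bonds.  Labels follow the ``resSeq@atom``
convention used in published interface tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MolecularSystem, Trajectory

__all__ = [
    "HBondCriterion",
    "DonorEntry",
    "HBondRecord",
    "InterfaceReport",
    "find_donors_acceptors",
    "detect_hbonds_frame",
    "occupancy",
    "mean_iphb",
    "interface_report",
]

# residue-template nitrogen acceptors (deprotonated ring/side-chain N)
_N_ACCEPTOR_TEMPLATE = {
    ("HIS", "ND1"),
    ("HIS", "NE2"),
    ("HID", "NE2"),
    ("HIE", "ND1"),
}

_H_ATTACH_CUTOFF = 1.25  # A, distance fallback when no bonds are recorded


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition."""

    d_max: float = 4.0  # donor-acceptor heavy-atom distance, A
    theta_min: float = 90.0  # degrees, strict >
    require_h: bool = True
    angle_vertex: str = "h"  # "h" (D-H...A at H) or "donor"

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0.0 <= self.theta_min <= 180.0):
            raise ValueError("theta_min must be in [0, 180]")
        if self.angle_vertex not in ("h", "donor"):
            raise ValueError("angle_vertex must be 'h' or 'donor'")


@dataclass(frozen=True)
class DonorEntry:
    """A donor heavy atom with one attached hydrogen (one entry per H)."""

    heavy: int
    h: int


@dataclass
class HBondRecord:
    """Per-bond presence across frames and resulting occupancy (%)."""

    donor: str
    acceptor: str
    donor_index: int
    h_index: int
    acceptor_index: int
    presence: np.ndarray

    @property
    def occupancy(self) -> float:
        return 100.0 * float(np.count_nonzero(self.presence)) / len(self.presence)


@dataclass
class InterfaceReport:
    """Occupancy table plus per-frame IPHB statistics."""

    records: list[HBondRecord]
    mean_iphb: float
    reference_count: int
    h_placement: str = "input"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bond": f"H{k + 1}",
                    "donor": r.donor,
                    "acceptor": r.acceptor,
                    "occupancy": r.occupancy,
                }
                for k, r in enumerate(self.records)
            ],
            columns=["bond", "donor", "acceptor", "occupancy"],
        )


def _h_attachments(system: MolecularSystem) -> dict[int, list[int]]:
    """Map heavy-atom index -> attached hydrogen indices."""
    out: dict[int, list[int]] = {}
    if system.bonds:
        for i, j in system.bonds:
            ai, aj = system.atoms[i], system.atoms[j]
            if ai.element == "H" and aj.element in ("N", "O", "S"):
                out.setdefault(j, []).append(i)
            elif aj.element == "H" and ai.element in ("N", "O", "S"):
                out.setdefault(i, []).append(j)
        return out
    coords = system.coords
    heavies = [i for i, a in enumerate(system.atoms) if a.element in ("N", "O", "S")]
    for i, a in enumerate(system.atoms):
        if a.element != "H" or not heavies:
            continue
        d = np.linalg.norm(coords[heavies] - coords[i], axis=1)
        jbest = int(np.argmin(d))
        if d[jbest] < _H_ATTACH_CUTOFF:
            out.setdefault(heavies[jbest], []).append(i)
    return out


def find_donors_acceptors(
    system: MolecularSystem,
) -> tuple[list[DonorEntry], list[int]]:
    """Enumerate donors (N/O/S with attached H, one entry per H) and acceptors.

    Acceptors are all O and S atoms plus nitrogens that either carry no
    hydrogen or appear in the residue acceptor template (e.g. a free His
    ring nitrogen).  Ordering is deterministic (ascending atom index).
    """
    attach = _h_attachments(system)
    donors: list[DonorEntry] = []
    acceptors: list[int] = []
    for i, a in enumerate(system.atoms):
        if a.element in ("N", "O", "S"):
            for h in sorted(attach.get(i, [])):
                donors.append(DonorEntry(heavy=i, h=h))
            if a.element in ("O", "S"):
                acceptors.append(i)
            elif (a.res_name, a.name) in _N_ACCEPTOR_TEMPLATE or i not in attach:
                acceptors.append(i)
    return donors, acceptors


def detect_hbonds_frame(
    coords: np.ndarray,
    donors: Sequence[DonorEntry],
    acceptors: Sequence[int],
    criterion: HBondCriterion | None = None,
    chain_ids: Sequence[str] | None = None,
    cross_chains_only: bool = False,
) -> set[tuple[int, int, int]]:
    """Hydrogen bonds present in one frame.

    Returns ``(donor_heavy, donor_h, acceptor)`` index triples.  A donor
    hydrogen may match several acceptors (no uniqueness filter).  With
    ``cross_chains_only`` the donor and acceptor chains must differ
    (``chain_ids`` required).
    """
    crit = criterion or HBondCriterion()
    coords = np.asarray(coords, dtype=float)
    if cross_chains_only and chain_ids is None:
        raise ValueError("cross_chains_only requires chain_ids")
    found: set[tuple[int, int, int]] = set()
    if not donors or not acceptors:
        return found
    acc = np.asarray(list(acceptors), dtype=int)
    for entry in donors:
        if crit.require_h and entry.h is None:
            raise ValueError(f"donor {entry.heavy} has no hydrogen")
        d_pos = coords[entry.heavy]
        h_pos = coords[entry.h]
        dist = np.linalg.norm(coords[acc] - d_pos, axis=1)
        for a_idx, d_da in zip(acc, dist):
            if a_idx in (entry.heavy, entry.h) or d_da >= crit.d_max:
                continue
            if cross_chains_only and chain_ids[a_idx] == chain_ids[entry.heavy]:
                continue
            a_pos = coords[a_idx]
            if crit.angle_vertex == "h":
                v1 = d_pos - h_pos
                v2 = a_pos - h_pos
            else:
                v1 = h_pos - d_pos
                v2 = a_pos - d_pos
            nrm = np.linalg.norm(v1) * np.linalg.norm(v2)
            if nrm < 1e-12:
                continue
            cosang = float(np.clip(np.dot(v1, v2) / nrm, -1.0, 1.0))
            angle = float(np.degrees(np.arccos(cosang)))
            if angle > crit.theta_min:  # strictly greater
                found.add((entry.heavy, entry.h, int(a_idx)))
    return found


def occupancy(
    trajectory: Trajectory,
    donors: Sequence[DonorEntry] | None = None,
    acceptors: Sequence[int] | None = None,
    criterion: HBondCriterion | None = None,
    cross_chains_only: bool = True,
) -> list[HBondRecord]:
    """Per-bond occupancy over all frames, sorted by occupancy descending.

    One record per (donor, acceptor) pair observed in at least one frame.
    The denominator is always the full frame count.
    """
    system = trajectory.reference
    if donors is None or acceptors is None:
        auto_d, auto_a = find_donors_acceptors(system)
        donors = donors if donors is not None else auto_d
        acceptors = acceptors if acceptors is not None else auto_a
    chain_ids = [a.chain_id for a in system.atoms]
    n_frames = trajectory.n_frames
    presence: dict[tuple[int, int, int], np.ndarray] = {}
    for f, frame in enumerate(trajectory.frames):
        for key in detect_hbonds_frame(
            frame, donors, acceptors, criterion, chain_ids, cross_chains_only
        ):
            if key not in presence:
                presence[key] = np.zeros(n_frames, dtype=bool)
            presence[key][f] = True
    records = [
        HBondRecord(
            donor=system.atoms[heavy].label,
            acceptor=system.atoms[a_idx].label,
            donor_index=heavy,
            h_index=h,
            acceptor_index=a_idx,
            presence=pres,
        )
        for (heavy, h, a_idx), pres in presence.items()
    ]
    records.sort(key=lambda r: (-r.occupancy, r.donor, r.acceptor))
    return records


def mean_iphb(
    trajectory: Trajectory,
    donors: Sequence[DonorEntry] | None = None,
    acceptors: Sequence[int] | None = None,
    criterion: HBondCriterion | None = None,
    cross_chains_only: bool = True,
) -> float:
    """Arithmetic mean over frames of the (cross-chain) bond count."""
    records = occupancy(trajectory, donors, acceptors, criterion, cross_chains_only)
    if not records:
        return 0.0
    counts = np.sum([r.presence for r in records], axis=0)
    return float(np.mean(counts))


def interface_report(
    trajectory: Trajectory,
    criterion: HBondCriterion | None = None,
    cross_chains_only: bool = True,
    h_placement: str = "input",
) -> InterfaceReport:
    """Occupancy table, mean IPHB and the frame-0 (crystal) bond count."""
    records = occupancy(
        trajectory, criterion=criterion, cross_chains_only=cross_chains_only
    )
    if records:
        counts = np.sum([r.presence for r in records], axis=0)
        mean = float(np.mean(counts))
        ref = int(counts[0])
    else:
        mean = 0.0
        ref = 0
    return InterfaceReport(
        records=records, mean_iphb=mean, reference_count=ref, h_placement=h_placement
    )
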