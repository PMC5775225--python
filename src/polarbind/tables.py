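"""Packaged reference fixtures: relative binding free energies, hydrogen-bond
inventories, and interface buried-surface areas of the PCSK9ΔC-EGFA wild
type and gain-of-function mutant complexes.

These are printed literature values used for consistency checks and report
layout, not quantities this package recomputes; absolute reproduction would
require the original explicit-solvent trajectories.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_tables", "RELATIVE_ENERGY_ROWS"]

#: Row labels of the relative binding free-energy table, in print order.
RELATIVE_ENERGY_ROWS = [
    "d(dEes + dGPB)",
    "d(dEvdW + dGnp)",
    "ddG_PBSA",
    "d(-TdS_solute)",
    "ddG_bind",
]

_MUTANTS = ["H306Y", "D374H", "D374Y", "D374A"]
_PDB_OF_MUTANT = {"H306Y": "2W2N", "D374H": "2W2Q", "D374Y": "2W2O", "D374A": "2W2P"}

# Relative energies (kcal/mol) vs the wild-type complex at T = 300 K,
# one block per force field.  Columns: H306Y, D374H, D374Y, D374A.
_RELATIVE_ENERGIES = {
    "AMBER14SB": {
        "d(dEes + dGPB)": [4.1, -1.1, 7.3, -8.6],
        "d(dEvdW + dGnp)": [8.3, 4.9, -0.7, 4.4],
        "ddG_PBSA": [12.4, 3.8, 6.6, -4.2],
        "d(-TdS_solute)": [-3.1, -4.0, -8.0, -4.2],
        "ddG_bind": [9.3, -0.2, -1.4, -8.4],
    },
    "EPB": {
        "d(dEes + dGPB)": [-11.0, -14.5, -8.9, -9.7],
        "d(dEvdW + dGnp)": [10.2, 8.1, 4.7, 5.7],
        "ddG_PBSA": [-0.8, -6.4, -4.2, -4.0],
        "d(-TdS_solute)": [-2.9, 2.4, -0.5, -2.3],
        "ddG_bind": [-3.7, -4.0, -4.7, -6.3],
    },
}

# Interface hydrogen bonds per complex: crystal-structure count, mean IPHB
# over the polarizable-charge trajectory, and the per-bond occupancy table
# (donor label, acceptor label, occupancy %).
_HBOND_INVENTORY = {
    "2W2M": {
        "label": "WT",
        "n_crystal": 7,
        "mean_iphb_epb": 5.25,
        "bonds": [
            ("394@O", "209@N", 100),
            ("209@O", "394@N", 100),
            ("207@O", "396@N", 100),
            ("395@OD1", "207@OG1", 96),
            ("209@O", "387@ND2", 93),
            ("396@O", "207@OG1", 23),
            ("207@OG1", "395@ND2", 13),
        ],
    },
    "2W2N": {
        "label": "H306Y",
        "n_crystal": 4,
        "mean_iphb_epb": 3.32,
        "bonds": [
            ("201@OD2", "389@OH", 99),
            ("384@OD1", "208@OG", 94),
            ("201@OD1", "389@OH", 93),
            ("206@O", "384@ND2", 40),
            ("392@OD1", "204@OG1", 4),
            ("393@O", "204@OG1", 2),
        ],
    },
    "2W2Q": {
        "label": "D374H",
        "n_crystal": 5,
        "mean_iphb_epb": 2.21,
        "bonds": [
            ("392@OD1", "205@OG1", 92),
            ("393@O", "205@OG1", 44),
            ("205@OG1", "392@ND2", 40),
            ("392@ND2", "205@OG1", 37),
            ("207@O", "384@ND2", 5),
            ("402@O", "202@NE2", 2),
            ("202@ND1", "389@NE2", 1),
        ],
    },
    "2W2O": {
        "label": "D374Y",
        "n_crystal": 7,
        "mean_iphb_epb": 5.64,
        "bonds": [
            ("390@OD1", "205@OG1", 100),
            ("389@O", "207@N", 100),
            ("205@O", "391@N", 100),
            ("382@OD1", "209@N", 96),
            ("400@O", "202@OH", 64),
            ("391@O", "205@OG1", 32),
            ("390@ND2", "205@OG1", 21),
            ("205@OG1", "390@ND2", 21),
            ("207@O", "382@ND2", 17),
            ("390@OD1", "205@N", 13),
        ],
    },
    "2W2P": {
        "label": "D374A",
        "n_crystal": 3,
        "mean_iphb_epb": 2.27,
        "bonds": [
            ("392@OD1", "204@OG1", 100),
            ("392@ND2", "204@OG1", 46),
            ("204@OG1", "392@ND2", 46),
            ("393@O", "204@OG1", 35),
        ],
    },
}

# Interface buried surface areas (A^2) quoted for three complexes.
_BURIED_SURFACE = {"2W2M": 982.0, "2W2Q": 1045.0, "2W2O": 1139.0}


def reference_tables() -> dict:
    """Return the packaged literature fixtures as structured objects.

    Keys: ``relative_energies`` (DataFrame indexed by (force_field, row)
    with one column per mutant), ``hbonds`` (per PDB id: crystal count,
    mean IPHB and bond inventory), ``buried_surface`` (A^2 per PDB id),
    ``pdb_of_mutant``, ``row_order``.
    """
    frames = {}
    for ff, block in _RELATIVE_ENERGIES.items():
        frames[ff] = pd.DataFrame(block, index=_MUTANTS).T.loc[RELATIVE_ENERGY_ROWS]
    rel = pd.concat(frames, names=["force_field", "component"])
    hbonds = {
        pdb: {
            "label": entry["label"],
            "n_crystal": entry["n_crystal"],
            "mean_iphb_epb": entry["mean_iphb_epb"],
            "bonds": pd.DataFrame(
                entry["bonds"], columns=["donor", "acceptor", "occupancy"]
            ),
        }
        for pdb, entry in _HBOND_INVENTORY.items()
    }
    return {
        "relative_energies": rel,
        "hbonds": hbonds,
        "buried_surface": dict(_BURIED_SURFACE),
        "pdb_of_mutant": dict(_PDB_OF_MUTANT),
        "row_order": list(RELATIVE_ENERGY_ROWS),
    }
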