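"""Inverse rotamers: expand functional-group poses into full side chains.

A placement fixes the functional group rigidly in space; the rest of the
side chain is grown *backward* from the group toward the backbone with
ideal bond lengths and angles, sampling every rotatable bond (default:
staggered -60/60/180).  Each realization therefore carries a backbone
anchor frame (N, CA, C) that a scaffold residue must reproduce for the
side chain to be buildable there.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem_model import LigandModel
from .enumeration import Placement
from .errors import HBNetForgeError, SpecError
from .fg_library import fg_template
from .geometry import place_atom

CHI_DEFAULT = (-60.0, 60.0, 180.0)
CLASH_MIN = 2.7  # A, chain heavy atoms vs ligand heavy atoms

# Backward z-matrix rows per residue identity: (atom, a, b, c, dist, angle,
# torsion) where torsion is a number or "chi" (sampled).  A row of the form
# (atom, "@attach", ...) places the atom along the template's attachment
# direction (used when the template geometry already fixes it, e.g. the
# tetrahedral completion of a primary amine).
_CHAINS = {
    "SER": [
        ("CA", "HG", "OG", "CB", 1.530, 110.1, "chi"),
        ("N", "OG", "CB", "CA", 1.458, 110.5, "chi"),
        ("C", "N", "CB", "CA", 1.525, 110.1, -122.6),
        ("O", "N", "CA", "C", 1.231, 120.5, 0.0),
    ],
    "TYR": [
        ("CB", "CE1", "CD1", "CG", 1.512, 120.9, 180.0),
        ("CA", "CD1", "CG", "CB", 1.530, 114.0, "chi"),
        ("N", "CG", "CB", "CA", 1.458, 110.5, "chi"),
        ("C", "N", "CB", "CA", 1.525, 110.1, -122.6),
        ("O", "N", "CA", "C", 1.231, 120.5, 0.0),
    ],
    "ASP": [
        ("CB", "OD2", "OD1", "CG", 1.516, 118.0, 180.0),
        ("CA", "OD1", "CG", "CB", 1.530, 113.0, "chi"),
        ("N", "CG", "CB", "CA", 1.458, 110.5, "chi"),
        ("C", "N", "CB", "CA", 1.525, 110.1, -122.6),
        ("O", "N", "CA", "C", 1.231, 120.5, 0.0),
    ],
    "GLU": [
        ("C1", "OD2", "OD1", "CG", 1.516, 118.0, 180.0),
        ("C2", "OD1", "CG", "C1", 1.530, 113.0, "chi"),
        ("CA", "CG", "C1", "C2", 1.530, 111.0, "chi"),
        ("N", "C1", "C2", "CA", 1.458, 110.5, "chi"),
        ("C", "N", "C2", "CA", 1.525, 110.1, -122.6),
        ("O", "N", "CA", "C", 1.231, 120.5, 0.0),
    ],
    "ASN": [
        ("CB", "ND2", "OD1", "CG", 1.516, 118.0, 180.0),
        ("CA", "OD1", "CG", "CB", 1.530, 113.0, "chi"),
        ("N", "CG", "CB", "CA", 1.458, 110.5, "chi"),
        ("C", "N", "CB", "CA", 1.525, 110.1, -122.6),
        ("O", "N", "CA", "C", 1.231, 120.5, 0.0),
    ],
    "GLN": [
        ("C1", "ND2", "OD1", "CG", 1.516, 118.0, 180.0),
        ("C2", "OD1", "CG", "C1", 1.530, 113.0, "chi"),
        ("CA", "CG", "C1", "C2", 1.530, 111.0, "chi"),
        ("N", "C1", "C2", "CA", 1.458, 110.5, "chi"),
        ("C", "N", "C2", "CA", 1.525, 110.1, -122.6),
        ("O", "N", "CA", "C", 1.231, 120.5, 0.0),
    ],
    "HIS": [
        ("CB", "CE1", "ND1", "CG", 1.500, 122.0, 180.0),
        ("CA", "ND1", "CG", "CB", 1.530, 114.0, "chi"),
        ("N", "CG", "CB", "CA", 1.458, 110.5, "chi"),
        ("C", "N", "CB", "CA", 1.525, 110.1, -122.6),
        ("O", "N", "CA", "C", 1.231, 120.5, 0.0),
    ],
    "ARG": [
        ("CD", "NH2", "CZ", "NE", 1.460, 124.0, 180.0),
        ("CG", "CZ", "NE", "CD", 1.520, 111.0, "chi"),
        ("CB", "NE", "CD", "CG", 1.520, 111.0, "chi"),
        ("CA", "CD", "CG", "CB", 1.530, 111.0, "chi"),
        ("N", "CG", "CB", "CA", 1.458, 110.5, "chi"),
        ("C", "N", "CB", "CA", 1.525, 110.1, -122.6),
        ("O", "N", "CA", "C", 1.231, 120.5, 0.0),
    ],
    "LYS": [
        ("CE", "@attach", None, None, 1.490, 0.0, 0.0),
        ("CD", "HZ2", "NZ", "CE", 1.530, 111.0, "chi"),
        ("CG", "NZ", "CE", "CD", 1.530, 111.0, "chi"),
        ("CB", "CE", "CD", "CG", 1.530, 111.0, "chi"),
        ("CA", "CD", "CG", "CB", 1.530, 111.0, "chi"),
        ("N", "CG", "CB", "CA", 1.458, 110.5, "chi"),
        ("C", "N", "CB", "CA", 1.525, 110.1, -122.6),
        ("O", "N", "CA", "C", 1.231, 120.5, 0.0),
    ],
}


def n_rotatable_bonds(residue_identity: str) -> int:
    return sum(1 for row in _CHAINS[residue_identity] if row[6] == "chi")


@dataclass
class SideChainRealization:
    """A full side chain grown backward from a fixed functional group."""

    residue_identity: str
    chi_angles: tuple
    atoms: dict  # name -> xyz, functional group + chain + backbone
    backbone_frame: np.ndarray  # (3, 3): N, CA, C
    placement: Placement

    def heavy_atom_items(self):
        return [
            (n, x) for n, x in self.atoms.items() if not n.startswith("H")
        ]

    def fg_atom_names(self):
        tpl = fg_template(self.placement.fg_name)
        return [n for n in tpl.atoms if n not in self.placement.omitted_atoms]


def inverse_rotamers(
    placement: Placement,
    residue_identity: str,
    chi_samples=CHI_DEFAULT,
    ligand: LigandModel | None = None,
    clash_min: float = CLASH_MIN,
) -> list:
    """All side-chain realizations of a placement for one residue identity.

    Every rotatable bond is sampled at ``chi_samples``; realizations whose
    chain heavy atoms clash with the ligand are removed.  The functional
    group atoms are never moved, so each realization reproduces its parent
    placement exactly.
    """
    fg = fg_template(placement.fg_name)
    identity = residue_identity.upper()
    if identity not in fg.residue_identities:
        raise SpecError(
            f"residue {identity} cannot carry a {placement.fg_name} group "
            f"(allowed: {', '.join(fg.residue_identities)})"
        )
    rows = _CHAINS[identity]
    chi_rows = [i for i, r in enumerate(rows) if r[6] == "chi"]
    chi_samples = tuple(float(c) for c in chi_samples)
    if not chi_samples:
        raise ValueError("chi_samples must be non-empty")

    lig_heavy = None
    if ligand is not None:
        lig_names = ligand.heavy_atom_names()
        if placement.omitted_atoms:
            # covalently attached group: ignore the ligand atom it is bonded
            # to (atoms one bond away are legitimately within clash range)
            anchor = placement.atom_xyz[placement.interacting_atom]
            lig_names = [
                n for n in lig_names
                if np.linalg.norm(ligand.xyz(n) - anchor) > 1.8
            ]
        lig_heavy = ligand.coords(lig_names) if lig_names else None

    attach_name, attach_dir = fg.attachment
    world_dir = placement.transform.rotation @ np.asarray(attach_dir, dtype=float)

    out = []
    for combo in itertools.product(chi_samples, repeat=len(chi_rows)):
        atoms = dict(placement.atom_xyz)
        it = iter(combo)
        ok = True
        for row in rows:
            name, a, b, c, dist, angle, torsion = row
            if a == "@attach":
                atoms[name] = atoms[attach_name] + dist * world_dir
                continue
            tor = next(it) if torsion == "chi" else torsion
            try:
                atoms[name] = place_atom(atoms[a], atoms[b], atoms[c], dist, angle, tor)
            except HBNetForgeError:
                ok = False
                break
        if not ok:
            continue
        if lig_heavy is not None:
            chain_heavy = np.array(
                [atoms[r[0]] for r in rows if not r[0].startswith("H")]
            )
            d2 = ((chain_heavy[:, None, :] - lig_heavy[None, :, :]) ** 2).sum(axis=2)
            if d2.min() < clash_min**2:
                continue
        frame = np.array([atoms["N"], atoms["CA"], atoms["C"]])
        full = {
            n: xyz
            for n, xyz in atoms.items()
            if n not in placement.omitted_atoms
        }
        out.append(
            SideChainRealization(identity, combo, full, frame, placement)
        )
    return out


def count_full_realizations(network, per_group_counts) -> int:
    """Product rule: 3D realizations of a network = product over its groups
    of the number of side-chain placements per functional-group placement."""
    if isinstance(per_group_counts, dict):
        counts = [per_group_counts[l] for l in network.placements]
    else:
        counts = list(per_group_counts)
    total = 1
    for c in counts:
        if c < 0:
            raise ValueError("realization counts must be non-negative")
        total *= int(c)
    return total


# ---------------------------------------------------------------------------
# PDB export


def export_network_pdb(network, realizations: dict, ligand: LigandModel, path) -> None:
    """Write one network (ligand + one realization per group) as PDB."""
    if not network.placements:
        raise ValueError("cannot export an empty network")
    if set(realizations) != set(network.placements):
        raise ValueError("need exactly one realization per group")
    lines = []
    serial = 1
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for gi, (label, real) in enumerate(sorted(realizations.items())):
        chain = chain_ids[gi % len(chain_ids)]
        for name, xyz in real.atoms.items():
            el = "H" if name.startswith("H") else name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s}{real.residue_identity:>4.3s} "
                f"{chain}{gi + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {el:>2.2s}"
            )
            serial += 1
    for aname, el, xyz in ligand.atoms:
        lines.append(
            f"HETATM{serial:5d} {aname:<4.4s}{'LIG':>4s} X{99:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {el:>2.2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
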