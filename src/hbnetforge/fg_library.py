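"""Built-in library of rigid side-chain functional-group templates.

Each template is a small rigid fragment in its own local frame with ideal
bond lengths and angles, annotated with its hydrogen-bond donor pairs
(heavy atom, hydrogen), acceptor atoms (heavy atom, lone-pair base atoms),
the attachment atom where the rest of the side chain continues, and the
amino-acid identities that can carry the group.

Templates are the functional-group-level representation of an active site:
a hydroxyl stands for Ser/Thr, a phenol for Tyr, a carboxylate for Asp/Glu,
a carboxamide for Asn/Gln, an imidazole for His, a guanidinium for Arg and
a primary amine for Lys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import place_atom

__all__ = ["FunctionalGroupType", "fg_template", "FG_NAMES"]


@dataclass(frozen=True)
class FunctionalGroupType:
    """Immutable rigid template for one side-chain functional group."""

    fg_name: str
    atoms: dict  # name -> np.ndarray(3,), local frame
    elements: dict  # name -> element symbol
    donors: tuple  # ((heavy, hydrogen), ...)
    acceptors: tuple  # ((heavy, (base, ...)), ...)
    attachment: tuple  # (atom_name, unit direction of chain continuation)
    residue_identities: tuple
    reference_atom: str  # central heavy atom used for grid keys / clustering
    covalent_atom: str | None = None  # atom capable of a covalent bond
    chain_anchors: tuple = ()  # (a, b) template atoms preceding the first
    # chain atom in the backward z-matrix (c = attachment atom)

    def __post_init__(self):
        for dh, hh in self.donors:
            assert dh in self.atoms and hh in self.atoms
        for ah, bases in self.acceptors:
            assert ah in self.atoms and all(b in self.atoms for b in bases)
        assert self.attachment[0] in self.atoms
        assert self.reference_atom in self.atoms

    def coords(self, names=None) -> np.ndarray:
        names = names if names is not None else list(self.atoms)
        return np.array([self.atoms[n] for n in names])

    def heavy_atoms(self) -> list:
        return [n for n in self.atoms if self.elements[n] != "H"]

    def donor_pairs(self):
        return list(self.donors)

    def acceptor_entries(self):
        return list(self.acceptors)


def _v(x, y, z):
    return np.array([x, y, z], dtype=float)


def _hydroxyl() -> FunctionalGroupType:
    # CB at origin, OG along +x; HG staggered in the xy-plane.
    cb = _v(0, 0, 0)
    og = _v(1.417, 0, 0)
    ref = _v(0, 1, 0)  # virtual point to define HG torsion
    hg = place_atom(ref, cb, og, 0.96, 109.5, 180.0)
    return FunctionalGroupType(
        fg_name="hydroxyl",
        atoms={"CB": cb, "OG": og, "HG": hg},
        elements={"CB": "C", "OG": "O", "HG": "H"},
        donors=(("OG", "HG"),),
        acceptors=(("OG", ("CB",)),),
        attachment=("CB", (-1.0, 0.0, 0.0)),
        residue_identities=("SER", "THR"),
        reference_atom="OG",
        covalent_atom="OG",
        chain_anchors=("HG", "OG"),
    )


def _phenol() -> FunctionalGroupType:
    # Benzene ring in the xy-plane, center at origin; CG toward -x, OH on CZ.
    r = 1.39
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    angles = [180.0, 120.0, 60.0, 0.0, -60.0, -120.0]
    atoms = {
        n: _v(r * np.cos(np.radians(a)), r * np.sin(np.radians(a)), 0.0)
        for n, a in zip(names, angles)
    }
    atoms["OH"] = _v(r + 1.364, 0.0, 0.0)
    atoms["HH"] = place_atom(atoms["CE1"], atoms["CZ"], atoms["OH"], 0.96, 109.5, 180.0)
    elements = {n: "C" for n in names}
    elements.update({"OH": "O", "HH": "H"})
    return FunctionalGroupType(
        fg_name="phenol",
        atoms=atoms,
        elements=elements,
        donors=(("OH", "HH"),),
        acceptors=(("OH", ("CZ",)),),
        attachment=("CG", (-1.0, 0.0, 0.0)),
        residue_identities=("TYR",),
        reference_atom="OH",
        chain_anchors=("CD1", "CG"),  # CB is placed in-plane first (sp2)
    )


def _carboxylate() -> FunctionalGroupType:
    # sp2 carbon at origin, CB continues toward -x, two equivalent oxygens.
    cg = _v(0, 0, 0)
    half = 63.0  # O-C-O ~ 126 deg
    od1 = _v(1.25 * np.cos(np.radians(half)), 1.25 * np.sin(np.radians(half)), 0)
    od2 = _v(1.25 * np.cos(np.radians(half)), -1.25 * np.sin(np.radians(half)), 0)
    return FunctionalGroupType(
        fg_name="carboxylate",
        atoms={"CG": cg, "OD1": od1, "OD2": od2},
        elements={"CG": "C", "OD1": "O", "OD2": "O"},
        donors=(),
        acceptors=(("OD1", ("CG",)), ("OD2", ("CG",))),
        attachment=("CG", (-1.0, 0.0, 0.0)),
        residue_identities=("ASP", "GLU"),
        reference_atom="CG",
        chain_anchors=("OD1", "CG"),
    )


def _carboxamide() -> FunctionalGroupType:
    cg = _v(0, 0, 0)
    od1 = _v(1.23 * np.cos(np.radians(60)), 1.23 * np.sin(np.radians(60)), 0)
    nd2 = _v(1.33 * np.cos(np.radians(60)), -1.33 * np.sin(np.radians(60)), 0)
    hd21 = place_atom(od1, cg, nd2, 1.01, 120.0, 180.0)  # anti to C=O
    hd22 = place_atom(od1, cg, nd2, 1.01, 120.0, 0.0)  # syn
    return FunctionalGroupType(
        fg_name="carboxamide",
        atoms={"CG": cg, "OD1": od1, "ND2": nd2, "HD21": hd21, "HD22": hd22},
        elements={"CG": "C", "OD1": "O", "ND2": "N", "HD21": "H", "HD22": "H"},
        donors=(("ND2", "HD21"), ("ND2", "HD22")),
        acceptors=(("OD1", ("CG",)),),
        attachment=("CG", (-1.0, 0.0, 0.0)),
        residue_identities=("ASN", "GLN"),
        reference_atom="CG",
        chain_anchors=("OD1", "CG"),
    )


def _imidazole() -> FunctionalGroupType:
    # Regular pentagon approximation in the xy-plane, CG toward -x.
    r = 1.37 / (2 * np.sin(np.pi / 5))  # circumradius for 1.37 A edges
    names = ["CG", "ND1", "CE1", "NE2", "CD2"]
    atoms = {}
    for i, n in enumerate(names):
        a = np.radians(180.0 - 72.0 * i)
        atoms[n] = _v(r * np.cos(a), r * np.sin(a), 0.0)
    # exocyclic H on NE2, in plane, bisecting the external angle
    ne2 = atoms["NE2"]
    ext = ne2 / np.linalg.norm(ne2)
    atoms["HE2"] = ne2 + 1.01 * ext
    elements = {"CG": "C", "ND1": "N", "CE1": "C", "NE2": "N", "CD2": "C", "HE2": "H"}
    return FunctionalGroupType(
        fg_name="imidazole",
        atoms=atoms,
        elements=elements,
        donors=(("NE2", "HE2"),),
        acceptors=(("ND1", ("CG", "CE1")),),
        attachment=("CG", (-1.0, 0.0, 0.0)),
        residue_identities=("HIS",),
        reference_atom="ND1",
        chain_anchors=("ND1", "CG"),
    )


def _guanidinium() -> FunctionalGroupType:
    cz = _v(0, 0, 0)
    ne = _v(-1.33, 0, 0)
    nh1 = _v(1.33 * np.cos(np.radians(60)), 1.33 * np.sin(np.radians(60)), 0)
    nh2 = _v(1.33 * np.cos(np.radians(60)), -1.33 * np.sin(np.radians(60)), 0)
    atoms = {"NE": ne, "CZ": cz, "NH1": nh1, "NH2": nh2}
    atoms["HE"] = place_atom(nh1, cz, ne, 1.01, 120.0, 180.0)
    atoms["HH11"] = place_atom(ne, cz, nh1, 1.01, 120.0, 0.0)
    atoms["HH12"] = place_atom(ne, cz, nh1, 1.01, 120.0, 180.0)
    atoms["HH21"] = place_atom(ne, cz, nh2, 1.01, 120.0, 0.0)
    atoms["HH22"] = place_atom(ne, cz, nh2, 1.01, 120.0, 180.0)
    elements = {n: ("N" if n.startswith("N") else "H" if n.startswith("H") else "C") for n in atoms}
    return FunctionalGroupType(
        fg_name="guanidinium",
        atoms=atoms,
        elements=elements,
        donors=(
            ("NE", "HE"),
            ("NH1", "HH11"),
            ("NH1", "HH12"),
            ("NH2", "HH21"),
            ("NH2", "HH22"),
        ),
        acceptors=(),
        attachment=("NE", tuple(_unit(place_atom(nh2, cz, ne, 1.46, 120.0, 180.0) - ne))),
        residue_identities=("ARG",),
        reference_atom="CZ",
        chain_anchors=("CZ", "NE"),
    )


def _unit(v):
    return v / np.linalg.norm(v)


def _primary_amine() -> FunctionalGroupType:
    # sp3 nitrogen at origin; chain continues toward -x; three H at
    # tetrahedral angles from the chain direction.
    nz = _v(0, 0, 0)
    u = _v(-1.0, 0, 0)
    atoms = {"NZ": nz}
    for i, az in enumerate((0.0, 120.0, 240.0)):
        a = np.radians(109.47)
        b = np.radians(az)
        d = _v(
            -np.cos(a),
            np.sin(a) * np.cos(b),
            np.sin(a) * np.sin(b),
        )
        atoms[f"HZ{i+1}"] = nz + 1.01 * d  # tetrahedral, away from the chain
    elements = {"NZ": "N", "HZ1": "H", "HZ2": "H", "HZ3": "H"}
    return FunctionalGroupType(
        fg_name="primary_amine",
        atoms=atoms,
        elements=elements,
        donors=(("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")),
        acceptors=(),
        attachment=("NZ", tuple(u)),
        residue_identities=("LYS",),
        reference_atom="NZ",
        covalent_atom="NZ",
        chain_anchors=("HZ3", "HZ2"),
    )


_BUILDERS = {
    "hydroxyl": _hydroxyl,
    "phenol": _phenol,
    "carboxylate": _carboxylate,
    "carboxamide": _carboxamide,
    "imidazole": _imidazole,
    "guanidinium": _guanidinium,
    "primary_amine": _primary_amine,
}

FG_NAMES = tuple(sorted(_BUILDERS))

_CACHE: dict = {}


def fg_template(fg_name: str) -> FunctionalGroupType:
    """Return the immutable built-in template for ``fg_name``."""
    if fg_name not in _BUILDERS:
        raise KeyError(
            f"unknown functional group {fg_name!r}; known: {', '.join(FG_NAMES)}"
        )
    if fg_name not in _CACHE:
        _CACHE[fg_name] = _BUILDERS[fg_name]()
    return _CACHE[fg_name]
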