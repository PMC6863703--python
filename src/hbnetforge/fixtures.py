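"""Deterministic toy systems: ligands, ideal scaffolds, planted networks.

Everything here is generated from closed-form ideal geometry — no data
files, no randomness — so every pipeline stage can be exercised and
audited at desk scale.  The toy ligands are chemically sensible minimal
molecules (a vicinal diol, a ketone bearing a phosphate, a carbinolamine
tetrahedral intermediate), not transition-state models of any particular
reaction.
"""

from __future__ import annotations

import numpy as np

from .chem_model import (
    ActiveSiteSpec,
    InteractionEdge,
    InteractionSite,
    LigandModel,
    validate_spec,
)
from .errors import ConstructionError
from .geometry import place_atom

_V = np.array([0.0, 1.0, 0.0])  # virtual reference for seeding z-matrices

TOY_LIGANDS = ("diol", "keto_phosphate", "carbinolamine_ts")


def make_toy_ligand(name: str) -> LigandModel:
    """Build one of the built-in toy ligands with annotated sites."""
    if name == "diol":
        return _diol()
    if name == "keto_phosphate":
        return _keto_phosphate()
    if name == "carbinolamine_ts":
        return _carbinolamine_ts()
    raise KeyError(f"unknown toy ligand {name!r}; known: {', '.join(TOY_LIGANDS)}")


def _diol() -> LigandModel:
    c1 = np.zeros(3)
    c2 = np.array([1.53, 0.0, 0.0])
    o1 = place_atom(_V, c2, c1, 1.43, 109.5, 60.0)
    c3 = place_atom(_V, c2, c1, 1.53, 109.5, 180.0)
    o2 = place_atom(o1, c1, c2, 1.43, 109.5, 60.0)
    c4 = place_atom(o1, c1, c2, 1.53, 109.5, 180.0)
    h1 = place_atom(c2, c1, o1, 0.96, 109.5, 180.0)
    h2 = place_atom(c1, c2, o2, 0.96, 109.5, 180.0)
    atoms = [
        ("C1", "C", c1), ("C2", "C", c2), ("O1", "O", o1), ("O2", "O", o2),
        ("C3", "C", c3), ("C4", "C", c4), ("H1", "H", h1), ("H2", "H", h2),
    ]
    sites = [
        InteractionSite("don1", "O1", "donor", ("H1",)),
        InteractionSite("don2", "O2", "donor", ("H2",)),
        InteractionSite("acc1", "O1", "acceptor", ("C1",)),
        InteractionSite("acc2", "O2", "acceptor", ("C2",)),
    ]
    return LigandModel("diol", atoms, sites)


def _keto_phosphate() -> LigandModel:
    c1 = np.zeros(3)
    c2 = np.array([-1.51, 0.0, 0.0])
    c3 = place_atom(_V, c2, c1, 1.51, 116.0, 180.0)
    o1 = place_atom(c3, c2, c1, 1.23, 122.0, 180.0)  # carbonyl, in plane
    o3 = place_atom(c2, c1, c3, 1.43, 109.5, 60.0)  # bridging ester O
    p = place_atom(c1, c3, o3, 1.60, 120.0, 180.0)
    op1 = place_atom(c3, o3, p, 1.50, 109.5, 60.0)
    op2 = place_atom(c3, o3, p, 1.50, 109.5, 180.0)
    op3 = place_atom(c3, o3, p, 1.50, 109.5, 300.0)
    atoms = [
        ("C1", "C", c1), ("C2", "C", c2), ("C3", "C", c3), ("O1", "O", o1),
        ("O3", "O", o3), ("P", "P", p),
        ("OP1", "O", op1), ("OP2", "O", op2), ("OP3", "O", op3),
    ]
    sites = [
        InteractionSite("acc_carbonyl", "O1", "acceptor", ("C1",)),
        InteractionSite("acc_p1", "OP1", "acceptor", ("P",)),
        InteractionSite("acc_p2", "OP2", "acceptor", ("P",)),
        InteractionSite("acc_p3", "OP3", "acceptor", ("P",)),
    ]
    return LigandModel("keto_phosphate", atoms, sites)


def _carbinolamine_ts() -> LigandModel:
    cn = np.zeros(3)
    c2 = np.array([1.54, 0.0, 0.0])
    oc = place_atom(_V, c2, cn, 1.40, 109.5, 60.0)
    hoc = place_atom(c2, cn, oc, 0.96, 109.5, 180.0)
    o2 = place_atom(oc, cn, c2, 1.43, 109.5, 60.0)
    ho2 = place_atom(cn, c2, o2, 0.96, 109.5, 180.0)
    c3 = place_atom(oc, cn, c2, 1.53, 109.5, 180.0)
    atoms = [
        ("CN", "C", cn), ("C2", "C", c2), ("OC", "O", oc), ("O2", "O", o2),
        ("C3", "C", c3), ("HOC", "H", hoc), ("HO2", "H", ho2),
    ]
    sites = [
        InteractionSite("cov", "CN", "covalent_attachment", ("C2",)),
        InteractionSite("acc_oc", "OC", "acceptor", ("CN",)),
        InteractionSite("don_oc", "OC", "donor", ("HOC",)),
        InteractionSite("acc_o2", "O2", "acceptor", ("C2",)),
        InteractionSite("don_o2", "O2", "donor", ("HO2",)),
    ]
    return LigandModel("carbinolamine_ts", atoms, sites)


# ---------------------------------------------------------------------------
# demo active-site specifications


def make_demo_spec(name: str, ligand: LigandModel | None = None) -> ActiveSiteSpec:
    """Built-in wiring diagrams matching the toy ligands.

    ``diol_pair``: a serine-like hydroxyl and an amide, bridged to each
    other and to the diol.  ``amine_quartet``: a covalently attached amine
    plus hydrogen-bonded polar groups around the carbinolamine intermediate
    (the topology of an evolved retro-aldolase active site).
    """
    if name == "diol_pair":
        ligand = ligand or make_toy_ligand("diol")
        spec = ActiveSiteSpec(
            name="diol_pair",
            groups=[("S1", "hydroxyl"), ("N1", "carboxamide")],
            edges=[
                InteractionEdge("e_lig_s1", "hbond", {"ligand": "don1"}, {"group": "S1", "role": "acceptor"}),
                InteractionEdge("e_lig_n1", "hbond", {"ligand": "acc2"}, {"group": "N1", "role": "donor"}),
                InteractionEdge("e_s1_n1", "hbond", {"group": "S1", "role": "donor"}, {"group": "N1", "role": "acceptor"}),
            ],
        )
    elif name == "phosphate_bridge":
        ligand = ligand or make_toy_ligand("keto_phosphate")
        spec = ActiveSiteSpec(
            name="phosphate_bridge",
            groups=[("N1", "carboxamide"), ("S1", "hydroxyl")],
            edges=[
                InteractionEdge("e_lig_n1", "hbond", {"ligand": "acc_p1"}, {"group": "N1", "role": "donor"}),
                InteractionEdge("e_lig_s1", "hbond", {"ligand": "acc_p2"}, {"group": "S1", "role": "donor"}),
                InteractionEdge("e_n1_s1", "hbond", {"group": "N1", "role": "donor"}, {"group": "S1", "role": "acceptor"}),
            ],
        )
    elif name == "amine_quartet":
        ligand = ligand or make_toy_ligand("carbinolamine_ts")
        spec = ActiveSiteSpec(
            name="amine_quartet",
            groups=[
                ("K1", "primary_amine"),
                ("Y1", "phenol"),
                ("Y2", "phenol"),
                ("N1", "carboxamide"),
            ],
            edges=[
                InteractionEdge("e_cov", "covalent", {"ligand": "cov"}, {"group": "K1"}),
                InteractionEdge("e_y1", "hbond", {"ligand": "acc_oc"}, {"group": "Y1", "role": "donor"}),
                InteractionEdge("e_y2", "hbond", {"ligand": "acc_o2"}, {"group": "Y2", "role": "donor"}),
                InteractionEdge("e_n1", "hbond", {"ligand": "don_o2"}, {"group": "N1", "role": "acceptor"}),
                InteractionEdge("e_k1_y1", "hbond", {"group": "K1", "role": "donor"}, {"group": "Y1", "role": "acceptor"}),
            ],
            require_ligand_contact=True,
        )
    else:
        raise KeyError(f"unknown demo spec {name!r}")
    validate_spec(spec, ligand)
    return spec


# ---------------------------------------------------------------------------
# scaffolds

_BB = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.5, "omega": 180.0,
}


def build_backbone(n_res: int, phi: float, psi: float):
    """Ideal poly-backbone with constant (phi, psi); returns a list of
    dicts with N, CA, C, O coordinates per residue."""
    if n_res < 1:
        raise ValueError("need at least one residue")
    res = []
    n = np.zeros(3)
    ca = np.array([_BB["n_ca"], 0.0, 0.0])
    c = place_atom(_V, n, ca, _BB["ca_c"], _BB["ang_n_ca_c"], 57.0)
    res.append({"N": n, "CA": ca, "C": c})
    for i in range(1, n_res):
        prev = res[-1]
        n_next = place_atom(prev["N"], prev["CA"], prev["C"],
                            _BB["c_n"], _BB["ang_ca_c_n"], psi)
        ca_next = place_atom(prev["CA"], prev["C"], n_next,
                             _BB["n_ca"], _BB["ang_c_n_ca"], _BB["omega"])
        c_next = place_atom(prev["C"], n_next, ca_next,
                            _BB["ca_c"], _BB["ang_n_ca_c"], phi)
        prev["O"] = place_atom(prev["N"], prev["CA"], prev["C"],
                               _BB["c_o"], _BB["ang_ca_c_o"], psi + 180.0)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    last = res[-1]
    last["O"] = place_atom(last["N"], last["CA"], last["C"],
                           _BB["c_o"], _BB["ang_ca_c_o"], psi + 180.0)
    return res


def make_helix_scaffold(n_res: int):
    """Ideal alpha-helical poly-alanine backbone (phi=-57, psi=-47)."""
    from .match import ScaffoldModel

    if n_res < 4:
        raise ValueError("helix scaffold needs at least 4 residues")
    bb = build_backbone(n_res, phi=-57.0, psi=-47.0)
    residues = [
        ("A", i + 1, r["N"], r["CA"], r["C"], r["O"]) for i, r in enumerate(bb)
    ]
    return ScaffoldModel(f"helix{n_res}", residues)


def plant_network_scaffold(network, realizations: dict, padding: float = 3.2,
                           segment_len: int = 5):
    """Scaffold with one ideal extended segment per group, whose central
    residue carries exactly that group's backbone anchor frame.

    A matcher run against this scaffold must, by construction, be able to
    re-place the network it was built from.  Raises ConstructionError when
    the segments cannot be placed without clashes (against each other, the
    other groups' side chains, or the ligand the network was built around).
    """
    from .match import ScaffoldModel

    if set(realizations) != set(network.placements):
        raise ValueError("need one realization per network group")
    if segment_len < 1 or segment_len % 2 == 0:
        raise ValueError("segment_len must be odd and positive")
    mid = segment_len // 2
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    residues = []
    seg_backbones = []
    labels = sorted(realizations)
    for gi, label in enumerate(labels):
        real = realizations[label]
        # the central residue carries the anchor frame *exactly*; the rest
        # of the segment is grown outward with ideal extended geometry
        placed = _extend_segment(real.backbone_frame, segment_len, mid,
                                 phi=-120.0, psi=120.0)
        seg_backbones.append((label, placed))
        for i, r in enumerate(placed):
            residues.append(
                (chain_ids[gi], i + 1, r["N"], r["CA"], r["C"], r.get("O"))
            )

    # clash audits
    def seg_atoms(i):
        return np.array(
            [v for r in seg_backbones[i][1] for v in r.values()]
        )

    for i in range(len(seg_backbones)):
        for j in range(i + 1, len(seg_backbones)):
            d = _min_dist(seg_atoms(i), seg_atoms(j))
            if d < padding:
                raise ConstructionError(
                    f"segments {labels[i]} and {labels[j]} overlap "
                    f"(min distance {d:.2f} A < {padding} A)"
                )
    lig_heavy = None
    ligand = getattr(network, "ligand", None)
    for i, (label, placed) in enumerate(seg_backbones):
        seg_xyz = seg_atoms(i)
        for j, other in enumerate(labels):
            if other == label:
                continue
            side = np.array([x for _, x in realizations[other].heavy_atom_items()])
            d = _min_dist(seg_xyz, side)
            if d < padding:
                raise ConstructionError(
                    f"segment {label} clashes with side chain {other} "
                    f"(min distance {d:.2f} A < {padding} A)"
                )
    return ScaffoldModel(f"planted_{network.index}", residues)


def _extend_segment(frame: np.ndarray, n_res: int, mid: int, phi: float, psi: float):
    """Grow an ideal backbone segment outward from one exact (N, CA, C)."""
    res = [None] * n_res
    res[mid] = {"N": np.asarray(frame[0]), "CA": np.asarray(frame[1]),
                "C": np.asarray(frame[2])}
    for i in range(mid + 1, n_res):
        p = res[i - 1]
        n_next = place_atom(p["N"], p["CA"], p["C"], _BB["c_n"],
                            _BB["ang_ca_c_n"], psi)
        ca_next = place_atom(p["CA"], p["C"], n_next, _BB["n_ca"],
                             _BB["ang_c_n_ca"], _BB["omega"])
        c_next = place_atom(p["C"], n_next, ca_next, _BB["ca_c"],
                            _BB["ang_n_ca_c"], phi)
        res[i] = {"N": n_next, "CA": ca_next, "C": c_next}
    for i in range(mid - 1, -1, -1):
        nxt = res[i + 1]
        c_prev = place_atom(nxt["C"], nxt["CA"], nxt["N"], _BB["c_n"],
                            _BB["ang_c_n_ca"], phi)
        ca_prev = place_atom(nxt["CA"], nxt["N"], c_prev, _BB["ca_c"],
                             _BB["ang_ca_c_n"], _BB["omega"])
        n_prev = place_atom(nxt["N"], c_prev, ca_prev, _BB["n_ca"],
                            _BB["ang_n_ca_c"], psi)
        res[i] = {"N": n_prev, "CA": ca_prev, "C": c_prev}
    for i, r in enumerate(res):
        if i + 1 < n_res:
            # carbonyl O in the peptide plane, anti to the next N
            r["O"] = place_atom(res[i + 1]["N"], r["CA"], r["C"],
                                _BB["c_o"], _BB["ang_ca_c_o"], 180.0)
        else:
            r["O"] = place_atom(r["N"], r["CA"], r["C"], _BB["c_o"],
                                _BB["ang_ca_c_o"], psi + 180.0)
    return res


def plant_first_viable(network, pools: dict, ligand: LigandModel | None = None,
                       padding: float = 3.2):
    """First rotamer combination of a network that plants cleanly.

    Iterates realization combinations in deterministic order and returns
    (scaffold, chosen realizations) for the first one whose segments are
    mutually clash-free (and clear of the ligand, when given); raises
    ConstructionError when no combination plants.
    """
    import itertools

    labels = sorted(pools)
    for combo in itertools.product(*(range(len(pools[l])) for l in labels)):
        chosen = {l: pools[l][i] for l, i in zip(labels, combo)}
        if _sidechains_clash(chosen):
            continue
        try:
            sc = plant_network_scaffold(network, chosen, padding)
            if ligand is not None:
                check_scaffold_vs_ligand(sc, ligand, padding)
        except ConstructionError:
            continue
        return sc, chosen
    raise ConstructionError("no rotamer combination of this network plants cleanly")


def _sidechains_clash(chosen: dict, threshold: float = 2.7) -> bool:
    """Heavy-atom clash between realizations, ignoring FG-FG contacts
    (those were already vetted, with hydrogen-bond exemptions, during
    network assembly)."""
    labels = sorted(chosen)
    for x in range(len(labels)):
        for y in range(x + 1, len(labels)):
            ra, rb = chosen[labels[x]], chosen[labels[y]]
            fg_a = set(ra.placement.atom_xyz)
            fg_b = set(rb.placement.atom_xyz)
            for na, xa in ra.heavy_atom_items():
                for nb, xb in rb.heavy_atom_items():
                    if na in fg_a and nb in fg_b:
                        continue
                    if np.linalg.norm(np.asarray(xa) - np.asarray(xb)) < threshold:
                        return True
    return False


def check_scaffold_vs_ligand(scaffold, ligand: LigandModel, padding: float = 3.2):
    """Raise ConstructionError if scaffold backbone sits on the ligand."""
    lig = ligand.coords(ligand.heavy_atom_names())
    bb = scaffold.backbone_coords()
    d = _min_dist(bb, lig)
    if d < padding:
        raise ConstructionError(
            f"scaffold backbone within {d:.2f} A of the ligand (< {padding} A)"
        )


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))
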