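"""Pairwise hydrogen-bond filtering and assembly of complete networks.

A network configuration assigns one placement to every group of the
active-site specification such that every specified interaction — with the
ligand and between groups — is geometrically realized and no two groups
clash.  Pair tables record, for each group-group edge, exactly which
placement pairs realize the bond; assembly is a deterministic backtracking
search over those tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chem_model import ActiveSiteSpec, InteractionEdge, LigandModel
from .errors import SpecError
from .fg_library import fg_template
from .geometry import HBondParams, hbond_eval

logger = logging.getLogger(__name__)

CLASH_THRESHOLD_DEFAULT = 2.7  # A heavy-heavy
MAX_NETWORKS_DEFAULT = 2_000_000
COVALENT_WINDOW = (1.2, 1.8)  # A, accepted covalent bond length


@dataclass
class PairTable:
    """Compatible placement pairs for one group-group edge."""

    edge_id: str
    label_a: str
    label_b: str
    pairs: list  # [(ia, ib, score, (donor_heavy, acceptor_heavy) names by side)]
    surviving_a: list
    surviving_b: list

    def pair_map(self):
        """(ia, ib) -> (score, exempt atom names (atom_on_a, atom_on_b))."""
        return {(ia, ib): (s, ex) for ia, ib, s, ex in self.pairs}


def _donor_options(fg, atom, omitted=()):
    opts = [p for p in fg.donor_pairs() if atom in (None, p[0]) and p[1] not in omitted]
    return opts


def _acceptor_options(fg, atom):
    return [e for e in fg.acceptor_entries() if atom in (None, e[0])]


def filter_pairs(
    edge: InteractionEdge,
    placements_a: list,
    placements_b: list,
    hbond_params: HBondParams | None = None,
):
    """All placement pairs of a group-group edge that realize its H-bond.

    ``placements_a`` belongs to the first endpoint of the edge and
    ``placements_b`` to the second.  Uses a spatial tree to prune candidate
    pairs but returns exactly what an all-pairs scan would.
    """
    params = hbond_params or HBondParams()
    if edge.kind != "hbond":
        raise SpecError(f"filter_pairs expects an hbond edge, got {edge.kind}")
    la, lb = edge.endpoints()
    if "ligand" in (la, lb):
        raise SpecError("filter_pairs is for group-group edges")
    donor_end, acceptor_end = edge.donor_end, edge.acceptor_end
    a_is_donor = donor_end.ref == la

    best: dict = {}
    if placements_a and placements_b:
        don_pls = placements_a if a_is_donor else placements_b
        acc_pls = placements_b if a_is_donor else placements_a
        don_fg = fg_template(don_pls[0].fg_name)
        acc_fg = fg_template(acc_pls[0].fg_name)
        for dh, dhyd in _donor_options(don_fg, donor_end.atom):
            for ah, bases in _acceptor_options(acc_fg, acceptor_end.atom):
                _scan_option(
                    don_pls, acc_pls, dh, dhyd, ah, bases, params, a_is_donor, best
                )

    pairs = [
        (ia, ib, best[(ia, ib)][0], best[(ia, ib)][1]) for ia, ib in sorted(best)
    ]
    surviving_a = sorted({p[0] for p in pairs})
    surviving_b = sorted({p[1] for p in pairs})
    table = PairTable(edge.edge_id, la, lb, pairs, surviving_a, surviving_b)
    return table, surviving_a, surviving_b


def _scan_option(don_pls, acc_pls, dh, dhyd, ah, bases, params, a_is_donor, best):
    D = np.array([p.atom_xyz[dh] for p in don_pls])
    H = np.array([p.atom_xyz[dhyd] for p in don_pls])
    skip_h = [dhyd in p.omitted_atoms for p in don_pls]
    A = np.array([p.atom_xyz[ah] for p in acc_pls])
    tree = cKDTree(A)
    cand = tree.query_ball_point(D, params.d_max)
    for i_d, js in enumerate(cand):
        if skip_h[i_d] or not js:
            continue
        for j in sorted(js):
            basecoords = np.array([acc_pls[j].atom_xyz[b] for b in bases])
            try:
                ok, score = hbond_eval(D[i_d], H[i_d], A[j], basecoords, params)
            except Exception:
                continue
            if not ok:
                continue
            key = (i_d, j) if a_is_donor else (j, i_d)
            exempt = (dh, ah) if a_is_donor else (ah, dh)
            cur = best.get(key)
            if cur is None or score < cur[0]:
                best[key] = (score, exempt)


def clash_check(atoms_a: dict, atoms_b: dict, threshold: float = CLASH_THRESHOLD_DEFAULT,
                exempt_pairs=()) -> bool:
    """True iff any non-exempt atom pair between the two sets is closer than
    ``threshold``.  ``exempt_pairs`` holds (name_in_a, name_in_b) tuples for
    legitimately close contacts such as hydrogen-bonded partners."""
    if threshold <= 0:
        raise ValueError("clash threshold must be positive")
    if not atoms_a or not atoms_b:
        return False
    names_a = list(atoms_a)
    names_b = list(atoms_b)
    xa = np.array([atoms_a[n] for n in names_a])
    xb = np.array([atoms_b[n] for n in names_b])
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    exempt = set(exempt_pairs)
    for i, na in enumerate(names_a):
        for j, nb in enumerate(names_b):
            if (na, nb) in exempt:
                d2[i, j] = np.inf
    return bool((d2 < threshold**2).any())


@dataclass
class NetworkConfiguration:
    """One placement per group satisfying every specified interaction."""

    placements: dict  # label -> Placement
    edge_scores: dict  # edge_id -> score
    edge_atoms: dict  # edge_id -> (atom names involved, by endpoint order)
    total_score: float
    indices: dict = None  # label -> index into the source placement set
    index: int = -1


def _heavy_atoms_of(placement):
    fg = fg_template(placement.fg_name)
    return {
        n: placement.atom_xyz[n]
        for n in fg.heavy_atoms()
        if n not in placement.omitted_atoms
    }


def assemble_networks(
    spec: ActiveSiteSpec,
    placement_sets: dict,
    pair_tables: dict,
    clash_threshold: float = CLASH_THRESHOLD_DEFAULT,
    max_networks: int = MAX_NETWORKS_DEFAULT,
    check_clashes: bool = True,
) -> list:
    """Backtracking assembly of complete, clash-free networks.

    ``placement_sets`` maps group label to its (ligand-interaction-filtered)
    placement list; ``pair_tables`` maps every group-group edge id to its
    PairTable.  Groups are assigned in spec order, candidate placements in
    ascending score order; output networks are sorted by ascending total
    score and truncated at ``max_networks``.
    """
    labels = spec.group_labels()
    gg_edges = spec.group_group_edges()
    for e in gg_edges:
        if e.edge_id not in pair_tables:
            raise SpecError(f"missing pair table for edge {e.edge_id}")

    # constraints[(earlier, later)] = (edge_id, orient, map idx->set(idx))
    constraints = {}
    for e in gg_edges:
        u, v = e.endpoints()
        iu, iv = labels.index(u), labels.index(v)
        tab = pair_tables[e.edge_id]
        fwd: dict = {}
        pmap = tab.pair_map()
        for (ia, ib), (score, exempt) in pmap.items():
            fwd.setdefault(ia, {})[ib] = (score, exempt)
        if iu < iv:
            constraints.setdefault((u, v), []).append((e.edge_id, tab, "ab", fwd))
        else:
            rev: dict = {}
            for (ia, ib), val in pmap.items():
                rev.setdefault(ib, {})[ia] = val
            constraints.setdefault((v, u), []).append((e.edge_id, tab, "ba", rev))

    order_by_label = {}
    for label in labels:
        pls = placement_sets.get(label, [])
        order_by_label[label] = sorted(
            range(len(pls)), key=lambda i: (pls[i].score, i)
        )

    results: list = []
    heavy_cache: dict = {}
    truncated = False

    def heavy(label, idx):
        key = (label, idx)
        if key not in heavy_cache:
            heavy_cache[key] = _heavy_atoms_of(placement_sets[label][idx])
        return heavy_cache[key]

    def backtrack(pos, chosen, edge_info):
        nonlocal truncated
        if truncated:
            return
        if pos == len(labels):
            placements = {l: placement_sets[l][chosen[l]] for l in labels}
            edge_scores = {}
            edge_atoms = {}
            total = 0.0
            for label in labels:
                for e in spec.ligand_edges_of(label):
                    pl = placements[label]
                    if e.edge_id == pl.source_edge:
                        edge_scores[e.edge_id] = pl.score
                        edge_atoms[e.edge_id] = (pl.interacting_atom, *pl.partner_atoms)
                        total += pl.score
            for eid, (score, exempt) in edge_info.items():
                edge_scores[eid] = score
                edge_atoms[eid] = exempt
                total += score
            if len(results) >= max_networks:
                truncated = True
                logger.warning("network cap %d reached; output truncated", max_networks)
                return
            results.append(
                NetworkConfiguration(
                    placements, edge_scores, edge_atoms, total, dict(chosen)
                )
            )
            return
        label = labels[pos]
        for idx in order_by_label[label]:
            ok = True
            new_edges = {}
            for prev in labels[:pos]:
                for eid, tab, orient, fwd in constraints.get((prev, label), []):
                    allowed = fwd.get(chosen[prev], {})
                    if idx not in allowed:
                        ok = False
                        break
                    score, exempt = allowed[idx]
                    # exempt atom names are ordered (endpoint a, endpoint b)
                    if orient == "ab":
                        ex_prev, ex_cur = exempt
                    else:
                        ex_cur, ex_prev = exempt
                    new_edges[eid] = (score, exempt, prev, ex_prev, ex_cur)
                if not ok:
                    break
            if not ok:
                continue
            if check_clashes:
                clash = False
                cur_atoms = heavy(label, idx)
                for prev in labels[:pos]:
                    exempts = []
                    for eid, (s, exempt, p, ex_prev, ex_cur) in new_edges.items():
                        if p == prev:
                            exempts.append((ex_prev, ex_cur))
                    if clash_check(
                        heavy(prev, chosen[prev]), cur_atoms,
                        clash_threshold, exempts,
                    ):
                        clash = True
                        break
                if clash:
                    continue
            chosen[label] = idx
            merged = dict(edge_info)
            merged.update({eid: (v[0], v[1]) for eid, v in new_edges.items()})
            backtrack(pos + 1, chosen, merged)
            del chosen[label]
            if truncated:
                return

    backtrack(0, {}, {})
    results.sort(
        key=lambda n: (n.total_score, tuple(n.indices[l] for l in labels))
    )
    for i, n in enumerate(results):
        n.index = i
    return results


# ---------------------------------------------------------------------------
# shared edge evaluation (used by assembly audits and match completeness)


def eval_edge(
    edge: InteractionEdge,
    spec: ActiveSiteSpec,
    ligand: LigandModel,
    group_atoms: dict,
    hbond_params: HBondParams | None = None,
    lig_transform=None,
    covalent_window=COVALENT_WINDOW,
):
    """Evaluate one spec edge in placed geometry.

    ``group_atoms`` maps label -> (atom_xyz dict, omitted atom set, fg_name).
    ``lig_transform`` optionally repositions the ligand (a RigidTransform).
    Returns (ok, score, exempt_atom_pairs).
    """
    params = hbond_params or HBondParams()

    def lig_xyz(name):
        p = ligand.xyz(name)
        return lig_transform.apply(p) if lig_transform is not None else p

    if edge.kind == "covalent":
        site = ligand.get_site(edge.site_end.ref)
        g = edge.group_end
        xyz, omitted, fgname = group_atoms[g.ref]
        atom = g.atom or fg_template(fgname).covalent_atom
        d = float(np.linalg.norm(np.asarray(xyz[atom]) - lig_xyz(site.atom_name)))
        ok = covalent_window[0] <= d <= covalent_window[1]
        return ok, 0.0, [((g.ref, atom), ("ligand", site.atom_name))] if ok else []

    donor_end, acceptor_end = edge.donor_end, edge.acceptor_end
    donor_opts = []
    if donor_end.kind == "ligand":
        site = ligand.get_site(donor_end.ref)
        D, H = ligand.donor_geometry(site)
        if lig_transform is not None:
            D, H = lig_transform.apply(D), lig_transform.apply(H)
        donor_opts.append((("ligand", site.atom_name), D, H))
    else:
        xyz, omitted, fgname = group_atoms[donor_end.ref]
        fg = fg_template(fgname)
        for dh, dhyd in _donor_options(fg, donor_end.atom, omitted):
            donor_opts.append(((donor_end.ref, dh), np.asarray(xyz[dh]), np.asarray(xyz[dhyd])))

    acc_opts = []
    if acceptor_end.kind == "ligand":
        site = ligand.get_site(acceptor_end.ref)
        A, bases = ligand.acceptor_geometry(site)
        if lig_transform is not None:
            A, bases = lig_transform.apply(A), lig_transform.apply(bases)
        acc_opts.append((("ligand", site.atom_name), A, bases))
    else:
        xyz, omitted, fgname = group_atoms[acceptor_end.ref]
        fg = fg_template(fgname)
        for ah, bases in _acceptor_options(fg, acceptor_end.atom):
            acc_opts.append(
                ((acceptor_end.ref, ah), np.asarray(xyz[ah]),
                 np.array([xyz[b] for b in bases]))
            )

    best = None
    for dkey, D, H in donor_opts:
        for akey, A, bases in acc_opts:
            try:
                ok, score = hbond_eval(D, H, A, bases, params)
            except Exception:
                continue
            if ok and (best is None or score < best[0]):
                best = (score, [(dkey, akey)])
    if best is None:
        return False, 0.0, []
    return True, best[0], best[1]


def audit_network(
    network: NetworkConfiguration,
    spec: ActiveSiteSpec,
    ligand: LigandModel,
    hbond_params: HBondParams | None = None,
) -> bool:
    """Re-check every spec edge of an assembled network from raw geometry."""
    group_atoms = {
        label: (pl.atom_xyz, set(pl.omitted_atoms), pl.fg_name)
        for label, pl in network.placements.items()
    }
    for e in spec.edges:
        ok, _, _ = eval_edge(e, spec, ligand, group_atoms, hbond_params)
        if not ok:
            return False
    return True
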