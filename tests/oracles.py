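"""Independent brute-force oracles used by the equivalence tests.

These re-derive the results of the fast implementations by the most direct
route available: plain nested loops, exhaustive pairwise deduplication and
scipy rotations instead of the package's hand-rolled Rodrigues kernels.
"""

import itertools

import numpy as np
from scipy.spatial.transform import Rotation

from hbnetforge.geometry import hbond_eval, place_atom, snap_to_grid


def _align(u_from, u_to):
    """Minimal rotation matrix taking u_from to u_to (via scipy)."""
    r, _ = Rotation.align_vectors([u_to], [u_from])
    return r.as_matrix()


def _spin(axis, deg):
    ax = np.asarray(axis) / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(deg) * ax).as_matrix()


def _torsion_reference(ligand, b, c):
    axis = c - b
    for name in ligand.atom_names():
        p = ligand.xyz(name)
        if np.linalg.norm(p - b) < 1e-6 or np.linalg.norm(p - c) < 1e-6:
            continue
        if np.linalg.norm(np.cross(p - b, axis)) > 1e-3:
            return p
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    return b + perp


def _clash(fg, coords, ligand, interacting, excluded_ligand, clash_min):
    for name in fg.heavy_atoms():
        for ln in ligand.heavy_atom_names():
            if name == interacting and ln in excluded_ligand:
                continue
            if np.linalg.norm(coords[name] - ligand.xyz(ln)) < clash_min:
                return True
    return False


def oracle_hbond_placements(ligand, site, fg, scheme, params, g, clash_min=2.7):
    """All-DOF enumeration of FG poses for one ligand site, deduplicated by
    exhaustive pairwise grid-key comparison.  Returns {key: best score}."""
    raw = []
    names = list(fg.atoms)
    if site.role == "acceptor":
        A, bases = ligand.acceptor_geometry(site)
        B = bases[0]
        ref = _torsion_reference(ligand, B, A)
        for dh, dhyd in fg.donor_pairs():
            Dt, Ht = fg.atoms[dh], fg.atoms[dhyd]
            r = np.linalg.norm(Ht - Dt)
            u_t = (Ht - Dt) / r
            for d, psi, chi_b, theta, chi_ax, s in itertools.product(
                scheme.distances, scheme.acceptor_angles, scheme.base_torsions,
                scheme.donor_angles, scheme.axis_torsions, scheme.spins,
            ):
                if d <= r:
                    continue
                D = place_atom(ref, B, A, d, psi, chi_b)
                href = B if np.linalg.norm(np.cross(B - A, D - A)) > 1e-6 else ref
                gamma = np.degrees(np.arcsin(min(1.0, r * np.sin(np.radians(theta)) / d)))
                alpha = 180.0 - theta - gamma
                if alpha < 1e-9:
                    if chi_ax != scheme.axis_torsions[0]:
                        continue
                    H = D + (A - D) / np.linalg.norm(A - D) * r
                else:
                    H = place_atom(href, A, D, r, alpha, chi_ax)
                ok, score = hbond_eval(D, H, A, bases, params)
                if not ok:
                    continue
                u_w = (H - D) / np.linalg.norm(H - D)
                R = _spin(u_w, s) @ _align(u_t, u_w)
                t = D - R @ Dt
                coords = {n: R @ fg.atoms[n] + t for n in names}
                if _clash(fg, coords, ligand, dh, {site.atom_name}, clash_min):
                    continue
                key = snap_to_grid(coords[fg.reference_atom], g)
                raw.append((key, score))
    elif site.role == "donor":
        D, H = ligand.donor_geometry(site)
        r = np.linalg.norm(H - D)
        ref = _torsion_reference(ligand, D, H)
        for ah, abases in fg.acceptor_entries():
            At = fg.atoms[ah]
            Bt = fg.atoms[abases[0]]
            lb = np.linalg.norm(Bt - At)
            u_t = (Bt - At) / lb
            for d, theta, chi_ax, psi, chi_b, s in itertools.product(
                scheme.distances, scheme.donor_angles, scheme.axis_torsions,
                scheme.acceptor_angles, scheme.base_torsions, scheme.spins,
            ):
                st = np.radians(theta)
                disc = d * d - (r * np.sin(st)) ** 2
                if disc <= 0:
                    continue
                l = r * np.cos(st) + np.sqrt(disc)
                if l <= 0:
                    continue
                A = place_atom(ref, D, H, l, theta, chi_ax)
                aref = D if np.linalg.norm(np.cross(D - H, A - H)) > 1e-6 else ref
                Bw = place_atom(aref, H, A, lb, psi, chi_b)
                u_w = (Bw - A) / np.linalg.norm(Bw - A)
                R = _spin(u_w, s) @ _align(u_t, u_w)
                t = A - R @ At
                coords = {n: R @ fg.atoms[n] + t for n in names}
                basecoords = np.array([coords[b] for b in abases])
                ok, score = hbond_eval(D, H, A, basecoords, params)
                if not ok:
                    continue
                if _clash(fg, coords, ligand, ah, {site.atom_name}, clash_min):
                    continue
                key = snap_to_grid(coords[fg.reference_atom], g)
                raw.append((key, score))
    else:
        raise ValueError(site.role)
    return _dedup(raw)


def oracle_covalent_placements(ligand, site, fg, scheme, g, bond_length=1.5,
                               bond_angle=109.5, clash_min=2.7):
    nuc = fg.covalent_atom
    consumed = next(h for heavy, h in fg.donor_pairs() if heavy == nuc)
    C = ligand.xyz(site.atom_name)
    aux = ligand.xyz(site.aux_atoms[0])
    ref = _torsion_reference(ligand, aux, C)
    Nt = fg.atoms[nuc]
    u_t = (fg.atoms[consumed] - Nt) / np.linalg.norm(fg.atoms[consumed] - Nt)
    near_c = {site.atom_name} | {
        n for n in ligand.heavy_atom_names()
        if np.linalg.norm(ligand.xyz(n) - C) < 1.8
    }
    raw = []
    for torsion, s in itertools.product(scheme.base_torsions, scheme.spins):
        N = place_atom(ref, aux, C, bond_length, bond_angle, torsion)
        u_w = (C - N) / np.linalg.norm(C - N)
        R = _spin(u_w, s) @ _align(u_t, u_w)
        t = N - R @ Nt
        coords = {n: R @ fg.atoms[n] + t for n in fg.atoms}
        if _clash(fg, coords, ligand, nuc, near_c, clash_min):
            continue
        key = snap_to_grid(coords[fg.reference_atom], g)
        raw.append((key, 0.0))
    return _dedup(raw)


def _dedup(raw):
    """Exhaustive pairwise dedup: best score per key, first seen on ties."""
    out = {}
    for key, score in raw:
        found = None
        for k in out:
            if k == key:
                found = k
                break
        if found is None or score < out[found]:
            out[key] = score if found is None else min(out[found], score)
    return out


# ---------------------------------------------------------------------------
# network oracles


def oracle_pair_table(edge, placements_a, placements_b, params):
    """O(n^2) scan over all placement pairs and donor/acceptor options."""
    from hbnetforge.fg_library import fg_template

    la, lb = edge.endpoints()
    a_is_donor = edge.donor_end.ref == la
    don_pls = placements_a if a_is_donor else placements_b
    acc_pls = placements_b if a_is_donor else placements_a
    pairs = {}
    if not don_pls or not acc_pls:
        return pairs
    don_fg = fg_template(don_pls[0].fg_name)
    acc_fg = fg_template(acc_pls[0].fg_name)
    for i, pd in enumerate(don_pls):
        for j, pa in enumerate(acc_pls):
            best = None
            for dh, dhyd in don_fg.donor_pairs():
                if edge.donor_end.atom not in (None, dh) or dhyd in pd.omitted_atoms:
                    continue
                for ah, bases in acc_fg.acceptor_entries():
                    if edge.acceptor_end.atom not in (None, ah):
                        continue
                    try:
                        ok, score = hbond_eval(
                            pd.atom_xyz[dh], pd.atom_xyz[dhyd], pa.atom_xyz[ah],
                            np.array([pa.atom_xyz[b] for b in bases]), params,
                        )
                    except Exception:
                        continue
                    if ok and (best is None or score < best):
                        best = score
            if best is not None:
                key = (i, j) if a_is_donor else (j, i)
                pairs[key] = best
    return pairs


def oracle_networks(spec, placement_sets, pair_maps, clash_threshold=2.7):
    """Cartesian-product enumeration with per-edge checks; returns the set
    of placement index tuples (in spec group order) of valid networks."""
    from hbnetforge.fg_library import fg_template

    labels = spec.group_labels()
    gg = spec.group_group_edges()
    out = set()
    for combo in itertools.product(*(range(len(placement_sets[l])) for l in labels)):
        chosen = dict(zip(labels, combo))
        ok = True
        exempts = {}
        for e in gg:
            u, v = e.endpoints()
            key = (chosen[u], chosen[v])
            pm = pair_maps[e.edge_id]
            if key not in pm:
                ok = False
                break
            exempts[(u, v)] = pm[key][1] if isinstance(pm[key], tuple) else None
        if not ok:
            continue
        # inter-group clash with H-bond exemption
        clash = False
        for x in range(len(labels)):
            for y in range(x + 1, len(labels)):
                lu, lv = labels[x], labels[y]
                pu = placement_sets[lu][chosen[lu]]
                pv = placement_sets[lv][chosen[lv]]
                ex = exempts.get((lu, lv)) or exempts.get((lv, lu))
                if exempts.get((lv, lu)) and not exempts.get((lu, lv)):
                    ex = (ex[1], ex[0])
                fg_u = fg_template(pu.fg_name)
                fg_v = fg_template(pv.fg_name)
                for nu in fg_u.heavy_atoms():
                    if nu in pu.omitted_atoms:
                        continue
                    for nv in fg_v.heavy_atoms():
                        if nv in pv.omitted_atoms:
                            continue
                        if ex and (nu, nv) == ex:
                            continue
                        if np.linalg.norm(pu.atom_xyz[nu] - pv.atom_xyz[nv]) < clash_threshold:
                            clash = True
                            break
                    if clash:
                        break
                if clash:
                    break
            if clash:
                break
        if not clash:
            out.add(combo)
    return out
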