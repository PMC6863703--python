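"""Grid-complete enumeration of functional-group placements.

One placement is a rigid pose of a functional-group template that realizes
one specified interaction with the ligand.  The continuous degrees of
freedom of a hydrogen bond (distance, donor angle, acceptor angle, two
torsions, and a spin of the group about its own interacting bond) are
sampled on user-controlled ladders, every sampled pose is audited against
the hydrogen-bond criteria and a ligand clash pre-filter, and the survivors
are deduplicated on a grid over the ligand's local frame: at most one pose
(the best-scoring one) is kept per grid cell of the group's reference atom.

The grid spacing therefore sets the effective resolution of the search:
with the default sampling and a 0.2 A grid a single donor-acceptor
interaction typically yields a few thousand unique placements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_model import InteractionSite, LigandModel
from .errors import SpecError
from .fg_library import FunctionalGroupType
from .geometry import (
    HBondParams,
    RigidTransform,
    hbond_eval,
    place_atom,
    rotation_about_axis,
    snap_to_grid,
)

COVALENT_BOND_LENGTH = 1.5  # A, partial covalent bond (e.g. carbinolamine N-C)
COVALENT_BOND_ANGLE = 109.5  # deg, ideal tetrahedral
CLASH_MIN_DEFAULT = 2.7  # A, heavy-heavy pre-filter against the ligand


def _frange(start, stop, step):
    out = []
    x = start
    while x <= stop + 1e-9:
        out.append(round(x, 6))
        x += step
    return out


@dataclass(frozen=True)
class SamplingScheme:
    """Discretization ladders for the hydrogen-bond degrees of freedom."""

    distances: tuple = tuple(_frange(2.6, 3.2, 0.1))
    donor_angles: tuple = tuple(_frange(120.0, 180.0, 15.0))
    acceptor_angles: tuple = tuple(_frange(90.0, 180.0, 10.0))
    base_torsions: tuple = tuple(_frange(0.0, 350.0, 10.0))
    axis_torsions: tuple = tuple(_frange(0.0, 340.0, 20.0))
    spins: tuple = tuple(_frange(0.0, 340.0, 20.0))

    def __post_init__(self):
        for name in ("distances", "donor_angles", "acceptor_angles",
                     "base_torsions", "axis_torsions", "spins"):
            vals = getattr(self, name)
            object.__setattr__(self, name, tuple(float(v) for v in vals))
            if not getattr(self, name):
                raise ValueError(f"sampling list {name} must be non-empty")
        if any(not 0 < a <= 180 for a in self.donor_angles):
            raise ValueError("donor angles must lie in (0, 180]")
        if any(not 0 < a <= 180 for a in self.acceptor_angles):
            raise ValueError("acceptor angles must lie in (0, 180]")

    def to_dict(self) -> dict:
        return {
            "distances": list(self.distances),
            "donor_angles": list(self.donor_angles),
            "acceptor_angles": list(self.acceptor_angles),
            "base_torsions": list(self.base_torsions),
            "axis_torsions": list(self.axis_torsions),
            "spins": list(self.spins),
        }

    @classmethod
    def from_dict(cls, d) -> "SamplingScheme":
        return cls(**{k: tuple(v) for k, v in d.items()})


def default_scheme() -> SamplingScheme:
    return SamplingScheme()


def coarse_scheme(n: int = 2) -> SamplingScheme:
    """A tiny scheme (n samples per degree of freedom) for oracle tests."""
    def pick(vals):
        vals = list(vals)
        if n >= len(vals):
            return tuple(vals)
        idx = np.linspace(0, len(vals) - 1, n).round().astype(int)
        return tuple(vals[i] for i in sorted(set(idx)))

    s = SamplingScheme()
    return SamplingScheme(
        distances=pick(s.distances),
        donor_angles=pick(s.donor_angles),
        acceptor_angles=pick(s.acceptor_angles),
        base_torsions=pick(s.base_torsions),
        axis_torsions=pick(s.axis_torsions),
        spins=pick(s.spins),
    )


@dataclass
class Placement:
    """One grid-deduplicated rigid pose of a functional group."""

    group_label: str
    fg_name: str
    transform: RigidTransform
    atom_xyz: dict  # template atom name -> realized xyz (ligand frame)
    grid_key: tuple  # tuple of integer triples for the reference atoms
    source_edge: str
    interacting_atom: str  # FG heavy atom realizing the source interaction
    partner_atoms: tuple  # ligand atoms on the other end
    score: float
    omitted_atoms: tuple = ()  # e.g. the hydrogen consumed by a covalent bond

    def coords(self, names) -> np.ndarray:
        return np.array([self.atom_xyz[n] for n in names])

    def heavy_coords(self, template: FunctionalGroupType) -> np.ndarray:
        names = [n for n in template.heavy_atoms() if n not in self.omitted_atoms]
        return self.coords(names)

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "fg_name": self.fg_name,
            "transform": self.transform.to_dict(),
            "atom_xyz": {k: list(map(float, v)) for k, v in self.atom_xyz.items()},
            "grid_key": [list(k) for k in self.grid_key],
            "source_edge": self.source_edge,
            "interacting_atom": self.interacting_atom,
            "partner_atoms": list(self.partner_atoms),
            "score": self.score,
            "omitted_atoms": list(self.omitted_atoms),
        }

    @classmethod
    def from_dict(cls, d) -> "Placement":
        return cls(
            group_label=d["group_label"],
            fg_name=d["fg_name"],
            transform=RigidTransform.from_dict(d["transform"]),
            atom_xyz={k: np.array(v) for k, v in d["atom_xyz"].items()},
            grid_key=tuple(tuple(k) for k in d["grid_key"]),
            source_edge=d["source_edge"],
            interacting_atom=d["interacting_atom"],
            partner_atoms=tuple(d["partner_atoms"]),
            score=float(d["score"]),
            omitted_atoms=tuple(d.get("omitted_atoms", ())),
        )


# ---------------------------------------------------------------------------
# internal helpers


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u to unit vector v."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    axis = axis / s
    return rotation_about_axis(axis, float(np.degrees(np.arctan2(s, c))))


def _spin_stack(axis: np.ndarray, angles) -> np.ndarray:
    """(n, 3, 3) rotations about a unit axis, vectorized Rodrigues."""
    ax = axis / np.linalg.norm(axis)
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    K2 = K @ K
    th = np.radians(np.asarray(angles, dtype=float))
    return (
        np.eye(3)[None, :, :]
        + np.sin(th)[:, None, None] * K[None, :, :]
        + (1 - np.cos(th))[:, None, None] * K2[None, :, :]
    )


def _torsion_reference(ligand: LigandModel, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Deterministic reference point defining torsion zero about the b-c axis."""
    axis = c - b
    for name in ligand.atom_names():
        p = ligand.xyz(name)
        if np.linalg.norm(p - b) < 1e-6 or np.linalg.norm(p - c) < 1e-6:
            continue
        if np.linalg.norm(np.cross(p - b, axis)) > 1e-3:
            return p
    # fall back to an arbitrary perpendicular direction
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    return b + perp


class _Accumulator:
    """Keeps the best-scoring placement per grid key (ties: first seen)."""

    def __init__(self):
        self.best: dict = {}
        self.counter = 0

    def add(self, key, score, maker):
        self.counter += 1
        cur = self.best.get(key)
        if cur is None or score < cur[0]:
            self.best[key] = (score, self.counter, maker())

    def sorted_placements(self) -> list:
        return [self.best[k][2] for k in sorted(self.best)]


def _clash_free(fg_heavy: np.ndarray, lig_heavy: np.ndarray, skip_mask: np.ndarray,
                clash_min: float) -> np.ndarray:
    """Boolean per-spin mask; fg_heavy is (s, m, 3), skip_mask is (m, L)."""
    diff = fg_heavy[:, :, None, :] - lig_heavy[None, None, :, :]
    d2 = np.einsum("smlk,smlk->sml", diff, diff)
    d2 = np.where(skip_mask[None, :, :], np.inf, d2)
    return d2.reshape(len(fg_heavy), -1).min(axis=1) >= clash_min**2


def _finalize(group_label, fg, R, t, site_atoms, source_edge, interacting_atom,
              score, grid_spacing, acc, omitted=()):
    names = list(fg.atoms)
    tpl = fg.coords(names)
    world = tpl @ R.T + t
    ref_xyz = world[names.index(fg.reference_atom)]
    key = (snap_to_grid(ref_xyz, grid_spacing),)

    def maker(world=world, R=R, t=t):
        return Placement(
            group_label=group_label,
            fg_name=fg.fg_name,
            transform=RigidTransform(R, t),
            atom_xyz={n: world[i] for i, n in enumerate(names)},
            grid_key=key,
            source_edge=source_edge,
            interacting_atom=interacting_atom,
            partner_atoms=tuple(site_atoms),
            score=score,
            omitted_atoms=tuple(omitted),
        )

    acc.add(key, score, maker)


# ---------------------------------------------------------------------------
# public operations


def enumerate_hbond_placements(
    ligand: LigandModel,
    site: InteractionSite,
    fg: FunctionalGroupType,
    scheme: SamplingScheme | None = None,
    hbond_params: HBondParams | None = None,
    grid_spacing: float = 0.2,
    group_label: str = "G",
    fg_atom: str | None = None,
    source_edge: str = "",
    clash_min: float = CLASH_MIN_DEFAULT,
) -> list:
    """Enumerate poses of ``fg`` hydrogen-bonded to one ligand site.

    The site role decides the pairing: an acceptor site is matched with the
    group's donor atoms and vice versa.  ``fg_atom`` restricts the group to
    one specific donor/acceptor heavy atom; by default all role-compatible
    atoms are tried.  Output is deduplicated on the grid and sorted by grid
    key, so identical inputs give byte-identical placement lists.
    """
    scheme = scheme or default_scheme()
    params = hbond_params or HBondParams()
    acc = _Accumulator()

    if site.role == "acceptor":
        pairs = [p for p in fg.donor_pairs() if fg_atom in (None, p[0])]
        if not pairs:
            raise SpecError(
                f"group {group_label} ({fg.fg_name}) has no donor atom"
                + (f" {fg_atom!r}" if fg_atom else "")
            )
        for heavy, hyd in pairs:
            _enumerate_fg_donor(
                ligand, site, fg, heavy, hyd, scheme, params, grid_spacing,
                group_label, source_edge, clash_min, acc,
            )
    elif site.role == "donor":
        entries = [e for e in fg.acceptor_entries() if fg_atom in (None, e[0])]
        if not entries:
            raise SpecError(
                f"group {group_label} ({fg.fg_name}) has no acceptor atom"
                + (f" {fg_atom!r}" if fg_atom else "")
            )
        for heavy, bases in entries:
            _enumerate_fg_acceptor(
                ligand, site, fg, heavy, bases, scheme, params, grid_spacing,
                group_label, source_edge, clash_min, acc,
            )
    else:
        raise SpecError(
            f"site {site.site_id} has role {site.role!r}; use "
            "enumerate_covalent_placements for covalent sites"
        )
    return acc.sorted_placements()


def _lig_heavy_setup(ligand: LigandModel, fg: FunctionalGroupType,
                     interacting_atom: str, excluded_ligand: set):
    lig_names = ligand.heavy_atom_names()
    lig_heavy = ligand.coords(lig_names)
    fg_names = fg.heavy_atoms()
    skip = np.zeros((len(fg_names), len(lig_names)), dtype=bool)
    gi = fg_names.index(interacting_atom)
    for j, ln in enumerate(lig_names):
        if ln in excluded_ligand:
            skip[gi, j] = True
    return fg_names, lig_heavy, skip


def _enumerate_fg_donor(ligand, site, fg, d_heavy, d_hyd, scheme, params,
                        grid_spacing, group_label, source_edge, clash_min, acc):
    """Group donor (D-H) against a ligand acceptor site."""
    A, bases = ligand.acceptor_geometry(site)
    B = bases[0]
    ref = _torsion_reference(ligand, B, A)
    r = float(np.linalg.norm(fg.atoms[d_hyd] - fg.atoms[d_heavy]))
    u_t = (fg.atoms[d_hyd] - fg.atoms[d_heavy]) / r
    names = list(fg.atoms)
    tpl = fg.coords(names)
    hvy_idx = [names.index(n) for n in fg.heavy_atoms()]
    fg_names, lig_heavy, skip = _lig_heavy_setup(
        ligand, fg, d_heavy, {site.atom_name}
    )
    Dt = fg.atoms[d_heavy]

    for d in scheme.distances:
        if d <= r:
            continue
        for psi in scheme.acceptor_angles:
            for chi_b in scheme.base_torsions:
                D = place_atom(ref, B, A, d, psi, chi_b)
                # psi = 180 puts D on the A-B axis; fall back to the external
                # reference to define the hydrogen's azimuth there
                if np.linalg.norm(np.cross(B - A, D - A)) > 1e-6:
                    href = B
                else:
                    href = ref
                for theta in scheme.donor_angles:
                    sin_g = r * np.sin(np.radians(theta)) / d
                    gamma = np.degrees(np.arcsin(min(1.0, sin_g)))
                    alpha = 180.0 - theta - gamma  # angle H-D-A at the donor
                    for chi_ax in scheme.axis_torsions:
                        if alpha < 1e-9:
                            H = D + (A - D) / np.linalg.norm(A - D) * r
                            if chi_ax != scheme.axis_torsions[0]:
                                continue  # degenerate: H on the D-A axis
                        else:
                            H = place_atom(href, A, D, r, alpha, chi_ax)
                        ok, score = hbond_eval(D, H, A, bases, params)
                        if not ok:
                            continue
                        u_w = (H - D) / np.linalg.norm(H - D)
                        R0 = _rotation_between(u_t, u_w)
                        spins = _spin_stack(u_w, scheme.spins)
                        Rs = spins @ R0
                        ts = D[None, :] - np.einsum("sij,j->si", Rs, Dt)
                        world = np.einsum("sij,aj->sai", Rs, tpl) + ts[:, None, :]
                        okmask = _clash_free(
                            world[:, hvy_idx, :], lig_heavy, skip, clash_min
                        )
                        for s_i in range(len(scheme.spins)):
                            if not okmask[s_i]:
                                continue
                            _finalize(
                                group_label, fg, Rs[s_i], ts[s_i],
                                (site.atom_name,), source_edge, d_heavy,
                                score, grid_spacing, acc,
                            )


def _enumerate_fg_acceptor(ligand, site, fg, a_heavy, a_bases, scheme, params,
                           grid_spacing, group_label, source_edge, clash_min, acc):
    """Group acceptor against a ligand donor site."""
    D, H = ligand.donor_geometry(site)
    r = float(np.linalg.norm(H - D))
    ref = _torsion_reference(ligand, D, H)
    At = fg.atoms[a_heavy]
    Bt = fg.atoms[a_bases[0]]
    lb = float(np.linalg.norm(Bt - At))
    u_t = (Bt - At) / lb
    names = list(fg.atoms)
    tpl = fg.coords(names)
    hvy_idx = [names.index(n) for n in fg.heavy_atoms()]
    base_idx = [names.index(b) for b in a_bases]
    fg_names, lig_heavy, skip = _lig_heavy_setup(
        ligand, fg, a_heavy, {site.atom_name}
    )

    for d in scheme.distances:
        for theta in scheme.donor_angles:
            st = np.radians(theta)
            disc = d * d - r * r * np.sin(st) ** 2
            if disc <= 0:
                continue
            l = r * np.cos(st) + np.sqrt(disc)  # |H-A| from the law of cosines
            if l <= 0:
                continue
            for chi_ax in scheme.axis_torsions:
                A = place_atom(ref, D, H, l, theta, chi_ax)
                # theta = 180 puts A on the D-H axis; fall back to the
                # external reference to define the base torsion there
                if np.linalg.norm(np.cross(D - H, A - H)) > 1e-6:
                    aref = D
                else:
                    aref = ref
                for psi in scheme.acceptor_angles:
                    for chi_b in scheme.base_torsions:
                        Bw = place_atom(aref, H, A, lb, psi, chi_b)
                        u_w = (Bw - A) / np.linalg.norm(Bw - A)
                        R0 = _rotation_between(u_t, u_w)
                        spins = _spin_stack(u_w, scheme.spins)
                        Rs = spins @ R0
                        ts = A[None, :] - np.einsum("sij,j->si", Rs, At)
                        world = np.einsum("sij,aj->sai", Rs, tpl) + ts[:, None, :]
                        okmask = _clash_free(
                            world[:, hvy_idx, :], lig_heavy, skip, clash_min
                        )
                        for s_i in range(len(scheme.spins)):
                            if not okmask[s_i]:
                                continue
                            bases_w = world[s_i, base_idx, :]
                            ok, score = hbond_eval(D, H, A, bases_w, params)
                            if not ok:
                                continue
                            _finalize(
                                group_label, fg, Rs[s_i], ts[s_i],
                                (site.atom_name,), source_edge, a_heavy,
                                score, grid_spacing, acc,
                            )


def enumerate_covalent_placements(
    ligand: LigandModel,
    site: InteractionSite,
    fg: FunctionalGroupType,
    scheme: SamplingScheme | None = None,
    grid_spacing: float = 0.2,
    group_label: str = "G",
    source_edge: str = "",
    bond_length: float = COVALENT_BOND_LENGTH,
    bond_angle: float = COVALENT_BOND_ANGLE,
    clash_min: float = CLASH_MIN_DEFAULT,
) -> list:
    """Enumerate poses of ``fg`` covalently bonded to a ligand site.

    The bond length and angle are fixed at their ideal values; the torsion
    about the ligand substituent axis and the spin of the group about the
    new bond are sampled.  The group's nucleophilic atom replaces one of its
    hydrogens with the bond (that hydrogen is dropped from the placement).
    """
    scheme = scheme or default_scheme()
    if site.role != "covalent_attachment":
        raise SpecError(f"site {site.site_id} is not a covalent_attachment site")
    if fg.covalent_atom is None:
        raise SpecError(f"group {group_label} ({fg.fg_name}) cannot bond covalently")
    nuc = fg.covalent_atom
    consumed = None
    for heavy, hyd in fg.donor_pairs():
        if heavy == nuc:
            consumed = hyd
            break
    if consumed is None:
        raise SpecError(f"{fg.fg_name}: no hydrogen on {nuc} to displace")

    C = ligand.xyz(site.atom_name)
    aux = ligand.xyz(site.aux_atoms[0])
    ref = _torsion_reference(ligand, aux, C)
    Nt = fg.atoms[nuc]
    u_t = fg.atoms[consumed] - Nt
    u_t = u_t / np.linalg.norm(u_t)

    names = list(fg.atoms)
    tpl = fg.coords(names)
    hvy = [n for n in fg.heavy_atoms()]
    hvy_idx = [names.index(n) for n in hvy]
    lig_names = ligand.heavy_atom_names()
    lig_heavy = ligand.coords(lig_names)
    # exempt the nucleophile against the bonded carbon and its substituents
    near_c = {site.atom_name} | {
        n for n in lig_names if np.linalg.norm(ligand.xyz(n) - C) < 1.8
    }
    skip = np.zeros((len(hvy), len(lig_names)), dtype=bool)
    ni = hvy.index(nuc)
    for j, ln in enumerate(lig_names):
        if ln in near_c:
            skip[ni, j] = True

    acc = _Accumulator()
    for torsion in scheme.base_torsions:
        N = place_atom(ref, aux, C, bond_length, bond_angle, torsion)
        u_w = (C - N) / np.linalg.norm(C - N)
        R0 = _rotation_between(u_t, u_w)
        spins = _spin_stack(u_w, scheme.spins)
        Rs = spins @ R0
        ts = N[None, :] - np.einsum("sij,j->si", Rs, Nt)
        world = np.einsum("sij,aj->sai", Rs, tpl) + ts[:, None, :]
        okmask = _clash_free(world[:, hvy_idx, :], lig_heavy, skip, clash_min)
        for s_i in range(len(scheme.spins)):
            if not okmask[s_i]:
                continue
            _finalize(
                group_label, fg, Rs[s_i], ts[s_i], (site.atom_name,),
                source_edge, nuc, 0.0, grid_spacing, acc, omitted=(consumed,),
            )
    return acc.sorted_placements()


def dedupe_on_grid(placements: list, grid_spacing: float) -> list:
    """Re-deduplicate a placement list on the grid at ``grid_spacing``.

    Keeps the best-scoring placement per key (first seen wins ties) and
    returns the survivors sorted lexicographically by grid key.
    """
    if not placements:
        return []
    fgs = {p.fg_name for p in placements}
    if len(fgs) > 1:
        raise ValueError(f"mixed functional groups in dedupe_on_grid: {fgs}")
    from .fg_library import fg_template

    ref = fg_template(next(iter(fgs))).reference_atom
    best: dict = {}
    for i, p in enumerate(placements):
        key = (snap_to_grid(p.atom_xyz[ref], grid_spacing),)
        cur = best.get(key)
        if cur is None or p.score < cur[0]:
            best[key] = (p.score, i, key)
    out = []
    for key in sorted(best):
        _, i, k = best[key]
        p = placements[i]
        out.append(
            Placement(
                group_label=p.group_label,
                fg_name=p.fg_name,
                transform=p.transform,
                atom_xyz=p.atom_xyz,
                grid_key=k,
                source_edge=p.source_edge,
                interacting_atom=p.interacting_atom,
                partner_atoms=p.partner_atoms,
                score=p.score,
                omitted_atoms=p.omitted_atoms,
            )
        )
    return out
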