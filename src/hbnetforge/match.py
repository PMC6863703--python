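"""Place networks into scaffold backbones via rigid-transform hashing.

For every (designable position, side-chain realization) pair, superposing
the realization's backbone anchor frame onto the scaffold residue implies a
unique rigid pose of the ligand relative to the scaffold.  Poses are
quantized into 6-D bins (3 translation, 3+1 quantized-quaternion
orientation components); a match is a bin in which every group of the
specification has at least one entry at pairwise-distinct positions.  Each
candidate combination is rebuilt in full coordinates, clash-checked, and
evaluated for network *completeness*: whether every specified hydrogen
bond (and covalent bond) of the wiring diagram is realized in the placed
geometry.

Four search modes are supported:

- ``residue``  — classic residue-centric matching: rotamers come from the
  ligand interaction of each group alone, ignoring network structure;
- ``pooled``   — rotamers pooled from all networks in one calculation
  (efficient, but side chains from different networks can be remixed);
- ``clustered``— one pooled calculation per network cluster, limiting the
  remixing to geometrically similar networks;
- ``per_network`` — one calculation per network; by construction any match
  it reports uses the side-chain conformations of a single network.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .chem_model import ActiveSiteSpec, LigandModel
from .errors import FormatError, ValidationError
from .geometry import (
    HBondParams,
    RigidTransform,
    local_frame,
    superpose_frames,
)
from .network import clash_check, eval_edge
from .realize import CHI_DEFAULT, SideChainRealization, inverse_rotamers

logger = logging.getLogger(__name__)

MODES = ("residue", "pooled", "clustered", "per_network")

_IDEAL_N_CA = 1.458
_IDEAL_CA_C = 1.525
_BOND_SLACK = 0.20  # fractional tolerance on backbone bond lengths


@dataclass
class ScaffoldModel:
    """Protein backbone: a list of residues with N/CA/C (+O, CB) coords."""

    scaffold_id: str
    residues: list  # [(chain, resnum, N, CA, C, O-or-None, [CB-or-None]), ...]
    designable: list | None = None  # residue indices; None = all

    def __post_init__(self):
        seen = set()
        norm = []
        for r in self.residues:
            chain, resnum, n, ca, c = r[0], r[1], r[2], r[3], r[4]
            o = r[5] if len(r) > 5 else None
            cb = r[6] if len(r) > 6 else None
            if (chain, resnum) in seen:
                raise ValidationError(
                    f"duplicate residue {chain}{resnum} in scaffold {self.scaffold_id}"
                )
            seen.add((chain, resnum))
            n, ca, c = (np.asarray(x, dtype=float) for x in (n, ca, c))
            d1 = np.linalg.norm(ca - n)
            d2 = np.linalg.norm(c - ca)
            if abs(d1 - _IDEAL_N_CA) > _BOND_SLACK * _IDEAL_N_CA or abs(
                d2 - _IDEAL_CA_C
            ) > _BOND_SLACK * _IDEAL_CA_C:
                raise ValidationError(
                    f"residue {chain}{resnum}: backbone bond lengths "
                    f"({d1:.2f}, {d2:.2f} A) deviate >20% from ideal"
                )
            norm.append(
                (chain, int(resnum), n, ca, c,
                 None if o is None else np.asarray(o, dtype=float),
                 None if cb is None else np.asarray(cb, dtype=float))
            )
        self.residues = norm
        if self.designable is None:
            self.designable = list(range(len(norm)))

    def __len__(self):
        return len(self.residues)

    def frame(self, i: int) -> np.ndarray:
        _, _, n, ca, c, _, _ = self.residues[i]
        return np.array([n, ca, c])

    def position_id(self, i: int):
        chain, resnum = self.residues[i][0], self.residues[i][1]
        return (chain, resnum)

    def backbone_coords(self) -> np.ndarray:
        pts = []
        for chain, resnum, n, ca, c, o, cb in self.residues:
            pts.extend([n, ca, c])
            if o is not None:
                pts.append(o)
        return np.array(pts)

    def canonical(self):
        """Scaffold in the frame of its first residue, rounded to 1e-9 A.

        The rounding is fine enough not to perturb pose binning (entries
        that should share a 6-D bin stay together) while still wiping out
        the ~1e-13 A numerical noise a global rigid motion introduces.

        Returns (canonical scaffold, transform mapping canonical coords back
        to the original world frame).  All matching runs on the canonical
        form so that match counts are invariant under rigid motions of the
        input scaffold.
        """
        f = local_frame(self.frame(0))
        out = []
        for chain, resnum, n, ca, c, o, cb in self.residues:
            tr = lambda x: None if x is None else np.round(f.apply(x), 9)
            out.append((chain, resnum, tr(n), tr(ca), tr(c), tr(o), tr(cb)))
        return (
            ScaffoldModel(self.scaffold_id, out, list(self.designable)),
            f.inverse(),
        )


def load_scaffold(path, scaffold_id: str | None = None) -> ScaffoldModel:
    """Load a PDB backbone; residues lacking any of N/CA/C are skipped.

    Only the first altloc of each atom is used (a warning is logged when
    alternates are dropped).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    residues = []
    skipped = 0
    altloc_seen = False
    for model in st:
        for chain in model:
            for res in chain:
                atoms = {}
                for at in res:
                    if at.name in ("N", "CA", "C", "O", "CB"):
                        if at.name in atoms:
                            altloc_seen = True
                            continue  # keep the first altloc only
                        atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
                if all(k in atoms for k in ("N", "CA", "C")):
                    residues.append(
                        (chain.name, res.seqid.num, atoms["N"], atoms["CA"],
                         atoms["C"], atoms.get("O"), atoms.get("CB"))
                    )
                elif len(res) > 0 and res.het_flag != "H":
                    skipped += 1
        break
    if altloc_seen:
        logger.warning("%s: alternate locations present; kept first altloc", path)
    if skipped:
        logger.warning("%s: skipped %d residues with incomplete backbone", path, skipped)
    if not residues:
        raise FormatError(f"{path}: no residues with complete N/CA/C backbone")
    return ScaffoldModel(scaffold_id or str(path), residues)


@dataclass(frozen=True)
class MatchParams:
    trans_bin: float = 1.0  # A
    ori_bin_deg: float = 10.0
    per_bin_cap: int = 100  # rotamer entries kept per bin per group; 0 = off
    backbone_clash: float = 2.8  # A
    combo_cap: int = 1000  # full rebuilds per bin

    def __post_init__(self):
        if self.trans_bin <= 0 or self.ori_bin_deg <= 0:
            raise ValidationError("bin sizes must be positive")

    def fine(self) -> "MatchParams":
        return MatchParams(0.25, 2.5, self.per_bin_cap, self.backbone_clash,
                           self.combo_cap)


def _quat_bin(R: np.ndarray, ori_bin_deg: float) -> tuple:
    q = Rotation.from_matrix(R).as_quat()  # x, y, z, w
    for v in q:
        if abs(v) > 1e-12:
            if v < 0:
                q = -q
            break
    h = np.radians(ori_bin_deg) / 2.0
    return tuple(int(np.floor(v / h)) for v in q)


def pose_bin(t: RigidTransform, params: MatchParams) -> tuple:
    """6-D bin of a ligand pose: translation cells + quaternion cells."""
    tr = tuple(int(np.floor(v / params.trans_bin)) for v in t.translation)
    return tr + _quat_bin(t.rotation, params.ori_bin_deg)


@dataclass
class HashEntry:
    position: int  # residue index in the scaffold
    realization: SideChainRealization
    transform: RigidTransform  # ligand frame -> scaffold frame
    score: float
    order: int


def build_transform_hash(
    scaffold: ScaffoldModel,
    group_label: str,
    realizations: list,
    params: MatchParams | None = None,
) -> dict:
    """bin -> entries for one group over all designable scaffold positions.

    Each entry records the rigid transform that carries the realization
    (and hence the ligand it was built around) onto the scaffold position;
    entries whose side chain collides with the scaffold backbone (outside
    the host residue's immediate neighborhood) are excluded, and at most
    ``per_bin_cap`` best-scoring entries are kept per bin.
    """
    params = params or MatchParams()
    bb = scaffold.backbone_coords()
    tree = cKDTree(bb)
    # backbone atom -> owning residue index, for the neighborhood exclusion
    owners = []
    for i, (chain, resnum, n, ca, c, o, cb) in enumerate(scaffold.residues):
        owners.extend([i] * (3 + (o is not None)))
    owners = np.array(owners)

    table: dict = {}
    order = 0
    for pos in scaffold.designable:
        dst = scaffold.frame(pos)
        host_chain, host_num = scaffold.position_id(pos)
        near_host = np.array(
            [
                scaffold.residues[o][0] == host_chain
                and abs(scaffold.residues[o][1] - host_num) <= 2
                for o in owners
            ]
        )
        for ridx, real in enumerate(realizations):
            try:
                t = superpose_frames(real.backbone_frame, dst, tol=0.5)
            except Exception:
                continue
            heavy = np.array([x for _, x in real.heavy_atom_items()])
            placed = t.apply(heavy)
            idxs = tree.query_ball_point(placed, params.backbone_clash)
            clash = False
            for hits in idxs:
                for h in hits:
                    if not near_host[h]:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                continue
            b = pose_bin(t, params)
            table.setdefault(b, []).append(
                HashEntry(pos, real, t, real.placement.score, order)
            )
            order += 1
    for b, entries in table.items():
        entries.sort(key=lambda e: (e.score, e.order))
        if params.per_bin_cap:
            del entries[params.per_bin_cap:]
    return table


@dataclass
class MatchResult:
    scaffold_id: str
    ligand_pose: RigidTransform
    bin_key: tuple
    assignments: dict  # label -> (position_id, identity, chi_angles)
    edge_flags: dict  # edge_id -> bool
    complete: bool
    mode: str
    network_index: int = -1
    group_atoms: dict = field(default_factory=dict, repr=False)

    def positions(self) -> tuple:
        return tuple(sorted(a[0] for a in self.assignments.values()))


def evaluate_completeness(
    group_atoms: dict,
    spec: ActiveSiteSpec,
    ligand: LigandModel,
    lig_transform: RigidTransform,
    hbond_params: HBondParams | None = None,
):
    """Check every spec edge in placed geometry.

    ``group_atoms`` maps label -> (atoms dict, omitted set, fg_name) in the
    scaffold frame.  Returns (complete, per-edge flags, exempt atom pairs).
    """
    flags = {}
    exempt = []
    for e in spec.edges:
        ok, _, pairs = eval_edge(
            e, spec, ligand, group_atoms, hbond_params, lig_transform
        )
        flags[e.edge_id] = ok
        if ok:
            exempt.extend(pairs)
    return all(flags.values()), flags, exempt


def _match_one_pool(
    scaffold: ScaffoldModel,
    spec: ActiveSiteSpec,
    ligand: LigandModel,
    pools: dict,
    params: MatchParams,
    hbond_params: HBondParams | None,
    mode: str,
    network_index: int = -1,
) -> list:
    labels = spec.group_labels()
    if len(scaffold.designable) < len(labels):
        return []
    tables = {}
    for label in labels:
        tables[label] = build_transform_hash(
            scaffold, label, pools.get(label, []), params
        )
        if not tables[label]:
            return []
    common = set(tables[labels[0]])
    for label in labels[1:]:
        common &= set(tables[label])
    lig_heavy = ligand.coords(ligand.heavy_atom_names())
    bb_tree = cKDTree(scaffold.backbone_coords())
    results = []
    for b in sorted(common):
        entry_lists = [tables[label][b] for label in labels]
        n_combos = 0
        for combo in itertools.product(*entry_lists):
            n_combos += 1
            if params.combo_cap and n_combos > params.combo_cap:
                logger.warning("combination cap hit in bin %s", (b,))
                break
            positions = [e.position for e in combo]
            if len(set(positions)) != len(positions):
                continue
            t_lig = combo[0].transform
            # ligand must sit off the backbone
            placed_lig = t_lig.apply(lig_heavy)
            hits = bb_tree.query_ball_point(placed_lig, params.backbone_clash)
            if any(len(h) for h in hits):
                continue
            group_atoms = {}
            for label, e in zip(labels, combo):
                placed = {
                    n: e.transform.apply(x) for n, x in e.realization.atoms.items()
                }
                pl = e.realization.placement
                group_atoms[label] = (placed, set(pl.omitted_atoms), pl.fg_name)
            complete, flags, exempt = evaluate_completeness(
                group_atoms, spec, ligand, t_lig, hbond_params
            )
            if _sidechain_clash(labels, group_atoms, exempt):
                continue
            results.append(
                MatchResult(
                    scaffold_id=scaffold.scaffold_id,
                    ligand_pose=t_lig,
                    bin_key=b,
                    assignments={
                        label: (
                            scaffold.position_id(e.position),
                            e.realization.residue_identity,
                            e.realization.chi_angles,
                        )
                        for label, e in zip(labels, combo)
                    },
                    edge_flags=flags,
                    complete=complete,
                    mode=mode,
                    network_index=network_index,
                    group_atoms=group_atoms,
                )
            )
    return results


def _sidechain_clash(labels, group_atoms, exempt_pairs) -> bool:
    # exempt pairs come back keyed ((label, atom), (label-or-ligand, atom))
    ex = set()
    for (ka, aa), (kb, ab) in exempt_pairs:
        ex.add(((ka, aa), (kb, ab)))
        ex.add(((kb, ab), (ka, aa)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            la, lb = labels[i], labels[j]
            atoms_a = {
                n: x for n, x in group_atoms[la][0].items() if not n.startswith("H")
            }
            atoms_b = {
                n: x for n, x in group_atoms[lb][0].items() if not n.startswith("H")
            }
            pair_ex = [
                (aa, ab)
                for (ka, aa), (kb, ab) in ex
                if ka == la and kb == lb
            ]
            if clash_check(atoms_a, atoms_b, 2.7, pair_ex):
                return True
    return False


def prepare_realizations(
    networks,
    spec: ActiveSiteSpec,
    ligand: LigandModel,
    identities: dict | None = None,
    chi_samples=CHI_DEFAULT,
) -> list:
    """Per-network side-chain realizations: list of dict label -> list."""
    from .fg_library import fg_template

    identities = identities or {}
    out = []
    for net in networks:
        pool = {}
        for label, pl in net.placements.items():
            ident = identities.get(label) or fg_template(pl.fg_name).residue_identities[0]
            pool[label] = inverse_rotamers(pl, ident, chi_samples, ligand)
        out.append(pool)
    return out


def find_matches(
    scaffold: ScaffoldModel,
    spec: ActiveSiteSpec,
    networks=None,
    mode: str = "per_network",
    params: MatchParams | None = None,
    *,
    ligand: LigandModel,
    realizations_by_network: list | None = None,
    identities: dict | None = None,
    chi_samples=CHI_DEFAULT,
    clusters=None,
    placements: dict | None = None,
    hbond_params: HBondParams | None = None,
) -> list:
    """Match networks (or bare placements) into one scaffold.

    ``networks`` and the derived per-network realizations drive the
    ``per_network``, ``pooled`` and ``clustered`` modes; ``residue`` mode
    ignores networks and takes ``placements`` (label -> placement list)
    generated from each group's ligand interaction alone.  Results are
    deduplicated on (scaffold, ligand bin, position set).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    params = params or MatchParams()
    scaffold_c, _ = scaffold.canonical()
    results = []
    if mode == "residue":
        if placements is None:
            raise ValueError("residue mode requires placements")
        pools = {}
        from .fg_library import fg_template

        for label, pls in placements.items():
            ident = (identities or {}).get(label) or fg_template(
                spec.fg_of(label)
            ).residue_identities[0]
            pool = []
            for pl in pls:
                pool.extend(inverse_rotamers(pl, ident, chi_samples, ligand))
            pools[label] = pool
        results = _match_one_pool(
            scaffold_c, spec, ligand, pools, params, hbond_params, mode
        )
    else:
        if realizations_by_network is None:
            if networks is None:
                raise ValueError(f"{mode} mode requires networks")
            realizations_by_network = prepare_realizations(
                networks, spec, ligand, identities, chi_samples
            )
        if mode == "per_network":
            for ni, pool in enumerate(realizations_by_network):
                results.extend(
                    _match_one_pool(
                        scaffold_c, spec, ligand, pool, params, hbond_params,
                        mode, network_index=ni,
                    )
                )
        elif mode == "pooled":
            pools = _pool_realizations(spec, realizations_by_network)
            results = _match_one_pool(
                scaffold_c, spec, ligand, pools, params, hbond_params, mode
            )
        else:  # clustered
            if clusters is None:
                raise ValueError("clustered mode requires clusters")
            for cid in range(clusters.k):
                member_pools = [
                    realizations_by_network[i] for i in clusters.members(cid)
                ]
                pools = _pool_realizations(spec, member_pools)
                results.extend(
                    _match_one_pool(
                        scaffold_c, spec, ligand, pools, params, hbond_params,
                        mode, network_index=-1,
                    )
                )
    # deduplicate on (scaffold, bin, position set); the first occurrence
    # wins, except that a complete match supersedes an incomplete duplicate
    seen: dict = {}
    order = []
    for m in results:
        key = (m.scaffold_id, m.bin_key, m.positions())
        if key not in seen:
            seen[key] = m
            order.append(key)
        elif m.complete and not seen[key].complete:
            seen[key] = m
    return [seen[k] for k in order]


def _pool_realizations(spec: ActiveSiteSpec, pools_list) -> dict:
    """Union of per-network pools with geometric deduplication per group."""
    merged: dict = {label: [] for label in spec.group_labels()}
    seen: dict = {label: set() for label in spec.group_labels()}
    for pool in pools_list:
        for label, reals in pool.items():
            for r in reals:
                key = (
                    r.residue_identity,
                    tuple(
                        tuple(np.round(x, 2)) for _, x in sorted(r.atoms.items())
                    ),
                )
                if key in seen[label]:
                    continue
                seen[label].add(key)
                merged[label].append(r)
    return merged


# ---------------------------------------------------------------------------
# completion report


@dataclass
class CompletionReport:
    rows: list  # (simulation id, first column count, n_complete, rate string)

    def as_text(self) -> str:
        header = f"{'Simulation':<28s}{'Incomplete':>12s}{'Complete':>10s}{'Rate':>10s}"
        lines = [header]
        for sim, first, comp, rate in self.rows:
            lines.append(f"{sim:<28s}{first:>12,d}{comp:>10,d}{rate:>10s}")
        return "\n".join(lines)

    def as_tsv(self) -> str:
        lines = ["simulation\tn_incomplete\tn_complete\tcompletion_rate"]
        for sim, first, comp, rate in self.rows:
            lines.append(f"{sim}\t{first}\t{comp}\t{rate}")
        return "\n".join(lines)


def format_rate(n_complete: int, denominator: int) -> str:
    """Percentage formatted the way completion tables print it: three
    decimals below 0.1%, two decimals otherwise; 'n/a' for an empty run."""
    if denominator == 0:
        return "n/a"
    rate = 100.0 * n_complete / denominator
    if rate == 0:
        return "0%"
    return (f"{rate:.3f}%" if rate < 0.1 else f"{rate:.2f}%")


def completion_report(matches=None, counts=None, simulation_id="run") -> CompletionReport:
    """Completion-rate table from matches or from raw printed counts.

    ``counts`` is a list of (simulation id, first-column count, n_complete)
    rows; the rate is the ratio of complete networks to the first column.
    When ``matches`` is given, the first column is the number of incomplete
    matches.
    """
    rows = []
    if matches is not None:
        n_complete = sum(1 for m in matches if m.complete)
        n_incomplete = sum(1 for m in matches if not m.complete)
        rows.append(
            (simulation_id, n_incomplete, n_complete,
             format_rate(n_complete, n_incomplete))
        )
    if counts:
        for sim, first, comp in counts:
            rows.append((sim, int(first), int(comp), format_rate(comp, int(first))))
    return CompletionReport(rows)
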