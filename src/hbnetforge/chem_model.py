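"""Ligand models, interaction sites, and the 2D active-site specification.

The active-site specification is the machine-readable analogue of the
schematic "wiring diagram" a chemist would draw for an enzyme active site:
a list of catalytic side-chain functional groups plus the hydrogen-bond and
covalent interactions they make with the ligand (or transition-state model)
and with each other.  It carries connectivity only; all 3D content comes
later from enumeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .errors import FormatError, ParseError, SpecError, ValidationError
from .fg_library import FG_NAMES, fg_template
from .geometry import canonicalize_coords, place_atom

SITE_ROLES = ("donor", "acceptor", "covalent_attachment")

# PDB annotation record used to carry interaction sites alongside HETATM
# coordinates (crystallographic PDB files have no standard slot for this).
_SITE_REMARK = "REMARK 400 SITE"


@dataclass(frozen=True)
class InteractionSite:
    """One annotated hydrogen-bond donor/acceptor or covalent site."""

    site_id: str
    atom_name: str
    role: str
    aux_atoms: tuple

    def __post_init__(self):
        if self.role not in SITE_ROLES:
            raise ValidationError(f"site {self.site_id}: unknown role {self.role!r}")
        object.__setattr__(self, "aux_atoms", tuple(self.aux_atoms))
        if not 1 <= len(self.aux_atoms) <= 2:
            raise ValidationError(
                f"site {self.site_id}: need 1-2 aux atoms, got {len(self.aux_atoms)}"
            )


@dataclass
class LigandModel:
    """A small molecule (ligand or transition-state model) with sites.

    ``atoms`` is a list of (atom_name, element, xyz) tuples; names must be
    unique and every site must reference an existing atom.
    """

    name: str
    atoms: list
    sites: list = field(default_factory=list)

    def __post_init__(self):
        names = [a[0] for a in self.atoms]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ParseError(f"duplicate ligand atom names: {', '.join(dupes)}")
        coords = np.array([a[2] for a in self.atoms], dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite ligand coordinates")
        self._index = {n: i for i, n in enumerate(names)}
        for s in self.sites:
            for an in (s.atom_name, *s.aux_atoms):
                if an not in self._index:
                    raise ValidationError(
                        f"site {s.site_id} references unknown atom {an!r}"
                    )

    # -- accessors ---------------------------------------------------------
    def atom_names(self) -> list:
        return [a[0] for a in self.atoms]

    def coords(self, names=None) -> np.ndarray:
        if names is None:
            return np.array([a[2] for a in self.atoms], dtype=float)
        return np.array([self.atoms[self._index[n]][2] for n in names], dtype=float)

    def xyz(self, name: str) -> np.ndarray:
        return np.asarray(self.atoms[self._index[name]][2], dtype=float)

    def element(self, name: str) -> str:
        return self.atoms[self._index[name]][1]

    def heavy_atom_names(self) -> list:
        return [a[0] for a in self.atoms if a[1] != "H"]

    def get_site(self, site_id: str) -> InteractionSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"no site {site_id!r} on ligand {self.name}")

    # -- canonical frame ---------------------------------------------------
    def canonical(self) -> "LigandModel":
        """Same ligand expressed in its own local frame (rounded to 1e-6 A).

        All enumeration and counting is done on the canonical form so that
        results are exactly invariant under rigid motions of the input.
        """
        new = canonicalize_coords(self.coords())
        atoms = [(n, e, new[i]) for i, (n, e, _) in enumerate(self.atoms)]
        return LigandModel(self.name, atoms, list(self.sites))

    def donor_geometry(self, site: InteractionSite):
        """(donor heavy, hydrogen) world coordinates for a donor site.

        If the aux atom is an explicit hydrogen it is used directly;
        otherwise an idealized hydrogen is constructed from the heavy-atom
        antecedent at tetrahedral geometry with a deterministic torsion.
        """
        if site.role != "donor":
            raise SpecError(f"site {site.site_id} is not a donor")
        d = self.xyz(site.atom_name)
        aux = site.aux_atoms[0]
        if self.element(aux) == "H":
            return d, self.xyz(aux)
        ref = None
        for other in self.atom_names():
            if other not in (site.atom_name, aux):
                v = self.xyz(other)
                if np.linalg.norm(np.cross(v - aux_xyz(self, aux), d - aux_xyz(self, aux))) > 1e-6:
                    ref = v
                    break
        if ref is None:
            ref = aux_xyz(self, aux) + np.array([0.0, 0.0, 1.0])
        h = place_atom(ref, aux_xyz(self, aux), d, 1.0, 109.5, 180.0)
        return d, h

    def acceptor_geometry(self, site: InteractionSite):
        """(acceptor heavy, base atoms array) for an acceptor site."""
        if site.role != "acceptor":
            raise SpecError(f"site {site.site_id} is not an acceptor")
        a = self.xyz(site.atom_name)
        bases = np.array([self.xyz(n) for n in site.aux_atoms])
        return a, bases


def aux_xyz(ligand: LigandModel, name: str) -> np.ndarray:
    return ligand.xyz(name)


# ---------------------------------------------------------------------------
# ligand I/O


def load_ligand(path, format: str = None, name: str = None) -> LigandModel:
    """Load a ligand from PDB (HETATM) or SDF V2000.

    Interaction sites are read from ``REMARK 400 SITE`` records (PDB) or an
    ``HBNET_SITES`` data field (SDF) when present; they can also be attached
    later from the active-site spec's ``ligand_sites`` section.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in (".sdf", ".mol") else "pdb"
    if format == "pdb":
        return _load_ligand_pdb(path, name)
    if format == "sdf":
        return _load_ligand_sdf(path, name)
    raise FormatError(f"unsupported ligand format {format!r}")


def _load_ligand_pdb(path: Path, name) -> LigandModel:
    import gemmi

    text = Path(path).read_text()
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as e:
        raise FormatError(f"cannot parse PDB {path}: {e}") from e
    atoms = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    el = at.element.name if at.element else "C"
                    atoms.append((at.name, el, np.array([at.pos.x, at.pos.y, at.pos.z])))
        break
    if not atoms:
        raise FormatError(f"{path}: no atoms found")
    sites = _parse_site_remarks(text)
    return LigandModel(name or (st.name or path.stem), atoms, sites)


def _parse_site_remarks(text: str) -> list:
    sites = []
    for line in text.splitlines():
        if line.startswith(_SITE_REMARK):
            parts = line[len(_SITE_REMARK):].split()
            if len(parts) < 4:
                raise ParseError(f"malformed site annotation: {line!r}")
            site_id, atom, role, *aux = parts
            sites.append(InteractionSite(site_id, atom, role, tuple(aux)))
    return sites


def _load_ligand_sdf(path: Path, name) -> LigandModel:
    try:
        from rdkit import Chem
    except ImportError as e:  # pragma: no cover
        raise FormatError("SDF input requires rdkit") from e

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise FormatError(f"{path}: no molecule records")
    mol = mols[0]
    conf = mol.GetConformer()
    atoms = []
    counts: dict = {}
    for atom in mol.GetAtoms():
        el = atom.GetSymbol()
        if atom.HasProp("molFileAlias"):
            aname = atom.GetProp("molFileAlias")
        else:
            counts[el] = counts.get(el, 0) + 1
            aname = f"{el}{counts[el]}"
        p = conf.GetAtomPosition(atom.GetIdx())
        atoms.append((aname, el, np.array([p.x, p.y, p.z])))
    sites = []
    if mol.HasProp("HBNET_SITES"):
        for rec in json.loads(mol.GetProp("HBNET_SITES")):
            sites.append(
                InteractionSite(rec["site_id"], rec["atom"], rec["role"], tuple(rec["aux"]))
            )
    return LigandModel(name or (mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem), atoms, sites)


def write_ligand_pdb(ligand: LigandModel, path) -> None:
    """Write a ligand (with site annotations) as a HETATM-only PDB file."""
    lines = []
    for s in ligand.sites:
        lines.append(f"{_SITE_REMARK} {s.site_id} {s.atom_name} {s.role} {' '.join(s.aux_atoms)}")
    for i, (aname, el, xyz) in enumerate(ligand.atoms, start=1):
        lines.append(
            f"HETATM{i:5d} {aname:<4.4s}{'LIG':>4s} X{1:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {el:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# active-site specification


@dataclass(frozen=True)
class ResolvedEnd:
    """One disambiguated end of an interaction edge."""

    kind: str  # 'ligand' | 'group'
    ref: str  # site_id or group label
    role: str  # donor | acceptor | covalent_attachment | attachment
    atom: str | None = None  # specific FG atom, or None for 'auto'


@dataclass
class InteractionEdge:
    edge_id: str
    kind: str  # 'hbond' | 'covalent'
    end_a: dict
    end_b: dict
    donor_end: ResolvedEnd | None = None
    acceptor_end: ResolvedEnd | None = None
    site_end: ResolvedEnd | None = None  # covalent: the ligand site
    group_end: ResolvedEnd | None = None  # covalent: the attaching group

    def endpoints(self):
        """Node names of the interaction graph this edge connects."""
        nodes = []
        for raw in (self.end_a, self.end_b):
            nodes.append("ligand" if "ligand" in raw else raw["group"])
        return tuple(nodes)

    def group_ends(self):
        out = []
        for e in (self.donor_end, self.acceptor_end, self.group_end):
            if e is not None and e.kind == "group":
                out.append(e)
        return out


@dataclass
class ActiveSiteSpec:
    """The 2D wiring diagram: groups plus interaction edges."""

    name: str
    groups: list  # [(label, fg_name), ...]
    edges: list  # [InteractionEdge, ...]
    require_ligand_contact: bool = False
    ligand_sites: list = field(default_factory=list)  # optional InteractionSite defs

    def __post_init__(self):
        labels = [g[0] for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValidationError("group labels must be unique")
        for _, fg in self.groups:
            if fg not in FG_NAMES:
                raise ValidationError(f"unknown functional group {fg!r}")

    def group_labels(self):
        return [g[0] for g in self.groups]

    def fg_of(self, label: str) -> str:
        for lab, fg in self.groups:
            if lab == label:
                return fg
        raise KeyError(label)

    def edges_of(self, label: str):
        return [e for e in self.edges if label in e.endpoints()]

    def ligand_edges_of(self, label: str):
        return [e for e in self.edges if set(e.endpoints()) == {"ligand", label}]

    def group_group_edges(self):
        return [e for e in self.edges if "ligand" not in e.endpoints()]


def _resolve_edges(spec: ActiveSiteSpec, ligand: LigandModel | None) -> None:
    """Disambiguate donor/acceptor ends of every edge in place."""
    site_roles = {}
    if ligand is not None:
        for s in ligand.sites:
            site_roles[s.site_id] = s.role
    for s in spec.ligand_sites:
        site_roles[s.site_id] = s.role

    fg_by_label = dict(spec.groups)

    for e in spec.edges:
        ends = []
        for raw in (e.end_a, e.end_b):
            if "ligand" in raw:
                sid = raw["ligand"]
                role = site_roles.get(sid)
                if role is None:
                    raise ValidationError(
                        f"edge {e.edge_id}: unknown ligand site {sid!r}"
                    )
                ends.append(ResolvedEnd("ligand", sid, role, None))
            else:
                label = raw["group"]
                if label not in fg_by_label:
                    raise ValidationError(
                        f"edge {e.edge_id}: unknown group {label!r}"
                    )
                atom = raw.get("atom")
                if atom in ("auto", None):
                    atom = None
                ends.append(ResolvedEnd("group", label, raw.get("role", "auto"), atom))
        a, b = ends

        if e.kind == "covalent":
            lig = [x for x in (a, b) if x.kind == "ligand"]
            grp = [x for x in (a, b) if x.kind == "group"]
            if len(lig) != 1 or lig[0].role != "covalent_attachment":
                raise ValidationError(
                    f"covalent edge {e.edge_id} must join a group to a ligand "
                    "covalent_attachment site"
                )
            g = grp[0]
            tpl = fg_template(fg_by_label[g.ref])
            if tpl.covalent_atom is None:
                raise SpecError(
                    f"edge {e.edge_id}: group {g.ref} ({tpl.fg_name}) has no "
                    "covalent-capable atom"
                )
            e.site_end = lig[0]
            e.group_end = ResolvedEnd("group", g.ref, "covalent_attachment", g.atom or tpl.covalent_atom)
            continue

        # hydrogen bond: exactly one donor end and one acceptor end
        roles = [a.role, b.role]
        for i, (end, other) in enumerate(((a, b), (b, a))):
            if end.role == "auto":
                if other.role == "donor":
                    roles[i] = "acceptor"
                elif other.role == "acceptor":
                    roles[i] = "donor"
                else:
                    raise ValidationError(
                        f"edge {e.edge_id}: cannot infer donor/acceptor roles "
                        "(specify 'role' on at least one group end)"
                    )
        a = replace(a, role=roles[0])
        b = replace(b, role=roles[1])
        if sorted((a.role, b.role)) != ["acceptor", "donor"]:
            raise ValidationError(
                f"edge {e.edge_id}: needs one donor and one acceptor end, "
                f"got {a.role}/{b.role}"
            )
        for end in (a, b):
            if end.kind == "group":
                tpl = fg_template(fg_by_label[end.ref])
                pool = (
                    {d[0] for d in tpl.donors}
                    if end.role == "donor"
                    else {x[0] for x in tpl.acceptors}
                )
                if not pool:
                    raise SpecError(
                        f"edge {e.edge_id}: group {end.ref} ({tpl.fg_name}) has "
                        f"no {end.role} atoms"
                    )
                if end.atom is not None and end.atom not in pool:
                    raise SpecError(
                        f"edge {e.edge_id}: atom {end.atom!r} of {end.ref} is "
                        f"not a {end.role} atom"
                    )
        e.donor_end = a if a.role == "donor" else b
        e.acceptor_end = b if a.role == "donor" else a


def validate_spec(spec: ActiveSiteSpec, ligand: LigandModel | None = None) -> None:
    """Resolve edges and check the connectivity invariants."""
    _resolve_edges(spec, ligand)
    g = nx.Graph()
    g.add_node("ligand")
    for label, _ in spec.groups:
        g.add_node(label)
    for e in spec.edges:
        u, v = e.endpoints()
        g.add_edge(u, v)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        comps.sort(key=lambda c: ("ligand" not in c, sorted(c)))
        stranded = sorted(comps[1])
        raise ValidationError(
            "interaction graph is not connected; disconnected component: "
            + ", ".join(stranded)
        )
    if spec.require_ligand_contact:
        for label, _ in spec.groups:
            if not spec.ligand_edges_of(label):
                raise ValidationError(
                    f"require_ligand_contact: group {label} has no ligand edge"
                )


def spec_to_dict(spec: ActiveSiteSpec) -> dict:
    return {
        "name": spec.name,
        "require_ligand_contact": spec.require_ligand_contact,
        "groups": [{"label": l, "fg": fg} for l, fg in spec.groups],
        "ligand_sites": [
            {
                "site_id": s.site_id,
                "atom": s.atom_name,
                "role": s.role,
                "aux": list(s.aux_atoms),
            }
            for s in spec.ligand_sites
        ],
        "edges": [
            {"id": e.edge_id, "kind": e.kind, "a": e.end_a, "b": e.end_b}
            for e in spec.edges
        ],
    }


def spec_from_dict(d: dict, ligand: LigandModel | None = None) -> ActiveSiteSpec:
    try:
        groups = [(g["label"], g["fg"]) for g in d.get("groups", [])]
        sites = [
            InteractionSite(s["site_id"], s["atom"], s["role"], tuple(s.get("aux", ())))
            for s in d.get("ligand_sites", [])
        ]
        edges = [
            InteractionEdge(e["id"], e.get("kind", "hbond"), dict(e["a"]), dict(e["b"]))
            for e in d.get("edges", [])
        ]
    except KeyError as exc:
        raise ParseError(f"active-site spec missing key: {exc}") from exc
    spec = ActiveSiteSpec(
        name=d.get("name", "active_site"),
        groups=groups,
        edges=edges,
        require_ligand_contact=bool(d.get("require_ligand_contact", False)),
        ligand_sites=sites,
    )
    validate_spec(spec, ligand)
    return spec


def parse_active_site_spec(path, ligand: LigandModel | None = None) -> ActiveSiteSpec:
    """Parse and validate a YAML active-site specification file."""
    raw = Path(path).read_text()
    try:
        d = yaml.safe_load(raw)
    except yaml.YAMLError as e:
        raise ParseError(f"cannot parse {path}: {e}") from e
    if not isinstance(d, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return spec_from_dict(d, ligand)


def serialize_active_site_spec(spec: ActiveSiteSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def attach_spec_sites(ligand: LigandModel, spec: ActiveSiteSpec) -> LigandModel:
    """Return a ligand carrying both its own and the spec's ligand sites."""
    merged = list(ligand.sites)
    have = {s.site_id for s in merged}
    for s in spec.ligand_sites:
        if s.site_id not in have:
            merged.append(s)
    return LigandModel(ligand.name, list(ligand.atoms), merged)
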