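"""Ligand I/O, functional-group templates, and active-site spec parsing."""

import numpy as np
import pytest

from hbnetforge.chem_model import (
    ActiveSiteSpec,
    InteractionEdge,
    InteractionSite,
    LigandModel,
    load_ligand,
    parse_active_site_spec,
    serialize_active_site_spec,
    spec_from_dict,
    spec_to_dict,
    validate_spec,
    write_ligand_pdb,
)
from hbnetforge.errors import (
    FormatError,
    ParseError,
    SpecError,
    ValidationError,
)
from hbnetforge.fg_library import FG_NAMES, fg_template
from hbnetforge.fixtures import make_toy_ligand


class TestLigandModel:
    def test_duplicate_atom_names_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            LigandModel("x", [("C1", "C", [0, 0, 0]), ("C1", "C", [1, 0, 0])])

    def test_site_referencing_unknown_atom_rejected(self):
        with pytest.raises(ValidationError):
            LigandModel(
                "x",
                [("C1", "C", [0, 0, 0])],
                [InteractionSite("s", "O9", "acceptor", ("C1",))],
            )

    def test_canonical_form_is_rigid_motion_invariant(self):
        from scipy.spatial.transform import Rotation

        lig = make_toy_ligand("diol")
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = LigandModel(
            lig.name,
            [(n, e, R @ np.asarray(x) + np.array([5.0, -3.0, 8.0]))
             for n, e, x in lig.atoms],
            list(lig.sites),
        )
        np.testing.assert_allclose(
            lig.canonical().coords(), moved.canonical().coords(), atol=1e-5
        )

    def test_donor_geometry_uses_explicit_hydrogen(self):
        lig = make_toy_ligand("diol")
        d, h = lig.donor_geometry(lig.get_site("don1"))
        np.testing.assert_allclose(d, lig.xyz("O1"))
        np.testing.assert_allclose(h, lig.xyz("H1"))
        assert np.linalg.norm(h - d) == pytest.approx(0.96, abs=1e-6)


class TestLigandIO:
    def test_pdb_round_trip_with_sites(self, tmp_path):
        lig = make_toy_ligand("diol")
        p = tmp_path / "diol.pdb"
        write_ligand_pdb(lig, p)
        back = load_ligand(p)
        assert back.atom_names() == lig.atom_names()
        roles = sorted(s.role for s in back.sites)
        assert roles == ["acceptor", "acceptor", "donor", "donor"]
        np.testing.assert_allclose(back.coords(), lig.coords(), atol=1.5e-3)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(FormatError):
            load_ligand(p)

    def test_duplicate_atom_names_in_pdb_rejected(self, tmp_path):
        p = tmp_path / "dup.pdb"
        p.write_text(
            "HETATM    1  C1   LIG X   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  C1   LIG X   1       1.500   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(ParseError):
            load_ligand(p)

    def test_sdf_input(self, tmp_path):
        pytest.importorskip("rdkit")
        sdf = """diol
  hand built

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.5300    0.0000    0.0000 C   0  0
    2.0000    1.3000    0.0000 O   0  0
  1  2  1  0
  2  3  1  0
M  END
>  <HBNET_SITES>
[{"site_id": "a1", "atom": "O1", "role": "acceptor", "aux": ["C2"]}]

$$$$
"""
        p = tmp_path / "m.sdf"
        p.write_text(sdf)
        lig = load_ligand(p, format="sdf")
        assert len(lig.atoms) == 3
        assert lig.sites[0].role == "acceptor"


class TestFGTemplates:
    def test_hydroxyl_roles(self):
        t = fg_template("hydroxyl")
        assert len(t.donors) == 1 and len(t.acceptors) == 1
        og, hg = t.donors[0]
        assert np.linalg.norm(t.atoms[hg] - t.atoms[og]) == pytest.approx(0.96, abs=1e-6)

    def test_carboxylate_is_acceptor_only(self):
        t = fg_template("carboxylate")
        assert len(t.donors) == 0
        assert sorted(a for a, _ in t.acceptors) == ["OD1", "OD2"]

    def test_guanidinium_is_donor_only(self):
        t = fg_template("guanidinium")
        assert len(t.donors) >= 3 and len(t.acceptors) == 0

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            fg_template("sulfhydryl")

    @pytest.mark.parametrize("name", FG_NAMES)
    def test_template_internal_geometry_is_sane(self, name):
        t = fg_template(name)
        coords = t.coords()
        # heavy-atom bonds should be chemically plausible lengths
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0.9  # no overlapping atoms
        assert t.attachment[0] in t.atoms
        for heavy, hyd in t.donors:
            assert 0.9 < np.linalg.norm(t.atoms[hyd] - t.atoms[heavy]) < 1.1


def _quartet_dict():
    return {
        "name": "quartet",
        "require_ligand_contact": True,
        "groups": [
            {"label": "K1", "fg": "primary_amine"},
            {"label": "Y1", "fg": "phenol"},
            {"label": "Y2", "fg": "phenol"},
            {"label": "N1", "fg": "carboxamide"},
        ],
        "edges": [
            {"id": "e_cov", "kind": "covalent", "a": {"ligand": "cov"}, "b": {"group": "K1"}},
            {"id": "e1", "kind": "hbond", "a": {"ligand": "acc_oc"}, "b": {"group": "Y1", "role": "donor"}},
            {"id": "e2", "kind": "hbond", "a": {"ligand": "acc_o2"}, "b": {"group": "Y2", "role": "donor"}},
            {"id": "e3", "kind": "hbond", "a": {"ligand": "don_o2"}, "b": {"group": "N1", "role": "acceptor"}},
            {"id": "e4", "kind": "hbond", "a": {"group": "K1", "role": "donor"}, "b": {"group": "Y1", "role": "acceptor"}},
        ],
    }


class TestActiveSiteSpec:
    def test_quartet_spec_parses_with_four_connected_groups(self):
        lig = make_toy_ligand("carbinolamine_ts")
        spec = spec_from_dict(_quartet_dict(), lig)
        assert len(spec.groups) == 4
        assert spec.edges[0].kind == "covalent"
        # every edge resolved to one donor and one acceptor (or covalent pair)
        for e in spec.edges:
            if e.kind == "hbond":
                assert e.donor_end.role == "donor"
                assert e.acceptor_end.role == "acceptor"
            else:
                assert e.site_end is not None and e.group_end is not None

    def test_group_without_edges_rejected(self):
        d = _quartet_dict()
        d["groups"].append({"label": "X1", "fg": "hydroxyl"})
        with pytest.raises(ValidationError, match="X1"):
            spec_from_dict(d, make_toy_ligand("carbinolamine_ts"))

    def test_single_group_single_edge_is_valid(self):
        lig = make_toy_ligand("diol")
        spec = spec_from_dict(
            {
                "name": "mini",
                "groups": [{"label": "S1", "fg": "hydroxyl"}],
                "edges": [
                    {"id": "e1", "kind": "hbond", "a": {"ligand": "acc1"},
                     "b": {"group": "S1", "role": "donor"}}
                ],
            },
            lig,
        )
        assert spec.group_labels() == ["S1"]

    def test_unknown_fg_rejected(self):
        with pytest.raises(ValidationError):
            ActiveSiteSpec("x", [("G1", "thiolate")], [])

    def test_yaml_round_trip(self, tmp_path):
        lig = make_toy_ligand("carbinolamine_ts")
        spec = spec_from_dict(_quartet_dict(), lig)
        p = tmp_path / "spec.yaml"
        serialize_active_site_spec(spec, p)
        back = parse_active_site_spec(p, lig)
        assert spec_to_dict(back) == spec_to_dict(spec)

    def test_ambiguous_roles_rejected(self):
        lig = make_toy_ligand("diol")
        with pytest.raises(ValidationError, match="infer"):
            spec_from_dict(
                {
                    "name": "x",
                    "groups": [{"label": "A", "fg": "hydroxyl"},
                               {"label": "B", "fg": "hydroxyl"}],
                    "edges": [
                        {"id": "e0", "kind": "hbond", "a": {"ligand": "acc1"},
                         "b": {"group": "A", "role": "donor"}},
                        {"id": "e1", "kind": "hbond", "a": {"group": "A"},
                         "b": {"group": "B"}},
                    ],
                },
                lig,
            )

    def test_covalent_edge_requires_capable_group(self):
        lig = make_toy_ligand("carbinolamine_ts")
        d = _quartet_dict()
        d["edges"][0]["b"] = {"group": "Y1"}  # phenol ring carbon cannot
        d["edges"][4] = {"id": "e4", "kind": "hbond",
                         "a": {"group": "K1", "role": "donor"},
                         "b": {"group": "Y1", "role": "acceptor"}}
        d["edges"].append({"id": "e5", "kind": "hbond", "a": {"ligand": "acc_oc"},
                           "b": {"group": "K1", "role": "donor"}})
        with pytest.raises(SpecError):
            spec_from_dict(d, lig)

    def test_require_ligand_contact_enforced(self):
        lig = make_toy_ligand("carbinolamine_ts")
        d = _quartet_dict()
        d["edges"][2] = {"id": "e2", "kind": "hbond",
                         "a": {"group": "Y2", "role": "donor"},
                         "b": {"group": "N1", "role": "acceptor"}}
        with pytest.raises(ValidationError, match="ligand"):
            spec_from_dict(d, lig)
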