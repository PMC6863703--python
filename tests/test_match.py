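"""Scaffold loading, transform hashing, matching, and completion reports."""

import numpy as np
import pytest

from hbnetforge.cluster import cluster_networks, network_features
from hbnetforge.errors import ConstructionError, FormatError, ValidationError
from hbnetforge.fixtures import (
    make_helix_scaffold,
    plant_first_viable,
)
from hbnetforge.match import (
    MatchParams,
    ScaffoldModel,
    build_transform_hash,
    completion_report,
    find_matches,
    format_rate,
    load_scaffold,
    pose_bin,
    prepare_realizations,
)


@pytest.fixture(scope="module")
def planted_set(bridge_run, spec_bridge, lig_keto):
    """First few plantable networks with their realization pools."""
    nets = bridge_run["networks"]
    pools = prepare_realizations(nets, spec_bridge, lig_keto)
    out = []
    for net, pool in zip(nets, pools):
        try:
            sc, chosen = plant_first_viable(net, pool, lig_keto)
        except ConstructionError:
            continue
        out.append((net, pool, sc, chosen))
        if len(out) == 5:
            break
    assert len(out) >= 3
    return out


class TestScaffoldModel:
    def test_helix_loads_back_from_pdb(self, tmp_path):
        from hbnetforge.cli import _write_scaffold_pdb

        sc = make_helix_scaffold(20)
        p = tmp_path / "helix.pdb"
        _write_scaffold_pdb(sc, p)
        back = load_scaffold(p)
        assert len(back.residues) == 20

    def test_ca_only_trace_rejected(self, tmp_path):
        p = tmp_path / "ca.pdb"
        lines = []
        for i in range(5):
            lines.append(
                f"ATOM  {i+1:5d}  CA  ALA A{i+1:4d}    "
                f"{3.8*i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
        p.write_text("\n".join(lines) + "\nEND\n")
        with pytest.raises(FormatError):
            load_scaffold(p)

    def test_first_altloc_kept(self, tmp_path, caplog):
        import logging

        sc = make_helix_scaffold(6)
        from hbnetforge.cli import _write_scaffold_pdb

        p = tmp_path / "helix.pdb"
        _write_scaffold_pdb(sc, p)
        text = p.read_text().splitlines()
        # duplicate residue 1's N as a fake second altloc
        dup = text[0][:16] + "B" + text[0][17:30] + "%8.3f" % 99.0 + text[0][38:]
        text.insert(1, dup)
        p.write_text("\n".join(text) + "\n")
        with caplog.at_level(logging.WARNING):
            back = load_scaffold(p)
        n0 = back.residues[0][2]
        assert abs(n0[0] - sc.residues[0][2][0]) < 1e-2  # first altloc won

    def test_distorted_backbone_rejected(self):
        with pytest.raises(ValidationError):
            ScaffoldModel(
                "bad",
                [("A", 1, [0, 0, 0], [3.0, 0, 0], [4.5, 0, 0], None, None)],
            )

    def test_duplicate_residue_numbering_rejected(self):
        r = ("A", 1, [0, 0, 0], [1.458, 0, 0], [2.0, 1.3, 0], None, None)
        with pytest.raises(ValidationError):
            ScaffoldModel("bad", [r, r])

    def test_canonical_form_is_motion_invariant(self):
        from scipy.spatial.transform import Rotation

        sc = make_helix_scaffold(8)
        R = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        moved = ScaffoldModel(
            sc.scaffold_id,
            [
                (c, n, R @ N + 3.0, R @ CA + 3.0, R @ C + 3.0,
                 None if O is None else R @ O + 3.0, None)
                for c, n, N, CA, C, O, CB in sc.residues
            ],
        )
        a, _ = sc.canonical()
        b, _ = moved.canonical()
        for ra, rb in zip(a.residues, b.residues):
            np.testing.assert_allclose(ra[2], rb[2], atol=1e-5)


class TestTransformHash:
    def test_empty_scaffold_gives_empty_table(self, planted_set, spec_bridge):
        net, pool, sc, chosen = planted_set[0]
        empty = ScaffoldModel("empty", [sc.residues[0]])
        empty.designable = []
        table = build_transform_hash(empty, "S1", pool["S1"], MatchParams())
        assert table == {}

    def test_entries_reproduce_their_bin(self, planted_set, spec_bridge):
        """Self-consistency: re-binning any entry's ligand transform gives
        the bin it is stored under."""
        net, pool, sc, chosen = planted_set[0]
        scc, _ = sc.canonical()
        params = MatchParams()
        for label in spec_bridge.group_labels():
            table = build_transform_hash(scc, label, pool[label], params)
            for b, entries in table.items():
                for e in entries:
                    assert pose_bin(e.transform, params) == b

    def test_per_bin_cap_limits_entries(self, planted_set):
        net, pool, sc, chosen = planted_set[0]
        scc, _ = sc.canonical()
        capped = MatchParams(per_bin_cap=1)
        table = build_transform_hash(scc, "S1", pool["S1"], capped)
        assert all(len(v) == 1 for v in table.values())


class TestFindMatches:
    def test_unknown_mode_rejected(self, planted_set, spec_bridge, lig_keto):
        net, pool, sc, chosen = planted_set[0]
        with pytest.raises(ValueError):
            find_matches(sc, spec_bridge, [net], "simulated_annealing",
                         ligand=lig_keto)

    def test_fewer_positions_than_groups_gives_no_match(
        self, planted_set, spec_bridge, lig_keto
    ):
        net, pool, sc, chosen = planted_set[0]
        tiny = ScaffoldModel("tiny", sc.residues[:1])
        ms = find_matches(tiny, spec_bridge, [net], "per_network",
                          MatchParams().fine(), ligand=lig_keto,
                          realizations_by_network=[pool])
        assert ms == []

    def test_planted_network_recovered_per_network(
        self, planted_set, spec_bridge, lig_keto
    ):
        net, pool, sc, chosen = planted_set[0]
        ms = find_matches(sc, spec_bridge, [net], "per_network",
                          MatchParams().fine(), ligand=lig_keto,
                          realizations_by_network=[pool])
        assert any(m.complete for m in ms)

    def test_per_network_fine_bins_only_complete(self, planted_set, spec_bridge, lig_keto):
        """Matching one network at a time at fine bins can only re-assemble
        that network, so every reported match is complete."""
        nets = [p[0] for p in planted_set]
        pools = [p[1] for p in planted_set]
        for _, _, sc, _ in planted_set:
            ms = find_matches(sc, spec_bridge, nets, "per_network",
                              MatchParams().fine(), ligand=lig_keto,
                              realizations_by_network=pools)
            assert ms
            assert all(m.complete for m in ms)

    def test_assigned_positions_are_distinct(self, planted_set, spec_bridge, lig_keto):
        net, pool, sc, chosen = planted_set[0]
        ms = find_matches(sc, spec_bridge, [net], "per_network",
                          MatchParams().fine(), ligand=lig_keto,
                          realizations_by_network=[pool])
        for m in ms:
            pos = [a[0] for a in m.assignments.values()]
            assert len(set(pos)) == len(pos)

    def test_pooled_mode_recovers_planted(self, planted_set, spec_bridge, lig_keto):
        nets = [p[0] for p in planted_set]
        pools = [p[1] for p in planted_set]
        net, pool, sc, chosen = planted_set[0]
        ms = find_matches(sc, spec_bridge, nets, "pooled",
                          MatchParams().fine(), ligand=lig_keto,
                          realizations_by_network=pools)
        assert any(m.complete for m in ms)

    def test_clustered_mode_with_singletons_recovers_planted(
        self, planted_set, spec_bridge, lig_keto
    ):
        nets = [p[0] for p in planted_set]
        pools = [p[1] for p in planted_set]
        feats = np.array([network_features(n, spec_bridge) for n in nets])
        cs = cluster_networks(feats, len(nets), seed=1)
        net, pool, sc, chosen = planted_set[0]
        ms = find_matches(sc, spec_bridge, nets, "clustered",
                          MatchParams().fine(), ligand=lig_keto,
                          realizations_by_network=pools, clusters=cs)
        assert any(m.complete for m in ms)

    def test_residue_mode_runs_on_bare_placements(
        self, planted_set, spec_bridge, lig_keto, bridge_run
    ):
        net, pool, sc, chosen = planted_set[0]
        placements = {k: v[:40] for k, v in bridge_run["placements"].items()}
        ms = find_matches(sc, spec_bridge, None, "residue", MatchParams(),
                          ligand=lig_keto, placements=placements)
        # matches may or may not exist; every reported one must be evaluated
        for m in ms:
            assert set(m.edge_flags) == {e.edge_id for e in spec_bridge.edges}
            assert m.complete == all(m.edge_flags.values())

    def test_disabling_prune_never_loses_complete_matches(
        self, planted_set, spec_bridge, lig_keto
    ):
        nets = [p[0] for p in planted_set]
        pools = [p[1] for p in planted_set]
        net, pool, sc, chosen = planted_set[0]
        capped = find_matches(sc, spec_bridge, nets, "pooled",
                              MatchParams(per_bin_cap=1), ligand=lig_keto,
                              realizations_by_network=pools)
        uncapped = find_matches(sc, spec_bridge, nets, "pooled",
                                MatchParams(per_bin_cap=0), ligand=lig_keto,
                                realizations_by_network=pools)
        assert sum(m.complete for m in uncapped) >= sum(m.complete for m in capped)


class TestCompletionReport:
    def test_rates_from_counts(self):
        rep = completion_report(
            counts=[("a", 7455, 1), ("b", 3991, 47), ("c", 3031, 98)]
        )
        assert [r[3] for r in rep.rows] == ["0.013%", "1.18%", "3.23%"]

    def test_zero_complete_gives_zero_rate(self):
        assert format_rate(0, 123) == "0%"

    def test_division_by_zero_reports_na(self):
        assert format_rate(5, 0) == "n/a"

    def test_report_from_matches(self, planted_set, spec_bridge, lig_keto):
        net, pool, sc, chosen = planted_set[0]
        ms = find_matches(sc, spec_bridge, [net], "per_network",
                          MatchParams().fine(), ligand=lig_keto,
                          realizations_by_network=[pool])
        rep = completion_report(ms, simulation_id="toy")
        sim, n_inc, n_comp, rate = rep.rows[0]
        assert n_comp == sum(m.complete for m in ms)
        assert n_inc == len(ms) - n_comp
        assert "toy" in rep.as_text() and "toy" in rep.as_tsv()
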