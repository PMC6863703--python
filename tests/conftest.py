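"""Shared fixtures: toy systems, small sampling schemes, assembled networks.

Everything is generated programmatically; heavier artifacts (enumerated
placement sets, assembled networks) are session-scoped so the suite builds
them once.
"""

import pytest

from hbnetforge.enumeration import SamplingScheme, _frange
from hbnetforge.fixtures import make_demo_spec, make_toy_ligand
from hbnetforge.geometry import HBondParams
from hbnetforge.network import assemble_networks, filter_pairs
from hbnetforge.reporting import RunConfig, enumerate_group_placements


@pytest.fixture(scope="session")
def lig_diol():
    return make_toy_ligand("diol").canonical()


@pytest.fixture(scope="session")
def spec_diol():
    return make_demo_spec("diol_pair", make_toy_ligand("diol"))


@pytest.fixture(scope="session")
def lig_carb():
    return make_toy_ligand("carbinolamine_ts").canonical()


@pytest.fixture(scope="session")
def spec_quartet():
    return make_demo_spec("amine_quartet", make_toy_ligand("carbinolamine_ts"))


@pytest.fixture(scope="session")
def test_scheme():
    """Mid-density scheme: rich enough to give hundreds of networks on the
    phosphate-bridge toy, small enough to enumerate in a few seconds."""
    return SamplingScheme(
        distances=(2.6, 2.8, 3.0),
        donor_angles=(150.0, 165.0, 180.0),
        acceptor_angles=tuple(_frange(90, 180, 15)),
        base_torsions=tuple(_frange(0, 330, 30)),
        axis_torsions=tuple(_frange(0, 330, 30)),
        spins=tuple(_frange(0, 330, 30)),
    )


@pytest.fixture(scope="session")
def lig_keto():
    return make_toy_ligand("keto_phosphate").canonical()


@pytest.fixture(scope="session")
def spec_bridge():
    return make_demo_spec("phosphate_bridge", make_toy_ligand("keto_phosphate"))


@pytest.fixture(scope="session")
def bridge_run(lig_keto, spec_bridge, test_scheme):
    """Placements, pair tables and a few hundred networks for the
    phosphate-bridge toy system."""
    cfg = RunConfig(scheme=test_scheme, grid_spacing=0.5, do_match=False)
    placements = enumerate_group_placements(lig_keto, spec_bridge, cfg)
    tables = {}
    for e in spec_bridge.group_group_edges():
        la, lb = e.endpoints()
        tab, _, _ = filter_pairs(e, placements[la], placements[lb], cfg.hbond)
        tables[e.edge_id] = tab
    networks = assemble_networks(spec_bridge, placements, tables)
    return {
        "config": cfg,
        "placements": placements,
        "tables": tables,
        "networks": networks,
    }


@pytest.fixture(scope="session")
def coarse2():
    """Two samples per degree of freedom; used by the brute-force oracles."""
    return SamplingScheme(
        distances=(2.7, 3.0),
        donor_angles=(150.0, 180.0),
        acceptor_angles=(100.0, 140.0),
        base_torsions=(0.0, 120.0),
        axis_torsions=(0.0, 120.0),
        spins=(0.0, 120.0),
    )


@pytest.fixture(scope="session")
def hb_params():
    return HBondParams()
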