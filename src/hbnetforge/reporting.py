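"""End-to-end pipeline driver, run configuration, and count summaries.

The pipeline ties the stages together under one configuration object:
enumerate functional-group placements for every group's ligand interaction,
filter group-group pairs, assemble complete networks, expand the best
networks into side chains, cluster, match into scaffolds, and report
completion statistics.  Every summary embeds the configuration that
produced it, and identical inputs always produce identical summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .chem_model import ActiveSiteSpec, LigandModel, attach_spec_sites
from .cluster import DEFAULT_K, DEFAULT_SEED, cluster_networks, network_features
from .enumeration import (
    SamplingScheme,
    default_scheme,
    enumerate_covalent_placements,
    enumerate_hbond_placements,
)
from .errors import HBNetForgeError, SpecError
from .fg_library import fg_template
from .geometry import HBondParams
from .match import (
    MatchParams,
    completion_report,
    find_matches,
    prepare_realizations,
)
from .network import assemble_networks, eval_edge, filter_pairs
from .realize import CHI_DEFAULT, count_full_realizations

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    grid_spacing: float = 0.2
    hbond: HBondParams = field(default_factory=HBondParams)
    scheme: SamplingScheme = field(default_factory=default_scheme)
    chi_samples: tuple = CHI_DEFAULT
    identities: dict | None = None
    clash_threshold: float = 2.7
    max_networks: int = 2_000_000
    realize_max_networks: int = 50  # best-scoring networks carried forward
    cluster_k: int = DEFAULT_K
    seed: int = DEFAULT_SEED
    match_params: MatchParams = field(default_factory=MatchParams)
    match_modes: tuple = ("per_network",)
    do_cluster: bool = True
    do_match: bool = True

    def to_dict(self) -> dict:
        return {
            "grid_spacing": self.grid_spacing,
            "hbond": self.hbond.to_dict(),
            "scheme": self.scheme.to_dict(),
            "chi_samples": list(self.chi_samples),
            "identities": dict(self.identities) if self.identities else None,
            "clash_threshold": self.clash_threshold,
            "max_networks": self.max_networks,
            "realize_max_networks": self.realize_max_networks,
            "cluster_k": self.cluster_k,
            "seed": self.seed,
            "match_params": {
                "trans_bin": self.match_params.trans_bin,
                "ori_bin_deg": self.match_params.ori_bin_deg,
                "per_bin_cap": self.match_params.per_bin_cap,
                "backbone_clash": self.match_params.backbone_clash,
                "combo_cap": self.match_params.combo_cap,
            },
            "match_modes": list(self.match_modes),
            "do_cluster": self.do_cluster,
            "do_match": self.do_match,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        if "hbond" in kw and isinstance(kw["hbond"], dict):
            kw["hbond"] = HBondParams.from_dict(kw["hbond"])
        if "scheme" in kw and isinstance(kw["scheme"], dict):
            kw["scheme"] = SamplingScheme.from_dict(kw["scheme"])
        if "match_params" in kw and isinstance(kw["match_params"], dict):
            kw["match_params"] = MatchParams(**kw["match_params"])
        if "chi_samples" in kw:
            kw["chi_samples"] = tuple(kw["chi_samples"])
        if "match_modes" in kw:
            kw["match_modes"] = tuple(kw["match_modes"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def enumerate_group_placements(
    ligand: LigandModel, spec: ActiveSiteSpec, config: RunConfig
) -> dict:
    """Placements per group from its ligand edges.

    Each group is enumerated from its first ligand edge (covalent edges
    take priority); placements are then audited against any additional
    ligand edges of the same group and failures discarded, so assembly can
    treat per-group candidate lists as ligand-valid.
    """
    out = {}
    for label in spec.group_labels():
        fg = fg_template(spec.fg_of(label))
        lig_edges = spec.ligand_edges_of(label)
        if not lig_edges:
            raise SpecError(
                f"group {label} has no direct ligand interaction; second-shell "
                "groups are not supported by the enumerator"
            )
        lig_edges = sorted(lig_edges, key=lambda e: (e.kind != "covalent"))
        primary = lig_edges[0]
        if primary.kind == "covalent":
            site = ligand.get_site(primary.site_end.ref)
            pls = enumerate_covalent_placements(
                ligand, site, fg, config.scheme, config.grid_spacing,
                group_label=label, source_edge=primary.edge_id,
                clash_min=config.clash_threshold,
            )
        else:
            end = (
                primary.donor_end
                if primary.donor_end.kind == "ligand"
                else primary.acceptor_end
            )
            site = ligand.get_site(end.ref)
            other = (
                primary.acceptor_end if end is primary.donor_end else primary.donor_end
            )
            pls = enumerate_hbond_placements(
                ligand, site, fg, config.scheme, config.hbond,
                config.grid_spacing, group_label=label,
                fg_atom=other.atom, source_edge=primary.edge_id,
                clash_min=config.clash_threshold,
            )
        for extra in lig_edges[1:]:
            kept = []
            for pl in pls:
                atoms = {label: (pl.atom_xyz, set(pl.omitted_atoms), pl.fg_name)}
                ok, _, _ = eval_edge(extra, spec, ligand, atoms, config.hbond)
                if ok:
                    kept.append(pl)
            pls = kept
        out[label] = pls
    return out


def run_pipeline(
    config: RunConfig,
    ligand: LigandModel,
    spec: ActiveSiteSpec,
    scaffolds=None,
) -> dict:
    """Execute enumerate -> filter/assemble -> realize -> cluster -> match.

    Returns a nested summary dict with per-stage counts and the full
    configuration; stage failures raise with the stage name attached.
    """
    summary = {"config": config.to_dict(), "ligand": ligand.name, "spec": spec.name}
    ligand = attach_spec_sites(ligand, spec).canonical()

    def stage(name, fn):
        try:
            return fn()
        except HBNetForgeError as e:
            raise type(e)(f"[stage {name}] {e}") from e

    placements = stage(
        "enumerate", lambda: enumerate_group_placements(ligand, spec, config)
    )
    summary["placements"] = {k: len(v) for k, v in placements.items()}

    tables = {}
    surviving = {k: set(range(len(v))) for k, v in placements.items()}

    def _filter():
        for e in spec.group_group_edges():
            la, lb = e.endpoints()
            tab, sa, sb = filter_pairs(e, placements[la], placements[lb], config.hbond)
            tables[e.edge_id] = tab
            surviving[la] &= set(sa)
            surviving[lb] &= set(sb)

    stage("filter_pairs", _filter)
    summary["pair_tables"] = {eid: len(t.pairs) for eid, t in tables.items()}
    summary["surviving"] = {k: len(v) for k, v in surviving.items()}

    networks = stage(
        "assemble",
        lambda: assemble_networks(
            spec, placements, tables, config.clash_threshold, config.max_networks
        ),
    )
    summary["n_networks"] = len(networks)

    selected = networks[: config.realize_max_networks]
    reals = stage(
        "realize",
        lambda: prepare_realizations(
            selected, spec, ligand, config.identities, config.chi_samples
        ),
    )
    per_network_products = [
        count_full_realizations(net, {l: len(pool[l]) for l in pool})
        for net, pool in zip(selected, reals)
    ]
    summary["realize"] = {
        "n_networks_realized": len(selected),
        "per_network_products": per_network_products,
        "total_full_realizations": int(sum(per_network_products)),
    }

    clusters = None
    if config.do_cluster and networks:
        feats = np.array([network_features(n, spec) for n in selected])
        k = min(config.cluster_k, len(selected))
        clusters = stage(
            "cluster", lambda: cluster_networks(feats, k, config.seed)
        )
        summary["cluster"] = {"k_requested": k, "k": clusters.k,
                              "sizes": clusters.sizes()}

    if config.do_match and scaffolds:
        match_summary = {}
        for mode in config.match_modes:
            all_matches = []
            for sc in scaffolds:
                kwargs = dict(
                    ligand=ligand,
                    identities=config.identities,
                    chi_samples=config.chi_samples,
                    hbond_params=config.hbond,
                )
                if mode == "residue":
                    kwargs["placements"] = placements
                elif mode == "clustered":
                    if clusters is None:
                        feats = np.array(
                            [network_features(n, spec) for n in selected]
                        )
                        clusters = cluster_networks(
                            feats, min(config.cluster_k, len(selected)), config.seed
                        )
                    kwargs["clusters"] = clusters
                m = stage(
                    "match",
                    lambda sc=sc, kw=kwargs: find_matches(
                        sc, spec, selected, mode, config.match_params,
                        realizations_by_network=(
                            reals if mode in ("per_network", "pooled", "clustered")
                            else None
                        ),
                        **kw,
                    ),
                )
                all_matches.extend(m)
            report = completion_report(all_matches, simulation_id=mode)
            sim, n_inc, n_comp, rate = report.rows[0]
            match_summary[mode] = {
                "n_matches": len(all_matches),
                "n_complete": n_comp,
                "n_incomplete": n_inc,
                "completion_rate": rate,
            }
        summary["match"] = match_summary
    return summary


def summarize_counts(summary: dict):
    """Human-readable text and TSV tables of a pipeline summary."""
    lines = [f"ligand: {summary['ligand']}   spec: {summary['spec']}"]
    tsv = ["stage\tkey\tvalue"]
    for label, n in summary.get("placements", {}).items():
        lines.append(f"placements[{label}]: {n}")
        tsv.append(f"placements\t{label}\t{n}")
    for eid, n in summary.get("pair_tables", {}).items():
        lines.append(f"compatible pairs[{eid}]: {n}")
        tsv.append(f"pairs\t{eid}\t{n}")
    if "n_networks" in summary:
        lines.append(f"complete networks: {summary['n_networks']}")
        tsv.append(f"networks\ttotal\t{summary['n_networks']}")
    r = summary.get("realize")
    if r:
        lines.append(
            f"full side-chain realizations (product rule over "
            f"{r['n_networks_realized']} networks): {r['total_full_realizations']}"
        )
        tsv.append(f"realize\ttotal\t{r['total_full_realizations']}")
    c = summary.get("cluster")
    if c:
        lines.append(f"clusters: {c['k']} (requested {c['k_requested']})")
        tsv.append(f"cluster\tk\t{c['k']}")
    m = summary.get("match")
    if m:
        for mode, row in m.items():
            lines.append(
                f"match[{mode}]: {row['n_matches']} matches, "
                f"{row['n_complete']} complete, rate {row['completion_rate']}"
            )
            tsv.append(f"match\t{mode}\t{row['n_complete']}/{row['n_matches']}")
    return "\n".join(lines), "\n".join(tsv)
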