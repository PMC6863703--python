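"""Cluster networks on the coordinates of their central functional groups.

Clustering controls how much side-chain "remixing" the matcher is allowed
to do: matching each network independently (k = N) forbids mixing, pooling
everything (k = 1) allows arbitrary mixing, and intermediate k interpolates
between the two.  Around 250 clusters is a practical operating point for
production-size network sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .chem_model import ActiveSiteSpec

DEFAULT_K = 250
DEFAULT_SEED = 2019


@dataclass
class ClusterSet:
    k: int  # number of non-empty clusters actually returned
    assignment: np.ndarray  # network index -> cluster id (dense 0..k-1)
    centroids: np.ndarray  # (k, n_features)

    def members(self, cid: int) -> list:
        return [int(i) for i in np.nonzero(self.assignment == cid)[0]]

    def sizes(self) -> list:
        return [int((self.assignment == c).sum()) for c in range(self.k)]


def network_features(network, spec: ActiveSiteSpec) -> np.ndarray:
    """Concatenated central-atom coordinates of each group, in spec order.

    The central atom of a group is the heavy atom through which it makes
    its ligand-facing interaction (the template's reference atom as a
    fallback); coordinates are in the ligand frame, so the feature vector
    is invariant under rigid motions of the original inputs.
    """
    feats = []
    for label in spec.group_labels():
        pl = network.placements[label]
        from .fg_library import fg_template

        atom = pl.interacting_atom or fg_template(pl.fg_name).reference_atom
        feats.append(np.asarray(pl.atom_xyz[atom], dtype=float))
    return np.concatenate(feats)


def cluster_networks(features: np.ndarray, k: int, seed: int = DEFAULT_SEED) -> ClusterSet:
    """Seeded k-means over network feature vectors.

    Empty clusters are dropped and ids renumbered densely in order of first
    appearance, so the returned k' may be smaller than requested.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array (networks x coords)")
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        # every network its own cluster; no fitting needed
        return ClusterSet(n, np.arange(n), X.copy())
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    remap: dict = {}
    dense = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        dense[i] = remap[lab]
    kk = len(remap)
    cents = np.array(
        [X[dense == c].mean(axis=0) for c in range(kk)]
    )
    return ClusterSet(kk, dense, cents)
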