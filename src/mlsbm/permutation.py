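"""Blocked-permutation null for cross-modal correspondence.

The procedure reorders all vertices of the non-predicted modality according
to a clustering learned on that modality: clusters are placed in uniformly
random order along the canonical traversal order, vertices within a cluster
keep their ascending traversal order. Parcel sizes and traversal-order
contiguity are preserved while any anatomical correspondence between the
modalities is destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError
from .metrics import VertexMetadata
from .model import BinaryNetwork, Parcellation


@dataclass(frozen=True)
class VertexPermutation:
    """A bijection on [0, n): ``mapping[v]`` is the new index of vertex v."""

    mapping: np.ndarray
    provenance: tuple = ()

    def __post_init__(self):
        m = np.asarray(self.mapping, dtype=np.int64)
        if not np.array_equal(np.sort(m), np.arange(m.size)):
            raise DimensionError("mapping must be a bijection on [0, n)")
        object.__setattr__(self, "mapping", m)

    @property
    def n_vertices(self) -> int:
        return self.mapping.size

    def inverse(self) -> "VertexPermutation":
        inv = np.empty_like(self.mapping)
        inv[self.mapping] = np.arange(self.mapping.size)
        return VertexPermutation(inv, provenance=self.provenance + ("inverse",))


def blocked_permutation(
    learned: Parcellation,
    meta: VertexMetadata,
    rng: np.random.Generator,
) -> VertexPermutation:
    """Permutation whose preimage blocks are exactly the learned clusters,
    each mapped to a contiguous run of traversal positions, with the cluster
    runs in uniformly random order."""
    if meta.n_vertices != learned.n_vertices:
        raise DimensionError("parcellation and metadata cover different vertices")
    trav = meta.traversal_index
    # vertex at each traversal position
    by_position = np.empty(learned.n_vertices, dtype=np.int64)
    by_position[trav] = np.arange(learned.n_vertices)

    nonempty = np.flatnonzero(learned.cluster_sizes() > 0)
    cluster_order = rng.permutation(nonempty)

    mapping = np.empty(learned.n_vertices, dtype=np.int64)
    pos = 0
    for c in cluster_order:
        members = np.flatnonzero(learned.labels == c)
        members = members[np.argsort(trav[members])]  # ascending traversal order
        # place this cluster on the next contiguous run of traversal positions
        mapping[members] = by_position[pos : pos + members.size]
        pos += members.size
    return VertexPermutation(mapping, provenance=("blocked",))


def apply_permutation(
    network: BinaryNetwork, perm: VertexPermutation
) -> BinaryNetwork:
    """Relabel vertices: edge {i, j} becomes {mapping[i], mapping[j]}."""
    if perm.n_vertices != network.n_vertices:
        raise DimensionError("permutation and network vertex counts differ")
    e = network.edge_array()
    m = perm.mapping
    return BinaryNetwork(network.n_vertices, zip(m[e[:, 0]].tolist(), m[e[:, 1]].tolist()))


def permute_parcellation(
    parcellation: Parcellation, perm: VertexPermutation
) -> Parcellation:
    """The partition as seen through the permutation (label of the vertex
    originally at each new position)."""
    inv = perm.inverse().mapping
    return Parcellation(parcellation.labels[inv], parcellation.K)
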