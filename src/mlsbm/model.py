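"""Core domain types and the collapsed log-probability machinery.

The generative model, per modality ``m`` over a shared vertex set:

.. math::

    A_{ij}^{(m)} \\sim \\mathrm{Bernoulli}(\\eta^{(m)}_{z_i z_j}), \\qquad
    \\eta^{(m)}_{\\ell h} \\sim \\mathrm{Beta}(\\beta^+, \\beta^-), \\qquad
    z_i \\sim \\mathrm{Categorical}(\\pi), \\qquad
    \\pi \\sim \\mathrm{Dirichlet}(\\alpha/K \\, \\mathbf{1}).

Both :math:`\\eta` and :math:`\\pi` are integrated out analytically
(Beta-Bernoulli and Dirichlet-Categorical conjugacy), leaving a collapsed
joint distribution over the networks and the shared partition ``z`` that is
evaluated entirely in the log domain through log-gamma / log-beta calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import betaln, gammaln

from .errors import DimensionError, LabelError, ParameterError

logger = logging.getLogger(__name__)

#: Dense adjacency materialization is refused above this vertex count unless
#: the caller explicitly raises the limit.
DENSE_LIMIT = 5000


class BinaryNetwork:
    """Undirected simple graph over ``n_vertices`` vertices, no self-links.

    Links are stored once as unordered pairs ``(i, j)`` with ``i < j``;
    symmetry is implicit.
    """

    __slots__ = ("n_vertices", "links", "_neighbors", "_edge_array")

    def __init__(self, n_vertices: int, links: Iterable[tuple[int, int]]):
        if n_vertices < 1:
            raise ParameterError("n_vertices must be >= 1")
        canonical = set()
        for i, j in links:
            if i == j:
                raise ParameterError(f"self-link ({i}, {j}) is not allowed")
            if not (0 <= i < n_vertices and 0 <= j < n_vertices):
                raise DimensionError(
                    f"link ({i}, {j}) outside vertex range [0, {n_vertices})"
                )
            canonical.add((i, j) if i < j else (j, i))
        self.n_vertices = int(n_vertices)
        self.links: frozenset[tuple[int, int]] = frozenset(canonical)
        self._neighbors: list[np.ndarray] | None = None
        self._edge_array: np.ndarray | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dense(cls, adjacency: np.ndarray) -> "BinaryNetwork":
        """Build from a symmetric 0/1 matrix; the diagonal is dropped
        (with a logged warning if nonzero)."""
        a = np.asarray(adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DimensionError("adjacency must be square")
        if np.trace(a != 0) > 0:
            logger.warning("dropping %d nonzero diagonal entries", int(np.trace(a != 0)))
        iu = np.triu_indices(a.shape[0], k=1)
        present = (a[iu] != 0) | (a[(iu[1], iu[0])] != 0)
        return cls(a.shape[0], zip(iu[0][present].tolist(), iu[1][present].tolist()))

    # -- cached views -------------------------------------------------------

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def n_pairs(self) -> int:
        return self.n_vertices * (self.n_vertices - 1) // 2

    @property
    def density(self) -> float:
        return self.n_links / self.n_pairs if self.n_pairs else 0.0

    def edge_array(self) -> np.ndarray:
        """(E, 2) int array of links with i < j, lexicographically sorted."""
        if self._edge_array is None:
            if self.links:
                self._edge_array = np.array(sorted(self.links), dtype=np.int64)
            else:
                self._edge_array = np.empty((0, 2), dtype=np.int64)
        return self._edge_array

    def neighbor_arrays(self) -> list[np.ndarray]:
        """Neighbor index array per vertex (both directions of each link)."""
        if self._neighbors is None:
            nbrs: list[list[int]] = [[] for _ in range(self.n_vertices)]
            for i, j in self.links:
                nbrs[i].append(j)
                nbrs[j].append(i)
            self._neighbors = [np.array(sorted(v), dtype=np.int64) for v in nbrs]
        return self._neighbors

    def adjacency(self, dense_limit: int = DENSE_LIMIT) -> np.ndarray:
        """Dense symmetric boolean adjacency; refused above ``dense_limit``."""
        if self.n_vertices > dense_limit:
            raise ParameterError(
                f"refusing dense adjacency for {self.n_vertices} > {dense_limit} vertices"
            )
        a = np.zeros((self.n_vertices, self.n_vertices), dtype=bool)
        e = self.edge_array()
        a[e[:, 0], e[:, 1]] = True
        a[e[:, 1], e[:, 0]] = True
        return a

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinaryNetwork)
            and self.n_vertices == other.n_vertices
            and self.links == other.links
        )

    def __hash__(self):
        return hash((self.n_vertices, self.links))

    def __repr__(self):
        return f"BinaryNetwork(n_vertices={self.n_vertices}, n_links={self.n_links})"


class MultiLayerNetwork:
    """An ordered collection of :class:`BinaryNetwork` layers (modalities)
    over one shared vertex set."""

    __slots__ = ("layers", "modality_names")

    def __init__(
        self,
        layers: Sequence[BinaryNetwork],
        modality_names: Sequence[str] | None = None,
    ):
        layers = list(layers)
        if len(layers) < 1:
            raise ParameterError("at least one layer is required")
        n = layers[0].n_vertices
        for k, layer in enumerate(layers):
            if layer.n_vertices != n:
                raise DimensionError(
                    f"layer {k} has {layer.n_vertices} vertices, expected {n}"
                )
        if modality_names is None:
            modality_names = [f"layer{m}" for m in range(len(layers))]
        if len(modality_names) != len(layers):
            raise DimensionError("one modality name per layer is required")
        self.layers = layers
        self.modality_names = list(modality_names)

    @property
    def n_vertices(self) -> int:
        return self.layers[0].n_vertices

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, m: int) -> BinaryNetwork:
        return self.layers[m]

    def __repr__(self):
        return (
            f"MultiLayerNetwork(n_vertices={self.n_vertices}, "
            f"layers={self.modality_names})"
        )


class Parcellation:
    """Per-vertex cluster label with a fixed label budget ``K``.

    Empty labels are valid states — this is a finite mixture, not a CRP.
    """

    __slots__ = ("labels", "K")

    def __init__(self, labels: Sequence[int] | np.ndarray, K: int):
        labels = np.asarray(labels, dtype=np.int64).copy()
        if labels.ndim != 1:
            raise DimensionError("labels must be one-dimensional")
        if K < 1:
            raise ParameterError("K must be >= 1")
        if labels.size and (labels.min() < 0 or labels.max() >= K):
            raise LabelError(f"labels must lie in [0, {K})")
        self.labels = labels
        self.K = int(K)

    @property
    def n_vertices(self) -> int:
        return self.labels.size

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)

    def copy(self) -> "Parcellation":
        return Parcellation(self.labels, self.K)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Parcellation)
            and self.K == other.K
            and np.array_equal(self.labels, other.labels)
        )

    def __repr__(self):
        return f"Parcellation(n_vertices={self.n_vertices}, K={self.K})"


@dataclass(frozen=True)
class Hyperparameters:
    """Beta pseudo-counts for block link densities and the Dirichlet
    concentration for cluster proportions; one (β⁺, β⁻) pair is shared by
    all modalities."""

    beta_plus: float = 1.0
    beta_minus: float = 1.0
    alpha: float = 1.0

    def __post_init__(self):
        for name in ("beta_plus", "beta_minus", "alpha"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")

    def replace(self, **kwargs) -> "Hyperparameters":
        d = {
            "beta_plus": self.beta_plus,
            "beta_minus": self.beta_minus,
            "alpha": self.alpha,
        }
        d.update(kwargs)
        return Hyperparameters(**d)


class BlockStats:
    """Per-modality link/non-link counts per unordered cluster pair plus
    cluster sizes — the sufficient statistics of the collapsed likelihood.

    ``n_plus[m, l, h]`` holds the link count of block (l, h) for modality
    ``m``; the matrix is kept symmetric with within-cluster counts on the
    diagonal. Non-link counts are derived from the pair-count identity
    ``N⁺ + N⁻ = n_l n_h`` (l ≠ h) and ``n_l (n_l − 1)/2`` (l = h).
    """

    __slots__ = ("n_plus", "sizes", "K", "M", "n_vertices")

    def __init__(self, n_plus: np.ndarray, sizes: np.ndarray):
        self.n_plus = np.asarray(n_plus, dtype=np.int64)
        self.sizes = np.asarray(sizes, dtype=np.int64)
        if self.n_plus.ndim != 3 or self.n_plus.shape[1] != self.n_plus.shape[2]:
            raise DimensionError("n_plus must have shape (M, K, K)")
        self.M = self.n_plus.shape[0]
        self.K = self.n_plus.shape[1]
        if self.sizes.shape != (self.K,):
            raise DimensionError("sizes must have shape (K,)")
        self.n_vertices = int(self.sizes.sum())

    def pair_counts(self) -> np.ndarray:
        """(K, K) total vertex-pair counts per block."""
        p = np.outer(self.sizes, self.sizes)
        np.fill_diagonal(p, self.sizes * (self.sizes - 1) // 2)
        return p

    @property
    def n_minus(self) -> np.ndarray:
        return self.pair_counts()[None, :, :] - self.n_plus

    def copy(self) -> "BlockStats":
        return BlockStats(self.n_plus.copy(), self.sizes.copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BlockStats)
            and np.array_equal(self.n_plus, other.n_plus)
            and np.array_equal(self.sizes, other.sizes)
        )

    def validate(self) -> None:
        """Check the count identities; raises on violation."""
        from .errors import ConsistencyError

        if not np.array_equal(self.n_plus, np.swapaxes(self.n_plus, 1, 2)):
            raise ConsistencyError("n_plus is not symmetric")
        if (self.n_minus < 0).any() or (self.n_plus < 0).any():
            raise ConsistencyError("negative block counts")

    def __repr__(self):
        return f"BlockStats(M={self.M}, K={self.K}, n_vertices={self.n_vertices})"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_block_stats(
    networks: MultiLayerNetwork, parcellation: Parcellation
) -> BlockStats:
    """Compute the block sufficient statistics of ``networks`` under
    ``parcellation`` from scratch."""
    if parcellation.n_vertices != networks.n_vertices:
        raise DimensionError(
            f"parcellation covers {parcellation.n_vertices} vertices, "
            f"networks have {networks.n_vertices}"
        )
    K = parcellation.K
    z = parcellation.labels
    n_plus = np.zeros((networks.n_layers, K, K), dtype=np.int64)
    for m, layer in enumerate(networks):
        e = layer.edge_array()
        if e.size:
            li, lh = z[e[:, 0]], z[e[:, 1]]
            np.add.at(n_plus[m], (li, lh), 1)
            np.add.at(n_plus[m], (lh, li), 1)
            # pairs within a cluster were counted twice on the diagonal
            idx = np.arange(K)
            n_plus[m, idx, idx] //= 2
    return BlockStats(n_plus, np.bincount(z, minlength=K))


def _vertex_link_counts(
    networks: MultiLayerNetwork, labels: np.ndarray, K: int, vertex: int
) -> np.ndarray:
    """(M, K) counts of links from ``vertex`` to each cluster, per layer."""
    r = np.zeros((networks.n_layers, K), dtype=np.int64)
    for m, layer in enumerate(networks):
        nbrs = layer.neighbor_arrays()[vertex]
        if nbrs.size:
            r[m] = np.bincount(labels[nbrs], minlength=K)
    return r


def _detach_vertex(stats: BlockStats, r: np.ndarray, label: int) -> None:
    """Remove one vertex (with link profile ``r``) from cluster ``label``,
    in place."""
    stats.sizes[label] -= 1
    stats.n_plus[:, label, :] -= r
    stats.n_plus[:, :, label] -= r
    # the diagonal was decremented twice but loses only r[label] links
    stats.n_plus[:, label, label] += r[:, label]


def _attach_vertex(stats: BlockStats, r: np.ndarray, label: int) -> None:
    """Inverse of :func:`_detach_vertex`."""
    stats.sizes[label] += 1
    stats.n_plus[:, label, :] += r
    stats.n_plus[:, :, label] += r
    stats.n_plus[:, label, label] -= r[:, label]


def move_vertex(
    stats: BlockStats,
    networks: MultiLayerNetwork,
    parcellation: Parcellation,
    vertex: int,
    target: int,
) -> BlockStats:
    """Relabel ``vertex`` to ``target``, updating ``stats`` and
    ``parcellation`` incrementally (in place).

    The result is identical to rebuilding the statistics from the updated
    labels, at O(M·K) cost instead of O(E).
    """
    if not (0 <= target < parcellation.K):
        raise LabelError(f"target label {target} outside [0, {parcellation.K})")
    if not (0 <= vertex < parcellation.n_vertices):
        raise DimensionError(f"vertex {vertex} out of range")
    current = int(parcellation.labels[vertex])
    if current == target:
        return stats
    r = _vertex_link_counts(networks, parcellation.labels, parcellation.K, vertex)
    _detach_vertex(stats, r, current)
    _attach_vertex(stats, r, target)
    parcellation.labels[vertex] = target
    return stats


def log_clustering_prior(parcellation: Parcellation, alpha: float) -> float:
    """Log of the marginal partition prior with symmetric concentration α/K:

    ``log P(z | α) = log Γ(α) − log Γ(α+N) + Σ_k [log Γ(α/K + n_k) − log Γ(α/K)]``.
    """
    if not (alpha > 0):
        raise ParameterError("alpha must be strictly positive")
    n_k = parcellation.cluster_sizes()
    K = parcellation.K
    N = parcellation.n_vertices
    return float(
        gammaln(alpha)
        - gammaln(alpha + N)
        + np.sum(gammaln(alpha / K + n_k) - gammaln(alpha / K))
    )


def log_likelihood_from_stats(stats: BlockStats, hypers: Hyperparameters) -> float:
    """Collapsed log-likelihood term ``Σ_m Σ_{l≤h} log B(N⁺+β⁺, N⁻+β⁻) −
    log B(β⁺, β⁻)`` evaluated from sufficient statistics."""
    iu = np.triu_indices(stats.K)
    n_plus = stats.n_plus[:, iu[0], iu[1]]
    n_minus = stats.n_minus[:, iu[0], iu[1]]
    bp, bm = hypers.beta_plus, hypers.beta_minus
    return float(
        np.sum(betaln(n_plus + bp, n_minus + bm)) - n_plus.size * betaln(bp, bm)
    )


def log_joint(
    networks: MultiLayerNetwork,
    parcellation: Parcellation,
    hypers: Hyperparameters,
    stats: BlockStats | None = None,
) -> float:
    """Collapsed log P(A, z | β⁺, β⁻, α): partition prior plus the product of
    per-block Beta-Bernoulli marginals over modalities."""
    if stats is None:
        stats = build_block_stats(networks, parcellation)
    return log_clustering_prior(parcellation, hypers.alpha) + log_likelihood_from_stats(
        stats, hypers
    )
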