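"""Synthetic multi-layer networks drawn from the model's own generative
process, planted-partition shortcuts, and group-network construction by
aggregation and density thresholding.

Every generator takes an explicit :class:`numpy.random.Generator`; identical
seeds give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError
from .metrics import VertexMetadata
from .model import BinaryNetwork, MultiLayerNetwork, Parcellation


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic draw.

    ``pi`` (cluster proportions) and ``eta`` (per-layer K×K symmetric block
    densities) may be given explicitly; otherwise they are drawn from the
    model's priors — symmetric Dirichlet(α/K) and entrywise Beta(β⁺, β⁻).
    ``labels`` fixes the partition outright (planted-partition use)."""

    n_vertices: int
    K: int
    M: int = 1
    pi: np.ndarray | None = None
    eta: list[np.ndarray] | None = None
    labels: np.ndarray | None = None
    alpha: float = 1.0
    beta_plus: float = 1.0
    beta_minus: float = 1.0

    def __post_init__(self):
        if self.n_vertices < 1 or self.K < 1 or self.M < 1:
            raise ParameterError("n_vertices, K and M must all be >= 1")
        if self.pi is not None:
            pi = np.asarray(self.pi, dtype=float)
            if pi.shape != (self.K,) or (pi < 0).any() or not math.isclose(
                pi.sum(), 1.0, abs_tol=1e-9
            ):
                raise ParameterError("pi must be a length-K probability vector")
            self.pi = pi
        if self.eta is not None:
            if len(self.eta) != self.M:
                raise ParameterError("one eta matrix per layer is required")
            mats = []
            for em in self.eta:
                em = np.asarray(em, dtype=float)
                if em.shape != (self.K, self.K) or not np.allclose(em, em.T):
                    raise ParameterError("each eta must be K x K symmetric")
                if (em < 0).any() or (em > 1).any():
                    raise ParameterError("eta entries must lie in [0, 1]")
                mats.append(em)
            self.eta = mats


def planted_config(
    n_vertices: int,
    K: int,
    within: float,
    between: float,
    M: int = 2,
) -> SyntheticConfig:
    """Equal-proportion planted-partition configuration: block density
    ``within`` on the diagonal and ``between`` off it, identical across
    layers."""
    eta = np.full((K, K), between)
    np.fill_diagonal(eta, within)
    return SyntheticConfig(
        n_vertices=n_vertices, K=K, M=M, pi=np.full(K, 1.0 / K), eta=[eta] * M
    )


def sample_sbm(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[MultiLayerNetwork, Parcellation]:
    """One exact draw: z is sampled once (from π, itself drawn from the
    Dirichlet prior if unspecified) and shared by all layers; each layer's
    links are independent Bernoulli(η_{z_i z_j}) over pairs i < j."""
    K, n, M = config.K, config.n_vertices, config.M
    if config.labels is not None:
        z = np.asarray(config.labels, dtype=np.int64)
        if z.shape != (n,):
            raise ParameterError("labels must have length n_vertices")
    else:
        pi = config.pi
        if pi is None:
            pi = rng.dirichlet(np.full(K, config.alpha / K))
        z = rng.choice(K, size=n, p=pi)
    eta = config.eta
    if eta is None:
        eta = []
        for _ in range(M):
            em = rng.beta(config.beta_plus, config.beta_minus, size=(K, K))
            em = np.triu(em) + np.triu(em, k=1).T
            eta.append(em)
    iu = np.triu_indices(n, k=1)
    p_block = [em[z[iu[0]], z[iu[1]]] for em in eta]
    layers = []
    for m in range(M):
        present = rng.random(iu[0].size) < p_block[m]
        layers.append(
            BinaryNetwork(n, zip(iu[0][present].tolist(), iu[1][present].tolist()))
        )
    return MultiLayerNetwork(layers), Parcellation(z, K)


def sample_layer(
    truth: Parcellation, eta: np.ndarray, rng: np.random.Generator
) -> BinaryNetwork:
    """A single fresh layer conditioned on an existing partition — the
    held-out replicate used for predictive evaluation."""
    cfg = SyntheticConfig(
        n_vertices=truth.n_vertices, K=truth.K, M=1, labels=truth.labels, eta=[eta]
    )
    return sample_sbm(cfg, rng)[0][0]


def threshold_to_density(weights: np.ndarray, density: float) -> BinaryNetwork:
    """Binarize a symmetric nonnegative weight matrix by keeping only the
    L = round(density · n(n−1)/2) strongest off-diagonal pairs.

    Rounding is half-away-from-zero. Ties at the cutoff are broken by weight
    descending, then lexicographic pair index ascending, so the result is
    deterministic with exactly L links."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DimensionError("weights must be a square matrix")
    if not (0 < density <= 1):
        raise ParameterError("density must lie in (0, 1]")
    if (w < 0).any():
        raise ParameterError("weights must be nonnegative")
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.maximum(w[iu], w[(iu[1], iu[0])])  # symmetrize defensively
    n_pairs = vals.size
    L = int(math.floor(density * n_pairs + 0.5))
    # stable descending sort keeps ties in triu (lexicographic) order
    order = np.argsort(-vals, kind="stable")[:L]
    return BinaryNetwork(n, zip(iu[0][order].tolist(), iu[1][order].tolist()))


def aggregate_layers(replicates: list) -> np.ndarray:
    """Elementwise sum of same-size replicate matrices (binary networks are
    densified first) — the group-network construction feeding
    :func:`threshold_to_density`."""
    if not replicates:
        raise ParameterError("at least one replicate is required")
    mats = []
    for r in replicates:
        if isinstance(r, BinaryNetwork):
            mats.append(r.adjacency().astype(float))
        else:
            mats.append(np.asarray(r, dtype=float))
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise DimensionError("replicates differ in shape")
    return np.sum(mats, axis=0)


def synthetic_metadata(n_vertices: int) -> VertexMetadata:
    """Hemisphere labels for synthetic data: the first ⌈n/2⌉ vertices are
    'left', the rest 'right'; traversal order is the identity."""
    half = -(-n_vertices // 2)
    hemi = np.array(["left"] * half + ["right"] * (n_vertices - half))
    return VertexMetadata(hemisphere=hemi, traversal_index=np.arange(n_vertices))
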