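"""MCMC inference for the multi-layer stochastic block model.

One iteration of the sampler is a full collapsed Gibbs sweep over vertex
assignments followed by a block of random-walk Metropolis-Hastings updates
for each hyperparameter (β⁺, β⁻, α, in that order). The last sampled state
is treated as the point estimate; no convergence diagnostics are attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

from .errors import ConsistencyError, ParameterError
from .model import (
    BlockStats,
    Hyperparameters,
    MultiLayerNetwork,
    Parcellation,
    _attach_vertex,
    _detach_vertex,
    _vertex_link_counts,
    build_block_stats,
    log_joint,
)

logger = logging.getLogger(__name__)

_PARAM_NAMES = ("beta_plus", "beta_minus", "alpha")


@dataclass
class FitResult:
    """Final MCMC state plus the per-iteration log-joint trace."""

    parcellation: Parcellation
    hypers: Hyperparameters
    log_joint_trace: np.ndarray
    seed: int | None
    schedule: tuple[int, int]
    mh_acceptances: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.log_joint_trace)


def _candidate_log_probs(
    stats: BlockStats, r: np.ndarray, hypers: Hyperparameters
) -> np.ndarray:
    """Unnormalized log conditional for placing a detached vertex (link
    profile ``r``) into each of the K clusters.

    With the vertex removed, moving it into cluster l changes only blocks
    (l, k); each gains ``r[m, k]`` links and ``sizes[k] − r[m, k]``
    non-links. Terms not involving l cancel in the conditional.
    """
    sizes = stats.sizes
    n_plus = stats.n_plus
    n_minus = stats.n_minus
    bp, bm = hypers.beta_plus, hypers.beta_minus
    # axes: (modality m, candidate cluster l, partner cluster k)
    new_plus = n_plus + r[:, None, :]
    new_minus = n_minus + (sizes[None, :] - r)[:, None, :]
    delta = betaln(new_plus + bp, new_minus + bm) - betaln(n_plus + bp, n_minus + bm)
    return delta.sum(axis=(0, 2)) + np.log(hypers.alpha / stats.K + sizes)


def full_conditional(
    networks: MultiLayerNetwork,
    parcellation: Parcellation,
    stats: BlockStats,
    hypers: Hyperparameters,
    vertex: int,
) -> np.ndarray:
    """Exact Gibbs full-conditional P(z_vertex = l | A, z_rest) over all K
    labels; ``stats`` and ``parcellation`` are restored before returning."""
    current = int(parcellation.labels[vertex])
    r = _vertex_link_counts(networks, parcellation.labels, parcellation.K, vertex)
    _detach_vertex(stats, r, current)
    logp = _candidate_log_probs(stats, r, hypers)
    _attach_vertex(stats, r, current)
    p = np.exp(logp - logp.max())
    return p / p.sum()


def gibbs_sweep(
    networks: MultiLayerNetwork,
    parcellation: Parcellation,
    stats: BlockStats,
    hypers: Hyperparameters,
    rng: np.random.Generator,
    randomize_order: bool = False,
) -> tuple[Parcellation, BlockStats]:
    """One full collapsed Gibbs sweep: every vertex is detached from the
    counts, its conditional over all K labels is computed from incremental
    statistics, and a new label is sampled. Updates are in place."""
    if int(stats.sizes.sum()) != parcellation.n_vertices:
        raise ConsistencyError("stats do not cover the parcellation's vertices")
    n = parcellation.n_vertices
    order = rng.permutation(n) if randomize_order else np.arange(n)
    K = parcellation.K
    for v in order:
        current = int(parcellation.labels[v])
        r = _vertex_link_counts(networks, parcellation.labels, K, v)
        _detach_vertex(stats, r, current)
        logp = _candidate_log_probs(stats, r, hypers)
        p = np.exp(logp - logp.max())
        p /= p.sum()
        new = int(rng.choice(K, p=p))
        _attach_vertex(stats, r, new)
        parcellation.labels[v] = new
    return parcellation, stats


# ---------------------------------------------------------------------------
# Metropolis-Hastings hyperparameter updates
# ---------------------------------------------------------------------------


def _beta_log_target(stats: BlockStats):
    """Closure: collapsed log-likelihood as a function of (β⁺, β⁻) with the
    partition fixed (the prior term is constant in the betas)."""
    iu = np.triu_indices(stats.K)
    n_plus = stats.n_plus[:, iu[0], iu[1]].ravel()
    n_minus = stats.n_minus[:, iu[0], iu[1]].ravel()
    n_blocks = n_plus.size

    def target(bp: float, bm: float) -> float:
        return float(
            np.sum(betaln(n_plus + bp, n_minus + bm)) - n_blocks * betaln(bp, bm)
        )

    return target

def _alpha_log_target(stats: BlockStats):
    """Closure: log partition prior as a function of α (the likelihood term
    is constant in α)."""
    sizes = stats.sizes
    K = stats.K
    N = stats.n_vertices

    def target(alpha: float) -> float:
        return float(
            gammaln(alpha)
            - gammaln(alpha + N)
            + np.sum(gammaln(alpha / K + sizes) - gammaln(alpha / K))
        )

    return target


def mh_update_hyperparameter(
    stats: BlockStats,
    hypers: Hyperparameters,
    which: str,
    n_proposals: int,
    rng: np.random.Generator,
) -> tuple[Hyperparameters, int]:
    """Random-walk Metropolis for one hyperparameter with the partition
    fixed.

    Proposals are Gaussian with variance 1 centered at the current value;
    values ≤ 0 are rejected outright (flat improper prior on (0, ∞), so the
    acceptance ratio is the collapsed-likelihood ratio alone). Returns the
    updated hyperparameters and the acceptance count.
    """
    if which not in _PARAM_NAMES:
        raise ParameterError(f"unknown hyperparameter {which!r}")
    if n_proposals < 1:
        raise ParameterError("n_proposals must be >= 1")

    if which == "alpha":
        target = _alpha_log_target(stats)
        current = hypers.alpha
        log_t = target(current)
        accepted = 0
        for _ in range(n_proposals):
            prop = current + rng.standard_normal()
            if prop <= 0:
                continue
            log_t_prop = target(prop)
            if np.log(rng.random()) < log_t_prop - log_t:
                current, log_t = prop, log_t_prop
                accepted += 1
        return hypers.replace(alpha=current), accepted

    target2 = _beta_log_target(stats)
    bp, bm = hypers.beta_plus, hypers.beta_minus
    log_t = target2(bp, bm)
    accepted = 0
    for _ in range(n_proposals):
        prop = (bp if which == "beta_plus" else bm) + rng.standard_normal()
        if prop <= 0:
            continue
        cand = (prop, bm) if which == "beta_plus" else (bp, prop)
        log_t_prop = target2(*cand)
        if np.log(rng.random()) < log_t_prop - log_t:
            bp, bm = cand
            log_t = log_t_prop
            accepted += 1
    return hypers.replace(beta_plus=bp, beta_minus=bm), accepted


# ---------------------------------------------------------------------------
# full fits
# ---------------------------------------------------------------------------


def fit(
    networks: MultiLayerNetwork,
    K: int = 360,
    n_iterations: int = 100,
    mh_proposals: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    init: Parcellation | None = None,
    randomize_order: bool = False,
) -> FitResult:
    """Run the full sampling schedule and return the last state.

    Per iteration: one complete Gibbs sweep over all vertices, then
    ``mh_proposals`` Metropolis steps for each of β⁺, β⁻, α in that order.
    Initialization: uniform random labels, β⁺ = β⁻ = 1, α = K.
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if init is None:
        parcellation = Parcellation(rng.integers(0, K, size=networks.n_vertices), K)
    else:
        parcellation = init.copy()
    stats = build_block_stats(networks, parcellation)
    hypers = Hyperparameters(beta_plus=1.0, beta_minus=1.0, alpha=float(K))
    trace = np.empty(n_iterations)
    acc = {name: 0 for name in _PARAM_NAMES}
    for it in range(n_iterations):
        gibbs_sweep(networks, parcellation, stats, hypers, rng,
                    randomize_order=randomize_order)
        for name in _PARAM_NAMES:
            hypers, a = mh_update_hyperparameter(stats, hypers, name, mh_proposals, rng)
            acc[name] += a
        trace[it] = log_joint(networks, parcellation, hypers, stats=stats)
        logger.info("iteration %d: log-joint %.4f", it, trace[it])
        logger.debug("cumulative MH acceptances: %s", acc)
    return FitResult(
        parcellation=parcellation,
        hypers=hypers,
        log_joint_trace=trace,
        seed=seed,
        schedule=(n_iterations, mh_proposals),
        mh_acceptances=acc,
    )


def fit_hyperparameters_fixed(
    networks: MultiLayerNetwork,
    fixed: Parcellation,
    n_iterations: int = 100,
    mh_proposals: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Hyperparameters:
    """Infer (β⁺, β⁻, α) with the partition frozen — the atlas-style
    baseline where only the hyperparameters adapt to the data."""
    if rng is None:
        rng = np.random.default_rng(seed)
    stats = build_block_stats(networks, fixed)
    hypers = Hyperparameters(beta_plus=1.0, beta_minus=1.0, alpha=float(fixed.K))
    for _ in range(n_iterations):
        for name in _PARAM_NAMES:
            hypers, _ = mh_update_hyperparameter(stats, hypers, name, mh_proposals, rng)
    return hypers
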