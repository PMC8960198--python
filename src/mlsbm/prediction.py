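"""Held-out-network evaluation.

Given a partition learned on training networks, unseen networks are scored
through the Beta posterior of each block's link density: the expected
predictive log-likelihood uses digamma closed forms of ⟨log η⟩ and
⟨log(1−η)⟩, and link-prediction AUC ranks vertex pairs by the posterior
mean ⟨η⟩.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma
from sklearn.metrics import roc_auc_score

from .errors import DegenerateNetworkError, DimensionError
from .model import BinaryNetwork, BlockStats, Hyperparameters, Parcellation


@dataclass(frozen=True)
class BlockScoreMatrix:
    """Posterior expectations of one modality's block link densities.

    ``eta`` is the K×K posterior mean ⟨η⟩; ``log_eta`` and ``log_1m_eta``
    are ⟨log η⟩ and ⟨log(1−η)⟩ under the Beta posterior of each block.
    """

    eta: np.ndarray
    log_eta: np.ndarray
    log_1m_eta: np.ndarray

    @property
    def K(self) -> int:
        return self.eta.shape[0]


def block_expectations(
    train_stats: BlockStats, modality: int, hypers: Hyperparameters
) -> BlockScoreMatrix:
    """Closed-form posterior expectations per cluster pair for one modality.

    With a = N⁺ + β⁺ and b = N⁻ + β⁻ the block posterior is Beta(a, b), so
    ⟨log η⟩ = ψ(a) − ψ(a+b), ⟨log(1−η)⟩ = ψ(b) − ψ(a+b), ⟨η⟩ = a/(a+b).
    """
    if not (0 <= modality < train_stats.M):
        raise DimensionError(f"modality {modality} outside [0, {train_stats.M})")
    a = train_stats.n_plus[modality] + hypers.beta_plus
    b = train_stats.n_minus[modality] + hypers.beta_minus
    total = digamma(a + b)
    return BlockScoreMatrix(
        eta=a / (a + b),
        log_eta=digamma(a) - total,
        log_1m_eta=digamma(b) - total,
    )


def _check_test(parcellation: Parcellation, test: BinaryNetwork) -> None:
    if test.n_vertices != parcellation.n_vertices:
        raise DimensionError(
            f"test network has {test.n_vertices} vertices, "
            f"parcellation covers {parcellation.n_vertices}"
        )


def expected_predictive_log_likelihood(
    train_stats: BlockStats,
    parcellation: Parcellation,
    hypers: Hyperparameters,
    test: BinaryNetwork,
    modality: int = 0,
) -> float:
    """Held-out log-likelihood averaged over the train-data Beta posterior:

    ``Σ_{i>j} A_ij ⟨log η_{z_i z_j}⟩ + (1 − A_ij) ⟨log(1−η_{z_i z_j})⟩``.
    """
    _check_test(parcellation, test)
    scores = block_expectations(train_stats, modality, hypers)
    z = parcellation.labels
    iu = np.triu_indices(test.n_vertices, k=1)
    zl, zh = z[iu[0]], z[iu[1]]
    adj = test.adjacency()[iu]
    return float(
        np.sum(np.where(adj, scores.log_eta[zl, zh], scores.log_1m_eta[zl, zh]))
    )


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware (average-rank / Mann-Whitney) ROC AUC; links positive."""
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise DegenerateNetworkError(
            "AUC needs at least one link and one non-link in the test network"
        )
    return float(roc_auc_score(labels, scores))


def predictive_auc(
    parcellation: Parcellation, scores: BlockScoreMatrix, test: BinaryNetwork
) -> float:
    """AUC of ⟨η_{z_i z_j}⟩ as a link score for the held-out network."""
    _check_test(parcellation, test)
    z = parcellation.labels
    iu = np.triu_indices(test.n_vertices, k=1)
    s = scores.eta[z[iu[0]], z[iu[1]]]
    return _rank_auc(s, test.adjacency()[iu])


def direct_network_auc(predictor: BinaryNetwork, test: BinaryNetwork) -> float:
    """Baseline: use one network's binary entries as scores for another.

    With average-rank tie handling this equals (sensitivity + specificity)/2
    of the 2×2 confusion table between the two networks.
    """
    if predictor.n_vertices != test.n_vertices:
        raise DimensionError("predictor and test vertex counts differ")
    iu = np.triu_indices(test.n_vertices, k=1)
    s = predictor.adjacency()[iu].astype(float)
    return _rank_auc(s, test.adjacency()[iu])
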