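"""Gibbs sweep correctness, Metropolis-Hastings updates, and full fits."""

import itertools

import numpy as np
import pytest

from mlsbm import (
    BinaryNetwork,
    Hyperparameters,
    MultiLayerNetwork,
    Parcellation,
    ParameterError,
    build_block_stats,
    fit,
    fit_hyperparameters_fixed,
    full_conditional,
    gibbs_sweep,
    log_joint,
    mh_update_hyperparameter,
    normalized_mutual_information,
    planted_config,
    sample_sbm,
)
from conftest import random_instance


def conditional_by_recomputation(networks, parcellation, hypers, vertex):
    """Oracle: normalized exp(log_joint) over all candidate relabelings."""
    lj = []
    for lab in range(parcellation.K):
        z2 = parcellation.copy()
        z2.labels[vertex] = lab
        lj.append(log_joint(networks, z2, hypers))
    lj = np.array(lj)
    p = np.exp(lj - lj.max())
    return p / p.sum()


class TestFullConditional:
    def test_matches_log_joint_recomputation(self, rng):
        nets, z = random_instance(5, 3, 2, rng)
        h = Hyperparameters(1.4, 0.6, 2.5)
        stats = build_block_stats(nets, z)
        for v in range(5):
            p = full_conditional(nets, z, stats, h, v)
            q = conditional_by_recomputation(nets, z, h, v)
            assert np.max(np.abs(p - q)) < 1e-13
        # stats and labels restored
        assert stats == build_block_stats(nets, z)

    def test_misassigned_vertex_in_planted_two_block_graph(self):
        # deterministic blocks: within-density 0.9 ~ complete, between 0.0
        n = 12
        half = n // 2
        links = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i < half) == (j < half)
        ]
        nets = MultiLayerNetwork([BinaryNetwork(n, links)])
        z = Parcellation([0] * half + [1] * half, 2)
        z.labels[0] = 1  # misassign one vertex
        stats = build_block_stats(nets, z)
        p = full_conditional(nets, z, stats, Hyperparameters(1, 1, 1), 0)
        assert p[0] > 0.99

    def test_probabilities_normalized(self, rng):
        nets, z = random_instance(6, 4, 1, rng)
        stats = build_block_stats(nets, z)
        p = full_conditional(nets, z, stats, Hyperparameters(1, 1, 1), 2)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()


class TestGibbsSweep:
    def test_stats_stay_consistent(self, rng):
        nets, z = random_instance(15, 4, 2, rng)
        stats = build_block_stats(nets, z)
        h = Hyperparameters(1, 1, 4)
        for _ in range(10):
            gibbs_sweep(nets, z, stats, h, rng)
            assert stats == build_block_stats(nets, z)

    def test_chain_matches_enumerated_posterior(self, rng):
        """Empirical state distribution of the Gibbs chain on a tiny
        instance approaches the exact posterior P(z | A)."""
        nets, _ = random_instance(6, 2, 1, rng, p=0.5)
        h = Hyperparameters(1.0, 1.0, 2.0)
        # exact posterior over the 64 labeled states
        states = list(itertools.product(range(2), repeat=6))
        lj = np.array([log_joint(nets, Parcellation(s, 2), h) for s in states])
        post = np.exp(lj - lj.max())
        post /= post.sum()
        index = {s: i for i, s in enumerate(states)}

        z = Parcellation(rng.integers(0, 2, 6), 2)
        stats = build_block_stats(nets, z)
        counts = np.zeros(len(states))
        n_burn, n_keep = 500, 15000
        for it in range(n_burn + n_keep):
            gibbs_sweep(nets, z, stats, h, rng)
            if it >= n_burn:
                counts[index[tuple(z.labels.tolist())]] += 1
        tv = 0.5 * np.abs(counts / n_keep - post).sum()
        assert tv < 0.05


class _ScriptedRng:
    """Deterministic stand-in for a Generator in MH unit tests."""

    def __init__(self, normals, uniforms):
        self._normals = iter(normals)
        self._uniforms = iter(uniforms)

    def standard_normal(self):
        return next(self._normals)

    def random(self):
        return next(self._uniforms)


class TestMetropolisHastings:
    def test_nonpositive_proposals_always_rejected(self, rng):
        nets, z = random_instance(8, 2, 1, rng)
        stats = build_block_stats(nets, z)
        h = Hyperparameters(0.5, 1.0, 1.0)
        # every proposal pushes beta_plus to 0.5 - 5 < 0
        scripted = _ScriptedRng(normals=[-5.0] * 10, uniforms=[])
        out, accepted = mh_update_hyperparameter(stats, h, "beta_plus", 10, scripted)
        assert out == h
        assert accepted == 0

    def test_zero_step_proposal_always_accepted(self, rng):
        nets, z = random_instance(8, 2, 1, rng)
        stats = build_block_stats(nets, z)
        h = Hyperparameters(1.5, 1.0, 1.0)
        scripted = _ScriptedRng(normals=[0.0] * 5, uniforms=[0.999999] * 5)
        out, accepted = mh_update_hyperparameter(stats, h, "beta_plus", 5, scripted)
        assert out == h
        assert accepted == 5

    def test_unknown_parameter_name(self, rng):
        nets, z = random_instance(6, 2, 1, rng)
        stats = build_block_stats(nets, z)
        with pytest.raises(ParameterError):
            mh_update_hyperparameter(stats, Hyperparameters(), "gamma", 1, rng)

    def test_histogram_matches_grid_posterior(self, rng):
        """Short-run check that the beta_plus chain tracks the 1-D posterior
        computed by grid quadrature (z frozen)."""
        nets, z = random_instance(10, 2, 1, rng, p=0.35)
        stats = build_block_stats(nets, z)
        h = Hyperparameters(1.0, 1.0, 2.0)
        samples = np.empty(20000)
        for i in range(samples.size):
            h, _ = mh_update_hyperparameter(stats, h, "beta_plus", 1, rng)
            samples[i] = h.beta_plus
        samples = samples[2000:]
        edges = np.linspace(0, 10, 21)
        from mlsbm.inference import _beta_log_target

        target = _beta_log_target(stats)
        grid = np.linspace(1e-4, 10, 4000)
        logp = np.array([target(g, 1.0) for g in grid])
        dens = np.exp(logp - logp.max())
        dens /= dens.sum()
        grid_bins = np.array(
            [dens[(grid > lo) & (grid <= hi)].sum() for lo, hi in zip(edges, edges[1:])]
        )
        inside = samples[samples <= 10]
        hist, _ = np.histogram(inside, bins=edges)
        tv = 0.5 * np.abs(hist / inside.size - grid_bins / grid_bins.sum()).sum()
        assert tv < 0.15


class TestFit:
    def test_seeded_determinism(self, rng):
        nets, _ = random_instance(20, 3, 2, rng)
        a = fit(nets, K=3, n_iterations=5, mh_proposals=20, seed=7)
        b = fit(nets, K=3, n_iterations=5, mh_proposals=20, seed=7)
        assert np.array_equal(a.parcellation.labels, b.parcellation.labels)
        assert a.hypers == b.hypers
        assert np.array_equal(a.log_joint_trace, b.log_joint_trace)

    def test_defaults_match_reference_schedule(self):
        import inspect

        sig = inspect.signature(fit)
        assert sig.parameters["K"].default == 360
        assert sig.parameters["n_iterations"].default == 100
        assert sig.parameters["mh_proposals"].default == 1000

    def test_trace_reproducible_from_final_state(self, rng):
        nets, _ = random_instance(25, 3, 2, rng)
        res = fit(nets, K=3, n_iterations=6, mh_proposals=30, seed=3)
        assert res.log_joint_trace.size == 6
        assert np.isfinite(res.log_joint_trace).all()
        assert log_joint(nets, res.parcellation, res.hypers) == pytest.approx(
            res.log_joint_trace[-1]
        )

    def test_improves_over_random_partition_on_planted_data(self):
        nets, truth = sample_sbm(
            planted_config(120, 3, 0.3, 0.03, M=2), np.random.default_rng(11)
        )
        res = fit(nets, K=3, n_iterations=40, mh_proposals=100, seed=11)
        random_z = Parcellation(
            np.random.default_rng(0).integers(0, 3, 120), 3
        )
        assert normalized_mutual_information(res.parcellation, truth) > 0.5
        assert log_joint(nets, res.parcellation, res.hypers) > log_joint(
            nets, random_z, res.hypers
        )

    def test_rejects_bad_k(self, rng):
        nets, _ = random_instance(6, 2, 1, rng)
        with pytest.raises(ParameterError):
            fit(nets, K=0, n_iterations=1, mh_proposals=1, seed=0)


class TestFixedParcellationFit:
    def test_density_matched_hyperparameters(self, rng):
        # K=1 on a graph with ~half the pairs linked: posterior mean of the
        # single block density is ~0.5, so beta+/(beta+ + beta-) should too
        n = 40
        iu = np.triu_indices(n, k=1)
        keep = rng.random(iu[0].size) < 0.5
        net = BinaryNetwork(n, zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
        nets = MultiLayerNetwork([net])
        frozen = Parcellation([0] * n, 1)
        draws = []
        h = None
        for rep in range(20):
            h = fit_hyperparameters_fixed(
                nets, frozen, n_iterations=5, mh_proposals=50, seed=rep
            )
            draws.append(h.beta_plus / (h.beta_plus + h.beta_minus))
        assert abs(np.mean(draws) - net.density) < 0.15

    def test_seeded_determinism(self, rng):
        nets, z = random_instance(12, 2, 2, rng)
        a = fit_hyperparameters_fixed(nets, z, n_iterations=3, mh_proposals=40, seed=5)
        b = fit_hyperparameters_fixed(nets, z, n_iterations=3, mh_proposals=40, seed=5)
        assert a == b
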