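"""Eigengap selection, spectral clustering, and medoid extraction."""

import numpy as np
import pytest

from termscape.clustering import (
    ClusterAssignment,
    eigengap_k,
    medoids,
    spectral_cluster,
)
from termscape.semsim import SimilarityMatrix


def affinity(values, prefix="GO:00000"):
    values = np.asarray(values, dtype=float)
    terms = tuple(f"{prefix}{i:02d}" for i in range(values.shape[0]))
    return SimilarityMatrix(terms=terms, values=values, index="lin")


def block_diag(sizes, bridge=0.0):
    n = sum(sizes)
    a = np.full((n, n), 0.0)
    start = 0
    for s in sizes:
        a[start : start + s, start : start + s] = 1.0
        start += s
    if bridge:
        a[0, sizes[0]] = a[sizes[0], 0] = bridge
    return affinity(a)


class TestEigengap:
    def test_three_disconnected_blocks(self):
        assert eigengap_k(block_diag([3, 3, 3]), k_max=5) == 3

    def test_all_ones_single_cluster(self):
        assert eigengap_k(affinity(np.ones((6, 6))), k_max=5) == 1

    def test_two_weakly_bridged_blocks(self):
        assert eigengap_k(block_diag([3, 3], bridge=0.01), k_max=5) == 2

    def test_input_validation(self):
        asym = np.eye(4)
        asym[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            eigengap_k(affinity(asym))
        with pytest.raises(ValueError, match="at least 3"):
            eigengap_k(affinity(np.ones((2, 2))))
        with pytest.raises(ValueError, match="k_max"):
            eigengap_k(affinity(np.ones((4, 4))), k_max=4)


class TestSpectralCluster:
    def test_k_one_all_same_label(self):
        asg = spectral_cluster(block_diag([2, 2]), k=1)
        assert asg.labels == (0, 0, 0, 0)

    def test_k_equal_n_singletons(self):
        sim = block_diag([2, 2])
        asg = spectral_cluster(sim, k=4)
        assert sorted(asg.labels) == [0, 1, 2, 3]
        assert set(asg.medoids) == set(sim.terms)

    @pytest.mark.parametrize("seed", range(20))
    def test_three_blocks_recovered_every_seed(self, seed):
        sim = block_diag([4, 3, 3])
        asg = spectral_cluster(sim, k=3, seed=seed)
        # canonical relabeling: first block (smallest ids) is cluster 0
        assert asg.labels == (0,) * 4 + (1,) * 3 + (2,) * 3

    def test_determinism(self):
        sim = block_diag([4, 3, 3], bridge=0.2)
        a1 = spectral_cluster(sim, k=3, seed=11)
        a2 = spectral_cluster(sim, k=3, seed=11)
        assert a1.labels == a2.labels and a1.medoids == a2.medoids

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            spectral_cluster(block_diag([2, 2]), k=5)
        with pytest.raises(ValueError):
            spectral_cluster(block_diag([2, 2]), k=0)


class TestMedoids:
    def test_singleton_cluster(self):
        sim = affinity([[1.0, 0.2], [0.2, 1.0]])
        assert medoids(sim, [0, 1]) == sim.terms

    def test_hand_example(self):
        # mean sims: a 0.9, b ~0.667, c ~0.633
        sim = affinity([[1.0, 0.9, 0.8], [0.9, 1.0, 0.1], [0.8, 0.1, 1.0]])
        assert medoids(sim, [0, 0, 0]) == (sim.terms[0],)

    def test_uniform_tie_breaks_to_smallest_id(self):
        sim = affinity(np.full((3, 3), 1.0))
        assert medoids(sim, [0, 0, 0]) == (min(sim.terms),)

    def test_empty_cluster_rejected(self):
        sim = affinity(np.ones((3, 3)))
        with pytest.raises(ValueError, match="empty"):
            medoids(sim, [0, 0, 2])

    @pytest.mark.parametrize("trial_block", range(10))
    def test_agrees_with_bruteforce_oracle(self, trial_block):
        rng = np.random.default_rng(trial_block)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            a = rng.uniform(size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            sim = affinity(a)
            k = int(rng.integers(1, n + 1))
            labels = list(rng.integers(0, k, size=n))
            for c in range(k):  # guarantee non-empty clusters
                if c not in labels:
                    labels[c % n] = c
            labels = _compact(labels)
            got = medoids(sim, labels)
            for c, m in enumerate(got):
                idx = [i for i, l in enumerate(labels) if l == c]
                best = max(
                    idx,
                    key=lambda i: (a[i, idx].mean(), sim.terms[i]),
                )
                # oracle: explicit argmax of mean within-cluster similarity
                means = {i: a[i, idx].mean() for i in idx}
                top = max(means.values())
                expect = min(
                    sim.terms[i] for i in idx if means[i] >= top - 1e-12
                )
                assert m == expect


def _compact(labels):
    remap = {}
    out = []
    for l in labels:
        if l not in remap:
            remap[l] = len(remap)
        out.append(remap[l])
    return out


def test_assignment_invariants_enforced():
    with pytest.raises(ValueError):
        ClusterAssignment(
            terms=("GO:1", "GO:2"), labels=(0, 0), k=2,
            medoids=("GO:1", "GO:2"), seed=0,
        )
    with pytest.raises(ValueError):
        ClusterAssignment(
            terms=("GO:1", "GO:2"), labels=(0, 1), k=2,
            medoids=("GO:1",), seed=0,
        )
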