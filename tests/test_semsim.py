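"""Information content and Lin/AIC semantic similarity."""

import math

import numpy as np
import pytest

import termscape.synthetic as syn
from termscape.semsim import (
    aic_similarity,
    information_content,
    lin_similarity,
    semantic_value,
    semantic_weight,
    similarity_matrix,
    term_stats,
)

from conftest import A, B, C, D, R


@pytest.fixture(scope="module")
def rcab_stats(rcab):
    dag, ann = rcab
    return dag, ann, term_stats(ann, dag)


class TestIC:
    def test_root_probability_one(self, rcab_stats):
        dag, ann, stats = rcab_stats
        assert stats[R].p == 1.0
        assert stats[R].ic == 0.0

    def test_quarter_and_half_coverage(self, rcab_stats):
        _, _, stats = rcab_stats
        assert math.isclose(stats[A].ic, math.log(4), rel_tol=1e-12)  # 2/8
        assert math.isclose(stats[C].ic, math.log(2), rel_tol=1e-12)  # 4/8

    def test_unannotated_term_rejected(self, rcab):
        dag, ann = rcab
        bare = ann.__class__(
            direct={}, propagated={}, universe=frozenset({"g"}),
        )
        with pytest.raises(ValueError):
            information_content(R, bare, dag)

    @pytest.mark.parametrize("seed", range(4))
    def test_ic_antimonotone_along_edges(self, seed):
        data = syn.generate(
            syn.SyntheticSpec(seed=seed, n_terms=25, n_genes=50,
                              target_size=0)
        )
        dag, ann = data.parse()
        stats = term_stats(ann, dag)
        for child, parent in dag.graph.edges():
            if child in stats and parent in stats:
                assert stats[parent].ic <= stats[child].ic + 1e-12


class TestLin:
    def test_self_similarity(self, rcab_stats):
        dag, _, stats = rcab_stats
        assert lin_similarity(A, A, stats, dag) == 1.0

    def test_root_only_common_ancestor_is_zero(self, rcab_stats):
        dag, _, stats = rcab_stats
        assert lin_similarity(A, D, stats, dag) == 0.0

    def test_hand_value_half(self, rcab_stats):
        """Siblings under C: 2*ln2 / (2*2ln2) = 0.5 exactly."""
        dag, _, stats = rcab_stats
        assert math.isclose(lin_similarity(A, B, stats, dag), 0.5,
                            rel_tol=1e-12)

    def test_both_ic_zero_convention(self, rcab_stats):
        dag, _, stats = rcab_stats
        assert lin_similarity(R, R, stats, dag) == 0.0


class TestAIC:
    def test_semantic_weight_limits(self):
        assert semantic_weight(0.0) == 1.0
        assert 0.5 < semantic_weight(1.0) < 1.0
        # weight decreases as terms get more specific
        assert semantic_weight(0.5) > semantic_weight(2.0)

    def test_self_similarity_one(self, rcab_stats):
        dag, _, stats = rcab_stats
        for t in (A, B, C, D, R):
            assert math.isclose(aic_similarity(t, t, stats, dag), 1.0,
                                rel_tol=1e-12)

    def test_hand_value_from_pinned_formula(self, rcab_stats):
        """aic(A, B) recomputed by hand from SW/SV definitions."""
        dag, _, stats = rcab_stats
        sw = {t: semantic_weight(stats[t].ic) for t in (R, C, A, B)}
        expected = (2 * (sw[R] + sw[C])) / (
            (sw[R] + sw[C] + sw[A]) + (sw[R] + sw[C] + sw[B])
        )
        assert math.isclose(aic_similarity(A, B, stats, dag), expected,
                            rel_tol=1e-12)
        assert math.isclose(semantic_value(A, stats, dag),
                            sw[R] + sw[C] + sw[A], rel_tol=1e-12)

    def test_deep_shared_lineage_beats_shallow(self, rcab_stats):
        """A and B share R and C; A and D share only R."""
        dag, _, stats = rcab_stats
        ab = aic_similarity(A, B, stats, dag)
        ad = aic_similarity(A, D, stats, dag)
        assert 0.0 < ad < ab < 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_on_random_pairs(self, seed):
        data = syn.generate(
            syn.SyntheticSpec(seed=seed, n_terms=20, n_genes=40,
                              target_size=0)
        )
        dag, ann = data.parse()
        stats = term_stats(ann, dag)
        rng = np.random.default_rng(seed)
        terms = sorted(stats)
        for _ in range(20):
            t1, t2 = rng.choice(terms, size=2)
            assert math.isclose(
                aic_similarity(t1, t2, stats, dag),
                aic_similarity(t2, t1, stats, dag),
                rel_tol=1e-12,
            )


class TestSimilarityMatrix:
    def test_duplicate_terms_give_all_ones(self, rcab_stats):
        dag, _, stats = rcab_stats
        m = similarity_matrix([A, A], "lin", stats, dag)
        assert np.allclose(m.values, 1.0)

    def test_rcab_offdiagonal_half_under_lin(self, rcab_stats):
        dag, _, stats = rcab_stats
        m = similarity_matrix([A, B], "lin", stats, dag)
        assert np.allclose(m.values, [[1.0, 0.5], [0.5, 1.0]])

    def test_fewer_than_two_terms_rejected(self, rcab_stats):
        dag, _, stats = rcab_stats
        with pytest.raises(ValueError):
            similarity_matrix([A], "lin", stats, dag)
        with pytest.raises(ValueError):
            similarity_matrix([A, B], "resnik", stats, dag)

    @pytest.mark.parametrize("measure", ["lin", "aic"])
    @pytest.mark.parametrize("seed", range(5))
    def test_contract_on_random_fixtures(self, measure, seed):
        """Symmetry, [0,1] range, unit diagonal for IC>0 terms."""
        data = syn.generate(
            syn.SyntheticSpec(seed=seed, n_terms=20, n_genes=40,
                              target_size=0)
        )
        dag, ann = data.parse()
        stats = term_stats(ann, dag)
        terms = sorted(stats)
        m = similarity_matrix(terms, measure, stats, dag)
        assert np.allclose(m.values, m.values.T)
        assert (m.values >= 0).all() and (m.values <= 1 + 1e-12).all()
        for i, t in enumerate(terms):
            if stats[t].ic > 0:
                assert math.isclose(m.values[i, i], 1.0, rel_tol=1e-12)

    def test_csv_dump_roundtrip(self, rcab_stats, tmp_path):
        import pandas as pd

        dag, _, stats = rcab_stats
        m = similarity_matrix([A, B, C], "aic", stats, dag)
        out = tmp_path / "sim.csv"
        m.to_csv(out)
        df = pd.read_csv(out, index_col=0)
        assert np.allclose(df.values, m.values)
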