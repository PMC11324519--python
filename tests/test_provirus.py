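"""CRF training/decoding and provirus island post-processing rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgeclass.provirus import (
    CRFParams,
    crf_decode,
    crf_loglik_grad,
    crf_train,
    evaluate_provirus_calls,
    extend_boundaries,
    filter_islands,
    islands_from_states,
    merge_islands,
)
from mgeclass.records import GeneRecord


def brute_force_decode(params, X):
    """Oracle: enumerate all 2^n paths, first maximum in lexicographic order."""
    n = X.shape[0]
    psi = X @ params.emission.T
    best, best_score = None, -np.inf
    for path in itertools.product([0, 1], repeat=n):
        s = sum(psi[t, path[t]] for t in range(n))
        s += sum(params.transition[path[t], path[t + 1]] for t in range(n - 1))
        if s > best_score:
            best_score, best = s, path
    return best


class TestCrf:
    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 100_000))
    def test_viterbi_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        X = rng.normal(size=(n, 4))
        params = CRFParams(rng.normal(0, 1, (2, 4)), rng.normal(0, 1, (2, 2)))
        assert tuple(crf_decode(params, X)) == brute_force_decode(params, X)

    def test_empty_chain(self):
        params = CRFParams(np.zeros((2, 4)), np.zeros((2, 2)))
        assert len(crf_decode(params, np.zeros((0, 4)))) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        X = rng.normal(size=(n, 4))
        states = rng.integers(0, 2, n)
        params = CRFParams(rng.normal(0, 0.5, (2, 4)), rng.normal(0, 0.5, (2, 2)))
        _, d_em, d_tr = crf_loglik_grad(params, X, states)
        eps = 1e-6
        for i, j in [(0, 1), (1, 3)]:
            up = CRFParams(params.emission.copy(), params.transition.copy())
            dn = CRFParams(params.emission.copy(), params.transition.copy())
            up.emission[i, j] += eps
            dn.emission[i, j] -= eps
            num = (crf_loglik_grad(up, X, states)[0] - crf_loglik_grad(dn, X, states)[0]) / (2 * eps)
            assert num == pytest.approx(d_em[i, j], abs=1e-5)
        for i, j in [(0, 1), (1, 1)]:
            up = CRFParams(params.emission.copy(), params.transition.copy())
            dn = CRFParams(params.emission.copy(), params.transition.copy())
            up.transition[i, j] += eps
            dn.transition[i, j] -= eps
            num = (crf_loglik_grad(up, X, states)[0] - crf_loglik_grad(dn, X, states)[0]) / (2 * eps)
            assert num == pytest.approx(d_tr[i, j], abs=1e-5)

    def test_training_reaches_stationarity(self, crf_fixture):
        # gradient of the penalized objective vanishes at the optimum
        params = crf_fixture["params"]
        chains = crf_fixture["chains"][:15]
        l2 = 0.01
        g_em = -2 * l2 * params.emission
        g_tr = -2 * l2 * params.transition
        for X, states in chains:
            _, d_em, d_tr = crf_loglik_grad(params, X, states)
            g_em = g_em + d_em
            g_tr = g_tr + d_tr
        assert np.abs(g_em).max() < 1e-4
        assert np.abs(g_tr).max() < 1e-4

    def test_objective_increases_during_training(self, crf_fixture):
        # the trained optimum beats the random initialization it started from
        chains = crf_fixture["chains"][:15]
        rng = np.random.default_rng(7)
        init = CRFParams(rng.normal(0, 0.01, (2, 4)), rng.normal(0, 0.01, (2, 2)))
        ll_init = sum(crf_loglik_grad(init, X, s)[0] for X, s in chains)
        trained = crf_fixture["params"]
        ll_trained = sum(crf_loglik_grad(trained, X, s)[0] for X, s in chains)
        assert ll_trained > ll_init

    def test_single_state_training_is_error(self):
        X = np.zeros((5, 4))
        with pytest.raises(ValueError):
            crf_train([(X, np.zeros(5, dtype=int))], seed=0)

    def test_learned_weights_decode_virus_block(self, crf_fixture):
        params = crf_fixture["params"]
        # pure virus-marker features must decode as provirus
        X = np.tile([0.05, 0.95, 1.0, 1.0], (6, 1))
        assert np.all(crf_decode(params, X) == 1)
        # unannotated genes decode as chromosome (host prior on null evidence)
        X0 = np.tile([0.0, 0.0, 0.0, 1.0], (1, 1))
        assert np.all(crf_decode(params, X0) == 0)

    def test_params_round_trip(self, crf_fixture, tmp_path):
        p = tmp_path / "crf.json"
        crf_fixture["params"].save(p)
        back = CRFParams.load(p)
        assert np.array_equal(back.emission, crf_fixture["params"].emission)
        assert np.array_equal(back.transition, crf_fixture["params"].transition)


class TestIslandOps:
    def test_islands_from_states(self):
        states = np.array([0, 1, 1, 0, 0, 1, 0, 1])
        assert islands_from_states(states) == [(1, 2), (5, 5), (7, 7)]

    def test_merge_short_clean_gap(self):
        classes = [None] * 40
        assert merge_islands([(10, 20), (24, 30)], classes) == [(10, 30)]

    def test_no_merge_six_gene_gap(self):
        classes = [None] * 40
        assert merge_islands([(10, 20), (27, 30)], classes) == [(10, 20), (27, 30)]

    def test_no_merge_two_chromosome_markers(self):
        classes = [None] * 40
        classes[21] = classes[22] = "chromosome"
        assert merge_islands([(10, 20), (24, 30)], classes) == [(10, 20), (24, 30)]

    def test_merge_one_chromosome_marker_allowed(self):
        classes = [None] * 40
        classes[22] = "chromosome"
        assert merge_islands([(10, 20), (24, 30)], classes) == [(10, 30)]

    def test_overlapping_islands_error(self):
        with pytest.raises(ValueError):
            merge_islands([(5, 12), (10, 20)], [None] * 30)

    def test_filter_by_virus_spm_sum(self):
        spm = [0.0] * 40
        for i in (11, 13, 15):
            spm[i] = 0.9
        assert filter_islands([(10, 16)], spm, 1.5) == [(10, 16)]  # 2.7 >= 1.5
        assert filter_islands([(20, 25)], spm, 0.5) == []  # no markers
        assert filter_islands([(10, 16)], spm, 2.8) == []

    def test_merge_transitive_closure(self):
        classes = [None] * 60
        assert merge_islands([(0, 5), (8, 12), (15, 20)], classes) == [(0, 20)]


def _genes_at(positions, seq_id="s"):
    return [
        GeneRecord(seq_id, i, start, start + 300, 1)
        for i, start in enumerate(positions)
    ]


class TestExtendBoundaries:
    def _setup(self):
        # genes every 1 kb: gene i spans [1000i, 1000i + 300)
        genes = _genes_at([1000 * i for i in range(20)])
        trna = [False] * 20
        integrase = [False] * 20
        classes = [None] * 20
        return genes, trna, integrase, classes

    def test_trna_within_5kb_extends(self):
        genes, trna, integrase, classes = self._setup()
        trna[13] = True  # 13000 - (10000+300) = 2700 <= 5000
        out = extend_boundaries([(5, 10)], genes, trna, integrase, classes)
        assert out == [(5, 13, "none", "trna")]

    def test_trna_beyond_5kb_integrase_within_10kb(self):
        genes, trna, integrase, classes = self._setup()
        trna[17] = True  # 17000 - 10300 = 6700 > 5000
        integrase[18] = True  # 18000 - 10300 = 7700 <= 10000
        out = extend_boundaries([(5, 10)], genes, trna, integrase, classes)
        assert out == [(5, 18, "none", "integrase")]

    def test_chromosome_marker_blocks_extension(self):
        genes, trna, integrase, classes = self._setup()
        trna[13] = True
        classes[12] = "chromosome"
        out = extend_boundaries([(5, 10)], genes, trna, integrase, classes)
        assert out == [(5, 10, "none", "none")]

    def test_left_edge_extension(self):
        genes, trna, integrase, classes = self._setup()
        trna[2] = True  # 5000 - (2000+300) = 2700 <= 5000
        out = extend_boundaries([(5, 10)], genes, trna, integrase, classes)
        assert out == [(2, 10, "trna", "none")]

    def test_trna_preferred_over_integrase(self):
        genes, trna, integrase, classes = self._setup()
        integrase[12] = True
        trna[13] = True
        out = extend_boundaries([(5, 10)], genes, trna, integrase, classes)
        assert out[0][1] == 13 and out[0][3] == "trna"

    def test_never_shrinks_and_stays_disjoint(self):
        genes, trna, integrase, classes = self._setup()
        trna[8] = True
        out = extend_boundaries([(3, 7), (9, 12)], genes, trna, integrase, classes)
        (a1, b1, _, _), (a2, b2, _, _) = out
        assert a1 <= 3 and b1 >= 7 and a2 <= 9 and b2 >= 12
        assert b1 < a2


class TestEvaluation:
    def test_perfect_call(self):
        assert evaluate_provirus_calls([(10, 20)], [(10, 20)]) == [(1.0, 1.0)]

    def test_half_coverage(self):
        # call covers half the truth and nothing else
        assert evaluate_provirus_calls([(10, 14)], [(10, 19)]) == [(1.0, 0.5)]

    def test_no_overlap(self):
        assert evaluate_provirus_calls([(30, 40)], [(10, 20)]) == [(0.0, 0.0)]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_set_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = []
        pos = 0
        for _ in range(4):
            a = pos + int(rng.integers(0, 10))
            b = a + int(rng.integers(0, 15))
            calls.append((a, b))
            pos = b + 2
        truth = (int(rng.integers(0, 30)), int(rng.integers(30, 60)))
        (prec, sens) = evaluate_provirus_calls(calls, [truth])[0]
        t = set(range(truth[0], truth[1] + 1))
        p = set()
        for a, b in calls:
            if a <= truth[1] and b >= truth[0]:
                p |= set(range(a, b + 1))
        if p:
            assert prec == len(p & t) / len(p)
            assert sens == len(p & t) / len(t)
        else:
            assert (prec, sens) == (0.0, 0.0)


class TestMockRecovery:
    def test_median_precision_and_sensitivity(self, crf_fixture, marker_db):
        from mgeclass.provirus import call_proviruses

        params = crf_fixture["params"]
        precs, sens = [], []
        for rec, ann in zip(crf_fixture["records"][15:], crf_fixture["anns"][15:]):
            calls = call_proviruses(ann, params)
            (p, s) = evaluate_provirus_calls(calls, [crf_fixture["truths"][rec.id]])[0]
            precs.append(p)
            sens.append(s)
        assert np.median(precs) >= 0.9
        assert np.median(sens) >= 0.9
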