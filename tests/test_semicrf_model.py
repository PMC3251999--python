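"""Semi-Markov CRF potentials, partition, gradients and decoding against
independent enumeration and finite-difference oracles."""

import numpy as np
import pytest

from actikit.errors import ContractError
from actikit.semicrf import (
    START,
    ArrayDurationStats,
    ModelParams,
    OpCounter,
    SemiSegment,
    enumerate_segmentations,
    gradients_bruteforce,
    gradients_fast,
    gradients_naive,
    infer,
    log_likelihood,
    log_partition,
    potentials,
    sequence_score,
)


def random_instance(rng, T=None, M=None, D=None, S=3):
    T = T or int(rng.integers(1, 7))
    M = M or int(rng.integers(1, 4))
    D = D or int(rng.integers(1, 4))
    w = ModelParams(
        w_tr=rng.normal(size=(M + 1, M)),
        w_d=rng.normal(size=M),
        w_o=rng.normal(size=(M + 1, S)),
    )
    stats = ArrayDurationStats(m=rng.uniform(1, 3, M), s2=rng.uniform(0.5, 2, M))
    x = rng.integers(0, S, T)
    return x, w, stats, D


class TestPotentials:
    def test_zero_weights_vanish(self):
        w = ModelParams.zeros(2, 3)
        stats = ArrayDurationStats(np.ones(2), np.ones(2))
        out = potentials(START, SemiSegment(0, 2, 4), np.array([0, 1, 2, 0, 1]), w, stats)
        assert out == (0.0, 0.0, 0.0, 0.0)

    def test_duration_at_mean_has_zero_penalty(self):
        w = ModelParams.zeros(1, 2)
        w.w_d[0] = 5.0
        stats = ArrayDurationStats(np.array([3.0]), np.array([1.0]))
        _, q_d, _, _ = potentials(START, SemiSegment(0, 1, 3), np.zeros(4, int), w, stats)
        assert q_d == 0.0

    def test_hand_evaluated_instance_with_gap(self):
        # 2 labels, 2 symbols; prev = (0,1,2), cur = (1,4,5); gap at t=3
        w = ModelParams.zeros(2, 2)
        w.w_tr[0, 1] = 0.7
        w.w_d[1] = 2.0
        w.w_o[1, 0], w.w_o[1, 1] = 0.3, -0.4
        w.w_o[2, 1] = 0.9  # IA row
        stats = ArrayDurationStats(np.array([2.0, 3.0]), np.array([1.0, 0.5]))
        x = np.array([0, 0, 1, 1, 0])
        q_tr, q_d, q_o, log_psi = potentials(
            SemiSegment(0, 1, 2), SemiSegment(1, 4, 5), x, w, stats
        )
        assert q_tr == pytest.approx(0.7)
        # d=2, m=3, s2=0.5 -> w_d * (2-3)^2/(2*0.5) = 2.0 * 1.0
        assert q_d == pytest.approx(2.0)
        # segment symbols x4=1, x5=0 -> -0.4 + 0.3; gap symbol x3=1 -> 0.9
        assert q_o == pytest.approx(-0.4 + 0.3 + 0.9)
        assert log_psi == pytest.approx(q_tr + q_d + q_o)

    def test_ordering_violation_rejected(self):
        w = ModelParams.zeros(1, 2)
        stats = ArrayDurationStats(np.ones(1), np.ones(1))
        with pytest.raises(ContractError):
            potentials(SemiSegment(0, 1, 3), SemiSegment(0, 3, 4), np.zeros(5, int), w, stats)


class TestPartition:
    def test_zero_weight_counts_segmentations(self):
        w = ModelParams.zeros(1, 2)
        stats = ArrayDurationStats(np.array([2.0]), np.array([1.0]))
        # T=2, D=2: empty, (1,1), (2,2), (1,2), {(1,1),(2,2)} -> 5
        assert log_partition(np.array([0, 1]), w, stats, 2) == pytest.approx(np.log(5))
        assert log_partition(np.array([0]), w, stats, 1) == pytest.approx(np.log(2))

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            x, w, stats, D = random_instance(rng)
            scores = [sequence_score(s, x, w, stats)
                      for s in enumerate_segmentations(len(x), w.n_labels, D)]
            assert log_partition(x, w, stats, D) == pytest.approx(
                np.logaddexp.reduce(scores), abs=1e-9
            )


class TestLikelihood:
    def test_zero_weights_is_minus_log_count(self):
        w = ModelParams.zeros(2, 2)
        stats = ArrayDurationStats(np.ones(2), np.ones(2))
        x = np.array([0, 1, 0])
        n = sum(1 for _ in enumerate_segmentations(3, 2, 2))
        ll = log_likelihood([SemiSegment(0, 1, 2)], x, w, stats, 2)
        assert ll == pytest.approx(-np.log(n))

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        x, w, stats, D = random_instance(rng, T=4, M=2, D=2)
        total = sum(
            np.exp(log_likelihood(s, x, w, stats, D))
            for s in enumerate_segmentations(4, 2, D)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_always_nonpositive(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x, w, stats, D = random_instance(rng)
            for s in enumerate_segmentations(len(x), w.n_labels, D):
                assert log_likelihood(s, x, w, stats, D) <= 1e-12
                break

    def test_overlong_truth_rejected(self):
        w = ModelParams.zeros(1, 2)
        stats = ArrayDurationStats(np.ones(1), np.ones(1))
        with pytest.raises(ContractError):
            log_likelihood([SemiSegment(0, 1, 3)], np.zeros(4, int), w, stats, 2)


class TestGradients:
    def test_fast_equals_bruteforce_and_finite_differences(self):
        rng = np.random.default_rng(4)
        for _ in range(8):
            x, w, stats, D = random_instance(rng, T=int(rng.integers(2, 6)),
                                             M=int(rng.integers(1, 3)), S=2)
            cands = [s for s in enumerate_segmentations(len(x), w.n_labels, D) if s]
            s_true = cands[int(rng.integers(0, len(cands)))]
            gf = gradients_fast(x, s_true, w, stats, D).as_vector()
            gb = gradients_bruteforce(x, s_true, w, stats, D).as_vector()
            np.testing.assert_allclose(gf, gb, atol=1e-8)
            vec = w.as_vector()
            M, S = w.n_labels, w.n_symbols

            def ll(v):
                return log_likelihood(s_true, x, ModelParams.from_vector(v, M, S), stats, D)

            for i in range(len(vec)):
                vp, vm = vec.copy(), vec.copy()
                vp[i] += 1e-5
                vm[i] -= 1e-5
                assert gf[i] == pytest.approx((ll(vp) - ll(vm)) / 2e-5, abs=1e-4)

    def test_naive_path_equals_bruteforce_including_ia_row(self):
        rng = np.random.default_rng(5)
        x, w, stats, D = random_instance(rng, T=4, M=2, D=2, S=2)
        s_true = [SemiSegment(0, 1, 2), SemiSegment(1, 4, 4)]
        gb = gradients_bruteforce(x, s_true, w, stats, D)
        M = w.n_labels
        feats = ([("tr", yp, y) for yp in range(M + 1) for y in range(M)]
                 + [("d", y) for y in range(M)]
                 + [("o", y, o) for y in range(M + 1) for o in range(2)])
        gn = gradients_naive(x, s_true, w, stats, D, params=feats)
        for feat, val in gn.items():
            ref = {"tr": gb.w_tr, "d": gb.w_d, "o": gb.w_o}[feat[0]][feat[1:]]
            assert val == pytest.approx(float(ref), abs=1e-8)

    def test_unused_symbol_gradient_is_nonpositive(self):
        rng = np.random.default_rng(6)
        w = ModelParams(rng.normal(size=(2, 1)), rng.normal(size=1),
                        rng.normal(size=(2, 3)))
        stats = ArrayDurationStats(np.array([2.0]), np.array([1.0]))
        x = np.array([0, 0, 0])  # symbols 1, 2 never observed
        g = gradients_fast(x, [SemiSegment(0, 1, 2)], w, stats, 2)
        assert g.w_o[0, 1] <= 0 and g.w_o[0, 2] <= 0

    def test_label_exchange_symmetry(self):
        # symmetric weights and a palindrome-symmetric observation: exchanging
        # the two labels maps the instance onto itself
        w = ModelParams.zeros(2, 2)
        w.w_o[0, 0] = w.w_o[1, 1] = 1.0
        w.w_o[0, 1] = w.w_o[1, 0] = -1.0
        stats = ArrayDurationStats(np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        x = np.array([0, 1])
        s = [SemiSegment(0, 1, 1), SemiSegment(1, 2, 2)]
        g = gradients_fast(x, s, w, stats, 2)
        # swapping labels AND symbols maps the truth onto itself
        assert g.w_o[0, 0] == pytest.approx(g.w_o[1, 1], abs=1e-10)
        assert g.w_o[0, 1] == pytest.approx(g.w_o[1, 0], abs=1e-10)
        assert g.w_d[0] == pytest.approx(g.w_d[1], abs=1e-10)

    def test_bruteforce_guard(self):
        w = ModelParams.zeros(1, 2)
        stats = ArrayDurationStats(np.ones(1), np.ones(1))
        with pytest.raises(ContractError):
            gradients_bruteforce(np.zeros(11, int), [], w, stats, 2)


class TestViterbi:
    def test_constructed_dominance(self):
        w = ModelParams.zeros(1, 2)
        w.w_o[0, 1] = 10.0  # label 0 loves symbol 1
        w.w_o[1, 0] = 1.0   # IA prefers symbol 0
        stats = ArrayDurationStats(np.array([3.0]), np.array([1.0]))
        x = np.array([0, 1, 1, 1, 0])
        assert infer(x, w, stats, 4) == [SemiSegment(0, 2, 4)]

    def test_matches_enumeration_argmax(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            x, w, stats, D = random_instance(rng)
            best = max(
                enumerate_segmentations(len(x), w.n_labels, D),
                key=lambda s: sequence_score(s, x, w, stats),
            )
            got = infer(x, w, stats, D)
            assert sequence_score(got, x, w, stats) == pytest.approx(
                sequence_score(best, x, w, stats), abs=1e-9
            )

    def test_zero_weight_tie_break_is_canonical(self):
        w = ModelParams.zeros(2, 2)
        stats = ArrayDurationStats(np.ones(2), np.ones(2))
        x = np.array([0, 1, 0])
        results = {tuple(infer(x, w, stats, 2)) for _ in range(3)}
        assert results == {()}  # fewest segments wins every tie


class TestComplexityCounters:
    def test_fast_work_is_linear_in_T(self):
        rng = np.random.default_rng(8)
        M, D, S = 3, 8, 4
        w = ModelParams(rng.normal(size=(M + 1, M)), rng.normal(size=M),
                        rng.normal(size=(M + 1, S)))
        stats = ArrayDurationStats(rng.uniform(2, 5, M), rng.uniform(1, 2, M))
        counts = []
        for T in (100, 150, 200):
            x = rng.integers(0, S, T)
            c = OpCounter()
            gradients_fast(x, [SemiSegment(0, 1, 2)], w, stats, D, counter=c)
            counts.append(c.potential_evals)
        # doubling T should double the work (within 5%)
        assert counts[2] / counts[0] == pytest.approx(2.0, rel=0.05)

    def test_naive_work_is_quadratic_in_M_and_scales_with_D(self):
        rng = np.random.default_rng(9)
        T, S = 30, 4
        out = {}
        for M, D in [(2, 4), (4, 4), (2, 8)]:
            w = ModelParams(rng.normal(size=(M + 1, M)), rng.normal(size=M),
                            rng.normal(size=(M + 1, S)))
            stats = ArrayDurationStats(rng.uniform(2, 4, M), rng.uniform(1, 2, M))
            x = rng.integers(0, S, T)
            c = OpCounter()
            gradients_naive(x, [SemiSegment(0, 1, 2)], w, stats, D,
                            params=[("d", 0)], counter=c)
            out[(M, D)] = c.potential_evals
        assert out[(4, 4)] / out[(2, 4)] == pytest.approx(4.0, rel=0.1)
        assert out[(2, 8)] / out[(2, 4)] == pytest.approx(2.0, rel=0.1)
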