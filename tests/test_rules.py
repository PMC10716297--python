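import numpy as np
import pytest

import hopmem as hm
from hopmem.core import embedding_margins, sync_step


def _all_stored(W, ps):
    return hm.count_stored(W, ps) == ps.P


@pytest.fixture(scope="module")
def irpush_t0(charset):
    return hm.irpush_train(charset, T=0, PF=1.0)


class TestHebbian:
    def test_single_pattern_outer_product(self):
        ps = hm.PatternSet(np.array([[1, -1, 1]]), ("p",))
        W = hm.hebbian_train(ps).W
        assert W[0, 1] == -1 and W[0, 2] == 1 and W[1, 2] == -1
        assert (np.diag(W) == 0).all()

    def test_matches_outer_product_summation(self, rng):
        ps = hm.random_patterns(2, 6, rng)
        W = hm.hebbian_train(ps).W
        expected = sum(np.outer(xi, xi) for xi in ps.patterns.astype(float))
        np.fill_diagonal(expected, 0.0)
        assert (W == expected).all()


class TestStorkey:
    def test_single_pattern_reduces_to_scaled_hebbian(self):
        ps = hm.PatternSet(np.array([[1, -1, 1, 1]]), ("p",))
        W = hm.storkey_train(ps).W
        expected = np.outer(ps.patterns[0], ps.patterns[0]) / 3.0
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(W, expected)

    def test_one_update_matches_elementwise_definition(self, rng):
        # recompute the second pattern's increment from the partial local
        # fields alone (locality of the rule)
        ps = hm.random_patterns(2, 8, rng)
        N = ps.N
        W1 = hm.storkey_train(ps.subset(1)).W
        W2 = hm.storkey_train(ps).W
        xi = ps.patterns[1].astype(float)
        dW = np.zeros((N, N))
        for i in range(N):
            for j in range(N):
                if i == j:
                    continue
                h_ij = sum(W1[i, l] * xi[l] for l in range(N) if l not in (i, j))
                h_ji = sum(W1[j, l] * xi[l] for l in range(N) if l not in (i, j))
                dW[i, j] = (xi[i] * xi[j] - xi[i] * h_ji - h_ij * xi[j]) / (N - 1)
        assert np.allclose(W2, W1 + dW)

    def test_few_shot_presentations_embed_the_full_charset(self, charset):
        W = hm.storkey_train(charset, repetitions=3)
        assert _all_stored(W, charset)
        assert (embedding_margins(W, charset) > 0).all()


class TestProjection:
    def test_single_pattern_is_rank_one_projector(self):
        ps = hm.PatternSet(np.array([[1, -1, 1, -1]]), ("p",))
        W = hm.projection_train(ps).W
        expected = np.outer(ps.patterns[0], ps.patterns[0]) / 4.0
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(W, expected)

    def test_matches_pseudoinverse_oracle(self, rng):
        ps = hm.random_patterns(3, 10, rng)
        X = ps.patterns.astype(float)
        oracle = X.T @ np.linalg.inv(X @ X.T) @ X
        # projector property before diagonal removal
        assert np.allclose(oracle @ X.T, X.T)
        np.fill_diagonal(oracle, 0.0)
        assert np.allclose(hm.projection_train(ps).W, (oracle + oracle.T) / 2)

    def test_duplicate_patterns_rejected(self):
        pats = np.array([[1, -1, 1, 1], [1, -1, 1, 1]])
        with pytest.raises(ValueError, match="depend"):
            hm.projection_train(hm.PatternSet(pats, ("a", "b")))

    def test_charset_fully_embedded(self, charset):
        assert _all_stored(hm.projection_train(charset), charset)


class TestIterativeHebbian:
    def test_verification_pass_makes_no_updates(self, rng):
        # one pass solves a single random pattern; the second pass finds
        # all margins above threshold and performs zero updates
        ps = hm.random_patterns(1, 8, rng)
        res = hm.ih_train(ps, T=0.0)
        assert res.converged
        assert res.epochs_used == 2
        assert res.updates_performed == ps.N

    def test_hand_traced_single_pattern_pass(self):
        # N=4, P=1, T=0 from W=0: every neuron fails once, each update is
        # the +-1/3 Hebbian row, margins land at exactly 1
        ps = hm.PatternSet(np.array([[1, 1, -1, 1]]), ("p",))
        res = hm.ih_train(ps, T=0.0)
        xi = ps.patterns[0].astype(float)
        expected = np.outer(xi, xi) / 3.0
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(res.weights.W, expected)
        assert res.converged and res.updates_performed == 4
        assert np.allclose(embedding_margins(res.weights, ps), 1.0)

    def test_charset_stored_at_high_threshold(self, charset):
        res = hm.ih_train(charset, T=150.0)
        assert res.converged
        assert _all_stored(res.weights, charset)
        assert res.min_margin > 150.0

    def test_agrees_with_bruteforce_perceptron(self, rng):
        # per-row perceptron on inputs xi_j^k xi_i^k is the classical
        # solver of the same embedding conditions
        for _ in range(10):
            ps = hm.random_patterns(2, 8, rng)
            res = hm.ih_train(ps, T=0.0, max_epochs=500)
            X = ps.patterns.astype(int)
            perceptron_ok = True
            for i in range(ps.N):
                w = np.zeros(ps.N)
                solved = False
                for _epoch in range(500):
                    changed = False
                    for k in range(ps.P):
                        z = X[k] * X[k, i]
                        z = z.copy()
                        z[i] = 0
                        if w @ z <= 0:
                            w += z
                            changed = True
                    if not changed:
                        solved = True
                        break
                perceptron_ok &= solved
            assert res.converged == perceptron_ok
            if res.converged:
                assert (embedding_margins(res.weights, ps) > 0).all()


class TestRuleTwo:
    def test_single_update_drives_margin_to_threshold(self):
        ps = hm.PatternSet(np.array([[1, -1, 1, 1, -1]]), ("p",))
        res = hm.rule2_train(ps, T=3.0)
        m = embedding_margins(res.weights, ps)
        assert res.converged
        assert np.allclose(m, 3.0, atol=1e-6)

    def test_charset_stored_at_classic_threshold(self, charset):
        res = hm.rule2_train(charset, T=95.0)
        assert res.converged
        assert _all_stored(res.weights, charset)
        assert res.min_margin > 95.0 - 1e-6


class TestGKM:
    def test_zero_rows_fail_initially(self, rng):
        ps = hm.random_patterns(1, 6, rng)
        res = hm.gkm_train(ps, T=0.5)
        # every neuron must have been updated at least once
        assert res.updates_performed >= ps.N

    def test_normalized_margins_exceed_threshold_at_convergence(self, charset):
        res = hm.gkm_train(charset, T=1.5)
        assert res.converged
        W = res.weights.W
        norms = np.linalg.norm(W, axis=1)
        m = embedding_margins(W, charset) / norms[None, :]
        assert (m > 1.5).all()
        assert _all_stored(res.weights, charset)


class TestDEB:
    def test_barrier_loss_decreases_initially(self, charset):
        X = charset.patterns.astype(float)
        beta, lr = 0.1, 0.1
        W = np.zeros((96, 96))
        losses = []
        for _ in range(10):
            M = (X @ W.T) * X
            E = np.exp(-beta * M)
            losses.append(E.sum())
            G = -beta * (E * X).T @ X
            G = (G + G.T) / 2
            np.fill_diagonal(G, 0.0)
            W -= lr * G
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_invalid_hyperparameters_rejected(self, charset):
        with pytest.raises(ValueError):
            hm.deb_train(charset, learning_rate=0.0)

    def test_divergence_reported(self, charset):
        with pytest.raises(RuntimeError, match="diverged"):
            hm.deb_train(charset, learning_rate=500.0, beta=1.0, max_iters=50)

    def test_weights_symmetric_zero_diagonal_and_charset_stored(self, charset):
        res = hm.deb_train(charset, T=50.0)
        W = res.weights.W
        assert (W == W.T).all()
        assert (np.diag(W) == 0).all()
        assert (embedding_margins(W, charset) > 0).all()
        assert _all_stored(res.weights, charset)


class TestIRPUSH:
    def test_full_partial_factor_is_seed_independent(self, charset):
        a = hm.irpush_train(charset, T=0, PF=1.0,
                            rng=np.random.default_rng(1))
        b = hm.irpush_train(charset, T=0, PF=1.0,
                            rng=np.random.default_rng(999))
        assert (a.weights.W == b.weights.W).all()
        assert a.epochs_used == b.epochs_used

    def test_seeded_determinism_at_partial_factor(self, charset):
        a = hm.irpush_train(charset, T=20, PF=0.25,
                            rng=np.random.default_rng(5))
        b = hm.irpush_train(charset, T=20, PF=0.25,
                            rng=np.random.default_rng(5))
        assert (a.weights.W == b.weights.W).all()
        assert a.updates_performed == b.updates_performed

    def test_symmetry_holds_after_every_update(self, rng):
        ps = hm.random_patterns(3, 16, rng)
        res = hm.irpush_train(ps, T=5.0, PF=0.3, rng=rng,
                              _check_symmetry=True)
        assert (res.weights.W == res.weights.W.T).all()

    def test_converged_charset_patterns_and_inverses_fixed(self, irpush_t0,
                                                           charset):
        assert irpush_t0.converged
        for xi in charset.patterns:
            assert (sync_step(irpush_t0.weights, xi) == xi).all()
            assert (sync_step(irpush_t0.weights, -xi) == -xi).all()

    def test_epochs_grow_as_partial_factor_shrinks(self, charset):
        epochs = []
        for pf in (1.0, 0.5, 0.25):
            res = hm.irpush_train(charset, T=95.0, PF=pf,
                                  rng=np.random.default_rng(11),
                                  max_epochs=20000)
            assert res.converged
            assert _all_stored(res.weights, charset)
            epochs.append(res.epochs_used)
        assert epochs[0] < epochs[1] < epochs[2]

    def test_convergence_flag_matches_margin_criterion(self, charset, rng):
        # converged <=> every embedding margin strictly above T
        good = hm.irpush_train(charset, T=10.0, PF=1.0)
        assert good.converged
        assert (embedding_margins(good.weights, charset) > 10.0).all()
        # far above capacity: P=N random patterns cannot all be embedded
        hard = hm.random_patterns(12, 12, rng)
        bad = hm.irpush_train(hard, T=0.0, PF=1.0, max_epochs=50)
        assert not bad.converged
        assert not (embedding_margins(bad.weights, hard) > 0.0).all()


class TestDispatch:
    @pytest.mark.parametrize("rule", hm.rules.RULES)
    def test_train_returns_result_for_every_rule(self, rule, rng):
        ps = hm.random_patterns(2, 12, rng)
        cfg = hm.TrainingConfig(rule=rule, T=0.0, max_epochs=200)
        res = hm.train(ps, cfg)
        assert isinstance(res, hm.TrainingResult)
        assert res.weights.N == 12

    def test_unknown_rule_rejected(self, rng):
        ps = hm.random_patterns(1, 4, rng)
        with pytest.raises(ValueError, match="unknown rule"):
            hm.train(ps, hm.TrainingConfig(rule="foo"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            hm.TrainingConfig(PF=0.0)
        with pytest.raises(ValueError):
            hm.TrainingConfig(T=-1.0)
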