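"""Co-clustering core: densities, MI coupling, training-stage behavior."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from pathstrat.srvcc import (AssignmentMatrices, CrossTab, DegenerateWeightsError,
                             GMMParams, SideModel, TrainConfig, cross_tab,
                             elbo_loss, gmm_log_density, hard_assign,
                             mi_coupling_loss, mutual_information,
                             reduced_cross_tab, responsibilities, train_srvcc)


class TestGMMDensity:
    def test_standard_normal_at_mode(self):
        prior = GMMParams(log_weights=[0.0], means=[[0.0]], log_vars=[[0.0]])
        assert gmm_log_density(np.array([0.0]), prior) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-9)

    def test_duplicate_components_collapse(self):
        one = GMMParams(log_weights=[0.0], means=[[0.3, -0.2]], log_vars=[[0.1, 0.2]])
        two = GMMParams(log_weights=[np.log(0.5)] * 2,
                        means=[[0.3, -0.2]] * 2, log_vars=[[0.1, 0.2]] * 2)
        z = np.array([0.5, 0.1])
        assert gmm_log_density(z, one) == pytest.approx(gmm_log_density(z, two))

    def test_two_component_hand_value(self):
        # z=0 between means -1, +1: p = 0.5 phi(1) + 0.5 phi(-1) = phi(1)
        prior = GMMParams(log_weights=[np.log(0.5)] * 2,
                          means=[[-1.0], [1.0]], log_vars=[[0.0], [0.0]])
        assert gmm_log_density(np.array([0.0]), prior) == pytest.approx(
            np.log(stats.norm.pdf(1.0)), abs=1e-9)

    def test_nonfinite_rejected(self):
        prior = GMMParams(log_weights=[0.0], means=[[0.0]], log_vars=[[0.0]])
        with pytest.raises(ValueError):
            gmm_log_density(np.array([np.inf]), prior)


class TestResponsibilities:
    def test_single_component(self):
        prior = GMMParams(log_weights=[0.0], means=[[0.0]], log_vars=[[0.0]])
        assert responsibilities(np.array([1.7]), prior) == pytest.approx([1.0])

    def test_midpoint_symmetry(self):
        prior = GMMParams(log_weights=[np.log(0.5)] * 2,
                          means=[[-1.0], [1.0]], log_vars=[[0.0], [0.0]])
        assert responsibilities(np.array([0.0]), prior) == pytest.approx([0.5, 0.5])

    def test_density_ratio_hand_value(self):
        # z=1: gamma_2 = 1 / (1 + e^{-2})
        prior = GMMParams(log_weights=[np.log(0.5)] * 2,
                          means=[[-1.0], [1.0]], log_vars=[[0.0], [0.0]])
        gamma = responsibilities(np.array([1.0]), prior)
        assert gamma[1] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-9)

    def test_far_tail_no_nan(self):
        prior = GMMParams(log_weights=[np.log(0.5)] * 2,
                          means=[[-1.0], [1.0]], log_vars=[[-4.0], [-4.0]])
        gamma = responsibilities(np.array([1e4]), prior)
        assert np.isfinite(gamma).all() and gamma.sum() == pytest.approx(1.0)


class TestElbo:
    def _identity_side(self, d=3):
        """A decoder that reproduces the encoder input exactly is not needed;
        evaluate on a batch the model reconstructs perfectly by training."""
        side = SideModel(input_dim=d, latent_dim=2, hidden=(8, 8), seed=0)
        return side

    def test_beta_zero_equals_recon(self):
        side = self._identity_side()
        x = np.random.default_rng(0).normal(size=(5, 3))
        recon, kl, total = elbo_loss(x, side, beta=0.0)
        assert kl == 0.0 and total == recon

    def test_perfect_reconstruction_zero_total(self):
        """A decoder that reproduces the batch exactly gives total = 0 at beta=0."""
        side = self._identity_side()
        x0 = np.array([0.4, -1.1, 0.8])
        side.params["dW3"].data[:] = 0.0
        side.params["db3"].data[:] = x0
        recon, kl, total = elbo_loss(x0[None, :], side, beta=0.0)
        assert recon == pytest.approx(0.0, abs=1e-12)
        assert total == 0.0

    def test_recon_is_sum_over_features_mean_over_batch(self):
        side = self._identity_side()
        x = np.random.default_rng(1).normal(size=(4, 3))
        eps = np.zeros((4, side.latent_dim))
        recon, _, _ = elbo_loss(x, side, beta=0.0, eps=eps)
        from pathstrat.autodiff import Tensor
        mu, _ = side.encode_t(Tensor(x))
        xhat = side.decode_t(mu).data
        assert recon == pytest.approx(((x - xhat) ** 2).sum(axis=1).mean())

    def test_kl_single_sample_matches_hand_computation(self):
        side = SideModel(input_dim=2, latent_dim=1, hidden=(4, 4), seed=5)
        side.prior_params = None
        # install a standard-normal single-component prior
        from pathstrat.autodiff import Tensor
        side.prior_params = {"log_weights": Tensor(np.zeros(1), True),
                             "means": Tensor(np.zeros((1, 1)), True),
                             "log_vars": Tensor(np.zeros((1, 1)), True)}
        x = np.array([[0.3, -0.7]])
        eps = np.array([[0.4]])
        out = side.encode(x)
        mu, lv = out.mu[0, 0], out.log_var[0, 0]
        z = mu + 0.4 * np.exp(0.5 * lv)
        log_q = -0.5 * (np.log(2 * np.pi) + lv + 0.4**2)
        log_p = stats.norm.logpdf(z)
        _, kl, _ = elbo_loss(x, side, beta=1.0, eps=eps)
        assert kl == pytest.approx(log_q - log_p, abs=1e-9)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            elbo_loss(np.zeros((2, 3)), self._identity_side(), beta=1.5)


class TestCrossTabMI:
    def test_one_hot_diagonal(self):
        eye = np.eye(2)
        t = cross_tab(eye, eye, np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(t.table, [[0.5, 0.0], [0.0, 0.5]])

    def test_uniform_inputs_uniform_table(self):
        gr = np.full((6, 2), 0.5)
        gc = np.full((4, 3), 1 / 3)
        t = cross_tab(gr, gc, np.ones((6, 4)))
        assert np.allclose(t.table, 1 / 6)

    def test_grand_sum_one(self):
        rng = np.random.default_rng(2)
        gr = rng.dirichlet(np.ones(3), size=10)
        gc = rng.dirichlet(np.ones(4), size=7)
        t = cross_tab(gr, gc, np.abs(rng.normal(size=(10, 7))))
        assert t.table.sum() == pytest.approx(1.0)

    def test_zero_weights_rejected(self):
        with pytest.raises(DegenerateWeightsError):
            cross_tab(np.eye(2), np.eye(2), np.zeros((2, 2)))

    def test_mi_perfect_association(self):
        assert mutual_information(np.array([[0.5, 0.0], [0.0, 0.5]])) == \
            pytest.approx(np.log(2))

    def test_mi_independence_zero(self):
        r = np.array([0.3, 0.7])
        c = np.array([0.2, 0.5, 0.3])
        assert mutual_information(np.outer(r, c)) == pytest.approx(0.0, abs=1e-12)

    def test_mi_hand_value(self):
        assert mutual_information(np.array([[0.4, 0.1], [0.1, 0.4]])) == \
            pytest.approx(0.192745, abs=1e-6)

    def test_mi_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.dirichlet(np.ones(12)).reshape(3, 4)
            mi = mutual_information(t)
            assert -1e-12 <= mi <= min(np.log(3), np.log(4)) + 1e-12


class TestMICoupling:
    def test_one_hot_assignments_zero_loss(self):
        rng = np.random.default_rng(4)
        gr = np.eye(3)[rng.integers(0, 3, 12)]
        gc = np.eye(2)[rng.integers(0, 2, 9)]
        w = np.abs(rng.normal(size=(12, 9)))
        assert mi_coupling_loss(gr, gc, w, lambda_mi=1.0) == pytest.approx(0.0)

    def test_lambda_zero(self):
        rng = np.random.default_rng(5)
        gr = rng.dirichlet(np.ones(3), 8)
        gc = rng.dirichlet(np.ones(2), 6)
        assert mi_coupling_loss(gr, gc, np.ones((8, 6)), 0.0) == 0.0

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(6)
        gr = rng.dirichlet(np.ones(2), 10)
        gc = rng.dirichlet(np.ones(2), 7)
        w = np.abs(rng.normal(size=(10, 7)))
        mi_org = mutual_information(cross_tab(gr, gc, w))
        mi_red = mutual_information(reduced_cross_tab(gr, gc, w))
        expected = np.log(1 + (1 - np.clip(mi_red / mi_org, 0, 2 - 1e-6)))
        assert mi_coupling_loss(gr, gc, w, 1.0) == pytest.approx(expected)

    def test_degenerate_mi_warns_and_returns_zero(self):
        gr = np.full((6, 2), 0.5)
        gc = np.full((4, 2), 0.5)
        with pytest.warns(UserWarning):
            assert mi_coupling_loss(gr, gc, np.ones((6, 4)), 1.0) == 0.0


class TestHardAssign:
    def test_one_hot(self):
        assert hard_assign(np.eye(3)[[2, 0, 1]]).tolist() == [2, 0, 1]

    def test_tie_breaks_low_index(self):
        assert hard_assign(np.array([[0.5, 0.5]]))[0] == 0

    def test_interior_max(self):
        assert hard_assign(np.array([[0.2, 0.5, 0.3]]))[0] == 1


class TestTraining:
    def test_kr_one_single_cluster(self, fast_train):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(40, 12))
        cfg = TrainConfig(**{**fast_train.__dict__, "epochs": 10,
                             "pretrain_epochs": 5})
        _, asg, _ = train_srvcc(x, 1, 2, cfg)
        assert np.allclose(asg.gamma_rows, 1.0)
        assert set(asg.hard_rows) == {0}

    def test_two_cluster_recovery_across_seeds(self):
        """Two planted row clusters at 5-sigma, n=200: exact across 5 seeds."""
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 200)
        x = np.where(labels[:, None] == 0, 2.5, -2.5) * np.ones((200, 20)) \
            + rng.normal(0, 0.5, (200, 20))
        for seed in range(5):
            cfg = TrainConfig(epochs=25, pretrain_epochs=10, beta_warmup_epochs=10,
                              latent_dim=4, hidden=(32, 16), learning_rate=3e-3,
                              seed=seed)
            _, asg, _ = train_srvcc(x, 2, 2, cfg)
            assert adjusted_rand_score(labels, asg.hard_rows) == 1.0

    def test_checkerboard_recovery_both_sides(self, checkerboard, fast_train):
        x, row_labels, col_labels = checkerboard
        _, asg, _ = train_srvcc(x, 4, 3, fast_train)
        assert adjusted_rand_score(row_labels, asg.hard_rows) == 1.0
        assert adjusted_rand_score(col_labels, asg.hard_cols) == 1.0

    def test_pretrain_loss_decreases(self, checkerboard, fast_train):
        x, _, _ = checkerboard
        _, _, log = train_srvcc(x, 3, 3, fast_train)
        pre = log[log.phase == "pretrain"]
        assert pre.iloc[-1]["l_row"] <= pre.iloc[0]["l_row"] * 1.05

    def test_seed_determinism(self, checkerboard, fast_train):
        x, _, _ = checkerboard
        _, a, _ = train_srvcc(x, 4, 3, fast_train)
        _, b, _ = train_srvcc(x, 4, 3, fast_train)
        assert np.array_equal(a.hard_rows, b.hard_rows)
        assert np.array_equal(a.gamma_rows, b.gamma_rows)

    def test_loss_decomposition_every_epoch(self, checkerboard, fast_train):
        x, _, _ = checkerboard
        _, _, log = train_srvcc(x, 3, 3, fast_train)
        total = log["l_row"] + log["l_col"] + log["l_mi"]
        assert np.allclose(log["total"], total, atol=1e-6)

    def test_gamma_rows_stochastic(self, checkerboard, fast_train):
        x, _, _ = checkerboard
        _, asg, _ = train_srvcc(x, 4, 3, fast_train)
        assert np.allclose(asg.gamma_rows.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(asg.gamma_cols.sum(axis=1), 1.0, atol=1e-6)

    def test_k_capped_with_warning(self, fast_train):
        x = np.random.default_rng(9).normal(size=(6, 5))
        cfg = TrainConfig(**{**fast_train.__dict__, "epochs": 3,
                             "pretrain_epochs": 2, "val_frac": 0.0})
        with pytest.warns(UserWarning):
            _, asg, _ = train_srvcc(x, 10, 3, cfg)
        assert asg.gamma_rows.shape[1] == 6

    def test_invalid_assignment_matrices_rejected(self):
        with pytest.raises(ValueError):
            AssignmentMatrices(gamma_rows=np.array([[0.7, 0.7]]),
                               gamma_cols=np.eye(2))


def test_crosstab_container_validation():
    with pytest.raises(ValueError):
        CrossTab(np.array([[0.5, 0.2], [0.1, 0.1]]))  # sums to 0.9
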