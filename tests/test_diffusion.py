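"""DDPM process identities: schedule, forward/reverse algebra, loss, EMA."""

import numpy as np
import pytest

from lgenoise import diffusion as dd
from lgenoise import phantom, preprocess
from lgenoise.diffusion import ClassWeights


@pytest.fixture(scope="module")
def sch50():
    return dd.cosine_beta_schedule(50)


@pytest.fixture(scope="module")
def toy_scene():
    spec = phantom.PhantomSpec(
        height=32, width=32, center=(16, 16), r_inner=5, r_outer=10,
        scar_angle_span=np.pi / 2,
    )
    mask = phantom.make_annulus_mask(spec)
    x0 = preprocess.to_diffusion_scale(phantom.render_clean_image(mask, spec.levels))
    return mask, x0, preprocess.one_hot(mask)


class TestSchedule:
    def test_alpha_bar_strictly_decreasing_in_unit_interval(self, sch50):
        ab = sch50.alpha_bar
        assert (np.diff(ab) < 0).all()
        assert ab[0] <= 1 and ab[-1] > 0

    def test_alpha_bar_product_identity(self):
        sch = dd.cosine_beta_schedule(100)
        rebuilt = np.cumprod(1.0 - sch.beta)
        np.testing.assert_allclose(rebuilt, sch.alpha_bar, rtol=1e-12)

    def test_t250_endpoints(self):
        sch = dd.cosine_beta_schedule(250)
        assert sch.alpha_bar[0] > 0.99
        assert sch.alpha_bar[-1] < 0.01

    def test_too_small_T_rejected(self):
        with pytest.raises(ValueError):
            dd.cosine_beta_schedule(1)


class TestForwardProcess:
    def test_eps_zero_scales_x0(self, sch50):
        x0 = np.ones((4, 4))
        t = 7
        xt = dd.forward_sample(x0, t, np.zeros_like(x0), sch50)
        np.testing.assert_allclose(xt, np.sqrt(sch50.alpha_bar[t]) * x0)

    def test_marginal_moments_monte_carlo(self, sch50):
        rng = np.random.default_rng(0)
        x0 = rng.standard_normal((16, 16))
        t = 20
        draws = np.stack(
            [dd.forward_sample(x0, t, rng.standard_normal(x0.shape), sch50) for _ in range(300)]
        )
        ab = sch50.alpha_bar[t]
        tol = 3.0 / np.sqrt(300)
        assert np.abs(draws.mean(0) - np.sqrt(ab) * x0).mean() < tol
        assert abs(draws.std(0).mean() - np.sqrt(1 - ab)) < tol

    def test_iterated_steps_match_closed_form_marginal(self, sch50):
        # distributional equivalence of the stepwise chain and the marginal
        rng = np.random.default_rng(1)
        x0 = rng.standard_normal((12, 12))
        t = 15
        draws = np.stack([dd.iterate_forward(x0, t, sch50, 100 + i) for i in range(300)])
        ab = sch50.alpha_bar[t]
        tol = 3.0 / np.sqrt(300)
        assert np.abs(draws.mean(0) - np.sqrt(ab) * x0).mean() < tol
        assert abs(draws.var(0).mean() - (1 - ab)) < 2 * tol

    def test_out_of_range_t_rejected(self, sch50):
        with pytest.raises(IndexError):
            dd.forward_sample(np.zeros((2, 2)), 50, np.zeros((2, 2)), sch50)


class TestInversion:
    def test_round_trip_all_timesteps(self, sch50):
        rng = np.random.default_rng(2)
        x0 = rng.standard_normal((8, 8))
        for t in range(sch50.T):
            eps = rng.standard_normal(x0.shape)
            xt = dd.forward_sample(x0, t, eps, sch50)
            back = dd.invert_forward(xt, t, eps, sch50)
            assert np.abs(back - x0).max() <= 1e-10

    def test_eps_zero_reduces_to_rescaling(self, sch50):
        x0 = np.full((3, 3), 0.5)
        t = 5
        xt = dd.forward_sample(x0, t, np.zeros_like(x0), sch50)
        np.testing.assert_allclose(
            dd.invert_forward(xt, t, np.zeros_like(x0), sch50), x0, atol=1e-14
        )


class TestReverseProcess:
    def test_reverse_mean_eps_zero(self, sch50):
        xt = np.ones((2, 2))
        t = 3
        mu = dd.reverse_mean(xt, t, np.zeros_like(xt), sch50)
        np.testing.assert_allclose(mu, xt / np.sqrt(sch50.alpha[t]))

    def test_reverse_mean_scalar_oracle(self):
        # hand-coded scalar formula with alpha=0.99, alpha_bar=0.9
        beta = np.array([0.01, 1 - 0.9 / 0.99])
        sch = dd.NoiseSchedule(beta)
        np.testing.assert_allclose(sch.alpha[0], 0.99)
        np.testing.assert_allclose(sch.alpha_bar[1], 0.9, rtol=1e-12)
        xt = np.array([[0.4, -0.2], [1.0, 0.0]])
        eh = np.array([[0.1, 0.3], [-0.5, 0.2]])
        a, ab = sch.alpha[1], sch.alpha_bar[1]
        expected = (xt - (1 - a) / np.sqrt(1 - ab) * eh) / np.sqrt(a)
        np.testing.assert_allclose(dd.reverse_mean(xt, 1, eh, sch), expected)

    def test_step_t0_ignores_z(self, sch50):
        xt = np.ones((2, 2))
        eh = 0.1 * np.ones_like(xt)
        out1 = dd.reverse_step(xt, 0, eh, np.ones_like(xt), sch50)
        out2 = dd.reverse_step(xt, 0, eh, -np.ones_like(xt), sch50)
        np.testing.assert_array_equal(out1, out2)
        np.testing.assert_allclose(out1, dd.reverse_mean(xt, 0, eh, sch50))

    def test_step_variance_matches_beta(self, sch50):
        rng = np.random.default_rng(3)
        xt = np.zeros((8, 8))
        eh = np.zeros_like(xt)
        t = 10
        mu = dd.reverse_mean(xt, t, eh, sch50)
        draws = np.stack(
            [dd.reverse_step(xt, t, eh, rng.standard_normal(xt.shape), sch50) - mu for _ in range(200)]
        )
        assert abs(draws.var() / sch50.beta[t] - 1) < 0.2


class TestConditioning:
    def test_concat_layout(self, toy_scene):
        _, x0, oh = toy_scene
        xt = dd.condition(x0, oh)
        assert xt.shape == (4, *x0.shape)
        np.testing.assert_array_equal(xt[0], x0)
        np.testing.assert_array_equal(xt[1:].sum(axis=0), np.ones(x0.shape))

    def test_shape_mismatch_rejected(self, toy_scene):
        _, x0, oh = toy_scene
        with pytest.raises(ValueError):
            dd.condition(x0[:16], oh)


class TestSampling:
    def test_oracle_guided_sampling_converges_to_target(self, sch50, toy_scene):
        _, x0, oh = toy_scene
        predictor = dd.OraclePredictor(x0, sch50)
        out = dd.sample(oh, predictor, sch50, seed=0)
        assert np.abs(out - x0).max() < 1e-6

    def test_same_seed_identical(self, sch50, toy_scene):
        _, x0, oh = toy_scene
        predictor = dd.OraclePredictor(x0, sch50)
        a = dd.sample(oh, predictor, sch50, seed=9)
        b = dd.sample(oh, predictor, sch50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_bad_predictor_shape_raises(self, sch50, toy_scene):
        _, _, oh = toy_scene
        with pytest.raises(ValueError):
            dd.sample(oh, lambda x, t: np.zeros((3, 3)), sch50, seed=0)


class TestWeightedObjective:
    def test_weight_map_values(self):
        # 2x2 mask [bg, myo; scar, bg] with the published class weights
        mask = np.array([[0, 1], [2, 0]])
        oh = (np.arange(3)[:, None, None] == mask).astype(float)
        W = dd.weight_map(oh, ClassWeights(0.2, 1.5, 3.0))
        np.testing.assert_allclose(W, [[0.2, 1.5], [3.0, 0.2]])

    def test_uniform_weights_all_ones(self, toy_scene):
        _, _, oh = toy_scene
        W = dd.weight_map(oh, ClassWeights(1, 1, 1))
        np.testing.assert_allclose(W, np.ones(oh.shape[1:]))

    def test_perfect_prediction_zero_loss(self):
        eps = np.random.default_rng(0).standard_normal((4, 4))
        assert dd.weighted_loss(eps, eps, np.ones_like(eps)) == 0.0

    def test_unit_weights_reduce_to_mean(self):
        rng = np.random.default_rng(1)
        eps = rng.standard_normal((5, 5))
        eh = rng.standard_normal((5, 5))
        got = dd.weighted_loss(eps, eh, np.ones_like(eps), ell="l1", epsilon_stab=0.0)
        np.testing.assert_allclose(got, np.abs(eps - eh).mean())

    def test_two_pixel_hand_case(self):
        eps = np.array([[0.0, 0.0]])
        eh = np.array([[0.1, 0.3]])
        W = np.array([[1.0, 3.0]])
        got = dd.weighted_loss(eps, eh, W, ell="l1", epsilon_stab=0.0)
        assert got == pytest.approx((0.1 + 0.9) / 4.0)

    def test_zero_weights_guarded(self):
        with pytest.raises(ZeroDivisionError):
            dd.weighted_loss(np.zeros((2, 2)), np.ones((2, 2)), np.zeros((2, 2)), epsilon_stab=0.0)


class TestEMA:
    def test_decay_extremes(self):
        cur = {"w": np.array([1.0, 2.0])}
        sh = {"w": np.array([0.0, 0.0])}
        np.testing.assert_array_equal(dd.ema_update(cur, sh, decay=1.0)["w"], sh["w"])
        np.testing.assert_array_equal(dd.ema_update(cur, sh, decay=0.0)["w"], cur["w"])

    def test_geometric_closed_form(self):
        c = {"w": np.array([2.0])}
        shadow = {"w": np.array([10.0])}
        decay = 0.995
        for _ in range(40):
            shadow = dd.ema_update(c, shadow, decay)
        expected = 2.0 + (10.0 - 2.0) * decay**40
        np.testing.assert_allclose(shadow["w"], [expected], rtol=1e-12)

    def test_misaligned_collections_rejected(self):
        with pytest.raises(ValueError):
            dd.ema_update({"a": np.zeros(2)}, {"b": np.zeros(2)})


class TestToyTraining:
    def test_l1_objective_strictly_decreases(self, sch50, toy_scene):
        _, x0, oh = toy_scene
        rng = np.random.default_rng(4)
        x0b = np.stack([x0 + 0.01 * rng.standard_normal(x0.shape) for _ in range(4)])
        ohb = np.stack([oh] * 4)
        toy = dd.ToyConvPredictor(sch50.T, seed=0)
        history = dd.train_toy_predictor(toy, x0b, ohb, sch50, n_iters=300, seed=1)
        assert np.mean(history[-50:]) < np.mean(history[:50])
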