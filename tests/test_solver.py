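import numpy as np
import pytest

from w1ot.evaluation import mmd_rbf
from w1ot.solver import (
    DiscriminatorNetwork,
    EmpiricalDistribution,
    GanTrainingConfig,
    PotentialTrainingConfig,
    StepSizeNetwork,
    TransportMap,
    adversarial_losses,
    dual_loss,
    fit_w1ot,
    train_potential,
    train_step_size,
    transport_apply,
)
from w1ot.synthetic_data import make_gaussian_pair


class _StubPotential:
    """f(x) = w . x, with a fixed gradient field, for closed-form checks."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def forward(self, X):
        return np.atleast_2d(X) @ self.w

    def gradient(self, X):
        return np.tile(self.w, (np.atleast_2d(X).shape[0], 1))


class _StubStep:
    def __init__(self, value):
        self.value = value

    def __call__(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.value)


class _StubDisc:
    def __init__(self, fn):
        self.fn = fn

    def prob(self, X):
        return np.clip(self.fn(np.atleast_2d(X)), 1e-7, 1 - 1e-7)


class TestEmpiricalDistribution:
    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            EmpiricalDistribution(np.array([[np.inf, 0.0]]))

    def test_rejects_mismatched_labels(self):
        with pytest.raises(ValueError, match="labels"):
            EmpiricalDistribution(np.zeros((3, 2)), labels=np.array([1, 2]))

    def test_shape_properties(self):
        d = EmpiricalDistribution(np.zeros((5, 3)))
        assert (d.n, d.dim) == (5, 3)


class TestDualLoss:
    def test_zero_function(self):
        f = _StubPotential([0.0, 0.0])
        assert dual_loss(f, np.zeros((4, 2)), np.ones((3, 2))) == 0.0

    def test_point_masses_translation(self):
        # f(x) = -x1 on x0=(0,0), y0=(4,0): loss -4, dual estimate 4 = ||x0-y0||
        f = _StubPotential([-1.0, 0.0])
        loss = dual_loss(f, np.array([[0.0, 0.0]]), np.array([[4.0, 0.0]]))
        assert loss == pytest.approx(-4.0)

    def test_identical_batches_cancel(self, rng):
        from w1ot.lipschitz_nets import LipschitzPotential

        f = LipschitzPotential(2, hidden=(8,), group_size=2, seed=0)
        X = rng.normal(size=(10, 2))
        assert dual_loss(f, X, X) == pytest.approx(0.0, abs=1e-12)

    def test_empty_batch_rejected(self):
        f = _StubPotential([1.0, 0.0])
        with pytest.raises(ValueError, match="non-empty"):
            dual_loss(f, np.empty((0, 2)), np.ones((2, 2)))

    def test_dimension_mismatch_rejected(self):
        f = _StubPotential([1.0, 0.0])
        with pytest.raises(ValueError, match="dimensionality"):
            dual_loss(f, np.zeros((2, 2)), np.zeros((2, 3)))


class TestTransportApply:
    def test_zero_step_size_is_identity(self, rng):
        T = TransportMap(_StubPotential([1.0, 0.0]), _StubStep(0.0))
        X = rng.normal(size=(10, 2))
        np.testing.assert_array_equal(transport_apply(T, X), X)

    def test_unit_gradient_substitution(self):
        # f(x) = x1 so grad f = e1; eta = 2; (5,3) -> (3,3)
        T = TransportMap(_StubPotential([1.0, 0.0]), _StubStep(2.0))
        np.testing.assert_allclose(
            transport_apply(T, np.array([[5.0, 3.0]])), [[3.0, 3.0]]
        )

    def test_normalized_direction(self):
        # grad = (0.5, 0) normalizes to e1; eta = 2; (5,3) -> (3,3)
        T = TransportMap(
            _StubPotential([0.5, 0.0]), _StubStep(2.0), normalize_direction=True
        )
        np.testing.assert_allclose(
            transport_apply(T, np.array([[5.0, 3.0]])), [[3.0, 3.0]]
        )

    def test_zero_gradient_row_warns_and_passes_through(self):
        T = TransportMap(
            _StubPotential([0.0, 0.0]), _StubStep(2.0), normalize_direction=True
        )
        X = np.array([[1.0, 2.0]])
        with pytest.warns(UserWarning, match="zero transport direction"):
            out = transport_apply(T, X)
        np.testing.assert_array_equal(out, X)


class TestAdversarialLosses:
    def setup_method(self):
        self.T = TransportMap(_StubPotential([1.0, 0.0]), _StubStep(1.0))
        self.bx = np.zeros((5, 2))
        self.by = np.ones((4, 2))

    def test_uninformative_discriminator(self):
        D = _StubDisc(lambda X: np.full(X.shape[0], 0.5))
        gen, disc = adversarial_losses(D, self.T, self.bx, self.by)
        assert gen == pytest.approx(np.log(2.0))
        assert disc == pytest.approx(2.0 * np.log(2.0))

    def test_perfect_discriminator_limits(self):
        transported = self.T(self.bx)

        def fn(X):
            # 1 on the target batch, 0 on transported points
            is_target = np.all(np.isclose(X, 1.0), axis=1)
            return np.where(is_target, 1.0, 0.0)

        D = _StubDisc(fn)
        gen, disc = adversarial_losses(D, self.T, self.bx, self.by)
        assert gen == pytest.approx(-np.log(1e-7))
        assert disc == pytest.approx(0.0, abs=1e-6)
        assert not np.all(np.isclose(transported, 1.0))

    def test_empty_batch_rejected(self):
        D = _StubDisc(lambda X: np.full(X.shape[0], 0.5))
        with pytest.raises(ValueError, match="non-empty"):
            adversarial_losses(D, self.T, np.empty((0, 2)), self.by)


class TestTrainPotential:
    def test_identical_clouds_give_zero_estimate(self, rng):
        pts = rng.normal(size=(300, 2))
        mu = EmpiricalDistribution(pts)
        nu = EmpiricalDistribution(pts.copy())
        f, trace = train_potential(
            mu, nu, PotentialTrainingConfig(iterations=300), seed=0
        )
        assert abs(trace[-1]) < 0.05

    def test_gaussian_shift_dual_estimate(self, gaussian_potential):
        _, trace = gaussian_potential
        assert -trace[-1] == pytest.approx(4.0, rel=0.05)

    def test_gradient_norm_near_one_at_optimum(self, gaussian_potential, rng):
        f, _ = gaussian_potential
        fresh = rng.normal(size=(1000, 2))
        norms = np.linalg.norm(f.gradient(fresh), axis=1)
        assert 0.9 <= norms.mean() <= 1.1

    def test_nonfinite_abort(self):
        mu = EmpiricalDistribution(np.zeros((4, 2)))
        nu = EmpiricalDistribution(np.ones((4, 2)))
        cfg = PotentialTrainingConfig(iterations=5, lr_max=1e300, lr_min=1e299)
        with pytest.raises((RuntimeError, FloatingPointError, ValueError)):
            with np.errstate(all="raise"):
                train_potential(mu, nu, cfg, seed=0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PotentialTrainingConfig(iterations=0)
        with pytest.raises(ValueError):
            GanTrainingConfig(lr=-1.0)


class TestTrainStepSize:
    def test_step_size_positive_everywhere(self, gaussian_transport, rng):
        eta = gaussian_transport["eta"]
        X = rng.normal(scale=5.0, size=(10_000, 2))
        assert np.all(eta(X) > 0)

    def test_potential_frozen_during_stage_two(self, gaussian_transport):
        f = gaussian_transport["potential"]
        frozen = gaussian_transport["potential_frozen_state"]
        for k, v in f.state_dict().items():
            np.testing.assert_array_equal(v, frozen[k])

    def test_step_size_concentrates_on_translation(self, gaussian_transport):
        # The OT-optimal map is the constant translation by ||s|| = 4.  The
        # saturating GAN matches distributions but does not uniquely force
        # the constant map, so the spread bound here is looser than a pure
        # closed-form argument would suggest.
        pair = gaussian_transport["pair"]
        eta = gaussian_transport["eta"](pair.source.points)
        assert eta.mean() == pytest.approx(4.0, rel=0.1)
        assert eta.std() / eta.mean() < 0.5

    def test_mmd_improves_over_identity(self, gaussian_transport):
        pair = gaussian_transport["pair"]
        fresh = make_gaussian_pair([4.0, 0.0], n=500, seed=77)
        TX = gaussian_transport["transport"](fresh.source.points)
        before = mmd_rbf(fresh.source.points, fresh.target.points)
        after = mmd_rbf(TX, fresh.target.points)
        assert after < before

    def test_determinism_same_seed_same_traces(self):
        pair = make_gaussian_pair([1.0, 0.0], n=100, seed=0)
        f, _ = train_potential(
            pair.source, pair.target, PotentialTrainingConfig(iterations=30), seed=5
        )
        cfg = GanTrainingConfig(iterations=30, batch_size=64)
        _, _, t1 = train_step_size(f, pair.source, pair.target, cfg, seed=9)
        _, _, t2 = train_step_size(f, pair.source, pair.target, cfg, seed=9)
        np.testing.assert_array_equal(t1["gen_loss"], t2["gen_loss"])
        np.testing.assert_array_equal(t1["disc_loss"], t2["disc_loss"])


class TestFitW1ot:
    def test_identical_pair_near_identity_map(self, rng):
        pts = rng.normal(size=(300, 2))
        mu = EmpiricalDistribution(pts)
        nu = EmpiricalDistribution(pts.copy())
        transport, traces = fit_w1ot(
            mu,
            nu,
            PotentialTrainingConfig(iterations=300),
            GanTrainingConfig(iterations=600),
            seed=0,
        )
        TX = transport(pts)
        assert mmd_rbf(TX, pts) < 0.05

    def test_weak_duality_on_trained_pair(self, gaussian_transport):
        pair = gaussian_transport["pair"]
        dual = -gaussian_transport["potential_trace"][-1]
        cost = gaussian_transport["transport"].displacement(pair.source.points).mean()
        assert dual <= cost * 1.05

    def test_translation_recovery(self, gaussian_transport):
        pair = gaussian_transport["pair"]
        disp = gaussian_transport["transport"].displacement(pair.source.points)
        assert disp.mean() == pytest.approx(4.0, rel=0.10)

    def test_dimension_mismatch_rejected(self):
        mu = EmpiricalDistribution(np.zeros((5, 2)))
        nu = EmpiricalDistribution(np.zeros((5, 3)))
        with pytest.raises(ValueError, match="dimensionality"):
            fit_w1ot(mu, nu)

    def test_determinism_full_pipeline(self):
        pair = make_gaussian_pair([1.0, 0.0], n=80, seed=1)
        kw = dict(
            potential_cfg=PotentialTrainingConfig(iterations=25, batch_size=32),
            gan_cfg=GanTrainingConfig(iterations=25, batch_size=32),
            seed=3,
        )
        _, tr1 = fit_w1ot(pair.source, pair.target, **kw)
        _, tr2 = fit_w1ot(pair.source, pair.target, **kw)
        np.testing.assert_array_equal(tr1["potential_loss"], tr2["potential_loss"])
        np.testing.assert_array_equal(tr1["gan"]["gen_loss"], tr2["gan"]["gen_loss"])
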