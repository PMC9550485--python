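import numpy as np
import pytest

from conftest import numeric_grad
from mhnet.autodiff import Tensor
from mhnet.losses import (
    LossConfig,
    ncc,
    ncc_graph,
    similarity_loss,
    smoothness_graph,
    smoothness_loss,
    total_loss,
    total_loss_graph,
)
from mhnet.volumes import DisplacementField, Volume


def ncc_window_oracle(f, w, window, eps):
    """Explicit-sum windowed CC^2 over each voxel's in-bounds cubic window."""
    r = window // 2
    X, Y, Z = f.shape
    vals = np.zeros(f.shape)
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                sf = sw = sff = sww = sfw = 0.0
                n = 0
                for i in range(x - r, x + r + 1):
                    for j in range(y - r, y + r + 1):
                        for k in range(z - r, z + r + 1):
                            if 0 <= i < X and 0 <= j < Y and 0 <= k < Z:
                                a, b = f[i, j, k], w[i, j, k]
                                sf += a
                                sw += b
                                sff += a * a
                                sww += b * b
                                sfw += a * b
                                n += 1
                cross = sfw - sf * sw / n
                vf = sff - sf * sf / n
                vw = sww - sw * sw / n
                vals[x, y, z] = cross**2 / (vf * vw + eps)
    return vals.mean()


class TestNcc:
    def test_self_similarity_is_one(self, rng):
        f = Volume(rng.random((12, 12, 12)))
        assert ncc(f, f) == pytest.approx(1.0, abs=1e-3)

    def test_affine_invariance(self, rng):
        f = Volume(rng.random((12, 12, 12)))
        g = Volume(2.0 * f.data + 3.0)
        assert ncc(f, g) == pytest.approx(1.0, abs=1e-3)

    def test_matches_explicit_window_oracle(self, rng):
        cfg = LossConfig(ncc_window=3)
        f = rng.random((3, 3, 3))
        w = rng.random((3, 3, 3))
        got = ncc(Volume(f), Volume(w), cfg)
        want = ncc_window_oracle(f, w, 3, cfg.eps)
        assert got == pytest.approx(want, abs=1e-8)

    def test_value_in_unit_interval(self, rng):
        cfg = LossConfig(ncc_window=5)
        for _ in range(5):
            a = Volume(rng.random((9, 9, 9)))
            b = Volume(rng.random((9, 9, 9)))
            v = ncc(a, b, cfg)
            assert -1e-6 <= v <= 1.0 + 1e-6

    def test_symmetry(self, rng):
        a = Volume(rng.random((10, 10, 10)))
        b = Volume(rng.random((10, 10, 10)))
        assert abs(ncc(a, b) - ncc(b, a)) <= 1e-6

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            ncc(Volume(rng.random((4, 4, 4))), Volume(rng.random((5, 5, 5))))

    def test_window_must_be_odd(self):
        with pytest.raises(ValueError, match="odd"):
            LossConfig(ncc_window=4)


class TestSimilarityLoss:
    def test_perfect_match_gives_minus_one(self, rng):
        f = Volume(rng.random((12, 12, 12)))
        phi = DisplacementField(np.zeros((3, 12, 12, 12), dtype=np.float32))
        assert similarity_loss(f, f, phi) == pytest.approx(-1.0, abs=1e-3)

    def test_constant_moving_gives_zero_correlation(self, rng):
        f = Volume(rng.random((10, 10, 10)))
        m = Volume(np.full((10, 10, 10), 0.5))
        phi = DisplacementField(np.zeros((3, 10, 10, 10), dtype=np.float32))
        assert similarity_loss(f, m, phi) == pytest.approx(0.0, abs=1e-6)

    def test_improves_toward_true_field(self, phantom_pair):
        fixed, moving, _, _, truth = phantom_pair
        losses = []
        for t in (0.0, 0.5, 1.0):
            phi = DisplacementField((t * truth.u).astype(np.float32))
            losses.append(similarity_loss(moving, fixed, phi))
        assert losses[2] < losses[1] < losses[0]


class TestSmoothness:
    def test_constant_field_is_zero(self):
        u = np.full((3, 6, 6, 6), 2.5, dtype=np.float32)
        assert smoothness_loss(DisplacementField(u)) == pytest.approx(0.0, abs=1e-10)

    def test_unit_ramp_closed_form(self):
        u = np.zeros((3, 6, 6, 6), dtype=np.float32)
        u[0] = np.arange(6, dtype=np.float32)[:, None, None]
        assert smoothness_loss(DisplacementField(u)) == pytest.approx(1.0, abs=1e-6)

    def test_translation_invariance(self, rng):
        u = rng.normal(size=(3, 6, 6, 6)).astype(np.float32)
        base = smoothness_loss(DisplacementField(u))
        shifted = smoothness_loss(DisplacementField(u + 4.0))
        assert shifted == pytest.approx(base, rel=1e-5)

    def test_zero_iff_constant(self, rng):
        u = rng.normal(size=(3, 5, 5, 5)).astype(np.float32)
        assert smoothness_loss(DisplacementField(u)) > 1e-4


class TestTotalLoss:
    def test_perfect_match_defaults(self, rng):
        f = Volume(rng.random((12, 12, 12)))
        phi = DisplacementField(np.zeros((3, 12, 12, 12), dtype=np.float32))
        assert total_loss(f, f, phi) == pytest.approx(-1.0, abs=1e-3)

    def test_lambda_zero_reduces_to_similarity(self, phantom_pair):
        fixed, moving, _, _, truth = phantom_pair
        cfg = LossConfig(lam=0.0)
        assert total_loss(fixed, moving, truth, cfg) == pytest.approx(
            similarity_loss(fixed, moving, truth, cfg), abs=1e-10
        )

    def test_componentwise_recomputation(self, phantom_pair):
        fixed, moving, _, _, truth = phantom_pair
        cfg = LossConfig(alpha=1.0, lam=3.0)
        want = 1.0 * similarity_loss(fixed, moving, truth, cfg) + 3.0 * (
            smoothness_loss(truth)
        )
        assert total_loss(fixed, moving, truth, cfg) == pytest.approx(want, abs=1e-8)


class TestGradients:
    def test_total_loss_gradient_matches_finite_differences(self, rng):
        f = rng.random((6, 6, 6))
        m = rng.random((6, 6, 6))
        u0 = rng.uniform(-0.4, 0.4, (3, 6, 6, 6))
        cfg = LossConfig(ncc_window=3)

        u = Tensor(u0.copy(), requires_grad=True)
        loss = total_loss_graph(Tensor(f), Tensor(m), u, cfg)
        loss.backward()

        def fn(x):
            return total_loss_graph(Tensor(f), Tensor(m), Tensor(x), cfg).item()

        num = numeric_grad(fn, u0.copy(), eps=1e-6)
        denom = np.abs(num).max() + 1e-8
        np.testing.assert_allclose(u.grad / denom, num / denom, atol=1e-3)

    def test_ncc_gradient_in_image(self, rng):
        f = rng.random((5, 5, 5))
        w0 = rng.random((5, 5, 5))
        cfg = LossConfig(ncc_window=3)
        w = Tensor(w0.copy(), requires_grad=True)
        ncc_graph(Tensor(f), w, cfg).backward()

        def fn(x):
            return ncc_graph(Tensor(f), Tensor(x), cfg).item()

        num = numeric_grad(fn, w0.copy(), eps=1e-6)
        denom = np.abs(num).max() + 1e-8
        np.testing.assert_allclose(w.grad / denom, num / denom, atol=1e-3)

    def test_smoothness_gradient(self, rng):
        u0 = rng.normal(size=(3, 4, 4, 4))
        u = Tensor(u0.copy(), requires_grad=True)
        smoothness_graph(u).backward()

        def fn(x):
            return smoothness_graph(Tensor(x)).item()

        num = numeric_grad(fn, u0.copy(), eps=1e-6)
        np.testing.assert_allclose(u.grad, num, atol=1e-5)
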