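"""Ghost layers, backbone shape contracts and HSIC/nHSIC/CKA correctness."""

import numpy as np
import pytest

from foveaseg import hghost as hg
from foveaseg import nn
from foveaseg.autodiff import Tensor


# ---------------------------------------------------------------------------
# ghost layers / backbone
# ---------------------------------------------------------------------------


def test_ghost_output_channel_arithmetic(rng):
    nn.manual_seed(0)
    spec = hg.GhostLayerSpec(in_channels=4, intrinsic_m=8, ratio_s=2)
    y = hg.ghost_layer(rng.normal(size=(1, 4, 6, 6)).astype(np.float32), spec)
    assert y.shape[1] == 16 == spec.out_channels


def test_ghost_ratio_one_equals_primary_convolution(rng):
    nn.manual_seed(0)
    layer = hg.GhostLayer(hg.GhostLayerSpec(in_channels=4, intrinsic_m=8, ratio_s=1))
    x = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
    np.testing.assert_array_equal(layer(x).data, layer.primary(x).data)


def test_ghost_identity_branch_preserves_intrinsics(rng):
    nn.manual_seed(0)
    layer = hg.GhostLayer(hg.GhostLayerSpec(in_channels=3, intrinsic_m=4, ratio_s=2))
    x = Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32))
    out = layer(x)
    np.testing.assert_array_equal(out.data[:, :4], layer.last_intrinsic.data)


def test_primary_convolution_against_hand_correlation():
    """3x3 all-ones kernel, zero bias: the intrinsic map is the local window sum."""
    spec = hg.GhostLayerSpec(in_channels=1, intrinsic_m=1, ratio_s=1, primary_kernel=3)
    layer = hg.GhostLayer(spec)
    layer.primary.weight.data = np.ones((1, 1, 3, 3), dtype=np.float32)
    layer.primary.bias.data = np.zeros(1, dtype=np.float32)
    x = np.arange(25, dtype=np.float32).reshape(1, 1, 5, 5)
    out = layer(Tensor(x)).data[0, 0]
    xp = np.pad(x[0, 0], 1)
    ref = np.array([[xp[i : i + 3, j : j + 3].sum() for j in range(5)] for i in range(5)])
    np.testing.assert_allclose(out, ref, rtol=1e-6)


def test_backbone_stage_resolutions(rng):
    nn.manual_seed(0)
    bb = hg.HGhostBackbone(hg.BackboneConfig(stem_channels=8, stage_channels=(8, 12, 16, 24)))
    for size in (96, 128):
        feats = bb(Tensor(rng.normal(size=(1, 3, size, size)).astype(np.float32)))
        assert [f.shape[2] for f in feats] == [size // 2, size // 4, size // 8, size // 8]
        assert [f.shape[1] for f in feats] == [8, 12, 16, 24]


def test_backbone_rejects_indivisible_input(rng):
    nn.manual_seed(0)
    bb = hg.HGhostBackbone(hg.BackboneConfig(stem_channels=8, stage_channels=(8, 12, 16, 24)))
    with pytest.raises(ValueError, match="divisible by 8"):
        bb(Tensor(rng.normal(size=(1, 3, 50, 50)).astype(np.float32)))


def test_monitored_intrinsics_exposed_per_bottleneck(rng):
    nn.manual_seed(0)
    bb = hg.HGhostBackbone(hg.BackboneConfig(stem_channels=8, stage_channels=(8, 12, 16, 24)))
    bb(Tensor(rng.normal(size=(2, 3, 96, 96)).astype(np.float32)))
    intr = bb.monitored_intrinsics()
    assert len(intr) == 4
    assert [t.shape[1] for t in intr] == [4, 6, 8, 12]  # m = out_channels / ratio_s


# ---------------------------------------------------------------------------
# HSIC / nHSIC
# ---------------------------------------------------------------------------


def test_hsic_hand_computed_identity_case():
    """m=2, Kx=Ky=I: tr(H I H I) = tr(H) = 1 with H = [[.5,-.5],[-.5,.5]]."""
    assert hg.hsic_empirical(np.eye(2), np.eye(2)) == pytest.approx(1.0, abs=1e-12)


def test_hsic_annihilates_constant_features(rng):
    K = rng.normal(size=(5, 5))
    assert hg.hsic_empirical(K, np.ones((5, 5))) == pytest.approx(0.0, abs=1e-12)


def test_hsic_symmetric_on_random_psd_pairs(rng):
    for _ in range(10):
        A = rng.normal(size=(6, 3))
        B = rng.normal(size=(6, 4))
        Kx, Ky = A @ A.T, B @ B.T
        assert hg.hsic_empirical(Kx, Ky) == pytest.approx(hg.hsic_empirical(Ky, Kx), rel=1e-12)


def test_linear_hsic_equals_cross_covariance_frobenius_norm(rng):
    """(m-1)^-2 tr(KxHKyH) with linear kernels is ||cov(X,Y)||_F^2."""
    for _ in range(50):
        m = int(rng.integers(4, 10))
        X = rng.normal(size=(m, int(rng.integers(2, 5))))
        Y = rng.normal(size=(m, int(rng.integers(2, 5))))
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        C = Xc.T @ Yc / (m - 1)
        assert hg.hsic_empirical(X @ X.T, Y @ Y.T) == pytest.approx(
            np.linalg.norm(C, "fro") ** 2, abs=1e-8, rel=1e-8
        )


def test_hsic_rejects_single_sample():
    with pytest.raises(ValueError, match="two samples"):
        hg.hsic_empirical(np.ones((1, 1)), np.ones((1, 1)))


def test_nhsic_symmetry_zero_and_bounds(rng):
    A = rng.normal(size=(5, 3))
    B = rng.normal(size=(5, 2))
    assert hg.nhsic(A, B).item() == pytest.approx(hg.nhsic(B, A).item(), abs=1e-10)
    assert hg.nhsic(A, np.ones((5, 4))).item() == pytest.approx(0.0, abs=1e-12)
    v = hg.nhsic(A, A).item()
    assert 0.0 <= v <= 5.0


def test_nhsic_against_explicit_inverse_oracle():
    A = np.array([[1, 2], [0, 1], [3, -1], [2, 2]], dtype=float)
    B = np.array([[0, 1], [1, 1], [2, 0], [1, 3]], dtype=float)

    def oracle(Ii, Ij, eps=1e-5):
        s = Ii.shape[0]
        H = np.eye(s) - 1 / s

        def kt(I):
            Kb = H @ (I @ I.T) @ H
            return Kb @ np.linalg.inv(Kb + eps * s * np.eye(s))

        return np.trace(kt(Ii) @ kt(Ij))

    assert hg.nhsic(A, B).item() == pytest.approx(oracle(A, B), abs=1e-10)


def test_regularized_kernel_eigenvalues_in_unit_interval(rng):
    for _ in range(10):
        X = rng.normal(size=(6, int(rng.integers(2, 8))))
        Kt = hg._regularized_kernel(Tensor(X.astype(np.float64)), 1e-5).data
        ev = np.linalg.eigvalsh((Kt + Kt.T) / 2)
        assert ev.min() >= -1e-10
        assert ev.max() < 1.0


def test_l_nhsic_pair_counting_and_degenerate_cases(rng):
    feats = [rng.normal(size=(4, 2)) for _ in range(3)]
    total = hg.l_nhsic(feats, alpha=1.0).item()
    pair_sum = sum(
        hg.nhsic(feats[i], feats[j]).item() for i in range(3) for j in range(i + 1, 3)
    )
    assert total == pytest.approx(pair_sum, rel=1e-10)  # exactly 3 pair terms
    # identical features: positive; constants: zero; single feature warns
    same = rng.normal(size=(4, 2))
    assert hg.l_nhsic([same, same.copy()]).item() > 0
    assert hg.l_nhsic([np.ones((4, 2)), np.ones((4, 2))]).item() == pytest.approx(0.0, abs=1e-12)
    with pytest.warns(UserWarning):
        assert hg.l_nhsic([same]).item() == 0.0


def test_channel_penalty_matches_generic_nhsic(rng):
    """The vectorized training penalty equals nhsic over (s,1) channel pairs."""
    x = rng.normal(size=(4, 3, 2, 2))
    fast = hg.l_nhsic_channels(Tensor(x.astype(np.float64)), pool_hw=2).item()
    chans = [x[:, i].reshape(-1, 1) for i in range(3)]
    assert fast == pytest.approx(hg.l_nhsic(chans).item(), abs=1e-6)


# ---------------------------------------------------------------------------
# CKA
# ---------------------------------------------------------------------------


def test_cka_diagonal_symmetry_and_scale_invariance(rng):
    base = rng.normal(size=(5, 40))
    ch = np.vstack([base[0], 2.0 * base[0], base[2:]])
    M = hg.cka_matrix(ch)
    np.testing.assert_allclose(np.diag(M), 1.0)
    np.testing.assert_allclose(M, M.T, atol=1e-8)
    assert M[0, 1] == pytest.approx(1.0, abs=1e-10)  # channel B = 2*channel A
    # direct-formula oracle for one off-diagonal entry
    a = base[2] - base[2].mean()
    b = base[3] - base[3].mean()
    expect = (a @ b) ** 2 / ((a @ a) * (b @ b))
    assert M[2, 3] == pytest.approx(expect, rel=1e-10)


def test_cka_zero_variance_channel_convention(rng):
    ch = np.vstack([np.zeros(30), rng.normal(size=(3, 30))])
    M = hg.cka_matrix(ch)
    assert M[0, 0] == 1.0
    assert np.all(M[0, 1:] == 0.0)


def test_cka_heatmap_writes_png(tmp_path, rng):
    path = tmp_path / "heat.png"
    M = hg.cka_heatmap(rng.normal(size=(6, 50)), path)
    assert path.exists() and path.stat().st_size > 0
    assert M.shape == (6, 6)
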