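"""Fovea Pooling: attention indexing, importance, radius law and pooling oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foveaseg import autodiff as ad
from foveaseg import nn
from foveaseg import fovea_pooling as fp
from foveaseg.autodiff import Tensor


# ---------------------------------------------------------------------------
# attention assembly
# ---------------------------------------------------------------------------


def test_embedding_channel_count_arithmetic():
    idx = fp._attention_index(2, 2)
    assert idx.shape == (4, 4)
    assert idx.max() < (2 * 2 - 1) ** 2 == 9


def test_attention_index_rule_enumerated_by_hand():
    """For H=W=2, target [k,l] reads channel (1-k+s)*3 + (1-l+t) of the 3x3 grid."""
    idx = fp._attention_index(2, 2)
    for k in range(2):
        for l in range(2):
            for s in range(2):
                for t in range(2):
                    assert idx[k * 2 + l, s * 2 + t] == (1 - k + s) * 3 + (1 - l + t)
    # position [0,0] reads the lower-right 2x2 of the 3x3 offset grid: rows {1,2}, cols {1,2}
    assert sorted(idx[0]) == [4, 5, 7, 8]


def test_constant_embedding_gives_constant_attention(rng):
    emb = Tensor(np.full((1, 9, 2, 2), 3.25))
    att = fp.attention_from_embedding(emb, 2, 2)
    np.testing.assert_allclose(att.data, 3.25)


def test_attention_values_come_from_embedding(rng):
    h = w = 3
    emb = rng.normal(size=(1, (2 * h - 1) * (2 * w - 1), h, w))
    att = fp.attention_from_embedding(Tensor(emb), h, w).data
    for k in range(h):
        for l in range(w):
            for s in range(h):
                for t in range(w):
                    ch = (h - 1 - k + s) * (2 * w - 1) + (w - 1 - l + t)
                    assert att[0, k, l, s, t] == pytest.approx(emb[0, ch, k, l])


def test_wrong_channel_count_rejected(rng):
    with pytest.raises(ValueError, match="channels"):
        fp.attention_from_embedding(Tensor(rng.normal(size=(1, 8, 2, 2))), 2, 2)


def test_working_resolution_mismatch_rejected(rng):
    nn.manual_seed(0)
    mod = fp.ImportanceAware(4, 4, 4, branch_width=2)
    with pytest.raises(ValueError, match="downsample"):
        mod.collect_distribute_attention(Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32)))


# ---------------------------------------------------------------------------
# importance map
# ---------------------------------------------------------------------------


def _importance_oracle(ac, ad_, x):
    """Direct double-sum of the aggregation rule, channel-mean, min-max."""
    n, c, h, w = x.shape
    L = h * w
    xf = x.reshape(n, c, L)
    raw = np.zeros((n, L))
    for b in range(n):
        for i in range(L):
            z = np.zeros(c)
            ki, li = divmod(i, w)
            for j in range(L):
                kj, lj = divmod(j, w)
                z += (ac[b, ki, li, kj, lj] + ad_[b, ki, li, kj, lj]) * xf[b, :, j]
            raw[b, i] = (z / L).mean()
    out = np.zeros((n, L))
    for b in range(n):
        lo, hi = raw[b].min(), raw[b].max()
        out[b] = 1.0 if hi - lo < 1e-12 else (raw[b] - lo) / (hi - lo)
    return out.reshape(n, 1, h, w)


def test_uniform_attention_uniform_feature_degenerates_to_one(rng):
    x = Tensor(np.full((1, 3, 2, 2), 2.0))
    a = Tensor(np.full((1, 2, 2, 2, 2), 0.5))
    Z = fp.importance_map(a, a, x)
    np.testing.assert_allclose(Z.data, 1.0)


def test_importance_minmax_contract(rng):
    x = Tensor(rng.normal(size=(2, 3, 3, 3)))
    ac = Tensor(rng.normal(size=(2, 3, 3, 3, 3)))
    ad_ = Tensor(rng.normal(size=(2, 3, 3, 3, 3)))
    Z = fp.importance_map(ac, ad_, x).data
    assert Z.min() >= 0.0
    for b in range(2):
        assert Z[b].max() == pytest.approx(1.0)


def test_importance_against_double_sum_oracle(rng):
    x = np.zeros((1, 2, 2, 2))
    x[0, :, 1, 0] = 5.0  # single hot pixel
    ac = rng.normal(size=(1, 2, 2, 2, 2))
    ad_ = rng.normal(size=(1, 2, 2, 2, 2))
    Z = fp.importance_map(Tensor(ac), Tensor(ad_), Tensor(x)).data
    ref = _importance_oracle(ac, ad_, x)
    np.testing.assert_allclose(Z, ref, atol=1e-10)
    assert np.unravel_index(Z.argmax(), Z.shape) == np.unravel_index(ref.argmax(), ref.shape)


# ---------------------------------------------------------------------------
# boundary and radius law
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "s,w,expected",
    [(1 / 8, 64, np.log(8)), (1 / 16, 128, np.log(8)), (1 / 64, 64, 0.0)],
)
def test_boundary_to_sigma(s, w, expected):
    assert fp.boundary_to_sigma(s, w) == pytest.approx(expected, abs=1e-12)


def test_radius_law_endpoints_and_midpoint():
    sigma = np.log(8)
    assert fp.radius_map(np.array([[1.0]]), sigma)[0, 0] == 1
    assert fp.radius_map(np.array([[0.0]]), sigma)[0, 0] == 8
    # floor(exp(ln8 * 0.5)) = floor(2.8284) = 2
    assert fp.radius_map(np.array([[0.5]]), sigma)[0, 0] == 2


@pytest.mark.parametrize("cap", [2, 4, 8, 16, 32, 64])
def test_radius_endpoints_across_boundaries(cap):
    sigma = np.log(cap)
    assert fp.radius_map(np.ones((3, 3)), sigma).max() == 1
    assert (fp.radius_map(np.zeros((3, 3)), sigma) == cap).all()
    assert fp.radius_cap(sigma) == cap


@settings(deadline=None, max_examples=30)
@given(st.floats(0, 1), st.floats(0, 1), st.floats(0.1, 4.0))
def test_radius_monotone_nonincreasing_in_importance(za, zb, sigma):
    ra = fp.radius_map(np.array([[za]]), sigma)[0, 0]
    rb = fp.radius_map(np.array([[zb]]), sigma)[0, 0]
    if za <= zb:
        assert ra >= rb


def test_radius_out_of_range_clamps_with_warning():
    with pytest.warns(UserWarning, match="clamping"):
        r = fp.radius_map(np.array([[1.5, -0.5]]), np.log(4))
    assert r[0, 0] == 1 and r[0, 1] == 4


def test_mean_radius_monotone_in_boundary(rng):
    """Coarser boundaries (larger s) never shrink the mean pooling radius."""
    Z = rng.uniform(size=(16, 16))
    w = 64
    means = [fp.radius_map(Z, fp.boundary_to_sigma(s, w)).mean() for s in (1 / 32, 1 / 16, 1 / 8, 1 / 4, 1 / 2)]
    assert all(b >= a for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# adaptive pooling
# ---------------------------------------------------------------------------


def pool_oracle(x, radii, method="average", p=2.0, mix=0.5):
    """Nested-loop reference that explicitly builds each reflect-padded window."""
    N, C, H, W = x.shape
    radii = np.broadcast_to(np.asarray(radii), (N, H, W))
    out = np.zeros_like(x)
    for n in range(N):
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    r = int(radii[n, i, j])
                    pad = r - 1
                    xp = np.pad(x[n, c], pad, mode="reflect") if pad else x[n, c]
                    win = xp[i : i + 2 * r - 1, j : j + 2 * r - 1]
                    if method == "average":
                        out[n, c, i, j] = win.mean()
                    elif method == "lp":
                        out[n, c, i, j] = (np.abs(win) ** p).mean() ** (1 / p)
                    else:
                        out[n, c, i, j] = mix * win.max() + (1 - mix) * win.mean()
    return out


@pytest.mark.parametrize("method", ["average", "lp", "mixed"])
def test_adaptive_pool_against_nested_loop_oracle(method, rng):
    for trial in range(100):
        H = W = int(rng.integers(6, 13))
        x = rng.normal(size=(1, 2, H, W))
        radii = rng.integers(1, 4, size=(H, W))
        got = fp.adaptive_pool(x, radii, method).data
        ref = pool_oracle(x, radii, method)
        np.testing.assert_allclose(got, ref, rtol=1e-5, atol=1e-8)


@pytest.mark.parametrize("method", ["average", "mixed", "identity"])
def test_radius_one_is_exact_identity(method, rng):
    x = rng.normal(size=(2, 3, 6, 6))
    out = fp.adaptive_pool(x, np.ones((6, 6), dtype=int), method).data
    np.testing.assert_array_equal(out, x)


def test_constant_input_average_is_constant(rng):
    x = np.full((1, 1, 8, 8), 2.5)
    radii = rng.integers(1, 4, size=(8, 8))
    out = fp.adaptive_pool(x, radii, "average").data
    np.testing.assert_allclose(out, 2.5, rtol=1e-6)


def test_radius_above_cap_rejected(rng):
    x = rng.normal(size=(1, 1, 4, 4))
    with pytest.raises(ValueError, match="boundary cap"):
        fp.adaptive_pool(x, np.full((4, 4), 5), "average", max_radius=4)


def test_average_pool_gradient_is_one_over_n_per_window(rng):
    """Analytic gradient equals eta/n summed over windows containing the element."""
    x = Tensor(rng.normal(size=(1, 1, 5, 5)))
    x.requires_grad = True
    radii = rng.integers(1, 3, size=(5, 5))
    out = ad.adaptive_pool(x, radii, method="average")
    out.backward(np.ones_like(out.data))
    # brute-force: accumulate 1/n for every output window containing each input pixel
    ref = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            r = int(radii[i, j])
            n = (2 * r - 1) ** 2
            pad = r - 1
            # indices of the window in reflect-padded coordinates, mapped back
            for a in range(i - pad, i + pad + 1):
                for b in range(j - pad, j + pad + 1):
                    aa = a if 0 <= a < 5 else (-a if a < 0 else 2 * (5 - 1) - a)
                    bb = b if 0 <= b < 5 else (-b if b < 0 else 2 * (5 - 1) - b)
                    ref[aa, bb] += 1.0 / n
    np.testing.assert_allclose(x.grad[0, 0], ref, atol=1e-6)


# ---------------------------------------------------------------------------
# full module
# ---------------------------------------------------------------------------


@pytest.fixture
def fp_module():
    nn.manual_seed(3)
    return fp.FoveaPooling(channels=8, stage_size=16, boundary=0.25, attention_max_hw=8, branch_width=4)


@pytest.mark.parametrize("size", [16, 24, 32])
def test_module_preserves_spatial_size(fp_module, size, rng):
    x = Tensor(rng.normal(size=(1, 8, size, size)).astype(np.float32))
    assert fp_module(x).shape == (1, 8, size, size)


def test_module_identity_when_importance_is_one(fp_module, rng, monkeypatch):
    """Z = 1 everywhere collapses the pooling to the prior/restore path."""
    x = Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))

    def forced(xx):
        xr = fp_module.prior(xx)
        return Tensor(np.ones((1, 1, 16, 16), dtype=np.float32)), xr

    monkeypatch.setattr(fp_module, "importance_full", forced)
    out = fp_module(x)
    ref = fp_module.restore(fp_module.prior(x))
    np.testing.assert_allclose(out.data, ref.data, rtol=1e-6)


def test_module_gradient_matches_finite_differences():
    """Central differences through the whole pooled path on a 5x5 input."""
    nn.manual_seed(4)
    mod = fp.FoveaPooling(
        channels=4, stage_size=5, boundary=0.6, method=fp.PoolingMethod("average"),
        attention_max_hw=5, branch_width=2,
    )
    # float64 parameters for accurate finite differences
    for p in mod.parameters():
        p.data = p.data.astype(np.float64)
    rng = np.random.default_rng(0)
    x = Tensor(rng.normal(size=(1, 4, 5, 5)))
    x.requires_grad = True
    out = mod(x)
    loss = (out ** 2).sum()
    loss.backward()
    ana = x.grad.copy()
    eps = 1e-5
    fd = np.zeros_like(x.data)
    flat = x.data.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = (mod(x) ** 2).sum().item()
        flat[i] = orig - eps
        lo = (mod(x) ** 2).sum().item()
        flat[i] = orig
        fd.ravel()[i] = (hi - lo) / (2 * eps)
    # radii are piecewise constant; away from flips the gradients agree
    np.testing.assert_allclose(ana, fd, atol=1e-4)


def test_boundary_cap_limits_radius(fp_module, rng):
    x = Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
    Z, _ = fp_module.importance_full(x)
    radii = fp.radius_map(Z.data[:, 0], fp_module.sigma)
    assert radii.max() <= int(np.floor(0.25 * 16))
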