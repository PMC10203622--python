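"""Engine correctness: forward oracles and finite-difference gradients."""

import numpy as np
import pytest

from vesselseg import nn
from vesselseg.nn import Tensor

from conftest import naive_conv2d, numerical_gradient

RNG = np.random.default_rng(42)


def autodiff_grad(fn_t, x):
    t = Tensor(x.astype(np.float64), requires_grad=True)
    fn_t(t).backward()
    return t.grad


@pytest.mark.parametrize(
    "fn",
    [
        lambda t: (t * t + 2.0 * t).sum(),
        lambda t: (t.sigmoid() * t.exp()).mean(),
        lambda t: ((t + 1.5).log() * t.relu()).sum(),
        lambda t: (t / (t * t + 1.0)).sum(),
        lambda t: (t**3.0).mean(axis=0).sum(),
        lambda t: t.max(axis=1).sum(),
        lambda t: t.reshape(-1).sum(axis=0),
        lambda t: (t.transpose(1, 0) @ t).sum(),
    ],
)
def test_elementwise_gradients_match_finite_differences(fn):
    x = RNG.uniform(0.1, 1.0, (4, 5))
    got = autodiff_grad(fn, x)
    want = numerical_gradient(lambda a: float(fn(Tensor(a)).data), x)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-7)


def test_broadcasting_gradients_are_summed_to_shape():
    a = Tensor(RNG.normal(size=(3, 1, 4)), requires_grad=True)
    b = Tensor(RNG.normal(size=(5, 1)), requires_grad=True)
    (a * b).sum().backward()
    assert a.grad.shape == (3, 1, 4)
    assert b.grad.shape == (5, 1)
    np.testing.assert_allclose(b.grad, (a.data * np.ones((3, 5, 4))).sum(axis=(0, 2))[:, None])


def test_grad_accumulates_over_reuse():
    x = Tensor(np.array([2.0]), requires_grad=True)
    y = x * x + x * 3.0
    y.backward()
    np.testing.assert_allclose(x.grad, [7.0])


def test_no_grad_blocks_taping():
    x = Tensor(np.ones(3), requires_grad=True)
    with nn.no_grad():
        y = x * 2.0
    assert not y.requires_grad


@pytest.mark.parametrize("stride,padding,dilation", [(1, 0, 1), (1, 1, 1), (2, 1, 1), (1, 2, 2), (1, 3, 3)])
def test_conv2d_forward_matches_nested_loop(stride, padding, dilation):
    x = RNG.normal(size=(2, 3, 9, 8))
    w = RNG.normal(size=(4, 3, 3, 3))
    got = nn.conv2d(Tensor(x), Tensor(w), stride=stride, padding=padding, dilation=dilation)
    want = naive_conv2d(x, w, stride=stride, padding=padding, dilation=dilation)
    np.testing.assert_allclose(got.data, want, rtol=1e-10, atol=1e-12)


@pytest.mark.parametrize("stride,padding,dilation", [(1, 1, 1), (2, 1, 1), (1, 2, 2)])
def test_conv2d_gradients_match_finite_differences(stride, padding, dilation):
    x = RNG.normal(size=(2, 2, 6, 6))
    w = RNG.normal(size=(3, 2, 3, 3))
    b = RNG.normal(size=3)

    def run(xt, wt, bt):
        return (
            nn.conv2d(xt, wt, bias=bt, stride=stride, padding=padding, dilation=dilation)
            .sigmoid()
            .sum()
        )

    xt = Tensor(x, requires_grad=True)
    wt = Tensor(w, requires_grad=True)
    bt = Tensor(b, requires_grad=True)
    run(xt, wt, bt).backward()

    num_x = numerical_gradient(lambda a: float(run(Tensor(a), Tensor(w), Tensor(b)).data), x)
    num_w = numerical_gradient(lambda a: float(run(Tensor(x), Tensor(a), Tensor(b)).data), w)
    num_b = numerical_gradient(lambda a: float(run(Tensor(x), Tensor(w), Tensor(a)).data), b)
    np.testing.assert_allclose(xt.grad, num_x, rtol=1e-5, atol=1e-8)
    np.testing.assert_allclose(wt.grad, num_w, rtol=1e-5, atol=1e-8)
    np.testing.assert_allclose(bt.grad, num_b, rtol=1e-5, atol=1e-8)


def test_upsample_matches_skimage_resize():
    from skimage.transform import resize

    x = RNG.normal(size=(2, 3, 7, 5))
    got = nn.upsample_bilinear2x(Tensor(x)).data
    for ni in range(2):
        for ci in range(3):
            want = resize(x[ni, ci], (14, 10), order=1, anti_aliasing=False, mode="edge")
            np.testing.assert_allclose(got[ni, ci], want, rtol=1e-7, atol=1e-9)


def test_upsample_gradient_is_exact_adjoint():
    x = RNG.normal(size=(1, 2, 4, 3))
    g = RNG.normal(size=(1, 2, 8, 6))

    xt = Tensor(x, requires_grad=True)
    nn.upsample_bilinear2x(xt).backward(g)
    num = numerical_gradient(
        lambda a: float((nn.upsample_bilinear2x(Tensor(a)).data * g).sum()), x
    )
    np.testing.assert_allclose(xt.grad, num, rtol=1e-6, atol=1e-9)


def test_batchnorm_normalises_and_backprops():
    bn = nn.BatchNorm2d(3, dtype=np.float64)
    x = RNG.normal(2.0, 3.0, size=(4, 3, 5, 5))
    xt = Tensor(x, requires_grad=True)
    y = bn(xt)
    np.testing.assert_allclose(y.data.mean(axis=(0, 2, 3)), 0.0, atol=1e-10)
    np.testing.assert_allclose(y.data.std(axis=(0, 2, 3)), 1.0, atol=1e-3)

    (y.sigmoid().sum()).backward()
    num = numerical_gradient(
        lambda a: float(_bn_stateless(a, bn).data), x
    )
    np.testing.assert_allclose(xt.grad, num, rtol=1e-4, atol=1e-7)


def _bn_stateless(x, bn):
    # recompute with frozen running buffers so finite differences see a pure function
    saved = (bn.running_mean.copy(), bn.running_var.copy())
    out = bn(Tensor(x)).sigmoid().sum()
    bn.running_mean, bn.running_var = saved
    return out


def test_batchnorm_eval_uses_running_statistics():
    bn = nn.BatchNorm2d(2, momentum=1.0)
    x = RNG.normal(5.0, 2.0, size=(8, 2, 6, 6)).astype(np.float32)
    bn(Tensor(x))  # momentum 1.0: running stats become the batch stats
    bn.eval()
    y = bn(Tensor(x)).data
    np.testing.assert_allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-4)


def test_adam_minimises_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        loss = ((p - Tensor(np.array([1.0, 2.0]))) ** 2.0).sum()
        loss.backward()
        opt.step()
    np.testing.assert_allclose(p.data, [1.0, 2.0], atol=1e-3)


def test_multistep_schedule_decays_at_milestones():
    p = nn.Parameter(np.zeros(1))
    opt = nn.Adam([p], lr=1e-3)
    sched = nn.MultiStepLR(opt, milestones=(2, 4), factor=0.1)
    lrs = []
    for epoch in range(5):
        sched.step(epoch)
        lrs.append(opt.lr)
    np.testing.assert_allclose(lrs, [1e-3, 1e-3, 1e-4, 1e-4, 1e-5])
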