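import numpy as np
import pytest

from stargardt_oct.synthetic_data import SynthEyeParams, generate_eye


@pytest.fixture(scope="session")
def small_eye():
    """A quick-to-generate synthetic eye for feature/registration tests."""
    return generate_eye(SynthEyeParams(shape=(48, 64, 16), seed=5))


@pytest.fixture(scope="session")
def medium_eye():
    """Default-condition synthetic eye (larger grid, default effect sizes)."""
    return generate_eye(SynthEyeParams(shape=(96, 128, 48), seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def ensemble_grad_rel_error(net, x, gt, weightmap, lam=1e-4, n_per_param=3,
                            seed=7, h=1e-6):
    """Worst relative error of analytic vs central-difference gradients.

    The loss surface has kinks (max combination, ReLU, pool argmax); entries
    whose second difference reveals nonsmoothness at the step scale are
    excluded, since the central difference is not the derivative there.
    Returns (worst relative error, n_checked, n_skipped).
    """
    from stargardt_oct.ensemble_model import (_loss_and_grad, _max_routing,
                                              weight_penalty)

    def full_loss():
        combined, _ = net.forward(x, train=True)
        loss, _ = _loss_and_grad(combined, gt, weightmap)
        return loss + lam * weight_penalty(net.params())

    params = net.params()
    for p in params:
        p.zero_grad()
    combined, acts = net.forward(x, train=True)
    _, dz = _loss_and_grad(combined, gt, weightmap)
    for comp, route in zip(net.components, _max_routing(acts, combined)):
        comp.backward(dz * route)
    for p in params:
        if p.decay:
            p.grad += 2 * lam * p.value

    l0 = full_loss()
    check = np.random.default_rng(seed)
    worst, n_checked, n_skipped = 0.0, 0, 0
    for p in params:
        flat, gflat = p.value.ravel(), p.grad.ravel()
        for i in check.choice(flat.size, size=min(n_per_param, flat.size),
                              replace=False):
            old = flat[i]
            flat[i] = old + h
            lp = full_loss()
            flat[i] = old - h
            lm = full_loss()
            flat[i] = old
            s_plus, s_minus = (lp - l0) / h, (l0 - lm) / h
            if abs(s_plus - s_minus) > 1e-3 * max(abs(s_plus), abs(s_minus), 1e-6):
                n_skipped += 1  # one-sided slopes disagree: kink within +-h
                continue
            num = (lp - lm) / (2 * h)
            worst = max(worst, abs(num - gflat[i]) / max(abs(num), abs(gflat[i]), 1e-8))
            n_checked += 1
    return worst, n_checked, n_skipped
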