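import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_rotation
from pldiffusion.diffusion import (
    LatentState,
    LiteralAlphaSchedule,
    SCHEDULE_REGISTRY,
    center,
    denoised_estimate,
    forward_sample,
    make_schedule,
    posterior_params,
    reverse_step,
    sample_centered_noise,
    sample_complex,
)
from pldiffusion.fixtures import generate_toy_complex


@pytest.fixture(params=sorted(SCHEDULE_REGISTRY))
def sched(request):
    return make_schedule(16, request.param)


def test_unknown_schedule_kind():
    with pytest.raises(ValueError, match="unknown schedule"):
        make_schedule(8, "nope")


def test_schedule_invariants_dense_grid(sched):
    t = np.linspace(0.0, 1.0, 1000)
    a, s = sched.alpha(t), sched.sigma(t)
    assert np.abs(a**2 + s**2 - 1).max() < 1e-12
    assert np.all(np.diff(a) <= 1e-15)  # monotone non-increasing
    assert (a > 0).all()
    assert float(sched.alpha(0.0)) >= 1 - 1e-4
    assert float(sched.alpha(1.0)) <= 1e-2


def test_transition_identities(sched):
    rng = np.random.default_rng(0)
    for _ in range(100):
        s, t = np.sort(rng.uniform(0.01, 1.0, 2))
        if s == t:
            continue
        assert sched.alpha_ts(t, t) == pytest.approx(1.0)
        assert sched.sigma2_ts(t, t) == pytest.approx(0.0, abs=1e-15)
        direct = sched.sigma(t) ** 2 - sched.alpha_ts(t, s) ** 2 * sched.sigma(s) ** 2
        assert sched.sigma2_ts(t, s) == pytest.approx(direct, abs=1e-15)


def test_literal_alpha_schedule_exists_but_not_registered():
    lit = LiteralAlphaSchedule(8)
    t = np.linspace(0, 1, 50)
    # literal reading alpha = 1 - sigma^2 breaks the VP identity
    assert np.abs(lit.alpha(t) ** 2 + lit.sigma(t) ** 2 - 1).max() > 1e-3
    assert "literal" not in {k.lower() for k in SCHEDULE_REGISTRY}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed_=st.integers(0, 10_000))
def test_center_idempotent_translation_invariant(seed_):
    x = np.random.default_rng(seed_).standard_normal((7, 3)) * 5
    c = center(x)
    assert np.abs(c.mean(0)).max() < 1e-12
    np.testing.assert_allclose(center(c), c, atol=1e-12)
    np.testing.assert_allclose(center(x + np.array([1.0, 2.0, 3.0])), c, atol=1e-12)


def test_forward_sample_rejects_uncentered():
    sched = make_schedule(8)
    x = np.ones((4, 3))
    with pytest.raises(ValueError, match="centered"):
        forward_sample(x, 0.5, sched, seed=0)
    state = forward_sample(x, 0.5, sched, seed=0, auto_center=True)
    assert np.abs(state.z.mean(0)).max() < 1e-9


def test_forward_sample_near_identity_at_t0():
    sched = make_schedule(8)
    x = center(np.random.default_rng(1).standard_normal((10, 3)) * 3)
    state = forward_sample(x, 0.0, sched, seed=2)
    assert np.linalg.norm(state.z - x) / np.linalg.norm(x) < 0.05


def test_forward_sample_statistics():
    """t=1 variance matches the centered-subspace factor (n-1)/n; mid-t mean
    matches alpha(t) x within 3 standard errors."""
    sched = make_schedule(8)
    n, draws = 8, 10_000
    x = center(np.random.default_rng(3).standard_normal((n, 3)) * 2)
    zs = np.array([forward_sample(x, 1.0, sched, seed=k).z for k in range(draws)])
    var = zs.var()
    expect = (n - 1) / n
    assert abs(var - expect) < 3 * expect * np.sqrt(2 / (draws * n * 3))

    zm = np.array([forward_sample(x, 0.5, sched, seed=k).z for k in range(draws)])
    mean = zm.mean(0)
    se = zm.std(0) / np.sqrt(draws)
    assert np.all(np.abs(mean - float(sched.alpha(0.5)) * x) <= 3 * se + 1e-9)


def test_posterior_rejects_bad_order():
    sched = make_schedule(8)
    z = LatentState(z=center(np.random.default_rng(0).standard_normal((5, 3))), t=0.5)
    with pytest.raises(ValueError, match="s < t"):
        posterior_params(z, z.z, 0.7, 0.5, sched)


def test_posterior_degenerate_limit():
    """s -> t: mean -> z_t, var -> 0."""
    sched = make_schedule(64)
    x = center(np.random.default_rng(4).standard_normal((6, 3)))
    state, _ = forward_sample(x, 0.6, sched, seed=5, return_noise=True)
    post = posterior_params(state, x, 0.6 - 1e-7, 0.6, sched)
    np.testing.assert_allclose(post.mean, state.z, atol=1e-4)
    assert post.var < 1e-6


def test_posterior_sigma_zero_limit():
    """With x = z_t / alpha_t and sigma_s -> 0, the mean tends to alpha_s x."""
    sched = make_schedule(64)
    z = center(np.random.default_rng(5).standard_normal((5, 3)))
    t, s = 0.9, 1e-6
    state = LatentState(z=z, t=t)
    x = z / float(sched.alpha(t))
    post = posterior_params(state, x, s, t, sched)
    np.testing.assert_allclose(post.mean, float(sched.alpha(s)) * center(x), atol=1e-3)


def test_posterior_conditional_moments_monte_carlo():
    """Gaussian-conditioning oracle: regression of a centered projection of
    z_s on z_t recovers the posterior coefficients and variance (3 SE)."""
    sched = make_schedule(16)
    rng = np.random.default_rng(6)
    n, draws = 6, 20_000
    x = center(rng.standard_normal((n, 3)) * 2)
    s, t = 0.35, 0.75
    a_s, a_ts = float(sched.alpha(s)), float(sched.alpha_ts(t, s))
    s_s, s_t = float(sched.sigma(s)), float(sched.sigma(t))
    s2_ts = float(sched.sigma2_ts(t, s))

    u = np.zeros((n, 3))
    u[0, 0], u[1, 0] = 1 / np.sqrt(2), -1 / np.sqrt(2)  # orthogonal to centroid
    zs_p, zt_p = np.empty(draws), np.empty(draws)
    for k in range(draws):
        eps1 = sample_centered_noise(rng, n)
        z_s = a_s * x + s_s * eps1
        eps2 = sample_centered_noise(rng, n)
        z_t = a_ts * z_s + np.sqrt(s2_ts) * eps2
        zs_p[k] = (u * z_s).sum()
        zt_p[k] = (u * z_t).sum()
    # theory: zs | zt is Gaussian with slope alpha_{t|s} sigma_s^2 / sigma_t^2
    slope_hat = np.cov(zs_p, zt_p)[0, 1] / zt_p.var()
    slope = a_ts * s_s**2 / s_t**2
    se_slope = np.sqrt((zs_p.var() / zt_p.var() - slope_hat**2) / draws)
    assert abs(slope_hat - slope) < 3 * se_slope + 1e-4
    # conditional variance sigma^2_{t->s}
    resid_var = zs_p.var() - slope_hat**2 * zt_p.var()
    var = s2_ts * s_s**2 / s_t**2
    assert abs(resid_var - var) < 3 * var * np.sqrt(2 / draws) + 1e-4
    # marginal consistency (Markov property): z_t moments match q(z_t | x)
    assert abs(zt_p.mean() - float(sched.alpha(t)) * (u * x).sum()) < 3 * zt_p.std() / np.sqrt(draws)
    assert abs(zt_p.var() - s_t**2) < 3 * s_t**2 * np.sqrt(2 / draws)


def test_denoised_estimate_inverts_forward():
    sched = make_schedule(8)
    x = center(np.random.default_rng(7).standard_normal((6, 3)))
    state, eps = forward_sample(x, 0.4, sched, seed=8, return_noise=True)
    np.testing.assert_allclose(denoised_estimate(state, eps, 0.4, sched), x, atol=1e-10)
    zero_hat = denoised_estimate(state, np.zeros_like(eps), 0.4, sched)
    np.testing.assert_allclose(zero_hat, state.z / float(sched.alpha(0.4)), atol=1e-10)


def test_reverse_mean_equals_posterior_with_estimate():
    """The two printed forms of the reverse mean agree to 1e-10."""
    sched = make_schedule(32)
    rng = np.random.default_rng(9)
    for _ in range(100):
        n = int(rng.integers(4, 10))
        x = center(rng.standard_normal((n, 3)))
        s, t = np.sort(rng.uniform(0.05, 1.0, 2))
        if t - s < 1e-3:
            continue
        state, eps = forward_sample(x, t, sched, seed=int(rng.integers(2**31)), return_noise=True)
        eps_hat = eps + 0.1 * rng.standard_normal(eps.shape)
        eps_hat = center(eps_hat)
        z_s = reverse_step(state, eps_hat, s, t, sched, seed=0, add_noise=False)
        post = posterior_params(state, denoised_estimate(state, eps_hat, t, sched), s, t, sched)
        np.testing.assert_allclose(z_s.z, post.mean, atol=1e-10)
        assert np.abs(z_s.z.mean(0)).max() < 1e-10


def test_reverse_step_pure_rescaling_with_zero_noise_prediction():
    sched = make_schedule(16)
    z = center(np.random.default_rng(10).standard_normal((5, 3)))
    state = LatentState(z=z, t=0.5)
    out = reverse_step(state, np.zeros_like(z), 0.25, 0.5, sched, seed=0, add_noise=False)
    np.testing.assert_allclose(out.z, z / float(sched.alpha_ts(0.5, 0.25)), atol=1e-12)


def test_sampler_T1_and_determinism(model, toy):
    from pldiffusion.sequence import stochastic_mask

    masked = stochastic_mask(toy.sequence, 0.5, seed=3)
    one = make_schedule(1)
    c1, s1 = sample_complex(model, masked, toy.ligand, seed=4, sched=one)
    assert c1.shape == (toy.n_tokens, 3)
    c2, s2 = sample_complex(model, masked, toy.ligand, seed=4, sched=one)
    np.testing.assert_array_equal(c1, c2)
    assert s1.residues == s2.residues
    assert "#" not in s1.residues  # masked positions decoded


def test_oracle_denoiser_recovers_structure():
    """Plugging the true-noise oracle into the sampler recovers x."""
    tc = generate_toy_complex(10, "*", seed=2)
    x = center(tc.coords)
    sched = make_schedule(64)

    def oracle(z, t):
        return (z - float(sched.alpha(t)) * x) / float(sched.sigma(t))

    coords, _ = sample_complex(None, tc.sequence, tc.ligand, seed=9, sched=sched,
                               denoiser=oracle)
    assert np.sqrt(((coords - x) ** 2).mean()) < 0.1


def test_step_level_rotation_equivariance(rng):
    """Rotating latent and noise prediction rotates the next latent."""
    sched = make_schedule(16)
    z = center(rng.standard_normal((6, 3)))
    eps_hat = center(rng.standard_normal((6, 3)))
    R = random_rotation(rng)
    a = reverse_step(LatentState(z=z, t=0.5), eps_hat, 0.3, 0.5, sched, 0, add_noise=False)
    b = reverse_step(LatentState(z=z @ R.T, t=0.5), eps_hat @ R.T, 0.3, 0.5, sched, 0,
                     add_noise=False)
    np.testing.assert_allclose(b.z, a.z @ R.T, atol=1e-10)
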