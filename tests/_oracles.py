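"""Independent numerical oracles used by the test suite.

These deliberately avoid the implementation paths they check: the sphere
signal oracle is a particle random walk, the powder oracles are dense
spherical quadratures, and the Watson-stick oracle is plain Monte-Carlo
sampling of the Watson distribution.
"""

import numpy as np


def mc_sphere_signal(r_s, d_is, b, delta, Delta, n_walkers=100_000,
                     dt=0.02, seed=0):
    """PGSE signal of diffusion in an impermeable sphere by random walk.

    Walkers start uniformly in a sphere of radius ``r_s`` (um), take
    Gaussian steps of variance 2 D dt per axis, and are reflected
    radially at the boundary.  The phase accumulates gamma*g*z(t) during
    the two rectangular gradient pulses (opposite signs); the signal is
    the mean cosine of the final phase.  Units: ms, um.
    """
    rng = np.random.default_rng(seed)
    # uniform start positions in the sphere
    pos = rng.normal(size=(n_walkers, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    pos *= r_s * rng.uniform(0, 1, size=(n_walkers, 1)) ** (1.0 / 3.0)
    gamma_g = np.sqrt(b / (delta ** 2 * (Delta - delta / 3.0)))
    sigma = np.sqrt(2.0 * d_is * dt)
    n_steps = int(round((Delta + delta) / dt))
    phase = np.zeros(n_walkers)
    for step in range(n_steps):
        t = (step + 0.5) * dt
        pos += rng.normal(0.0, sigma, size=pos.shape)
        radius = np.linalg.norm(pos, axis=1)
        outside = radius > r_s
        if outside.any():
            # radial (mirror) reflection about the boundary
            scale = (2.0 * r_s - radius[outside]) / radius[outside]
            pos[outside] *= np.maximum(scale, 0.0)[:, None]
        if t < delta:
            phase += gamma_g * pos[:, 2] * dt
        elif Delta <= t < Delta + delta:
            phase -= gamma_g * pos[:, 2] * dt
    return float(np.mean(np.cos(phase)))


def quadrature_powder_stick(b, d, n_theta=2000):
    """Spherical average of exp(-b d cos^2 theta) by dense quadrature."""
    t, w = np.polynomial.legendre.leggauss(n_theta)
    return float(np.sum(w * np.exp(-b * d * t ** 2)) / 2.0)


def mc_watson_stick(bd, mu, g, kappa, n_samples=1_000_000, seed=0):
    """Watson-averaged stick attenuation by Monte-Carlo orientation
    sampling (rejection sampler for the Watson density)."""
    rng = np.random.default_rng(seed)
    samples = np.empty((0, 3))
    while samples.shape[0] < n_samples:
        cand = rng.normal(size=(n_samples, 3))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        logw = kappa * (cand @ mu) ** 2 - kappa
        keep = np.log(rng.uniform(size=n_samples)) < logw
        samples = np.vstack([samples, cand[keep]])
    samples = samples[:n_samples]
    return float(np.mean(np.exp(-bd * (samples @ g) ** 2)))
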