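"""Shared fixtures: quadrature oracles and randomized problem generators.

The oracles compute event-posterior moments by dense numerical
integration, fully independently of the filters' closed forms, and are
the arbiter for the moment-matching contracts.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from pippet import ExpectationTemplate, GaussianPeak
from pippet.templates import evaluate_rate


def oracle_moments_1d(mu, V, template, n_grid=200_001):
    """Mean/variance of p(phi) ~ rate(phi) * N(phi; mu, V) by quadrature."""
    sd = np.sqrt(V)
    lo = min([mu - 10 * sd] + [p.phi - 10 * np.sqrt(p.v) for p in template.peaks])
    hi = max([mu + 10 * sd] + [p.phi + 10 * np.sqrt(p.v) for p in template.peaks])
    x = np.linspace(lo, hi, n_grid)
    w = np.asarray(evaluate_rate(template, x)) * norm.pdf(x, mu, sd)
    Z = np.trapezoid(w, x)
    m = np.trapezoid(x * w, x) / Z
    v = np.trapezoid((x - m) ** 2 * w, x) / Z
    return m, v, Z


def oracle_moments_2d(mu2, V2, template, n_phi=1601, n_theta=801):
    """Moments of p(x) ~ tempo * rate(phi) * N(x; mu2, V2) on a 2D grid.

    Grid spans +-8 standard deviations per dimension (widened to cover
    template peaks in phase).
    """
    sd0, sd1 = np.sqrt(V2[0, 0]), np.sqrt(V2[1, 1])
    lo0 = min([mu2[0] - 8 * sd0] + [p.phi - 8 * np.sqrt(p.v) for p in template.peaks])
    hi0 = max([mu2[0] + 8 * sd0] + [p.phi + 8 * np.sqrt(p.v) for p in template.peaks])
    x = np.linspace(lo0, hi0, n_phi)
    y = np.linspace(mu2[1] - 8 * sd1, mu2[1] + 8 * sd1, n_theta)
    X, Y = np.meshgrid(x, y, indexing="ij")
    g = multivariate_normal(mu2, V2).pdf(np.dstack([X, Y]))
    w = Y * np.asarray(evaluate_rate(template, X)) * g

    def integrate(f):
        return np.trapezoid(np.trapezoid(f, y, axis=1), x)

    Z = integrate(w)
    mx = integrate(X * w) / Z
    my = integrate(Y * w) / Z
    vxx = integrate((X - mx) ** 2 * w) / Z
    vyy = integrate((Y - my) ** 2 * w) / Z
    vxy = integrate((X - mx) * (Y - my) * w) / Z
    return np.array([mx, my]), np.array([[vxx, vxy], [vxy, vyy]]), Z


def random_template(rng, max_peaks=3, lambda_0_range=(0.0, 1.0)):
    n = int(rng.integers(1, max_peaks + 1))
    phis = np.sort(rng.uniform(-1.0, 1.0, n))
    while n > 1 and np.min(np.diff(phis)) <= 0.02:
        phis = np.sort(rng.uniform(-1.0, 1.0, n))
    peaks = tuple(
        GaussianPeak(
            phi=float(p),
            v=float(rng.uniform(0.0005, 0.05)),
            lam=float(rng.uniform(0.1, 3.0)),
        )
        for p in phis
    )
    return ExpectationTemplate(
        lambda_0=float(rng.uniform(*lambda_0_range)), peaks=peaks
    )


def random_belief_2d(rng):
    mu2 = np.array([rng.uniform(-0.5, 0.5), rng.uniform(0.7, 1.4)])
    a = rng.uniform(0.002, 0.05)
    c = rng.uniform(0.002, 0.05)
    b = rng.uniform(-0.6, 0.6) * np.sqrt(a * c)
    return mu2, np.array([[a, b], [b, c]])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
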