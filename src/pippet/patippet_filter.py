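"""Joint phase-and-tempo filter with a 2D Gaussian belief.

State is ``x = (phase, tempo)``.  The generative prior advances phase at
the current tempo with independent phase/tempo diffusion, and the event
rate is the phase template scaled by tempo, ``rate(phase, tempo) = tempo *
rate_1d(phase)``.  Event updates are exact Gaussian moment matches of the
product ``rate(x) * N(x; mu2, V2)``: each mixture component is a Gaussian
conditioned on the peak (a rank-one Kalman update in the phase
coordinate) reweighted by the linear tempo factor, whose first and second
moments against a Gaussian are analytic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .pippet_filter import EventStream, _snap_events_to_grid
from .templates import TRUNCATION_SD, ExpectationTemplate, tile_periodic

__all__ = [
    "GaussianBelief2D",
    "PatippetConfig",
    "Trajectory2D",
    "rate_2d",
    "event_update_2d",
    "drift_2d",
    "run_patippet",
]

EIG_FLOOR = 1e-12
_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianBelief2D:
    """2D Gaussian over (phase, tempo): mean vector and SPD covariance."""

    mu2: np.ndarray
    V2: np.ndarray

    def __post_init__(self) -> None:
        mu2 = np.asarray(self.mu2, dtype=float).reshape(2)
        V2 = np.asarray(self.V2, dtype=float).reshape(2, 2)
        object.__setattr__(self, "mu2", mu2)
        object.__setattr__(self, "V2", V2)
        if not np.allclose(V2, V2.T, rtol=0, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(V2) <= 0):
            raise ValueError("covariance must be positive definite")

    @property
    def mu_phi(self) -> float:
        return float(self.mu2[0])

    @property
    def mu_theta(self) -> float:
        return float(self.mu2[1])


@dataclass(frozen=True)
class PatippetConfig:
    """Step size, phase/tempo noise, 2D prior and duration."""

    dt: float = 0.001
    sigma: float = 0.1
    sigma_theta: float = 0.05
    mu2_0: tuple[float, float] = (0.0, 1.0)
    V2_0: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0001, 0.0),
        (0.0, 0.01),
    )
    t_end: float = 1.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.sigma < 0 or self.sigma_theta < 0:
            raise ValueError("noise levels must be >= 0")
        V = np.asarray(self.V2_0, dtype=float)
        if np.any(np.linalg.eigvalsh((V + V.T) / 2) <= 0):
            raise ValueError("prior covariance must be positive definite")


@dataclass
class Trajectory2D:
    """Time-gridded record of a 2D filter run."""

    times: np.ndarray
    mu_phi: np.ndarray
    mu_theta: np.ndarray
    V_pp: np.ndarray
    V_pt: np.ndarray
    V_tt: np.ndarray
    Lambda: np.ndarray
    event_marks: np.ndarray
    warnings: list[str] = field(default_factory=list)


def rate_2d(template: ExpectationTemplate, phase, tempo):
    """Event rate ``tempo * rate_1d(phase)``; negative for negative tempo."""
    from .templates import evaluate_rate

    return np.asarray(tempo, dtype=float) * evaluate_rate(template, phase)


def _tile_for_belief(
    template: ExpectationTemplate, mu_phi: float, sd: float
) -> ExpectationTemplate:
    if template.period is None:
        return template
    pad = (TRUNCATION_SD + 1) * sd
    return tile_periodic(template, mu_phi - pad, mu_phi + pad)


def _moment_match(mu2: np.ndarray, V2: np.ndarray, template: ExpectationTemplate):
    """Exact posterior moments of ``tempo * rate_1d(phase) * N(x; mu2, V2)``.

    Returns ``(x_hat, V_hat, Lambda)`` where ``Lambda`` is the normalizer
    (the subjective hazard).  Per mixture component ``c`` with Gaussian
    ``N(x; m_c, C_c)`` and scalar weight ``z_c``, the tempo-weighted
    unnormalized moments are analytic:

        w_c             = z_c * m_c[theta]
        w_c * mean_c    = z_c * (m_c * m_c[theta] + C_c[:, theta])
        w_c * second_c  = z_c * (m_c[theta] (C_c + m_c m_c^T)
                                 + u m_c^T + m_c u^T),  u = C_c[:, theta]

    so no division by a (possibly non-positive) component tempo mean is
    ever needed; only the total normalizer must be positive.
    """
    template = _tile_for_belief(template, float(mu2[0]), math.sqrt(V2[0, 0]))
    phi, v, lam = template.phi_arr, template.v_arr, template.lam_arr

    comps: list[tuple[float, np.ndarray, np.ndarray]] = []  # (z, m, C)
    if template.lambda_0 > 0:
        comps.append((template.lambda_0, mu2, V2))
    if phi.size:
        total_var = v + V2[0, 0]
        keep = np.abs(mu2[0] - phi) <= TRUNCATION_SD * np.sqrt(total_var)
        for j in np.flatnonzero(keep):
            z = (
                lam[j]
                * math.exp(-0.5 * (mu2[0] - phi[j]) ** 2 / total_var[j])
                / (_SQRT_2PI * math.sqrt(total_var[j]))
            )
            gain = V2[:, 0] / total_var[j]  # Kalman gain for phase observation
            m = mu2 + gain * (phi[j] - mu2[0])
            C = V2 - np.outer(gain, V2[0, :])
            comps.append((z, m, C))

    Lambda = 0.0
    first = np.zeros(2)
    second = np.zeros((2, 2))
    for z, m, C in comps:
        u = C[:, 1]
        Lambda += z * m[1]
        first += z * (m * m[1] + u)
        second += z * (
            m[1] * (C + np.outer(m, m)) + np.outer(u, m) + np.outer(m, u)
        )
    if Lambda <= 0.0:
        raise ValueError(
            "non-positive event normalizer (posterior tempo mass is "
            "dominated by negative tempo or no cause is in range)"
        )
    x_hat = first / Lambda
    V_hat = second / Lambda - np.outer(x_hat, x_hat)
    return x_hat, V_hat, Lambda


def _repair_psd(V: np.ndarray) -> tuple[np.ndarray, bool]:
    V = (V + V.T) / 2.0
    w, Q = np.linalg.eigh(V)
    if w[0] >= EIG_FLOOR:
        return V, False
    w = np.maximum(w, EIG_FLOOR)
    return (Q * w) @ Q.T, True


def event_update_2d(
    belief: GaussianBelief2D, template: ExpectationTemplate
) -> GaussianBelief2D:
    """Moment-matched 2D Gaussian reset applied at an event."""
    x_hat, V_hat, _ = _moment_match(belief.mu2, belief.V2, template)
    V_hat, _ = _repair_psd(V_hat)
    return GaussianBelief2D(mu2=x_hat, V2=V_hat)


def drift_2d(
    belief: GaussianBelief2D,
    template: ExpectationTemplate,
    config: PatippetConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Between-event derivatives ``(dmu2/dt, dV2/dt)``.

    Prior part: phase advances at the mean tempo, covariance follows the
    linear-Gaussian prediction ``A V + V A^T + Q`` with ``A`` coupling
    tempo into phase and ``Q = diag(sigma^2, sigma_theta^2)``.  No-event
    part: ``-Lambda * (x_hat - mu2)`` and ``-Lambda * (V_hat - V2)``,
    the continuous push away from the would-be event posterior.
    """
    mu2, V2 = belief.mu2, belief.V2
    dmu = np.array([mu2[1], 0.0])
    dV = np.array(
        [
            [2.0 * V2[0, 1] + config.sigma**2, V2[1, 1]],
            [V2[1, 1], config.sigma_theta**2],
        ]
    )
    try:
        x_hat, V_hat, Lambda = _moment_match(mu2, V2, template)
    except ValueError:
        return dmu, dV  # no expected cause in range: pure prior drift
    dmu = dmu - Lambda * (x_hat - mu2)
    dV = dV - Lambda * (V_hat - V2)
    return dmu, dV


def run_patippet(
    template: ExpectationTemplate, events: EventStream, config: PatippetConfig
) -> Trajectory2D:
    """Integrate the 2D filter: Euler drift steps plus event resets.

    The covariance is re-symmetrized after every step; negative
    eigenvalues are clamped at ``1e-12`` with a recorded warning.  Runs
    placing more than 1% posterior mass at negative tempo log a warning
    but are not altered (the Gaussian posterior is kept as-is).
    """
    if template.period is not None:
        lo = config.mu2_0[0] - 2.0 - 2 * template.period
        hi = (
            config.mu2_0[0]
            + 2.0 * max(config.mu2_0[1], 1.0) * config.t_end
            + 2 * template.period
            + 2.0
        )
        template = tile_periodic(template, lo, hi)

    n_steps = int(round(config.t_end / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    event_idx = _snap_events_to_grid(events.times, config.dt, n_steps)
    events_at = set(int(i) for i in event_idx)

    mu = np.array(config.mu2_0, dtype=float)
    V = np.array(config.V2_0, dtype=float)
    Q = np.array([[config.sigma**2, 0.0], [0.0, config.sigma_theta**2]])

    out = {
        name: np.empty(n_steps + 1)
        for name in ("mu_phi", "mu_theta", "V_pp", "V_pt", "V_tt", "Lambda")
    }
    run_warnings: list[str] = []
    n_repaired = 0
    neg_tempo_flagged = False

    def record(k: int) -> None:
        out["mu_phi"][k] = mu[0]
        out["mu_theta"][k] = mu[1]
        out["V_pp"][k] = V[0, 0]
        out["V_pt"][k] = V[0, 1]
        out["V_tt"][k] = V[1, 1]
        try:
            _, _, Lam = _moment_match(mu, V, template)
        except ValueError:
            Lam = 0.0
        out["Lambda"][k] = Lam

    def check_neg_tempo() -> None:
        nonlocal neg_tempo_flagged
        if neg_tempo_flagged:
            return
        mass = norm.cdf(-mu[1] / math.sqrt(V[1, 1]))
        if mass > 0.01:
            neg_tempo_flagged = True
            msg = (
                f"posterior places {mass:.1%} mass at negative tempo "
                f"(mu_theta={mu[1]:.4f}, V_tt={V[1, 1]:.4g})"
            )
            run_warnings.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=3)

    if 0 in events_at:
        x_hat, V_hat, _ = _moment_match(mu, V, template)
        mu, (V, rep) = x_hat, _repair_psd(V_hat)
        n_repaired += int(rep)
    record(0)
    check_neg_tempo()

    for k in range(1, n_steps + 1):
        dmu = np.array([mu[1], 0.0])
        dV = np.array([[2.0 * V[0, 1], V[1, 1]], [V[1, 1], 0.0]]) + Q
        try:
            x_hat, V_hat, Lam = _moment_match(mu, V, template)
            dmu = dmu - Lam * (x_hat - mu)
            dV = dV - Lam * (V_hat - V)
        except ValueError:
            pass
        mu = mu + config.dt * dmu
        V, rep = _repair_psd(V + config.dt * dV)
        n_repaired += int(rep)
        if k in events_at:
            x_hat, V_hat, _ = _moment_match(mu, V, template)
            mu = x_hat
            V, rep = _repair_psd(V_hat)
            n_repaired += int(rep)
        record(k)
        check_neg_tempo()

    if n_repaired:
        msg = f"covariance PSD repair applied on {n_repaired} of {n_steps} steps"
        run_warnings.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        if n_repaired > 0.05 * n_steps:
            raise RuntimeError("covariance repeatedly lost PSD: " + msg)

    return Trajectory2D(
        times=times,
        mu_phi=out["mu_phi"],
        mu_theta=out["mu_theta"],
        V_pp=out["V_pp"],
        V_pt=out["V_pt"],
        V_tt=out["V_tt"],
        Lambda=out["Lambda"],
        event_marks=np.unique(event_idx).astype(int),
        warnings=run_warnings,
    )
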