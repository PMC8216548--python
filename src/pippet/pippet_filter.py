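"""Continuous-time Gaussian phase filter driven by point-process events.

The belief over the hidden phase is a 1D Gaussian (mean ``mu``, variance
``V``).  Between events it follows a deterministic ODE; at each event it
is discontinuously reset by moment-matching the product of the current
Gaussian and the expectation template's rate function.  The multi-stream
generalization keeps one template per labelled event stream over a shared
phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .templates import (
    TRUNCATION_SD,
    ExpectationTemplate,
    GaussianPeak,
    tile_periodic,
)

__all__ = [
    "GaussianBelief1D",
    "HazardBundle",
    "EventStream",
    "FilterConfig",
    "FilterTrajectory",
    "candidate_posterior",
    "hazards",
    "event_update",
    "between_event_derivative",
    "run_pippet",
    "run_mpippet",
    "plan_next_tap",
]

V_FLOOR = 1e-12
_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianBelief1D:
    """Gaussian posterior over phase: mean ``mu`` and variance ``V > 0``."""

    mu: float
    V: float

    def __post_init__(self) -> None:
        if not self.V > 0:
            raise ValueError(f"belief variance must be positive, got V={self.V}")


@dataclass(frozen=True)
class HazardBundle:
    """Subjective hazard decomposition at the current belief.

    ``Lambda_total = Lambda_0 + sum of per-peak hazards``; each per-peak
    entry carries the conditional hazard and the candidate posterior that
    would result were the event known to come from that peak.
    """

    Lambda_total: float
    Lambda_0: float
    per_peak: tuple[tuple[float, float, float], ...]  # (Lambda_i, mu_hat_i, V_hat_i)


@dataclass(frozen=True)
class EventStream:
    """Strictly increasing event times, optionally labelled by stream."""

    times: np.ndarray
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("event times must be a 1D array")
        if self.labels is None:
            if times.size > 1 and not np.all(np.diff(times) > 0):
                raise ValueError("event times must be strictly increasing")
        else:
            labels = tuple(str(s) for s in self.labels)
            object.__setattr__(self, "labels", labels)
            if len(labels) != times.size:
                raise ValueError("labels must match times in length")
            # simultaneous events are fine across streams, not within one
            if times.size > 1 and not np.all(np.diff(times) >= 0):
                raise ValueError("event times must be sorted")
            for lab in set(labels):
                sub = times[[l == lab for l in labels]]
                if sub.size > 1 and not np.all(np.diff(sub) > 0):
                    raise ValueError(
                        f"event times must be strictly increasing within "
                        f"stream {lab!r}"
                    )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FilterConfig:
    """Integration step, phase-noise level, prior belief and duration."""

    dt: float = 0.001
    sigma: float = 0.1
    mu0: float = 0.0
    V0: float = 0.0001
    t_end: float = 1.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not self.V0 > 0:
            raise ValueError(f"V0 must be positive, got {self.V0}")


@dataclass
class FilterTrajectory:
    """Time-gridded record of a filter run."""

    times: np.ndarray
    mu: np.ndarray
    V: np.ndarray
    Lambda: np.ndarray
    event_marks: np.ndarray  # grid indices at which events were applied
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.times.size
        for name in ("mu", "V", "Lambda"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match time grid")


def _as_peak_arrays(template: ExpectationTemplate):
    return template.phi_arr, template.v_arr, template.lam_arr


def candidate_posterior(
    belief: GaussianBelief1D, peak: GaussianPeak
) -> tuple[float, float]:
    """Posterior (mean, variance) if the event were known to come from ``peak``.

    Precision-weighted combination of the current belief and the peak:
    ``mu_hat_i = (mu/V + phi_i/v_i) / (1/V + 1/v_i)``,
    ``V_hat_i = 1 / (1/V + 1/v_i)``.
    """
    prec = 1.0 / belief.V + 1.0 / peak.v
    mu_hat = (belief.mu / belief.V + peak.phi / peak.v) / prec
    return mu_hat, 1.0 / prec


def _hazard_terms(mu: float, V: float, template: ExpectationTemplate):
    """Vectorized per-peak hazards and candidate posteriors.

    Returns (Lambda_i, mu_hat_i, V_hat_i) arrays over the template peaks,
    with peaks beyond the truncation radius contributing exactly zero.
    """
    phi, v, lam = _as_peak_arrays(template)
    if phi.size == 0:
        z = np.zeros(0)
        return z, z, z
    total_var = v + V
    Lam = np.zeros_like(phi)
    near = np.abs(mu - phi) <= TRUNCATION_SD * np.sqrt(total_var)
    Lam[near] = (
        lam[near]
        * np.exp(-0.5 * (mu - phi[near]) ** 2 / total_var[near])
        / (_SQRT_2PI * np.sqrt(total_var[near]))
    )
    prec = 1.0 / V + 1.0 / v
    V_hat = 1.0 / prec
    mu_hat = (mu / V + phi / v) / prec
    return Lam, mu_hat, V_hat


def hazards(belief: GaussianBelief1D, template: ExpectationTemplate) -> HazardBundle:
    """Subjective hazard rate and per-peak decomposition.

    Each conditional hazard is the peak strength times a Gaussian density
    with the peak variance inflated by the current phase uncertainty:
    ``Lambda_i = lam_i * N(mu; phi_i, v_i + V)``.  The total includes the
    background: ``Lambda = lambda_0 + sum_i Lambda_i`` (the normalizer of
    the posterior product, so that event-update weights sum to one).
    """
    if template.period is not None:
        lo = belief.mu - (TRUNCATION_SD + 1) * math.sqrt(belief.V)
        hi = belief.mu + (TRUNCATION_SD + 1) * math.sqrt(belief.V)
        template = tile_periodic(template, lo, hi)
    Lam, mu_hat, V_hat = _hazard_terms(belief.mu, belief.V, template)
    total = template.lambda_0 + float(np.sum(Lam))
    per_peak = tuple(
        (float(L), float(m), float(vv)) for L, m, vv in zip(Lam, mu_hat, V_hat)
    )
    return HazardBundle(
        Lambda_total=total, Lambda_0=template.lambda_0, per_peak=per_peak
    )


def _posterior_moments(mu: float, V: float, template: ExpectationTemplate):
    """Moment-matched posterior (mu_plus, V_plus, Lambda_total) at an event.

    The event posterior is proportional to ``rate(phi) * N(phi; mu, V)``;
    its exact mean and variance are a hazard-weighted mixture of the prior
    (background cause) and the per-peak candidate posteriors, with
    between-cause dispersion terms inflating the variance.  The mean is
    computed before the variance, which depends on it.
    """
    Lam, mu_hat, V_hat = _hazard_terms(mu, V, template)
    total = template.lambda_0 + float(np.sum(Lam))
    if total <= 0.0:
        raise ValueError(
            "event has zero subjective hazard under the template "
            "(lambda_0 = 0 and no peak within range); set lambda_0 > 0 "
            "to give stray events a background cause"
        )
    w0 = template.lambda_0 / total
    w = Lam / total
    mu_plus = w0 * mu + float(np.sum(w * mu_hat))
    V_plus = w0 * (V + (mu - mu_plus) ** 2) + float(
        np.sum(w * (V_hat + (mu_hat - mu_plus) ** 2))
    )
    return mu_plus, V_plus, total


def event_update(
    belief: GaussianBelief1D, template: ExpectationTemplate
) -> GaussianBelief1D:
    """Discontinuous belief reset applied when an event is observed."""
    if template.period is not None:
        lo = belief.mu - (TRUNCATION_SD + 1) * math.sqrt(belief.V)
        hi = belief.mu + (TRUNCATION_SD + 1) * math.sqrt(belief.V)
        template = tile_periodic(template, lo, hi)
    mu_plus, V_plus, _ = _posterior_moments(belief.mu, belief.V, template)
    return GaussianBelief1D(mu=mu_plus, V=max(V_plus, V_FLOOR))


def between_event_derivative(
    belief: GaussianBelief1D, template: ExpectationTemplate, sigma: float
) -> tuple[float, float]:
    """Time derivatives (dmu/dt, dV/dt) of the belief while no event occurs.

    dmu/dt = 1 - Lambda * (mu_hat - mu)
    dV/dt  = sigma^2 - Lambda * (V_hat - V)

    where (mu_hat, V_hat) is the would-be event posterior: the absence of
    an event pushes the belief opposite to the push an event would give.
    """
    if template.period is not None:
        lo = belief.mu - (TRUNCATION_SD + 1) * math.sqrt(belief.V)
        hi = belief.mu + (TRUNCATION_SD + 1) * math.sqrt(belief.V)
        template = tile_periodic(template, lo, hi)
    Lam, mu_hat, V_hat = _hazard_terms(belief.mu, belief.V, template)
    total = template.lambda_0 + float(np.sum(Lam))
    if total <= 0.0:
        return 1.0, sigma**2
    w0 = template.lambda_0 / total
    w = Lam / total
    mu_plus = w0 * belief.mu + float(np.sum(w * mu_hat))
    V_plus = w0 * (belief.V + (belief.mu - mu_plus) ** 2) + float(
        np.sum(w * (V_hat + (mu_hat - mu_plus) ** 2))
    )
    dmu = 1.0 - total * (mu_plus - belief.mu)
    dV = sigma**2 - total * (V_plus - belief.V)
    return dmu, dV


def _snap_events_to_grid(times: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    idx = np.rint(np.asarray(times, dtype=float) / dt).astype(int)
    if np.any(idx < 0) or np.any(idx > n_steps):
        raise ValueError("event outside the [0, t_end] integration window")
    return idx


def _prepare(template: ExpectationTemplate, config: FilterConfig) -> ExpectationTemplate:
    """Tile periodic templates over the phase range a run can visit."""
    if template.period is None:
        return template
    lo = config.mu0 - 1.0 - 2 * template.period
    hi = config.mu0 + config.t_end + 1.0 + 2 * template.period
    return tile_periodic(template, lo, hi)


def run_pippet(
    template: ExpectationTemplate, events: EventStream, config: FilterConfig
) -> FilterTrajectory:
    """Integrate the phase filter over ``[0, t_end]``.

    Explicit Euler on a uniform ``dt`` grid; event times are snapped to
    the nearest grid point (error <= dt/2) and the event update is applied
    after the drift step for that bin.
    """
    return run_mpippet({"default": _prepare(template, config)}, events, config)


def run_mpippet(
    templates: Mapping[str, ExpectationTemplate],
    events: EventStream,
    config: FilterConfig,
) -> FilterTrajectory:
    """Multi-stream filter run: one expectation template per event label.

    Between events the drift corrections from all streams add; an event in
    stream ``j`` resets the belief using template ``j`` alone.
    """
    templates = {k: _prepare(t, config) for k, t in templates.items()}
    stream_names = list(templates)
    if events.labels is None:
        if len(templates) > 1:
            raise ValueError(
                "unlabelled events are ambiguous with multiple templates; "
                "label each event with its stream"
            )
        labels = [stream_names[0]] * len(events)
    else:
        labels = list(events.labels)
        unknown = set(labels) - set(stream_names)
        if unknown:
            raise ValueError(f"event labels without a template: {sorted(unknown)}")

    n_steps = int(round(config.t_end / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    event_idx = _snap_events_to_grid(events.times, config.dt, n_steps)
    events_at: dict[int, list[str]] = {}
    for idx, lab in zip(event_idx, labels):
        events_at.setdefault(int(idx), []).append(lab)

    mu = np.empty(n_steps + 1)
    V = np.empty(n_steps + 1)
    Lambda = np.empty(n_steps + 1)
    mu_t, V_t = config.mu0, config.V0
    sigma2 = config.sigma**2
    run_warnings: list[str] = []
    n_clamped = 0

    def total_hazard(m: float, vv: float) -> float:
        tot = 0.0
        for tmpl in templates.values():
            Lam, _, _ = _hazard_terms(m, vv, tmpl)
            tot += tmpl.lambda_0 + float(np.sum(Lam))
        return tot

    mu[0], V[0] = mu_t, V_t
    # events snapped to grid index 0 are applied before any drift
    for lab in events_at.get(0, []):
        mu_t, V_t, _ = _posterior_moments(mu_t, V_t, templates[lab])
        V_t = max(V_t, V_FLOOR)
        mu[0], V[0] = mu_t, V_t
    Lambda[0] = total_hazard(mu_t, V_t)

    for k in range(1, n_steps + 1):
        dmu, dV = 1.0, sigma2
        for tmpl in templates.values():
            Lam, mu_hat, V_hat = _hazard_terms(mu_t, V_t, tmpl)
            tot = tmpl.lambda_0 + float(np.sum(Lam))
            if tot <= 0.0:
                continue
            w0 = tmpl.lambda_0 / tot
            w = Lam / tot
            mu_plus = w0 * mu_t + float(np.sum(w * mu_hat))
            V_plus = w0 * (V_t + (mu_t - mu_plus) ** 2) + float(
                np.sum(w * (V_hat + (mu_hat - mu_plus) ** 2))
            )
            dmu -= tot * (mu_plus - mu_t)
            dV -= tot * (V_plus - V_t)
        mu_t += config.dt * dmu
        V_t += config.dt * dV
        if V_t < V_FLOOR:
            V_t = V_FLOOR
            n_clamped += 1
        for lab in events_at.get(k, []):
            mu_t, V_t, _ = _posterior_moments(mu_t, V_t, templates[lab])
            V_t = max(V_t, V_FLOOR)
        mu[k], V[k] = mu_t, V_t
        Lambda[k] = total_hazard(mu_t, V_t)

    if n_clamped:
        msg = (
            f"variance clamped at floor {V_FLOOR:g} on {n_clamped} of "
            f"{n_steps} steps (dt={config.dt}, sigma={config.sigma})"
        )
        run_warnings.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        if n_clamped > 0.01 * n_steps:
            raise RuntimeError(
                "persistent variance collapse: " + msg + "; reduce dt or raise sigma"
            )

    marks = np.unique(event_idx).astype(int)
    return FilterTrajectory(
        times=times, mu=mu, V=V, Lambda=Lambda, event_marks=marks,
        warnings=run_warnings,
    )


def plan_next_tap(
    belief: GaussianBelief1D,
    tap_template: ExpectationTemplate,
    now: float,
    horizon: float = 10.0,
) -> float:
    """Time at which the mean phase reaches the next expected tap phase.

    Extrapolates ``mu`` forward at unit rate and returns
    ``now + (next tap-peak phase - mu)``.  A belief sitting exactly on a
    tap phase schedules the following peak, never an instantaneous tap.
    """
    if tap_template.period is not None:
        tap_template = tile_periodic(
            tap_template, belief.mu, belief.mu + horizon
        )
    future = [p.phi for p in tap_template.peaks if p.phi > belief.mu]
    future = [p for p in future if p - belief.mu <= horizon]
    if not future:
        raise ValueError(
            f"no tap peak within horizon {horizon} ahead of mu={belief.mu}"
        )
    return now + (min(future) - belief.mu)
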