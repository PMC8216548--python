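"""Generative simulation and deterministic stimulus construction.

Simulates the hidden drift-diffusion phase (and tempo) paths and the
inhomogeneous point process that emits events at template-expected
phases, and builds the deterministic event sequences (metronomes, shifted
and omitted variants, grid rhythms) used by the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .patippet_filter import PatippetConfig
from .pippet_filter import EventStream
from .templates import ExpectationTemplate, evaluate_rate

__all__ = [
    "SimWorld",
    "simulate_phase_path",
    "simulate_events",
    "simulate_patippet_world",
    "metronome",
    "event_shift",
    "phase_shift",
    "omission",
    "grid_rhythm",
    "build_stimulus",
]

#: Per-bin event probability above which Bernoulli thinning is refused.
MAX_BIN_PROB = 0.1


@dataclass(frozen=True)
class SimWorld:
    """A simulated hidden path plus the events it emitted."""

    times: np.ndarray
    true_phase: np.ndarray
    true_tempo: np.ndarray
    events: EventStream
    seed: int


def simulate_phase_path(
    sigma: float, dt: float, t_end: float, seed: int, phi0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama drift-diffusion phase path.

    ``phi(t + dt) = phi(t) + dt + sigma * sqrt(dt) * z`` with unit drift
    and standard-normal increments ``z``.  Returns ``(times, phi)``.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    increments = dt + sigma * np.sqrt(dt) * rng.standard_normal(n)
    phi = np.concatenate([[phi0], phi0 + np.cumsum(increments)])
    return times, phi


def simulate_events(
    path: np.ndarray,
    template: ExpectationTemplate,
    dt: float,
    seed: int,
    tempo_path: Optional[np.ndarray] = None,
) -> EventStream:
    """Thin a point process from a phase path by per-bin Bernoulli draws.

    Each grid bin emits at most one event, with probability
    ``rate(phi) * dt`` (scaled by tempo when a tempo path is given).
    Refuses to run if any bin probability reaches ``MAX_BIN_PROB``, where
    the one-event-per-bin approximation breaks down.
    """
    phi = np.asarray(path, dtype=float)
    rate = np.asarray(evaluate_rate(template, phi), dtype=float)
    if tempo_path is not None:
        rate = rate * np.asarray(tempo_path, dtype=float)
    prob = rate * dt
    if np.any(prob >= MAX_BIN_PROB):
        raise ValueError(
            f"per-bin event probability reaches {prob.max():.3f} >= "
            f"{MAX_BIN_PROB}; use a smaller dt"
        )
    rng = np.random.default_rng(seed)
    hits = rng.random(phi.size) < prob
    times = np.flatnonzero(hits) * dt
    return EventStream(times=times.astype(float))


def simulate_patippet_world(
    config: PatippetConfig, template: ExpectationTemplate, seed: int
) -> SimWorld:
    """Simulate the joint phase/tempo generative model.

    Tempo diffuses with level ``sigma_theta`` around its initial value;
    phase advances at the instantaneous tempo with phase noise ``sigma``;
    events are thinned at rate ``tempo * rate(phase)``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(config.t_end / config.dt))
    times = np.arange(n + 1) * config.dt
    sqdt = np.sqrt(config.dt)
    theta = np.empty(n + 1)
    phi = np.empty(n + 1)
    phi[0] = config.mu2_0[0]
    theta[0] = config.mu2_0[1]
    z_phi = rng.standard_normal(n)
    z_theta = rng.standard_normal(n)
    for k in range(n):
        theta[k + 1] = theta[k] + config.sigma_theta * sqdt * z_theta[k]
        phi[k + 1] = phi[k] + theta[k] * config.dt + config.sigma * sqdt * z_phi[k]
    events = simulate_events(
        phi, template, config.dt, seed=seed + 1, tempo_path=theta
    )
    return SimWorld(
        times=times, true_phase=phi, true_tempo=theta, events=events, seed=seed
    )


# -- deterministic stimulus builders ----------------------------------------


def metronome(ioi: float, n: int, start: float = 0.0) -> EventStream:
    """``n`` isochronous events spaced ``ioi`` apart."""
    if not ioi > 0:
        raise ValueError("ioi must be positive")
    return EventStream(times=start + ioi * np.arange(n))


def event_shift(base: EventStream, index: int, delta: float) -> EventStream:
    """Move a single event by ``delta`` (negative = earlier)."""
    times = base.times.copy()
    if not 0 <= index < times.size:
        raise IndexError(f"event index {index} out of range")
    times[index] += delta
    return EventStream(times=times, labels=base.labels)


def phase_shift(base: EventStream, from_index: int, delta: float) -> EventStream:
    """Move all events from ``from_index`` onward by ``delta``."""
    times = base.times.copy()
    if not 0 <= from_index < times.size:
        raise IndexError(f"event index {from_index} out of range")
    times[from_index:] += delta
    return EventStream(times=times, labels=base.labels)


def omission(base: EventStream, indices: Sequence[int]) -> EventStream:
    """Drop the events at the given indices."""
    idx = sorted(set(int(i) for i in indices))
    if idx and (idx[0] < 0 or idx[-1] >= base.times.size):
        raise IndexError(f"omission indices {idx} out of range")
    keep = np.ones(base.times.size, dtype=bool)
    keep[idx] = False
    labels = None
    if base.labels is not None:
        labels = tuple(l for l, k in zip(base.labels, keep) if k)
    return EventStream(times=base.times[keep], labels=labels)


def grid_rhythm(
    grid_template: ExpectationTemplate,
    occupancy: Sequence[int],
    n_cycles: Optional[int] = None,
) -> EventStream:
    """Place events at occupied grid positions of a (tiled) template.

    The grid positions are the template peak means in order (tiled over
    ``n_cycles`` copies for periodic templates); ``occupancy`` lists the
    position indices that carry an event.
    """
    if grid_template.period is not None:
        if n_cycles is None:
            raise ValueError("n_cycles required for a periodic grid template")
        from .templates import tile_periodic

        grid_template = tile_periodic(
            grid_template, 0.0, n_cycles * grid_template.period - 1e-9
        )
        positions = [p.phi for p in grid_template.peaks if p.phi >= 0]
    else:
        positions = [p.phi for p in grid_template.peaks]
    occupancy = list(occupancy)
    if occupancy and (min(occupancy) < 0 or max(occupancy) >= len(positions)):
        raise IndexError("occupancy index out of grid range")
    return EventStream(times=np.array(sorted(positions[i] for i in occupancy)))


_BUILDERS = {
    "metronome": metronome,
    "event_shift": event_shift,
    "phase_shift": phase_shift,
    "omission": omission,
    "grid_rhythm": grid_rhythm,
}


def build_stimulus(spec: dict) -> EventStream:
    """Build a deterministic stimulus from a ``{"builder": ..., ...}`` dict.

    Nested dicts with a ``builder`` key are built recursively, so shifted
    variants can wrap their base stimulus inline.
    """
    spec = dict(spec)
    try:
        name = spec.pop("builder")
    except KeyError:
        raise ValueError("stimulus spec needs a 'builder' key") from None
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown stimulus builder {name!r}; options: {sorted(_BUILDERS)}"
        ) from None
    kwargs = {
        k: build_stimulus(v) if isinstance(v, dict) and "builder" in v else v
        for k, v in spec.items()
    }
    return builder(**kwargs)
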