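"""Expectation templates: background rate plus Gaussian peaks over phase.

A template specifies the phase-dependent event rate (hazard)

    rate(phi) = lambda_0 + sum_i lambda_i * N(phi; phi_i, v_i)

where ``N`` is the Gaussian density.  Phase is measured in
seconds-at-nominal-tempo, so peak positions share units with event times.
Templates may be periodic (peaks tile the real line with a fixed period)
or aperiodic (an explicit finite list of peaks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "GaussianPeak",
    "ExpectationTemplate",
    "evaluate_rate",
    "tile_periodic",
    "make_isochronous_template",
    "make_swing_template",
]

#: Peaks contribute only within this many standard deviations of their mean.
#: exp(-8**2 / 2) ~ 1.3e-14, far below any tolerance used here.
TRUNCATION_SD = 8.0


@dataclass(frozen=True)
class GaussianPeak:
    """One Gaussian expectation peak.

    Parameters
    ----------
    phi : float
        Expected event phase (phase units).
    v : float
        Temporal variance of the expectation (phase units squared).
    lam : float
        Expectation strength (scale of the rate contribution).
    """

    phi: float
    v: float
    lam: float

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError(f"peak variance must be positive, got v={self.v}")
        if self.lam < 0:
            raise ValueError(f"peak strength must be >= 0, got lam={self.lam}")


@dataclass(frozen=True)
class ExpectationTemplate:
    """Background-plus-Gaussian-mixture event rate over phase.

    Parameters
    ----------
    lambda_0 : float
        Background event rate (events per unit phase, >= 0).
    peaks : sequence of GaussianPeak
        Expectation peaks with strictly increasing means (within one
        period for periodic templates).
    period : float, optional
        Repetition period for periodic tiling; ``None`` for aperiodic
        templates.
    """

    lambda_0: float
    peaks: tuple[GaussianPeak, ...] = field(default_factory=tuple)
    period: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if self.lambda_0 < 0:
            raise ValueError(f"lambda_0 must be >= 0, got {self.lambda_0}")
        means = [p.phi for p in self.peaks]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("peak means must be strictly increasing")
        if self.period is not None:
            if not self.period > 0:
                raise ValueError(f"period must be positive, got {self.period}")
            if any(not (0 <= m < self.period) for m in means):
                raise ValueError("periodic template peaks must lie in [0, period)")

    # -- array views used by the filters ------------------------------------

    @property
    def phi_arr(self) -> np.ndarray:
        return np.array([p.phi for p in self.peaks], dtype=float)

    @property
    def v_arr(self) -> np.ndarray:
        return np.array([p.v for p in self.peaks], dtype=float)

    @property
    def lam_arr(self) -> np.ndarray:
        return np.array([p.lam for p in self.peaks], dtype=float)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "lambda_0": self.lambda_0,
            "peaks": [{"phi": p.phi, "v": p.v, "lam": p.lam} for p in self.peaks],
        }
        if self.period is not None:
            d["period"] = self.period
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExpectationTemplate":
        peaks = tuple(
            GaussianPeak(phi=float(p["phi"]), v=float(p["v"]), lam=float(p["lam"]))
            for p in d.get("peaks", [])
        )
        period = d.get("period")
        return cls(
            lambda_0=float(d["lambda_0"]),
            peaks=peaks,
            period=None if period is None else float(period),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExpectationTemplate":
        return cls.from_dict(yaml.safe_load(text))


def _gauss_pdf(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2.0 * math.pi * var)


def evaluate_rate(template: ExpectationTemplate, phase) -> np.ndarray | float:
    """Evaluate the event rate ``lambda(phase)``.

    For periodic templates the Gaussian-mixture sum runs over all tiled
    copies of each peak whose mean lies within ``TRUNCATION_SD`` standard
    deviations of the query phase.
    """
    phase_arr = np.asarray(phase, dtype=float)
    out = np.full(phase_arr.shape, template.lambda_0, dtype=float)
    for peak in template.peaks:
        half_width = TRUNCATION_SD * math.sqrt(peak.v)
        if template.period is None:
            mask = np.abs(phase_arr - peak.phi) <= half_width
            if np.any(mask):
                out[mask] += peak.lam * _gauss_pdf(phase_arr[mask], peak.phi, peak.v)
        else:
            # nearest periodic copies of the peak for each query point
            k_lo = np.floor((phase_arr - peak.phi - half_width) / template.period)
            k_hi = np.ceil((phase_arr - peak.phi + half_width) / template.period)
            n_copies = int(np.max(k_hi - k_lo)) + 1 if phase_arr.size else 0
            for j in range(n_copies):
                centers = peak.phi + (k_lo + j) * template.period
                mask = np.abs(phase_arr - centers) <= half_width
                if np.any(mask):
                    out[mask] += peak.lam * _gauss_pdf(
                        phase_arr[mask], centers[mask], peak.v
                    )
    if np.isscalar(phase) or np.ndim(phase) == 0:
        return float(out)
    return out


def tile_periodic(
    template: ExpectationTemplate, phase_lo: float, phase_hi: float
) -> ExpectationTemplate:
    """Unroll a periodic template into an aperiodic one covering a range.

    The result carries every periodic peak copy whose mean falls in
    ``[phase_lo - margin, phase_hi + margin]``; ``evaluate_rate`` of the
    result agrees with the periodic original on ``[phase_lo, phase_hi]``
    to within the truncation tolerance.
    """
    if template.period is None:
        raise ValueError("tile_periodic requires a periodic template")
    if not phase_lo < phase_hi:
        raise ValueError("phase_lo must be < phase_hi")
    period = template.period
    peaks: list[GaussianPeak] = []
    for peak in template.peaks:
        margin = TRUNCATION_SD * math.sqrt(peak.v)
        k_lo = math.floor((phase_lo - margin - peak.phi) / period)
        k_hi = math.ceil((phase_hi + margin - peak.phi) / period)
        for k in range(k_lo, k_hi + 1):
            center = peak.phi + k * period
            if phase_lo - margin <= center <= phase_hi + margin:
                peaks.append(GaussianPeak(phi=center, v=peak.v, lam=peak.lam))
    peaks.sort(key=lambda p: p.phi)
    return ExpectationTemplate(lambda_0=template.lambda_0, peaks=tuple(peaks))


def make_isochronous_template(
    period: float,
    n_or_range,
    strength: float = 1.0,
    variance: float = 0.001,
    lambda_0: float = 0.01,
    periodic: bool = False,
) -> ExpectationTemplate:
    """Metronomic template: identical peaks at 0, period, 2*period, ...

    ``n_or_range`` is either an integer count of peaks or a ``(lo, hi)``
    phase range to fill.  With ``periodic=True`` a single-peak periodic
    template is returned instead (``n_or_range`` ignored).
    """
    if not period > 0:
        raise ValueError(f"period must be positive, got {period}")
    if not variance > 0:
        raise ValueError(f"variance must be positive, got {variance}")
    if periodic:
        return ExpectationTemplate(
            lambda_0=lambda_0,
            peaks=(GaussianPeak(phi=0.0, v=variance, lam=strength),),
            period=period,
        )
    if isinstance(n_or_range, (tuple, list)):
        lo, hi = n_or_range
        first = math.ceil(lo / period)
        last = math.floor(hi / period)
        positions = [k * period for k in range(first, last + 1)]
    else:
        positions = [k * period for k in range(int(n_or_range))]
    peaks = tuple(GaussianPeak(phi=p, v=variance, lam=strength) for p in positions)
    return ExpectationTemplate(lambda_0=lambda_0, peaks=peaks)


def make_swing_template(
    cycle: float,
    swing_ratio: tuple[float, float],
    strong: tuple[float, float],
    weak: tuple[float, float],
    lambda_0: float = 0.01,
    n_cycles: Optional[int] = None,
) -> ExpectationTemplate:
    """Swung-eighth-note template: alternating strong/weak peaks.

    Each cycle holds one pair of expected events: a strong peak at the
    start of the cycle and a weak peak after the long sub-interval.  For
    a ``(a, b)`` swing ratio the weak peak sits ``a / (a + b)`` of the
    cycle after the strong one (3:2 puts it at 0.6 of the cycle).

    ``strong`` and ``weak`` are ``(lam, v)`` pairs.  With ``n_cycles``
    given, an aperiodic template covering that many cycles is built;
    otherwise the template is periodic with period ``cycle``.
    """
    a, b = swing_ratio
    if a <= 0 or b <= 0:
        raise ValueError(f"degenerate swing ratio {swing_ratio}")
    if not cycle > 0:
        raise ValueError(f"cycle must be positive, got {cycle}")
    offset = cycle * a / (a + b)
    lam_s, v_s = strong
    lam_w, v_w = weak
    if n_cycles is None:
        peaks = (
            GaussianPeak(phi=0.0, v=v_s, lam=lam_s),
            GaussianPeak(phi=offset, v=v_w, lam=lam_w),
        )
        return ExpectationTemplate(lambda_0=lambda_0, peaks=peaks, period=cycle)
    peaks_list: list[GaussianPeak] = []
    for k in range(int(n_cycles)):
        peaks_list.append(GaussianPeak(phi=k * cycle, v=v_s, lam=lam_s))
        peaks_list.append(GaussianPeak(phi=k * cycle + offset, v=v_w, lam=lam_w))
    return ExpectationTemplate(lambda_0=lambda_0, peaks=tuple(peaks_list))
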