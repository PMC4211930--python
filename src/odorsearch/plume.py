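"""Turbulent-plume encounter model.

Far downwind from a source that sheds discrete odor patches into a turbulent
flow, an agent does not perceive a smooth concentration gradient: it
experiences rare, intermittent patch encounters.  The standard idealization
treats the encounters of an agent of linear size ``a`` as an inhomogeneous
Poisson process whose mean rate depends only on the agent's position relative
to the source.  In two dimensions, for a source emitting ``R0`` patches per
second with lifetime ``tau``, effective diffusivity ``D`` and a mean wind of
speed ``V`` blowing in the -y direction, the rate is

    R(r | r0) = R0 / ln(lambda / a)
                * exp((y0 - y) * V / (2 D))
                * K0(|r - r0| / lambda)

with the plume correlation length

    lambda = sqrt( D tau / (1 + V^2 tau / (4 D)) )

and ``K0`` the modified Bessel function of the second kind, order zero.  The
exponential advection factor enhances the rate *downwind* of the source
(between source and a searcher starting downwind) relative to equidistant
upwind positions; ``K0`` provides the overall radial decay.

This field plays two roles in the package: it is the likelihood model of the
infotaxis agent, and — Poissonized by :func:`sample_detections` — the
synthetic environment in which all simulated trials run (standing in for the
moth antenna that registered detections in the original robotic assay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import k0e as _bessel_k0e

__all__ = [
    "PlumeParams",
    "DoseLevel",
    "DOSE_LEVELS",
    "get_dose",
    "correlation_length",
    "mean_detection_rate",
    "sample_detections",
    "plume_contour",
]


@dataclass(frozen=True)
class PlumeParams:
    """Physical parameters of the mean encounter-rate field.

    Parameters
    ----------
    emission_rate
        Patch emission rate ``R0`` (encounters/s scale factor).
    patch_lifetime
        Patch lifetime ``tau`` in seconds.
    diffusivity
        Effective (turbulent) diffusivity ``D`` in m^2/s.
    wind_speed
        Mean wind speed ``V`` in m/s; the wind blows toward -y.
    agent_size
        Linear size ``a`` of the searching agent in m.  Must be smaller than
        the correlation length so that ``ln(lambda/a) > 0``.
    source_pos
        Source location ``(x, y)`` in m.
    """

    emission_rate: float = 0.5
    patch_lifetime: float = 400.0
    diffusivity: float = 0.01
    wind_speed: float = 0.88
    agent_size: float = 0.01
    source_pos: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        for name in ("emission_rate", "patch_lifetime", "diffusivity", "agent_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.wind_speed < 0:
            raise ValueError("wind_speed must be non-negative")
        lam = _corr_length(
            self.diffusivity, self.patch_lifetime, self.wind_speed
        )
        if lam <= self.agent_size:
            raise ValueError(
                f"agent_size ({self.agent_size}) must be smaller than the "
                f"correlation length ({lam:.4g}) so that ln(lambda/a) > 0"
            )

    def with_emission_rate(self, emission_rate: float) -> "PlumeParams":
        return replace(self, emission_rate=emission_rate)


@dataclass(frozen=True)
class DoseLevel:
    """A stimulation dose: a multiplier on R0 plus a position-independent
    false-detection rate (events/s) emulating spurious sensor events."""

    label: str
    emission_scale: float
    false_detection_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.emission_scale < 0:
            raise ValueError("emission_scale must be >= 0")
        if self.false_detection_rate < 0:
            raise ValueError("false_detection_rate must be >= 0")


#: Default dose table.  The three stimulated doses mirror the 0.1/0.3/1
#: microgram-per-microliter solutions of the original assay, but the
#: *effective* encounter-rate multipliers saturate (1/2/3 rather than the
#: 10-fold solution ratio): antennal detection-event rates rise strongly
#: sublinearly with dose.  'none' emits nothing and produces only false
#: detections.
DOSE_LEVELS: dict[str, DoseLevel] = {
    "none": DoseLevel("none", 0.0),
    "minimum": DoseLevel("minimum", 1.0),
    "medium": DoseLevel("medium", 2.0),
    "maximum": DoseLevel("maximum", 3.0),
}

_DOSE_ALIASES = {"min": "minimum", "med": "medium", "max": "maximum", "no": "none"}


def get_dose(label: str) -> DoseLevel:
    """Look up a dose level by label ('none'/'minimum'/'medium'/'maximum',
    with 'min'/'med'/'max' accepted as aliases)."""
    key = _DOSE_ALIASES.get(label, label)
    try:
        return DOSE_LEVELS[key]
    except KeyError:
        raise KeyError(f"unknown dose label {label!r}") from None


def _corr_length(D: float, tau: float, V: float) -> float:
    return math.sqrt(D * tau / (1.0 + V * V * tau / (4.0 * D)))


def correlation_length(params: PlumeParams) -> float:
    """Plume correlation length lambda = sqrt(D tau / (1 + V^2 tau / 4D)), m."""
    return _corr_length(
        params.diffusivity, params.patch_lifetime, params.wind_speed
    )


def mean_detection_rate(pos, params: PlumeParams):
    """Mean patch-encounter rate at ``pos`` (encounters/s).

    ``pos`` is an array-like of shape (..., 2); the result has shape (...,).
    The singularity of K0 at the source is regularized by capping the distance
    from below at the agent size ``a`` (a physical sensor has finite extent).
    """
    pos = np.asarray(pos, dtype=float)
    x0, y0 = params.source_pos
    dx = pos[..., 0] - x0
    dy = pos[..., 1] - y0
    lam = correlation_length(params)
    dist = np.hypot(dx, dy)
    dist = np.maximum(dist, params.agent_size)
    prefactor = params.emission_rate / math.log(lam / params.agent_size)
    # exp(-dy V/2D) K0(d/lam) evaluated as k0e(d/lam) exp(-(d/lam + dy V/2D));
    # the exponent is always <= 0 because 1/lam >= V/2D and d >= |dy|, so the
    # advection factor can never overflow however sharp the plume.
    exponent = -(dist / lam + dy * params.wind_speed / (2.0 * params.diffusivity))
    return prefactor * _bessel_k0e(dist / lam) * np.exp(exponent)


def sample_detections(pos, dt: float, dose: DoseLevel, params: PlumeParams,
                      rng: np.random.Generator) -> int:
    """Draw a Poisson detection count for a dwell of ``dt`` seconds at ``pos``.

    The rate is ``emission_scale * R(pos) + false_detection_rate``; for the
    'none' dose only false detections remain.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rate = dose.false_detection_rate
    if dose.emission_scale > 0:
        rate = rate + dose.emission_scale * float(mean_detection_rate(pos, params))
    return int(rng.poisson(rate * dt))


def plume_contour(detections, source_y: float = 2.0, coverage: float = 0.9) -> float:
    """Fit the parabolic plume contour x^2 <= c (y_source - y).

    Returns the smallest c >= 0 such that the parabola contains at least
    ``coverage`` (default 90%) of the detection points, all of which must lie
    at or downwind of the source (y <= y_source).
    """
    pts = np.asarray(detections, dtype=float)
    if pts.size == 0:
        raise ValueError("plume_contour requires at least one detection point")
    pts = pts.reshape(-1, 2)
    if len(pts) < 10:
        raise ValueError("plume_contour requires at least 10 detection points")
    depth = source_y - pts[:, 1]
    if np.any(depth < 0):
        raise ValueError("all detection points must satisfy y <= y_source")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            depth > 0,
            pts[:, 0] ** 2 / np.where(depth > 0, depth, 1.0),
            np.where(pts[:, 0] == 0.0, 0.0, np.inf),
        )
    order = np.sort(ratio)
    k = math.ceil(coverage * len(order))
    return float(order[k - 1])
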