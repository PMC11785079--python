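"""Log-Gaussian spatial-frequency tuning: 1D per-bin curves and the 2D map model.

The core object is a log-Gaussian tuning curve over spatial period
(degrees/cycle): the predicted response is ``A * exp(-(log2 p_l - log2 p_v)**2
/ (2 * sigma**2))``, with the bandwidth sigma the standard deviation of the
Gaussian in octaves (log base 2 throughout; natural-log variants are not
used anywhere in the package).

The 2D map model describes tuning across an entire retinotopic map with 9
parameters. The preferred period of a vertex at eccentricity r_v and polar
angle theta_v, probed at local stimulus orientation theta_l, is

    p_v = (a*r_v + b) * (1 + p1*cos(2*theta_l) + p2*cos(4*theta_l)
                           + p3*cos(2*(theta_l - theta_v))
                           + p4*cos(4*(theta_l - theta_v)))

and the response gain is ``A_v = 1 + A1*cos(2*theta_l) + A2*cos(4*theta_l)``.
Positive p1/A1 mean larger period/amplitude for vertical than horizontal
orientations; positive p2/A2 mean cardinal > oblique; positive p3 means
annulus (radial) > pinwheel (tangential); positive p4 means non-spirals >
spirals. Amplitude is not allowed to vary with relative orientation. A single
sigma is shared across the whole map.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from .stimuli import LocalStimulus

__all__ = [
    "LOG2_FWHM_FACTOR",
    "Model2DParams",
    "TuningCurve1D",
    "VertexLocation",
    "amplitude_gain",
    "fwhm_octaves",
    "log_gaussian_response",
    "predict_matrix",
    "predict_response",
    "preferred_period",
]

#: FWHM of a Gaussian in units of its standard deviation.
LOG2_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Ordered JSON/array key set for the 9 map parameters (interchange format).
PARAM_KEYS = ("sigma", "slope", "intercept", "p1", "p2", "p3", "p4", "A1", "A2")


@dataclass(frozen=True)
class VertexLocation:
    """pRF center of one cortical-surface vertex."""

    ecc_deg: float
    angle_rad: float
    prf_size_deg: float

    def __post_init__(self) -> None:
        if self.ecc_deg < 0:
            raise ValueError("ecc_deg must be >= 0")
        if self.prf_size_deg <= 0:
            raise ValueError("prf_size_deg must be > 0")


@dataclass(frozen=True)
class TuningCurve1D:
    """Log-Gaussian tuning fit for one eccentricity bin."""

    bin_center_deg: float
    gain_A: float
    p_peak_dpc: float
    sigma_oct: float

    def __post_init__(self) -> None:
        if self.p_peak_dpc <= 0:
            raise ValueError("p_peak_dpc must be > 0")
        if self.sigma_oct <= 0:
            raise ValueError("sigma_oct must be > 0")

    @property
    def fwhm_oct(self) -> float:
        return fwhm_octaves(self.sigma_oct)


@dataclass(frozen=True)
class Model2DParams:
    """The 9 parameters of the 2D spatial-frequency map model.

    sigma : bandwidth in octaves (SD of the log2-period Gaussian), shared
        across the map.
    slope, intercept : affine dependence of preferred period (deg/cycle) on
        eccentricity (deg); base period is slope*r + intercept.
    p1..p4 : dimensionless orientation modulations of preferred period
        (vertical>horizontal, cardinal>oblique, annulus>pinwheel,
        non-spirals>spirals for positive values).
    A1, A2 : dimensionless orientation modulations of response amplitude
        (vertical>horizontal, cardinal>oblique for positive values).

    The container enforces ``|p1|+|p2|+|p3|+|p4| < 1`` and ``|A1|+|A2| < 1``
    so that periods and gains stay positive everywhere; fitted values in
    practice are an order of magnitude inside these bounds.
    """

    sigma: float
    slope: float
    intercept: float
    p1: float = 0.0
    p2: float = 0.0
    p3: float = 0.0
    p4: float = 0.0
    A1: float = 0.0
    A2: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        psum = abs(self.p1) + abs(self.p2) + abs(self.p3) + abs(self.p4)
        if psum >= 1:
            raise ValueError("|p1|+|p2|+|p3|+|p4| must be < 1")
        if abs(self.A1) + abs(self.A2) >= 1:
            raise ValueError("|A1|+|A2| must be < 1")

    def validate_positive_period(self, ecc_max_deg: float, ecc_min_deg: float = 0.0) -> None:
        """Raise if slope*r + intercept is not positive over [ecc_min, ecc_max]."""
        for r in (ecc_min_deg, ecc_max_deg):
            if self.slope * r + self.intercept <= 0:
                raise ValueError(
                    f"slope*r + intercept must be positive over the fitted range; "
                    f"violated at r={r}"
                )

    def to_dict(self) -> dict[str, float]:
        d = asdict(self)
        return {k: float(d[k]) for k in PARAM_KEYS}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "Model2DParams":
        return cls(**{k: float(d[k]) for k in PARAM_KEYS})

    def to_array(self) -> np.ndarray:
        d = asdict(self)
        return np.array([d[k] for k in PARAM_KEYS], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "Model2DParams":
        return cls(**dict(zip(PARAM_KEYS, (float(v) for v in a))))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Model2DParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fwhm_octaves(sigma_oct: float) -> float:
    """Full width at half maximum (octaves) of a log2-Gaussian with SD sigma.

    For a Gaussian the FWHM is ``2*sqrt(2*ln 2) * sigma``; e.g. a bandwidth
    of 2.2 octaves corresponds to a FWHM of about 5.2 octaves.
    """
    if sigma_oct < 0:
        raise ValueError("sigma_oct must be >= 0")
    return LOG2_FWHM_FACTOR * sigma_oct


def log_gaussian_response(p_local_dpc, gain_A, p_peak_dpc, sigma_oct):
    """Log-Gaussian tuning curve over spatial period.

    ``A * exp(-(log2 p_local - log2 p_peak)**2 / (2 * sigma**2))`` — symmetric
    in log2 period around the preferred period. Accepts scalars or arrays.
    """
    p_local_dpc = np.asarray(p_local_dpc, dtype=float)
    if np.any(p_local_dpc <= 0):
        raise ValueError("p_local_dpc must be positive")
    if np.any(np.asarray(p_peak_dpc) <= 0) or np.any(np.asarray(sigma_oct) <= 0):
        raise ValueError("p_peak_dpc and sigma_oct must be positive")
    z = np.log2(p_local_dpc) - np.log2(p_peak_dpc)
    out = gain_A * np.exp(-(z**2) / (2.0 * np.asarray(sigma_oct) ** 2))
    return out if out.ndim else float(out)


def preferred_period(
    loc: VertexLocation, theta_l: float, params: Model2DParams
) -> float:
    """Preferred period (deg/cycle) of a vertex at local orientation theta_l.

    Affine in eccentricity (slope*r_v + intercept) and modulated by absolute
    orientation (p1, p2: cos of 2/4 theta_l) and orientation relative to the
    vertex's polar angle (p3, p4: cos of 2/4 (theta_l - theta_v)).
    """
    base = params.slope * loc.ecc_deg + params.intercept
    if base <= 0:
        raise ValueError("slope*ecc + intercept must be positive at this vertex")
    rel = theta_l - loc.angle_rad
    mod = (
        1.0
        + params.p1 * math.cos(2.0 * theta_l)
        + params.p2 * math.cos(4.0 * theta_l)
        + params.p3 * math.cos(2.0 * rel)
        + params.p4 * math.cos(4.0 * rel)
    )
    return base * mod


def amplitude_gain(theta_l, A1: float, A2: float):
    """Orientation-dependent response gain ``1 + A1*cos(2t) + A2*cos(4t)``.

    Strictly positive when |A1| + |A2| < 1. Accepts scalars or arrays.
    """
    theta_l = np.asarray(theta_l, dtype=float)
    out = 1.0 + A1 * np.cos(2.0 * theta_l) + A2 * np.cos(4.0 * theta_l)
    return out if out.ndim else float(out)


def predict_response(
    loc: VertexLocation, stim: "LocalStimulus", params: Model2DParams
) -> float:
    """Predicted BOLD response (% signal) of a vertex to a local stimulus.

    The log-Gaussian tuning curve evaluated at the vertex's preferred period,
    scaled by the orientation-dependent amplitude gain. A single bandwidth
    sigma is shared across the whole map; with all orientation terms zero the
    model reduces exactly to the 1D per-bin tuning-curve form.
    """
    if stim.period_dpc <= 0:
        raise ValueError("stimulus period must be positive")
    p_v = preferred_period(loc, stim.ori_rad, params)
    a_v = amplitude_gain(stim.ori_rad, params.A1, params.A2)
    return log_gaussian_response(stim.period_dpc, a_v, p_v, params.sigma)


def predict_matrix(
    ecc_deg: np.ndarray,
    angle_rad: np.ndarray,
    period_dpc: np.ndarray,
    ori_rad: np.ndarray,
    theta: np.ndarray,
) -> np.ndarray:
    """Vectorized model predictions for a whole map.

    Parameters
    ----------
    ecc_deg, angle_rad : (V,) vertex pRF coordinates.
    period_dpc, ori_rad : (V, C) local stimulus period and orientation per
        vertex and stimulus class.
    theta : (9,) parameter vector in ``PARAM_KEYS`` order.

    Returns
    -------
    (V, C) predicted responses. Used as the fitting kernel; equivalent to
    calling :func:`predict_response` elementwise.
    """
    sigma, a, b, p1, p2, p3, p4, A1, A2 = theta
    base = (a * ecc_deg + b)[:, None]
    rel = ori_rad - angle_rad[:, None]
    p_v = base * (
        1.0
        + p1 * np.cos(2.0 * ori_rad)
        + p2 * np.cos(4.0 * ori_rad)
        + p3 * np.cos(2.0 * rel)
        + p4 * np.cos(4.0 * rel)
    )
    a_v = 1.0 + A1 * np.cos(2.0 * ori_rad) + A2 * np.cos(4.0 * ori_rad)
    z = np.log2(period_dpc) - np.log2(p_v)
    return a_v * np.exp(-(z**2) / (2.0 * sigma**2))
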