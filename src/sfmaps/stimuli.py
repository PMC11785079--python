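"""Log-polar scaled-grating stimuli and their local frequency/orientation fields.

A scaled grating is the image ``I(r, theta) = cos(omega_r * ln(r) +
omega_a * theta + phi)`` in polar visual-field coordinates. Its local spatial
frequency falls off as 1/eccentricity, so a single image probes every
retinotopic location near its sensitive range. The frequency vector
``(omega_r, omega_a)`` determines both the local spatial frequency (which
depends only on eccentricity) and the local orientation (which depends only on
polar angle).

Conventions used throughout the package:

* theta is measured counterclockwise from the positive x-axis, with the image
  y-axis pointing up in visual-field coordinates.
* Local spatial frequency from the phase gradient is
  ``sqrt(omega_r**2 + omega_a**2) / r`` in radians per degree; it is divided
  by ``2 * pi`` to report cycles per degree.
* Local orientation is the direction of the phase gradient reduced mod pi.
  Under this convention an annulus on the right horizontal meridian has
  orientation 0 and vertically oriented contours, so ``cos(2 * theta_l) = 1``
  selects "vertical".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NSD_PHASES",
    "FrequencyVector",
    "StimulusClass",
    "GratingImage",
    "LocalStimulus",
    "make_catalog",
    "render_grating",
    "local_stimulus",
    "mask_radius",
    "write_stimulus_set",
]

#: The four exemplar phases (radians) used for every NSD stimulus class.
NSD_PHASES: tuple[float, ...] = (0.0, 1.57, 3.14, 4.71)

Shape = Literal["pinwheel", "annulus", "forward_spiral", "reverse_spiral", "mixture"]

# Frequency-vector lists of the NSD scaled-grating design. Angular frequencies
# are integers (non-integer circular frequencies produce edge artifacts), which
# forces slight base-frequency discrepancies between the annulus/pinwheel and
# spiral shapes.
_NSD_PINWHEEL_OMEGA_A = (-6, -11, -20, -37, -69, -128)
_NSD_ANNULUS_OMEGA_R = (6, 11, 20, 37, 69, 128)
_NSD_SPIRAL_MAG = (4, 7, 14, 26, 49, 91)
_NSD_MIXTURES = ((14, -34), (34, -14), (34, 14), (14, 34))


@dataclass(frozen=True)
class FrequencyVector:
    """Frequency vector (omega_r, omega_a) of a scaled grating.

    Parameters
    ----------
    omega_r : float
        Radial frequency, in radians per unit increase in ln(r).
    omega_a : int
        Angular frequency, in cycles per revolution. Must be an integer.
    """

    omega_r: float
    omega_a: int

    def __post_init__(self) -> None:
        if float(self.omega_a) != int(self.omega_a):
            raise ValueError(f"omega_a must be an integer, got {self.omega_a!r}")
        object.__setattr__(self, "omega_a", int(self.omega_a))

    @property
    def base_frequency(self) -> float:
        """Vector length sqrt(omega_r**2 + omega_a**2)."""
        return math.hypot(self.omega_r, self.omega_a)

    def orientation_offset(self) -> float:
        """Phase-gradient direction offset atan2(omega_a, omega_r), radians."""
        return math.atan2(self.omega_a, self.omega_r)


@dataclass(frozen=True)
class StimulusClass:
    """One stimulus class: a frequency vector with its exemplar phases."""

    class_id: int
    shape: Shape
    freq: FrequencyVector
    phases: tuple[float, ...] = NSD_PHASES

    def __post_init__(self) -> None:
        # a (0, 0) vector is permitted here (degenerate uniform image, useful
        # for renderer tests); make_catalog rejects it for catalog entries
        if self.shape == "pinwheel" and self.freq.omega_r != 0:
            raise ValueError("pinwheel requires omega_r = 0")
        if self.shape == "annulus" and self.freq.omega_a != 0:
            raise ValueError("annulus requires omega_a = 0")
        if self.shape in ("forward_spiral", "reverse_spiral") and abs(
            self.freq.omega_r
        ) != abs(self.freq.omega_a):
            raise ValueError("spirals require |omega_r| = |omega_a|")

    @property
    def base_frequency(self) -> float:
        return self.freq.base_frequency


@dataclass
class GratingImage:
    """A rendered scaled grating.

    Attributes
    ----------
    pixels : ndarray
        2D intensities in [-1, 1]; row 0 is the top of the image (y up in
        visual-field coordinates).
    extent_deg : float
        Width/height of the square image in degrees of visual angle.
    ppd : float
        Pixels per degree.
    mask_radius_deg : float
        Radius of the central anti-aliasing mask; pixels inside are 0
        (mean luminance).
    """

    pixels: np.ndarray
    extent_deg: float
    ppd: float
    mask_radius_deg: float


@dataclass(frozen=True)
class LocalStimulus:
    """Local spatial frequency and orientation at one visual-field location."""

    sf_cpd: float
    period_dpc: float
    ori_rad: float

    def __post_init__(self) -> None:
        if self.sf_cpd <= 0:
            raise ValueError("sf_cpd must be positive")


def make_catalog(
    design: Literal["nsd", "custom"] = "nsd",
    custom_vectors: Sequence[tuple[float, int]] | None = None,
    phases: Sequence[float] = NSD_PHASES,
) -> list[StimulusClass]:
    """Build a stimulus-class catalog.

    For ``design="nsd"`` this is the 28-class scaled-grating set: 6 pinwheels,
    6 annuli, 6 forward spirals, 6 reverse spirals and 4 mixtures, each with
    4 phase exemplars (112 stimuli). Class ids run 0-27 in that order.

    For ``design="custom"``, ``custom_vectors`` supplies (omega_r, omega_a)
    pairs; shapes are inferred from the zero/equal-magnitude structure.
    """
    if design == "nsd":
        vectors: list[tuple[float, int, Shape]] = []
        vectors += [(0.0, wa, "pinwheel") for wa in _NSD_PINWHEEL_OMEGA_A]
        vectors += [(float(wr), 0, "annulus") for wr in _NSD_ANNULUS_OMEGA_R]
        vectors += [(float(k), -k, "forward_spiral") for k in _NSD_SPIRAL_MAG]
        vectors += [(float(k), k, "reverse_spiral") for k in _NSD_SPIRAL_MAG]
        vectors += [(float(wr), wa, "mixture") for wr, wa in _NSD_MIXTURES]
    elif design == "custom":
        if not custom_vectors:
            raise ValueError("custom design requires custom_vectors")
        vectors = [(float(wr), int(wa), _infer_shape(wr, wa)) for wr, wa in custom_vectors]
    else:
        raise ValueError(f"unknown design {design!r}")

    catalog = []
    for i, (wr, wa, shape) in enumerate(vectors):
        if wr == 0 and wa == 0:
            raise ValueError("invalid stimulus class: omega_r = omega_a = 0")
        catalog.append(
            StimulusClass(
                class_id=i,
                shape=shape,
                freq=FrequencyVector(wr, wa),
                phases=tuple(float(p) for p in phases),
            )
        )
    return catalog


def _infer_shape(wr: float, wa: int) -> Shape:
    if wr == 0:
        return "pinwheel"
    if wa == 0:
        return "annulus"
    if abs(wr) == abs(wa):
        return "forward_spiral" if wa == -wr else "reverse_spiral"
    return "mixture"


def mask_radius(freq: FrequencyVector, cutoff_cpd: float) -> float:
    """Radius (degrees) at which the local spatial frequency hits a cutoff.

    Inside this radius the grating's local frequency exceeds ``cutoff_cpd``
    and cannot be rendered without aliasing, so the anti-aliasing mask covers
    it. The radius grows with base frequency and shrinks inversely with the
    cutoff.
    """
    if cutoff_cpd <= 0:
        raise ValueError("cutoff_cpd must be positive")
    return freq.base_frequency / (2.0 * math.pi * cutoff_cpd)


def local_stimulus(
    r_deg: float, theta_rad: float, freq: FrequencyVector
) -> LocalStimulus:
    """Local spatial frequency and orientation at a visual-field location.

    The phase gradient of the grating has magnitude
    ``sqrt(omega_r**2 + omega_a**2) / r`` radians per degree (converted to
    cycles/degree by dividing by 2*pi) and direction
    ``theta + atan2(omega_a, omega_r)`` (reduced mod pi for reporting).
    """
    if r_deg <= 0:
        raise ValueError("r_deg must be positive")
    sf_cpd = freq.base_frequency / (2.0 * math.pi * r_deg)
    ori = (theta_rad + freq.orientation_offset()) % math.pi
    return LocalStimulus(sf_cpd=sf_cpd, period_dpc=1.0 / sf_cpd, ori_rad=ori)


def local_stimulus_arrays(
    r_deg: np.ndarray, theta_rad: np.ndarray, catalog: Sequence[StimulusClass]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized local stimulus over locations x catalog classes.

    Returns ``(period_dpc, ori_rad)`` arrays of shape ``(n_locations,
    n_classes)``; orientations are reduced mod pi.
    """
    r = np.asarray(r_deg, dtype=float)[:, None]
    th = np.asarray(theta_rad, dtype=float)[:, None]
    if np.any(r <= 0):
        raise ValueError("all eccentricities must be positive")
    base = np.array([c.base_frequency for c in catalog])[None, :]
    offset = np.array([c.freq.orientation_offset() for c in catalog])[None, :]
    sf_cpd = base / (2.0 * np.pi * r)
    ori = np.mod(th + offset, np.pi)
    return 1.0 / sf_cpd, ori


def render_grating(
    cls: StimulusClass,
    phase: float,
    n_px: int,
    extent_deg: float,
    cutoff_cpd: float | None = None,
) -> GratingImage:
    """Render one scaled-grating exemplar on a square pixel grid.

    Pixel (x, y) gets intensity ``cos(omega_r * ln(r) + omega_a * theta +
    phase)`` with (r, theta) the pixel center's polar coordinates about the
    image center. Pixels inside the anti-aliasing mask radius are set to 0
    (mean luminance); the ln(r) singularity at the center is always inside
    the mask.

    ``cutoff_cpd`` defaults to the rendering grid's Nyquist frequency
    (ppd / 2), which guarantees every unmasked pixel is below aliasing.
    """
    if n_px < 16:
        raise ValueError("n_px must be >= 16")
    if extent_deg <= 0:
        raise ValueError("extent_deg must be positive")
    ppd = n_px / extent_deg
    if cutoff_cpd is None:
        cutoff_cpd = ppd / 2.0
    r_mask = mask_radius(cls.freq, cutoff_cpd)

    # Pixel-center coordinates in degrees; y increases upward so row 0 is the
    # top of the image.
    coords = (np.arange(n_px) + 0.5) * (extent_deg / n_px) - extent_deg / 2.0
    x = coords[None, :]
    y = coords[::-1][:, None]
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    with np.errstate(divide="ignore"):
        phase_map = cls.freq.omega_r * np.log(r) + cls.freq.omega_a * theta + phase
    pixels = np.cos(phase_map)
    pixels[r <= r_mask] = 0.0
    return GratingImage(
        pixels=pixels, extent_deg=extent_deg, ppd=ppd, mask_radius_deg=r_mask
    )


def write_stimulus_set(
    catalog: Sequence[StimulusClass],
    out_dir: str | Path,
    n_px: int = 512,
    extent_deg: float = 8.4,
    cutoff_cpd: float | None = None,
) -> pd.DataFrame:
    """Write all (class, phase) exemplars as 8-bit PNGs plus a sidecar CSV.

    Intensities are mapped [-1, 1] -> [0, 255]. Returns the catalog table
    (class_id, shape, omega_r, omega_a, phase, base_frequency,
    mask_radius_deg) that is also written as ``catalog.csv``.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cls in catalog:
        for phase in cls.phases:
            img = render_grating(cls, phase, n_px=n_px, extent_deg=extent_deg,
                                 cutoff_cpd=cutoff_cpd)
            u8 = np.round((img.pixels + 1.0) * 127.5).astype(np.uint8)
            name = f"class{cls.class_id:02d}_phase{phase:.2f}.png"
            Image.fromarray(u8, mode="L").save(out / name)
            rows.append(
                dict(
                    class_id=cls.class_id,
                    shape=cls.shape,
                    omega_r=cls.freq.omega_r,
                    omega_a=cls.freq.omega_a,
                    phase=phase,
                    base_frequency=cls.base_frequency,
                    mask_radius_deg=img.mask_radius_deg,
                    filename=name,
                )
            )
    table = pd.DataFrame(rows)
    table.to_csv(out / "catalog.csv", index=False)
    return table
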