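"""Numerical oracles independent of the package's analytic formulas.

The phase-gradient oracle measures local spatial frequency and orientation
directly from rendered pixel data: two renders a quarter-cycle apart form the
analytic signal z = exp(i*Phi), whose per-pixel phase differences give the
phase gradient without any call to the analytic local-frequency formula.
"""

import numpy as np

from sfmaps import render_grating


def measure_local_field(cls, n_px, extent_deg):
    """Measure local sf (cycles/deg) and orientation (rad, mod pi) per pixel.

    Returns (r_deg, theta_rad, sf_cpd, ori_rad, mask_radius_deg) arrays of
    shape (n_px-1, n_px-1), valid wherever the phase step per pixel is
    unambiguous (|step| < pi, i.e. below the grid Nyquist).
    """
    img_c = render_grating(cls, 0.0, n_px, extent_deg)
    # cos(Phi - pi/2) = sin(Phi), so z = cos + i*sin = exp(i*Phi)
    img_s = render_grating(cls, -np.pi / 2.0, n_px, extent_deg)
    z = img_c.pixels + 1j * img_s.pixels
    dpp = extent_deg / n_px

    # phase differences between neighboring pixels, exact mod 2*pi
    dphi_dx = (np.angle(z[:, 1:] * np.conj(z[:, :-1])) / dpp)[:-1, :]
    # row index grows downward while y grows upward, so rows i, i+1 step -y
    dphi_dy = (np.angle(z[:-1, :] * np.conj(z[1:, :])) / dpp)[:, :-1]

    coords = (np.arange(n_px) + 0.5) * dpp - extent_deg / 2.0
    x = coords[None, :]
    y = coords[::-1][:, None]
    r = np.hypot(x, y)[: n_px - 1, : n_px - 1]
    theta = np.arctan2(y, x)[: n_px - 1, : n_px - 1]

    sf_cpd = np.hypot(dphi_dx, dphi_dy) / (2.0 * np.pi)
    ori = np.mod(np.arctan2(dphi_dy, dphi_dx), np.pi)
    return r, theta, sf_cpd, ori, img_c.mask_radius_deg


def angular_diff_mod_pi(a, b):
    """Smallest absolute difference between two orientations mod pi."""
    d = np.abs(np.mod(a - b, np.pi))
    return np.minimum(d, np.pi - d)
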