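"""Estimation: per-bin 1D tuning curves and the 9-parameter 2D map model.

The 2D model is fit to all vertices of a retinotopic map at once by minimizing
the precision-weighted, L2-normalized mean-squared error between measured and
predicted beta weights,

    L_v = (1 / sigma_v^2) * (1/n) * sum_i (beta_iv / ||beta_v|| -
                                           betahat_iv / ||betahat_v||)^2

averaged over vertices. The L2 normalization makes the loss invariant to the
overall response scale of each vertex; the 1/sigma_v^2 weight down-weights
noisy vertices, where sigma_v^2 is the mean over stimulus classes of the
trial-to-trial sample variance of the betas.

Optimization uses L-BFGS-B with box bounds that keep the bandwidth and the
orientation modulations inside the region where periods and gains are
positive everywhere (|p_i| <= 0.24 each, |A_i| <= 0.49 each). The problem is
smooth and 9-dimensional, so a quasi-Newton method with finite-difference
gradients converges quickly and deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .stimuli import StimulusClass, local_stimulus_arrays
from .tuning import Model2DParams, TuningCurve1D, VertexLocation, predict_matrix

__all__ = [
    "PRIMARY_SHAPES",
    "BinData",
    "FitResult",
    "InsufficientTrialsError",
    "DegenerateVertexError",
    "OptConfig",
    "VertexRecord",
    "bin_vertices",
    "fit_2d_model",
    "fit_period_line",
    "fit_tuning_1d",
    "map_loss",
    "nsd_bin_edges",
    "normalized_loss",
    "read_vertex_tables",
    "vertex_variance",
    "write_vertex_tables",
]

PRIMARY_SHAPES = ("pinwheel", "annulus", "forward_spiral", "reverse_spiral")


class InsufficientTrialsError(ValueError):
    """A stimulus class used for the variance has fewer than 2 trials."""


class DegenerateVertexError(ValueError):
    """A vertex with zero-norm betas reached the loss; it should be filtered."""


@dataclass
class VertexRecord:
    """One surface vertex: pRF location, ROI label and its trial betas.

    ``betas`` is a (n_classes, n_trials) array in % signal change; ragged
    trial counts (e.g. trials dropped as consecutive repeats) are represented
    by NaN padding.
    """

    vertex_id: int
    location: VertexLocation
    roi: str
    betas: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))

    @property
    def n_classes(self) -> int:
        return self.betas.shape[0]

    def mean_betas(self, classes_used: Sequence[int] | None = None) -> np.ndarray:
        """Per-class mean over trials (NaN-aware)."""
        b = self.betas if classes_used is None else self.betas[list(classes_used)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(b, axis=1)

    def variance(self, classes_used: Sequence[int] | None = None) -> float:
        """Vertex variance sigma_v^2 (see :func:`vertex_variance`)."""
        return vertex_variance(self.betas, classes_used)


def vertex_variance(
    betas: np.ndarray, classes_used: Sequence[int] | None = None
) -> float:
    """Vertex noise variance sigma_v^2 in squared % signal change.

    The sample variance (n-1 denominator) of the betas across repeated trials
    is computed separately for each stimulus class and averaged over
    ``classes_used`` (all classes by default; the 1D pathway uses the 24
    primary classes, the 2D loss all 28). Shift-invariant: adding a constant
    to every beta leaves it unchanged.
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    if classes_used is not None:
        betas = betas[list(classes_used)]
    n_trials = np.sum(~np.isnan(betas), axis=1)
    if np.any(n_trials < 2):
        bad = np.nonzero(n_trials < 2)[0]
        raise InsufficientTrialsError(
            f"classes {bad.tolist()} have fewer than 2 trials; "
            "variance is undefined"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_class = np.nanvar(betas, axis=1, ddof=1)
    return float(np.mean(per_class))


def normalized_loss(
    beta_v: np.ndarray, beta_hat_v: np.ndarray, variance_v: float
) -> float:
    """Precision-weighted, L2-normalized MSE between data and prediction.

    Both vectors are divided by their own L2 norm before the squared
    difference, so the loss is invariant to a positive rescaling of either
    argument; the result is divided by the vertex variance.
    """
    beta_v = np.asarray(beta_v, dtype=float)
    beta_hat_v = np.asarray(beta_hat_v, dtype=float)
    if beta_v.shape != beta_hat_v.shape:
        raise ValueError("beta vectors must have the same shape")
    if variance_v <= 0:
        raise ValueError("variance_v must be positive")
    nb = np.linalg.norm(beta_v)
    nh = np.linalg.norm(beta_hat_v)
    if nb == 0 or nh == 0:
        raise DegenerateVertexError("zero-norm beta vector in the loss")
    d = beta_v / nb - beta_hat_v / nh
    return float(np.mean(d**2) / variance_v)


@dataclass
class OptConfig:
    """Optimizer settings for the 2D map fit (L-BFGS-B)."""

    max_iter: int = 5000
    ftol: float = 1e-14
    gtol: float = 1e-10
    min_vertices: int = 50
    sigma_bounds: tuple[float, float] = (0.05, 10.0)
    slope_bounds: tuple[float, float] = (0.0, 2.0)
    intercept_bounds: tuple[float, float] = (0.01, 5.0)
    p_bound: float = 0.24
    a_bound: float = 0.49

    def bounds(self) -> list[tuple[float, float]]:
        return (
            [self.sigma_bounds, self.slope_bounds, self.intercept_bounds]
            + [(-self.p_bound, self.p_bound)] * 4
            + [(-self.a_bound, self.a_bound)] * 2
        )


@dataclass
class FitResult:
    """Outcome of one 2D map fit."""

    params: Model2DParams
    final_loss: float
    loss_trace: list[float]
    n_vertices_used: int
    seed: int
    converged: bool
    n_iter: int = 0


DEFAULT_INIT = Model2DParams(sigma=2.0, slope=0.1, intercept=0.3)


def map_loss(
    vertices: Sequence[VertexRecord],
    catalog: Sequence[StimulusClass],
    params: Model2DParams,
    classes_used: Sequence[int] | None = None,
) -> float:
    """Mean precision-weighted normalized loss of a parameter set on a map.

    This is the objective minimized by :func:`fit_2d_model` (vectorized over
    vertices and classes).
    """
    ecc, ang, betas, var, period, ori = _prepare_fit_arrays(
        vertices, catalog, classes_used
    )
    norms = np.linalg.norm(betas, axis=1)
    if np.any(norms == 0):
        raise DegenerateVertexError("zero-norm mean betas in map_loss")
    weights = _loss_weights(var)
    pred = predict_matrix(ecc, ang, period, ori, params.to_array())
    pn = np.linalg.norm(pred, axis=1, keepdims=True)
    d = betas / norms[:, None] - pred / pn
    per_vertex = np.mean(d**2, axis=1)
    return float(np.mean(weights * per_vertex))


def _prepare_fit_arrays(
    vertices: Sequence[VertexRecord],
    catalog: Sequence[StimulusClass],
    classes_used: Sequence[int] | None,
):
    """Stack per-vertex mean betas, variances and local stimuli into arrays."""
    idx = list(range(len(catalog))) if classes_used is None else list(classes_used)
    ecc = np.array([v.location.ecc_deg for v in vertices])
    ang = np.array([v.location.angle_rad for v in vertices])
    betas = np.stack([v.mean_betas(idx) for v in vertices])
    var = np.array([v.variance(idx) for v in vertices])
    sub_catalog = [catalog[i] for i in idx]
    period, ori = local_stimulus_arrays(ecc, ang, sub_catalog)
    return ecc, ang, betas, var, period, ori


def _loss_weights(variance: np.ndarray) -> np.ndarray:
    """Precision weights 1/sigma_v^2, with a floor for zero-variance vertices.

    Noiseless synthetic data have sigma_v^2 = 0 for every vertex; then the
    precision weighting is vacuous and unit weights are used. If only some
    vertices have zero variance they are floored at the smallest positive
    variance so no vertex gets infinite weight.
    """
    variance = np.asarray(variance, dtype=float)
    if np.all(variance == 0):
        return np.ones_like(variance)
    floor = variance[variance > 0].min()
    return 1.0 / np.maximum(variance, floor)


def fit_2d_model(
    vertices: Sequence[VertexRecord],
    catalog: Sequence[StimulusClass],
    init: Model2DParams | None = None,
    opt_config: OptConfig | None = None,
    seed: int = 0,
    classes_used: Sequence[int] | None = None,
) -> FitResult:
    """Fit the 9-parameter map model to all vertices of one map at once.

    Minimizes the mean over vertices of the precision-weighted normalized
    loss. Local stimulus period and orientation are evaluated at each
    vertex's pRF center for every catalog class. Deterministic given
    (data, init, opt_config); ``seed`` is recorded in the result for
    provenance.

    Returns a :class:`FitResult`; non-convergence within ``max_iter`` sets
    ``converged=False`` rather than raising.
    """
    cfg = opt_config or OptConfig()
    init = init or DEFAULT_INIT
    if len(vertices) < cfg.min_vertices:
        raise ValueError(
            f"need at least {cfg.min_vertices} vertices after filtering, "
            f"got {len(vertices)}"
        )
    ecc, ang, betas, var, period, ori = _prepare_fit_arrays(
        vertices, catalog, classes_used
    )
    norms = np.linalg.norm(betas, axis=1)
    if np.any(norms == 0):
        raise DegenerateVertexError(
            "vertices with zero-norm mean betas must be filtered before fitting"
        )
    betas_n = betas / norms[:, None]
    weights = _loss_weights(var)
    n_classes = betas.shape[1]

    def loss(theta: np.ndarray) -> float:
        pred = predict_matrix(ecc, ang, period, ori, theta)
        pn = np.linalg.norm(pred, axis=1, keepdims=True)
        d = betas_n - pred / pn
        per_vertex = np.sum(d**2, axis=1) / n_classes
        return float(np.mean(weights * per_vertex))

    trace: list[float] = []

    def record(theta: np.ndarray) -> None:
        trace.append(loss(theta))

    res = optimize.minimize(
        loss,
        init.to_array(),
        method="L-BFGS-B",
        bounds=cfg.bounds(),
        callback=record,
        options={"maxiter": cfg.max_iter, "ftol": cfg.ftol, "gtol": cfg.gtol},
    )
    params = Model2DParams.from_array(res.x)
    return FitResult(
        params=params,
        final_loss=float(res.fun),
        loss_trace=trace,
        n_vertices_used=len(vertices),
        seed=seed,
        converged=bool(res.success),
        n_iter=int(res.nit),
    )


# --------------------------------------------------------------------------
# 1D pathway: eccentricity binning and per-bin log-Gaussian fits
# --------------------------------------------------------------------------


@dataclass
class BinData:
    """Mean responses of one eccentricity bin at each base-frequency level."""

    bin_center_deg: float
    period_dpc: np.ndarray
    response: np.ndarray
    n_vertices: int


def nsd_bin_edges() -> np.ndarray:
    """Default NSD eccentricity-bin edges: 0.5 to 4.0 deg in 0.5 deg steps."""
    return np.arange(0.5, 4.0 + 1e-9, 0.5)


def bin_vertices(
    vertices: Sequence[VertexRecord],
    bin_edges: np.ndarray,
    catalog: Sequence[StimulusClass],
) -> list[BinData]:
    """Bin vertices by eccentricity and collapse the four primary shapes.

    For each bin, betas are averaged over trials, over the vertices whose
    pRF eccentricity falls in the bin (half-open [left, right) intervals,
    except the last bin which includes its right edge), and over the four
    primary shapes at each of the base-frequency levels (mixture classes are
    excluded). The local spatial period of each level is evaluated at the bin
    center from the mean base frequency of the collapsed shapes. Empty bins
    are reported with ``n_vertices=0`` and empty arrays.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")

    # Group primary-shape classes into base-frequency levels by rank.
    by_shape: dict[str, list[StimulusClass]] = {s: [] for s in PRIMARY_SHAPES}
    for c in catalog:
        if c.shape in by_shape:
            by_shape[c.shape].append(c)
    n_levels = min(len(v) for v in by_shape.values())
    levels = []
    for k in range(n_levels):
        members = [
            sorted(by_shape[s], key=lambda c: c.base_frequency)[k]
            for s in PRIMARY_SHAPES
        ]
        levels.append(members)
    level_base = np.array(
        [np.mean([c.base_frequency for c in members]) for members in levels]
    )

    ecc = np.array([v.location.ecc_deg for v in vertices])
    out: list[BinData] = []
    for i in range(len(bin_edges) - 1):
        left, right = bin_edges[i], bin_edges[i + 1]
        last = i == len(bin_edges) - 2
        in_bin = (ecc >= left) & ((ecc <= right) if last else (ecc < right))
        center = 0.5 * (left + right)
        members_idx = np.nonzero(in_bin)[0]
        if len(members_idx) == 0:
            out.append(
                BinData(center, np.empty(0), np.empty(0), 0)
            )
            continue
        responses = np.empty(n_levels)
        for k, members in enumerate(levels):
            class_ids = [c.class_id for c in members]
            vals = [
                np.mean(vertices[j].mean_betas(class_ids)) for j in members_idx
            ]
            responses[k] = float(np.mean(vals))
        period = 2.0 * np.pi * center / level_base
        out.append(BinData(center, period, responses, int(len(members_idx))))
    return out


def fit_tuning_1d(bin_data: BinData) -> tuple[TuningCurve1D, bool]:
    """Least-squares log-Gaussian fit to one bin's (period, response) points.

    Fits (gain, preferred period, bandwidth) with the period and bandwidth
    constrained positive. Returns ``(curve, converged)``; degenerate inputs
    (constant responses, failed optimization) yield ``converged=False`` with
    the best-effort curve.
    """
    if bin_data.n_vertices == 0 or len(np.unique(bin_data.period_dpc)) < 3:
        raise ValueError("need >= 3 distinct base-frequency levels with data")
    period = np.asarray(bin_data.period_dpc, dtype=float)
    resp = np.asarray(bin_data.response, dtype=float)

    def model(p, A, p_peak, sigma):
        z = np.log2(p) - np.log2(p_peak)
        return A * np.exp(-(z**2) / (2.0 * sigma**2))

    a0 = float(resp.max()) if resp.max() > 0 else 1.0
    p0 = float(period[np.argmax(resp)])
    converged = True
    if np.ptp(resp) < 1e-12 * max(1.0, abs(resp.max())):
        converged = False
        popt = (a0, p0, 2.0)
    else:
        try:
            popt, _ = optimize.curve_fit(
                model,
                period,
                resp,
                p0=(a0, p0, 2.0),
                bounds=([1e-9, 1e-4, 1e-3], [np.inf, 1e3, 1e2]),
                maxfev=20000,
            )
        except RuntimeError:
            converged = False
            popt = (a0, p0, 2.0)
    curve = TuningCurve1D(
        bin_center_deg=bin_data.bin_center_deg,
        gain_A=float(popt[0]),
        p_peak_dpc=float(popt[1]),
        sigma_oct=float(popt[2]),
    )
    return curve, converged


def fit_period_line(curves: Sequence[TuningCurve1D]) -> tuple[float, float]:
    """OLS line of preferred period against bin-center eccentricity.

    Returns (slope, intercept) in deg/cycle per deg and deg/cycle.
    """
    if len(curves) < 2:
        raise ValueError("need >= 2 bins for a line fit")
    x = np.array([c.bin_center_deg for c in curves])
    y = np.array([c.p_peak_dpc for c in curves])
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


# --------------------------------------------------------------------------
# CSV interchange (written by the synthetic module, read back for fitting)
# --------------------------------------------------------------------------


def write_vertex_tables(
    vertices: Sequence[VertexRecord],
    vertex_csv: str | Path,
    beta_csv: str | Path,
) -> None:
    """Write the vertex geometry table and the long-format beta table.

    Schema: vertex CSV has columns (vertex_id, roi, ecc_deg, angle_rad,
    prf_size_deg); beta CSV has (vertex_id, class_id, trial, beta). NaN-padded
    trials are omitted from the beta table, so ragged trial counts round-trip.
    The same schema is the adapter point for real per-vertex GLM exports.
    """
    vrows = [
        dict(
            vertex_id=v.vertex_id,
            roi=v.roi,
            ecc_deg=v.location.ecc_deg,
            angle_rad=v.location.angle_rad,
            prf_size_deg=v.location.prf_size_deg,
        )
        for v in vertices
    ]
    # %.17g guarantees exact float64 round-trip through the text format
    pd.DataFrame(vrows).to_csv(vertex_csv, index=False, float_format="%.17g")

    brows = []
    for v in vertices:
        cls_idx, trial_idx = np.nonzero(~np.isnan(v.betas))
        brows.append(
            pd.DataFrame(
                dict(
                    vertex_id=v.vertex_id,
                    class_id=cls_idx,
                    trial=trial_idx,
                    beta=v.betas[cls_idx, trial_idx],
                )
            )
        )
    pd.concat(brows, ignore_index=True).to_csv(
        beta_csv, index=False, float_format="%.17g"
    )


def read_vertex_tables(
    vertex_csv: str | Path, beta_csv: str | Path, n_classes: int = 28
) -> list[VertexRecord]:
    """Read the vertex/beta CSV schema back into VertexRecord objects."""
    # round_trip parsing + 17-significant-digit writing give exact float64
    # fidelity through the text format
    vt = pd.read_csv(vertex_csv, float_precision="round_trip")
    bt = pd.read_csv(beta_csv, float_precision="round_trip")
    grouped = dict(list(bt.groupby("vertex_id")))
    records = []
    for row in vt.itertuples(index=False):
        g = grouped.get(row.vertex_id)
        if g is None:
            raise ValueError(f"vertex {row.vertex_id} has no betas")
        n_trials = int(g["trial"].max()) + 1
        betas = np.full((n_classes, n_trials), np.nan)
        betas[g["class_id"].to_numpy(), g["trial"].to_numpy()] = g["beta"].to_numpy()
        records.append(
            VertexRecord(
                vertex_id=int(row.vertex_id),
                location=VertexLocation(
                    ecc_deg=float(row.ecc_deg),
                    angle_rad=float(row.angle_rad),
                    prf_size_deg=float(row.prf_size_deg),
                ),
                roi=str(row.roi),
                betas=betas,
            )
        )
    return records
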