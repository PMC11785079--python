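"""Synthetic cohorts: pRF layouts and trial-level betas with known ground truth.

The generator emulates the structure of per-vertex scaled-grating data: a
retinotopic map of pRF centers (log-uniform eccentricities — denser foveally,
mimicking cortical magnification — uniform polar angles, pRF size affine in
eccentricity), noiseless responses produced by the 2D map model evaluated at
each vertex's pRF center for the 28-class stimulus catalog, and independent
Gaussian trial noise whose SD varies across vertices (lognormal spread) so
that vertex and subject precisions are meaningful. A small fraction of
vertices is generated with sign-flipped gain to exercise the negative-mean
exclusion rule.

Defaults mirror the NSD-like study conditions: 8 subjects, 1000 V1 vertices
over 0.5-4.2 deg eccentricity, 8 trials per class, trial noise SD equal to
half the mean response. A wider 1-12 deg layout emulates the earlier
24.4-deg-aperture design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import VertexRecord, write_vertex_tables
from .stimuli import StimulusClass, make_catalog, local_stimulus_arrays
from .tuning import Model2DParams, VertexLocation, predict_matrix

__all__ = [
    "BRODERICK_V1_PARAMS",
    "NSD_V1_PARAMS",
    "NSD_V2_PARAMS",
    "NSD_V3_PARAMS",
    "SimulationConfig",
    "SyntheticSubject",
    "simulate_cohort",
    "simulate_prf_layout",
    "simulate_subject",
    "write_cohort",
]

#: Cohort-mean 2D-model parameter estimates for NSD V1 (the replication
#: dataset): bandwidth 2.2 octaves, preferred period 0.14*ecc + 0.18 deg/cycle,
#: vertical>horizontal period effect p1=0.08, oblique>cardinal p2=-0.02,
#: no radial effect, spiral>non-spiral p4=-0.03, amplitude effects A1=0.06,
#: A2=-0.02.
NSD_V1_PARAMS = Model2DParams(
    sigma=2.2, slope=0.14, intercept=0.18,
    p1=0.08, p2=-0.02, p3=0.0, p4=-0.03, A1=0.06, A2=-0.02,
)

#: NSD V2: markedly broader bandwidth (3.8 octaves) and the largest absolute
#: orientation effects; slope/intercept inside the printed 0.15-0.17 /
#: 0.17-0.25 ranges.
NSD_V2_PARAMS = Model2DParams(
    sigma=3.8, slope=0.17, intercept=0.25,
    p1=0.16, p2=-0.03, p3=-0.02, p4=0.0, A1=0.05, A2=-0.02,
)

#: NSD V3: the broadest bandwidth (4.5 octaves), weaker vertical-horizontal
#: effect.
NSD_V3_PARAMS = Model2DParams(
    sigma=4.5, slope=0.15, intercept=0.21,
    p1=0.05, p2=-0.02, p3=-0.02, p4=0.0, A1=0.04, A2=-0.02,
)

#: V1 estimates from the earlier 3T dataset (1-12 deg stimuli): same
#: bandwidth, shallower slope, about twice the intercept, positive radial
#: effect p3.
BRODERICK_V1_PARAMS = Model2DParams(
    sigma=2.2, slope=0.12, intercept=0.35,
    p1=0.07, p2=-0.03, p3=0.06, p4=0.0, A1=0.04, A2=-0.01,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Parameters
    ----------
    n_vertices : vertices per ROI per subject.
    ecc_range_deg : pRF eccentricity range; (0.5, 4.2) NSD-like, (1, 12)
        for the wide-aperture variant.
    true_params : generating 2D-model parameters per ROI.
    noise_sd_scale : trial noise SD as a fraction of the subject's mean
        noiseless response.
    noise_heterogeneity : lognormal sigma of the per-vertex noise-SD spread
        (0 = homoscedastic across vertices; the multiplier is normalized to
        mean 1).
    n_trials : trials per stimulus class.
    n_subjects : cohort size.
    param_jitter_sd : optional per-parameter SD of additive between-subject
        jitter of the generating parameters (keys from the parameter JSON
        key set, e.g. {"slope": 0.01}).
    negative_fraction : fraction of vertices generated with sign-flipped gain
        (exercises the negative-mean exclusion rule).
    prf_size_intercept, prf_size_slope : pRF size = intercept + slope * ecc.
    seed : master seed; every subject's data regenerate bit-identically from
        (config, subject_index).
    """

    n_vertices: int = 1000
    ecc_range_deg: tuple[float, float] = (0.5, 4.2)
    true_params: Mapping[str, Model2DParams] = field(
        default_factory=lambda: {"V1": NSD_V1_PARAMS}
    )
    noise_sd_scale: float = 0.5
    noise_heterogeneity: float = 0.3
    n_trials: int = 8
    n_subjects: int = 8
    param_jitter_sd: Mapping[str, float] | None = None
    negative_fraction: float = 0.02
    prf_size_intercept: float = 0.1
    prf_size_slope: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertices < 1 or self.n_trials < 1 or self.n_subjects < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd_scale < 0 or self.noise_heterogeneity < 0:
            raise ValueError("noise scales must be >= 0")
        lo, hi = self.ecc_range_deg
        if not (0 < lo < hi < 90):
            raise ValueError("ecc_range_deg must satisfy 0 < lo < hi < 90")


@dataclass
class SyntheticSubject:
    """One simulated subject: vertices with betas, plus the generating truth."""

    subject_id: str
    vertices: list[VertexRecord]
    truth: dict[str, Model2DParams]
    subject_precision: dict[str, float]
    noise_sd: dict[str, np.ndarray]


def simulate_prf_layout(
    n: int,
    ecc_range: tuple[float, float],
    seed: int | np.random.Generator = 0,
    size_intercept: float = 0.1,
    size_slope: float = 0.2,
) -> list[VertexLocation]:
    """Draw a pRF layout: log-uniform eccentricity, uniform polar angle.

    Log-uniform eccentricities put more vertices near the fovea, a coarse
    stand-in for cortical magnification; the empirical median sits near the
    geometric mean of the range. pRF size is affine in eccentricity.
    """
    lo, hi = ecc_range
    if not (0 < lo < hi < 90):
        raise ValueError("ecc_range must satisfy 0 < lo < hi < 90")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return []
    ecc = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    angle = rng.uniform(0.0, 2.0 * np.pi, size=n)
    size = size_intercept + size_slope * ecc
    return [
        VertexLocation(ecc_deg=float(e), angle_rad=float(a), prf_size_deg=float(s))
        for e, a, s in zip(ecc, angle, size)
    ]


def _jittered_truth(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, Model2DParams]:
    """Per-subject generating parameters, optionally jittered across subjects."""
    truth = {}
    for roi, params in config.true_params.items():
        if not config.param_jitter_sd:
            truth[roi] = params
            continue
        d = params.to_dict()
        for key, sd in config.param_jitter_sd.items():
            d[key] = d[key] + rng.normal(0.0, sd)
        # keep the jittered set inside the validity region
        d["sigma"] = max(d["sigma"], 0.05)
        d["intercept"] = max(d["intercept"], 0.01)
        truth[roi] = Model2DParams.from_dict(d)
    return truth


def simulate_subject(
    config: SimulationConfig,
    subject_index: int,
    catalog: Sequence[StimulusClass] | None = None,
) -> SyntheticSubject:
    """Simulate one subject's vertices and trial betas.

    For each vertex and each catalog class the noiseless beta is the 2D-model
    prediction at the vertex's pRF center; trials add independent Gaussian
    noise with a per-vertex SD drawn once per vertex. The per-vertex SD is
    ``noise_sd_scale * mean(noiseless betas)`` times a lognormal multiplier
    with unit mean and log-SD ``noise_heterogeneity``. Bit-identical given
    (config, subject_index).
    """
    catalog = catalog or make_catalog("nsd")
    rng = np.random.default_rng([config.seed, subject_index])
    truth = _jittered_truth(config, rng)

    vertices: list[VertexRecord] = []
    precision: dict[str, float] = {}
    noise_sd: dict[str, np.ndarray] = {}
    vid = 0
    for roi in sorted(truth):
        params = truth[roi]
        layout = simulate_prf_layout(
            config.n_vertices,
            config.ecc_range_deg,
            seed=rng,
            size_intercept=config.prf_size_intercept,
            size_slope=config.prf_size_slope,
        )
        ecc = np.array([l.ecc_deg for l in layout])
        ang = np.array([l.angle_rad for l in layout])
        period, ori = local_stimulus_arrays(ecc, ang, catalog)
        clean = predict_matrix(ecc, ang, period, ori, params.to_array())

        n_flip = int(round(config.negative_fraction * config.n_vertices))
        if n_flip:
            flip_idx = rng.choice(config.n_vertices, size=n_flip, replace=False)
            clean[flip_idx] *= -1.0

        base_sd = config.noise_sd_scale * float(np.mean(np.abs(clean)))
        h = config.noise_heterogeneity
        mult = np.exp(rng.normal(0.0, h, size=config.n_vertices) - 0.5 * h**2)
        sd = base_sd * mult
        noise = rng.normal(
            0.0, 1.0, size=(config.n_vertices, len(catalog), config.n_trials)
        ) * sd[:, None, None]
        betas = clean[:, :, None] + noise

        variances = []
        for i, loc in enumerate(layout):
            rec = VertexRecord(
                vertex_id=vid, location=loc, roi=roi, betas=betas[i]
            )
            vertices.append(rec)
            if config.n_trials >= 2:
                variances.append(rec.variance())
            vid += 1
        precision[roi] = float(np.mean(variances)) if variances else 0.0
        noise_sd[roi] = sd
    return SyntheticSubject(
        subject_id=f"subj{subject_index:02d}",
        vertices=vertices,
        truth=truth,
        subject_precision=precision,
        noise_sd=noise_sd,
    )


def simulate_cohort(
    config: SimulationConfig, catalog: Sequence[StimulusClass] | None = None
) -> list[SyntheticSubject]:
    """Simulate all subjects of a cohort (independently seeded per subject)."""
    catalog = catalog or make_catalog("nsd")
    return [
        simulate_subject(config, i, catalog) for i in range(config.n_subjects)
    ]


def write_cohort(
    cohort: Sequence[SyntheticSubject], out_dir: str | Path
) -> None:
    """Write a cohort in the vertex/beta CSV schema consumed by fitting.

    Per subject: ``<id>_vertices.csv``, ``<id>_betas.csv`` and a
    ``<id>_truth.json`` with the generating parameters per ROI; plus a
    cohort-level ``precision.csv`` (subject_id, roi, sigma_s2).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort:
        write_vertex_tables(
            subj.vertices,
            out / f"{subj.subject_id}_vertices.csv",
            out / f"{subj.subject_id}_betas.csv",
        )
        truth = {roi: p.to_dict() for roi, p in subj.truth.items()}
        (out / f"{subj.subject_id}_truth.json").write_text(
            json.dumps(truth, indent=2)
        )
        for roi, s2 in subj.subject_precision.items():
            rows.append(dict(subject_id=subj.subject_id, roi=roi, sigma_s2=s2))
    pd.DataFrame(rows).to_csv(out / "precision.csv", index=False)
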