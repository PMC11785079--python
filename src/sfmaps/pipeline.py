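"""Vertex filtering, run configuration, and the end-to-end cohort driver.

``run_replication`` chains every stage on a directory of per-subject
vertex/beta tables (synthetic or adapted real exports): filtering -> 1D binned
tuning fits and a period-vs-eccentricity line -> the 9-parameter 2D map fit
per subject and ROI -> precision-weighted aggregation with bootstrap CIs
across subjects, plus within-subject ROI contrasts when several ROIs are fit.
Everything is reproducible from the RunConfig alone; inputs are never mutated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .aggregation import (
    SubjectEstimate,
    bootstrap_ci68,
    roi_differences,
)
from .fitting import (
    OptConfig,
    VertexRecord,
    bin_vertices,
    fit_2d_model,
    fit_period_line,
    fit_tuning_1d,
    read_vertex_tables,
)
from .stimuli import StimulusClass, make_catalog
from .tuning import PARAM_KEYS

__all__ = [
    "FilterConfig",
    "RunConfig",
    "filter_vertices",
    "run_replication",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Vertex exclusion rules.

    Vertices are dropped when (i) their mean response across the stimulus
    classes relevant to the pathway is negative, (ii) their pRF center lies
    inside the largest anti-aliasing mask, or (iii), for the 2D pathway only,
    their pRF center is more than one pRF size outside the stimulus extent.
    Boundary cases keep the vertex (inclusive conventions).
    """

    max_mask_radius_deg: float = 0.5
    stimulus_extent_radius_deg: float = 4.2
    exclude_negative_mean: bool = True
    prf_size_rule: bool = True

    def __post_init__(self) -> None:
        if self.max_mask_radius_deg <= 0 or self.stimulus_extent_radius_deg <= 0:
            raise ValueError("radii must be positive")


def filter_vertices(
    vertices: Sequence[VertexRecord],
    filter_config: FilterConfig,
    mode: str,
    primary_class_ids: Sequence[int] | None = None,
) -> tuple[list[VertexRecord], dict[str, int]]:
    """Apply the exclusion rules; return survivors and a per-rule count log.

    ``mode`` is "1d" or "2d": the negative-mean rule uses the 24 primary
    classes for the 1D pathway and all classes for the 2D pathway, matching
    the class sets each model consumes; the pRF-size extent rule applies only
    in 2D mode. Each dropped vertex is charged to the first rule that catches
    it, so the counts sum to input - kept.
    """
    if mode not in ("1d", "2d"):
        raise ValueError("mode must be '1d' or '2d'")
    if primary_class_ids is None:
        primary_class_ids = range(24)
    primary = list(primary_class_ids)

    log = {"input": len(vertices), "negative_mean": 0, "inside_mask": 0,
           "outside_stimulus": 0, "kept": 0}
    kept: list[VertexRecord] = []
    for v in vertices:
        if filter_config.exclude_negative_mean:
            classes = primary if mode == "1d" else None
            if float(np.mean(v.mean_betas(classes))) < 0:
                log["negative_mean"] += 1
                continue
        if v.location.ecc_deg < filter_config.max_mask_radius_deg:
            log["inside_mask"] += 1
            continue
        if mode == "2d" and filter_config.prf_size_rule:
            limit = filter_config.stimulus_extent_radius_deg + v.location.prf_size_deg
            if v.location.ecc_deg > limit:
                log["outside_stimulus"] += 1
                continue
        kept.append(v)
    log["kept"] = len(kept)
    return kept, log


@dataclass
class RunConfig:
    """Everything needed to reproduce one cohort analysis run."""

    dataset: str = "nsd_synthetic"
    rois: tuple[str, ...] = ("V1",)
    bin_edges: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    n_boot: int = 10_000
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    opt: OptConfig = field(default_factory=OptConfig)
    out_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["rois"] = tuple(d["rois"])
        d["bin_edges"] = tuple(d["bin_edges"])
        d["filter"] = FilterConfig(**d.get("filter", {}))
        d["opt"] = OptConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d.get("opt", {}).items()
            }
        )
        return cls(**d)


def _subject_ids(input_dir: Path) -> list[str]:
    ids = sorted(p.name[: -len("_vertices.csv")]
                 for p in input_dir.glob("*_vertices.csv"))
    if not ids:
        raise FileNotFoundError(f"no *_vertices.csv files in {input_dir}")
    for sid in ids:
        beta = input_dir / f"{sid}_betas.csv"
        if not beta.exists():
            raise FileNotFoundError(f"missing beta table {beta}")
    return ids


def run_replication(
    config: RunConfig,
    input_dir: str | Path,
    catalog: Sequence[StimulusClass] | None = None,
) -> dict:
    """Run the full per-subject analysis and cohort aggregation.

    For each subject and ROI: filter vertices, fit 1D tuning curves per
    eccentricity bin and the period-vs-eccentricity line, then fit the
    9-parameter 2D model. Across subjects: precision-weighted means with
    bootstrapped 68% CIs for every 2D parameter and the 1D line coefficients,
    and within-subject ROI contrasts of each 2D parameter when more than one
    ROI is analyzed.

    Writes cohort.csv, roi_differences.csv, exclusion_log.csv, per-subject
    fit JSONs and a run manifest under ``config.out_dir``; also returns the
    results in memory. Fully deterministic given the RunConfig and inputs.
    """
    input_dir = Path(input_dir)
    catalog = catalog or make_catalog("nsd")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subject_ids = _subject_ids(input_dir)
    primary_ids = [c.class_id for c in catalog if c.shape != "mixture"]

    fits: dict[tuple[str, str], dict] = {}
    estimates: list[SubjectEstimate] = []
    line_estimates: list[SubjectEstimate] = []
    exclusion_rows = []
    for sid in subject_ids:
        records = read_vertex_tables(
            input_dir / f"{sid}_vertices.csv",
            input_dir / f"{sid}_betas.csv",
            n_classes=len(catalog),
        )
        by_roi: dict[str, list[VertexRecord]] = {}
        for r in records:
            by_roi.setdefault(r.roi, []).append(r)
        for roi in config.rois:
            vertices = by_roi.get(roi, [])
            if not vertices:
                logger.warning("subject %s has no %s vertices; skipped", sid, roi)
                continue
            # ---- 1D pathway ----
            kept1d, log1d = filter_vertices(
                vertices, config.filter, "1d", primary_ids
            )
            exclusion_rows.append(dict(subject_id=sid, roi=roi, mode="1d", **log1d))
            bins = bin_vertices(kept1d, np.asarray(config.bin_edges), catalog)
            curves = []
            for b in bins:
                if b.n_vertices == 0:
                    continue
                curve, ok = fit_tuning_1d(b)
                if ok:
                    curves.append(curve)
            slope1d, intercept1d = (np.nan, np.nan)
            if len(curves) >= 2:
                slope1d, intercept1d = fit_period_line(curves)

            # ---- 2D pathway ----
            kept2d, log2d = filter_vertices(
                vertices, config.filter, "2d", primary_ids
            )
            exclusion_rows.append(dict(subject_id=sid, roi=roi, mode="2d", **log2d))
            fit = fit_2d_model(
                kept2d, catalog, opt_config=config.opt, seed=config.seed
            )
            sigma_s2 = float(np.mean([v.variance() for v in kept2d]))
            sigma_s2_1d = float(
                np.mean([v.variance(primary_ids) for v in kept1d])
            ) if kept1d else np.nan

            fits[(sid, roi)] = dict(
                subject_id=sid,
                roi=roi,
                params=fit.params.to_dict(),
                final_loss=fit.final_loss,
                n_vertices=fit.n_vertices_used,
                n_iter=fit.n_iter,
                converged=fit.converged,
                seed=config.seed,
                sigma_s2=sigma_s2,
                line_1d=dict(slope=slope1d, intercept=intercept1d,
                             sigma_s2=sigma_s2_1d),
                curves_1d=[
                    dict(bin_center_deg=c.bin_center_deg, gain_A=c.gain_A,
                         p_peak_dpc=c.p_peak_dpc, sigma_oct=c.sigma_oct)
                    for c in curves
                ],
            )
            (out / f"{sid}_{roi}_fit.json").write_text(
                json.dumps(fits[(sid, roi)], indent=2)
            )
            for key, val in fit.params.to_dict().items():
                estimates.append(
                    SubjectEstimate(subject_id=sid, roi=roi, value=val,
                                    precision_var=sigma_s2)
                )
            if np.isfinite(slope1d):
                line_estimates.append(
                    SubjectEstimate(subject_id=sid, roi=roi, value=slope1d,
                                    precision_var=sigma_s2_1d)
                )
        logger.info("subject %s done", sid)

    # ---- aggregation ----
    cohort_rows = []
    for roi_i, roi in enumerate(config.rois):
        for par_i, key in enumerate(PARAM_KEYS):
            ests = [
                SubjectEstimate(sid, roi, fits[(sid, roi)]["params"][key],
                                fits[(sid, roi)]["sigma_s2"])
                for sid in subject_ids if (sid, roi) in fits
            ]
            if len(ests) < 2:
                continue
            summary = bootstrap_ci68(
                ests, n_boot=config.n_boot,
                seed=config.seed + 1000 * roi_i + par_i,
            )
            cohort_rows.append(
                dict(roi=roi, parameter=key, mean=summary.mean,
                     ci_low=summary.ci68[0], ci_high=summary.ci68[1],
                     n_subjects=summary.n_subjects, n_boot=summary.n_boot,
                     seed=summary.seed)
            )
        # 1D line slope across subjects
        line_ests = [e for e in line_estimates if e.roi == roi]
        if len(line_ests) >= 2:
            summary = bootstrap_ci68(
                line_ests, n_boot=config.n_boot,
                seed=config.seed + 1000 * roi_i + 500,
            )
            cohort_rows.append(
                dict(roi=roi, parameter="slope_1d", mean=summary.mean,
                     ci_low=summary.ci68[0], ci_high=summary.ci68[1],
                     n_subjects=summary.n_subjects, n_boot=summary.n_boot,
                     seed=summary.seed)
            )
    cohort = pd.DataFrame(cohort_rows)
    cohort.to_csv(out / "cohort.csv", index=False)

    diff_rows = []
    contrasts = [
        (a, b) for i, b in enumerate(config.rois) for a in config.rois[i + 1:]
    ]
    for par_i, key in enumerate(PARAM_KEYS):
        ests = [
            SubjectEstimate(sid, roi, fits[(sid, roi)]["params"][key],
                            fits[(sid, roi)]["sigma_s2"])
            for (sid, roi) in fits
        ]
        for c_i, (roi_a, roi_b) in enumerate(contrasts):
            try:
                _, summary = roi_differences(
                    ests, roi_a, roi_b, n_boot=config.n_boot,
                    seed=config.seed + 10_000 + 100 * c_i + par_i,
                )
            except ValueError:
                continue
            diff_rows.append(
                dict(contrast=f"{roi_a}-{roi_b}", parameter=key,
                     mean=summary.mean, ci_low=summary.ci68[0],
                     ci_high=summary.ci68[1], n_subjects=summary.n_subjects)
            )
    differences = pd.DataFrame(diff_rows)
    if not differences.empty:
        differences.to_csv(out / "roi_differences.csv", index=False)

    exclusions = pd.DataFrame(exclusion_rows)
    exclusions.to_csv(out / "exclusion_log.csv", index=False)
    from . import __version__

    manifest = dict(
        package_version=__version__,
        config=asdict(config),
        subjects=subject_ids,
        input_dir=str(input_dir),
    )
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))

    return dict(
        fits=fits,
        cohort=cohort,
        roi_differences=differences,
        exclusions=exclusions,
        manifest=manifest,
    )
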