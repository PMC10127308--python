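"""Headless orchestration of the full cone-segmentation pipeline.

Stages: global PCA alignment of the cornea point cloud → division into
overlapping sub-regions with local alignment and poly55 surface modelling →
unfolding of each sub-region along interior surface normals → patch-
dictionary texture segmentation of the unfolded slices → back-transformation
into scan coordinates → post-processing cascade.  Sub-region results are
merged before the final de-duplication stage, so duplicates arising in the
overlap strips are resolved by the same 13 μm cut-off mechanism as any other
abnormally close pair.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
import yaml

from coneseg import cones as cones_mod
from coneseg import metrics as metrics_mod
from coneseg.geometry import divide_subregions, fit_poly55, pca_frame
from coneseg.texseg import PatchDictionary, annotation_from_mask
from coneseg.unfold import back_transform, spline_coefficients, surface_grid, unfold_volume
from coneseg.volio import ConeTable, LabelVolume, Volume, write_cone_table

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """User-set parameters of a segmentation run; lengths in μm."""

    # geometry
    n_subregions: int = 9
    overlap: float = 20.0
    uv_spacing: float | None = None      # default: half a voxel (oversampled)
    depth_min: float = 0.0
    depth_max: float = 120.0
    depth_step: float | None = None      # default: half a voxel
    # texture segmentation
    patch_size: int = 5                  # ~one ommatidial spacing at 4 μm/voxel
    n_clusters: int = 1000
    p_threshold: float = 0.6
    train_subregion: int = 0
    train_slice: int | None = None       # default: slice with most annotated cone pixels
    # post-processing
    min_size: int = 10
    k_mad: float = 4.0
    cutoff_um: float = 13.0
    gmm_mode: str = "auto"
    # metrics
    range_um: float = 100.0
    density_points: int = 200
    # reproducibility
    seed: int = 0
    interpolation_order: int = 3         # 3 tricubic, 1 trilinear fallback

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f)


@dataclasses.dataclass
class PipelineResult:
    cone_table: ConeTable
    report: cones_mod.EliminationReport
    global_frame: object
    grid: object
    subregion_frames: list
    surfaces: list
    metrics: metrics_mod.MetricsReport | None = None
    stage_log: list = dataclasses.field(default_factory=list)


def _stage(stage_log, name, t0, **counts):
    entry = {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **counts}
    stage_log.append(entry)
    log.info("stage %s: %s", name, entry)


def run_pipeline(volume: Volume, cornea: LabelVolume, eye: LabelVolume,
                 config: RunConfig | None = None, *,
                 annotation: np.ndarray | None = None,
                 train_mask_volume: LabelVolume | None = None,
                 dictionary: PatchDictionary | None = None,
                 facet_samples: np.ndarray | None = None,
                 reference_cones: ConeTable | None = None,
                 out_dir=None) -> PipelineResult:
    """Run alignment → surfaces → unfolding → segmentation → back-mapping →
    post-processing (→ metrics) end to end.

    The dictionary-training annotation comes from (in order of precedence) a
    pre-trained ``dictionary``, an ``annotation`` image for the training
    slice, or a ``train_mask_volume`` (e.g. phantom ground-truth cone label)
    that is unfolded alongside the data to derive a dense annotation.
    """
    cfg = config or RunConfig()
    # oversample the unfolded grid 2x relative to the scan: 1:1 resampling
    # leaves nearest-voxel rounding holes on back-transformation wherever the
    # surface is tilted, which fragments cones under 6-connectivity
    uv = cfg.uv_spacing or volume.voxel_size / 2
    dd = cfg.depth_step or volume.voxel_size / 2
    stage_log = []

    # (a) global alignment
    t0 = time.perf_counter()
    cornea_pts = cornea.coords()
    interior_ref = eye.index_to_world(np.argwhere(eye.data > 0).mean(axis=0))
    gframe = pca_frame(cornea_pts, interior_ref)
    gpts = gframe.to_local(cornea_pts)
    interior_g = gframe.to_local(interior_ref)
    _stage(stage_log, "align", t0, n_cornea_voxels=len(cornea_pts))

    # (b) sub-regions and surface modelling
    t0 = time.perf_counter()
    grid = divide_subregions(gpts[:, :2], cfg.n_subregions, cfg.overlap)
    membership = grid.membership(gpts[:, :2])
    lframes, surfaces = [], []
    for sr, idx in enumerate(membership):
        # in-plane orientation locked to the global x' axis so one patch
        # dictionary transfers across sub-regions
        lframe = pca_frame(gpts[idx], interior_g, orientation_ref=(1.0, 0.0, 0.0))
        lframes.append(lframe)
        surfaces.append(fit_poly55(lframe.to_local(gpts[idx])))
    _stage(stage_log, "surfaces", t0,
           rmse_um=[round(s.rmse, 3) for s in surfaces])

    # (c–e) per sub-region: unfold, segment, back-transform
    coeffs = spline_coefficients(volume)
    combined = np.zeros(volume.shape, dtype=np.int32)
    depth = (cfg.depth_min, cfg.depth_max, dd)
    unfolded_cache = []
    for sr, idx in enumerate(membership):
        t0 = time.perf_counter()
        local = lframes[sr].to_local(gpts[idx])
        rect = (local[:, 0].min(), local[:, 0].max(), local[:, 1].min(), local[:, 1].max())
        sgrid = surface_grid(surfaces[sr], rect, uv)
        unf = unfold_volume(volume, sgrid, (gframe, lframes[sr]), depth,
                            order=cfg.interpolation_order, coefficients=coeffs)
        # columns outside the cornea footprint (rectangle corners of a curved
        # patch) are polynomial extrapolation, not surface: mask them out
        support = cKDTree(local[:, :2])
        U, V = np.meshgrid(sgrid.u, sgrid.v, indexing="ij")
        dist, _ = support.query(np.column_stack([U.ravel(), V.ravel()]))
        valid_uv = (dist <= 1.5 * volume.voxel_size).reshape(U.shape)
        unfolded_cache.append((sgrid, unf, valid_uv))
        _stage(stage_log, f"unfold[{sr}]", t0, shape=list(unf.data.shape),
               n_valid_columns=int(valid_uv.sum()))

    if dictionary is None:
        t0 = time.perf_counter()
        sr = cfg.train_subregion
        sgrid, unf, valid_uv = unfolded_cache[sr]
        if annotation is None:
            if train_mask_volume is None:
                raise ValueError("need a dictionary, an annotation image, or a training mask volume")
            fmask = Volume(np.asarray(train_mask_volume.data > 0, float),
                           train_mask_volume.voxel_size, train_mask_volume.origin)
            unf_mask = unfold_volume(fmask, sgrid, (gframe, lframes[sr]), depth, order=1)
            mask3d = unf_mask.data > 0.5
            iw = cfg.train_slice if cfg.train_slice is not None \
                else int(np.argmax(mask3d.sum(axis=(0, 1))))
            annotation = annotation_from_mask(mask3d[:, :, iw])
            annotation[~valid_uv] = 0  # extrapolated columns carry no signal
            train_slice = unf.data[:, :, iw]
        else:
            iw = cfg.train_slice if cfg.train_slice is not None else unf.data.shape[2] // 2
            train_slice = unf.data[:, :, iw]
        dictionary = PatchDictionary(cfg.patch_size, cfg.n_clusters, cfg.seed)
        dictionary.build(train_slice).train(train_slice, annotation)
        _stage(stage_log, "train", t0, train_subregion=sr, train_slice=int(iw))

    for sr, (sgrid, unf, valid_uv) in enumerate(unfolded_cache):
        t0 = time.perf_counter()
        mask = dictionary.segment_stack(unf, cfg.p_threshold)
        mask &= valid_uv[:, :, None]
        back = back_transform(unf, mask, volume)
        np.maximum(combined, (back.data > 0).astype(np.int32), out=combined)
        _stage(stage_log, f"segment[{sr}]", t0, n_mask_voxels=int(mask.sum()))

    # (f) post-processing
    t0 = time.perf_counter()
    raw_label = LabelVolume(combined, volume.voxel_size, volume.origin)
    table, report = cones_mod.postprocess(
        raw_label, cornea_pts, gframe, grid, lframes,
        min_size=cfg.min_size, k_mad=cfg.k_mad, cutoff_um=cfg.cutoff_um,
        gmm_mode=cfg.gmm_mode, seed=cfg.seed)
    _stage(stage_log, "postprocess", t0, n_raw=report.n_raw, n_valid=report.n_valid,
           removed=report.removed)

    result = PipelineResult(table, report, gframe, grid, lframes, surfaces,
                            stage_log=stage_log)

    # metrics (optional)
    mrep = metrics_mod.MetricsReport()
    mrep.surface_modelling_error = metrics_mod.surface_modelling_error(surfaces)
    mrep.n_valid = report.n_valid
    if facet_samples is not None:
        mrep.n_predicted = metrics_mod.predict_ommatidia(facet_samples, cornea)
        mrep.pct_segmented = metrics_mod.pct_segmented(report.n_valid, mrep.n_predicted)
        mrep.density_ratio = metrics_mod.density_ratio(
            table.valid, cornea, facet_samples, cfg.range_um, cfg.density_points)
    if reference_cones is not None:
        _, alphas = metrics_mod.match_duplicates(table.valid, reference_cones,
                                                 volume.voxel_size)
        mrep.alpha_per_pair = alphas
        mrep.alpha_mean = float(np.mean(alphas)) if alphas else np.nan
    result.metrics = mrep

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cone_table(table, out / "cones.csv")
        report.to_json(out / "elimination_report.json")
        mrep.to_json(out / "metrics.json")
        with open(out / "stages.jsonl", "w") as f:
            for entry in stage_log:
                f.write(json.dumps(entry) + "\n")
    return result
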