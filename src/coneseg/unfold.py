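"""Unfolding a curved cornea-referenced layer into a flat (u, v, w) volume.

The fitted sub-region surface is resampled on a regular (u, v) grid; each
sample point carries the surface normal pointing toward the eye interior.
Marching a depth ``w`` along the normal and sampling the scan volume with
tricubic interpolation produces an "unfolded" sub-volume in which the
crystalline-cone layer is flat and the cone cross-sections form a regular
pattern of small discs.  The exact (u, v, w) → world map is stored so labels
drawn in unfolded coordinates can be mapped back into scan coordinates.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from coneseg.geometry import PcaFrame, PolySurface
from coneseg.volio import LabelVolume, Volume

__all__ = [
    "SampleGrid", "UnfoldedVolume", "surface_grid", "unfold_volume",
    "back_transform", "spline_coefficients", "save_unfolded", "load_unfolded",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class SampleGrid:
    """Regular (u, v) resampling of a fitted surface, in the local frame.

    ``points[iu, iv]`` is the 3D surface point at (u[iu], v[iv], f(u, v));
    ``normals[iu, iv]`` is the unit surface normal pointing toward the eye
    interior (positive local z component).
    """

    u: np.ndarray
    v: np.ndarray
    points: np.ndarray   # (nu, nv, 3)
    normals: np.ndarray  # (nu, nv, 3)
    uv_spacing: float

    def __post_init__(self):
        norms = np.linalg.norm(self.normals, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("normals must be unit vectors")
        if not (self.normals[..., 2] > 0).all():
            raise ValueError("normals must point toward the interior (+z in the local frame)")


def surface_grid(surface: PolySurface, rectangle, uv_spacing: float) -> SampleGrid:
    """Resample ``surface`` over ``rectangle = (xmin, xmax, ymin, ymax)``.

    Normals are the analytic surface normals ∝ (−∂f/∂x, −∂f/∂y, 1),
    normalized; with the local frame's interior-at-+z convention they point
    into the eye.
    """
    if uv_spacing <= 0:
        raise ValueError("uv_spacing must be positive")
    x0, x1, y0, y1 = rectangle
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty rectangle")
    u = np.arange(x0, x1 + uv_spacing / 2, uv_spacing)
    v = np.arange(y0, y1 + uv_spacing / 2, uv_spacing)
    U, V = np.meshgrid(u, v, indexing="ij")
    Z = surface.evaluate(U, V)
    gx, gy = surface.gradient(U, V)
    n = np.stack([-gx, -gy, np.ones_like(gx)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    points = np.stack([U, V, Z], axis=-1)
    return SampleGrid(u, v, points, n, uv_spacing)


@dataclasses.dataclass
class UnfoldedVolume:
    """A sub-volume resampled into flat (u, v, w) coordinates.

    ``data[iu, iv, iw]`` is the intensity at depth ``w = d_min + iw * Δd``
    along the interior normal of surface sample (iu, iv).  ``world_map``
    stores the original scan world coordinate (μm) of every unfolded voxel;
    ``outside`` flags queries that fell outside the scan volume.
    """

    data: np.ndarray        # (nu, nv, nw)
    depth_range: tuple      # (d_min, d_max, Δd) μm
    world_map: np.ndarray   # (nu, nv, nw, 3) μm
    outside: np.ndarray     # (nu, nv, nw) bool

    def __post_init__(self):
        if self.world_map.shape != self.data.shape + (3,):
            raise ValueError("world_map shape inconsistent with data")

    @property
    def w(self) -> np.ndarray:
        d0, d1, dd = self.depth_range
        return d0 + dd * np.arange(self.data.shape[2])


def spline_coefficients(volume: Volume) -> np.ndarray:
    """Precompute cubic-spline coefficients of a volume for repeated unfolds."""
    return ndimage.spline_filter(np.asarray(volume.data, float), order=3, mode="mirror")


def unfold_volume(volume: Volume, grid: SampleGrid, frames, depth_range,
                  order: int = 3, fill: float = 0.0,
                  coefficients: np.ndarray | None = None) -> UnfoldedVolume:
    """Sample ``volume`` along the grid normals into a flat (u, v, w) block.

    Parameters
    ----------
    frames : (PcaFrame, PcaFrame)
        The (global, local) frames to undo: a grid point p (local frame)
        maps to scan world coordinates ``global.to_world(local.to_world(p))``.
    depth_range : (d_min, d_max, Δd) μm
        Depths along the normal; the last layer is at the largest
        ``d_min + k Δd ≤ d_max``.
    order : int
        3 = tricubic (cubic-spline) interpolation, the default; 1 = trilinear
        fallback for memory-constrained runs.
    coefficients : ndarray, optional
        Output of :func:`spline_coefficients` to reuse across sub-regions.
    """
    gframe, lframe = frames
    d0, d1, dd = depth_range
    if dd <= 0 or d1 < d0:
        raise ValueError("invalid depth_range")
    w = d0 + dd * np.arange(int(np.floor((d1 - d0) / dd + 1e-9)) + 1)

    pts_local = grid.points[:, :, None, :] + w[None, None, :, None] * grid.normals[:, :, None, :]
    nu, nv, nw = pts_local.shape[:3]
    world = gframe.to_world(lframe.to_world(pts_local.reshape(-1, 3)))
    idx = volume.world_to_index(world)

    shape = np.array(volume.shape)
    outside = ((idx < -0.5) | (idx > shape - 0.5)).any(axis=1)
    if outside.all():
        raise ValueError("sample grid lies entirely outside the volume")

    if order == 3:
        src = coefficients if coefficients is not None else spline_coefficients(volume)
        data = ndimage.map_coordinates(src, idx.T, order=3, mode="mirror", prefilter=False)
    else:
        data = ndimage.map_coordinates(np.asarray(volume.data, float), idx.T,
                                       order=order, mode="nearest")
    data[outside] = fill
    return UnfoldedVolume(data.reshape(nu, nv, nw), (d0, d1, dd),
                          world.reshape(nu, nv, nw, 3), outside.reshape(nu, nv, nw))


def save_unfolded(unfolded: UnfoldedVolume, surface: PolySurface, rectangle,
                  uv_spacing: float, frames, volume: Volume, path_base) -> None:
    """Persist an unfolded sub-volume as TIFF + JSON sidecar.

    The sidecar stores the surface model, rectangle, spacing, frames, depth
    range and the source volume geometry with full float precision, which is
    sufficient to reconstruct the (u, v, w) → world map bit-exactly by
    re-running the deterministic grid construction.
    """
    import json
    from pathlib import Path

    import tifffile

    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(base.with_suffix(".tif")),
                     np.transpose(unfolded.data, (2, 1, 0)).astype(np.float32))
    gframe, lframe = frames
    meta = {
        "surface": surface.to_dict(),
        "rectangle": [float(v) for v in rectangle],
        "uv_spacing": float(uv_spacing),
        "global_frame": gframe.to_dict(),
        "local_frame": lframe.to_dict(),
        "depth_range": [float(v) for v in unfolded.depth_range],
        "volume": {"shape": list(volume.shape), "voxel_size": volume.voxel_size,
                   "origin": volume.origin.tolist()},
    }
    with open(base.with_suffix(".json"), "w") as f:
        json.dump(meta, f)


def load_unfolded(path_base):
    """Reload a persisted unfolded sub-volume and rebuild its world map.

    Returns ``(unfolded, sample_grid, frames)``.
    """
    import json
    from pathlib import Path

    import tifffile

    base = Path(path_base)
    data = np.transpose(tifffile.imread(str(base.with_suffix(".tif"))), (2, 1, 0)).astype(float)
    with open(base.with_suffix(".json")) as f:
        meta = json.load(f)
    surface = PolySurface.from_dict(meta["surface"])
    grid = surface_grid(surface, meta["rectangle"], meta["uv_spacing"])
    gframe = PcaFrame.from_dict(meta["global_frame"])
    lframe = PcaFrame.from_dict(meta["local_frame"])
    d0, d1, dd = meta["depth_range"]
    w = d0 + dd * np.arange(data.shape[2])
    pts_local = grid.points[:, :, None, :] + w[None, None, :, None] * grid.normals[:, :, None, :]
    world = gframe.to_world(lframe.to_world(pts_local.reshape(-1, 3)))
    vol = meta["volume"]
    idx = (world - np.asarray(vol["origin"])) / vol["voxel_size"]
    shape = np.asarray(vol["shape"])
    outside = ((idx < -0.5) | (idx > shape - 0.5)).any(axis=1)
    unf = UnfoldedVolume(data, (d0, d1, dd), world.reshape(data.shape + (3,)),
                         outside.reshape(data.shape))
    return unf, grid, (gframe, lframe)


def back_transform(unfolded: UnfoldedVolume, labels: np.ndarray,
                   target: Volume | LabelVolume) -> LabelVolume:
    """Map unfolded (u, v, w) labels back into scan voxel coordinates.

    Each labelled unfolded voxel maps through the stored world map and rounds
    to the nearest scan voxel.  Foreground wins over background; where two
    label ids collide the lower id is kept.  Targets outside the volume are
    dropped (counted in the log).
    """
    labels = np.asarray(labels)
    if labels.shape != unfolded.data.shape:
        raise ValueError("labels shape must match the unfolded data")
    out = np.zeros(target.shape, dtype=np.int32)
    sel = (labels > 0) & ~unfolded.outside
    if not sel.any():
        return LabelVolume(out, target.voxel_size, target.origin)
    idx = np.rint(target.world_to_index(unfolded.world_map[sel])).astype(np.int64)
    vals = labels[sel].astype(np.int32)
    shape = np.array(target.shape)
    ok = ((idx >= 0) & (idx < shape)).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("back_transform: dropped %d out-of-volume targets", n_dropped)
    idx, vals = idx[ok], vals[ok]
    sentinel = np.iinfo(np.int32).max
    acc = np.full(target.shape, sentinel, dtype=np.int32)
    np.minimum.at(acc, (idx[:, 0], idx[:, 1], idx[:, 2]), vals)
    out = np.where(acc == sentinel, 0, acc).astype(np.int32)
    return LabelVolume(out, target.voxel_size, target.origin)
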