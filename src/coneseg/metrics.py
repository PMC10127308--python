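"""Performance measures of the cone auto-segmentation.

Five measures: mean surface-modelling rmse over sub-regions; predicted
ommatidium count from the cornea isosurface area and an interpolated facet
area (regular-hexagon area (√3/2)·d² from the flat-to-flat facet diameter d);
the percentage of predicted ommatidia recovered as valid cones; the angular
discrepancy α between paired elongation axes of two segmentations of the
same cone; and the local cone density ratio R ∈ [0, 1] on equidistant
sampling points over the cornea surface.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree
from skimage import measure

from coneseg.volio import ConeTable, LabelVolume

__all__ = [
    "MetricsReport", "surface_modelling_error", "hexagon_area", "cornea_mesh",
    "predict_ommatidia", "pct_segmented", "match_duplicates", "density_ratio",
    "farthest_point_sampling",
]


@dataclasses.dataclass
class MetricsReport:
    surface_modelling_error: float = np.nan   # μm
    n_valid: int = 0
    n_predicted: float = np.nan
    pct_segmented: float = np.nan             # %
    alpha_mean: float = np.nan                # degrees
    alpha_per_pair: list = dataclasses.field(default_factory=list)
    density_ratio: list = dataclasses.field(default_factory=list)  # dicts x,y,z,R

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, default=float)


def surface_modelling_error(surfaces) -> float:
    """Unweighted mean of the per-sub-region poly55 rmse, in μm."""
    rmses = [s.rmse for s in surfaces]
    if not rmses:
        raise ValueError("need at least one fitted surface")
    return float(np.mean(rmses))


def hexagon_area(diameter_um) -> np.ndarray:
    """Area of a regular hexagonal facet from its flat-to-flat diameter."""
    d = np.asarray(diameter_um, float)
    return np.sqrt(3) / 2 * d**2


def cornea_mesh(cornea_label: LabelVolume):
    """Triangulated 0.5-isosurface of the cornea label, in world μm.

    The label is a thin surface shell, so marching cubes meshes both its
    faces; the reported total area is half the raw mesh area.  Returns
    ``(verts, faces, tri_areas, total_area)`` with per-triangle areas already
    halved.
    """
    from scipy import ndimage

    vs = cornea_label.voxel_size
    # smooth the binary mask before meshing: a staircase isosurface of a raw
    # binary volume overestimates the area by tens of percent
    field = ndimage.gaussian_filter((cornea_label.data > 0).astype(np.float64), sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=(vs, vs, vs))
    verts = verts + cornea_label.origin
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    tri_areas = 0.5 * np.linalg.norm(cross, axis=1) / 2.0  # half: shell has two faces
    return verts, faces, tri_areas, float(tri_areas.sum())


def _facet_area_interpolant(facet_samples: np.ndarray):
    """Nearest-neighbour + linear interpolant of facet area over the surface.

    Sample positions lie on a curved surface, so the linear part operates in
    the plane of the samples' two leading principal axes, with
    nearest-neighbour fallback outside the convex hull (or for degenerate
    footprints).
    """
    samples = np.asarray(facet_samples, float)
    if samples.shape[0] < 3 or samples.shape[1] != 4:
        raise ValueError("facet_samples must be (n >= 3, 4): x, y, z, diameter")
    pos, areas = samples[:, :3], hexagon_area(samples[:, 3])
    mean = pos.mean(axis=0)
    _, _, vt = np.linalg.svd(pos - mean, full_matrices=False)
    plane = vt[:2]

    def project(p):
        return (np.asarray(p, float) - mean) @ plane.T

    p2 = project(pos)
    nearest = NearestNDInterpolator(p2, areas)
    try:
        lin = LinearNDInterpolator(p2, areas)
    except Exception:
        lin = None

    def interp(points3d):
        q = project(points3d)
        out = lin(q) if lin is not None else np.full(len(q), np.nan)
        bad = ~np.isfinite(out)
        if bad.any():
            out[bad] = nearest(q[bad])
        return out

    return interp


def predict_ommatidia(facet_samples: np.ndarray, cornea_label: LabelVolume) -> float:
    """Predicted total ommatidium count: cornea area / mean facet area.

    ``facet_samples`` rows are (x, y, z, flat-to-flat diameter μm) measured at
    scattered locations over the eye.  The facet area is interpolated at the
    mesh triangle centroids and averaged with triangle-area weights.
    """
    verts, faces, tri_areas, total_area = cornea_mesh(cornea_label)
    if total_area <= 0:
        raise ValueError("degenerate cornea mesh")
    centroids = verts[faces].mean(axis=1)
    interp = _facet_area_interpolant(facet_samples)
    facet_areas = interp(centroids)
    mean_area = float(np.average(facet_areas, weights=tri_areas))
    return total_area / mean_area


def pct_segmented(n_valid: int, n_predicted: float) -> float:
    """Percentage of predicted ommatidia recovered as valid cones."""
    if not n_predicted > 0:
        raise ValueError("predicted count must be positive")
    pct = 100.0 * n_valid / n_predicted
    return pct


def match_duplicates(auto: ConeTable, reference: ConeTable, voxel_size: float,
                     max_dist: float | None = None):
    """Greedy one-to-one pairing of auto and reference cones by centre distance.

    Two segmentations of the same cone are duplicates if their centres are
    less than a voxel apart (``max_dist`` overrides the radius).  Pairs are
    formed nearest-first, each cone used once.  Returns
    ``(pairs, alpha_deg)``: index pairs (auto_row, ref_row) and the angle α ∈
    [0°, 180°] between the paired elongation axes.
    """
    radius = voxel_size if max_dist is None else max_dist
    a_pts, r_pts = auto.centres, reference.centres
    if len(a_pts) == 0 or len(r_pts) == 0:
        return [], []
    tree = cKDTree(r_pts)
    cand = []
    for ia, p in enumerate(a_pts):
        for ir in tree.query_ball_point(p, radius):
            d = np.linalg.norm(p - r_pts[ir])
            if d < radius:
                cand.append((d, ia, ir))
    cand.sort()
    used_a, used_r, pairs = set(), set(), []
    for _, ia, ir in cand:
        if ia in used_a or ir in used_r:
            continue
        used_a.add(ia)
        used_r.add(ir)
        pairs.append((ia, ir))
    a_axes, r_axes = auto.axes, reference.axes
    alphas = []
    for ia, ir in pairs:
        dot = float(np.clip(np.dot(a_axes[ia], r_axes[ir]), -1.0, 1.0))
        alphas.append(float(np.degrees(np.arccos(dot))))
    return pairs, alphas


def farthest_point_sampling(points: np.ndarray, n_points: int) -> np.ndarray:
    """Deterministic farthest-point subset; start at the point of extreme x."""
    pts = np.asarray(points, float)
    n_points = min(n_points, len(pts))
    chosen = [int(np.argmax(pts[:, 0]))]
    dist = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for _ in range(n_points - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[chosen]


def density_ratio(valid_cones: ConeTable, cornea_label: LabelVolume,
                  facet_samples: np.ndarray, range_um: float = 100.0,
                  n_points: int = 200):
    """Local cone density ratio R ∈ [0, 1] at equidistant surface points.

    At each sampling point (farthest-point sampling over the cornea surface
    voxels), R is the number of valid cone centres within ``range_um``
    divided by the expected ommatidium count there — the local cornea area
    within range over the local mean facet area — clamped to [0, 1].
    R = 1 means every locally predicted cone was identified.
    """
    surf_pts = cornea_label.coords()
    samples = farthest_point_sampling(surf_pts, n_points)
    verts, faces, tri_areas, _ = cornea_mesh(cornea_label)
    centroids = verts[faces].mean(axis=1)
    interp = _facet_area_interpolant(facet_samples)
    facet_at_tri = interp(centroids)
    tri_tree = cKDTree(centroids)
    cone_tree = cKDTree(valid_cones.centres) if len(valid_cones) else None

    out = []
    for p in samples:
        tri_idx = tri_tree.query_ball_point(p, range_um)
        local_area = float(tri_areas[tri_idx].sum())
        if local_area <= 0:
            continue
        mean_facet = float(np.average(facet_at_tri[tri_idx], weights=tri_areas[tri_idx]))
        expected = local_area / mean_facet
        n_found = len(cone_tree.query_ball_point(p, range_um)) if cone_tree else 0
        R = float(np.clip(n_found / expected, 0.0, 1.0))
        out.append({"x": float(p[0]), "y": float(p[1]), "z": float(p[2]), "R": R})
    return out


def density_ratio_to_csv(ratios: list, path) -> None:
    import pandas as pd

    pd.DataFrame(ratios, columns=["x", "y", "z", "R"]).to_csv(path, index=False)
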