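"""Post-processing of raw back-transformed cone labels.

The raw segmentation unavoidably contains detections that are not crystalline
cones.  The cascade here: (i) connected-component analysis in scan
coordinates under 6-connectivity; (ii) per-component PCA characteristics
(centre, elongation axis oriented toward the cornea, length, radius, voxel
count, mean distance to the three nearest neighbours); (iii) four elimination
stages — minimum size, per-sub-region surface-residual Gaussian-mixture/AIC
group validation, robust poly55 residual screening of five per-cone fields,
and single-linkage de-duplication of abnormally close fitted centres.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from sklearn.mixture import GaussianMixture

from coneseg.geometry import PcaFrame, SubregionGrid, fit_poly55
from coneseg.volio import ConeTable, CONE_COLUMNS, LabelVolume

__all__ = [
    "RawCone", "EliminationReport", "extract_raw_cones", "cone_characteristics",
    "neighbour_distances", "filter_min_size", "filter_gmm_residuals",
    "filter_poly_outliers", "dedup_linkage", "gmm_select", "postprocess",
    "cones_to_table",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RawCone:
    """One connected component of the raw segmentation, in world μm."""

    id: int
    voxels: np.ndarray           # (n, 3) world μm voxel centres
    centre: np.ndarray = None
    axis: np.ndarray = None      # unit, oriented toward the cornea
    length: float = np.nan
    radius: float = np.nan
    nn_dist: float = np.nan
    status: str = "raw"

    @property
    def size(self) -> int:
        return len(self.voxels)


def extract_raw_cones(label: LabelVolume) -> list[RawCone]:
    """Individually label each raw cone by 6-connected component analysis."""
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    lab, n = ndimage.label(label.data > 0, structure=structure)
    if n == 0:
        return []
    objects = ndimage.find_objects(lab)
    cones = []
    for i, sl in enumerate(objects, start=1):
        local = np.argwhere(lab[sl] == i)
        idx = local + np.array([s.start for s in sl])
        cones.append(RawCone(id=i, voxels=label.index_to_world(idx)))
    return cones


def cone_characteristics(voxels: np.ndarray, cornea_points) -> RawCone:
    """PCA characteristics of one voxel set.

    The elongation axis is the first principal eigenvector, signed so it
    points toward the nearest cornea surface point; length is the extent of
    the projections on the axis and radius the mean half-extent on the two
    minor axes.  Components with fewer than 4 voxels get undefined
    characteristics (they are always removed by the size filter anyway).
    """
    voxels = np.asarray(voxels, float)
    cone = RawCone(id=0, voxels=voxels)
    cone.centre = voxels.mean(axis=0)
    if len(voxels) < 4:
        return cone
    cov = np.cov((voxels - cone.centre).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    axis = evecs[:, 0]
    tree = cornea_points if isinstance(cornea_points, cKDTree) else cKDTree(np.asarray(cornea_points, float))
    nearest = tree.data[tree.query(cone.centre)[1]]
    if np.dot(np.asarray(nearest) - cone.centre, axis) < 0:
        axis = -axis
    cone.axis = axis
    proj = (voxels - cone.centre) @ evecs
    cone.length = float(proj[:, 0].max() - proj[:, 0].min())
    cone.radius = float(np.mean([(proj[:, k].max() - proj[:, k].min()) / 2 for k in (1, 2)]))
    return cone


def neighbour_distances(cones: list[RawCone]) -> list[RawCone]:
    """Mean centre distance to the 3 nearest neighbouring raw cones, per cone."""
    if len(cones) < 4:
        warnings.warn("fewer than 4 cones: neighbour distances undefined")
        return cones
    centres = np.array([c.centre for c in cones])
    tree = cKDTree(centres)
    d, _ = tree.query(centres, k=4)
    for cone, di in zip(cones, d):
        cone.nn_dist = float(di[1:4].mean())
    return cones


# -- elimination cascade ----------------------------------------------------

@dataclasses.dataclass
class EliminationReport:
    """Per-stage accounting of the cascade."""

    n_raw: int = 0
    removed: dict = dataclasses.field(default_factory=dict)     # stage -> count
    gmm: list = dataclasses.field(default_factory=list)         # per-sub-region dicts
    n_valid: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)


def filter_min_size(cones: list[RawCone], min_size: int = 10) -> list[RawCone]:
    """Remove raw cones smaller than ``min_size`` voxels (strictly smaller)."""
    for c in cones:
        if c.status == "raw" and c.size < min_size:
            c.status = "removed_size"
    return cones


def gmm_select(residuals: np.ndarray, seed: int = 0, max_components: int = 3):
    """Fit 1..max_components 1-D Gaussian mixtures, select the best AIC.

    Returns ``(best_k, aics, means, labels)`` with hard component labels.
    Non-convergence falls back to the single-component model.
    """
    r = np.asarray(residuals, float).reshape(-1, 1)
    models, aics = [], []
    for k in range(1, max_components + 1):
        if k > len(r):
            break
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(r)
        if not gm.converged_ and k > 1:
            continue
        models.append(gm)
        aics.append(gm.aic(r))
    if not models:  # pathological: keep everything together
        return 1, [np.inf], np.array([r.mean()]), np.zeros(len(r), int)
    best = int(np.argmin(aics))
    gm = models[best]
    return gm.n_components, aics, gm.means_.ravel(), gm.predict(r)


def filter_gmm_residuals(cones: list[RawCone], grid: SubregionGrid,
                         global_frame: PcaFrame, subregion_frames: list[PcaFrame],
                         mode: str = "auto", seed: int = 0,
                         report: EliminationReport | None = None,
                         keep_tol_um: float = 2.0,
                         choose_groups=None) -> list[RawCone]:
    """Per sub-region, validate groups of cones by their surface-fit residuals.

    Cone centres are transformed into the sub-region's local PCA space, a
    poly55 surface is fitted to their z-component, and 1–3 component Gaussian
    mixtures are fitted to the residuals; the best-AIC model clusters the
    cones into groups.  In ``auto`` mode the group with the largest
    membership is kept, together with any group whose mean residual lies
    within ``keep_tol_um`` μm of it; in ``interactive`` mode ``choose_groups``
    (or a terminal prompt) picks the valid group ids.  Members of
    unvalidated groups are removed.  Sub-regions with fewer than 21 cones
    pass through unfiltered.
    """
    active = [c for c in cones if c.status == "raw"]
    if not active:
        return cones
    centres = np.array([c.centre for c in active])
    xy = global_frame.to_local(centres)[:, :2]
    assign = grid.assign_unique(xy)
    for sr in range(len(grid)):
        members = [active[i] for i in np.flatnonzero(assign == sr)]
        info = {"subregion": sr, "n": len(members)}
        if len(members) < 21:
            info["skipped"] = "fewer than 21 cones; pass-through"
            log.warning("GMM stage: sub-region %d has %d cones, passing through", sr, len(members))
            if report is not None:
                report.gmm.append(info)
            continue
        local = subregion_frames[sr].to_local(np.array([c.centre for c in members]))
        surf = fit_poly55(local)
        resid = local[:, 2] - surf.evaluate(local[:, 0], local[:, 1])
        best_k, aics, means, labels = gmm_select(resid, seed=seed)
        counts = np.bincount(labels, minlength=best_k)
        if mode == "auto":
            ref = int(np.argmax(counts))
            keep = {k for k in range(best_k) if abs(means[k] - means[ref]) <= keep_tol_um}
        elif mode == "interactive":
            chooser = choose_groups or _prompt_groups
            keep = set(chooser(sr, means, counts))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for c, lab in zip(members, labels):
            if lab not in keep:
                c.status = "removed_gmm"
        info.update({"best_k": int(best_k), "aic": [float(a) for a in aics],
                     "component_means": [float(m) for m in means],
                     "component_counts": [int(n) for n in counts],
                     "validated_groups": sorted(int(k) for k in keep)})
        if report is not None:
            report.gmm.append(info)
    return cones


def _prompt_groups(subregion, means, counts):
    print(f"sub-region {subregion}: residual groups "
          + ", ".join(f"[{k}] mean={m:.1f} um n={n}" for k, (m, n) in enumerate(zip(means, counts))))
    raw = input("valid group ids (comma separated): ")
    return [int(t) for t in raw.replace(",", " ").split()]


def filter_poly_outliers(cones: list[RawCone], full_frame: PcaFrame,
                         k_mad: float = 4.0) -> list[RawCone]:
    """Robust residual screen of five per-cone fields against poly55 trends.

    In the full-cornea PCA space, the z-component of the centres (z-scored),
    size, length, radius and neighbour distance are each fitted as poly55
    functions of (x, y); a cone whose residual exceeds ``k_mad`` times the
    normal-consistent MAD of that fit's residuals in any field is removed.
    The fields vary smoothly over a real eye, so gross residuals flag noise
    detections.  Fields whose MAD is zero are skipped.
    """
    active = [c for c in cones if c.status == "raw"]
    if len(active) < 21:
        log.warning("outlier stage: only %d cones, skipped", len(active))
        return cones
    centres = full_frame.to_local(np.array([c.centre for c in active]))
    x, y, z = centres.T
    zs = (z - z.mean()) / (z.std() or 1.0)
    fields = {
        "z": zs,
        "size": np.array([c.size for c in active], float),
        "length": np.array([c.length for c in active]),
        "radius": np.array([c.radius for c in active]),
        "nn_dist": np.array([c.nn_dist for c in active]),
    }
    flag = np.zeros(len(active), bool)
    for name, vals in fields.items():
        if not np.isfinite(vals).all():
            continue
        if not np.isfinite(k_mad):
            continue
        surf = fit_poly55(np.column_stack([x, y, vals]))
        resid = vals - surf.evaluate(x, y)
        mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        # a (near-)zero MAD means the field is exactly polynomial in (x, y);
        # the screen carries no information there
        if mad <= 1e-9 * max(np.abs(vals).max(), 1.0):
            continue
        first = np.abs(resid) > k_mad * mad
        if first.any() and (~first).sum() >= 21:
            # gross outliers drag the least-squares fit; refit without them
            # and re-screen everything against the clean surface
            keep = ~first
            surf = fit_poly55(np.column_stack([x[keep], y[keep], vals[keep]]))
            resid = vals - surf.evaluate(x, y)
            mad = 1.4826 * np.median(np.abs(resid[keep] - np.median(resid[keep])))
            if mad <= 1e-9 * max(np.abs(vals).max(), 1.0):
                flag |= first
                continue
        flag |= np.abs(resid) > k_mad * mad
    for c, f in zip(active, flag):
        if f:
            c.status = "removed_outlier"
    return cones


def dedup_linkage(cones: list[RawCone], full_frame: PcaFrame,
                  cutoff_um: float = 13.0) -> list[RawCone]:
    """Remove duplicates whose fitted centres are abnormally close.

    A final poly55 surface is fitted to the remaining centres; each centre is
    projected to its fitted z ("fitted cone centre").  Single-linkage
    clusters of fitted centres closer than the cut-off (13 μm by default —
    well under the ~20 μm ommatidial spacing) are thinned by iteratively
    removing the member with the largest fitting residual among the violating
    pairs until all surviving fitted centres are farther apart than the
    cut-off.  Survivors become valid.
    """
    active = [c for c in cones if c.status == "raw"]
    if not active:
        return cones
    if len(active) == 1:
        active[0].status = "valid"
        return cones
    centres = full_frame.to_local(np.array([c.centre for c in active]))
    if len(active) >= 21:
        surf = fit_poly55(centres)
        fitted_z = surf.evaluate(centres[:, 0], centres[:, 1])
        resid = np.abs(centres[:, 2] - fitted_z)
    else:  # too few points for a surface; keep raw centres, score deviation
        fitted_z = centres[:, 2]
        resid = np.abs(centres[:, 2] - np.median(centres[:, 2]))
    fitted = np.column_stack([centres[:, 0], centres[:, 1], fitted_z])

    Z = linkage(fitted, method="single")
    clusters = fcluster(Z, t=cutoff_um, criterion="distance")
    removed = np.zeros(len(active), bool)
    for cl in np.unique(clusters):
        idx = np.flatnonzero(clusters == cl)
        if len(idx) == 1:
            continue
        alive = list(idx)
        while len(alive) > 1:
            D = squareform(pdist(fitted[alive]))
            np.fill_diagonal(D, np.inf)
            viol = np.flatnonzero((D < cutoff_um).any(axis=1))
            if viol.size == 0:
                break
            worst = viol[np.argmax(resid[[alive[v] for v in viol]])]
            removed[alive[worst]] = True
            del alive[worst]
    for c, r in zip(active, removed):
        c.status = "removed_linkage" if r else "valid"
    return cones


# -- orchestration ----------------------------------------------------------

def cones_to_table(cones: list[RawCone]) -> ConeTable:
    import pandas as pd

    rows = []
    for c in cones:
        cx, cy, cz = (c.centre if c.centre is not None else (np.nan,) * 3)
        ax, ay, az = (c.axis if c.axis is not None else (np.nan,) * 3)
        rows.append((c.id, cx, cy, cz, ax, ay, az, c.length, c.radius,
                     c.size, c.nn_dist, c.status))
    return ConeTable(pd.DataFrame(rows, columns=CONE_COLUMNS))


def postprocess(label: LabelVolume, cornea_points: np.ndarray,
                global_frame: PcaFrame, grid: SubregionGrid,
                subregion_frames: list[PcaFrame], *,
                min_size: int = 10, k_mad: float = 4.0, cutoff_um: float = 13.0,
                gmm_mode: str = "auto", seed: int = 0,
                choose_groups=None) -> tuple[ConeTable, EliminationReport]:
    """Run the full cascade on a raw binary cone label volume."""
    report = EliminationReport()
    cones = extract_raw_cones(label)
    report.n_raw = len(cones)
    tree = cKDTree(np.asarray(cornea_points, float))
    for c in cones:
        chars = cone_characteristics(c.voxels, tree)
        c.centre, c.axis = chars.centre, chars.axis
        c.length, c.radius = chars.length, chars.radius
    neighbour_distances(cones)

    filter_min_size(cones, min_size)
    filter_gmm_residuals(cones, grid, global_frame, subregion_frames,
                         mode=gmm_mode, seed=seed, report=report,
                         choose_groups=choose_groups)
    filter_poly_outliers(cones, global_frame, k_mad)
    dedup_linkage(cones, global_frame, cutoff_um)

    for stage in ("removed_size", "removed_gmm", "removed_outlier", "removed_linkage"):
        report.removed[stage] = sum(c.status == stage for c in cones)
    report.n_valid = sum(c.status == "valid" for c in cones)
    log.info("postprocess: %d raw -> %d valid (%s)", report.n_raw, report.n_valid, report.removed)
    return cones_to_table(cones), report
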