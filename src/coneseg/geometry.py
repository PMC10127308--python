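"""PCA alignment of the cornea point cloud, sub-region grids and poly55 surfaces.

The eye sits in the scanner at an arbitrary pose; a PCA of the cornea surface
voxels defines an eye-referenced frame ("PCA space") in which the surface is
roughly parallel to the (x', y') plane and z' increases from the outside of
the eye toward its interior.  Highly curved corneas are split into a grid of
overlapping rectangular sub-regions in (x', y'); each sub-region is locally
re-aligned the same way and modelled as a bivariate polynomial surface
z = f(x, y) with all terms of total degree ≤ 5 (``poly55``, 21 coefficients).
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

__all__ = [
    "PcaFrame", "SubregionGrid", "PolySurface",
    "pca_frame", "divide_subregions", "fit_poly55", "POLY55_EXPONENTS",
]

# exponent pairs (i, j), i + j <= 5, in a fixed deterministic order
POLY55_EXPONENTS = tuple((i, j) for total in range(6) for i in range(total, -1, -1)
                         for j in [total - i])


@dataclasses.dataclass
class PcaFrame:
    """A rigid frame: ``local = (world - mean) @ rotation.T``.

    Rows of ``rotation`` are the principal axes in descending-variance order;
    the third row points from the eye exterior toward its interior, and the
    frame is right-handed.
    """

    mean: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.rotation = np.asarray(self.rotation, float)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    def to_local(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.mean) @ self.rotation.T

    def to_world(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) @ self.rotation + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "rotation": self.rotation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PcaFrame":
        return cls(np.asarray(d["mean"]), np.asarray(d["rotation"]))


def pca_frame(points: np.ndarray, interior_ref: np.ndarray,
              orientation_ref: np.ndarray | None = None) -> PcaFrame:
    """Principal-axes frame of a 3D point cloud.

    Parameters
    ----------
    points : (n, 3) array, n >= 4, non-collinear
        World μm coordinates (e.g. cornea surface voxels).
    interior_ref : (3,) array
        A point known to lie inside the eye (e.g. the eye-label centroid);
        fixes the sign of the third axis so that z' increases external →
        internal.
    orientation_ref : (3,) vector, optional
        If given, the first two axes are replaced by the projection of this
        vector onto the plane normal to the third axis (and its completion
        to a right-handed frame).  Sub-region frames use the parent frame's
        x' axis here, so the in-plane orientation of every unfolded
        sub-volume agrees and a single patch dictionary transfers across
        sub-regions; plain PCA leaves that rotation arbitrary.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need at least 4 points of dimension 3")
    mean = pts.mean(axis=0)
    cov = np.cov((pts - mean).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, axes = evals[order], evecs[:, order].T  # rows = axes
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("degenerate covariance: points are collinear or coincident")
    # sign conventions: axis 3 toward the interior; axis 2 deterministic;
    # axis 1 chosen to make the frame right-handed.
    if np.dot(np.asarray(interior_ref, float) - mean, axes[2]) <= 0:
        axes[2] = -axes[2]
    if orientation_ref is not None:
        ref = np.asarray(orientation_ref, float)
        a1 = ref - np.dot(ref, axes[2]) * axes[2]
        n1 = np.linalg.norm(a1)
        if n1 < 1e-9:
            raise ValueError("orientation_ref is parallel to the surface normal")
        axes[0] = a1 / n1
        axes[1] = np.cross(axes[2], axes[0])
    else:
        k = np.argmax(np.abs(axes[1]))
        if axes[1, k] < 0:
            axes[1] = -axes[1]
        if np.linalg.det(axes) < 0:
            axes[0] = -axes[0]
    return PcaFrame(mean, axes)


@dataclasses.dataclass
class SubregionGrid:
    """Overlapping rectangular masks tiling the (x', y') footprint of the cornea.

    ``rectangles[r * n_cols + c]`` is ``(xmin, xmax, ymin, ymax)`` in μm,
    already expanded by ``overlap`` so adjacent rectangles share a strip of
    width ``2 * overlap``.
    """

    n_rows: int
    n_cols: int
    rectangles: list
    overlap: float

    def __len__(self) -> int:
        return len(self.rectangles)

    def membership(self, points_2d: np.ndarray) -> list:
        """Per rectangle, the indices of the points it contains."""
        p = np.asarray(points_2d, float)
        out = []
        for (x0, x1, y0, y1) in self.rectangles:
            inside = (p[:, 0] >= x0) & (p[:, 0] <= x1) & (p[:, 1] >= y0) & (p[:, 1] <= y1)
            out.append(np.flatnonzero(inside))
        return out

    def assign_unique(self, points_2d: np.ndarray) -> np.ndarray:
        """One rectangle index per point: the containing (else nearest) rectangle
        whose centre is closest, so overlap points are handled exactly once."""
        p = np.asarray(points_2d, float)
        centres = np.array([[(x0 + x1) / 2, (y0 + y1) / 2] for x0, x1, y0, y1 in self.rectangles])
        d = np.linalg.norm(p[:, None, :] - centres[None, :, :], axis=2)
        return np.argmin(d, axis=1)

    def to_dict(self) -> dict:
        return {"n_rows": self.n_rows, "n_cols": self.n_cols,
                "rectangles": [list(map(float, r)) for r in self.rectangles],
                "overlap": self.overlap}

    @classmethod
    def from_dict(cls, d: dict) -> "SubregionGrid":
        return cls(d["n_rows"], d["n_cols"], [tuple(r) for r in d["rectangles"]], d["overlap"])


def divide_subregions(points_2d: np.ndarray, n_subregions: int, overlap_um: float = 20.0) -> SubregionGrid:
    """Divide the (x', y') bounding box of the cornea into ``n_subregions``
    overlapping rectangles.

    The grid shape (rows, cols) is the factor pair of ``n_subregions`` whose
    cell aspect ratio is closest to the bounding-box aspect ratio, with the
    larger factor placed along the longer bounding-box side.  The default
    overlap of 20 μm is one expected cone spacing, so cones near sub-region
    borders are never lost.
    """
    if n_subregions < 1:
        raise ValueError("n_subregions must be >= 1")
    p = np.asarray(points_2d, float)
    x0, y0 = p.min(axis=0)
    x1, y1 = p.max(axis=0)
    width, height = x1 - x0, y1 - y0

    best = None
    for r in range(1, n_subregions + 1):
        if n_subregions % r:
            continue
        c = n_subregions // r
        # cell aspect closest to bbox aspect on a log scale
        score = abs(np.log(max(r, 1) / max(c, 1)))
        # tie-break: more columns along the longer side
        pref = (c >= r) if width >= height else (r >= c)
        key = (round(score, 12), 0 if pref else 1)
        if best is None or key < best[0]:
            best = (key, r, c)
    _, n_rows, n_cols = best

    xs = np.linspace(x0, x1, n_cols + 1)
    ys = np.linspace(y0, y1, n_rows + 1)
    rects = []
    for r in range(n_rows):
        for c in range(n_cols):
            rects.append((xs[c] - overlap_um, xs[c + 1] + overlap_um,
                          ys[r] - overlap_um, ys[r + 1] + overlap_um))
    return SubregionGrid(n_rows, n_cols, rects, overlap_um)


@dataclasses.dataclass
class PolySurface:
    """Bivariate polynomial surface z = Σ c_ij x^i y^j, total degree ≤ 5.

    (x, y) are centred and scaled (stored in ``normalization``) before
    evaluation, purely for numerical conditioning.
    """

    coeffs: np.ndarray  # (21,), ordered as POLY55_EXPONENTS
    normalization: dict  # x_center, x_scale, y_center, y_scale
    rmse: float = 0.0

    def _uv(self, x, y):
        n = self.normalization
        u = (np.asarray(x, float) - n["x_center"]) / n["x_scale"]
        v = (np.asarray(y, float) - n["y_center"]) / n["y_scale"]
        return u, v

    def evaluate(self, x, y):
        u, v = self._uv(x, y)
        z = np.zeros(np.broadcast(u, v).shape)
        for c, (i, j) in zip(self.coeffs, POLY55_EXPONENTS):
            z += c * u**i * v**j
        return z

    def gradient(self, x, y):
        """(∂z/∂x, ∂z/∂y) at (x, y), chain rule through the normalization."""
        u, v = self._uv(x, y)
        shape = np.broadcast(u, v).shape
        gx = np.zeros(shape)
        gy = np.zeros(shape)
        for c, (i, j) in zip(self.coeffs, POLY55_EXPONENTS):
            if i:
                gx += c * i * u**(i - 1) * v**j
            if j:
                gy += c * j * u**i * v**(j - 1)
        n = self.normalization
        return gx / n["x_scale"], gy / n["y_scale"]

    def to_dict(self) -> dict:
        return {"coeffs": self.coeffs.tolist(), "normalization": dict(self.normalization),
                "rmse": float(self.rmse)}

    @classmethod
    def from_dict(cls, d: dict) -> "PolySurface":
        return cls(np.asarray(d["coeffs"]), d["normalization"], d["rmse"])

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f)

    @classmethod
    def from_json(cls, path) -> "PolySurface":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def design_matrix(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vandermonde matrix over the 21 poly55 monomials."""
    return np.stack([u**i * v**j for i, j in POLY55_EXPONENTS], axis=1)


def fit_poly55(points: np.ndarray) -> PolySurface:
    """Least-squares poly55 fit of z on (x, y) for a 3D point set (μm).

    Requires ≥ 21 points with a non-degenerate (x, y) footprint.  The rmse is
    the root-mean-square of the z residuals in μm.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 21:
        raise ValueError("need at least 21 points of dimension 3")
    x, y, z = pts.T
    norm = {"x_center": float(x.mean()), "x_scale": float(x.std()) or 1.0,
            "y_center": float(y.mean()), "y_scale": float(y.std()) or 1.0}
    u = (x - norm["x_center"]) / norm["x_scale"]
    v = (y - norm["y_center"]) / norm["y_scale"]
    A = design_matrix(u, v)
    coeffs, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(f"rank-deficient poly55 design (rank {rank}/21); "
                      "solution is the minimum-norm least squares fit")
    resid = z - A @ coeffs
    return PolySurface(coeffs, norm, float(np.sqrt(np.mean(resid**2))))
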