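"""Volume, label and cone-table I/O, and the coordinate convention.

Conventions used throughout the package:

* In-memory arrays are indexed ``(i, j, k)`` along the world ``(x, y, z)``
  axes; the world coordinate (in μm) of voxel ``(i, j, k)`` is
  ``origin + voxel_size * (i, j, k)``.  Voxels are isotropic.
* On disk, TIFF stacks are slice-major ``(z, y, x)``; the transpose happens
  only at the I/O boundary.
* All geometry elsewhere in the package is done in world μm coordinates.
* Intensities are floating point internally regardless of on-disk bit depth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Volume", "LabelVolume", "ConeTable", "CONE_STATUSES",
    "read_volume", "write_volume", "read_label", "write_label",
    "read_cone_table", "write_cone_table",
]

CONE_STATUSES = (
    "raw", "removed_size", "removed_gmm", "removed_outlier", "removed_linkage", "valid",
)

CONE_COLUMNS = [
    "id", "cx", "cy", "cz", "ax", "ay", "az",
    "length", "radius", "size", "nn_dist", "status",
]


@dataclasses.dataclass
class Volume:
    """A 3D scalar image with isotropic voxels.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities, arbitrary units; handled as float internally.
    voxel_size : float
        Edge length of a voxel in μm.
    origin : ndarray, shape (3,)
        World offset in μm of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be 3D with positive dimensions")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.zeros(3) if self.origin is None else np.asarray(self.origin, float)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World μm coordinates of (fractional) voxel indices, shape (..., 3)."""
        return self.origin + self.voxel_size * np.asarray(idx, float)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world μm points, shape (..., 3)."""
        return (np.asarray(pts, float) - self.origin) / self.voxel_size


class LabelVolume(Volume):
    """Integer label image: 0 = background, >0 = label id."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    def coords(self) -> np.ndarray:
        """World μm coordinates of all foreground voxels, shape (n, 3)."""
        return self.index_to_world(np.argwhere(self.data > 0))


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def read_volume(path, voxel_size: float | None = None, origin=None) -> Volume:
    """Read a multi-page TIFF stack or NIfTI file as a :class:`Volume`.

    For NIfTI the voxel size is read from the header and overrides the
    argument; anisotropic voxels are rejected.  TIFF carries no scale, so
    ``voxel_size`` is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        zooms = np.asarray(img.header.get_zooms()[:3], float)
        if not np.allclose(zooms, zooms[0], rtol=1e-3):
            raise ValueError(f"anisotropic voxels {zooms} are not supported; resample first")
        data = np.asanyarray(img.dataobj)  # nibabel axes are (x, y, z) already
        voxel_size = float(zooms[0])
    else:
        import tifffile

        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        data = np.transpose(data, (2, 1, 0))  # (z, y, x) on disk -> (x, y, z)
        if voxel_size is None:
            raise ValueError("voxel_size is required for TIFF volumes")
    return Volume(data, float(voxel_size), origin)


def write_volume(volume: Volume, path) -> None:
    """Write a :class:`Volume` as a multi-page TIFF (slice-major) or NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag([volume.voxel_size] * 3 + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.data, affine), str(path))
    else:
        import tifffile

        tifffile.imwrite(str(path), np.transpose(volume.data, (2, 1, 0)))


def read_label(path, voxel_size: float | None = None, origin=None) -> LabelVolume:
    """Read a label volume (same formats as :func:`read_volume`)."""
    v = read_volume(path, voxel_size, origin)
    data = v.data
    if not np.issubdtype(data.dtype, np.integer):
        data = np.rint(data).astype(np.int32)
    return LabelVolume(data, v.voxel_size, v.origin)


write_label = write_volume


class ConeTable:
    """Tabular per-cone record: centre, elongation axis, shape descriptors, status.

    Backed by a pandas DataFrame with columns
    ``id,cx,cy,cz,ax,ay,az,length,radius,size,nn_dist,status``.
    Lengths in μm; the elongation axis is a unit vector oriented toward the
    cornea surface.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame({c: pd.Series(dtype=float) for c in CONE_COLUMNS})
            df["id"] = df["id"].astype(int)
            df["size"] = df["size"].astype(int)
            df["status"] = df["status"].astype(str)
        self.df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in CONE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cone table missing columns {missing}")
        if len(self.df):
            bad = ~self.df["status"].isin(CONE_STATUSES)
            if bad.any():
                raise ValueError(f"invalid statuses: {sorted(self.df.loc[bad, 'status'].unique())}")
            axes = self.df[["ax", "ay", "az"]].to_numpy(float)
            finite = np.isfinite(axes).all(axis=1)
            norms = np.linalg.norm(axes[finite], axis=1)
            if norms.size and not np.allclose(norms, 1.0, atol=1e-5):
                raise ValueError("elongation axes must be unit vectors")
            if (self.df["size"] < 1).any():
                raise ValueError("cone size must be >= 1")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def centres(self) -> np.ndarray:
        return self.df[["cx", "cy", "cz"]].to_numpy(float)

    @property
    def axes(self) -> np.ndarray:
        return self.df[["ax", "ay", "az"]].to_numpy(float)

    def with_status(self, status: str) -> "ConeTable":
        return ConeTable(self.df[self.df["status"] == status].copy())

    @property
    def valid(self) -> "ConeTable":
        return self.with_status("valid")


def write_cone_table(table: ConeTable, path) -> None:
    """Write a cone table as CSV; floats at 6 decimals so round trips are exact."""
    path = Path(path)
    if path.suffix != ".csv":
        raise ValueError("cone tables are CSV files")
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False, float_format="%.6f")


def read_cone_table(path) -> ConeTable:
    df = pd.read_csv(path, dtype={"status": str})
    if list(df.columns) != CONE_COLUMNS:
        raise ValueError(f"malformed cone table header {list(df.columns)}; expected {CONE_COLUMNS}")
    if len(df):
        df["id"] = df["id"].astype(int)
        df["size"] = df["size"].astype(int)
    return ConeTable(df)
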