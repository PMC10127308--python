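"""Synthetic compound-eye phantoms with ground truth.

The phantom emulates the inputs the pipeline assumes — a micro-CT-like
intensity volume, a cornea surface label and a whole-eye label — plus a
ground-truth cone table.  Geometry: a spherical-cap cornea shell with bright
crystalline-cone frusta beneath it, one per site of a ~20 μm hexagonal
lattice mapped onto the cap with a Lambert equal-area projection (so lattice
density is preserved over the whole cap).  Cone axes follow the inward
surface normal, optionally skewed by an angle growing linearly toward the
cap rim as in real bee eyes.  Gaussian noise and optional concentric
ring-artefact stripes mimic reconstruction imperfections.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from coneseg.volio import LabelVolume, Volume

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "degrade_phantom",
           "facet_samples_from_truth", "write_phantom"]


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of the synthetic eye; lengths in μm, angles in degrees.

    Defaults describe a mid-sized bee-like eye patch: a 300 μm sphere cap of
    60° half-angle, a 10 μm cornea, cones 40 μm long on a 20 μm lattice
    (the typical ommatidial spacing), skew growing to 10° at the rim, and
    additive Gaussian noise at 10% of the cone/matrix contrast.
    """

    eye_radius: float = 300.0
    cap_half_angle: float = 60.0
    cornea_thickness: float = 10.0
    cone_spacing: float = 20.0
    cone_length: float = 40.0
    cone_radius_top: float = 5.0
    cone_radius_bottom: float = 2.5
    cone_depth_offset: float = 10.0     # below the external cornea surface
    skew_max: float = 10.0              # cone tilt vs surface normal at the rim
    lattice_margin_deg: float = 5.0     # keep lattice off the cap rim
    intensity_background: float = 20.0
    intensity_cornea: float = 200.0
    intensity_cone: float = 160.0
    intensity_matrix: float = 80.0      # eye interior (retina etc.)
    noise_sigma: float = 8.0
    ring_artifact: bool = False
    ring_amplitude: float = 15.0
    ring_period_um: float = 30.0
    voxel_size: float = 4.0
    seed: int = 0

    def __post_init__(self):
        lengths = (self.eye_radius, self.cornea_thickness, self.cone_spacing,
                   self.cone_length, self.cone_radius_top, self.cone_radius_bottom,
                   self.voxel_size)
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if not 0 < self.cap_half_angle <= 90:
            raise ValueError("cap_half_angle must be in (0, 90] degrees")
        if self.cone_spacing <= 2 * self.cone_radius_top:
            raise ValueError("cone_spacing must exceed the cone diameter (cones would overlap)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class Phantom:
    """Generated phantom: intensity volume, labels, cone-id label and truth table."""

    volume: Volume
    cornea: LabelVolume
    eye: LabelVolume
    cones: LabelVolume            # per-cone id label (ground-truth voxels)
    truth: pd.DataFrame           # id, cx..az, length, radius, lattice_i, lattice_j, dropped
    spec: PhantomSpec


def _lattice_directions(spec: PhantomSpec):
    """Hexagonal lattice sites mapped onto the cap (Lambert equal-area).

    Returns surface points (n, 3) on the sphere of radius R (cap axis +z,
    centre at the origin), and the lattice integer indices.
    """
    R, s = spec.eye_radius, spec.cone_spacing
    theta_keep = np.radians(spec.cap_half_angle - spec.lattice_margin_deg)
    rho_max = 2 * R * np.sin(theta_keep / 2)
    a1 = np.array([s, 0.0])
    a2 = np.array([s / 2, s * np.sqrt(3) / 2])
    n_max = int(np.ceil(rho_max / (s * np.sqrt(3) / 2))) + 2
    pts, idx = [], []
    for i in range(-n_max, n_max + 1):
        for j in range(-n_max, n_max + 1):
            p = i * a1 + j * a2
            rho = np.linalg.norm(p)
            if rho <= rho_max:
                pts.append(p)
                idx.append((i, j))
    pts = np.array(pts)
    idx = np.array(idx)
    rho = np.linalg.norm(pts, axis=1)
    with np.errstate(invalid="ignore"):
        theta = 2 * np.arcsin(np.clip(rho / (2 * R), 0, 1))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    surf = R * np.column_stack([np.sin(theta) * np.cos(phi),
                                np.sin(theta) * np.sin(phi),
                                np.cos(theta)])
    return surf, idx, theta, phi


def _cone_axes(spec: PhantomSpec, surf, theta, phi):
    """Inward (into the eye) unit cone axes, skewed toward the rim."""
    inward = -surf / spec.eye_radius
    # meridional tangent pointing toward increasing theta ("towards the sides")
    t_hat = np.column_stack([np.cos(theta) * np.cos(phi),
                             np.cos(theta) * np.sin(phi),
                             -np.sin(theta)])
    theta_cap = np.radians(spec.cap_half_angle)
    beta = np.radians(spec.skew_max) * (theta / theta_cap)
    d = np.cos(beta)[:, None] * inward + np.sin(beta)[:, None] * t_hat
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Rasterize the phantom volume, labels and ground-truth table."""
    spec = spec or PhantomSpec()
    R, t, vs = spec.eye_radius, spec.cornea_thickness, spec.voxel_size
    theta_cap = np.radians(spec.cap_half_angle)
    rng = np.random.default_rng(spec.seed)

    surf, lattice_idx, theta, phi = _lattice_directions(spec)
    d = _cone_axes(spec, surf, theta, phi)
    starts = surf + spec.cone_depth_offset * d
    ends = starts + spec.cone_length * d
    centres = surf + (spec.cone_depth_offset + spec.cone_length / 2) * d

    # sanity: cones must not overlap on the (equal-area-projected) lattice
    from scipy.spatial import cKDTree

    dmin = cKDTree(centres).query(centres, k=2)[0][:, 1].min()
    if dmin <= 2 * spec.cone_radius_top:
        raise ValueError(f"cone spacing too tight: nearest centres {dmin:.1f} um")

    # volume extents (world μm); cap axis is +z, sphere centre at the origin
    margin = 2 * vs
    xy_half = R * np.sin(theta_cap) + spec.cone_radius_top + 2 * margin
    z_lo = (R - t - spec.cone_depth_offset - spec.cone_length - 5 * vs) * np.cos(theta_cap)
    z_hi = R + 2 * margin
    nx = ny = int(np.ceil(2 * xy_half / vs)) + 1
    nz = int(np.ceil((z_hi - z_lo) / vs)) + 1
    origin = np.array([-xy_half, -xy_half, z_lo])

    xs = origin[0] + vs * np.arange(nx)
    ys = origin[1] + vs * np.arange(ny)
    zs = origin[2] + vs * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
    r2 = X**2 + Y**2 + Z**2
    r = np.sqrt(r2)
    with np.errstate(invalid="ignore", divide="ignore"):
        polar = np.arccos(np.clip(Z / np.where(r == 0, 1, r), -1, 1))
    in_cap = polar <= theta_cap

    data = np.full((nx, ny, nz), spec.intensity_background)
    eye = (r <= R) & in_cap
    data[eye] = spec.intensity_matrix
    cornea = (r >= R - t) & (r <= R) & in_cap
    data[cornea] = spec.intensity_cornea

    cone_label = np.zeros((nx, ny, nz), dtype=np.int32)
    for cid, (S, D) in enumerate(zip(starts, d), start=1):
        E = S + spec.cone_length * D
        rmax = max(spec.cone_radius_top, spec.cone_radius_bottom)
        lo = np.minimum(S, E) - rmax - vs
        hi = np.maximum(S, E) + rmax + vs
        i0 = np.maximum(np.floor((lo - origin) / vs).astype(int), 0)
        i1 = np.minimum(np.ceil((hi - origin) / vs).astype(int) + 1, [nx, ny, nz])
        if (i0 >= i1).any():
            continue
        gx, gy, gz = np.meshgrid(xs[i0[0]:i1[0]], ys[i0[1]:i1[1]], zs[i0[2]:i1[2]],
                                 indexing="ij", sparse=True)
        px, py, pz = gx - S[0], gy - S[1], gz - S[2]
        s_ax = px * D[0] + py * D[1] + pz * D[2]
        rad2 = (px - s_ax * D[0])**2 + (py - s_ax * D[1])**2 + (pz - s_ax * D[2])**2
        r_at = spec.cone_radius_top + (spec.cone_radius_bottom - spec.cone_radius_top) \
            * s_ax / spec.cone_length
        # floor the rasterized radius so thin cone tips stay 6-connected
        r_at = np.maximum(r_at, 0.75 * vs)
        mask = (s_ax >= 0) & (s_ax <= spec.cone_length) & (rad2 <= r_at**2)
        # cones abut but never invade the cornea shell
        mask &= gx**2 + gy**2 + gz**2 < (R - t) ** 2
        sub = (slice(i0[0], i1[0]), slice(i0[1], i1[1]), slice(i0[2], i1[2]))
        data[sub][mask] = spec.intensity_cone
        cone_label[sub][mask] = cid

    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, data.shape)
    if spec.ring_artifact:
        rho_xy = np.sqrt(X**2 + Y**2)
        phases = rng.uniform(0, 2 * np.pi, nz)
        data = data + spec.ring_amplitude * np.sin(
            2 * np.pi * rho_xy / spec.ring_period_um + phases[None, None, :])

    truth = pd.DataFrame({
        "id": np.arange(1, len(centres) + 1),
        "cx": centres[:, 0], "cy": centres[:, 1], "cz": centres[:, 2],
        # truth axis points toward the cornea, matching the post-processing convention
        "ax": -d[:, 0], "ay": -d[:, 1], "az": -d[:, 2],
        "length": spec.cone_length,
        "radius": (spec.cone_radius_top + spec.cone_radius_bottom) / 2,
        "lattice_i": lattice_idx[:, 0], "lattice_j": lattice_idx[:, 1],
        "dropped": False, "artifact": False,
    })
    return Phantom(
        volume=Volume(data, vs, origin),
        cornea=LabelVolume(cornea.astype(np.int32), vs, origin),
        eye=LabelVolume(eye.astype(np.int32), vs, origin),
        cones=LabelVolume(cone_label, vs, origin),
        truth=truth, spec=spec)


def degrade_phantom(phantom: Phantom, drop_fraction: float = 0.0,
                    n_blobs: int = 0, blob_size: int = 5, seed: int = 0,
                    hemisphere: str | None = None) -> Phantom:
    """Delete cones and/or inject small bright artefact blobs, for stress tests.

    ``hemisphere`` ("+y"/"-y") restricts deletions to one half of the eye so
    the density-ratio map shows the gap.  Injected blobs (6-connected,
    ``blob_size`` voxels, under the min-size threshold or far off-surface)
    are painted at cone intensity and flagged in the truth table.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    spec = phantom.spec
    data = phantom.volume.data.copy()
    cones = phantom.cones.data.copy()
    truth = phantom.truth.copy()

    candidates = truth.index.to_numpy()
    if hemisphere == "+y":
        candidates = candidates[truth["cy"].to_numpy() > 0]
    elif hemisphere == "-y":
        candidates = candidates[truth["cy"].to_numpy() < 0]
    n_drop = int(round(drop_fraction * len(candidates)))
    dropped = rng.choice(candidates, size=n_drop, replace=False) if n_drop else []
    for row in dropped:
        cid = int(truth.loc[row, "id"])
        sel = cones == cid
        data[sel] = spec.intensity_matrix
        cones[sel] = 0
        truth.loc[row, "dropped"] = True

    blob_rows = []
    nx, ny, nz = data.shape
    from scipy import ndimage as _ndi

    # blobs must not touch cones (or each other), else they merge into one
    # component and stop being a size-filter target
    forbidden = _ndi.binary_dilation(cones > 0, iterations=2)
    for b in range(n_blobs):
        for _ in range(500):
            idx = rng.integers([0, 0, 0], [nx, ny, nz])
            if phantom.eye.data[tuple(idx)] and not forbidden[tuple(idx)] \
                    and not phantom.cornea.data[tuple(idx)]:
                break
        voxels = {tuple(idx)}
        while len(voxels) < blob_size:
            base = list(sorted(voxels))[rng.integers(len(voxels))]
            step = np.zeros(3, int)
            ax = rng.integers(3)
            step[ax] = rng.choice([-1, 1])
            cand = tuple(np.clip(np.array(base) + step, 0, [nx - 1, ny - 1, nz - 1]))
            if not forbidden[cand]:
                voxels.add(cand)
        for vx in voxels:
            data[vx] = spec.intensity_cone
            forbidden[vx] = True
        # keep future blobs off this one's 6-neighbourhood
        vx_arr = np.array(sorted(voxels))
        lo = np.maximum(vx_arr.min(axis=0) - 2, 0)
        hi = np.minimum(vx_arr.max(axis=0) + 3, [nx, ny, nz])
        sub = tuple(slice(a, b) for a, b in zip(lo, hi))
        forbidden[sub] = _ndi.binary_dilation(forbidden[sub], iterations=2)
        centre = phantom.volume.index_to_world(np.mean(sorted(voxels), axis=0))
        blob_rows.append(centre)

    out = Phantom(Volume(data, spec.voxel_size, phantom.volume.origin),
                  phantom.cornea, phantom.eye,
                  LabelVolume(cones, spec.voxel_size, phantom.volume.origin),
                  truth, spec)
    out.blobs = np.array(blob_rows).reshape(-1, 3)
    return out


def facet_samples_from_truth(phantom: Phantom, n_samples: int = 30,
                             seed: int = 0) -> np.ndarray:
    """Facet-diameter samples (x, y, z, d) at scattered truth cone positions.

    On a hexagonal lattice the centre spacing equals the flat-to-flat facet
    diameter, so d = cone_spacing everywhere on the phantom.
    """
    rng = np.random.default_rng(seed)
    truth = phantom.truth
    rows = rng.choice(len(truth), size=min(n_samples, len(truth)), replace=False)
    pos = truth.iloc[rows][["cx", "cy", "cz"]].to_numpy(float)
    # samples sit on the cornea surface above each cone
    pos = pos * (phantom.spec.eye_radius / np.linalg.norm(pos, axis=1))[:, None]
    d = np.full(len(pos), phantom.spec.cone_spacing)
    return np.column_stack([pos, d])


def write_phantom(phantom: Phantom, out_dir) -> dict:
    """Write the phantom in the formats the pipeline reads."""
    from pathlib import Path

    import yaml

    from coneseg.volio import write_cone_table, write_volume, ConeTable, CONE_COLUMNS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out / "volume.tif",
        "cornea": out / "cornea_label.tif",
        "eye": out / "eye_label.tif",
        "cones": out / "cone_label.tif",
        "truth": out / "truth.csv",
        "spec": out / "phantom.yaml",
    }
    write_volume(Volume(phantom.volume.data.astype(np.float32),
                        phantom.spec.voxel_size, phantom.volume.origin), paths["volume"])
    write_volume(phantom.cornea, paths["cornea"])
    write_volume(phantom.eye, paths["eye"])
    write_volume(phantom.cones, paths["cones"])
    # TIFF carries no world offset, so shift the truth into the zero-origin
    # frame the files will be read back in
    t = phantom.truth
    o = phantom.volume.origin
    df = pd.DataFrame({
        "id": t["id"], "cx": t["cx"] - o[0], "cy": t["cy"] - o[1], "cz": t["cz"] - o[2],
        "ax": t["ax"], "ay": t["ay"], "az": t["az"],
        "length": t["length"], "radius": t["radius"],
        "size": 1, "nn_dist": np.nan, "status": "valid",
    })[CONE_COLUMNS]
    write_cone_table(ConeTable(df), paths["truth"])
    with open(paths["spec"], "w") as f:
        yaml.safe_dump(phantom.spec.to_dict(), f)
    return {k: str(v) for k, v in paths.items()}
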