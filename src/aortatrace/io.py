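"""Mask / surface / table I-O and the package's coordinate contract.

Every geometric quantity in this package lives in world millimetres. A voxel
index ``(i, j, k)`` (0-based) names the *center* of that voxel, and the NIfTI
affine maps index space to world space; downstream modules never touch raw
index arithmetic except through :class:`AortaMask`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates


class MaskFormatError(ValueError):
    """The file is not a readable volume/surface of the expected kind."""


class EmptyMaskError(ValueError):
    """A mask contains no foreground voxels."""


class VoxelizationError(ValueError):
    """A surface cannot be voxelized (e.g. it is not watertight)."""


@dataclass
class AortaMask:
    """A binary aortic segmentation with its voxel-to-world geometry.

    Parameters
    ----------
    voxels
        3D ``{0,1}`` array (any integer/bool dtype; stored as uint8).
    affine
        4x4 homogeneous voxel-index -> world-mm transform, voxel-center
        convention.
    axis_labels
        Anatomic direction codes per array axis toward increasing index,
        e.g. ``('R', 'A', 'S')``; exactly one must be 'S' or 'I' so the
        inferior-superior axis is recoverable.
    """

    voxels: np.ndarray
    affine: np.ndarray
    axis_labels: tuple[str, str, str] = ("R", "A", "S")
    _float_vol: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise MaskFormatError(f"mask must be 3D, got shape {vox.shape}")
        uniq = np.unique(vox)
        if not np.isin(uniq, [0, 1]).all():
            raise MaskFormatError("mask voxels must contain only 0/1")
        if not vox.any():
            raise EmptyMaskError("mask has no foreground voxels")
        self.voxels = vox.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise MaskFormatError("affine must be 4x4")
        if not (self.spacing > 0).all():
            raise MaskFormatError("voxel spacing must be strictly positive")
        labels = tuple(self.axis_labels)
        if sum(c in ("S", "I") for c in labels) != 1:
            raise MaskFormatError(
                "exactly one axis label must be 'S' or 'I' "
                f"(inferior-superior axis), got {labels}"
            )
        self.axis_labels = labels
        self._float_vol = self.voxels.astype(np.float32)

    # ---- geometry -------------------------------------------------------

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (affine column norms)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def is_axis(self) -> int:
        """Index of the array axis running inferior-superior."""
        return next(i for i, c in enumerate(self.axis_labels) if c in ("S", "I"))

    @property
    def superior_sign(self) -> int:
        """+1 if increasing index along :attr:`is_axis` moves superior."""
        return 1 if self.axis_labels[self.is_axis] == "S" else -1

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def sample_world(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated mask value at world points (0 outside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vox = self.world_to_voxel(pts)
        vals = map_coordinates(
            self._float_vol, vox.T, order=1, mode="constant", cval=0.0
        )
        return vals if np.asarray(points).ndim > 1 else float(vals[0])

    def foreground_volume_mm3(self) -> float:
        return float(self.voxels.sum() * np.prod(self.spacing))


# ---- NIfTI ---------------------------------------------------------------


def load_mask(path: str | Path, threshold: float = 0.5) -> AortaMask:
    """Read a NIfTI volume and binarize it at ``threshold``.

    The affine and spacing come from the header; the inferior-superior axis
    is inferred from the header orientation codes.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise MaskFormatError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MaskFormatError(f"expected a 3D volume, got shape {data.shape}")
    vox = (data > threshold).astype(np.uint8)
    if not vox.any():
        raise EmptyMaskError(f"{path!r}: no voxels above threshold {threshold}")
    labels = nib.aff2axcodes(img.affine)
    return AortaMask(vox, np.asarray(img.affine, dtype=float), tuple(labels))


def save_mask(mask: AortaMask, path: str | Path) -> None:
    """Write a mask as a uint8 NIfTI volume."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


# ---- STL -----------------------------------------------------------------


def voxelize_stl(
    path: str | Path, target_spacing: float | tuple[float, float, float] = 1.3
) -> AortaMask:
    """Voxelize a watertight STL surface on an isotropic-per-axis grid.

    Foreground is the set of voxel centers strictly inside the surface
    (inside/outside testing, not surface dilation), with the bounding box
    padded by two voxels on every side. ``target_spacing`` defaults to the
    middle of the 1.2-1.5 mm range typical of the source acquisitions.
    """
    import trimesh

    mesh = trimesh.load(str(path), force="mesh")
    if mesh.is_empty or len(mesh.faces) == 0:
        raise MaskFormatError(f"{path!r} contains no triangles")
    if not mesh.is_watertight:
        edges, counts = np.unique(mesh.edges_sorted, axis=0, return_counts=True)
        n_open = int((counts != 2).sum())
        raise VoxelizationError(
            f"surface is not watertight: {n_open} open/irregular edges"
        )
    spacing = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,)).copy()
    if (spacing <= 0).any():
        raise ValueError("target_spacing must be positive")
    lo, hi = mesh.bounds
    origin = lo - 2.0 * spacing  # world position of voxel (0,0,0) center
    shape = np.ceil((hi - origin) / spacing).astype(int) + 3
    axes = [origin[k] + spacing[k] * np.arange(shape[k]) for k in range(3)]
    inside = _grid_parity_inside(np.asarray(mesh.triangles, dtype=float), axes)
    if not inside.any():
        raise EmptyMaskError("no voxel centers fall inside the surface")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return AortaMask(inside.astype(np.uint8), affine, ("R", "A", "S"))


def _grid_parity_inside(triangles: np.ndarray, axes: list[np.ndarray]) -> np.ndarray:
    """Inside/outside test of grid points against a closed surface.

    Casts one ray per (x, y) voxel column along +z and counts triangle
    crossings; a voxel center is inside when an odd number of crossings lie
    above it. The ray lattice is sheared by a tiny irrational offset so no
    ray passes exactly through a mesh edge or vertex.
    """
    xs, ys, zs = axes
    dx = (xs[1] - xs[0]) if len(xs) > 1 else 1.0
    dy = (ys[1] - ys[0]) if len(ys) > 1 else 1.0
    rx = xs + 1.23456789e-4 * dx
    ry = ys + 0.98765432e-4 * dy
    crossings: dict[tuple[int, int], list[float]] = {}
    for a, b, c in triangles:
        lo_x = np.searchsorted(rx, min(a[0], b[0], c[0]))
        hi_x = np.searchsorted(rx, max(a[0], b[0], c[0]), side="right")
        lo_y = np.searchsorted(ry, min(a[1], b[1], c[1]))
        hi_y = np.searchsorted(ry, max(a[1], b[1], c[1]), side="right")
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        gx, gy = np.meshgrid(rx[lo_x:hi_x], ry[lo_y:hi_y], indexing="ij")
        v0 = (b - a)[:2]
        v1 = (c - a)[:2]
        denom = v0[0] * v1[1] - v0[1] * v1[0]
        if denom == 0:  # triangle edge-on to the ray; sheared rays miss it
            continue
        px = gx - a[0]
        py = gy - a[1]
        u = (px * v1[1] - py * v1[0]) / denom
        v = (v0[0] * py - v0[1] * px) / denom
        hit = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not hit.any():
            continue
        zhit = a[2] + u[hit] * (b[2] - a[2]) + v[hit] * (c[2] - a[2])
        ii, jj = np.nonzero(hit)
        for i, j, z in zip(ii + lo_x, jj + lo_y, zhit):
            crossings.setdefault((int(i), int(j)), []).append(float(z))
    inside = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    for (i, j), zlist in crossings.items():
        above = len(zlist) - np.searchsorted(np.sort(zlist), zs)
        inside[i, j, :] = (above % 2) == 1
    return inside


# ---- profile CSV ---------------------------------------------------------

PROFILE_COLUMNS = [
    "step",
    "arc_length_mm",
    "center_x_mm",
    "center_y_mm",
    "center_z_mm",
    "normal_x",
    "normal_y",
    "normal_z",
    "area_mm2",
    "max_diameter_mm",
    "min_diameter_mm",
]


def write_profile_csv(trace, path: str | Path) -> None:
    """Write one CSV row per centerline step, ordered by step index."""
    steps = getattr(trace, "steps", trace)
    if len(steps) == 0:
        raise ValueError("cannot write a profile for an empty trace")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PROFILE_COLUMNS)
        for s in sorted(steps, key=lambda s: s.index):
            writer.writerow(
                [s.index, repr(float(s.arc_length))]
                + [repr(float(c)) for c in s.center]
                + [repr(float(c)) for c in s.frame.normal]
                + [repr(float(s.area)), repr(float(s.max_diameter)),
                   repr(float(s.min_diameter))]
            )


def read_profile_csv(path: str | Path):
    """Read a profile CSV back into a :class:`~aortatrace.tracker.CenterlineTrace`.

    The trace carries status ``"completed"`` (the file format does not store
    status) and frames rebuilt deterministically from each stored normal.
    """
    from .cross_section import make_frame
    from .tracker import CenterlineStep, CenterlineTrace

    import pandas as pd

    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise MaskFormatError(f"profile CSV missing columns: {sorted(missing)}")
    steps = []
    for row in df.itertuples(index=False):
        center = np.array([row.center_x_mm, row.center_y_mm, row.center_z_mm])
        normal = np.array([row.normal_x, row.normal_y, row.normal_z])
        steps.append(
            CenterlineStep(
                index=int(row.step),
                center=center,
                frame=make_frame(center, normal),
                area=float(row.area_mm2),
                max_diameter=float(row.max_diameter_mm),
                min_diameter=float(row.min_diameter_mm),
                arc_length=float(row.arc_length_mm),
            )
        )
    return CenterlineTrace(steps=steps, status="completed", config=None)
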