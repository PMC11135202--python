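"""Synthetic aortic phantoms with exact analytic ground truth.

Clinical masks are proprietary, so every test and benchmark in this package
runs on constructed tubular solids whose centerline, cross-sectional area
and maximal diameter are known in closed form: straight/tilted/elliptical
tubes, a half-torus arch, a "candy cane" (descending limb + arch +
ascending limb, the topology of a real aortic arch), the candy cane with a
supra-aortic branch (the vessel a tracker can erroneously follow), and a
tube with an interior cavitation (the segmentation defect that interrupts
tracking).

Masks are produced by evaluating an approximate signed distance at every
voxel center; optional seeded jitter perturbs the surface threshold to
emulate rough manual segmentation. Truth functions always describe the
unjittered solid and are declared valid at least two tube radii away from
each open end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .io import AortaMask

SHAPES = (
    "straight_cylinder",
    "tilted_cylinder",
    "elliptical_tube",
    "torus_arch",
    "candy_cane",
    "candy_cane_with_branch",
    "cavitated_tube",
)


class PhantomSpecError(ValueError):
    """Geometry is not resolvable at the requested voxel spacing."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic solid; units mm / degrees.

    Only the fields relevant to ``shape`` are used. Tube radii must exceed
    twice the largest voxel edge so the lumen spans at least four voxels.
    """

    shape: str = "straight_cylinder"
    radius: float = 10.0
    length: float = 80.0
    semi_axis_a: float = 15.0  # elliptical_tube, in-plane x
    semi_axis_b: float = 10.0  # elliptical_tube, in-plane y
    tilt_deg: float = 20.0  # tilted_cylinder, from the z axis in x-z
    major_radius: float = 40.0  # torus_arch / candy_cane arch radius
    descending_length: float = 60.0  # candy_cane inferior limb
    ascending_length: float = 40.0  # candy_cane anterior limb
    branch_ratio: float = 0.5  # branch radius / trunk radius (subclavian-like)
    branch_theta_deg: float = 60.0  # take-off position along the arch
    branch_angle_deg: float = 30.0  # take-off angle from local travel dir
    branch_azimuth_deg: float = 90.0  # take-off azimuth: 0 = outward in the
    # arch plane, 90 = sideways out of it (as real head/neck vessels leave it)
    branch_length: float = 35.0
    cavity_radius: float = 8.0  # cavitated_tube void radius
    cavity_fraction: float = 0.5  # void center position / length
    bulge_amplitude: float = 0.0  # Gaussian aneurysm added to tube radius
    bulge_sigma: float = 8.0
    bulge_fraction: float = 0.5
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise: float = 0.0  # boundary jitter amplitude, voxels
    seed: int = 0

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise PhantomSpecError(f"unknown shape {self.shape!r}")
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or (sp <= 0).any():
            raise PhantomSpecError("spacing must be a positive mm-triple")
        limit = 2.0 * sp.max()
        radii = [self.radius]
        if self.shape == "elliptical_tube":
            radii = [self.semi_axis_a, self.semi_axis_b]
        if self.shape == "candy_cane_with_branch":
            radii.append(self.branch_ratio * self.radius)
        if min(radii) <= limit:
            raise PhantomSpecError(
                f"tube radius {min(radii):g} mm not resolvable at spacing "
                f"{sp.max():g} mm (needs > {limit:g} mm)"
            )


@dataclass
class PhantomTruth:
    """Analytic centerline and profile functions for the unjittered solid."""

    centerline: Callable[[np.ndarray], np.ndarray]  # s (mm) -> (..., 3) mm
    area_fn: Callable[[np.ndarray], np.ndarray]  # mm^2
    maxdiam_fn: Callable[[np.ndarray], np.ndarray]  # mm
    length: float  # total centerline arc length, mm
    valid_range: tuple[float, float]  # arc interval free of end effects
    _tree: cKDTree | None = field(default=None, repr=False)
    _s_dense: np.ndarray | None = field(default=None, repr=False)

    def _ensure_tree(self, ds: float = 0.2) -> None:
        if self._tree is None:
            s = np.arange(0.0, self.length + ds, ds)
            s = np.clip(s, 0.0, self.length)
            self._s_dense = s
            self._tree = cKDTree(self.centerline(s))

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Arc-length position and distance of each point to the centerline."""
        self._ensure_tree()
        dist, idx = self._tree.query(np.atleast_2d(points))
        return self._s_dense[idx], dist

    def centerline_rmse(self, points: np.ndarray, valid_only: bool = True) -> float:
        """RMS distance (mm) of tracked centers to the analytic curve."""
        s, dist = self.project(points)
        if valid_only:
            lo, hi = self.valid_range
            keep = (s >= lo) & (s <= hi)
            if keep.any():
                dist = dist[keep]
        return float(np.sqrt(np.mean(dist**2)))


# ---- implicit solids -----------------------------------------------------


def _capped_cylinder(px, py, pz, base, axis, radius, length, eps=0.0):
    """Approximate SDF of a finite cylinder (negative inside).

    ``eps`` perturbs the lateral wall only; the flat caps stand for the
    edge of the imaging volume and stay exact.
    """
    dx, dy, dz = px - base[0], py - base[1], pz - base[2]
    s = dx * axis[0] + dy * axis[1] + dz * axis[2]
    perp2 = (dx * dx + dy * dy + dz * dz) - s * s
    radial = np.sqrt(np.maximum(perp2, 0.0)) - radius - eps
    return np.maximum(radial, np.maximum(-s, s - length))


def _candy_cane_pieces(spec: PhantomSpec):
    r, R = spec.radius, spec.major_radius
    H, La = spec.descending_length, spec.ascending_length
    if La >= H:
        raise PhantomSpecError(
            "ascending limb must be shorter than descending so the two most "
            "inferior axial slices contain the descending limb only"
        )
    return r, R, H, La


def _eval_solid(spec: PhantomSpec, px, py, pz, eps=0.0):
    """Approximate signed distance (mm) of the spec's solid; negative inside.

    ``eps`` (scalar or per-voxel array) jitters the vessel wall outward;
    open-end caps — stand-ins for the crop of the imaging volume — and the
    cavitation void surface stay exact.
    """
    r, L = spec.radius, spec.length
    if spec.shape == "straight_cylinder":
        rad = np.sqrt(px * px + py * py)
        r_of_z = r + spec.bulge_amplitude * np.exp(
            -((pz - spec.bulge_fraction * L) ** 2) / (2.0 * spec.bulge_sigma**2)
        )
        return np.maximum(rad - r_of_z - eps, np.maximum(-pz, pz - L))
    if spec.shape == "cavitated_tube":
        body = _capped_cylinder(px, py, pz, (0, 0, 0), (0, 0, 1), r, L, eps)
        cz = spec.cavity_fraction * L
        void = spec.cavity_radius - np.sqrt(px * px + py * py + (pz - cz) ** 2)
        return np.maximum(body, void)
    if spec.shape == "tilted_cylinder":
        t = np.deg2rad(spec.tilt_deg)
        axis = (np.sin(t), 0.0, np.cos(t))
        return _capped_cylinder(px, py, pz, (0, 0, 0), axis, r, L, eps)
    if spec.shape == "elliptical_tube":
        a, b = spec.semi_axis_a, spec.semi_axis_b
        radial = (np.sqrt((px / a) ** 2 + (py / b) ** 2) - 1.0) * min(a, b)
        return np.maximum(radial - eps, np.maximum(-pz, pz - L))
    if spec.shape == "torus_arch":
        R = spec.major_radius
        ring = np.sqrt((np.sqrt(px * px + pz * pz) - R) ** 2 + py * py) - r
        return np.maximum(ring - eps, -pz)
    if spec.shape in ("candy_cane", "candy_cane_with_branch"):
        r, R, H, La = _candy_cane_pieces(spec)
        # limbs overrun the junction plane slightly: with exact caps the
        # three pieces all have f=0 on z=H and the whole junction voxel
        # layer would rasterize to background (the union would have a seam)
        ov = 1.5 * float(np.max(spec.spacing))
        desc = _capped_cylinder(px, py, pz, (R, 0, 0), (0, 0, 1), r, H + ov, eps)
        ring = np.sqrt((np.sqrt(px * px + (pz - H) ** 2) - R) ** 2 + py * py) - r
        arch = np.maximum(ring - eps, H - pz)
        asc = _capped_cylinder(px, py, pz, (-R, 0, H - La), (0, 0, 1), r, La + ov, eps)
        f = np.minimum(desc, np.minimum(arch, asc))
        if spec.shape == "candy_cane_with_branch":
            base, axis = _branch_geometry(spec)
            br = _capped_cylinder(
                px, py, pz, base, axis, spec.branch_ratio * r, spec.branch_length, eps
            )
            f = np.minimum(f, br)
        return f
    raise PhantomSpecError(spec.shape)


def _branch_geometry(spec: PhantomSpec):
    """Take-off point and unit axis of the supra-aortic branch."""
    r, R, H, _ = _candy_cane_pieces(spec)
    th = np.deg2rad(spec.branch_theta_deg)
    base = np.array([R * np.cos(th), 0.0, H + R * np.sin(th)])
    tangent = np.array([-np.sin(th), 0.0, np.cos(th)])  # travel direction
    radial = np.array([np.cos(th), 0.0, np.sin(th)])  # outward / superior
    lateral = np.array([0.0, 1.0, 0.0])  # out of the arch plane
    a = np.deg2rad(spec.branch_angle_deg)
    az = np.deg2rad(spec.branch_azimuth_deg)
    off = np.cos(az) * radial + np.sin(az) * lateral
    axis = np.cos(a) * tangent + np.sin(a) * off
    return base, axis / np.linalg.norm(axis)


def _bounds(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    r, L = spec.radius, spec.length
    if spec.shape in ("straight_cylinder", "cavitated_tube"):
        rm = r + spec.bulge_amplitude
        return np.array([-rm, -rm, 0.0]), np.array([rm, rm, L])
    if spec.shape == "tilted_cylinder":
        t = np.deg2rad(spec.tilt_deg)
        p1 = L * np.array([np.sin(t), 0, np.cos(t)])
        lo = np.minimum(0, p1) - r
        hi = np.maximum(0, p1) + r
        return lo, hi
    if spec.shape == "elliptical_tube":
        a, b = spec.semi_axis_a, spec.semi_axis_b
        return np.array([-a, -b, 0.0]), np.array([a, b, spec.length])
    if spec.shape == "torus_arch":
        R = spec.major_radius
        return np.array([-R - r, -r, 0.0]), np.array([R + r, r, R + r])
    r, R, H, La = _candy_cane_pieces(spec)
    lo = np.array([-R - r, -r, 0.0])
    hi = np.array([R + r, r, H + R + r])
    if spec.shape == "candy_cane_with_branch":
        base, axis = _branch_geometry(spec)
        tip = base + spec.branch_length * axis
        rb = spec.branch_ratio * r
        lo = np.minimum(lo, np.minimum(base, tip) - rb)
        hi = np.maximum(hi, np.maximum(base, tip) + rb)
    return lo, hi


# ---- truth ---------------------------------------------------------------


def _constant_tube_truth(centerline, length, radius):
    return PhantomTruth(
        centerline=centerline,
        area_fn=lambda s: np.full_like(np.asarray(s, float), np.pi * radius**2),
        maxdiam_fn=lambda s: np.full_like(np.asarray(s, float), 2.0 * radius),
        length=length,
        valid_range=(2.0 * radius, length - 2.0 * radius),
    )


def _truth(spec: PhantomSpec) -> PhantomTruth:
    r, L = spec.radius, spec.length
    if spec.shape in ("straight_cylinder", "cavitated_tube"):

        def line(s):
            s = np.asarray(s, dtype=float)
            return np.stack([np.zeros_like(s), np.zeros_like(s), s], axis=-1)

        if spec.shape == "straight_cylinder" and spec.bulge_amplitude > 0:

            def r_of(s):
                s = np.asarray(s, dtype=float)
                return r + spec.bulge_amplitude * np.exp(
                    -((s - spec.bulge_fraction * L) ** 2)
                    / (2.0 * spec.bulge_sigma**2)
                )

            return PhantomTruth(
                centerline=line,
                area_fn=lambda s: np.pi * r_of(s) ** 2,
                maxdiam_fn=lambda s: 2.0 * r_of(s),
                length=L,
                valid_range=(2.0 * r, L - 2.0 * r),
            )
        return _constant_tube_truth(line, L, r)
    if spec.shape == "tilted_cylinder":
        t = np.deg2rad(spec.tilt_deg)
        axis = np.array([np.sin(t), 0.0, np.cos(t)])

        def line(s):
            return np.asarray(s, dtype=float)[..., None] * axis

        return _constant_tube_truth(line, L, r)
    if spec.shape == "elliptical_tube":
        a, b = spec.semi_axis_a, spec.semi_axis_b

        def line(s):
            s = np.asarray(s, dtype=float)
            return np.stack([np.zeros_like(s), np.zeros_like(s), s], axis=-1)

        return PhantomTruth(
            centerline=line,
            area_fn=lambda s: np.full_like(np.asarray(s, float), np.pi * a * b),
            maxdiam_fn=lambda s: np.full_like(
                np.asarray(s, float), 2.0 * max(a, b)
            ),
            length=spec.length,
            valid_range=(2.0 * max(a, b), spec.length - 2.0 * max(a, b)),
        )
    if spec.shape == "torus_arch":
        R = spec.major_radius

        def arc(s):
            th = np.asarray(s, dtype=float) / R
            return np.stack(
                [R * np.cos(th), np.zeros_like(th), R * np.sin(th)], axis=-1
            )

        return _constant_tube_truth(arc, np.pi * R, r)
    # candy cane (with or without branch: truth describes the trunk)
    r, R, H, La = _candy_cane_pieces(spec)
    total = H + np.pi * R + La

    def cane(s):
        s = np.asarray(s, dtype=float)
        out = np.empty(s.shape + (3,), dtype=float)
        seg1 = s <= H
        seg2 = (s > H) & (s <= H + np.pi * R)
        seg3 = s > H + np.pi * R
        out[seg1] = np.stack(
            [np.full_like(s[seg1], R), np.zeros_like(s[seg1]), s[seg1]], axis=-1
        )
        th = (s[seg2] - H) / R
        out[seg2] = np.stack(
            [R * np.cos(th), np.zeros_like(th), H + R * np.sin(th)], axis=-1
        )
        down = s[seg3] - H - np.pi * R
        out[seg3] = np.stack(
            [np.full_like(down, -R), np.zeros_like(down), H - down], axis=-1
        )
        return out

    return _constant_tube_truth(cane, total, r)


# ---- generation ----------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[AortaMask, PhantomTruth]:
    """Rasterize the spec's solid on its voxel grid and return mask + truth.

    Deterministic for a fixed spec (including seed). Foreground is exactly
    the set of voxel centers strictly inside the analytic solid, after the
    optional per-voxel jitter of the surface threshold.
    """
    sp = np.asarray(spec.spacing, dtype=float)
    lo, hi = _bounds(spec)
    # snap the origin to the spacing lattice so phantoms sharing a spacing
    # share a world sampling lattice (differential comparisons stay exact)
    origin = np.floor(lo / sp - 3.0) * sp
    shape = np.ceil((hi - origin) / sp).astype(int) + 4
    ax = [origin[k] + sp[k] * np.arange(shape[k]) for k in range(3)]
    px, py, pz = np.meshgrid(*ax, indexing="ij")
    eps = 0.0
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        eps = spec.noise * sp.min() * rng.standard_normal(px.shape)
    f = _eval_solid(spec, px, py, pz, eps)
    inside = f < 0.0
    affine = np.eye(4)
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = origin
    mask = AortaMask(inside.astype(np.uint8), affine, ("R", "A", "S"))
    return mask, _truth(spec)


def truth_table(truth: PhantomTruth, ds: float = 1.0):
    """Tabulate the analytic truth: arc length, area, max diameter, center."""
    import pandas as pd

    s = np.arange(0.0, truth.length + ds, ds)
    s = s[s <= truth.length]
    pts = truth.centerline(s)
    return pd.DataFrame(
        {
            "arc_length_mm": s,
            "area_mm2": truth.area_fn(s),
            "max_diameter_mm": truth.maxdiam_fn(s),
            "center_x_mm": pts[:, 0],
            "center_y_mm": pts[:, 1],
            "center_z_mm": pts[:, 2],
        }
    )


def branch_free_spec(spec: PhantomSpec) -> PhantomSpec:
    """The same candy cane without its branch (for differential tests)."""
    return replace(spec, shape="candy_cane")
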