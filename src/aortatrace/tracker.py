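"""Stepwise centerline tracking with wobble-minimized perpendicular planes.

The algorithm walks the aorta from the diaphragm toward the root: seed the
direction of travel from the centers of mass of the two most inferior axial
slices (the descending aorta runs nearly vertical there), then repeat

1. extrapolate one step along the current direction,
2. "wobble" — search plane orientations within a +/-30 degree cap around
   the travel direction for the plane of minimal connected cross-sectional
   area (the clinical perpendicular plane),
3. restrict the plane to the lumen component at the current position,
4. re-center on that component's center of mass and record area, maximum
   and minimum Feret diameter,

until the centerline exits the mask. No smoothing is applied to the
centerline: only the diameter profile is the deliverable, not the curve's
exact shape. Everything is deterministic — there is no randomness anywhere
in the tracker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, label, map_coordinates

from .cross_section import (
    _CROSS,
    _OFFSETS,
    CONNECT_THRESHOLD,
    LostLumenError,
    PlaneFrame,
    cross_section_at,
    make_frame,
)
from .io import AortaMask

log = logging.getLogger(__name__)

Status = str  # {completed, exited_mask, branch_exit_suspected, stalled, lost_lumen, max_steps}


class InitializationError(RuntimeError):
    """No usable pair of inferior axial slices to seed the tracker."""


@dataclass
class TrackingConfig:
    """Tunable parameters of the tracker; lengths in mm, angles in degrees.

    ``step_mm`` and ``pitch_mm`` default to the smallest voxel dimension and
    half of it respectively when left as None.
    """

    step_mm: float | None = None
    wobble_max_deg: float = 30.0
    wobble_coarse_deg: float = 3.0
    wobble_fine_deg: float = 0.5
    max_steps: int = 2000
    min_area_mm2: float = 10.0
    stall_window: int = 5
    pitch_mm: float | None = None  # measurement-plane pixel pitch
    wobble_pitch_mm: float | None = None  # coarser pitch used inside the search
    half_fov_floor_mm: float = 20.0
    lookahead_mm: float = 20.0  # cavity-vs-exit probe distance

    def __post_init__(self):
        if not (0 < self.wobble_fine_deg <= self.wobble_coarse_deg <= self.wobble_max_deg):
            raise ValueError("need 0 < fine <= coarse <= max wobble angle")
        for name in ("step_mm", "pitch_mm", "wobble_pitch_mm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")

    def resolved(self, mask: AortaMask) -> "TrackingConfig":
        sp = float(mask.spacing.min())
        out = TrackingConfig(**{**self.__dict__})
        out.step_mm = self.step_mm or sp
        out.pitch_mm = self.pitch_mm or sp / 2.0
        out.wobble_pitch_mm = self.wobble_pitch_mm or sp
        return out


@dataclass
class CenterlineStep:
    index: int
    center: np.ndarray  # world mm
    frame: PlaneFrame
    area: float  # mm^2
    max_diameter: float  # mm
    min_diameter: float  # mm
    arc_length: float  # mm, 0 at the first recorded step


@dataclass
class CenterlineTrace:
    steps: list[CenterlineStep]
    status: Status
    config: TrackingConfig | None = None

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def arc_lengths(self) -> np.ndarray:
        return np.array([s.arc_length for s in self.steps])

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.area for s in self.steps])

    @property
    def max_diameters(self) -> np.ndarray:
        return np.array([s.max_diameter for s in self.steps])

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.steps]).reshape(-1, 3)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": [s.index for s in self.steps],
                "arc_length_mm": self.arc_lengths,
                "center_x_mm": self.centers[:, 0],
                "center_y_mm": self.centers[:, 1],
                "center_z_mm": self.centers[:, 2],
                "area_mm2": self.areas,
                "max_diameter_mm": self.max_diameters,
                "min_diameter_mm": [s.min_diameter for s in self.steps],
            }
        )


# ---- initialization ------------------------------------------------------


def initialize(mask: AortaMask, min_area_mm2: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Seed points from the two most inferior qualifying axial slices.

    Each point is the center of mass of the largest in-slice 4-connected
    foreground component; a slice qualifies when that component's area is at
    least ``min_area_mm2``. Returns (inferior point, next point) in world mm.
    """
    ax = mask.is_axis
    n = mask.voxels.shape[ax]
    order = range(n) if mask.superior_sign > 0 else range(n - 1, -1, -1)
    inplane_axes = [k for k in range(3) if k != ax]
    pixel_area = float(np.prod(mask.spacing[inplane_axes]))
    found = []
    for idx in order:
        sl = np.take(mask.voxels, idx, axis=ax)
        if not sl.any():
            continue
        labels, nlab = label(sl, structure=_CROSS)
        counts = np.bincount(labels.ravel())[1:]
        best = int(counts.argmax()) + 1
        if counts[best - 1] * pixel_area < min_area_mm2:
            continue
        ij = np.argwhere(labels == best).mean(axis=0)
        ijk = np.empty(3)
        ijk[ax] = idx
        ijk[inplane_axes[0]], ijk[inplane_axes[1]] = ij
        found.append(mask.voxel_to_world(ijk))
        if len(found) == 2:
            return found[0], found[1]
    raise InitializationError(
        f"fewer than two axial slices with >= {min_area_mm2} mm^2 of foreground"
    )


def extrapolate(p_prev: np.ndarray, p_curr: np.ndarray, step_mm: float) -> np.ndarray:
    """One step beyond ``p_curr`` along the direction from ``p_prev``."""
    p_prev = np.asarray(p_prev, dtype=float)
    p_curr = np.asarray(p_curr, dtype=float)
    d = p_curr - p_prev
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("coincident centerline points give no direction")
    return p_curr + step_mm * d / norm


# ---- wobble --------------------------------------------------------------


def _rotate(vec: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of ``vec`` about unit ``axis`` by ``angle`` (rad).

    Broadcasts over leading dimensions of ``angle``.
    """
    angle = np.asarray(angle, dtype=float)[..., None]
    c, s = np.cos(angle), np.sin(angle)
    k = np.asarray(axis, dtype=float)
    return (
        vec * c
        + np.cross(np.broadcast_to(k, vec.shape if vec.ndim > 1 else (3,)), vec) * s
        + k * (k * vec).sum(-1, keepdims=True) * (1.0 - c)
    )


def _candidate_normals(base: PlaneFrame, tilts_u: np.ndarray, tilts_v: np.ndarray,
                       max_deg: float):
    """Normals for every (tilt-u, tilt-v) pair within the spherical cap.

    Tilt-u rotates about the base u axis, then tilt-v about the base v axis.
    Returns (pairs (N,2) deg, normals (N,3), total tilt from base (N,) deg),
    ordered lexicographically by (tilt_u, tilt_v).
    """
    au, av = np.meshgrid(tilts_u, tilts_v, indexing="ij")
    pairs = np.column_stack([au.ravel(), av.ravel()])
    n1 = _rotate(base.normal, base.u_axis, np.deg2rad(pairs[:, 0]))
    n2 = _rotate(n1, base.v_axis, np.deg2rad(pairs[:, 1]))
    cosang = np.clip(n2 @ base.normal, -1.0, 1.0)
    total = np.rad2deg(np.arccos(cosang))
    keep = total <= max_deg + 1e-9
    return pairs[keep], n2[keep], total[keep]


def _connected_areas(mask: AortaMask, point: np.ndarray, normals: np.ndarray,
                     half_fov: float, pitch: float) -> np.ndarray:
    """Connected cross-sectional area (mm^2) at ``point`` for many normals.

    One batched trilinear resampling over all candidate planes, then a
    per-plane 4-connected component restriction seeded at the plane center
    (snapping within the usual 5-pixel radius). Candidates that lose the
    lumen get +inf.

    The returned area is the *soft* area: the sum of the interpolated mask
    values over the component and its one-pixel rim, times the pixel area.
    Thresholded pixel counting is piecewise constant in the tilt angles —
    plateaus many degrees wide at clinical resolutions — so the search
    objective needs the sub-pixel sensitivity of the fractional boundary
    values to localize the true area minimum.
    """
    frames = [make_frame(point, n) for n in normals]
    m = int(np.ceil(half_fov / pitch))
    coords = (np.arange(2 * m + 1) - m) * pitch
    iu, iv = np.meshgrid(coords, coords, indexing="ij")
    U = np.stack([f.u_axis for f in frames])  # (N, 3)
    V = np.stack([f.v_axis for f in frames])
    pts = (
        point[None, None, None, :]
        + iu[None, :, :, None] * U[:, None, None, :]
        + iv[None, :, :, None] * V[:, None, None, :]
    )
    vox = mask.world_to_voxel(pts.reshape(-1, 3))
    vals = map_coordinates(
        mask._float_vol, vox.T, order=1, mode="constant", cval=0.0
    ).reshape(len(frames), 2 * m + 1, 2 * m + 1)
    grids = vals >= 0.5
    areas = np.full(len(frames), np.inf)
    h = w = 2 * m + 1
    for k, grid in enumerate(grids):
        seed = None
        for di, dj in _OFFSETS:
            i, j = m + di, m + dj
            if 0 <= i < h and 0 <= j < w and grid[i, j]:
                seed = (i, j)
                break
        if seed is None:
            continue
        # connectivity at the half-voxel level, measurement at 0.5 (see
        # cross_section.connected_region_values)
        labels, _ = label(vals[k] >= CONNECT_THRESHOLD, structure=_CROSS)
        region = grid & (labels == labels[seed])
        rim = binary_dilation(region, structure=_CROSS)
        areas[k] = vals[k][rim].sum() * pitch * pitch
    return areas


def wobble(mask: AortaMask, point: np.ndarray, base_normal: np.ndarray,
           config: TrackingConfig, half_fov: float | None = None
           ) -> tuple[PlaneFrame, float]:
    """Find the plane of minimal connected cross-sectional area at ``point``.

    Coarse-to-fine grid search over two tilt angles (about the base frame's
    u and v axes) inside a spherical cap of half-angle ``wobble_max_deg``
    around ``base_normal``. Ties break toward the smallest tilt from the
    base normal, then lexicographic (tilt-u, tilt-v). Returns the winning
    frame and its (search-resolution) area.
    """
    cfg = config.resolved(mask)
    if half_fov is None:
        half_fov = cfg.half_fov_floor_mm
    point = np.asarray(point, dtype=float)
    base = make_frame(point, base_normal)
    pitch = cfg.wobble_pitch_mm

    def search(tilts_u, tilts_v):
        pairs, normals, total = _candidate_normals(
            base, tilts_u, tilts_v, cfg.wobble_max_deg
        )
        areas = _connected_areas(mask, point, normals, half_fov, pitch)
        if not np.isfinite(areas).any():
            raise LostLumenError("lumen lost at every wobble candidate")
        # deterministic tie-break: area, then tilt from base, then (u, v)
        order = np.lexsort(
            (pairs[:, 1], pairs[:, 0], np.round(total, 6), areas)
        )
        k = order[0]
        return pairs[k], normals[k], areas[k]

    nc = int(np.floor(cfg.wobble_max_deg / cfg.wobble_coarse_deg))
    coarse = np.arange(-nc, nc + 1) * cfg.wobble_coarse_deg
    (cu, cv), _, _ = search(coarse, coarse)
    nf = int(np.round(cfg.wobble_coarse_deg / cfg.wobble_fine_deg))
    fine_off = np.arange(-nf, nf + 1) * cfg.wobble_fine_deg
    (fu, fv), n_best, area = search(cu + fine_off, cv + fine_off)
    log.debug("wobble at %s: tilt=(%.1f,%.1f) deg area=%.1f mm^2", point, fu, fv, area)
    return make_frame(point, n_best), float(area)


# ---- main loop -----------------------------------------------------------


def _lookahead_reenters(mask: AortaMask, point: np.ndarray, direction: np.ndarray,
                        step_mm: float, lookahead_mm: float) -> bool:
    """True if the straight ray from ``point`` re-enters foreground within
    ``lookahead_mm`` — i.e. the point sits in an enclosed cavity or gap
    rather than outside the vessel."""
    t = np.arange(step_mm, lookahead_mm + step_mm, step_mm)
    probes = point[None, :] + t[:, None] * direction[None, :]
    return bool((mask.sample_world(probes) >= 0.5).any())


def _ray_exits_for_good(mask: AortaMask, point: np.ndarray, direction: np.ndarray,
                        step_mm: float, lookahead_mm: float,
                        margin_mm: float = 5.0) -> bool:
    """True if the forward ray leaves the foreground and stays out.

    Distinguishes the open end of the vessel (exit imminent: the ray's
    trailing ``margin_mm`` is all background) from a cavitation or sharp
    bend, where foreground persists or reappears along the ray.
    """
    t = np.arange(step_mm, lookahead_mm + step_mm, step_mm)
    fg = mask.sample_world(point[None, :] + t[:, None] * direction[None, :]) >= 0.5
    if not fg.any():
        return True
    last = int(np.where(fg)[0].max())
    trailing = len(fg) - 1 - last
    return trailing * step_mm >= margin_mm


def _travel_axis(steps: list, fallback: np.ndarray) -> np.ndarray:
    """Best local estimate of the vessel axis: the last wobbled plane normal,
    sign-aligned with the direction of travel."""
    if not steps:
        return fallback
    n = steps[-1].frame.normal
    return n if float(n @ fallback) >= 0 else -n


def _direction_coherent(steps: list, axis: np.ndarray, window: int = 10,
                        max_deg: float = 25.0) -> bool:
    """True when ``axis`` agrees with the recent mean direction of travel.

    A vessel end is reached along the established direction; a walk that
    has veered (e.g. dragged sideways by a merging side vessel) has not
    arrived at an end, whatever the local rays say.
    """
    if len(steps) < window + 1:
        return True
    c = np.array([s.center for s in steps[-(window + 1):]])
    mean_dir = c[-1] - c[0]
    n = np.linalg.norm(mean_dir)
    if n == 0:
        return False
    cosang = float(np.clip(mean_dir / n @ axis, -1.0, 1.0))
    return np.degrees(np.arccos(cosang)) <= max_deg


def _locally_stable(steps: list, window: int = 5, tol: float = 0.15) -> bool:
    """True when the recent area series is steady.

    A vessel end is approached through a stable lumen, so the end-of-vessel
    probes only run then; wild area swings mean the plane is entangled with
    a side structure and the walk should continue uncorrected.
    """
    if len(steps) < window:
        return True
    a = np.array([s.area for s in steps[-window:]])
    m = a.mean()
    return bool(m > 0 and a.std() / m < tol)


def track(mask: AortaMask, config: TrackingConfig | None = None) -> CenterlineTrace:
    """Run the full tracking loop and return the measured trace.

    Terminal status:

    - ``completed`` — the centerline left the mask through an end after a
      substantive traverse with no suspected branch exit;
    - ``branch_exit_suspected`` — it left the mask but the area profile
      shows an unrecovered >60% collapse (tracked up a side vessel);
    - ``exited_mask`` — it left the mask almost immediately, or the
      connected area fell below ``min_area_mm2``;
    - ``lost_lumen`` — the plane lost the lumen or the extrapolated point
      entered an enclosed cavity in the segmentation;
    - ``stalled`` — travel direction kept reversing (cavitation behaviour);
    - ``max_steps`` — hard iteration cap.
    """
    cfg = (config or TrackingConfig()).resolved(mask)
    p0, p1 = initialize(mask, cfg.min_area_mm2)
    d0 = (p1 - p0) / np.linalg.norm(p1 - p0)
    # The minimal-area objective is degenerate within ~r/2 of an open end
    # (a tilted plane wins by clipping the cap), so start the walk one
    # radius-scaled advance beyond the seed slices.
    a0 = _connected_areas(mask, p1, d0[None, :], cfg.half_fov_floor_mm,
                          cfg.wobble_pitch_mm)[0]
    advance = 0.6 * np.sqrt(a0 / np.pi) if np.isfinite(a0) else 0.0
    p_prev, p_curr = p1, p1 + advance * d0
    if mask.sample_world(p_curr) < 0.5:
        p_prev, p_curr = p0, p1
    steps: list[CenterlineStep] = []
    arc = 0.0
    half_fov = cfg.half_fov_floor_mm  # measurement plane
    search_fov = cfg.half_fov_floor_mm  # wobble candidates (cross-section + slack)
    reversals = 0
    prev_disp: np.ndarray | None = None
    status: Status = "max_steps"
    exit_pending = False

    for i in range(cfg.max_steps):
        try:
            p_new = extrapolate(p_prev, p_curr, cfg.step_mm)
        except ValueError:
            status = "stalled"
            break
        direction = (p_new - p_curr) / cfg.step_mm
        try:
            frame, _ = wobble(mask, p_new, direction, cfg, search_fov)
            sec = cross_section_at(mask, frame, half_fov, cfg.pitch_mm)
        except LostLumenError:
            # No lumen near the point in any candidate plane: an enclosed
            # cavity or gap if foreground reappears ahead, otherwise the
            # walk has left the vessel.
            if _lookahead_reenters(mask, p_new, direction, cfg.step_mm, cfg.lookahead_mm):
                status = "lost_lumen"
            else:
                exit_pending = True
            break
        if sec.area < cfg.min_area_mm2:
            exit_pending = True
            break
        center = sec.centroid_world
        disp = center - p_curr
        dist = float(np.linalg.norm(disp))
        if dist < 1e-9:
            status = "stalled"
            break
        if dist > 3.0 * cfg.step_mm:
            # Re-centering jumped implausibly far. At an open end this is the
            # cap-clip artifact and the walk is over; elsewhere (e.g. a side
            # vessel merging into the section) the jump is real dynamics —
            # record it and keep tracking, exactly as an uncorrected
            # minimal-area walker would.
            axis = _travel_axis(steps, direction)
            if (
                _locally_stable(steps)
                and _direction_coherent(steps, axis)
                and _ray_exits_for_good(mask, p_curr, axis, cfg.step_mm, cfg.lookahead_mm)
            ):
                exit_pending = True
                break
        if steps:
            arc += dist
        steps.append(
            CenterlineStep(
                index=len(steps),
                center=center,
                frame=frame,
                area=sec.area,
                max_diameter=sec.max_diameter,
                min_diameter=sec.min_diameter,
                arc_length=arc,
            )
        )
        log.debug(
            "step %d: arc=%.1f area=%.1f dmax=%.2f", len(steps) - 1, arc,
            sec.area, sec.max_diameter,
        )
        if prev_disp is not None and float(disp @ prev_disp) < 0.0:
            # Direction reversal: either the minimal-area plane has started
            # clipping the open end of the vessel (exit imminent) or the
            # tracker is turning back on itself inside a defect.
            fwd = _travel_axis(steps, prev_disp / np.linalg.norm(prev_disp))
            if (
                _locally_stable(steps)
                and _direction_coherent(steps, fwd)
                and _ray_exits_for_good(mask, p_curr, fwd, cfg.step_mm, cfg.lookahead_mm)
            ):
                steps.pop()  # the backward step is an end-cap artifact
                exit_pending = True
                break
            reversals += 1
            if reversals >= cfg.stall_window:
                status = "stalled"
                break
        else:
            reversals = 0
        prev_disp = disp
        half_fov = max(cfg.half_fov_floor_mm, 3.0 * sec.max_diameter / 2.0)
        # candidates only need the (possibly 30-degree-oblique) section to fit
        search_fov = max(cfg.half_fov_floor_mm, 0.7 * sec.max_diameter + 5.0)
        p_prev, p_curr = p_curr, center

    trace = CenterlineTrace(steps=steps, status=status, config=cfg)
    if exit_pending:
        if len(steps) < 10:
            trace.status = "exited_mask"
        elif detect_branch_exit(trace, mask):
            trace.status = "branch_exit_suspected"
        elif _turned_back(trace):
            # left the mask only after retracing its own path
            trace.status = (
                "branch_exit_suspected" if _entangled(trace) else "stalled"
            )
        else:
            trace.status = "completed"
    if trace.status in ("completed", "branch_exit_suspected"):
        _trim_end_artifacts(trace)
    elif trace.status == "stalled" and len(steps) >= 10 and _entangled(trace):
        # A stall amid violently spiking sections is the side-vessel
        # entanglement failure, not a cavitation turn-back.
        trace.status = "branch_exit_suspected"
    log.info(
        "tracking finished: status=%s steps=%d arc=%.1f mm",
        trace.status, len(steps), arc,
    )
    return trace


def _turned_back(trace: CenterlineTrace) -> bool:
    """True when the walk ended much closer to its start than its farthest
    excursion — it turned around and retraced the vessel."""
    c = trace.centers
    if len(c) < 10:
        return False
    extent = np.linalg.norm(c - c[0], axis=1)
    return bool(extent[-1] < 0.5 * extent.max())


def _entangled(trace: CenterlineTrace, factor: float = 1.6) -> bool:
    """True when the area series carries large transient spikes — the
    signature of measurement planes slicing longitudinally into a side
    vessel (cavitation failures show no such spikes)."""
    a = trace.areas
    if len(a) < 10:
        return False
    return bool(a.max() > factor * np.median(a))


def _trim_end_artifacts(trace: CenterlineTrace, max_trim: int = 20,
                        max_tilt_deg: float = 15.0) -> None:
    """Drop the trailing steps measured in cap-clipping planes.

    Approaching the open end of the vessel, the minimal-area plane tilts to
    clip the flat cap; those oblique sections carry elongated diameters that
    would otherwise masquerade as the profile peak. They are identified
    geometrically: the recorded plane normal veers away from the local
    direction of travel.
    """
    steps = trace.steps
    lim = max(1, len(steps) - max_trim)
    cutoff = np.cos(np.deg2rad(max_tilt_deg))
    k = len(steps)
    while k > lim:
        disp = steps[k - 1].center - steps[k - 2].center
        norm = np.linalg.norm(disp)
        if norm == 0:
            break
        if abs(float(steps[k - 1].frame.normal @ disp) / norm) >= cutoff:
            break
        k -= 1
    del steps[k:]


def detect_branch_exit(trace: CenterlineTrace, mask: AortaMask | None = None,
                       drop_fraction: float = 0.6, window: int = 10) -> bool:
    """Advisory flag: did the tracker leave up a side vessel?

    True when the cross-sectional area collapses by more than
    ``drop_fraction`` within ``window`` steps and never recovers to 80% of
    its pre-drop level. Traces shorter than ``window`` are never flagged.
    The default tracker takes no corrective action on this flag.
    """
    a = trace.areas
    if len(a) < window:
        return False
    # rolling-median baseline so isolated spike planes (sections slipping
    # into head/neck vessels) cannot serve as the pre-drop reference
    base = (
        pd.Series(a).rolling(5, min_periods=1).median().to_numpy()
    )
    for i in range(len(a) - 1):
        lo = a[i + 1 : i + 1 + window]
        if lo.size == 0:
            break
        j = i + 1 + int(np.argmin(lo))
        if a[j] < (1.0 - drop_fraction) * base[i]:
            if not (a[j:] >= 0.8 * base[i]).any():
                return True
    return False
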