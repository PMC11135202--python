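"""Per-step audit renderings.

Every measurement should be verifiable by eye, so each step renders as a
three-panel composite: (a) an orthographic silhouette of the segmented
model with the centerline and a marker at the current step, (b) the
diameter-vs-arc-length curve with a cursor at the step, and (c) the
resampled oblique plane with the connected lumen region tinted. Panel (c)
uses the mask itself as the grayscale background unless a co-registered
intensity volume is supplied.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PolyCollection

from .cross_section import connected_region, plane_points, sample_plane
from .metrics import peak_diameter, spike_filter


def _silhouette_triangles(mask):
    """Marching-cubes surface projected orthographically onto world x-z."""
    from skimage.measure import marching_cubes

    vol = np.pad(mask.voxels.astype(float), 1)
    verts, faces, _, _ = marching_cubes(vol, level=0.5)
    verts_world = mask.voxel_to_world(verts - 1.0)
    tri = verts_world[faces][:, :, [0, 2]]  # drop world y (projection axis)
    return tri


def render_step(mask, trace, step_index: int, out_path: str | Path,
                image=None) -> Path:
    """Write the three-panel composite PNG for one step."""
    if not 0 <= step_index < len(trace.steps):
        raise IndexError(f"step {step_index} outside trace of {len(trace.steps)}")
    step = trace.steps[step_index]
    fig, axes = plt.subplots(1, 3, figsize=(13, 4.2))

    # (a) model silhouette + centerline + marker
    ax = axes[0]
    ax.add_collection(
        PolyCollection(_silhouette_triangles(mask), facecolor="0.8",
                       edgecolor="none")
    )
    centers = trace.centers
    ax.plot(centers[:, 0], centers[:, 2], color="tab:red", lw=1.0)
    ax.plot(step.center[0], step.center[2], "o", color="tab:blue", ms=8)
    ax.set_aspect("equal")
    ax.autoscale_view()
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_title("model + centerline")

    # (b) diameter curve with cursor
    ax = axes[1]
    _profile_axes(ax, trace, cursor=step)

    # (c) oblique plane with lumen overlay
    ax = axes[2]
    half_fov = max(20.0, 1.5 * step.max_diameter)
    pitch = 0.5
    if trace.config is not None and trace.config.pitch_mm:
        pitch = trace.config.pitch_mm
    vol = image if image is not None else mask
    bg_grid = _plane_intensity(vol, step.frame, half_fov, pitch)
    region = connected_region(
        sample_plane(mask, step.frame, half_fov, pitch),
        (bg_grid.shape[0] // 2, bg_grid.shape[1] // 2),
    )
    extent = [-half_fov, half_fov, -half_fov, half_fov]
    ax.imshow(bg_grid.T, cmap="gray", origin="lower", extent=extent)
    overlay = np.ma.masked_where(region == 0, region)
    ax.imshow(overlay.T, cmap="autumn", origin="lower", extent=extent,
              alpha=0.45, vmin=0, vmax=1)
    ax.set_title(f"cross-section, {step.max_diameter:.1f} mm max")
    ax.set_xlabel("u (mm)")
    ax.set_ylabel("v (mm)")

    fig.suptitle(f"step {step.index} / arc {step.arc_length:.1f} mm")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def _plane_intensity(volume, frame, half_fov, pitch):
    pts = plane_points(frame, half_fov, pitch)
    vals = volume.sample_world(pts.reshape(-1, 3))
    return np.asarray(vals).reshape(pts.shape[:2])


def _profile_axes(ax, trace, cursor=None, annotate_peak=True):
    s = trace.arc_lengths
    d = trace.max_diameters
    flags = spike_filter(trace)
    ax.plot(s, d, color="tab:blue", lw=1.2)
    if flags.any():
        ax.plot(s[flags], d[flags], "x", color="tab:orange", ms=5,
                label="spike-flagged")
        ax.legend(loc="lower right", fontsize=8)
    if annotate_peak and not flags.all():
        ps, pd_ = peak_diameter(trace)
        ax.annotate(f"peak {pd_:.2f} mm", (ps, pd_),
                    textcoords="offset points", xytext=(4, 6), fontsize=8)
        ax.plot(ps, pd_, "v", color="tab:green", ms=6)
    if cursor is not None:
        ax.plot(cursor.arc_length, cursor.max_diameter, "+", color="tab:red",
                ms=12, mew=2)
    ax.set_xlabel("arc length from diaphragm (mm)")
    ax.set_ylabel("max diameter (mm)")


def render_profile(trace, out_path: str | Path) -> Path:
    """Write the diameter-vs-arc-length curve with spikes and peak marked."""
    if len(trace.steps) == 0:
        raise ValueError("empty trace")
    fig, ax = plt.subplots(figsize=(7, 4))
    _profile_axes(ax, trace)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def render_all_steps(mask, trace, out_dir: str | Path, every: int = 1,
                     image=None) -> list[Path]:
    """Render ``frame_0000.png``-style composites for every ``every``-th step."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(0, len(trace.steps), every):
        paths.append(
            render_step(mask, trace, k, out_dir / f"frame_{k:04d}.png", image)
        )
    return paths
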