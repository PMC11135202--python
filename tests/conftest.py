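"""Shared fixtures: phantoms are generated once per session and tracked
traces are cached, since tracking is the expensive step every module needs."""

from __future__ import annotations

import time

import numpy as np
import pytest

from aortatrace import (
    CenterlineStep,
    CenterlineTrace,
    PhantomSpec,
    generate_phantom,
    make_frame,
    track,
)

CYLINDER_RADII = (8, 10, 15)
CANE_KW = dict(radius=12, major_radius=35, descending_length=60, ascending_length=35)


def cylinder_spec(radius: float) -> PhantomSpec:
    return PhantomSpec(shape="straight_cylinder", radius=radius, length=80)


@pytest.fixture(scope="session")
def tracked():
    """Factory caching (mask, truth, trace, seconds) per named scenario."""
    cache: dict[str, tuple] = {}

    def get(name: str):
        if name not in cache:
            if name.startswith("cylinder"):
                spec = cylinder_spec(int(name.split("_r")[1]))
            elif name == "candy_cane":
                spec = PhantomSpec(shape="candy_cane", **CANE_KW)
            elif name == "branch":
                spec = PhantomSpec(shape="candy_cane_with_branch", **CANE_KW)
            elif name == "cavitated":
                spec = PhantomSpec(
                    shape="cavitated_tube", radius=10, length=80, cavity_radius=8
                )
            elif name == "bulge":
                # gentle fusiform aneurysm: 20 mm tube dilating to 34 mm
                spec = PhantomSpec(
                    shape="straight_cylinder", radius=10, length=120,
                    bulge_amplitude=7.0, bulge_sigma=16.0, bulge_fraction=0.5,
                )
            else:  # pragma: no cover
                raise KeyError(name)
            mask, truth = generate_phantom(spec)
            t0 = time.perf_counter()
            trace = track(mask)
            cache[name] = (mask, truth, trace, time.perf_counter() - t0)
        return cache[name]

    return get


def synthetic_trace(max_diameters, areas=None, step_mm=1.0) -> CenterlineTrace:
    """A straight-line trace with prescribed per-step measurements, for
    profile-summary and I/O tests that need no actual tracking."""
    d = np.asarray(max_diameters, dtype=float)
    if areas is None:
        areas = np.pi * (d / 2.0) ** 2
    steps = []
    for i, (di, ai) in enumerate(zip(d, areas)):
        center = np.array([0.0, 0.0, i * step_mm])
        steps.append(
            CenterlineStep(
                index=i,
                center=center,
                frame=make_frame(center, np.array([0.0, 0.0, 1.0])),
                area=float(ai),
                max_diameter=float(di),
                min_diameter=float(di) * 0.9,
                arc_length=i * step_mm,
            )
        )
    return CenterlineTrace(steps=steps, status="completed", config=None)


def valid_region_stats(trace, truth):
    """Median tracked max diameter and centerline RMSE over the end-effect-free
    region of a phantom."""
    s, dist = truth.project(trace.centers)
    lo, hi = truth.valid_range
    keep = (s >= lo) & (s <= hi)
    med = float(np.median(trace.max_diameters[keep]))
    return med, truth.centerline_rmse(trace.centers)


def random_blob(rng: np.random.Generator, size: int = 30) -> np.ndarray:
    """A random single-4-connected-component {0,1} grid."""
    from scipy import ndimage

    while True:
        field = ndimage.gaussian_filter(rng.random((size, size)), 2.5)
        grid = (field > np.quantile(field, 0.75)).astype(np.uint8)
        labels, n = ndimage.label(
            grid, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        )
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())[1:]
        comp = (labels == (int(counts.argmax()) + 1)).astype(np.uint8)
        if comp.sum() >= 4:
            return comp
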