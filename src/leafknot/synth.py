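"""Synthetic transilluminated leaf images with analytic ground truth.

The generator emulates the image classes the pipeline is built for: a bright
background, a mid-gray lobed blade, darker double-thickness regions where a
lobe overlaps the blade (OL), and background-bright sinuses enclosed by
touching (TL) or overlapping lobes.  The blade is a smooth polar shape with
sinusoidal lobes; OL and TL features are built from discs whose positions
are snapped to the pixel grid so that the separating blade strips rasterize
to exactly the widths that place contour junctions at 2 px — the adjacency
default of the topology stage — without 8-connected leaks between bright
regions.  Because everything is constructive, region classes, junction kinds
and locations, and the expected contour count are known exactly.

Presets mirror the canonical image classes: ``simple`` (plain lobed leaf),
``tl`` (one enclosed sinus behind touching lobes), ``ol`` (one overlapping
lobe with its closed sinus), and ``fig1d`` (two OL and two TL clusters,
giving the seven-contour worked example: one blade, two OL outlines, two
OL-closed sinuses, two TL-closed sinuses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracing import RegionClass

__all__ = ["LeafSpec", "GroundTruth", "make_leaf", "preset", "PRESETS", "LeafGeometryError"]


class LeafGeometryError(ValueError):
    """The requested lobe layout cannot be built on the given canvas."""


@dataclass
class LeafSpec:
    """Parameters of a synthetic leaf image.

    ``overlap_lobes`` / ``touch_lobes`` list lobe indices (lobe ``k`` points
    along angle ``2*pi*k/n_lobes``, screen axes).  Cluster geometry is snapped
    to the pixel grid, which requires the chosen lobes to point along image
    axes.  ``sinus_depth`` is the relative amplitude of the lobing.
    """

    n_lobes: int = 4
    sinus_depth: float = 0.12
    base_radius: float = 120.0
    overlap_lobes: tuple[int, ...] = ()
    touch_lobes: tuple[int, ...] = ()
    gray_levels: tuple[int, int, int] = (230, 140, 60)  # background, blade, overlap
    noise_sigma: float = 3.0
    seed: int = 0
    canvas: tuple[int, int] = (400, 400)  # (height, width)
    venation: bool = False


@dataclass
class GroundTruth:
    """Analytic truth accompanying a generated image."""

    region_label_image: np.ndarray
    region_classes: dict[int, RegionClass]
    junctions: list[tuple[str, float, float]]  # (kind, x, y)
    expected_contour_count: int
    seed: int
    class_means: tuple[int, int, int] = (0, 0, 0)


# disc radii and grid-snapped offsets (relative to m = floor(apex radius));
# chosen so the A-O and O-H / A-TL junction gaps rasterize to 2.0 px
_RHO_OL = 16.2       # overlap disc radius
_RHO_OL_SINUS = 11.4  # sinus disc closed by the overlap
_RHO_TL = 12.4       # sinus disc closed by touching lobes
_OL_EDGE = 1.8       # overlap outer edge sits at m - _OL_EDGE
_OL_SINUS_EDGE = 35.8
_TL_EDGE = 1.8


def _axis_direction(k: int, n_lobes: int) -> tuple[int, int]:
    angle_deg = 360.0 * k / n_lobes
    for deg, u in ((0, (1, 0)), (90, (0, 1)), (180, (-1, 0)), (270, (0, -1))):
        if abs(((angle_deg - deg) + 180.0) % 360.0 - 180.0) < 1e-9:
            return u
    raise LeafGeometryError(
        f"lobe {k} of {n_lobes} points along {angle_deg:.1f} deg; touching/"
        "overlapping clusters require an axis-aligned lobe (0/90/180/270 deg)"
    )


def make_leaf(spec: LeafSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic leaf image and its ground truth.

    Raises :class:`LeafGeometryError` when the requested clusters are
    geometrically impossible on the canvas.
    """
    h, w = spec.canvas
    bg, blade_gray, overlap_gray = spec.gray_levels
    if not bg > blade_gray > overlap_gray:
        raise LeafGeometryError("gray levels must satisfy background > blade > overlap")
    if set(spec.overlap_lobes) & set(spec.touch_lobes):
        raise LeafGeometryError("a lobe cannot both overlap and touch")
    for k in list(spec.overlap_lobes) + list(spec.touch_lobes):
        if not (0 <= k < spec.n_lobes):
            raise LeafGeometryError(f"lobe index {k} out of range for {spec.n_lobes} lobes")

    cx, cy = w // 2, h // 2
    amp = spec.sinus_depth
    r_apex = spec.base_radius * (1.0 + amp)
    m = int(np.floor(r_apex))
    frac = r_apex - m
    if not (0.05 < frac < 0.95):
        raise LeafGeometryError(
            f"apex radius {r_apex} lies too close to a pixel boundary; "
            "adjust base_radius or sinus_depth"
        )
    if m + 4 > min(cx, cy, w - 1 - cx, h - 1 - cy):
        raise LeafGeometryError("canvas too small for the requested blade")
    if (spec.overlap_lobes or spec.touch_lobes) and m < 52:
        raise LeafGeometryError("blade too small to host touching/overlapping clusters")

    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - cx, ys - cy
    r = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    blade = r <= spec.base_radius * (1.0 + amp * np.cos(spec.n_lobes * phi))

    def disc(center: tuple[float, float], rho: float) -> np.ndarray:
        return (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= rho**2

    overlaps: list[np.ndarray] = []
    holes: list[np.ndarray] = []
    junctions: list[tuple[str, float, float]] = []
    ordered_regions: list[tuple[np.ndarray, RegionClass]] = []

    for k in spec.overlap_lobes:
        ux, uy = _axis_direction(k, spec.n_lobes)
        o_center = (cx + (m - _OL_EDGE - _RHO_OL) * ux, cy + (m - _OL_EDGE - _RHO_OL) * uy)
        s_center = (
            cx + (m - _OL_SINUS_EDGE - _RHO_OL_SINUS) * ux,
            cy + (m - _OL_SINUS_EDGE - _RHO_OL_SINUS) * uy,
        )
        o_mask = disc(o_center, _RHO_OL)
        s_mask = disc(s_center, _RHO_OL_SINUS)
        if not (o_mask <= blade).all() or not (s_mask <= blade).all():
            raise LeafGeometryError(f"overlap cluster on lobe {k} does not fit inside the blade")
        overlaps.append(o_mask)
        holes.append(s_mask)
        ordered_regions.append((o_mask, RegionClass.OL_OUTLINE))
        ordered_regions.append((s_mask, RegionClass.SINUS))
        junctions.append(("cross", cx + (m - 1) * ux, cy + (m - 1) * uy))
        junctions.append(("cross", cx + (m - 35) * ux, cy + (m - 35) * uy))

    for k in spec.touch_lobes:
        ux, uy = _axis_direction(k, spec.n_lobes)
        t_center = (cx + (m - _TL_EDGE - _RHO_TL) * ux, cy + (m - _TL_EDGE - _RHO_TL) * uy)
        t_mask = disc(t_center, _RHO_TL)
        if not (t_mask <= blade).all():
            raise LeafGeometryError(f"touch cluster on lobe {k} does not fit inside the blade")
        holes.append(t_mask)
        ordered_regions.append((t_mask, RegionClass.SINUS))
        junctions.append(("touch", cx + (m - 1) * ux, cy + (m - 1) * uy))

    base = np.full((h, w), float(bg))
    base[blade] = blade_gray
    for hole in holes:
        base[hole] = bg
    for o_mask in overlaps:
        base[o_mask] = overlap_gray

    if spec.venation:
        from skimage.draw import line as draw_line

        for k in range(spec.n_lobes):
            ang = 2.0 * np.pi * (k + 0.5) / spec.n_lobes
            x1 = cx + 0.7 * spec.base_radius * (1 - amp) * np.cos(ang)
            y1 = cy + 0.7 * spec.base_radius * (1 - amp) * np.sin(ang)
            rr, cc = draw_line(cy, cx, int(round(y1)), int(round(x1)))
            base[rr, cc] = overlap_gray

    label_image = np.zeros((h, w), dtype=np.int32)
    classes: dict[int, RegionClass] = {}
    blade_region = blade.copy()
    for hole in holes:
        blade_region &= ~hole
    for o_mask in overlaps:
        blade_region &= ~o_mask
    label_image[blade_region] = 1
    classes[1] = RegionClass.BLADE
    for i, (mask, cls) in enumerate(ordered_regions, start=2):
        label_image[mask] = i
        classes[i] = cls

    rng = np.random.default_rng(spec.seed)
    noisy = base + rng.normal(0.0, spec.noise_sigma, size=base.shape)
    image = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        region_label_image=label_image,
        region_classes=classes,
        junctions=junctions,
        expected_contour_count=1 + len(ordered_regions),
        seed=spec.seed,
        class_means=spec.gray_levels,
    )
    return image, truth


PRESETS: dict[str, LeafSpec] = {
    "simple": LeafSpec(n_lobes=5),
    "tl": LeafSpec(n_lobes=4, touch_lobes=(1,)),
    "ol": LeafSpec(n_lobes=4, overlap_lobes=(0,)),
    "fig1d": LeafSpec(n_lobes=4, overlap_lobes=(0, 2), touch_lobes=(1, 3)),
}


def preset(name: str, seed: int | None = None, **overrides) -> LeafSpec:
    """Return a copy of a named preset, optionally re-seeded/overridden."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    from dataclasses import replace

    spec = PRESETS[name]
    if seed is not None:
        overrides["seed"] = seed
    return replace(spec, **overrides) if overrides else spec
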