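"""Contour editing utilities and coordinate-file / raster I/O.

The cut function splits a closed ring along a straight line segment — used
to remove petioles, separate overlapping herbarium leaves sharing a twig,
and "repair" small breaks of the leaf border by replacing the defective arc
with a chord.  XY coordinate files use the plain two-column tab-separated
raw format that ImageJ imports via File > Import > XY Coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .tracing import Contour, signed_area

__all__ = [
    "CutLine",
    "CutError",
    "cut_contour",
    "save_xy",
    "load_xy",
    "render_contours",
    "fill_ring",
]


@dataclass
class CutLine:
    """A finite split segment given by its two endpoints (pixel units)."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise ValueError("cut line endpoints must differ")


class CutError(ValueError):
    def __init__(self, crossings: int):
        self.crossings = crossings
        super().__init__(
            f"cut line crosses the contour {crossings} times; exactly 2 required"
        )


def _segment_intersection(p0, p1, q0, q1):
    """Intersection parameter/point of two segments, or None.

    Returns (s, point) with s the parameter along q0->q1 when the open
    intersection exists; parallel/collinear pairs return None.
    """
    p0, p1, q0, q1 = (np.asarray(v, float) for v in (p0, p1, q0, q1))
    r = p1 - p0
    s = q1 - q0
    denom = r[0] * s[1] - r[1] * s[0]
    if denom == 0.0:
        return None
    qp = q0 - p0
    t = (qp[0] * s[1] - qp[1] * s[0]) / denom   # along p
    u = (qp[0] * r[1] - qp[1] * r[0]) / denom  # along q
    if 0.0 <= t <= 1.0 and 0.0 <= u < 1.0:
        return u, q0 + u * s
    return None


def cut_contour(c: Contour, line: CutLine) -> tuple[Contour, Contour]:
    """Split a closed ring along a cut segment crossing it exactly twice.

    New vertices are inserted at the exact (sub-pixel) crossing coordinates;
    the two resulting rings are each closed by the chord between the two
    crossings, and together they partition the original vertex set (plus the
    two inserted chord endpoints each appearing in both parts).
    """
    v = c.vertices
    n = len(v)
    hits: list[tuple[int, float, np.ndarray]] = []
    for i in range(n):
        res = _segment_intersection(line.p0, line.p1, v[i], v[(i + 1) % n])
        if res is not None:
            hits.append((i, res[0], res[1]))
    if len(hits) != 2:
        raise CutError(len(hits))
    hits.sort(key=lambda h: (h[0], h[1]))
    (i1, _, x1), (i2, _, x2) = hits

    seg_a = np.vstack([[x1], v[i1 + 1 : i2 + 1], [x2]])
    wrap = np.vstack([v[i2 + 1 :], v[: i1 + 1]])
    seg_b = np.vstack([[x2], wrap, [x1]])
    part_a = Contour(seg_a, label=f"{c.label}:a", region_class=c.region_class)
    part_b = Contour(seg_b, label=f"{c.label}:b", region_class=c.region_class)
    return part_a, part_b


def keep_largest(parts: tuple[Contour, Contour]) -> Contour:
    """Repair semantics: keep the part with the larger enclosed area."""
    return max(parts, key=lambda p: abs(signed_area(p)))


def _format_coord(x: float, decimals: int = 3) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:.{decimals}f}"


def save_xy(c: Contour, path, sep: str = "\t", decimals: int = 3) -> None:
    """Write a contour as raw two-column text (ImageJ XY-coordinates format).

    One vertex per line, x then y, tab separated, no header.  Integer
    coordinates are written without a decimal point; fractional ones with
    ``decimals`` places (so a save/load/save cycle is byte-stable).
    """
    with open(path, "w") as fh:
        for x, y in c.vertices:
            fh.write(f"{_format_coord(x, decimals)}{sep}{_format_coord(y, decimals)}\n")


def load_xy(path, sep: str | None = None) -> Contour:
    """Read a raw XY coordinate file back into a contour."""
    verts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.strip().replace(",", " ").split() if sep is None else raw.strip().split(sep)
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                verts.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: not numeric: {raw.strip()!r}") from exc
    if not verts:
        raise ValueError(f"{path}: empty coordinate file")
    import os

    return Contour(np.array(verts), label=os.path.splitext(os.path.basename(str(path)))[0])


_PALETTE = [
    (230, 60, 60), (60, 120, 230), (60, 180, 90), (230, 160, 40),
    (160, 80, 200), (80, 200, 200), (200, 200, 70),
]


def render_contours(
    contours: list[Contour],
    canvas_shape: tuple[int, int],
    junctions=None,
    line_value: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Rasterize contour polylines (and optional junction markers) to RGB.

    Cross points are drawn red and touch points blue, matching the figure
    color code of the tracing stage.
    """
    h, w = canvas_shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    for k, c in enumerate(contours):
        color = line_value or _PALETTE[k % len(_PALETTE)]
        v = np.round(c.vertices).astype(int)
        for i in range(len(v)):
            x0, y0 = v[i]
            x1, y1 = v[(i + 1) % len(v)]
            rr, cc = draw_line(y0, x0, y1, x1)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            img[rr[ok], cc[ok]] = color
    if junctions:
        from .topology import JunctionKind

        for j in junctions:
            color = (255, 0, 0) if j.kind is JunctionKind.CROSS else (0, 0, 255)
            rr, cc = draw_disk((j.point[1], j.point[0]), 2.5, shape=(h, w))
            img[rr, cc] = color
    return img


def fill_ring(ring: Contour | np.ndarray, canvas_shape: tuple[int, int]) -> np.ndarray:
    """Fill a (possibly self-intersecting) closed ring with the nonzero
    winding rule.

    Regions wound twice — the overlap regions the slalom traverses — are
    filled; loops wound oppositely — enclosed sinuses — are holes, so the
    fill reproduces the leaf silhouette the whole-leaf threshold mask shows.
    """
    v = ring.vertices if isinstance(ring, Contour) else np.asarray(ring, float)
    h, w = canvas_shape
    mask = np.zeros((h, w), dtype=bool)
    y_lo = max(int(np.ceil(v[:, 1].min())), 0)
    y_hi = min(int(np.floor(v[:, 1].max())), h - 1)
    if y_hi < y_lo:
        return mask

    # scanline winding numbers: each non-horizontal edge contributes a signed
    # crossing to every pixel-center row it spans (half-open in y, so shared
    # vertices are counted once)
    rows: dict[int, list[tuple[float, int]]] = {}
    n = len(v)
    for i in range(n):
        x0, y0 = v[i]
        x1, y1 = v[(i + 1) % n]
        if y0 == y1:
            continue
        sign = 1 if y1 > y0 else -1
        ya, yb = (y0, y1) if y1 > y0 else (y1, y0)
        for yc in range(max(int(np.ceil(ya)), y_lo), min(int(np.floor(yb)) + 1, y_hi + 1)):
            if not (ya <= yc < yb):
                continue
            xc = x0 + (yc - y0) * (x1 - x0) / (y1 - y0)
            rows.setdefault(yc, []).append((xc, sign))

    for yc, crossings in rows.items():
        crossings.sort()
        xs = np.array([c[0] for c in crossings])
        signs = np.array([c[1] for c in crossings])
        # winding at a pixel = signed crossings of the rightward ray
        suffix = np.concatenate([np.cumsum(signs[::-1])[::-1], [0]])
        cols = np.arange(w)
        idx = np.searchsorted(xs, cols, side="right")
        mask[yc] = suffix[idx] != 0
    return mask
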