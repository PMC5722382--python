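"""Contour extraction from the composite mask.

Replaces the interactive "magic wand": every connected region of the
composite mask — bright (8-connected) or dark (4-connected) — that does not
touch the image border is traced along its outer boundary with Moore-neighbor
following, yielding an ordered closed ring of boundary-pixel centers per
region.  Regions are then classified as the main blade (largest ring), an
overlapping-lobe outline (interior mostly dark in the source image) or an
enclosed sinus.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import label as cc_label

from .segmentation import BinaryMask

__all__ = [
    "RegionClass",
    "Contour",
    "ContourSet",
    "trace_contours",
    "moore_trace",
    "signed_area",
    "reverse",
    "classify_regions",
]


class RegionClass(enum.Enum):
    BLADE = "blade"
    OL_OUTLINE = "ol_outline"
    SINUS = "sinus"
    OTHER = "other"


@dataclass
class Contour:
    """An ordered closed ring of pixel coordinates.

    ``vertices`` is an (n, 2) float array of (x, y) = (column, row) positions,
    0-based pixel centers with y increasing downward.  The ring is implicitly
    closed (last vertex connects to the first).  After splicing, consecutive
    vertices are no longer guaranteed to be 8-adjacent and the junction
    vertices appear twice.
    """

    vertices: np.ndarray
    label: str = ""
    region_class: RegionClass = RegionClass.OTHER
    region_id: int = 0  # value in the owning ContourSet's label_image

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        self.vertices = v

    @property
    def n(self) -> int:
        return len(self.vertices)


@dataclass
class ContourSet:
    contours: list[Contour] = field(default_factory=list)
    source_shape: tuple[int, int] = (0, 0)
    #: integer raster mapping pixels to Contour.region_id (0 = untraced)
    label_image: np.ndarray | None = None

    def __iter__(self):
        return iter(self.contours)

    def __len__(self) -> int:
        return len(self.contours)

    def get(self, label: str) -> Contour:
        for c in self.contours:
            if c.label == label:
                return c
        raise KeyError(label)


# Moore neighborhood in clockwise screen order (x right, y down).
_NEIGHBORS = np.array(
    [(0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1)]
)


def moore_trace(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of the single region in ``mask``.

    Moore-neighbor tracing with Jacob's stopping criterion: starting from the
    topmost-then-leftmost region pixel (entered from the west), the walk stops
    when the start pixel is re-entered from the same direction.  Returns the
    ordered (x, y) boundary-pixel centers; consecutive entries are 8-adjacent
    and distinct.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty region")
    # row-major scan: first pixel of the top occupied row
    top = ys.min()
    start = (int(xs[ys == top].min()), int(top))

    h, w = mask.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and mask[y, x]

    ring = [start]
    # entered from the west => backtrack neighbor index 6 (-1, 0)
    cur, back = start, 6
    first_state = None
    while True:
        # scan clockwise starting just after the backtrack direction
        for k in range(1, 9):
            d = (back + k) % 8
            nx, ny = cur[0] + int(_NEIGHBORS[d][0]), cur[1] + int(_NEIGHBORS[d][1])
            if fg(nx, ny):
                # backtrack for the next pixel: direction pointing to the
                # previously scanned (background) neighbor, seen from (nx, ny)
                prev_d = (back + k - 1) % 8
                px, py = cur[0] + int(_NEIGHBORS[prev_d][0]), cur[1] + int(_NEIGHBORS[prev_d][1])
                dx, dy = px - nx, py - ny
                back = int(np.nonzero((_NEIGHBORS == (dx, dy)).all(axis=1))[0][0])
                cur = (nx, ny)
                break
        else:  # isolated pixel
            return np.array([start], dtype=np.float64)
        state = (cur, back)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break
        if cur != ring[-1]:
            ring.append(cur)
        if len(ring) > 4 * mask.size:  # safety net; cannot trigger on valid input
            raise RuntimeError("boundary tracing failed to terminate")
    if len(ring) > 1 and ring[-1] == ring[0]:
        ring.pop()
    return np.array(ring, dtype=np.float64)


def trace_contours(composite: BinaryMask | np.ndarray, min_area: int = 16) -> ContourSet:
    """Extract the outer boundary ring of every interior region.

    Bright regions are 8-connected, dark regions 4-connected (preventing
    self-crossing traces at diagonal necks); any region touching the image
    border — the outer background in a composite mask — is excluded, as are
    regions smaller than ``min_area`` pixels (venation specks).
    """
    pixels = composite.pixels if isinstance(composite, BinaryMask) else np.asarray(composite, bool)
    if not pixels.any():
        raise ValueError("empty mask: nothing to trace")

    h, w = pixels.shape
    label_image = np.zeros((h, w), dtype=np.int32)
    regions: list[tuple[int, int, np.ndarray, int]] = []  # (top, left, mask, id)
    next_id = 1
    for polarity, connectivity in ((True, 2), (False, 1)):
        labeled = cc_label(pixels == polarity, connectivity=connectivity, background=-1)
        labeled[pixels != polarity] = 0
        border = set(np.unique(labeled[0])) | set(np.unique(labeled[-1]))
        border |= set(np.unique(labeled[:, 0])) | set(np.unique(labeled[:, -1]))
        for lbl in np.unique(labeled):
            if lbl == 0 or lbl in border:
                continue
            region = labeled == lbl
            if int(region.sum()) < min_area:
                continue
            ys, xs = np.nonzero(region)
            regions.append((int(ys.min()), int(xs[ys == ys.min()].min()), region, next_id))
            label_image[region] = next_id
            next_id += 1

    if not regions:
        raise ValueError("no interior region to trace (only border-touching regions)")

    regions.sort(key=lambda r: (r[0], r[1]))  # deterministic: topmost, then leftmost
    contours = []
    for i, (_, _, region, rid) in enumerate(regions):
        ring = moore_trace(region)
        contours.append(Contour(ring, label=f"C{i}", region_id=rid))
    return ContourSet(contours=contours, source_shape=(h, w), label_image=label_image)


def signed_area(contour: Contour | np.ndarray) -> float:
    """Shoelace signed area in px².

    Positive for counter-clockwise order in mathematical axes, which is
    clockwise on screen where y grows downward.
    """
    v = contour.vertices if isinstance(contour, Contour) else np.asarray(contour, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def reverse(contour: Contour) -> Contour:
    """Reverse traversal order, keeping the same starting vertex."""
    v = contour.vertices
    rev = np.concatenate([v[:1], v[:0:-1]])
    return replace(contour, vertices=rev)


def classify_regions(cset: ContourSet, t1_inverted: BinaryMask) -> ContourSet:
    """Assign BLADE / OL_OUTLINE / SINUS classes to a traced contour set.

    The largest ring (by |signed area|) is the blade.  Any other region whose
    interior is at least 50% dark-class in the source image (background in the
    inverted-T1 mask) is an overlapping-lobe outline; the rest are enclosed
    sinuses.
    """
    if cset.label_image is None:
        raise ValueError("contour set carries no region label image")
    if t1_inverted.shape != cset.label_image.shape:
        raise ValueError("mask shape does not match the contour set's source shape")
    if not cset.contours:
        return cset
    areas = [abs(signed_area(c)) for c in cset.contours]
    blade_idx = int(np.argmax(areas))
    dark = ~t1_inverted.pixels
    out = []
    for i, c in enumerate(cset.contours):
        if i == blade_idx:
            cls = RegionClass.BLADE
        else:
            region = cset.label_image == c.region_id
            frac_dark = float(dark[region].mean()) if region.any() else 0.0
            cls = RegionClass.OL_OUTLINE if frac_dark >= 0.5 else RegionClass.SINUS
        out.append(replace(c, region_class=cls))
    return ContourSet(contours=out, source_shape=cset.source_shape, label_image=cset.label_image)
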