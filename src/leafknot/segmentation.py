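"""Two-level segmentation of transilluminated leaf images.

Under transillumination, optical density encodes tissue thickness: the bright
background, the mid-gray leaf blade and the darker double-thickness regions
where one lobe overlaps another form three well separated intensity classes.
Two thresholds pull these apart:

* ``T1`` — a maximum-entropy (Kapur) threshold that isolates the dark
  overlap regions; the mask is used *inverted*, so the overlaps are the only
  background pixels.
* ``T2`` — a conventional bimodal ("default") iterative-intermeans threshold
  that separates the whole leaf from the bright background.

The pixelwise XOR of the inverted-T1 and T2 masks is the *composite* mask in
which the blade appears as one dark region while overlap outlines, enclosed
sinuses and the outer background appear as separate bright regions — the
input of the contour-tracing stage.

Because automatic thresholds are sensitive to image composition, a 3x3 panel
of composites built from T1 and T2 perturbed by ±5% is provided so a user can
pick the cleanest combination.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import closing as _closing, opening as _opening, disk

logger = logging.getLogger(__name__)

__all__ = [
    "MaskRole",
    "BinaryMask",
    "ThresholdPanel",
    "as_gray_image",
    "max_entropy_threshold",
    "default_threshold",
    "auto_thresholds",
    "make_masks",
    "binary_close",
    "despeckle",
    "build_composite",
    "xor_compose",
    "threshold_panel",
    "load_image",
]

#: factors applied to the base thresholds when building the exploration panel
PANEL_FACTORS = (0.95, 1.00, 1.05)


class MaskRole(enum.Enum):
    """Provenance tag of a binary mask within the two-level scheme."""

    T1_INVERTED = "t1_inverted"
    T2 = "t2"
    COMPOSITE = "composite"


@dataclass
class BinaryMask:
    """A 2-D boolean raster; ``True`` marks foreground."""

    pixels: np.ndarray
    role: MaskRole

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ThresholdPanel:
    """The nine XOR composites built from ±5% perturbed base thresholds.

    ``entries`` is row-major in (f1, f2) over ``PANEL_FACTORS``; each entry is
    ``(f1, f2, composite_mask)``.
    """

    t1_value: int
    t2_value: int
    entries: list[tuple[float, float, BinaryMask]] = field(default_factory=list)


def as_gray_image(image: np.ndarray) -> np.ndarray:
    """Validate and return an 8-bit grayscale image as a uint8 array.

    Accepts uint8 input or any 2-D numeric array with values in [0, 255].
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):  # luminance conversion
        rgb = arr[..., :3].astype(np.float64)
        arr = rgb @ np.array([0.2126, 0.7152, 0.0722])
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"image too small: {arr.shape} (need at least 8x8)")
    if arr.dtype != np.uint8:
        a = arr.astype(np.float64)
        if a.min() < 0 or a.max() > 255:
            # linear rescale (e.g. 16-bit scanner output)
            lo, hi = a.min(), a.max()
            if hi == lo:
                a = np.zeros_like(a)
            else:
                a = (a - lo) * (255.0 / (hi - lo))
        arr = np.round(a).astype(np.uint8)
    return arr


def _histogram(image: np.ndarray) -> np.ndarray:
    return np.bincount(image.ravel(), minlength=256).astype(np.float64)


def max_entropy_threshold(image: np.ndarray) -> int:
    """Kapur–Sahoo–Wong maximum-entropy threshold on the 256-bin histogram.

    Returns the integer ``t`` in [0, 254] maximizing the sum of the Shannon
    entropies of the dark class (intensities <= t) and the bright class
    (intensities > t).  Ties are broken toward the smallest ``t``.

    Raises
    ------
    ValueError
        If the image is constant (degenerate single-bin histogram).
    """
    image = as_gray_image(image)
    hist = _histogram(image)
    p = hist / hist.sum()
    occupied = np.flatnonzero(p)
    if occupied.size < 2:
        raise ValueError("constant image: maximum-entropy threshold undefined")

    plogp = np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
    P = np.cumsum(p)           # P[t] = mass of dark class for threshold t
    S = np.cumsum(plogp)       # S[t] = sum p log p over dark class
    total_S = S[-1]

    best_t, best_h = None, -np.inf
    for t in range(0, 255):
        pb = P[t]
        pf = 1.0 - pb
        if pb <= 0.0 or pf <= 0.0:
            continue
        hb = np.log(pb) - S[t] / pb
        hf = np.log(pf) - (total_S - S[t]) / pf
        h = hb + hf
        if h > best_h + 1e-12:
            best_h, best_t = h, t
    assert best_t is not None
    return int(best_t)


def default_threshold(image: np.ndarray) -> int:
    """Iterative intermeans ("default" bimodal / isodata-style) threshold.

    Starting from the midpoint of the occupied intensity range, iterate
    ``t <- floor((mean(<=t) + mean(>t)) / 2)`` on the 256-bin histogram until
    a fixed point is reached.  Pixels with intensity <= t form the dark class.

    Starting at the occupied-range midpoint (rather than bin 127) matters on
    trimodal leaf histograms: it lands the threshold in the blade/background
    gap, i.e. the whole-leaf segmentation the T2 mask needs.
    """
    image = as_gray_image(image)
    hist = _histogram(image)
    occupied = np.flatnonzero(hist)
    if occupied.size < 2:
        raise ValueError("constant image: bimodal threshold undefined")
    lo, hi = int(occupied[0]), int(occupied[-1])

    levels = np.arange(256, dtype=np.float64)
    w = hist
    t = (lo + hi) // 2
    seen: set[int] = set()
    while t not in seen:
        seen.add(t)
        m_low = (w[: t + 1] @ levels[: t + 1]) / max(w[: t + 1].sum(), 1e-300)
        m_high = (w[t + 1 :] @ levels[t + 1 :]) / max(w[t + 1 :].sum(), 1e-300)
        t = int((m_low + m_high) // 2)
        t = min(max(t, lo), hi - 1)
    return int(t)


def _snap_to_gap(hist: np.ndarray, t: int, max_jump: int = 32, min_gap: int = 4) -> int:
    """Re-center a threshold into the nearest empty histogram gap.

    With well-separated intensity classes every threshold inside a
    zero-density gap yields the same classification, but one in the middle of
    the gap is maximally robust to noise; automatic criteria often land in a
    class tail instead.  When a run of >= ``min_gap`` empty bins lies within
    ``max_jump`` levels of ``t``, ``t`` is moved to that run's midpoint;
    histograms without such gaps (genuinely merged classes) are untouched.
    """
    empty = hist == 0
    runs = []
    i = 0
    while i < 256:
        if empty[i]:
            j = i
            while j + 1 < 256 and empty[j + 1]:
                j += 1
            if j - i + 1 >= min_gap:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    best = None
    for a, b in runs:
        d = 0 if a <= t <= b else min(abs(t - a), abs(t - b))
        if d <= max_jump and (best is None or d < best[0]):
            best = (d, (a + b) // 2)
    return best[1] if best else t


def auto_thresholds(image: np.ndarray) -> tuple[int, int]:
    """Choose both thresholds, detecting images without an overlap class.

    Leaves whose lobes only touch (or do not meet at all) have a bimodal
    histogram: the maximum-entropy threshold then lands in the same
    leaf/background gap as the default threshold and the XOR composite would
    collapse.  Such images need only the single default threshold, so when
    the dark class of the max-entropy split covers most (> 50%) of the leaf
    selected by T2, T1 is set to 0 — the inverted-T1 mask becomes
    all-foreground and the composite reduces to the inverted T2 mask.
    """
    image = as_gray_image(image)
    hist = _histogram(image)
    t2 = _snap_to_gap(hist, default_threshold(image))
    t1 = _snap_to_gap(hist, max_entropy_threshold(image))
    leaf = int(np.count_nonzero(image <= t2))
    dark = int(np.count_nonzero(image <= t1))
    if leaf == 0 or dark / leaf > 0.5:
        logger.info("no distinct overlap class (T1 splits leaf/background); using T1 = 0")
        t1 = 0
    return t1, t2


def make_masks(image: np.ndarray, t1: int, t2: int) -> tuple[BinaryMask, BinaryMask]:
    """Build the inverted-T1 and T2 masks from the two thresholds.

    ``T1_INVERTED`` foreground is ``intensity > t1`` (the dark overlap class,
    selected by the max-entropy threshold, ends up as background after the
    inversion).  ``T2`` foreground is ``intensity <= t2`` (the leaf, darker
    than the bright background).
    """
    image = as_gray_image(image)
    for name, t in (("t1", t1), ("t2", t2)):
        if not (0 <= int(t) <= 254):
            raise ValueError(f"{name} must be in [0, 254], got {t}")
    t1_inv = BinaryMask(image > t1, MaskRole.T1_INVERTED)
    t2_mask = BinaryMask(image <= t2, MaskRole.T2)
    return t1_inv, t2_mask


def binary_close(mask: BinaryMask, radius: int) -> BinaryMask:
    """Morphological closing with a disk element of the given pixel radius.

    Closing (dilation then erosion) of the mask foreground removes thin
    background features — the traces left by thick venation in the inverted
    maximum-entropy mask — narrower than about ``2 * radius``.  ``radius = 0``
    is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return BinaryMask(mask.pixels.copy(), mask.role)
    closed = _closing(mask.pixels, disk(int(radius)))
    return BinaryMask(closed, mask.role)


def xor_compose(t1_mask: BinaryMask, t2_mask: BinaryMask) -> BinaryMask:
    """Pixelwise XOR of the inverted-T1 and T2 masks (the composite mask)."""
    if t1_mask.shape != t2_mask.shape:
        raise ValueError(f"shape mismatch: {t1_mask.shape} vs {t2_mask.shape}")
    return BinaryMask(np.logical_xor(t1_mask.pixels, t2_mask.pixels), MaskRole.COMPOSITE)


def despeckle(mask: BinaryMask, radius: int = 1) -> BinaryMask:
    """Morphological opening of the mask foreground (noise cleanup).

    Removes single-pixel specks and 1-px bridges that intensity noise can
    punch through the thin blade strips separating bright composite regions,
    while restoring the wide regions themselves; ``radius = 0`` is the
    identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return BinaryMask(mask.pixels.copy(), mask.role)
    return BinaryMask(_opening(mask.pixels, disk(int(radius))), mask.role)


def build_composite(
    image: np.ndarray,
    t1: int,
    t2: int,
    close_radius: int = 2,
    despeckle_radius: int = 1,
) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Masks plus cleaned XOR composite in one step.

    Closing is applied to the inverted-T1 mask (where venation traces
    arise), despeckling to the composite.  Returns
    ``(t1_inverted, t2_mask, composite)``.
    """
    t1_inv, t2_mask = make_masks(image, t1, t2)
    t1_inv = binary_close(t1_inv, close_radius)
    composite = despeckle(xor_compose(t1_inv, t2_mask), despeckle_radius)
    return t1_inv, t2_mask, composite


def _clamp_threshold(value: float) -> int:
    return int(min(max(int(np.floor(value + 0.5)), 0), 254))


def threshold_panel(
    image: np.ndarray, t1: int, t2: int, close_radius: int = 0
) -> ThresholdPanel:
    """Build the 3x3 exploration panel of XOR composites.

    For every ``(f1, f2)`` in ``PANEL_FACTORS²`` (row-major), the thresholds
    ``round(f1*t1)`` and ``round(f2*t2)`` are clamped to [0, 254], the masks
    rebuilt (optionally closing the inverted-T1 mask) and XOR-composed.
    """
    image = as_gray_image(image)
    panel = ThresholdPanel(t1_value=int(t1), t2_value=int(t2))
    for f1 in PANEL_FACTORS:
        for f2 in PANEL_FACTORS:
            t1f = _clamp_threshold(f1 * t1)
            t2f = _clamp_threshold(f2 * t2)
            m1, m2 = make_masks(image, t1f, t2f)
            if close_radius:
                m1 = binary_close(m1, close_radius)
            panel.entries.append((f1, f2, xor_compose(m1, m2)))
    return panel


def load_image(path) -> np.ndarray:
    """Read a raster image file and return it as an 8-bit gray array.

    Lossless formats (TIFF/PNG/BMP) are expected; JPEG input is accepted but
    logged as a warning since compression artifacts blur the intensity classes
    the two thresholds rely on.
    """
    import imageio.v3 as iio

    path = str(path)
    if path.lower().endswith((".jpg", ".jpeg")):
        logger.warning("JPEG input %s: lossy compression degrades segmentation", path)
    return as_gray_image(iio.imread(path))
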