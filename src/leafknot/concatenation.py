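"""Concatenation of traced contours into one self-intersecting leaf contour.

Two adjacent contours A and B are joined at a junction by opening both rings
at their junction-nearest vertices (``a_c``, ``b_c``) and splicing B's full
tour into A's.  Whether the splice weaves correctly depends on the relative
traversal direction of the two rings near the junction, which is tested on
the two diagonal chords

* ``p`` from ``a1`` (predecessor of ``a_c``) to ``b2`` (successor of ``b_c``)
* ``q`` from ``a2`` (successor of ``a_c``) to ``b1`` (predecessor of ``b_c``)

via their slopes, intercepts and the intersection point Z of their carrier
lines: the segments intersect iff Z falls within the common range of the two
segments' coordinates.  At a cross point (overlapping lobes) the contours can
be concatenated only if p and q intersect; at a touch point (touching lobes)
only if they do not.  When the condition fails, contour B is reversed.  Each
splice reduces the live contour count by one; iterating over all junctions
leaves a single closed contour that self-intersects at cross points and
self-contacts at touch points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import Junction, JunctionKind, closest_vertices
from .tracing import Contour, ContourSet, reverse, signed_area

__all__ = [
    "SegmentPair",
    "MergeRecord",
    "neighbor_points",
    "build_segment_pair",
    "segments_cross",
    "orient_for_junction",
    "splice",
    "concatenate_all",
    "local_crossing_number",
    "JunctionGeometryError",
]

#: below this |dx| a chord is treated as vertical and the slope/intercept
#: algebra is replaced by the exact orientation-predicate test
VERTICAL_EPS = 1e-9
#: slope difference below which the chords are treated as parallel
PARALLEL_EPS = 1e-9


class JunctionGeometryError(ValueError):
    """A junction whose orientation condition cannot be satisfied."""


def neighbor_points(c: Contour, i: int) -> tuple[int, int]:
    """Predecessor and successor indices of vertex ``i`` (modular)."""
    n = c.n
    if n < 3:
        raise ValueError("contour must have at least 3 vertices")
    return ((i - 1) % n, (i + 1) % n)


def _ccw(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def segments_cross(p1, p2, q1, q2) -> bool:
    """Exact orientation-predicate segment intersection (closed segments).

    Proper crossings and endpoint contacts count as intersections; collinear
    overlaps do not (they fall under the parallelism exception).
    """
    d1 = _ccw(q1, q2, p1)
    d2 = _ccw(q1, q2, p2)
    d3 = _ccw(p1, p2, q1)
    d4 = _ccw(p1, p2, q2)
    if d1 == d2 == d3 == d4 == 0.0:
        return False  # collinear: parallel carrier lines
    if ((d1 > 0) != (d2 > 0) or d1 == 0 or d2 == 0) and (
        (d3 > 0) != (d4 > 0) or d3 == 0 or d4 == 0
    ):
        # sign change (or contact) on both sides; exclude far-collinear touches
        def on_segment(a, b, c):
            return (
                min(a[0], b[0]) <= c[0] <= max(a[0], b[0])
                and min(a[1], b[1]) <= c[1] <= max(a[1], b[1])
            )

        if d1 == 0 and not on_segment(q1, q2, p1):
            return False
        if d2 == 0 and not on_segment(q1, q2, p2):
            return False
        if d3 == 0 and not on_segment(p1, p2, q1):
            return False
        if d4 == 0 and not on_segment(p1, p2, q2):
            return False
        return True
    return False


@dataclass
class SegmentPair:
    """The diagonal chords p and q at a junction, and their intersection test.

    ``R`` is the common range of the p and q coordinates — the overlap of the
    two segments' x- and y-ranges — as (Rxmin, Rxmax, Rymin, Rymax).  ``Z``
    is the carrier-line intersection when the slopes differ.  For vertical
    chords the slope/intercept algebra is undefined and ``intersects`` comes
    from the exact predicate instead (``used_fallback``).
    """

    a1: tuple[float, float]
    a2: tuple[float, float]
    b1: tuple[float, float]
    b2: tuple[float, float]
    p_slope: float = np.nan
    p_intercept: float = np.nan
    q_slope: float = np.nan
    q_intercept: float = np.nan
    R: tuple[float, float, float, float] = (np.nan,) * 4
    Z: tuple[float, float] | None = None
    intersects: bool = False
    used_fallback: bool = False


def build_segment_pair(a: Contour, b: Contour, a_c: int, b_c: int) -> SegmentPair:
    """Build the p/q chord pair for a junction and test their intersection."""
    ia1, ia2 = neighbor_points(a, a_c)
    ib1, ib2 = neighbor_points(b, b_c)
    a1 = tuple(a.vertices[ia1])
    a2 = tuple(a.vertices[ia2])
    b1 = tuple(b.vertices[ib1])
    b2 = tuple(b.vertices[ib2])
    sp = SegmentPair(a1=a1, a2=a2, b1=b1, b2=b2)

    # common range: overlap of the two segments' coordinate ranges
    rxmin = max(min(a1[0], b2[0]), min(a2[0], b1[0]))
    rxmax = min(max(a1[0], b2[0]), max(a2[0], b1[0]))
    rymin = max(min(a1[1], b2[1]), min(a2[1], b1[1]))
    rymax = min(max(a1[1], b2[1]), max(a2[1], b1[1]))
    sp.R = (rxmin, rxmax, rymin, rymax)

    if abs(a1[0] - b2[0]) < VERTICAL_EPS or abs(a2[0] - b1[0]) < VERTICAL_EPS:
        sp.used_fallback = True
        sp.intersects = segments_cross(a1, b2, a2, b1)
        return sp

    sp.p_slope = (a1[1] - b2[1]) / (a1[0] - b2[0])
    sp.p_intercept = (a1[1] + b2[1]) / 2.0 - sp.p_slope * (a1[0] + b2[0]) / 2.0
    sp.q_slope = (a2[1] - b1[1]) / (a2[0] - b1[0])
    sp.q_intercept = (a2[1] + b1[1]) / 2.0 - sp.q_slope * (a2[0] + b1[0]) / 2.0

    if abs(sp.p_slope - sp.q_slope) < PARALLEL_EPS:
        sp.intersects = False  # parallelism exception
        return sp

    zx = (sp.p_intercept - sp.q_intercept) / (sp.q_slope - sp.p_slope)
    zy = sp.p_intercept + sp.p_slope * zx
    sp.Z = (zx, zy)
    sp.intersects = rxmin <= zx <= rxmax and rymin <= zy <= rymax
    return sp


def _condition_met(sp: SegmentPair, kind: JunctionKind) -> bool:
    return sp.intersects if kind is JunctionKind.CROSS else not sp.intersects


def orient_for_junction(
    a: Contour, b: Contour, junction: Junction, a_c: int | None = None, b_c: int | None = None
) -> tuple[Contour, Contour, int, int, SegmentPair]:
    """Repair contour orientations so the junction's condition holds.

    Cross junctions require p and q to intersect, touch junctions require
    them not to.  When the initial configuration fails, contour B (the
    absorbed one) is reversed and the test repeated; a junction that fails
    both ways has degenerate geometry and raises
    :class:`JunctionGeometryError`.
    """
    if a_c is None:
        a_c = junction.a_c
    if b_c is None:
        b_c = junction.b_c
    sp = build_segment_pair(a, b, a_c, b_c)
    if _condition_met(sp, junction.kind):
        return a, b, a_c, b_c, sp
    b_rev = reverse(b)
    b_c_rev = 0 if b_c == 0 else b.n - b_c
    sp = build_segment_pair(a, b_rev, a_c, b_c_rev)
    if _condition_met(sp, junction.kind):
        return a, b_rev, a_c, b_c_rev, sp
    raise JunctionGeometryError(
        f"junction {junction.contour_a}/{junction.contour_b} at {junction.point}: "
        f"{junction.kind.value} condition unsatisfied in both orientations"
    )


def splice(a: Contour, b: Contour, a_c: int, b_c: int) -> Contour:
    """Join two rings at their junction vertices.

    The merged ring is ``[a_c, b_c, b_{c+1}, ..., b_{c-1}, b_c, a_c,
    a_{c+1}, ..., a_{c-1}]``: A opens at ``a_c``, links to ``b_c``, makes a
    complete tour of B back to ``b_c``, links back to ``a_c`` and completes
    the tour of A.  The merged ring has ``n_A + n_B + 2`` vertices with both
    junction vertices duplicated, and replaces A and B.
    """
    va, vb = a.vertices, b.vertices
    tour_b = np.roll(vb, -b_c, axis=0)            # b_c .. b_{c-1}
    tour_a_rest = np.roll(va, -a_c, axis=0)[1:]   # a_{c+1} .. a_{c-1}
    merged = np.concatenate(
        [va[a_c : a_c + 1], tour_b, vb[b_c : b_c + 1], va[a_c : a_c + 1], tour_a_rest]
    )
    return Contour(
        merged,
        label=f"{a.label}+{b.label}",
        region_class=a.region_class,
        region_id=a.region_id,
    )


@dataclass
class MergeRecord:
    """One line of the per-merge ledger kept during concatenation."""

    junction: Junction
    absorbed: str
    into: str
    b_reversed: bool
    contours_before: int
    contours_after: int
    skipped: bool = False


def concatenate_all(
    cset: ContourSet,
    junctions: list[Junction],
    log: list[MergeRecord] | None = None,
) -> Contour:
    """Iteratively splice all contours into a single closed leaf contour.

    Junctions are processed in ascending (x, y) order of their location; a
    junction whose two contours already belong to the same merged ring is
    skipped.  At each effective merge the larger-|area| ring absorbs the
    smaller (the blade absorbs its satellites), junction vertices are
    re-located on the current rings with :func:`closest_vertices`, the
    orientation is repaired, and the rings are spliced — reducing the live
    contour count by exactly one.  Terminates with a single ring.
    """
    live: dict[str, Contour] = {c.label: c for c in cset.contours}
    if not live:
        raise ValueError("empty contour set")
    root: dict[str, str] = {lbl: lbl for lbl in live}

    def find(x: str) -> str:
        while root[x] != x:
            root[x] = root[root[x]]
            x = root[x]
        return x

    for j in sorted(junctions, key=lambda j: (j.point[0], j.point[1])):
        ra, rb = find(j.contour_a), find(j.contour_b)
        if ra == rb:
            if log is not None:
                log.append(
                    MergeRecord(j, "", ra, False, len(live), len(live), skipped=True)
                )
            continue
        A, B = live[ra], live[rb]
        if abs(signed_area(B)) > abs(signed_area(A)):
            A, B, ra, rb = B, A, rb, ra
        a_c, b_c = closest_vertices(A, B, j.point)
        B_orig = B
        A, B, a_c, b_c, _ = orient_for_junction(A, B, j, a_c, b_c)
        was_reversed = B is not B_orig
        merged = splice(A, B, a_c, b_c)
        merged.label = ra  # keep the absorbing root label for bookkeeping
        before = len(live)
        del live[rb]
        live[ra] = merged
        root[rb] = ra
        if log is not None:
            log.append(MergeRecord(j, rb, ra, was_reversed, before, len(live)))

    if len(live) != 1:
        raise ValueError(
            f"{len(live)} contours remain after processing all junctions; "
            "junction graph was not connected"
        )
    (final,) = live.values()
    return final


def _circle_hit(p0: np.ndarray, p1: np.ndarray, center: np.ndarray, r: float, inward: bool) -> float:
    """Angle (on the window circle) where segment p0->p1 crosses the circle."""
    d = p1 - p0
    f = p0 - center
    a = float(d @ d)
    b = 2.0 * float(f @ d)
    c = float(f @ f) - r * r
    disc = max(b * b - 4 * a * c, 0.0)
    sq = np.sqrt(disc)
    ts = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
    # entering: take the crossing going inside; exiting: going outside
    t = ts[0] if inward else ts[1]
    t = min(max(t, 0.0), 1.0)
    hit = p0 + t * d
    return float(np.arctan2(hit[1] - center[1], hit[0] - center[0]))


def _chord_hits(
    p0: np.ndarray, p1: np.ndarray, center: np.ndarray, r: float
) -> tuple[float, float] | None:
    """Entry/exit angles of an edge crossing the circle with both ends outside."""
    d = p1 - p0
    f = p0 - center
    a = float(d @ d)
    if a == 0.0:
        return None
    b = 2.0 * float(f @ d)
    c = float(f @ f) - r * r
    disc = b * b - 4 * a * c
    if disc <= 0.0:
        return None
    sq = np.sqrt(disc)
    t0, t1 = (-b - sq) / (2 * a), (-b + sq) / (2 * a)
    if not (0.0 < t0 < 1.0 and 0.0 < t1 < 1.0):
        return None
    h0, h1 = p0 + t0 * d, p0 + t1 * d
    return (
        float(np.arctan2(h0[1] - center[1], h0[0] - center[0])),
        float(np.arctan2(h1[1] - center[1], h1[0] - center[0])),
    )


def local_crossing_number(
    ring: Contour | np.ndarray, center: tuple[float, float], radius: float = 5.0
) -> int:
    """Topological self-crossing count of a closed ring inside a disc window.

    The ring is clipped to the disc; each maximal arc through the window is
    reduced to its entry/exit angles on the window circle, and two arcs cross
    (an odd number of times) iff their endpoints interleave around the
    circle.  This resolves the degenerate doubled splice chords without
    perturbation: a correctly spliced cross point scores 1, a touch point 0.
    """
    v = ring.vertices if isinstance(ring, Contour) else np.asarray(ring, float)
    c = np.asarray(center, float)
    inside = np.linalg.norm(v - c, axis=1) <= radius
    if inside.all():
        return 0
    n = len(v)
    # walk the ring starting from an outside vertex, building the maximal
    # arcs that pass through the window (including edges that cross it
    # without carrying a vertex inside)
    start = int(np.flatnonzero(~inside)[0])
    arcs: list[tuple[float, float]] = []
    entry: float | None = None
    for k in range(n):
        i = (start + k) % n
        j = (start + k + 1) % n
        p0, p1 = v[i], v[j]
        in0, in1 = bool(inside[i]), bool(inside[j])
        if in0 and in1:
            continue
        if not in0 and in1:
            entry = _circle_hit(p0, p1, c, radius, inward=True)
        elif in0 and not in1:
            assert entry is not None
            arcs.append((entry, _circle_hit(p0, p1, c, radius, inward=False)))
            entry = None
        else:
            hits = _chord_hits(p0, p1, c, radius)
            if hits is not None:
                arcs.append(hits)

    def between(x: float, lo: float, hi: float) -> bool:
        # is angle x strictly inside the ccw interval (lo, hi)?
        span = (hi - lo) % (2 * np.pi)
        pos = (x - lo) % (2 * np.pi)
        return 0.0 < pos < span

    crossings = 0
    for i in range(len(arcs)):
        for jj in range(i + 1, len(arcs)):
            inside_count = int(between(arcs[jj][0], *arcs[i])) + int(
                between(arcs[jj][1], *arcs[i])
            )
            if inside_count == 1:
                crossings += 1
    return crossings
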