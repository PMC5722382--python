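"""Cross- and touch-point localization between traced contours.

Where two lobes overlap, the outline of the overlap region approaches the
outer leaf contour (and the contour of the sinus it closes) at *cross
points*; where two lobes merely touch, the enclosed sinus contour approaches
the blade contour at a single *touch point*.  These junctions are found as
locally minimal vertex-pair distances between contour pairs and drive the
concatenation stage.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .tracing import Contour, ContourSet, RegionClass

__all__ = [
    "JunctionKind",
    "Junction",
    "find_junctions",
    "closest_vertices",
    "save_junctions",
    "load_junctions",
    "DisconnectedContoursError",
]


class JunctionKind(enum.Enum):
    CROSS = "cross"
    TOUCH = "touch"


class DisconnectedContoursError(ValueError):
    """The junction graph does not connect all contours."""

    def __init__(self, unreachable: list[str]):
        self.unreachable = unreachable
        super().__init__(
            "junction graph is disconnected; unreachable contours: "
            + ", ".join(unreachable)
        )


@dataclass
class Junction:
    kind: JunctionKind
    point: tuple[float, float]
    contour_a: str
    contour_b: str
    a_c: int
    b_c: int
    distance: float

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "x": self.point[0],
            "y": self.point[1],
            "a": self.contour_a,
            "b": self.contour_b,
            "a_c": self.a_c,
            "b_c": self.b_c,
        }


def closest_vertices(a: Contour, b: Contour, near: tuple[float, float]) -> tuple[int, int]:
    """Indices of the vertex of each contour nearest to ``near``.

    Ties are broken toward the lowest index (argmin semantics).
    """
    p = np.asarray(near, dtype=float)
    da = np.linalg.norm(a.vertices - p, axis=1)
    db = np.linalg.norm(b.vertices - p, axis=1)
    return int(np.argmin(da)), int(np.argmin(db))


def _circular_gap(i: int, j: int, n: int) -> int:
    d = abs(i - j)
    return min(d, n - d)


def _pair_junctions(
    a: Contour, b: Contour, d_adj: float, min_separation: int
) -> list[Junction]:
    """All locally minimal close approaches between two contours.

    Candidate vertex pairs with distance <= d_adj are selected greedily by
    ascending distance; a selected pair suppresses candidates within
    ``min_separation`` vertices along either contour, so a short stretch of
    near contact yields exactly one junction.
    """
    tree = cKDTree(b.vertices)
    dist, idx_b = tree.query(a.vertices)
    cand = np.flatnonzero(dist <= d_adj)
    if cand.size == 0:
        return []
    order = cand[np.lexsort((cand, dist[cand]))]
    chosen: list[tuple[int, int, float]] = []
    for i in order:
        j = int(idx_b[i])
        if any(
            _circular_gap(i, ci, a.n) < min_separation
            or _circular_gap(j, cj, b.n) < min_separation
            for ci, cj, _ in chosen
        ):
            continue
        chosen.append((int(i), j, float(dist[i])))

    kind = (
        JunctionKind.CROSS
        if RegionClass.OL_OUTLINE in (a.region_class, b.region_class)
        else JunctionKind.TOUCH
    )
    out = []
    for i, j, d in chosen:
        mid = (a.vertices[i] + b.vertices[j]) / 2.0
        out.append(
            Junction(
                kind=kind,
                point=(float(mid[0]), float(mid[1])),
                contour_a=a.label,
                contour_b=b.label,
                a_c=i,
                b_c=j,
                distance=d,
            )
        )
    return out


def find_junctions(
    cset: ContourSet, d_adj: float = 2.0, min_separation: int = 10
) -> list[Junction]:
    """Locate all cross and touch points of a classified contour set.

    One junction per locally minimal vertex-pair distance <= ``d_adj``
    between each unordered contour pair; a junction is a cross point when
    either contour is an overlapping-lobe outline, a touch point otherwise.
    The resulting list, sorted by (x, y), must connect all contours into a
    single component, otherwise :class:`DisconnectedContoursError` is raised.
    """
    contours = sorted(cset.contours, key=lambda c: c.label)
    junctions: list[Junction] = []
    for ia in range(len(contours)):
        for ib in range(ia + 1, len(contours)):
            junctions.extend(
                _pair_junctions(contours[ia], contours[ib], d_adj, min_separation)
            )
    junctions.sort(key=lambda j: (j.point[0], j.point[1]))

    if len(contours) > 1:
        parent = {c.label: c.label for c in contours}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for j in junctions:
            parent[find(j.contour_a)] = find(j.contour_b)
        roots = {find(c.label) for c in contours}
        if len(roots) > 1:
            main = find(max(contours, key=lambda c: c.n).label)
            unreachable = sorted(c.label for c in contours if find(c.label) != main)
            raise DisconnectedContoursError(unreachable)
    return junctions


def save_junctions(junctions: list[Junction], path) -> None:
    with open(path, "w") as fh:
        json.dump([j.to_dict() for j in junctions], fh, indent=2)


def load_junctions(path) -> list[Junction]:
    """Read a junction list (e.g. a user-supplied manual override) from JSON."""
    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for d in raw:
        out.append(
            Junction(
                kind=JunctionKind(d["kind"]),
                point=(float(d["x"]), float(d["y"])),
                contour_a=d["a"],
                contour_b=d["b"],
                a_c=int(d.get("a_c", 0)),
                b_c=int(d.get("b_c", 0)),
                distance=float(d.get("distance", 0.0)),
            )
        )
    return out
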