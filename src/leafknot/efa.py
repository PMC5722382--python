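"""Elliptic Fourier analysis of closed contours.

Kuhl–Giardina elliptic Fourier descriptors under cumulative chord-length
parameterization.  The contour (x(t), y(t)) is expanded as

    x(t) = A0 + sum_n a_n cos(2*pi*n*t/T) + b_n sin(2*pi*n*t/T)
    y(t) = C0 + sum_n c_n cos(2*pi*n*t/T) + d_n sin(2*pi*n*t/T)

with T the total chord length.  The parameterization simply follows the
vertex chain, so self-intersecting rings — the concatenated contours of
leaves with overlapping lobes — are processed exactly like simple ones,
which is the point of feeding the spliced leaf contour to EFA.  Truncated
inverse synthesis reconstructs progressively detailed shapes and shows which
harmonics carry the lobe overlaps.

No size/rotation/phase normalization is applied by default; the standard
Kuhl–Giardina normalization is available explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .tracing import Contour

__all__ = [
    "EFACoefficients",
    "efa_forward",
    "efa_evaluate",
    "efa_inverse",
    "stepwise_reconstruction",
    "harmonic_energy",
    "normalize_coefficients",
    "save_coefficients",
    "load_coefficients",
]


@dataclass
class EFACoefficients:
    """Per-harmonic quadruples (a_n, b_n, c_n, d_n) plus offsets A0, C0."""

    harmonics: np.ndarray  # (N, 4)
    A0: float
    C0: float
    perimeter: float
    normalized: bool = False

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)


def _chain(vertices: np.ndarray) -> np.ndarray:
    """Closed vertex chain with consecutive duplicates collapsed.

    Zero-length chords are undefined under chord-length parameterization;
    splicing duplicates junction vertices, so they are dropped here.
    """
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("vertices must be an (n, 2) array")
    keep = np.any(v != np.roll(v, 1, axis=0), axis=1)
    v = v[keep]
    if len(v) < 3:
        raise ValueError("contour degenerate: fewer than 3 distinct vertices")
    return v


def efa_forward(contour: Contour | np.ndarray, n_harmonics: int = 20) -> EFACoefficients:
    """Compute the first ``n_harmonics`` elliptic Fourier harmonics."""
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    v = _chain(contour.vertices if isinstance(contour, Contour) else contour)
    d = np.diff(np.vstack([v, v[:1]]), axis=0)  # chord vectors
    dt = np.hypot(d[:, 0], d[:, 1])
    if not np.all(dt > 0):
        raise ValueError("zero-length chord in contour")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = (2.0 * np.pi / T) * t  # (K+1,)

    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (N, K)
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    coef = T / (2.0 * (n * np.pi) ** 2)
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = (coef * (dx_dt * cos_d)).sum(axis=1)
    b = (coef * (dx_dt * sin_d)).sum(axis=1)
    c = (coef * (dy_dt * cos_d)).sum(axis=1)
    dd = (coef * (dy_dt * sin_d)).sum(axis=1)

    # offsets: mean of the piecewise-linear x(t), y(t) over one period
    xi = np.concatenate([[0.0], np.cumsum(d[:-1, 0])]) - dx_dt * t[:-1]
    A0 = v[0, 0] + (1.0 / T) * np.sum(
        (d[:, 0] / (2.0 * dt)) * np.diff(t**2) + xi * dt
    )
    delta = np.concatenate([[0.0], np.cumsum(d[:-1, 1])]) - dy_dt * t[:-1]
    C0 = v[0, 1] + (1.0 / T) * np.sum(
        (d[:, 1] / (2.0 * dt)) * np.diff(t**2) + delta * dt
    )

    return EFACoefficients(
        harmonics=np.column_stack([a, b, c, dd]),
        A0=float(A0),
        C0=float(C0),
        perimeter=float(T),
    )


def efa_evaluate(
    coeffs: EFACoefficients, t_values: np.ndarray, use_n: int | None = None
) -> np.ndarray:
    """Evaluate the truncated series at arbitrary parameter values."""
    N = coeffs.n_harmonics
    if use_n is None:
        use_n = N
    if not (1 <= use_n <= N):
        raise ValueError(f"use_n must be in [1, {N}], got {use_n}")
    t = np.asarray(t_values, dtype=np.float64)
    n = np.arange(1, use_n + 1)[:, None]
    ang = 2.0 * np.pi * n * t[None, :] / coeffs.perimeter
    h = coeffs.harmonics[:use_n]
    x = coeffs.A0 + h[:, 0] @ np.cos(ang) + h[:, 1] @ np.sin(ang)
    y = coeffs.C0 + h[:, 2] @ np.cos(ang) + h[:, 3] @ np.sin(ang)
    return np.column_stack([x, y])


def efa_inverse(coeffs: EFACoefficients, use_n: int | None = None, n_points: int = 512) -> Contour:
    """Re-synthesize a contour from the first ``use_n`` harmonics."""
    t = np.linspace(0.0, coeffs.perimeter, n_points, endpoint=False)
    pts = efa_evaluate(coeffs, t, use_n)
    return Contour(pts, label=f"efa{use_n if use_n else coeffs.n_harmonics}")


def stepwise_reconstruction(
    coeffs: EFACoefficients, steps: list[int], n_points: int = 512
) -> list[Contour]:
    """One truncated reconstruction per harmonic count in ``steps``.

    Used for panels showing how detail (and lobe overlaps) accumulates with
    harmonic order, e.g. steps 1..15 by 1 then 60..270 by 30.
    """
    if any(s2 <= s1 for s1, s2 in zip(steps, steps[1:])):
        raise ValueError("steps must be strictly ascending")
    return [efa_inverse(coeffs, s, n_points) for s in steps]


def harmonic_energy(coeffs: EFACoefficients) -> np.ndarray:
    """Per-harmonic energy a² + b² + c² + d²."""
    return np.sum(coeffs.harmonics**2, axis=1)


def normalize_coefficients(coeffs: EFACoefficients) -> EFACoefficients:
    """Kuhl–Giardina size/rotation/phase normalization (explicit opt-in).

    Rotates the starting phase to the first semi-major axis, aligns the
    first-harmonic ellipse with the x-axis and scales by its semi-major
    length; offsets are zeroed.
    """
    a, b, c, d = coeffs.harmonics[0]
    theta = 0.5 * np.arctan2(2.0 * (a * b + c * d), a**2 + c**2 - b**2 - d**2)
    ct, st = np.cos(theta), np.sin(theta)
    a_s = a * ct + b * st
    c_s = c * ct + d * st
    psi = np.arctan2(c_s, a_s)
    cp, sp = np.cos(psi), np.sin(psi)
    scale = np.hypot(a_s, c_s)

    out = np.empty_like(coeffs.harmonics)
    for i in range(coeffs.n_harmonics):
        n = i + 1
        an, bn, cn, dn = coeffs.harmonics[i]
        m = np.array([[an, bn], [cn, dn]])
        rot_psi = np.array([[cp, sp], [-sp, cp]])
        rot_theta = np.array(
            [[np.cos(n * theta), np.sin(n * theta)], [-np.sin(n * theta), np.cos(n * theta)]]
        )
        out[i] = (rot_psi @ m @ rot_theta.T).ravel() / scale
    return EFACoefficients(
        harmonics=out, A0=0.0, C0=0.0, perimeter=coeffs.perimeter, normalized=True
    )


def save_coefficients(coeffs: EFACoefficients, path) -> None:
    """CSV export: A0 and C0 rows, then one row per harmonic (n, a, b, c, d)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["A0", repr(coeffs.A0)])
        w.writerow(["C0", repr(coeffs.C0)])
        w.writerow(["perimeter", repr(coeffs.perimeter)])
        w.writerow(["n", "a", "b", "c", "d"])
        for i, row in enumerate(coeffs.harmonics, start=1):
            w.writerow([i] + [repr(float(x)) for x in row])


def load_coefficients(path) -> EFACoefficients:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    head = {r[0]: float(r[1]) for r in rows[:3]}
    harm = np.array([[float(x) for x in r[1:]] for r in rows[4:]])
    return EFACoefficients(
        harmonics=harm, A0=head["A0"], C0=head["C0"], perimeter=head["perimeter"]
    )
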