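"""Elliptic Fourier descriptors (EFDs) for closed contours.

A closed planar contour traversed at constant speed along its perimeter can
be written as a pair of Fourier series in the arc-length parameter ``t``:

.. math::

    x(t) = A_0 + \\sum_{n=1}^{H} a_n \\cos\\frac{2\\pi n t}{T}
                 + b_n \\sin\\frac{2\\pi n t}{T}, \\qquad
    y(t) = C_0 + \\sum_{n=1}^{H} c_n \\cos\\frac{2\\pi n t}{T}
                 + d_n \\sin\\frac{2\\pi n t}{T},

where ``T`` is the perimeter. Each harmonic ``n`` contributes the quadruple
``(a_n, b_n, c_n, d_n)`` — geometrically an ellipse traversed ``n`` times per
contour revolution. ``H`` harmonics therefore give ``4 H`` shape
coefficients plus the two DC offsets ``(A_0, C_0)``.

The coefficients depend on where the contour sits, how large it is, how it
is rotated, and where the traversal starts. :func:`normalize` removes all
four nuisances (the classical Kuhl–Giardina procedure), leaving a shape
code whose first harmonic is the canonical unit ellipse
``(a_1, b_1, c_1, d_1) = (1, 0, 0, d_1)``. With the default ``H = 20`` the
flattened code has 80 entries, the representation used throughout the
shape-PCA stage.

Coefficients are computed from the polygon's exact segment lengths (chain
parameterization), not from pixel chain codes, because upstream contours
arrive as sub-pixel polygons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import FormatError, GeometryError, ParameterError

__all__ = [
    "EFDCoefficients",
    "NormalizedEFD",
    "decompose",
    "normalize",
    "reconstruct",
    "flatten",
    "unflatten",
]

# Entries closer than this are treated as tied when picking a canonical
# branch of the two-fold starting-point / mirror ambiguities.
_BRANCH_TOL = 1e-6


@dataclass(frozen=True)
class EFDCoefficients:
    """Raw elliptic Fourier coefficients of one contour.

    Attributes
    ----------
    coeffs : (H, 4) array
        Rows are harmonics 1..H; columns are ``(a_n, b_n, c_n, d_n)`` in px.
    A0, C0 : float
        DC offsets (arc-length mean of x and y), px.
    T : float
        Contour perimeter, px.
    """

    coeffs: np.ndarray
    A0: float
    C0: float
    T: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.coeffs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
            raise FormatError(f"coeffs must be (H, 4) with H >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise FormatError("coefficients must be finite")
        object.__setattr__(self, "coeffs", arr)

    @property
    def H(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class NormalizedEFD(EFDCoefficients):
    """EFD coefficients after Kuhl–Giardina normalization.

    Carries the applied normalization so it can be audited or undone:
    ``scale`` is the divisor (semi-major axis of the first-harmonic
    ellipse), ``psi1`` the removed orientation, ``theta1`` the removed
    starting-point phase, and ``mirrored`` whether the canonical-chirality
    option reflected the contour.
    """

    scale: float = 1.0
    psi1: float = 0.0
    theta1: float = 0.0
    mirrored: bool = False


def _as_points(contour) -> np.ndarray:
    pts = np.asarray(getattr(contour, "points", contour), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GeometryError(f"contour must be an (N, 2) array with N >= 3, got {pts.shape}")
    return pts


def decompose(contour, H: int = 20) -> EFDCoefficients:
    """Elliptic Fourier decomposition of a closed polygonal contour.

    Parameters
    ----------
    contour : Contour or (N, 2) array
        Ordered closed polygon (last point implicitly connects to the
        first), counterclockwise. At least ``2 H + 1`` points are
        recommended to avoid aliasing.
    H : int
        Number of harmonics (the study default is 20, i.e. 80 coefficients).

    Returns
    -------
    EFDCoefficients
    """
    if H < 1:
        raise ParameterError(f"H must be >= 1, got {H}")
    pts = _as_points(contour)

    dxy = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(dxy[:, 0], dxy[:, 1])
    keep = dt > 0
    if keep.sum() < 3:
        raise GeometryError("degenerate contour: fewer than 3 distinct points")
    dxy, dt = dxy[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise GeometryError("degenerate contour: zero perimeter")

    n = np.arange(1, H + 1)[:, None]                      # (H, 1)
    phi = 2.0 * np.pi * n * t[None, :] / T                # (H, K+1)
    dcos = np.diff(np.cos(phi), axis=1)                   # cos φ_i − cos φ_{i−1}
    dsin = np.diff(np.sin(phi), axis=1)
    slope = dxy / dt[:, None]                             # (K, 2) velocity per segment
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)         # (H,)

    a = const * (dcos @ slope[:, 0])
    b = const * (dsin @ slope[:, 0])
    c = const * (dcos @ slope[:, 1])
    d = const * (dsin @ slope[:, 1])

    # DC terms: arc-length mean of the (piecewise-linear) trajectory.
    # Over segment i the coordinate is linear in t, so its integral is the
    # segment midpoint times the segment length.
    mids = pts[keep] + 0.5 * dxy
    A0 = float(np.sum(mids[:, 0] * dt) / T)
    C0 = float(np.sum(mids[:, 1] * dt) / T)

    return EFDCoefficients(np.column_stack([a, b, c, d]), A0, C0, float(T))


def _harmonic_matrices(coeffs: np.ndarray) -> np.ndarray:
    """Stack (H, 4) coefficients into (H, 2, 2) matrices [[a, b], [c, d]]."""
    H = coeffs.shape[0]
    return coeffs.reshape(H, 2, 2)


def _rot(angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([[ca, -sa], [sa, ca]])


def _apply(coeffs: np.ndarray, theta: float, psi: float) -> np.ndarray:
    """Shift starting point by phase ``theta`` and remove orientation ``psi``.

    Harmonic ``n`` is right-multiplied by a rotation of ``n * theta`` (the
    starting-point shift acts at n times the fundamental phase) and
    left-multiplied by a rotation of ``-psi``.
    """
    M = _harmonic_matrices(coeffs)
    H = M.shape[0]
    out = np.empty_like(M)
    Rpsi = _rot(-psi)
    for i in range(H):
        out[i] = Rpsi @ M[i] @ _rot((i + 1) * theta)
    return out.reshape(H, 4)


def _mirror_coeffs(coeffs: np.ndarray) -> np.ndarray:
    """Reflect the contour about the y-axis, re-parameterized to keep the
    traversal direction (t -> T - t): (a, b, c, d) -> (-a, b, c, -d)."""
    out = coeffs.copy()
    out[:, 0] *= -1.0
    out[:, 3] *= -1.0
    return out


def _pick_branch(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Deterministically pick one of two candidate coefficient arrays.

    The first entry where the candidates differ by more than a small
    tolerance decides (larger wins). Robust to O(1e-9) numerical noise, so
    transformed copies of the same contour always land on the same branch.
    """
    uf, vf = u.ravel(), v.ravel()
    diff = np.abs(uf - vf) > _BRANCH_TOL
    if not diff.any():
        return u
    i = int(np.argmax(diff))
    return u if uf[i] > vf[i] else v


def normalize(
    coeffs: EFDCoefficients,
    do_scale: bool = True,
    do_rotation: bool = True,
    do_start: bool = True,
    canonical_chirality: bool = False,
) -> NormalizedEFD:
    """Kuhl–Giardina normalization of EFD coefficients.

    Removes the starting point of the traversal (phase ``theta1``), the
    orientation of the contour (angle ``psi1``), and its size (division by
    the first-harmonic semi-major axis), each controllable by a flag.
    Translation is already excluded because the DC offsets are carried
    separately. After full normalization the first harmonic is
    ``(1, 0, 0, d_1)`` with ``d_1``'s sign recording the traversal
    direction.

    The starting-point phase is only determined modulo pi; the residual
    two-fold ambiguity (theta1 vs theta1 + pi, which flips the sign of the
    even harmonics) is resolved by a deterministic branch pick on the
    coefficient values, so that rotated/scaled/start-shifted copies of one
    contour map to identical codes.

    Chirality is *not* normalized by default — for sperm heads the hook's
    handedness is biologically meaningful. ``canonical_chirality=True``
    additionally identifies each shape with its mirror image (useful when
    slides may be flipped), again via the deterministic branch pick.
    """
    C = coeffs.coeffs
    a1, b1, c1, d1 = C[0]
    power = a1 * a1 + b1 * b1 + c1 * c1 + d1 * d1
    if power <= 0 or not np.isfinite(power):
        raise GeometryError("degenerate first harmonic: cannot normalize")

    def _one_branch(raw: np.ndarray, extra: float) -> tuple[np.ndarray, float, float, float]:
        ra1, rb1, rc1, rd1 = raw[0]
        theta = 0.0
        if do_start:
            theta = 0.5 * np.arctan2(
                2.0 * (ra1 * rb1 + rc1 * rd1),
                ra1 * ra1 + rc1 * rc1 - rb1 * rb1 - rd1 * rd1,
            ) + extra
        shifted = _apply(raw, theta, 0.0)
        psi = 0.0
        if do_rotation:
            psi = float(np.arctan2(shifted[0, 2], shifted[0, 0]))
        rotated = _apply(shifted, 0.0, psi) if do_rotation else shifted
        scale = 1.0
        if do_scale:
            scale = float(rotated[0, 0])
            if not np.isfinite(scale) or abs(scale) <= 0:
                raise GeometryError("degenerate first harmonic after rotation")
            rotated = rotated / scale
        return rotated, theta, psi, scale

    def _normalized(raw: np.ndarray) -> tuple[np.ndarray, float, float, float]:
        cand0 = _one_branch(raw, 0.0)
        if not do_start:
            return cand0
        cand1 = _one_branch(raw, np.pi)
        chosen = _pick_branch(cand0[0], cand1[0])
        return cand0 if chosen is cand0[0] else cand1

    arr, theta1, psi1, scale = _normalized(C)
    mirrored = False
    if canonical_chirality:
        arr_m, theta_m, psi_m, scale_m = _normalized(_mirror_coeffs(C))
        chosen = _pick_branch(arr, arr_m)
        if chosen is arr_m:
            arr, theta1, psi1, scale, mirrored = arr_m, theta_m, psi_m, scale_m, True

    return NormalizedEFD(
        coeffs=arr,
        A0=0.0,
        C0=0.0,
        T=coeffs.T,
        scale=scale,
        psi1=psi1,
        theta1=theta1,
        mirrored=mirrored,
    )


def reconstruct(coeffs: EFDCoefficients, n_points: int = 256):
    """Evaluate the truncated elliptic Fourier series.

    Returns an ``(n_points, 2)`` closed contour (the closing edge back to
    the first point is implicit) sampled at uniform parameter values.
    Includes the DC offsets, so raw coefficients reconstruct in place and
    normalized ones reconstruct about the origin.
    """
    if n_points < 8:
        raise ParameterError(f"n_points must be >= 8, got {n_points}")
    C = coeffs.coeffs
    H = C.shape[0]
    tau = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, H + 1)[:, None]
    cosn = np.cos(n * tau[None, :])
    sinn = np.sin(n * tau[None, :])
    x = coeffs.A0 + C[:, 0] @ cosn + C[:, 1] @ sinn
    y = coeffs.C0 + C[:, 2] @ cosn + C[:, 3] @ sinn
    from .contour_io import Contour

    return Contour(np.column_stack([x, y]), require_ccw=False)


def flatten(coeffs: EFDCoefficients) -> np.ndarray:
    """Flatten to the 4H coefficient vector (a1, b1, c1, d1, ..., d_H).

    DC offsets are dropped: the vector encodes shape only. At the study
    default H = 20 the length is 80.
    """
    return coeffs.coeffs.reshape(-1).copy()


def unflatten(vector, H: int) -> NormalizedEFD:
    """Inverse of :func:`flatten`; DC terms are zero, perimeter set to 1."""
    v = np.asarray(vector, dtype=float).ravel()
    if v.size != 4 * H:
        raise FormatError(f"expected a vector of length {4 * H} for H={H}, got {v.size}")
    return NormalizedEFD(coeffs=v.reshape(H, 4), A0=0.0, C0=0.0, T=1.0)
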