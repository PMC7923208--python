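"""Low-level 3-D geometry for anatomical joint-frame construction.

Coordinates are millimetres in a right-handed digitizer space; angles are
degrees throughout. The module is deliberately free of anatomy: it knows
about spheres, planes, frames and axis-angle rotations, nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateConfigurationError,
    DegeneratePlaneError,
    InsufficientPointsError,
    NonUnitAxisError,
)

__all__ = [
    "SphereFit",
    "CoordinateFrame",
    "fit_sphere",
    "build_frame",
    "rotate_about_axis",
    "distance",
    "UNIT_TOL",
    "DEGENERACY_CONDITION_LIMIT",
    "COLLINEARITY_TOL",
]

#: Tolerance on unit norm and axis orthogonality.
UNIT_TOL = 1e-9

#: Condition-number limit on the sphere-fit normal equations; beyond this the
#: point configuration is treated as coplanar/collinear (no unique sphere).
DEGENERACY_CONDITION_LIMIT = 1e8

#: Relative cross-product norm below which three landmarks are collinear.
COLLINEARITY_TOL = 1e-8


def _point(p, name: str = "point") -> np.ndarray:
    arr = np.asarray(p, dtype=float).reshape(-1)
    if arr.shape != (3,):
        raise ValueError(f"{name} must have 3 coordinates, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} has non-finite coordinates: {arr}")
    return arr


def _points(points, name: str = "points") -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    arr = np.atleast_2d(arr)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contain non-finite coordinates")
    return arr


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere: center (mm), radius (mm) and RMS radial residual."""

    center: np.ndarray
    radius: float
    rms_residual: float


@dataclass(frozen=True)
class CoordinateFrame:
    """Humerus-fixed anatomical frame.

    ``origin`` is the midpoint of the epicondyle tips; ``y_axis`` points from
    there toward the glenohumeral rotation center; ``x_axis`` is normal to the
    epicondyles/rotation-center plane (varus-valgus axis); ``z_axis`` completes
    a right-handed triad (flexion-extension axis).
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def axes_matrix(self) -> np.ndarray:
        """Rows are the x, y, z axis directions (a rotation matrix)."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])


def fit_sphere(points, method: str = "algebraic") -> SphereFit:
    """Fit a sphere to 3-D points by least squares.

    ``algebraic`` solves the linearized sphere equation
    ``|p|^2 = 2 p.c + (r^2 - |c|^2)`` directly; ``geometric`` refines that
    solution by minimizing the sum of squared radial residuals
    ``(|p - c| - r)^2`` with Levenberg-Marquardt.

    Raises
    ------
    InsufficientPointsError
        Fewer than 4 points.
    DegenerateConfigurationError
        Points coplanar/collinear within tolerance (normal-equation condition
        number above ``DEGENERACY_CONDITION_LIMIT``).
    """
    pts = _points(points)
    if len(pts) < 4:
        raise InsufficientPointsError(
            f"sphere fit requires at least 4 points, got {len(pts)}"
        )
    if method not in ("algebraic", "geometric"):
        raise ValueError(f"unknown sphere-fit method {method!r}")

    # Center the data to keep the normal equations well scaled; the condition
    # check is then a pure shape test, independent of the coordinate offset.
    shift = pts.mean(axis=0)
    q = pts - shift
    design = np.column_stack([2.0 * q, np.ones(len(q))])
    gram = design.T @ design
    if np.linalg.cond(gram) > DEGENERACY_CONDITION_LIMIT:
        raise DegenerateConfigurationError(
            "points are coplanar or collinear within tolerance; "
            "a sphere fit is not determined"
        )
    rhs = np.einsum("ij,ij->i", q, q)
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    center = sol[:3] + shift
    radius = float(np.sqrt(sol[3] + sol[:3] @ sol[:3]))

    if method == "geometric":
        def radial_residuals(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        result = least_squares(
            radial_residuals, x0=np.append(center, radius), method="lm"
        )
        center = result.x[:3]
        radius = float(result.x[3])

    dists = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    return SphereFit(center=center, radius=radius, rms_residual=rms)


def build_frame(ghc, me, le, side: str) -> CoordinateFrame:
    """Construct the humerus-fixed anatomical frame.

    Parameters
    ----------
    ghc : point
        Glenohumeral rotation center (best-fit humeral-head sphere center).
    me, le : point
        Medial and lateral epicondyle tips.
    side : {"left", "right"}
        Side of the body (validated; recorded by callers). Because the
        medial/lateral roles of ``me`` and ``le`` are fixed, the cross
        product below yields the valgus-positive X axis on both sides
        (anterior plane normal on a left elbow, posterior on a right one);
        the side-dependent flexion sense about Z is handled when posing.

    Raises
    ------
    DegeneratePlaneError
        The three landmarks are collinear within ``COLLINEARITY_TOL``.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    ghc = _point(ghc, "ghc")
    me = _point(me, "me")
    le = _point(le, "le")

    u = le - me
    v = ghc - me
    normal = np.cross(u, v)
    if np.linalg.norm(normal) <= COLLINEARITY_TOL * np.linalg.norm(u) * np.linalg.norm(v):
        raise DegeneratePlaneError(
            "epicondyle tips and glenohumeral center are collinear; "
            "no epicondylar plane exists"
        )
    origin = 0.5 * (me + le)
    y_axis = _unit(ghc - origin)
    x_axis = _unit(normal)
    # y lies in the (me, le, ghc) plane, so x and y are orthogonal exactly.
    z_axis = _unit(np.cross(x_axis, y_axis))
    return CoordinateFrame(origin=origin, x_axis=x_axis, y_axis=y_axis, z_axis=z_axis)


def rotate_about_axis(p, axis_origin, axis_dir, angle_deg: float):
    """Rodrigues rotation of point(s) ``p`` about an arbitrary axis line.

    ``p`` may be a single point or an (n, 3) array; the return matches the
    input shape. ``angle_deg == 0`` returns the input coordinates unchanged
    (bit-exact), so a zero rotation is a true identity.

    Raises
    ------
    NonUnitAxisError
        ``axis_dir`` does not have unit norm (tolerance ``UNIT_TOL``).
    """
    axis_origin = _point(axis_origin, "axis_origin")
    axis_dir = _point(axis_dir, "axis_dir")
    if abs(np.linalg.norm(axis_dir) - 1.0) > UNIT_TOL:
        raise NonUnitAxisError(
            f"axis direction must be unit norm, got |d| = {np.linalg.norm(axis_dir)!r}"
        )
    arr = np.asarray(p, dtype=float)
    if angle_deg == 0.0:
        return arr.copy()
    single = arr.ndim == 1
    pts = _points(arr)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis_dir)
    out = rot.apply(pts - axis_origin) + axis_origin
    return out[0] if single else out


def distance(a, b) -> float:
    """Euclidean distance between two points, in mm."""
    return float(np.linalg.norm(_point(b, "b") - _point(a, "a")))
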