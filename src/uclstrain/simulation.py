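"""Pose the forearm over a flexion x valgus grid and compute fiber strain.

The digitized posture (90° elbow flexion, 0° valgus) is the reference. Every
other pose is reached by rigidly rotating the ulna-fixed attachment points
about humerus-fixed axes through the anatomical frame origin: first by
``flexion - 90`` degrees about the flexion-extension (Z) axis, then by the
valgus angle about the varus-valgus (X) axis. Strain is the percent length
change of each straight-line fiber relative to its reference length:

    strain% = (LT - LST) / LST * 100

where LST is the fiber length at the reference pose and LT its length at the
simulated pose. Positive strain means the fiber is taut (lengthened),
negative means shortened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import FIBER_NAMES, SpecimenLandmarks, derive_fibers
from .errors import (
    IncompleteTableError,
    MissingReferencePoseError,
    NonpositiveReferenceLengthError,
)
from .geometry import CoordinateFrame, build_frame, distance, fit_sphere, rotate_about_axis

__all__ = [
    "DEFAULT_FLEXION_GRID",
    "DEFAULT_VALGUS_GRID",
    "REFERENCE_POSE",
    "Pose",
    "StrainResult",
    "StrainTable",
    "pose_insertions",
    "strain_percent",
    "run_strain_study",
    "average_strain",
]

DEFAULT_FLEXION_GRID = (0.0, 30.0, 60.0, 90.0, 120.0)
DEFAULT_VALGUS_GRID = (0.0, 10.0)

#: Rotation orders supported by the posing step (humerus-fixed axes both ways).
ROTATION_ORDERS = ("flexion_then_valgus", "valgus_then_flexion")


@dataclass(frozen=True)
class Pose:
    """Elbow pose: flexion and valgus angles in degrees."""

    flexion_deg: float
    valgus_deg: float


REFERENCE_POSE = Pose(flexion_deg=90.0, valgus_deg=0.0)


@dataclass(frozen=True)
class StrainResult:
    fiber_name: str
    pose: Pose
    reference_length_mm: float
    length_mm: float
    strain_pct: float


def strain_percent(lt: float, lst: float) -> float:
    """Percent strain of a fiber of reference length ``lst`` now at ``lt``."""
    if lst <= 0:
        raise NonpositiveReferenceLengthError(
            f"reference length must be positive, got {lst!r}"
        )
    return (lt - lst) / lst * 100.0


def _pose_point(
    point: np.ndarray,
    frame: CoordinateFrame,
    pose: Pose,
    side: str = "left",
    order: str = "flexion_then_valgus",
) -> np.ndarray:
    if order not in ROTATION_ORDERS:
        raise ValueError(f"rotation order must be one of {ROTATION_ORDERS}")
    # The right-handed frame keeps +X rotation = valgus on both sides; the
    # flexion sense about Z mirrors with the side (a reflection commutes
    # with rotations about its normal axis but flips the other two).
    flexion_sign = 1.0 if side == "left" else -1.0
    steps = [
        (frame.z_axis, flexion_sign * (pose.flexion_deg - REFERENCE_POSE.flexion_deg)),
        (frame.x_axis, pose.valgus_deg),
    ]
    if order == "valgus_then_flexion":
        steps.reverse()
    out = point
    for axis, angle in steps:
        out = rotate_about_axis(out, frame.origin, axis, angle)
    return out


def pose_insertions(
    landmarks: SpecimenLandmarks,
    frame: CoordinateFrame,
    pose: Pose,
    order: str = "flexion_then_valgus",
) -> dict[str, np.ndarray]:
    """Rigidly rotate every ulna-fixed insertion point to the given pose.

    Humerus-fixed origin points are untouched; the returned mapping holds one
    posed insertion per canonical fiber. At the reference pose the points are
    returned bit-identical to the digitized coordinates.
    """
    fibers = derive_fibers(landmarks)
    return {
        fiber.name: _pose_point(fiber.insertion, frame, pose, landmarks.side, order)
        for fiber in fibers
    }


class StrainTable:
    """Complete fiber x pose grid of strain results for one specimen.

    Fibers are kept in canonical order; poses are ordered valgus-major with
    flexion ascending. Provides long- and wide-format pandas views.
    """

    def __init__(
        self,
        results: list[StrainResult],
        specimen_id: str,
        group: str,
    ):
        self.specimen_id = specimen_id
        self.group = group
        self.results = list(results)
        self._by_key = {(r.fiber_name, r.pose): r for r in self.results}

    @property
    def fibers(self) -> tuple[str, ...]:
        present = {r.fiber_name for r in self.results}
        return tuple(n for n in FIBER_NAMES if n in present)

    @property
    def poses(self) -> tuple[Pose, ...]:
        seen: dict[Pose, None] = {}
        for r in self.results:
            seen.setdefault(r.pose, None)
        return tuple(
            sorted(seen, key=lambda p: (p.valgus_deg, p.flexion_deg))
        )

    def strain(self, fiber_name: str, flexion_deg: float, valgus_deg: float) -> float:
        return self._by_key[(fiber_name, Pose(flexion_deg, valgus_deg))].strain_pct

    def is_complete(self) -> bool:
        return all(
            (f, p) in self._by_key for f in self.fibers for p in self.poses
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view, full precision, deterministic row order."""
        rows = [
            {
                "specimen_id": self.specimen_id,
                "group": self.group,
                "fiber": f,
                "flexion_deg": p.flexion_deg,
                "valgus_deg": p.valgus_deg,
                "reference_length_mm": self._by_key[(f, p)].reference_length_mm,
                "length_mm": self._by_key[(f, p)].length_mm,
                "strain_pct": self._by_key[(f, p)].strain_pct,
            }
            for p in self.poses
            for f in self.fibers
        ]
        return pd.DataFrame(rows)

    def to_wide(
        self,
        valgus_deg: float,
        decimals: int | None = 1,
        include_average: bool = True,
    ) -> pd.DataFrame:
        """Wide view at one valgus setting: fibers x flexion angles.

        Mirrors the familiar journal-table layout; ``decimals`` rounds for
        display (None keeps full precision). The Average row is computed from
        unrounded strains, then rounded.
        """
        flexions = sorted({p.flexion_deg for p in self.poses if p.valgus_deg == valgus_deg})
        if not flexions:
            raise KeyError(f"no poses at valgus {valgus_deg!r}")
        data = {
            f: [self.strain(f, fx, valgus_deg) for fx in flexions] for f in self.fibers
        }
        frame = pd.DataFrame.from_dict(data, orient="index", columns=flexions)
        if include_average:
            frame.loc["Average"] = frame.loc[list(self.fibers)].mean(axis=0)
        if decimals is not None:
            frame = frame.round(decimals)
        frame.index.name = "fiber"
        return frame

    def average_strain(self) -> dict[Pose, float]:
        return average_strain(self)


def average_strain(table: StrainTable) -> dict[Pose, float]:
    """Unweighted arithmetic mean strain over all fibers, per pose."""
    if not table.results or not table.is_complete():
        raise IncompleteTableError("strain table is missing fiber x pose cells")
    return {
        pose: float(
            np.mean([table.strain(f, pose.flexion_deg, pose.valgus_deg) for f in table.fibers])
        )
        for pose in table.poses
    }


def run_strain_study(
    landmarks: SpecimenLandmarks,
    flexion_grid=None,
    valgus_grid=None,
    *,
    sphere_method: str = "algebraic",
    rotation_order: str = "flexion_then_valgus",
) -> StrainTable:
    """Full pipeline: sphere fit, frame construction, posing, strain.

    The glenohumeral rotation center is the least-squares sphere center of the
    humeral-head cloud; the anatomical frame is built from it and the two
    epicondyle tips. Reference lengths are measured from the digitized
    geometry at 90° flexion / 0° valgus, so every strain at the reference
    pose is exactly zero.
    """
    flexion_grid = DEFAULT_FLEXION_GRID if flexion_grid is None else tuple(float(v) for v in flexion_grid)
    valgus_grid = DEFAULT_VALGUS_GRID if valgus_grid is None else tuple(float(v) for v in valgus_grid)
    if not flexion_grid or not valgus_grid:
        raise MissingReferencePoseError("flexion and valgus grids must be non-empty")
    if not any(math.isclose(f, REFERENCE_POSE.flexion_deg) for f in flexion_grid):
        raise MissingReferencePoseError("flexion grid must include 90°")
    if not any(math.isclose(v, REFERENCE_POSE.valgus_deg) for v in valgus_grid):
        raise MissingReferencePoseError("valgus grid must include 0°")

    sphere = fit_sphere(landmarks.humeral_head_cloud, method=sphere_method)
    frame = build_frame(
        sphere.center,
        landmarks.medial_epicondyle_tip,
        landmarks.lateral_epicondyle_tip,
        landmarks.side,
    )
    fibers = derive_fibers(landmarks)
    reference_lengths = {f.name: f.length for f in fibers}
    for name, lst in reference_lengths.items():
        if lst <= 0:
            raise NonpositiveReferenceLengthError(
                f"fiber {name} has non-positive reference length {lst!r}"
            )

    results = []
    for valgus in sorted(valgus_grid):
        for flexion in sorted(flexion_grid):
            pose = Pose(flexion_deg=flexion, valgus_deg=valgus)
            posed = pose_insertions(landmarks, frame, pose, order=rotation_order)
            for fiber in fibers:
                lst = reference_lengths[fiber.name]
                lt = distance(fiber.origin, posed[fiber.name])
                results.append(
                    StrainResult(
                        fiber_name=fiber.name,
                        pose=pose,
                        reference_length_mm=lst,
                        length_mm=lt,
                        strain_pct=strain_percent(lt, lst),
                    )
                )
    return StrainTable(results, specimen_id=landmarks.specimen_id, group=landmarks.group)
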