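"""Landmark schema, fiber taxonomy and landmark file I/O.

The model covers the medial elbow stabilizers: the anterior and posterior
bundles of the ulnar collateral ligament (AB, PB) and the anterior and
posterior common tendons of the flexor-pronator muscles (ACT, PCT). Each
structure is reduced to straight line fibers between digitized attachment
points: ACT and PCT one fiber each (2 points), the AB three bands (6 points,
the central band constructed from edge midpoints), and the PB four bands
(8 points) — nine fibers in all.

Landmark names form a fixed controlled vocabulary; unknown names in a file
are schema errors, never silently ignored.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingLandmarkError, ParseError, SchemaViolationError
from .geometry import distance

__all__ = [
    "GROUPS",
    "SIDES",
    "FIBER_NAMES",
    "ATTACHMENT_NAMES",
    "OPTIONAL_ATTACHMENT_NAMES",
    "EPICONDYLE_NAMES",
    "FILE_DECIMALS",
    "Fiber",
    "SpecimenLandmarks",
    "ValidationIssue",
    "derive_fibers",
    "read_landmarks",
    "write_landmarks",
    "validate_specimen",
]

GROUPS = ("I", "II", "III")
SIDES = ("left", "right")

#: Canonical fiber order used in every table and output.
FIBER_NAMES = ("ACT", "PCT", "AB1", "AB2", "AB3", "PB1", "PB2", "PB3", "PB4")

#: Required attachment landmarks (controlled vocabulary).
ATTACHMENT_NAMES = (
    "act_proximal",
    "act_distal",
    "pct_proximal",
    "pct_distal",
    "ab_ant_origin",
    "ab_ant_insertion",
    "ab_post_origin",
    "ab_post_insertion",
    "pb_ant_origin",
    "pb_ant_insertion",
    "pb_antcen_origin",
    "pb_antcen_insertion",
    "pb_postcen_origin",
    "pb_postcen_insertion",
    "pb_post_origin",
    "pb_post_insertion",
)

#: The AB central band may be digitized explicitly or derived from midpoints.
OPTIONAL_ATTACHMENT_NAMES = ("ab_cen_origin", "ab_cen_insertion")

EPICONDYLE_NAMES = ("medial_epicondyle_tip", "lateral_epicondyle_tip")

#: Decimal places written to landmark files (1 µm; digitizer precision is
#: 0.23 mm, one extra order prevents round-trip drift).
FILE_DECIMALS = 3

_CSV_COLUMNS = ["specimen_id", "group", "side", "landmark_name", "x_mm", "y_mm", "z_mm"]


def _pt(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.shape != (3,):
        raise ValueError(f"landmark {name!r} must have 3 coordinates")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"landmark {name!r} has non-finite coordinates")
    return arr


@dataclass(frozen=True)
class Fiber:
    """One modeled straight-line fiber: humeral origin to ulnar insertion."""

    name: str
    origin: np.ndarray
    insertion: np.ndarray

    @property
    def length(self) -> float:
        return distance(self.origin, self.insertion)


@dataclass
class SpecimenLandmarks:
    """All digitized points of one elbow plus morphology-group metadata.

    Coordinates are mm in the digitizer frame, recorded at the reference
    posture (90° elbow flexion, 0° valgus, neutral rotation). ``group`` is
    declared metadata from macroscopic dissection, never inferred.
    """

    specimen_id: str
    group: str
    side: str
    medial_epicondyle_tip: np.ndarray
    lateral_epicondyle_tip: np.ndarray
    humeral_head_cloud: np.ndarray
    act_proximal: np.ndarray
    act_distal: np.ndarray
    pct_proximal: np.ndarray
    pct_distal: np.ndarray
    ab_ant_origin: np.ndarray
    ab_ant_insertion: np.ndarray
    ab_post_origin: np.ndarray
    ab_post_insertion: np.ndarray
    pb_ant_origin: np.ndarray
    pb_ant_insertion: np.ndarray
    pb_antcen_origin: np.ndarray
    pb_antcen_insertion: np.ndarray
    pb_postcen_origin: np.ndarray
    pb_postcen_insertion: np.ndarray
    pb_post_origin: np.ndarray
    pb_post_insertion: np.ndarray
    ab_cen_origin: np.ndarray | None = None
    ab_cen_insertion: np.ndarray | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        for name in EPICONDYLE_NAMES + ATTACHMENT_NAMES:
            setattr(self, name, _pt(getattr(self, name), name))
        for name in OPTIONAL_ATTACHMENT_NAMES:
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, _pt(value, name))
        cloud = np.asarray(self.humeral_head_cloud, dtype=float)
        if cloud.ndim != 2 or cloud.shape[1] != 3:
            raise ValueError("humeral_head_cloud must be an (n, 3) array")
        self.humeral_head_cloud = cloud

    def attachment(self, name: str) -> np.ndarray | None:
        if name not in ATTACHMENT_NAMES + OPTIONAL_ATTACHMENT_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def attachment_items(self):
        """(name, point) pairs for all present attachment landmarks."""
        for name in ATTACHMENT_NAMES + OPTIONAL_ATTACHMENT_NAMES:
            value = getattr(self, name)
            if value is not None:
                yield name, value

    def copy(self) -> "SpecimenLandmarks":
        kwargs = {}
        for f in fields(self):
            value = getattr(self, f.name)
            kwargs[f.name] = value.copy() if isinstance(value, np.ndarray) else value
        return SpecimenLandmarks(**kwargs)


# Fiber name -> (origin landmark, insertion landmark); AB2 handled separately.
_FIBER_ENDPOINTS = {
    "ACT": ("act_proximal", "act_distal"),
    "PCT": ("pct_proximal", "pct_distal"),
    "AB1": ("ab_ant_origin", "ab_ant_insertion"),
    "AB3": ("ab_post_origin", "ab_post_insertion"),
    "PB1": ("pb_ant_origin", "pb_ant_insertion"),
    "PB2": ("pb_antcen_origin", "pb_antcen_insertion"),
    "PB3": ("pb_postcen_origin", "pb_postcen_insertion"),
    "PB4": ("pb_post_origin", "pb_post_insertion"),
}


def derive_fibers(landmarks: SpecimenLandmarks) -> list[Fiber]:
    """Return the nine canonical fibers in order ACT, PCT, AB1-3, PB1-4.

    The AB central band (AB2) uses explicitly digitized central points when
    present; otherwise its endpoints are the midpoints of the AB anterior and
    posterior edge origins and insertions, which is how the central band is
    defined as a constructed line.
    """
    for name in ATTACHMENT_NAMES:
        if getattr(landmarks, name) is None:
            raise MissingLandmarkError(name)
    fibers = []
    for fiber_name in FIBER_NAMES:
        if fiber_name == "AB2":
            if landmarks.ab_cen_origin is not None and landmarks.ab_cen_insertion is not None:
                origin = landmarks.ab_cen_origin.copy()
                insertion = landmarks.ab_cen_insertion.copy()
            else:
                origin = 0.5 * (landmarks.ab_ant_origin + landmarks.ab_post_origin)
                insertion = 0.5 * (landmarks.ab_ant_insertion + landmarks.ab_post_insertion)
        else:
            o_name, i_name = _FIBER_ENDPOINTS[fiber_name]
            origin = getattr(landmarks, o_name).copy()
            insertion = getattr(landmarks, i_name).copy()
        fibers.append(Fiber(name=fiber_name, origin=origin, insertion=insertion))
    return fibers


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _cloud_name(i: int) -> str:
    return f"head_{i:03d}"


def _landmark_rows(landmarks: SpecimenLandmarks):
    for name in EPICONDYLE_NAMES:
        yield name, getattr(landmarks, name)
    for i, p in enumerate(landmarks.humeral_head_cloud):
        yield _cloud_name(i), p
    for name, p in landmarks.attachment_items():
        yield name, p


def write_landmarks(landmarks: SpecimenLandmarks, format: str = "csv") -> str:
    """Serialize a specimen to CSV or JSON text.

    Field order is deterministic (epicondyles, head cloud, attachments) and
    coordinates are written with ``FILE_DECIMALS`` decimal places, so output
    is byte-identical for identical specimens.
    """
    if format == "csv":
        lines = [",".join(_CSV_COLUMNS)]
        for name, p in _landmark_rows(landmarks):
            coords = ",".join(f"{v:.{FILE_DECIMALS}f}" for v in p)
            lines.append(
                f"{landmarks.specimen_id},{landmarks.group},{landmarks.side},{name},{coords}"
            )
        return "\n".join(lines) + "\n"
    if format == "json":
        payload = {
            "specimen_id": landmarks.specimen_id,
            "group": landmarks.group,
            "side": landmarks.side,
            "landmarks": {
                name: [round(float(v), FILE_DECIMALS) for v in p]
                for name, p in _landmark_rows(landmarks)
            },
        }
        return json.dumps(payload, indent=2) + "\n"
    raise ValueError(f"unknown format {format!r}")


def _source_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, bytes):
        return source.decode()
    if isinstance(source, str):
        # A string with newlines is literal content; otherwise a path.
        if "\n" in source:
            return source
        return Path(source).read_text()
    if hasattr(source, "read"):
        data = source.read()
        return data.decode() if isinstance(data, bytes) else data
    raise TypeError(f"cannot read landmarks from {type(source)!r}")


def _assemble(specimen_id: str, group: str, side: str, named: dict[str, np.ndarray]) -> SpecimenLandmarks:
    cloud_keys = sorted(k for k in named if k.startswith("head_"))
    for k in cloud_keys:
        suffix = k[len("head_"):]
        if not suffix.isdigit():
            raise SchemaViolationError(f"unknown landmark_name {k!r}")
    cloud = np.array([named.pop(k) for k in cloud_keys], dtype=float).reshape(-1, 3)
    kwargs = {}
    for name in EPICONDYLE_NAMES + ATTACHMENT_NAMES:
        if name not in named:
            raise SchemaViolationError(f"missing required landmark {name!r}")
        kwargs[name] = named.pop(name)
    for name in OPTIONAL_ATTACHMENT_NAMES:
        if name in named:
            kwargs[name] = named.pop(name)
    if named:
        unknown = sorted(named)[0]
        raise SchemaViolationError(f"unknown landmark_name {unknown!r}")
    if len(cloud) < 4:
        raise SchemaViolationError(
            f"humeral_head_cloud needs at least 4 points, got {len(cloud)}"
        )
    try:
        return SpecimenLandmarks(
            specimen_id=specimen_id,
            group=group,
            side=side,
            humeral_head_cloud=cloud,
            **kwargs,
        )
    except ValueError as exc:
        raise SchemaViolationError(str(exc)) from exc


def read_landmarks(source, format: str = "csv") -> SpecimenLandmarks:
    """Parse a single-specimen landmark file (CSV or JSON).

    ``source`` may be a path, an open stream, or literal file content (any
    string containing a newline). Round-trips with :func:`write_landmarks`
    exactly at the declared file precision.
    """
    text = _source_text(source)
    if format == "csv":
        try:
            frame = pd.read_csv(io.StringIO(text), dtype={"specimen_id": str})
        except Exception as exc:
            raise ParseError(f"malformed landmark CSV: {exc}") from exc
        if list(frame.columns) != _CSV_COLUMNS:
            raise SchemaViolationError(
                f"expected CSV header {_CSV_COLUMNS}, got {list(frame.columns)}"
            )
        for col in ("x_mm", "y_mm", "z_mm"):
            if not np.issubdtype(frame[col].dtype, np.number):
                bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index[0]
                raise ParseError(f"non-numeric {col} at data row {bad + 1}")
        for col in ("specimen_id", "group", "side"):
            if frame[col].nunique() != 1:
                raise SchemaViolationError(f"file must describe one specimen; {col} varies")
        names = frame["landmark_name"]
        dupes = names[names.duplicated()]
        if len(dupes):
            raise SchemaViolationError(f"duplicate landmark_name {dupes.iloc[0]!r}")
        named = {
            row.landmark_name: np.array([row.x_mm, row.y_mm, row.z_mm])
            for row in frame.itertuples()
        }
        return _assemble(
            str(frame["specimen_id"].iloc[0]),
            str(frame["group"].iloc[0]),
            str(frame["side"].iloc[0]),
            named,
        )
    if format == "json":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed landmark JSON: {exc}") from exc
        for key in ("specimen_id", "group", "side", "landmarks"):
            if key not in payload:
                raise SchemaViolationError(f"missing top-level key {key!r}")
        named = {
            name: np.asarray(coords, dtype=float)
            for name, coords in payload["landmarks"].items()
        }
        for name, arr in named.items():
            if arr.shape != (3,):
                raise SchemaViolationError(f"landmark {name!r} must have 3 coordinates")
        return _assemble(
            str(payload["specimen_id"]), str(payload["group"]), str(payload["side"]), named
        )
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str


def validate_specimen(
    landmarks: SpecimenLandmarks,
    *,
    pb_central_offset: float = 2.0,
    offset_tolerance: float = 1.0,
) -> list[ValidationIssue]:
    """Check anatomical-plausibility invariants; return issues, never raise.

    For Groups II and III the PB central digitization sites are capsule points
    about ``pb_central_offset`` mm anterior and posterior of the medial
    epicondyle tip, so their combined spread should be about twice that
    (≈4 mm at defaults); deviations beyond ``offset_tolerance`` are flagged.
    """
    issues: list[ValidationIssue] = []
    if len(landmarks.humeral_head_cloud) < 4:
        issues.append(
            ValidationIssue(
                "cloud_too_small",
                f"humeral_head_cloud has {len(landmarks.humeral_head_cloud)} points; "
                "need at least 4 for a sphere fit",
            )
        )
    if distance(landmarks.medial_epicondyle_tip, landmarks.lateral_epicondyle_tip) < 1e-6:
        issues.append(
            ValidationIssue("epicondyles_coincident", "epicondyle tips are not distinct")
        )
    for name in ATTACHMENT_NAMES:
        if getattr(landmarks, name) is None:
            issues.append(ValidationIssue("missing_landmark", f"missing landmark {name!r}"))
    pairs = list(_FIBER_ENDPOINTS.values())
    for o_name, i_name in pairs:
        o, i = getattr(landmarks, o_name), getattr(landmarks, i_name)
        if o is not None and i is not None and distance(o, i) < 1e-6:
            issues.append(
                ValidationIssue(
                    "zero_length_fiber", f"{o_name} and {i_name} coincide"
                )
            )
    if landmarks.group in ("II", "III"):
        me = landmarks.medial_epicondyle_tip
        for site in ("pb_antcen_origin", "pb_postcen_origin"):
            p = getattr(landmarks, site)
            if p is None:
                continue
            off = distance(me, p)
            if not math.isclose(off, pb_central_offset, abs_tol=offset_tolerance):
                issues.append(
                    ValidationIssue(
                        "pb_central_site_offset",
                        f"{site} is {off:.2f} mm from the medial epicondyle tip "
                        f"(expected ≈{pb_central_offset:g} mm)",
                    )
                )
        a, p = landmarks.pb_antcen_origin, landmarks.pb_postcen_origin
        if a is not None and p is not None:
            spread = distance(a, p)
            expected = 2.0 * pb_central_offset
            if not math.isclose(spread, expected, abs_tol=offset_tolerance):
                issues.append(
                    ValidationIssue(
                        "pb_central_site_spread",
                        f"PB central origin sites are {spread:.2f} mm apart "
                        f"(expected ≈{expected:g} mm)",
                    )
                )
    return issues
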