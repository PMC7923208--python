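"""Seedable generator of anatomically plausible elbow landmark sets.

No real digitized coordinates ship with the package, so this module builds
synthetic specimens that emulate the digitization protocol: a ~40-point
humeral-head cloud with digitizer-scale noise, epicondyle tips, and the full
set of ligament/tendon attachment points for each morphology group.

Geometry convention (left elbow, digitizer space, mm):

* the humeral shaft runs along +Y (the glenohumeral head proximal at +Y);
* the epicondylar axis runs along X with the medial epicondyle at -X;
* the forearm at the digitized posture (90° flexion) points along +Z, so +Z
  is anterior.

With these choices the anatomical frame of :func:`uclstrain.geometry.build_frame`
is axis-aligned: X (valgus axis) = +Z digitizer, Y = +Y, Z (flexion axis) = -X.
Attachment sites are placed deterministically (per group); digitizer noise is
applied to the head cloud only, and :func:`perturb_specimen` adds optional
noise to attachments for sensitivity studies. Right-sided specimens are exact
mirror images (x -> -x).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .anatomy import GROUPS, SIDES, SpecimenLandmarks
from .errors import InvalidParamsError

__all__ = [
    "GeneratorParams",
    "generate_humeral_head",
    "generate_specimen",
    "perturb_specimen",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic-anatomy generator.

    Defaults are representative adult dimensions: humeral head radius
    22.5 mm, epicondyle width 55 mm, humerus length 290 mm. The head-cloud
    noise (0.23 mm) matches the stated precision of the digitizing arm, and
    the PB central capsule sites sit 2 mm anterior/posterior of the medial
    epicondyle tip in Groups II/III.
    """

    seed: int = 0
    group: str = "I"
    side: str = "left"
    humeral_head_radius: float = 22.5
    head_cloud_size: int = 40
    digitizer_noise_sd: float = 0.23
    epicondyle_width: float = 55.0
    humerus_length: float = 290.0
    pb_central_offset: float = 2.0

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise InvalidParamsError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.side not in SIDES:
            raise InvalidParamsError(f"side must be one of {SIDES}, got {self.side!r}")
        for name in ("humeral_head_radius", "epicondyle_width", "humerus_length", "pb_central_offset"):
            if getattr(self, name) <= 0:
                raise InvalidParamsError(f"{name} must be > 0")
        if self.head_cloud_size < 4:
            raise InvalidParamsError("head_cloud_size must be at least 4")
        if self.digitizer_noise_sd < 0:
            raise InvalidParamsError("digitizer_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorParams":
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidParamsError(f"unknown generator parameter(s): {sorted(unknown)}")
        params = cls(**data)
        params.validate()
        return params


def _head_center(params: GeneratorParams) -> np.ndarray:
    return np.array([0.0, params.humerus_length, 0.0])


def generate_humeral_head(params: GeneratorParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample the humeral-head digitization cloud.

    Points are drawn on the proximal hemisphere of a sphere of the configured
    radius centered ``humerus_length`` proximal of the elbow, then perturbed
    by isotropic Gaussian noise with sd ``digitizer_noise_sd``. Deterministic
    per seed.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.head_cloud_size
    # Uniform over the proximal (+Y) hemisphere.
    cos_polar = rng.uniform(0.0, 1.0, size=n)
    sin_polar = np.sqrt(1.0 - cos_polar**2)
    azimuth = rng.uniform(0.0, 2.0 * np.pi, size=n)
    directions = np.column_stack(
        [sin_polar * np.cos(azimuth), cos_polar, sin_polar * np.sin(azimuth)]
    )
    cloud = _head_center(params) + params.humeral_head_radius * directions
    if params.digitizer_noise_sd > 0:
        cloud = cloud + rng.normal(0.0, params.digitizer_noise_sd, size=cloud.shape)
    return cloud


# ---------------------------------------------------------------------------
# Attachment layout (left side, digitized posture: 90° flexion, 0° valgus)
# ---------------------------------------------------------------------------
#
# Humeral origins are offsets (dx, dy, dz) from the medial epicondyle tip;
# structures are ordered anterior (+z) to posterior (-z) around it:
# ACT, AB anterior/posterior edges, PCT, then the PB fan down toward the
# olecranon. Ulnar/forearm insertions are absolute coordinates at the
# digitized posture (forearm along +z): the AB inserts on the sublime
# tubercle, the PB fans onto the medial proximal olecranon, and the common
# tendons continue distally along the flexor-pronator mass.
#
# The layout was shaped once, by construction, so the default specimens show
# the expected qualitative behavior (anterior structures taut in extension,
# posterior taut in flexion, medial structures taut under valgus) and then
# frozen; it is not fit to any measured dataset.

_ORIGIN_OFFSETS = {
    "act_proximal": (1.0, 0.5, 3.5),
    "ab_ant_origin": (1.0, -0.3, 1.8),
    "ab_post_origin": (1.0, -0.8, 0.3),
    "pct_proximal": (1.0, 0.5, -2.0),
    "pb_ant_origin": (1.0, -0.5, -3.0),
    "pb_post_origin": (0.5, -1.5, -4.0),
    # Group I only: PB central bands are the edges of the PB proper.
    "pb_antcen_origin": (0.5, -0.5, -3.5),
    "pb_postcen_origin": (0.5, -0.5, -7.5),
}

_INSERTIONS = {
    "act_distal": (-20.0, -13.0, 22.5),
    "ab_ant_insertion": (-22.0, -8.5, 13.5),
    "ab_post_insertion": (-22.0, -9.5, 11.0),
    "pct_distal": (-20.0, -12.0, 20.0),
    "pb_ant_insertion": (-16.0, -1.0, -4.5),
    "pb_antcen_insertion": (-15.0, -1.0, -5.0),
    "pb_postcen_insertion": (-15.0, -0.5, -5.5),
    "pb_post_insertion": (-13.0, -0.5, -7.0),
}

# Group-conditional deterministic shifts (same keys as above). Group II has a
# capsular PB (slightly different fan); Group III is the continuous-sheet
# morphology where AB1 sits at the ACT posterior edge, AB3 at the PCT
# anterior edge, and the PCT behaves like an anterior structure.
_GROUP_SHIFTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "I": {},
    "II": {
        "act_proximal": (0.0, 0.3, 1.4),
        "ab_ant_origin": (0.0, 0.3, 1.1),
        "ab_post_origin": (0.0, 0.2, 1.1),
        "pb_antcen_insertion": (0.0, -2.0, 11.0),
        "pb_post_insertion": (0.5, -2.5, 12.0),
    },
    "III": {
        "ab_ant_origin": (0.0, 0.5, 1.5),
        "ab_post_origin": (0.0, 0.3, 1.5),
        "pct_proximal": (0.0, 0.0, 4.0),
        "pct_distal": (0.0, 2.0, 2.0),
        "pb_antcen_insertion": (0.0, -2.0, 11.0),
        "pb_postcen_insertion": (0.0, -2.5, 9.0),
        "pb_post_insertion": (0.5, -2.5, 12.0),
    },
}


def generate_specimen(params: GeneratorParams) -> SpecimenLandmarks:
    """Build a full synthetic specimen for the configured morphology group.

    Attachment sites are deterministic given the parameters; only the
    humeral-head cloud carries (seeded) digitizer noise. For Groups II and
    III the PB central origin sites are placed exactly ``pb_central_offset``
    mm anterior and posterior of the medial epicondyle tip.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    half_width = params.epicondyle_width / 2.0
    me = np.array([-half_width, 0.0, 0.0])
    le = np.array([half_width, 0.0, 0.0])
    cloud = generate_humeral_head(params, rng=rng)

    shifts = _GROUP_SHIFTS[params.group]
    points: dict[str, np.ndarray] = {}
    for name, offset in _ORIGIN_OFFSETS.items():
        points[name] = me + np.asarray(offset) + np.asarray(shifts.get(name, (0.0, 0.0, 0.0)))
    for name, pos in _INSERTIONS.items():
        points[name] = np.asarray(pos) + np.asarray(shifts.get(name, (0.0, 0.0, 0.0)))

    if params.group in ("II", "III"):
        # Capsule digitization sites straddling the medial epicondyle tip
        # along the anterior-posterior direction.
        points["pb_antcen_origin"] = me + np.array([0.0, 0.0, params.pb_central_offset])
        points["pb_postcen_origin"] = me + np.array([0.0, 0.0, -params.pb_central_offset])

    landmarks = SpecimenLandmarks(
        specimen_id=f"synthetic-{params.group}-{params.seed}",
        group=params.group,
        side="left",
        medial_epicondyle_tip=me,
        lateral_epicondyle_tip=le,
        humeral_head_cloud=cloud,
        **points,
    )
    if params.side == "right":
        landmarks = _mirror(landmarks)
    return landmarks


def _mirror(landmarks: SpecimenLandmarks) -> SpecimenLandmarks:
    """Mirror a left specimen into an anatomically equivalent right one."""
    flipped = landmarks.copy()
    flipped.side = "right"
    for name, p in list(flipped.attachment_items()):
        q = p.copy()
        q[0] = -q[0]
        setattr(flipped, name, q)
    for name in ("medial_epicondyle_tip", "lateral_epicondyle_tip"):
        q = getattr(flipped, name).copy()
        q[0] = -q[0]
        setattr(flipped, name, q)
    cloud = flipped.humeral_head_cloud.copy()
    cloud[:, 0] = -cloud[:, 0]
    flipped.humeral_head_cloud = cloud
    return flipped


def perturb_specimen(
    landmarks: SpecimenLandmarks,
    noise_sd: float,
    seed: int,
    include_cloud: bool = False,
) -> SpecimenLandmarks:
    """Add isotropic Gaussian noise to every attachment point.

    Used for digitization-noise sensitivity studies; the head cloud is left
    untouched unless ``include_cloud`` is set. Deterministic per seed;
    ``noise_sd = 0`` returns an identical copy.
    """
    if noise_sd < 0:
        raise InvalidParamsError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = landmarks.copy()
    for name, p in list(noisy.attachment_items()):
        setattr(noisy, name, p + rng.normal(0.0, noise_sd, size=3))
    if include_cloud:
        noisy.humeral_head_cloud = noisy.humeral_head_cloud + rng.normal(
            0.0, noise_sd, size=noisy.humeral_head_cloud.shape
        )
    return noisy
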