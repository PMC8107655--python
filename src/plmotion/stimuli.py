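"""Synthetic point-light stimuli: birds in flight and human walkers.

The original displays came from manually tagged bird videos (7 dots: beak,
2 body, 4 wing points; 75 frames at 30 Hz, ~4.8 x 2.1 deg) and a
motion-capture walker shown at seven profile views 150-210 deg (13 dots;
30 frames at 30 Hz, ~2.5 x 5.5 deg).  Those files are unavailable, so these
generators produce parametric stand-ins that honour the contractual facts:
dot counts, durations, angular extents, and the axis of dominant motion —
vertical for flapping birds, horizontal for walking humans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import ScreenGeometry, Trajectory, center_and_scale

__all__ = [
    "StimulusSpec",
    "BIRD_SPEC",
    "HUMAN_SPEC",
    "WALKER_VIEW_ANGLES",
    "generate_bird_trajectory",
    "generate_walker_trajectory",
    "generate_stimulus",
]

WALKER_VIEW_ANGLES = tuple(range(150, 211, 10))

_BIRD_SPECIES = ("crane", "crow", "duck", "eagle", "heron", "seagull", "swan")


@dataclass(frozen=True)
class StimulusSpec:
    """What to synthesize: object domain, orientation, facing, and geometry.

    ``exemplar_id`` is a bird species index (1-7) or a walker view angle
    (150-210 in 10 deg steps).  Durations and extents default to the
    domain-standard values: birds 2.5 s and 4.8 x 2.1 deg, humans 1 s and
    2.5 x 5.5 deg, both at 30 Hz.
    """

    domain: str  # "bird" | "human"
    orientation: str = "upright"  # "upright" | "inverted"
    facing: str = "right"  # "left" | "right"
    exemplar_id: int = 1
    duration_s: float = 0.0  # 0 -> domain default
    extent_deg: tuple[float, float] = (0.0, 0.0)  # (width, height); 0 -> default

    def __post_init__(self) -> None:
        if self.domain not in ("bird", "human"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.orientation not in ("upright", "inverted"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.facing not in ("left", "right"):
            raise ValueError(f"unknown facing {self.facing!r}")
        if self.domain == "bird":
            if self.duration_s == 0.0:
                object.__setattr__(self, "duration_s", 2.5)
            if self.extent_deg == (0.0, 0.0):
                object.__setattr__(self, "extent_deg", (4.8, 2.1))
            if not 1 <= self.exemplar_id <= len(_BIRD_SPECIES):
                raise ValueError(
                    f"bird exemplar_id must be 1-{len(_BIRD_SPECIES)}, "
                    f"got {self.exemplar_id}"
                )
        else:
            if self.duration_s == 0.0:
                object.__setattr__(self, "duration_s", 1.0)
            if self.extent_deg == (0.0, 0.0):
                object.__setattr__(self, "extent_deg", (2.5, 5.5))
            if self.exemplar_id not in WALKER_VIEW_ANGLES:
                raise ValueError(
                    f"walker view angle must be in {WALKER_VIEW_ANGLES}, "
                    f"got {self.exemplar_id}"
                )


BIRD_SPEC = StimulusSpec(domain="bird")
HUMAN_SPEC = StimulusSpec(domain="human", exemplar_id=180)

_BIRD_LABELS = ["beak", "body_front", "body_rear", "wing_mid_l", "wing_tip_l",
                "wing_mid_r", "wing_tip_r"]

_WALKER_LABELS = ["head", "shoulder_l", "shoulder_r", "elbow_l", "elbow_r",
                  "wrist_l", "wrist_r", "hip_l", "hip_r", "knee_l", "knee_r",
                  "foot_l", "foot_r"]


def generate_bird_trajectory(
    spec: StimulusSpec,
    rng: np.random.Generator,
    *,
    flap_amplitude: float = 0.16,
    flap_frequency_hz: float = 2.0,
    flap_phase: float = 0.0,
    glide_span: float = 0.6,
    jitter_sd: float = 0.01,
    screen: ScreenGeometry | None = None,
) -> Trajectory:
    """Synthesize a 7-dot flying bird: 2 body dots and a beak on a central
    horizontal axis with small positional jitter, plus 4 wing dots (mid-wing
    and wing-tip per side) flapping sinusoidally and in phase, the whole
    bird gliding slowly across its bounding rectangle.

    Wing-tip flap amplitude is ``flap_amplitude`` (body-length units before
    scaling), mid-wing half that; ``glide_span`` is the horizontal distance
    the bird covers over the clip.  The glide widens the bounding rectangle
    so the dots themselves sit fairly close to the display center, as with
    footage of a bird traversing the frame.  Amplitudes are kept small
    relative to the static footprint so every dot's travel fits inside any
    scrambler grid segment (bounding rectangle / 3 plus the 25 px slack).
    The output is centered on the origin and scaled to ``spec.extent_deg``;
    the flapping makes mean |dy| per frame exceed mean |dx|.  A zero
    ``flap_amplitude`` freezes the wings (still a valid trajectory); a
    non-positive ``flap_frequency_hz`` is an error.
    """
    if spec.domain != "bird":
        raise ValueError("generate_bird_trajectory requires a bird spec")
    if flap_frequency_hz <= 0:
        raise ValueError("flap frequency must be positive")
    screen = screen or ScreenGeometry()
    n_frames = screen.seconds_to_frames(spec.duration_s)
    t = np.arange(n_frames) / screen.frame_rate
    phase = 2.0 * np.pi * flap_frequency_hz * t + flap_phase
    # species differ slightly in wingbeat phase offset and body proportions
    species_shift = 0.15 * (spec.exemplar_id - 1)
    glide = np.linspace(-glide_span / 2, glide_span / 2, n_frames)

    coords = np.zeros((7, n_frames, 2))
    # axis dots: beak + 2 body (tail end hangs low), small per-frame jitter
    axis_x = np.array([0.30, 0.02, -0.22]) + species_shift * 0.01
    axis_y = np.array([-0.10, 0.00, -0.28])
    for k in range(3):
        coords[k, :, 0] = axis_x[k] + glide + rng.normal(0.0, jitter_sd, n_frames)
        coords[k, :, 1] = axis_y[k] + rng.normal(0.0, jitter_sd, n_frames)
    # wing dots: glide in x, sinusoidal y about a raised rest position
    flap = np.sin(phase + species_shift)
    wings = [(-0.18, 0.10, 0.5), (-0.50, 0.14, 1.0),   # left mid, tip
             (0.18, 0.10, 0.5), (0.50, 0.14, 1.0)]     # right mid, tip
    for k, (wx, wy, rel_amp) in enumerate(wings):
        coords[3 + k, :, 0] = wx + glide
        coords[3 + k, :, 1] = wy + rel_amp * flap_amplitude * flap

    traj = Trajectory(coords, screen.frame_rate, list(_BIRD_LABELS))
    return center_and_scale(traj, spec.extent_deg[0], spec.extent_deg[1], screen)


def generate_walker_trajectory(
    spec: StimulusSpec,
    rng: np.random.Generator,
    *,
    gait_frequency_hz: float = 1.0,
    stride_amplitude: float = 0.25,
    arm_amplitude: float = 0.20,
    bob_amplitude: float = 0.03,
    screen: ScreenGeometry | None = None,
) -> Trajectory:
    """Synthesize a 13-dot treadmill walker (head, shoulders, elbows, wrists,
    hips, knees, feet) as a 3-D articulated sinusoidal gait, orthographically
    projected at the requested profile view angle (``spec.exemplar_id``,
    150-210 deg; 180 = pure profile).

    Left and right limbs swing in counter-phase along the walking axis; a
    small double-frequency vertical bob moves the trunk.  There is no net
    translation.  The result is centered and scaled to ``spec.extent_deg``,
    and limb swing makes mean |dx| per frame exceed mean |dy|.  Zero
    amplitudes give a static posture (all displacements zero).
    """
    if spec.domain != "human":
        raise ValueError("generate_walker_trajectory requires a human spec")
    view = spec.exemplar_id  # validated by StimulusSpec
    screen = screen or ScreenGeometry()
    n_frames = screen.seconds_to_frames(spec.duration_s)
    t = np.arange(n_frames) / screen.frame_rate
    w = 2.0 * np.pi * gait_frequency_hz
    # gait phase: right-side limbs at phase 0, left-side at pi
    ph_r = w * t
    ph_l = w * t + np.pi
    bob = bob_amplitude * np.sin(2.0 * w * t)

    # body-frame joints: x = walking axis, y = vertical, z = lateral (meters).
    # limb swing amplitudes are fractions of the stride/arm amplitudes so that
    # zero amplitudes yield a fully static posture; the static foot stance is
    # wide enough that a foot's full swing fits inside any scrambler grid
    # segment (bounding rectangle / 3 plus the 25 px slack).
    st, ar = stride_amplitude, arm_amplitude
    # (label, base_x, base_y, base_z, swing_amp, phase, bob_frac)
    joints = [
        ("head",        0.00, 1.75,  0.00, 0.00 * st, ph_r, 1.0),
        ("shoulder_l",  0.00, 1.50,  0.20, 0.12 * ar, ph_l, 1.0),
        ("shoulder_r",  0.00, 1.50, -0.20, 0.12 * ar, ph_r, 1.0),
        ("elbow_l",    -0.02, 1.20,  0.22, 0.55 * ar, ph_l, 0.8),
        ("elbow_r",    -0.02, 1.20, -0.22, 0.55 * ar, ph_r, 0.8),
        ("wrist_l",     0.05, 0.95,  0.22, 1.00 * ar, ph_l, 0.6),
        ("wrist_r",    -0.05, 0.95, -0.22, 1.00 * ar, ph_r, 0.6),
        ("hip_l",       0.00, 1.00,  0.12, 0.15 * st, ph_r, 1.0),
        ("hip_r",       0.00, 1.00, -0.12, 0.15 * st, ph_l, 1.0),
        ("knee_l",      0.02, 0.55,  0.14, 0.60 * st, ph_r, 0.4),
        ("knee_r",     -0.02, 0.55, -0.14, 0.60 * st, ph_l, 0.4),
        ("foot_l",      0.20, 0.10,  0.16, 1.00 * st, ph_r, 0.2),
        ("foot_r",     -0.20, 0.10, -0.16, 1.00 * st, ph_l, 0.2),
    ]
    # orthographic projection: deviation from pure profile rotates the
    # lateral axis into view
    dev = np.deg2rad(view - 180.0)
    cos_d, sin_d = np.cos(dev), np.sin(dev)

    coords = np.zeros((13, n_frames, 2))
    for k, (_, bx, by, bz, amp, ph, bobf) in enumerate(joints):
        x3 = bx + amp * np.sin(ph)
        y3 = by + bobf * bob
        z3 = bz
        coords[k, :, 0] = x3 * cos_d + z3 * sin_d
        coords[k, :, 1] = y3

    traj = Trajectory(coords, screen.frame_rate, list(_WALKER_LABELS))
    return center_and_scale(traj, spec.extent_deg[0], spec.extent_deg[1], screen)


def generate_stimulus(
    spec: StimulusSpec, rng: np.random.Generator, screen: ScreenGeometry | None = None
) -> Trajectory:
    """Generate a signal trajectory for *spec*, applying orientation and facing.

    Inversion is a literal 180 deg picture-plane rotation (point reflection);
    facing "left" mirrors x about the vertical midline.
    """
    from .trajectory import invert, mirror_facing

    if spec.domain == "bird":
        traj = generate_bird_trajectory(spec, rng, screen=screen)
    else:
        traj = generate_walker_trajectory(spec, rng, screen=screen)
    if spec.facing == "left":
        traj = mirror_facing(traj)
    if spec.orientation == "inverted":
        traj = invert(traj)
    return traj
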