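"""Point-light trajectories: container, geometric transforms, motion metrics, I/O.

A point-light (PL) display is a set of dots, each tracing a 2-D path over a
fixed number of frames.  Coordinates are in screen pixels with y increasing
upward and, after centering, the origin at the stimulus center.  All
transforms here are exact (no resampling), so displacement sequences — the
"local motion" that spatial scrambling must preserve — survive bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScreenGeometry",
    "Trajectory",
    "bounding_rect",
    "invert",
    "mirror_facing",
    "center_and_scale",
    "motion_stats",
    "inversion_displacement",
    "read_trajectory",
    "write_trajectory",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Display calibration: degrees of visual angle <-> pixels, frames <-> seconds.

    Parameters
    ----------
    pixels_per_degree
        Conversion factor in px/deg; default 40 (the original display's pixel
        geometry is a free parameter of the simulation).
    frame_rate
        Presentation rate in Hz; the stimuli here run at 30 Hz.
    """

    pixels_per_degree: float = 40.0
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def deg_to_px(self, deg: float) -> float:
        return deg * self.pixels_per_degree

    def px_to_deg(self, px: float) -> float:
        return px / self.pixels_per_degree

    def seconds_to_frames(self, s: float) -> int:
        return int(round(s * self.frame_rate))


@dataclass
class Trajectory:
    """Per-dot, per-frame 2-D positions of a point-light display.

    Attributes
    ----------
    coords
        Array of shape (n_dots, n_frames, 2) holding (x, y) in pixels.
    frame_rate
        Frames per second.
    labels
        One role tag per dot (e.g. ``beak``, ``hip_l``, ``noise``).
    """

    coords: np.ndarray
    frame_rate: float = 30.0
    labels: list[str] = field(default_factory=list)

    #: coordinates are snapped to this binary grid (about 1e-9 px).  With all
    #: positions on a common power-of-two grid and magnitudes below ~8e6 px,
    #: translations and point reflections are exact in double precision, so
    #: scrambling preserves displacement sequences bit-for-bit.
    GRID: float = 2.0**-30

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n_dots, n_frames, 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")
        if np.abs(self.coords).max(initial=0.0) >= 2.0**22:
            raise ValueError("coordinates out of range (|px| < 4194304)")
        self.coords = np.round(self.coords / self.GRID) * self.GRID
        if self.coords.shape[0] > 0 and self.coords.shape[1] < 2:
            raise ValueError("trajectories need at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.labels:
            self.labels = [f"dot{i}" for i in range(self.coords.shape[0])]
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels must have one entry per dot")

    @property
    def n_dots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def displacements(self) -> np.ndarray:
        """Frame-to-frame displacement sequences, shape (n_dots, n_frames-1, 2)."""
        return np.diff(self.coords, axis=1)

    def copy(self) -> "Trajectory":
        return Trajectory(self.coords.copy(), self.frame_rate, list(self.labels))


def bounding_rect(traj: Trajectory) -> tuple[float, float, float, float]:
    """Tight bounding rectangle (xmin, ymin, xmax, ymax) over all dots and frames.

    A static single dot yields a degenerate zero-area rectangle; callers that
    need interior room (scrambling) reject that case themselves.
    """
    if traj.n_dots == 0:
        raise ValueError("empty trajectory has no bounding rectangle")
    xy = traj.coords.reshape(-1, 2)
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    return float(xmin), float(ymin), float(xmax), float(ymax)


def _rect_center(traj: Trajectory) -> tuple[float, float]:
    xmin, ymin, xmax, ymax = bounding_rect(traj)
    return (xmin + xmax) / 2.0, (ymin + ymax) / 2.0


def invert(traj: Trajectory) -> Trajectory:
    """Rotate a display 180 deg in the picture plane (point reflection).

    Every position (x, y) maps to (2*cx - x, 2*cy - y) about the bounding
    rectangle's center (cx, cy).  An involution; per-transition displacement
    magnitudes are preserved exactly (each displacement is negated).
    """
    cx, cy = _rect_center(traj)
    coords = np.empty_like(traj.coords)
    coords[..., 0] = 2.0 * cx - traj.coords[..., 0]
    coords[..., 1] = 2.0 * cy - traj.coords[..., 1]
    return replace(traj.copy(), coords=coords)


def mirror_facing(traj: Trajectory) -> Trajectory:
    """Reflect x about the bounding rectangle's vertical midline (left<->right)."""
    cx, _ = _rect_center(traj)
    coords = traj.coords.copy()
    coords[..., 0] = 2.0 * cx - coords[..., 0]
    return replace(traj.copy(), coords=coords)


def center_and_scale(
    traj: Trajectory,
    width_deg: float,
    height_deg: float,
    screen: ScreenGeometry | None = None,
) -> Trajectory:
    """Center a display on the origin and scale it to a target angular extent.

    x and y are rescaled independently so the bounding rectangle becomes
    exactly ``width_deg x height_deg`` (converted to pixels via *screen*),
    centered on (0, 0).  Raises on zero-extent input.
    """
    screen = screen or ScreenGeometry(frame_rate=traj.frame_rate)
    xmin, ymin, xmax, ymax = bounding_rect(traj)
    w, h = xmax - xmin, ymax - ymin
    if w <= 0 or h <= 0:
        raise ValueError("cannot scale a zero-extent trajectory")
    tw = screen.deg_to_px(width_deg)
    th = screen.deg_to_px(height_deg)
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    coords = np.empty_like(traj.coords)
    coords[..., 0] = (traj.coords[..., 0] - cx) * (tw / w)
    coords[..., 1] = (traj.coords[..., 1] - cy) * (th / h)
    return replace(traj.copy(), coords=coords)


def motion_stats(traj: Trajectory) -> tuple[float, float]:
    """Mean per-frame |dx| and |dy| in px/frame over all dots and transitions.

    Birds in flight move predominantly vertically (wing flapping), walkers
    predominantly horizontally (limb swing); this statistic quantifies that
    axis asymmetry.
    """
    d = traj.displacements()
    return float(np.abs(d[..., 0]).mean()), float(np.abs(d[..., 1]).mean())


def inversion_displacement(traj: Trajectory) -> float:
    """Mean Euclidean distance each dot-frame moves under picture-plane inversion.

    Equals twice the mean distance of the points from the bounding-rectangle
    center, so displays whose dots lie far from center (e.g. tall walkers)
    are displaced more by inversion than compact ones.
    """
    cx, cy = _rect_center(traj)
    r = np.hypot(traj.coords[..., 0] - cx, traj.coords[..., 1] - cy)
    return float(2.0 * r.mean())


# ---------------------------------------------------------------------------
# Serialization: delimited text, one row per dot-frame, structured header.
# ---------------------------------------------------------------------------

_MAGIC = "# plmotion trajectory v1"


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as delimited text (lossless at full float precision).

    Format: a header line, a metadata line with n_dots/n_frames/frame_rate,
    a column-name line, then one CSV row per dot-frame:
    ``dot_id,frame,x,y,label``.
    """
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(
            f"# n_dots={traj.n_dots} n_frames={traj.n_frames} "
            f"frame_rate={traj.frame_rate!r}\n"
        )
        fh.write("dot_id,frame,x,y,label\n")
        for i in range(traj.n_dots):
            lab = traj.labels[i]
            for t in range(traj.n_frames):
                x, y = traj.coords[i, t]
                fh.write(f"{i},{t},{float(x)!r},{float(y)!r},{lab}\n")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Raises ``ValueError`` on malformed rows or inconsistent frame counts.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not a plmotion trajectory file")
    meta = dict(kv.split("=") for kv in lines[1].lstrip("# ").split())
    n_dots, n_frames = int(meta["n_dots"]), int(meta["n_frames"])
    frame_rate = float(meta["frame_rate"])
    if lines[2] != "dot_id,frame,x,y,label":
        raise ValueError(f"{path}: unexpected column header")
    coords = np.full((n_dots, n_frames, 2), np.nan)
    labels: list[str | None] = [None] * n_dots
    for ln in lines[3:]:
        if not ln:
            continue
        parts = ln.split(",")
        if len(parts) != 5:
            raise ValueError(f"{path}: malformed row {ln!r}")
        i, t = int(parts[0]), int(parts[1])
        if not (0 <= i < n_dots and 0 <= t < n_frames):
            raise ValueError(f"{path}: dot/frame index out of range in {ln!r}")
        coords[i, t] = (float(parts[2]), float(parts[3]))
        if labels[i] is None:
            labels[i] = parts[4]
        elif labels[i] != parts[4]:
            raise ValueError(f"{path}: inconsistent label for dot {i}")
    if np.isnan(coords).any():
        raise ValueError(f"{path}: missing dot-frame rows (ragged frame counts?)")
    return Trajectory(coords, frame_rate, [str(l) for l in labels])
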