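"""Spatial scrambling and noise-dot generation.

Scrambling destroys the global configuration of a point-light display while
preserving each dot's local motion exactly: the dot keeps its frame-to-frame
displacement sequence and only its frame-1 position is redrawn.  New starting
positions are distributed as evenly as possible over a 3 x 3 grid covering
the display's bounding rectangle, and a repositioned dot is accepted only if
every frame of its path stays within the rectangle expanded by a slack margin
(25 px) on all sides.  Noise dots are built the same way from signal dots
sampled with replacement, so noise is statistically indistinguishable from
scrambled signal at the single-dot level — the display can only be recognized
from the relational structure of the signal dots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory, bounding_rect

__all__ = [
    "ScrambleConfig",
    "TrialStimulus",
    "assign_segments",
    "scramble",
    "make_noise_dots",
    "compose_trial",
    "configural_variance",
]


@dataclass(frozen=True)
class ScrambleConfig:
    """Grid geometry and containment slack for the scrambling procedure."""

    grid_rows: int = 3
    grid_cols: int = 3
    slack_px: float = 25.0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.slack_px < 0:
            raise ValueError("slack_px must be >= 0")

    @property
    def n_segments(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class TrialStimulus:
    """One trial's display: signal dots (intact or scrambled) plus noise dots,
    shuffled together so dot order carries no information."""

    dots: Trajectory
    n_signal: int
    n_noise: int
    truth: str  # "intact" | "scrambled"
    condition: tuple[str, str] = ("", "")  # (domain, orientation)

    def __post_init__(self) -> None:
        if self.truth not in ("intact", "scrambled"):
            raise ValueError(f"truth must be intact/scrambled, got {self.truth!r}")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if self.dots.n_dots != self.n_signal + self.n_noise:
            raise ValueError("dot count must equal n_signal + n_noise")


def assign_segments(
    n_items: int, config: ScrambleConfig, rng: np.random.Generator
) -> np.ndarray:
    """Assign items to grid segments as evenly as possible.

    Every segment receives floor(n/k) or ceil(n/k) items (k = number of
    segments); the segments taking the extra item are chosen uniformly
    without replacement, and the item -> segment mapping is then randomly
    permuted.  Returns an int array of length ``n_items``.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    k = config.n_segments
    base, extra = divmod(n_items, k)
    counts = np.full(k, base, dtype=int)
    if extra:
        counts[rng.choice(k, size=extra, replace=False)] += 1
    segments = np.repeat(np.arange(k), counts)
    return rng.permutation(segments)


def _segment_box(
    rect: tuple[float, float, float, float], seg: int, config: ScrambleConfig
) -> tuple[float, float, float, float]:
    """(xmin, ymin, xmax, ymax) of one grid segment; segments are numbered
    row-major from the bottom-left of the bounding rectangle."""
    xmin, ymin, xmax, ymax = rect
    row, col = divmod(seg, config.grid_cols)
    sw = (xmax - xmin) / config.grid_cols
    sh = (ymax - ymin) / config.grid_rows
    return (xmin + col * sw, ymin + row * sh, xmin + (col + 1) * sw, ymin + (row + 1) * sh)


def _reposition_dot(
    path_offsets: np.ndarray,
    rect: tuple[float, float, float, float],
    seg: int,
    config: ScrambleConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a frame-1 position uniformly in the segment, rejecting candidates
    whose full path leaves the rectangle expanded by slack_px; returns the
    accepted (x, y)."""
    sx0, sy0, sx1, sy1 = _segment_box(rect, seg, config)
    xmin, ymin, xmax, ymax = rect
    # tiny margin so the start can be snapped to the coordinate grid without
    # ever pushing a frame past the slack boundary
    s = config.slack_px - 2.0 * Trajectory.GRID
    lo_off = path_offsets.min(axis=0)  # (min dx, min dy) over frames
    hi_off = path_offsets.max(axis=0)
    batch = 64
    drawn = 0
    while drawn < config.max_attempts:
        cand = rng.uniform((sx0, sy0), (sx1, sy1), size=(batch, 2))
        drawn += batch
        ok = (
            (cand[:, 0] + lo_off[0] >= xmin - s)
            & (cand[:, 0] + hi_off[0] <= xmax + s)
            & (cand[:, 1] + lo_off[1] >= ymin - s)
            & (cand[:, 1] + hi_off[1] <= ymax + s)
        )
        hits = np.nonzero(ok)[0]
        if hits.size:
            return cand[hits[0]]
    raise RuntimeError(
        "scramble: no admissible starting position found after "
        f"{config.max_attempts} attempts (dot travel exceeds the bounding "
        "rectangle plus slack; enlarge slack_px)"
    )


def _replayed_path(
    path: np.ndarray,
    rect: tuple[float, float, float, float],
    seg: int,
    config: ScrambleConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replay *path* from a freshly drawn start: a pure translation by a
    grid-snapped shift, which is exact in double precision and therefore
    preserves the displacement sequence bit-for-bit."""
    offsets = path - path[0]
    start = _reposition_dot(offsets, rect, seg, config, rng)
    grid = Trajectory.GRID
    shift = np.round((start - path[0]) / grid) * grid
    return path + shift


def scramble(
    traj: Trajectory,
    config: ScrambleConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Spatially scramble a display, preserving local motion exactly.

    Each dot's frame-1 position is redrawn inside its assigned grid segment
    (rejection sampling under the all-frames containment constraint); the
    dot's displacement sequence is then replayed verbatim from the new start.
    Raises on a degenerate (zero-area) bounding rectangle.
    """
    config = config or ScrambleConfig()
    rng = rng if rng is not None else np.random.default_rng()
    rect = bounding_rect(traj)
    if rect[2] - rect[0] <= 0 or rect[3] - rect[1] <= 0:
        raise ValueError("cannot scramble a zero-area display")
    segs = assign_segments(traj.n_dots, config, rng)
    coords = np.empty_like(traj.coords)
    for i in range(traj.n_dots):
        coords[i] = _replayed_path(traj.coords[i], rect, segs[i], config, rng)
    return Trajectory(coords, traj.frame_rate, list(traj.labels))


def make_noise_dots(
    traj: Trajectory,
    n_noise: int,
    config: ScrambleConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Generate noise dots from a signal display.

    Each noise dot copies, with replacement, one signal dot's displacement
    sequence and is repositioned by the scrambling rule; segment assignment
    is computed over the noise set itself.  ``n_noise = 0`` yields an empty
    trajectory.
    """
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    config = config or ScrambleConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if n_noise == 0:
        return Trajectory(
            np.empty((0, traj.n_frames, 2)), traj.frame_rate, []
        )
    rect = bounding_rect(traj)
    if rect[2] - rect[0] <= 0 or rect[3] - rect[1] <= 0:
        raise ValueError("cannot build noise from a zero-area display")
    sources = rng.integers(0, traj.n_dots, size=n_noise)
    segs = assign_segments(n_noise, config, rng)
    coords = np.empty((n_noise, traj.n_frames, 2))
    for j in range(n_noise):
        coords[j] = _replayed_path(traj.coords[sources[j]], rect, segs[j], config, rng)
    return Trajectory(coords, traj.frame_rate, ["noise"] * n_noise)


def compose_trial(
    signal: Trajectory,
    truth: str,
    n_noise: int,
    config: ScrambleConfig | None = None,
    rng: np.random.Generator | None = None,
    condition: tuple[str, str] = ("", ""),
) -> TrialStimulus:
    """Build one trial's display: (optionally scrambled) signal plus noise,
    with dot order uniformly shuffled so identity does not leak through
    ordering.  Noise dots are generated from the un-scrambled signal, whose
    bounding rectangle defines the grid for both."""
    if truth not in ("intact", "scrambled"):
        raise ValueError(f"truth must be intact/scrambled, got {truth!r}")
    config = config or ScrambleConfig()
    rng = rng if rng is not None else np.random.default_rng()
    shown = scramble(signal, config, rng) if truth == "scrambled" else signal
    noise = make_noise_dots(signal, n_noise, config, rng)
    coords = np.concatenate([shown.coords, noise.coords], axis=0)
    labels = list(shown.labels) + list(noise.labels)
    order = rng.permutation(coords.shape[0])
    dots = Trajectory(coords[order], signal.frame_rate, [labels[i] for i in order])
    return TrialStimulus(
        dots=dots,
        n_signal=signal.n_dots,
        n_noise=n_noise,
        truth=truth,
        condition=condition,
    )


def configural_variance(traj: Trajectory, i: int, j: int) -> float:
    """Variance over frames of the distance between dots *i* and *j*.

    Zero for a rigidly co-moving pair (the configural structure scrambling
    destroys); strictly positive once the pair's motions differ.
    """
    d = traj.coords[i] - traj.coords[j]
    return float(np.hypot(d[:, 0], d[:, 1]).var())
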