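"""Spatial scrambling: local-motion preservation, containment, evenness."""

import numpy as np
import pytest

from plmotion import (
    ScrambleConfig,
    Trajectory,
    assign_segments,
    bounding_rect,
    compose_trial,
    configural_variance,
    make_noise_dots,
    scramble,
)


def _within(coords, rect, slack):
    xmin, ymin, xmax, ymax = rect
    xy = coords.reshape(-1, 2)
    return bool(
        (xy[:, 0] >= xmin - slack).all()
        and (xy[:, 0] <= xmax + slack).all()
        and (xy[:, 1] >= ymin - slack).all()
        and (xy[:, 1] <= ymax + slack).all()
    )


class TestAssignSegments:
    def test_seven_items_seven_distinct_segments(self, rng):
        segs = assign_segments(7, ScrambleConfig(), rng)
        assert len(segs) == 7
        assert len(set(segs.tolist())) == 7  # one per segment, two empty

    def test_nine_items_cover_all_segments(self, rng):
        segs = assign_segments(9, ScrambleConfig(), rng)
        assert sorted(segs.tolist()) == list(range(9))

    def test_thirteen_items_occupancy_pattern(self):
        # 13 over 9 segments: always four segments of 2 and five of 1
        for seed in range(1000):
            segs = assign_segments(13, ScrambleConfig(), np.random.default_rng(seed))
            occ = sorted(np.bincount(segs, minlength=9).tolist())
            assert occ == [1, 1, 1, 1, 1, 2, 2, 2, 2]

    def test_extra_segments_uniform(self):
        # with 10 items the doubled segment should be uniform over the nine
        counts = np.zeros(9, int)
        for seed in range(3000):
            segs = assign_segments(10, ScrambleConfig(), np.random.default_rng(seed))
            occ = np.bincount(segs, minlength=9)
            counts[np.argmax(occ)] += 1
        expected = 3000 / 9
        assert np.abs(counts - expected).max() < 5 * np.sqrt(expected)

    def test_invalid_n(self, rng):
        with pytest.raises(ValueError):
            assign_segments(0, ScrambleConfig(), rng)


class TestScramble:
    def test_displacements_preserved_exactly(self, bird, rng):
        out = scramble(bird, rng=rng)
        assert np.array_equal(out.displacements(), bird.displacements())
        assert (out.n_dots, out.n_frames) == (bird.n_dots, bird.n_frames)

    def test_containment_over_many_seeds(self, bird):
        rect = bounding_rect(bird)
        for seed in range(200):
            out = scramble(bird, rng=np.random.default_rng(seed))
            assert _within(out.coords, rect, 25.0)

    def test_static_dots_land_in_distinct_segments(self, rng):
        sq = Trajectory(np.tile(
            np.array([[0, 0], [90, 0], [0, 90], [90, 90]], float)[:, None, :],
            (1, 5, 1),
        ))
        out = scramble(sq, rng=rng)
        assert np.all(out.displacements() == 0.0)
        assert _within(out.coords, (0, 0, 90, 90), 25.0)

    def test_degenerate_rect_rejected(self, rng):
        t = Trajectory(np.zeros((2, 3, 2)))
        with pytest.raises(ValueError):
            scramble(t, rng=rng)

    def test_infeasible_travel_raises(self, rng):
        # a dot traveling far beyond the rectangle + slack cannot be placed
        coords = np.zeros((2, 3, 2))
        coords[0] = [(0, 0), (500, 0), (0, 500)]
        coords[1] = [(10, 10), (11, 10), (12, 10)]
        t = Trajectory(coords)
        with pytest.raises(RuntimeError, match="slack"):
            scramble(t, ScrambleConfig(max_attempts=500), rng)

    def test_configural_statistic(self, rng):
        # rigid pair (shared displacement sequence): distance variance is 0
        # and remains 0 after scrambling, because local motion is preserved
        base = np.stack([np.linspace(0, 30, 10), np.linspace(0, 30, 10)], axis=1)
        rigid = Trajectory(np.stack([base, base + [40.0, 10.0]]))
        assert configural_variance(rigid, 0, 1) == 0.0
        out = scramble(rigid, rng=rng)
        assert configural_variance(out, 0, 1) == pytest.approx(0.0, abs=1e-12)
        # dots with different motions: scrambling makes the pair non-rigid
        other = np.stack([np.linspace(0, 40, 10), np.linspace(30, 0, 10)], axis=1)
        mixed = Trajectory(np.stack([base, other + [40.0, 10.0]]))
        out = scramble(mixed, rng=rng)
        assert configural_variance(out, 0, 1) > 0.0


class TestNoise:
    def test_zero_noise_empty(self, bird, rng):
        out = make_noise_dots(bird, 0, rng=rng)
        assert out.n_dots == 0

    def test_noise_displacements_are_signal_displacements(self, bird, rng):
        out = make_noise_dots(bird, 20, rng=rng)
        assert out.n_dots == 20
        assert out.labels == ["noise"] * 20
        signal = {d.tobytes() for d in bird.displacements()}
        for d in out.displacements():
            assert d.tobytes() in signal

    def test_nine_noise_dots_one_per_segment(self, bird):
        cfg = ScrambleConfig()
        rect = bounding_rect(bird)
        xmin, ymin, xmax, ymax = rect
        sw, sh = (xmax - xmin) / 3, (ymax - ymin) / 3
        out = make_noise_dots(bird, 9, cfg, np.random.default_rng(0))
        col = np.clip(((out.coords[:, 0, 0] - xmin) // sw).astype(int), 0, 2)
        row = np.clip(((out.coords[:, 0, 1] - ymin) // sh).astype(int), 0, 2)
        assert len(set(zip(row.tolist(), col.tolist()))) == 9

    def test_containment(self, bird):
        rect = bounding_rect(bird)
        for seed in range(100):
            out = make_noise_dots(bird, 15, rng=np.random.default_rng(seed))
            assert _within(out.coords, rect, 25.0)


class TestComposeTrial:
    def test_intact_no_noise(self, bird, rng):
        tr = compose_trial(bird, "intact", 0, rng=rng)
        assert tr.dots.n_dots == 7
        assert tr.truth == "intact"
        # intact signal dots keep their configuration (just reordered)
        got = {c.tobytes() for c in tr.dots.coords}
        want = {c.tobytes() for c in bird.coords}
        assert got == want

    def test_scrambled_with_noise_counts(self, walker, rng):
        tr = compose_trial(walker, "scrambled", 8, rng=rng)
        assert tr.dots.n_dots == 21
        assert (tr.n_signal, tr.n_noise) == (13, 8)

    def test_seeded_reproducibility(self, bird):
        a = compose_trial(bird, "scrambled", 5, rng=np.random.default_rng(9))
        b = compose_trial(bird, "scrambled", 5, rng=np.random.default_rng(9))
        assert np.array_equal(a.dots.coords, b.dots.coords)
        assert a.dots.labels == b.dots.labels

    def test_order_shuffled(self, bird):
        # over seeds, the first dot is not always a signal dot
        first = [
            compose_trial(bird, "intact", 7, rng=np.random.default_rng(s))
            .dots.labels[0]
            for s in range(30)
        ]
        assert any(lab == "noise" for lab in first)
        assert any(lab != "noise" for lab in first)

    def test_bad_truth(self, bird, rng):
        with pytest.raises(ValueError):
            compose_trial(bird, "both", 0, rng=rng)
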