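import numpy as np
import pytest

from actogram import BackgroundModel, smd

from oracles import window_masks_loops, window_masks_oracle


def run_model(stack, **kw):
    model = BackgroundModel(**kw)
    return [model.apply(f) for f in stack]


class TestSMD:
    @pytest.mark.parametrize(
        "x, mu, var, expected",
        [
            (100, 100, 25, 0.0),
            (110, 100, 25, 4.0),
            (125, 100, 25, 25.0),  # crosses the default threshold of 20
        ],
    )
    def test_scalar_values(self, x, mu, var, expected):
        assert smd(x, mu, var) == pytest.approx(expected)

    def test_threshold_semantics(self):
        # a deviation of 25 grey levels at sigma^2=25 must be flagged at T=20
        assert smd(125, 100, 25) >= 20.0


class TestWindowMode:
    def test_constant_sequence_no_change(self, constant_stack):
        masks = run_model(constant_stack, history=28)
        assert not any(m.valid for m in masks[:28])
        for m in masks[28:]:
            assert m.valid
            assert m.mask.sum() == 0

    def test_warmup_masks_invalid(self, rng):
        stack = rng.integers(0, 256, (30, 8, 8), dtype=np.uint8)
        masks = run_model(stack, history=28)
        assert [m.valid for m in masks] == [False] * 28 + [True, True]
        assert [m.frame_index for m in masks] == list(range(30))

    def test_matches_vectorised_oracle(self, rng):
        stack = rng.integers(0, 256, (40, 16, 16), dtype=np.uint8)
        masks = run_model(stack, history=28)
        expected = window_masks_oracle(stack, history=28)
        for got, want in zip(masks[28:], expected):
            assert np.array_equal(got.mask, want)

    def test_matches_scalar_loop_oracle(self, rng):
        stack = rng.integers(0, 256, (12, 5, 6), dtype=np.uint8)
        masks = run_model(stack, history=8)
        expected = window_masks_loops(stack, 8, 20.0, 4.0)
        for got, want in zip(masks[8:], expected):
            assert np.array_equal(got.mask, want)

    def test_threshold_monotonicity(self, rng):
        stack = rng.integers(0, 256, (36, 12, 12), dtype=np.uint8)
        low = run_model(stack, history=28, threshold=10.0)
        high = run_model(stack, history=28, threshold=30.0)
        for lo, hi in zip(low[28:], high[28:]):
            # raising T can only clear pixels, never set new ones
            assert not np.any(hi.mask & ~lo.mask)

    def test_shift_invariance_with_wrap(self, rng):
        stack = rng.integers(0, 256, (34, 10, 14), dtype=np.uint8)
        shifted = np.roll(stack, shift=(3, 5), axis=(1, 2))
        base = run_model(stack, history=28)
        moved = run_model(shifted, history=28)
        for b, m in zip(base[28:], moved[28:]):
            assert np.array_equal(np.roll(b.mask, (3, 5), axis=(0, 1)), m.mask)

    def test_zero_noise_static_background_no_false_positives(self):
        frame = np.arange(64, dtype=np.uint8).reshape(8, 8)
        masks = run_model(np.repeat(frame[None], 40, axis=0), history=28)
        assert all(m.mask.sum() == 0 for m in masks if m.valid)

    def test_dimension_mismatch_rejected(self):
        model = BackgroundModel()
        model.apply(np.zeros((8, 8), np.uint8))
        with pytest.raises(ValueError, match="dimension mismatch"):
            model.apply(np.zeros((9, 9), np.uint8))

    @pytest.mark.parametrize(
        "kw", [{"history": 1}, {"threshold": 0}, {"variance_floor": 0},
               {"mode": "nope"}]
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            BackgroundModel(**kw)


class TestAdaptiveMode:
    def test_constant_sequence_no_change(self, constant_stack):
        masks = run_model(constant_stack, mode="adaptive")
        assert all(m.mask.sum() == 0 for m in masks if m.valid)
        assert any(m.valid for m in masks)

    def test_step_change_flagged_then_reabsorbed(self):
        # one pixel jumps 0 -> 200 and stays; the jump must be flagged and
        # then reabsorbed once the new component is designated background,
        # within a bound that follows from alpha and the background ratio
        frames = [np.zeros((6, 6), np.uint8) for _ in range(60)]
        for f in frames[35:]:
            f[3, 3] = 200
        masks = run_model(frames, mode="adaptive", history=28)
        flagged = [m.frame_index for m in masks if m.valid and m.mask[3, 3]]
        assert 35 in flagged
        alpha = 1.0 / 28
        bound = int(np.ceil(np.log(0.9) / np.log(1 - alpha))) + 1
        assert max(flagged) <= 35 + bound
        assert all(m.mask.sum() == 0 for m in masks[35 + bound + 1 :])

    def test_agrees_with_window_on_teleporting_blob(self):
        # high-contrast blob on zero-noise background, far jumps: both
        # maintenance strategies must produce the identical mask
        # positions run over a 7x7 grid of cells 7 px apart in a shuffled
        # order without any revisit (the adaptive mixture remembers old
        # appearances far longer than the sliding window does)
        stack = np.full((40, 52, 52), 50, dtype=np.uint8)
        rng = np.random.default_rng(7)
        cells = [(3 + 7 * i, 3 + 7 * j) for i in range(7) for j in range(7)]
        rng.shuffle(cells)
        pos = cells[:40]
        for f, (y, x) in zip(stack, pos):
            f[y - 1 : y + 2, x - 1 : x + 2] = 250
        win = run_model(stack, history=28, mode="window")
        ada = run_model(stack, history=28, mode="adaptive")
        for w, a in zip(win[28:], ada[28:]):
            assert np.array_equal(w.mask, a.mask)
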