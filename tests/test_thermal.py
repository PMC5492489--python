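"""Background model, imprint binarization and residual-heat disposal."""

import numpy as np
import pytest

from bedwatch.io import GRID_COLS, GRID_ROWS, FrameSequence
from bedwatch.thermal import (
    BackgroundModel,
    ImprintMask,
    ResidualHeatState,
    dispose_residual_heat,
    estimate_background,
    imprint_mask,
)

from conftest import make_frame, make_sequence


def flat_bg(value=420.0, n=10):
    return BackgroundModel(np.full((GRID_ROWS, GRID_COLS), value), n)


class TestBackground:
    def test_mean_of_constant_frames(self):
        seq = make_sequence([np.full((GRID_ROWS, GRID_COLS), 420)] * 10)
        bg = estimate_background(seq)
        assert bg.n_frames == 10
        assert np.all(bg.mean_grid == 420.0)

    def test_single_pixel_arithmetic_mean(self):
        grids = []
        for v in range(400, 410):
            g = np.full((GRID_ROWS, GRID_COLS), 420)
            g[5, 7] = v
            grids.append(g)
        bg = estimate_background(make_sequence(grids))
        assert bg.mean_grid[5, 7] == pytest.approx(404.5)

    def test_matches_brute_force_per_pixel_average(self, rng):
        grids = rng.integers(300, 700, size=(50, GRID_ROWS, GRID_COLS))
        bg = estimate_background(make_sequence(grids))
        # independent oracle: explicit per-pixel summation loop
        oracle = np.zeros((GRID_ROWS, GRID_COLS))
        for y in range(GRID_ROWS):
            for x in range(GRID_COLS):
                s = 0
                for g in grids:
                    s += int(g[y, x])
                oracle[y, x] = s / len(grids)
        assert np.allclose(bg.mean_grid, oracle, atol=1e-9)

    def test_empty_sequence_refused(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_background(FrameSequence([]))


class TestImprint:
    def test_frame_equal_to_background_gives_empty_mask(self):
        im = imprint_mask(make_frame(value=420), flat_bg())
        assert not im.mask.any()
        assert np.all(im.magnitude == 0.0)

    @pytest.mark.parametrize("delta", [21, -21])
    def test_single_deviating_pixel_flagged_either_sign(self, delta):
        g = np.full((GRID_ROWS, GRID_COLS), 420)
        g[12, 34] += delta
        im = imprint_mask(make_frame(grid=g), flat_bg(), threshold=20)
        assert im.mask.sum() == 1
        assert im.mask[12, 34]
        assert im.magnitude[12, 34] == 21.0

    def test_threshold_is_strict(self):
        g = np.full((GRID_ROWS, GRID_COLS), 440)  # exactly 20 above
        im = imprint_mask(make_frame(grid=g), flat_bg(), threshold=20)
        assert not im.mask.any()

    def test_deterministic_and_sign_invariant(self, rng):
        bg = flat_bg()
        g = rng.integers(380, 460, size=(GRID_ROWS, GRID_COLS))
        f = make_frame(grid=g)
        a = imprint_mask(f, bg)
        b = imprint_mask(f, bg)
        assert np.array_equal(a.mask, b.mask)
        mirrored = make_frame(grid=(2 * 420 - g))  # reflect deviations
        c = imprint_mask(mirrored, bg)
        assert np.allclose(a.magnitude, c.magnitude)
        assert np.array_equal(a.mask, c.mask)


def _imprint_from_amp(amp, threshold=20.0):
    amp = np.asarray(amp, dtype=float)
    return ImprintMask(mask=amp > threshold, magnitude=amp, threshold=threshold)


def _scene_amp(body_pos=None, body_peak=250.0, patch=None, patch_peak=0.0):
    """Build a magnitude grid with an optional 5x5 body and 6x6 patch."""
    amp = np.zeros((GRID_ROWS, GRID_COLS))
    if body_pos is not None:
        r, c = body_pos
        amp[r : r + 5, c : c + 5] = body_peak * 0.8
        amp[r + 2, c + 2] = body_peak
    if patch is not None:
        r, c = patch
        amp[r : r + 6, c : c + 6] = patch_peak
    return amp


class TestDisposal:
    def test_single_body_component_untouched(self):
        im = _imprint_from_amp(_scene_amp(body_pos=(10, 10)))
        state, filtered = dispose_residual_heat(ResidualHeatState(), im)
        assert np.array_equal(filtered.mask, im.mask)

    def test_decaying_vacated_patch_removed_and_released(self):
        state = ResidualHeatState(linger_frames=2)
        # body occupies the patch area for 3 frames, then moves away
        for _ in range(3):
            im = _imprint_from_amp(_scene_amp(body_pos=(20, 20), body_peak=250.0))
            state, filtered = dispose_residual_heat(state, im)
            assert filtered.mask.sum() == im.mask.sum()
        # body now elsewhere; old spot decays 60 -> 50 -> 40 -> 15 (released).
        # The collapse from the body-era peak flags the patch right away, so
        # all three decay frames come out clean.
        for peak in (60.0, 50.0, 40.0):
            im = _imprint_from_amp(
                _scene_amp(body_pos=(40, 60), body_peak=250.0, patch=(20, 20), patch_peak=peak)
            )
            state, filtered = dispose_residual_heat(state, im)
            assert not filtered.mask[22, 22]
            # the body is never disposed
            assert filtered.mask[42, 62]
        # below threshold: patch leaves the mask; after the linger window the
        # tracker releases it entirely
        for _ in range(3):
            im = _imprint_from_amp(_scene_amp(body_pos=(40, 60), body_peak=250.0))
            state, filtered = dispose_residual_heat(state, im)
            assert np.array_equal(filtered.mask, im.mask)
        assert len(state.regions) == 1 and not state.regions[0].residual

    def test_flagged_patch_stays_removed_after_body_leaves_area(self):
        state = ResidualHeatState()
        for _ in range(3):
            im = _imprint_from_amp(_scene_amp(body_pos=(20, 20), body_peak=250.0))
            state, _ = dispose_residual_heat(state, im)
        # two decay frames with the body still present -> patch flagged
        for peak in (60.0, 50.0):
            im = _imprint_from_amp(
                _scene_amp(body_pos=(40, 60), body_peak=250.0, patch=(20, 20), patch_peak=peak)
            )
            state, filtered = dispose_residual_heat(state, im)
        assert not filtered.mask[22, 22]
        # body gone: the patch is now the hottest thing but keeps decaying
        im = _imprint_from_amp(_scene_amp(patch=(20, 20), patch_peak=45.0))
        state, filtered = dispose_residual_heat(state, im)
        assert not filtered.mask.any()

    def test_body_reclaims_pixels_when_stepping_onto_flagged_patch(self):
        state = ResidualHeatState()
        for _ in range(3):
            im = _imprint_from_amp(_scene_amp(body_pos=(20, 20), body_peak=250.0))
            state, _ = dispose_residual_heat(state, im)
        for peak in (60.0, 50.0):
            im = _imprint_from_amp(
                _scene_amp(body_pos=(40, 60), body_peak=250.0, patch=(20, 20), patch_peak=peak)
            )
            state, filtered = dispose_residual_heat(state, im)
        assert not filtered.mask[22, 22]
        # the body returns onto the still-warm patch: pixels must come back
        im = _imprint_from_amp(_scene_amp(body_pos=(21, 21), body_peak=250.0))
        state, filtered = dispose_residual_heat(state, im)
        assert filtered.mask[23, 23]

    def test_filtered_mask_subset_of_input(self, rng):
        state = ResidualHeatState()
        for _ in range(20):
            amp = rng.random((GRID_ROWS, GRID_COLS)) * 60
            im = _imprint_from_amp(amp)
            state, filtered = dispose_residual_heat(state, im)
            assert not (filtered.mask & ~im.mask).any()

    def test_empty_mask_passes_through(self):
        im = _imprint_from_amp(np.zeros((GRID_ROWS, GRID_COLS)))
        state, filtered = dispose_residual_heat(ResidualHeatState(), im)
        assert not filtered.mask.any()
        assert state.regions == ()
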