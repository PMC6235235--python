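import numpy as np
import pytest

from _oracles import brute_crosscorr
from larvalight import (
    IntensityProfile,
    ProfileRecipe,
    TemplateLibrary,
    build_template,
    make_brightfield_profile,
    match_library,
    match_offset,
    profile_from_image,
    simulate_fine_positioning,
    tile_composite,
)
from larvalight.grids import DataError, ValidationError
from larvalight.positioning import shift_profile


@pytest.fixture
def template():
    return make_brightfield_profile(ProfileRecipe())


class TestProfileFromImage:
    def test_constant_frame_gives_constant_profile(self):
        p = profile_from_image(np.full((10, 20), 3.0), pixel_size=2.0)
        np.testing.assert_allclose(p.values, 3.0)
        assert p.step == 2.0

    def test_dark_column_is_profile_minimum(self):
        frame = np.full((8, 30), 100.0)
        frame[:, 17] = 10.0
        p = profile_from_image(frame)
        assert np.argmin(p.values) == 17

    def test_matches_columnwise_mean_oracle(self, rng):
        frame = rng.random((12, 25))
        p = profile_from_image(frame)
        expected = [sum(frame[y, x] for y in range(12)) / 12 for x in range(25)]
        np.testing.assert_allclose(p.values, expected)


class TestTileComposite:
    def test_single_frame_identity(self, rng):
        frame = rng.random((5, 8))
        np.testing.assert_array_equal(tile_composite([frame], 8.0, 1.0), frame)

    def test_abutting_frames_concatenate(self):
        a = np.full((4, 6), 1.0)
        b = np.full((4, 6), 2.0)
        comp = tile_composite([a, b], step_um=6.0, pixel_size=1.0)
        assert comp.shape == (4, 12)
        np.testing.assert_allclose(comp[:, :6], 1.0)
        np.testing.assert_allclose(comp[:, 6:], 2.0)

    def test_half_overlap_averages(self):
        frames = [np.full((3, 8), v) for v in (1.0, 2.0, 3.0)]
        comp = tile_composite(frames, step_um=4.0, pixel_size=1.0)
        assert comp.shape == (3, 16)
        np.testing.assert_allclose(comp[:, 4:8], 1.5)  # overlap of frames 1,2
        np.testing.assert_allclose(comp[:, 8:12], 2.5)  # overlap of frames 2,3

    def test_mixed_heights_rejected(self):
        with pytest.raises(ValidationError, match="height"):
            tile_composite([np.zeros((3, 5)), np.zeros((4, 5))], 5.0, 1.0)


class TestBuildTemplate:
    def test_identical_profiles_average_to_themselves(self, template):
        t = build_template([template, template], normalize=False)
        np.testing.assert_allclose(t.values, template.values)

    def test_mean_of_two_after_normalization(self):
        a = IntensityProfile(np.array([0.0, 1.0, 2.0, 3.0]), 1.0)
        b = IntensityProfile(np.array([6.0, 4.0, 2.0, 0.0]), 1.0)
        t = build_template([a, b])
        expected = (a.normalized().values + b.normalized().values) / 2
        np.testing.assert_allclose(t.values, expected)

    def test_mixed_steps_rejected(self):
        a = IntensityProfile(np.zeros(4) + [0, 1, 0, 1], 1.0)
        b = IntensityProfile(np.zeros(4) + [0, 1, 0, 1], 2.0)
        with pytest.raises(ValidationError, match="step"):
            build_template([a, b])


class TestMatchOffset:
    def test_identity_gives_zero_offset_both_methods(self, template):
        for method in ("crosscorr", "minimum"):
            r = match_offset(template, template, method=method)
            assert r.offset == 0.0

    @pytest.mark.parametrize("shift_um", [21.0, -21.0, 300.0])
    def test_planted_shift_recovered_exactly(self, template, shift_um):
        shifted = make_brightfield_profile(ProfileRecipe(offset=shift_um))
        for method in ("crosscorr", "minimum"):
            r = match_offset(shifted, template, method=method, max_shift=600.0)
            assert r.offset == pytest.approx(shift_um), method

    @pytest.mark.parametrize("scoring", ["pearson", "product"])
    def test_crosscorr_matches_exhaustive_oracle(self, rng, scoring):
        p_vals = rng.random(40)
        q_vals = rng.random(40)
        p = IntensityProfile(p_vals, 2.0)
        q = IntensityProfile(q_vals, 2.0)
        r = match_offset(p, q, max_shift=30.0, normalize=False, scoring=scoring)
        k, score = brute_crosscorr(p_vals, q_vals, max_lag=15, scoring=scoring)
        assert r.offset == pytest.approx(k * 2.0)
        assert r.score == pytest.approx(score)

    def test_shift_equivariance(self, template):
        base = make_brightfield_profile(ProfileRecipe(offset=30.0))
        more = make_brightfield_profile(ProfileRecipe(offset=30.0 + 12.0))
        r0 = match_offset(base, template, max_shift=300.0)
        r1 = match_offset(more, template, max_shift=300.0)
        assert r1.offset - r0.offset == pytest.approx(12.0)

    def test_methods_agree_on_noise_free_single_minimum(self):
        recipe = ProfileRecipe(feature_positions=(600.0,), feature_depths=(0.9,))
        template = make_brightfield_profile(recipe)
        for off in (0.0, 45.0, -90.0):
            shifted = make_brightfield_profile(
                ProfileRecipe(feature_positions=(600.0,), feature_depths=(0.9,), offset=off)
            )
            cc = match_offset(shifted, template, "crosscorr", max_shift=300.0).offset
            mn = match_offset(shifted, template, "minimum").offset
            assert abs(cc - mn) <= template.step

    def test_noise_robustness_crosscorr(self, template):
        hits = 0
        for seed in range(30):
            shifted = make_brightfield_profile(ProfileRecipe(offset=45.0, noise_sigma=50.0, seed=seed))
            r = match_offset(shifted, template, max_shift=300.0)
            hits += abs(r.offset - 45.0) <= template.step
        assert hits >= 28

    def test_mismatched_steps_rejected(self, template):
        other = IntensityProfile(template.values, template.step * 2)
        with pytest.raises(ValidationError):
            match_offset(other, template)

    def test_no_valid_overlap_is_an_error(self):
        p = IntensityProfile(np.array([0.0, 1.0]), 1000.0)
        q = IntensityProfile(np.zeros(200) + np.sin(np.arange(200)), 1000.0)
        with pytest.raises(DataError):
            match_offset(p, q, max_shift=1e9)


class TestMatchLibrary:
    def test_best_template_wins(self, template):
        # feature spacing differs from the target's (300, 900), so no shift
        # can align both dips of the wrong template
        other = make_brightfield_profile(
            ProfileRecipe(feature_positions=(600.0, 850.0), feature_depths=(0.3, 0.4))
        )
        lib = TemplateLibrary([("wrong", other), ("right", template)])
        shifted = make_brightfield_profile(ProfileRecipe(offset=21.0))
        r = match_library(shifted, lib, max_shift=300.0)
        assert r.best_template == "right"
        assert r.offset == pytest.approx(21.0)

    def test_empty_library_rejected(self):
        with pytest.raises(ValidationError):
            TemplateLibrary([])


class TestSimulateFinePositioning:
    def test_noise_free_converges_in_one_iteration(self):
        # features sit early in the field so a 900 μm displacement keeps
        # them inside the imaged region
        recipe = ProfileRecipe(feature_positions=(300.0, 500.0))
        template = make_brightfield_profile(recipe)
        traj = simulate_fine_positioning(template, true_offset=900.0, max_iter=3)
        assert traj[0] == pytest.approx(0.0)
        assert traj[-1] == pytest.approx(0.0)

    def test_zero_iterations_rejected(self, template):
        with pytest.raises(ValidationError):
            simulate_fine_positioning(template, 100.0, max_iter=0)

    def test_stage_noise_leaves_small_terminal_residual(self):
        # 20 μm sampling matches the registration precision scale of the
        # instrument; stage noise sd 10 μm then keeps |residual| ≤ 1 sample.
        # Features sit so the 900 μm displacement keeps them in the field.
        recipe = ProfileRecipe(length=128, step=20.0, feature_positions=(400.0, 1000.0))
        template = make_brightfield_profile(recipe)
        ok = 0
        for seed in range(40):
            traj = simulate_fine_positioning(
                template, true_offset=900.0, stage_noise_sd=10.0, max_iter=5, seed=seed
            )
            ok += abs(traj[-1]) <= 20.0
        assert ok >= 36
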