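"""Synthetic study generation: determinism, calibration, media contracts."""

import numpy as np
import pandas as pd
import pytest

from clipcontext import media, synthetic
from clipcontext.config import GeneratorConfig, MediaParams, RatingNoise
from clipcontext.fusion import fuse_ordinal, overall_loudness

NO_NOISE = RatingNoise(
    participant_bias=0.0,
    participant_sd=0.0,
    participant_attendance_cv=0.0,
    annotator_bias=0.0,
    annotator_sd=0.0,
    annotator_attendance_cv=0.0,
)


class TestGenerateStudy:
    def test_same_seed_identical_tables(self):
        cfg = GeneratorConfig(n_participants=20, seed=3)
        a = synthetic.situations_to_frame(synthetic.generate_situations(cfg), truth=True)
        b = synthetic.situations_to_frame(synthetic.generate_situations(cfg), truth=True)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = synthetic.generate_situations(GeneratorConfig(n_participants=20, seed=3))
        b = synthetic.generate_situations(GeneratorConfig(n_participants=20, seed=4))
        assert synthetic.situations_to_frame(a).ne(synthetic.situations_to_frame(b)).any().any()

    def test_null_alcohol_model_gives_half(self):
        cfg = GeneratorConfig(n_participants=200, seed=5)
        cfg.alcohol.sigma_u = 0.0
        for loc in cfg.alcohol.intercepts:
            cfg.alcohol.intercepts[loc] = 0.0
        for coarse in cfg.alcohol.coefficients:
            for term in cfg.alcohol.coefficients[coarse]:
                cfg.alcohol.coefficients[coarse][term] = 0.0
        df = synthetic.situations_to_frame(synthetic.generate_situations(cfg))
        n = len(df)
        se = 0.5 / np.sqrt(n)
        assert abs(df["alcohol"].mean() - 0.5) < 3 * se

    def test_nightclubs_mostly_alcoholic(self):
        df = synthetic.situations_to_frame(
            synthetic.generate_situations(GeneratorConfig(seed=0))
        )
        clubs = df[df["location_fine"] == "nightclubs"]
        assert clubs["alcohol"].mean() >= 0.86

    def test_participant_imbalance(self):
        df = synthetic.situations_to_frame(
            synthetic.generate_situations(GeneratorConfig(seed=2))
        )
        counts = df.groupby("participant_id").size().sort_values(ascending=False)
        top20 = counts.iloc[: max(1, int(0.2 * len(counts)))].sum() / counts.sum()
        assert 0.35 <= top20 <= 0.7

    def test_coarse_mapping_and_ranges(self, small_study):
        situations, _, _ = small_study
        from clipcontext.config import COARSE_MAP

        for s in situations:
            assert s.location_coarse == COARSE_MAP[s.location_fine]
            assert 0 <= s.p_brightness <= 4
            assert 0 <= s.p_loudness <= 4
            assert s.p_attendance >= 0
            assert s.prior_drinks >= 0

    def test_loudness_ordering_matches_study(self):
        # nightclubs loudest, private quietest, bars above restaurants
        wins = 0
        for seed in range(10):
            df = synthetic.situations_to_frame(
                synthetic.generate_situations(GeneratorConfig(n_participants=120, seed=seed)),
                truth=True,
            )
            m = df.groupby("location_fine")["true_db"].mean()
            ok = (
                m["nightclubs"] == m.max()
                and m["private"] == m.min()
                and m["bars/pubs"] > m["restaurants"] > m["private"]
            )
            wins += ok
        assert wins >= 9

    def test_invalid_probs_rejected(self):
        cfg = GeneratorConfig()
        cfg.location_probs = {k: 0.0 for k in cfg.location_probs}
        cfg.location_probs["private"] = 0.5
        with pytest.raises(ValueError):
            synthetic.generate_situations(cfg)

    def test_negative_sd_rejected(self):
        cfg = GeneratorConfig()
        cfg.profiles["private"].db_sd = -1.0
        with pytest.raises(ValueError):
            cfg.validate()


class TestRenderClip:
    def test_contract_luminance_level_count(self):
        clip = synthetic.render_clip(50.0, 60.0, 0, MediaParams(), seed=1)
        assert 49.0 <= media.mean_luminance(clip.frames) <= 51.0
        assert 59.5 <= media.smoothed_power_db(clip.audio, clip.sample_rate) <= 60.5
        assert media.count_people(clip.frames) == 0

    def test_dark_scene_blobs_still_detectable(self):
        clip = synthetic.render_clip(0.0, 50.0, 3, MediaParams(), seed=2)
        assert media.count_people(clip.frames) == 3
        assert media.mean_luminance(clip.frames) <= 1.0

    def test_shapes_and_ranges(self):
        mp = MediaParams()
        clip = synthetic.render_clip(80.0, 55.0, 1, mp, seed=5)
        assert clip.frames.shape == (mp.n_frames, mp.height, mp.width)
        assert clip.audio.size == mp.n_samples
        assert clip.frames.min() >= 0 and clip.frames.max() <= 255
        assert np.max(np.abs(clip.audio)) <= 1.0

    def test_unreachable_level_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            synthetic.render_clip(50.0, 95.0, 0, MediaParams(), seed=1)

    def test_too_many_people_raises(self):
        with pytest.raises(ValueError, match="fit"):
            synthetic.render_clip(50.0, 60.0, 50, MediaParams(), seed=1)

    def test_deterministic(self):
        a = synthetic.render_clip(30.0, 65.0, 2, MediaParams(), seed=7)
        b = synthetic.render_clip(30.0, 65.0, 2, MediaParams(), seed=7)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.audio, b.audio)


class TestParticipantRatings:
    def test_zero_noise_reproduces_bins(self):
        b, l, a = synthetic.simulate_participant_ratings((100.0, 39.0, 4), NO_NOISE, seed=0)
        assert (b, l, a) == (4, 0, 4)

    def test_39db_is_bottom_bin(self):
        _, l, _ = synthetic.simulate_participant_ratings((50.0, 39.0, 0), NO_NOISE, seed=0)
        assert l == 0

    def test_positive_bias_clamped_at_top(self):
        noise = RatingNoise(participant_bias=1.0, participant_sd=0.0, participant_attendance_cv=0.0)
        b, _, _ = synthetic.simulate_participant_ratings((100.0, 50.0, 0), noise, seed=0)
        assert b == 4


class TestAnnotatorPanel:
    def test_zero_noise_categories(self):
        p = synthetic.simulate_annotator_panel((50.0, 60.0, 7), NO_NOISE, seed=0)
        assert p.attendance_cat == ["5-10"] * 5

    def test_zero_noise_fusion_matches_bins(self):
        # lightness(50)=74.8 -> bin 3; 60 dB -> bin 2
        p = synthetic.simulate_annotator_panel((50.0, 60.0, 2), NO_NOISE, seed=0)
        assert fuse_ordinal(p.brightness) == 3
        assert overall_loudness(p.music, p.chatter) == 2

    def test_icc_decreases_with_rater_noise(self):
        from clipcontext.fusion import icc_2k

        means = []
        for sd in (0.1, 1.5):
            rng = np.random.default_rng(9)
            vals = []
            for rep in range(200):
                lum = rng.uniform(0, 100)
                noise = RatingNoise(annotator_bias=0.0, annotator_sd=sd, annotator_attendance_cv=0.0)
                p = synthetic.simulate_annotator_panel((lum, 60.0, 0), noise, seed=rng)
                vals.append(p.brightness)
            means.append(icc_2k(np.array(vals)))
        assert means[0] > means[1]


class TestDatasetIO:
    def test_round_trip(self, tmp_path, small_config):
        cfg = small_config.replace(n_participants=6, seed=21)
        situations, clips, panels = synthetic.generate_study(cfg)
        out = synthetic.write_dataset(situations, clips, panels, tmp_path / "study", config=cfg)
        sit2, ann2 = synthetic.read_dataset(out)
        pd.testing.assert_frame_equal(sit2, synthetic.situations_to_frame(situations))
        pd.testing.assert_frame_equal(ann2, synthetic.panels_to_frame(panels))

    def test_audio_quantization_bound(self, tmp_path):
        clip = synthetic.render_clip(50.0, 70.0, 1, MediaParams(), seed=3, situation_id=5)
        synthetic.write_clip(clip, tmp_path / "5")
        back = synthetic.read_clip(tmp_path / "5")
        assert np.max(np.abs(back.audio - clip.audio)) < 1e-4  # 16-bit PCM step
        assert np.array_equal(back.frames, clip.frames)

    def test_png_frame_sequence_round_trip(self, tmp_path):
        clip = synthetic.render_clip(60.0, 55.0, 2, MediaParams(), seed=8, situation_id=2)
        synthetic.write_clip(clip, tmp_path / "2", frame_format="png")
        back = synthetic.read_clip(tmp_path / "2")
        assert np.array_equal(back.frames, clip.frames)

    def test_missing_directory_error_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="no/such"):
            synthetic.write_dataset([], [], [], tmp_path / "no" / "such" / "dir")
        with pytest.raises(FileNotFoundError):
            synthetic.read_dataset(tmp_path / "absent")
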