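import numpy as np
import pytest

from emgtrace.features import detect_onset, segment_adjacent
from emgtrace.shapes import SHAPE_IDS, ShapeSpec, generate_trace
from emgtrace.synth import DatasetConfig, MuscleModel, generate_dataset, generate_emg


class TestTraces:
    def test_horizontal_line_geometry(self):
        spec = ShapeSpec("horizontal_line", duration_ms=1000.0, size=100.0,
                         jitter_frac=0.0, drift_frac=0.0)
        pts = generate_trace(spec, 0)
        assert pts.shape == (21, 2)
        assert np.allclose(pts[:, 1], pts[0, 1])
        assert (np.diff(pts[:, 0]) > 0).all()

    def test_reversed_line_is_reverse_of_base(self):
        kw = dict(duration_ms=1000.0, size=100.0)
        fwd = generate_trace(ShapeSpec("horizontal_line", **kw), 7)
        rev = generate_trace(ShapeSpec("reversed_horizontal_line", **kw), 7)
        np.testing.assert_array_equal(rev, fwd[::-1])

    def test_circle_diameter(self):
        spec = ShapeSpec("circle", size=200.0, jitter_frac=0.002, drift_frac=0.0)
        pts = generate_trace(spec, 3)
        # brute-force max pairwise distance ~ diameter
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).max()
        assert d == pytest.approx(200.0, rel=0.05)

    def test_unknown_shape_named_in_error(self):
        with pytest.raises(ValueError, match="pentagram"):
            ShapeSpec("pentagram")

    def test_start_point_honoured(self):
        spec = ShapeSpec("ellipse", start_point=(12.0, 34.0))
        pts = generate_trace(spec, 5)
        np.testing.assert_allclose(pts[0], [12.0, 34.0])

    def test_all_shapes_generate(self):
        for sid in SHAPE_IDS:
            pts = generate_trace(ShapeSpec(sid), 1)
            assert pts.shape == (31, 2)
            assert np.isfinite(pts).all()


class TestEmgForwardModel:
    def test_zero_velocity_trace_rests_at_baseline(self):
        model = MuscleModel(noise_sd=0.0)
        trace = np.tile([100.0, 100.0], (11, 1))
        emg, onset = generate_emg(trace, model, 1)
        fm = segment_adjacent(emg[:-1], onset_index=onset)
        np.testing.assert_allclose(fm.values[:10], model.baseline, rtol=1e-9)

    def test_noise_free_rms_equals_planted_envelope(self):
        """Carrier per-window RMS is normalised to 1, so RMS == envelope."""
        model = MuscleModel(noise_sd=0.0)
        trace = generate_trace(ShapeSpec("circle"), 2)
        emg, onset = generate_emg(trace, model, 3)
        deltas = np.diff(trace, axis=0)
        env = model.baseline + model.gains[:, None] * np.maximum(
            0.0, model.tuning @ deltas.T)
        fm = segment_adjacent(emg[:-1], onset_index=onset)
        np.testing.assert_allclose(fm.values[: deltas.shape[0]].T, env, rtol=1e-7)

    def test_rms_tracks_envelope_under_noise(self):
        model = MuscleModel()
        trace = generate_trace(ShapeSpec("circle"), 2)
        emg, onset = generate_emg(trace, model, 3)
        deltas = np.diff(trace, axis=0)
        env = model.baseline + model.gains[:, None] * np.maximum(
            0.0, model.tuning @ deltas.T)
        fm = segment_adjacent(emg[:-1], onset_index=onset)
        obs = fm.values[: deltas.shape[0]].T
        for m in range(model.n_channels):
            r = np.corrcoef(env[m], obs[m])[0, 1]
            assert r > 0.95

    def test_rank_deficient_tuning_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            MuscleModel(tuning=np.tile([1.0, 0.0], (7, 1)), gains=np.ones(7))

    def test_trigger_crosses_only_at_onset(self):
        model = MuscleModel()
        trace = generate_trace(ShapeSpec("arch"), 4)
        emg, onset = generate_emg(trace, model, 5)
        trig = np.abs(emg[-1])
        assert (trig[:onset] < 40.0).all()
        assert trig[onset] >= 40.0
        assert detect_onset(emg[-1]) == onset


class TestDataset:
    def test_default_design_is_480_trials(self):
        labels = DatasetConfig()
        assert len(labels.shapes) * labels.repetitions == 480

    def test_small_config_counts_and_labels(self):
        cfg = DatasetConfig(shapes=("circle",), repetitions=3, seed=1)
        recs = generate_dataset(cfg)
        assert len(recs) == 3
        assert {r.shape_id for r in recs} == {"circle"}

    def test_invalid_repetitions(self):
        with pytest.raises(ValueError):
            DatasetConfig(repetitions=0)

    def test_seed_reproducibility(self):
        cfg = DatasetConfig(shapes=("circle", "arch"), repetitions=2, seed=9)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        for ra, rb in zip(a, b):
            assert ra.shape_id == rb.shape_id
            np.testing.assert_array_equal(ra.coords, rb.coords)
            np.testing.assert_array_equal(ra.emg, rb.emg)

    def test_every_trial_trigger_valid(self, small_dataset):
        for rec in small_dataset:
            trig = np.abs(rec.emg[-1])
            assert (trig[: rec.onset_index] < 40.0).all()
            assert detect_onset(rec.emg[-1]) == rec.onset_index
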