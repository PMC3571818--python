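"""Feature extraction and the leave-one-subject-out protocol."""

import logging

import numpy as np
import pytest

from pirview import activity_recognition as ar
from pirview import sensor_sim as sim
from pirview import virtual_camera as vc

# disjoint anchors, one per activity, for the separable-classes scenario
SEPARABLE_ANCHORS = {
    "tidying": (1.2, 1.2),
    "watching_tv": (1.2, 4.5),
    "reading": (3.8, 1.2),
    "taking_drinks": (3.8, 4.5),
    "using_pc": (2.5, 3.0),
    "lying": (1.2, 3.0),
}
SEPARABLE_ACTIVITIES = tuple(SEPARABLE_ANCHORS)


def subject_dataset(subject_seed, set_id, activities=SEPARABLE_ACTIVITIES,
                    anchors=SEPARABLE_ANCHORS, segment_duration=8.0,
                    settle_s=4.0):
    """Labelled features from one subject's session, keeping only frames
    recorded ``settle_s`` after the last activity change (the walk to the
    next anchor and the averaging-window bleed are not location-pure)."""
    script = sim.adl_session_script(subject_seed, segment_duration=segment_duration,
                                    anchors=anchors, activities=activities)
    stream = sim.simulate_stream(sim.DEFAULT_GRID, script, 20, seed=subject_seed)
    series = vc.pixelize_stream(stream, "trailing")
    X, idx = ar.extract_features(series.values, set_id)
    y = stream.labels[series.t[idx]]
    labels = stream.labels
    changed = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    since = np.zeros(len(labels))
    last = 0
    for t in range(len(labels)):
        if t in set(changed.tolist()):
            last = t
        since[t] = t - last
    settled = since[series.t[idx]] >= settle_s * 20
    return X[settled], y[settled]


class TestExtractFeatures:
    @pytest.mark.parametrize("set_id,dim", [("F1", 20), ("F2", 1), ("F3", 21), ("F4", 60)])
    def test_dimensions_per_set(self, set_id, dim):
        rng = np.random.default_rng(0)
        X, _ = ar.extract_features(rng.random((10, 20)), set_id)
        assert X.shape[1] == dim

    def test_f2_of_saturated_frame_is_20(self):
        X, _ = ar.extract_features(np.ones((3, 20)), "F2")
        assert X[0, 0] == pytest.approx(20.0)

    def test_f3_is_f1_concat_f2(self):
        rng = np.random.default_rng(1)
        v = rng.random((30, 20))
        f1, _ = ar.extract_features(v, "F1")
        f2, _ = ar.extract_features(v, "F2")
        f3, _ = ar.extract_features(v, "F3")
        np.testing.assert_allclose(f3, np.hstack([f1, f2]))

    def test_f4_of_constant_stream_is_tiled_frame(self):
        v = np.tile(np.linspace(0, 1, 20), (5, 1))
        X, idx = ar.extract_features(v, "F4")
        assert X.shape == (3, 60)
        np.testing.assert_allclose(X[0], np.tile(v[0], 3))
        np.testing.assert_array_equal(idx, [1, 2, 3])

    def test_f4_drops_first_and_last_frame(self):
        rng = np.random.default_rng(2)
        v = rng.random((10, 20))
        X, idx = ar.extract_features(v, "F4")
        np.testing.assert_allclose(X[0], np.concatenate([v[0], v[1], v[2]]))
        assert idx[0] == 1 and idx[-1] == 8

    def test_too_short_sequence_for_f4_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ar.extract_features(np.zeros((2, 20)), "F4")

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError, match="F9"):
            ar.extract_features(np.zeros((5, 20)), "F9")


class TestProtocol:
    def test_needs_two_subjects(self):
        X = np.zeros((4, 20))
        y = np.array(["a"] * 4)
        with pytest.raises(ValueError, match="2 subject"):
            ar.run_protocol({"s1": (X, y)})

    def test_separable_locations_give_perfect_recognition(self):
        datasets = {f"s{k}": subject_dataset(100 + k, "F1") for k in range(3)}
        result = ar.run_protocol(datasets)
        assert result.recognition_rate == pytest.approx(100.0)
        assert all(r == pytest.approx(100.0) for r in result.fold_rates.values())

    def test_shuffled_labels_fall_to_chance_level(self):
        datasets = {}
        rng = np.random.default_rng(42)
        for k in range(3):
            X, y = subject_dataset(200 + k, "F1")
            datasets[f"s{k}"] = (X, rng.permutation(y))
        result = ar.run_protocol(datasets)
        chance = 100.0 / len(SEPARABLE_ACTIVITIES)
        assert result.recognition_rate == pytest.approx(chance, abs=8.0)

    def test_confusion_rows_sum_to_100(self):
        datasets = {f"s{k}": subject_dataset(300 + k, "F4") for k in range(2)}
        result = ar.run_protocol(datasets)
        sums = result.confusion.row_sums()
        present = result.confusion.counts.sum(axis=1) > 0
        np.testing.assert_allclose(sums[present], 100.0, atol=0.1)

    def test_f4_at_least_matches_f2_on_separable_data(self):
        d4 = {f"s{k}": subject_dataset(400 + k, "F4") for k in range(3)}
        d2 = {f"s{k}": subject_dataset(400 + k, "F2") for k in range(3)}
        r4 = ar.run_protocol(d4).recognition_rate
        r2 = ar.run_protocol(d2).recognition_rate
        assert r4 >= r2

    def test_no_subject_leaks_across_folds(self):
        # tag each subject's rows; a custom classifier asserts the held-out
        # tag never appears in training
        tags = {"s0": 0.0, "s1": 1.0, "s2": 2.0}
        datasets = {}
        for name, tag in tags.items():
            X = np.full((8, 2), tag)
            y = np.array(["a", "b"] * 4)
            datasets[name] = (X, y)

        seen = []

        class Probe:
            def fit(self, X, y):
                seen.append(set(np.unique(X[:, 0])))
                return self

            def predict(self, X):
                return np.array(["a"] * len(X))

        ar.run_protocol(datasets, classifier=Probe)
        all_tags = set(tags.values())
        held_out = [all_tags - s for s in seen]
        assert all(len(h) == 1 for h in held_out)
        assert set().union(*held_out) == all_tags

    def test_missing_class_in_training_warns_but_runs(self, caplog):
        X0 = np.random.default_rng(3).random((6, 2))
        d = {
            "s0": (X0, np.array(["a", "a", "b", "b", "c", "c"])),
            "s1": (X0 + 1, np.array(["a", "a", "b", "b", "b", "a"])),
        }
        with caplog.at_level(logging.WARNING):
            result = ar.run_protocol(d)
        assert any("lacks class" in r.message for r in caplog.records)
        assert "s0" in result.fold_rates
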