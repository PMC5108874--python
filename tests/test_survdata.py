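import numpy as np
import pytest

from survsvr.survdata import (
    SchemaError,
    Standardizer,
    SurvivalDataset,
    UnsplittableError,
    ValidationError,
    load_dataset,
    split_train_test,
    standardize,
    write_dataset,
)


def write_csv(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadDataset:
    def test_basic_parse(self, tmp_path):
        p = write_csv(tmp_path, "time,event,x\n1,1,0.5\n2,0,1.5\n3,1,2.5\n")
        ds = load_dataset(p, "time", "event")
        assert ds.n == 3 and ds.d == 1
        np.testing.assert_array_equal(ds.y, [1, 2, 3])
        np.testing.assert_array_equal(ds.delta, [1, 0, 1])
        assert ds.schema[0].kind == "continuous"

    def test_zero_time_rejected(self, tmp_path):
        p = write_csv(tmp_path, "time,event,x\n0,1,0.5\n2,0,1.5\n")
        with pytest.raises(ValidationError, match="row 0"):
            load_dataset(p, "time", "event")

    def test_missing_column(self, tmp_path):
        p = write_csv(tmp_path, "time,event,x\n1,1,0.5\n")
        with pytest.raises(SchemaError):
            load_dataset(p, "time", "status")

    def test_categorical_with_unknown(self, tmp_path):
        p = write_csv(tmp_path, "time,event,g\n1,1,A\n2,0,B\n3,1,Unknown\n")
        ds = load_dataset(p, "time", "event")
        s = ds.schema[0]
        assert s.kind == "categorical"
        assert set(s.categories) == {"A", "B", "Unknown"}

    def test_missing_categorical_becomes_unknown(self, tmp_path):
        p = write_csv(tmp_path, "time,event,g\n1,1,A\n2,0,\n3,1,B\n")
        ds = load_dataset(p, "time", "event")
        assert "Unknown" in ds.schema[0].categories
        assert ds.n == 3

    def test_missing_continuous_rows_dropped(self, tmp_path):
        p = write_csv(tmp_path, "time,event,x\n1,1,0.5\n2,0,\n3,1,2.5\n")
        ds = load_dataset(p, "time", "event")
        assert ds.n == 2

    def test_event_labels_need_mapping(self, tmp_path):
        p = write_csv(tmp_path, "time,event,x\n1,dead,0.5\n2,alive,1.5\n")
        with pytest.raises(ValidationError):
            load_dataset(p, "time", "event")
        ds = load_dataset(p, "time", "event",
                          schema_hints={"event": {"dead": 1, "alive": 0}})
        np.testing.assert_array_equal(ds.delta, [1, 0])

    def test_event_outside_01_rejected(self, tmp_path):
        p = write_csv(tmp_path, "time,event,x\n1,2,0.5\n")
        with pytest.raises(ValidationError):
            load_dataset(p, "time", "event")

    def test_kind_hint_overrides_inference(self, tmp_path):
        p = write_csv(tmp_path, "time,event,g\n1,1,0\n2,0,1\n3,1,0\n")
        ds = load_dataset(p, "time", "event", schema_hints={"g": "categorical"})
        assert ds.schema[0].kind == "categorical"

    def test_round_trip_exact(self, tmp_path):
        p = write_csv(
            tmp_path, "time,event,x,g\n1.25,1,0.5,A\n2.5,0,1.5,B\n3.75,1,2.5,A\n"
        )
        ds = load_dataset(p, "time", "event")
        out = tmp_path / "out.csv"
        write_dataset(ds, out)
        ds2 = load_dataset(out, "time", "event")
        np.testing.assert_array_equal(ds.X, ds2.X)
        np.testing.assert_array_equal(ds.y, ds2.y)
        np.testing.assert_array_equal(ds.delta, ds2.delta)


class TestSplit:
    def make(self, n, rng):
        return SurvivalDataset(
            rng.standard_normal((n, 2)), rng.exponential(1, n) + 0.1,
            rng.integers(0, 2, n) | 1,
        )

    def test_sizes_and_disjoint(self, rng):
        ds = self.make(6, rng)
        tr, te = split_train_test(ds, 2 / 3, seed=1)
        assert tr.n == 4 and te.n == 2

    def test_bc_protocol_sizes(self, rng):
        ds = self.make(542, rng)
        tr, te = split_train_test(ds, 2 / 3, seed=0)
        assert (tr.n, te.n) == (362, 180)

    def test_deterministic(self, rng):
        ds = self.make(20, rng)
        a = split_train_test(ds, 0.5, seed=1)
        b = split_train_test(ds, 0.5, seed=1)
        np.testing.assert_array_equal(a[0].X, b[0].X)
        np.testing.assert_array_equal(a[1].y, b[1].y)

    def test_partition_property(self, rng):
        ds = SurvivalDataset(
            np.arange(30.0).reshape(-1, 1), np.arange(1.0, 31.0),
            np.ones(30, dtype=int),
        )
        tr, te = split_train_test(ds, 2 / 3, seed=7)
        ys = np.sort(np.concatenate([tr.y, te.y]))
        np.testing.assert_array_equal(ys, ds.y)
        assert not set(tr.y) & set(te.y)

    def test_zero_events_unsplittable(self):
        ds = SurvivalDataset(np.zeros((5, 1)), np.arange(1.0, 6.0), np.zeros(5, int))
        with pytest.raises(UnsplittableError):
            split_train_test(ds, 0.5, seed=0)

    def test_train_always_has_event(self):
        delta = np.zeros(10, int)
        delta[3] = 1
        ds = SurvivalDataset(np.zeros((10, 1)), np.arange(1.0, 11.0), delta)
        for seed in range(20):
            tr, _ = split_train_test(ds, 0.5, seed=seed)
            assert tr.delta.sum() >= 1


class TestStandardize:
    def test_two_point(self):
        ds = SurvivalDataset(np.array([[0.0], [2.0]]), [1, 2], [1, 1])
        out, _ = standardize(ds)
        np.testing.assert_allclose(out.X[:, 0], [-1, 1])

    def test_constant_feature(self):
        ds = SurvivalDataset(np.full((3, 1), 5.0), [1, 2, 3], [1, 1, 1])
        out, _ = standardize(ds)
        np.testing.assert_array_equal(out.X[:, 0], [0, 0, 0])

    def test_train_params_applied_to_test(self, rng):
        tr = SurvivalDataset(rng.normal(3, 2, (50, 1)), rng.exponential(1, 50) + 0.1,
                             np.ones(50, int))
        te = SurvivalDataset(rng.normal(0, 1, (10, 1)), rng.exponential(1, 10) + 0.1,
                             np.ones(10, int))
        str_, (ste,) = standardize(tr, [te])
        tf = Standardizer.fit(tr)
        np.testing.assert_allclose(ste.X, (te.X - tf.mean) / tf.scale)
        # round-trip back to the original test values
        np.testing.assert_allclose(ste.X * tf.scale + tf.mean, te.X)

    def test_mean_zero_sd_one(self, rng):
        ds = SurvivalDataset(rng.normal(5, 3, (40, 3)), rng.exponential(1, 40) + 0.1,
                             np.ones(40, int))
        out, _ = standardize(ds)
        np.testing.assert_allclose(out.X.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.X.std(axis=0), 1, atol=1e-12)

    def test_categorical_untouched(self):
        from survsvr.survdata import FeatureSchema

        schema = [FeatureSchema("g", "categorical", categories=("A", "B", "C"))]
        ds = SurvivalDataset(np.array([[0.0], [1.0], [2.0]]), [1, 2, 3], [1, 1, 1],
                             schema)
        out, _ = standardize(ds)
        np.testing.assert_array_equal(out.X, ds.X)

    def test_schema_mismatch(self, rng):
        a = SurvivalDataset(rng.normal(size=(5, 1)), np.ones(5), np.ones(5, int))
        b = SurvivalDataset(rng.normal(size=(5, 2)), np.ones(5), np.ones(5, int))
        with pytest.raises(SchemaError):
            standardize(a, [b])


class TestInvariants:
    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalDataset(np.zeros((2, 1)), [1, -1], [1, 1])

    def test_bad_delta_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalDataset(np.zeros((2, 1)), [1, 2], [1, 2])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            SurvivalDataset(np.zeros((3, 1)), [1, 2], [1, 1])
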