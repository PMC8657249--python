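import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stackprune.cohort import (
    CohortTable,
    CohortValidationError,
    FeatureEncoder,
    FeatureSchema,
    SchemaError,
    encode_features,
    load_cohort,
    split_cohort,
    upsample_minority,
)


class TestFeatureSchema:
    def test_valid(self, tiny_schema):
        assert tiny_schema.p == 3
        assert tiny_schema.kind_of("grade") == "ordinal"

    def test_length_mismatch(self):
        with pytest.raises(SchemaError):
            FeatureSchema(("a", "b"), ("continuous",), "y")

    def test_duplicate_names(self):
        with pytest.raises(SchemaError, match="duplicate"):
            FeatureSchema(("a", "a"), ("continuous", "continuous"), "y")

    def test_outcome_is_feature(self):
        with pytest.raises(SchemaError):
            FeatureSchema(("a",), ("continuous",), "a")

    def test_bad_kind(self):
        with pytest.raises(SchemaError, match="invalid kind"):
            FeatureSchema(("a",), ("numeric",), "y")

    def test_mapping_round_trip(self, tiny_schema):
        again = FeatureSchema.from_mapping(tiny_schema.to_mapping())
        assert again == tiny_schema


class TestLoadCohort:
    def test_minimal_valid(self, tmp_path, tiny_schema):
        path = tmp_path / "c.csv"
        path.write_text(
            "age,grade,site,event\n50,1,a,0\n60,2,b,1\n70,3,c,0\n"
        )
        cohort = load_cohort(path, tiny_schema)
        assert cohort.n == 3
        assert list(cohort.labels) == [0, 1, 0]

    def test_missing_outcome_column(self, tmp_path, tiny_schema):
        path = tmp_path / "c.csv"
        path.write_text("age,grade,site\n50,1,a\n")
        with pytest.raises(SchemaError, match="event"):
            load_cohort(path, tiny_schema)

    def test_nonbinary_outcome_cites_row(self, tmp_path, tiny_schema):
        rows = ["50,1,a,0"] * 5 + ["50,1,a,2"]
        path = tmp_path / "c.csv"
        path.write_text("age,grade,site,event\n" + "\n".join(rows) + "\n")
        with pytest.raises(CohortValidationError, match="row 5"):
            load_cohort(path, tiny_schema)


class TestSplitCohort:
    def test_sizes_disjoint(self, tiny_schema):
        rng = np.random.default_rng(1)
        cohort = CohortTable(
            schema=tiny_schema,
            records=pd.DataFrame(
                {"age": rng.normal(size=100), "grade": rng.integers(1, 4, 100),
                 "site": rng.choice(list("abc"), 100)}
            ),
            labels=rng.integers(0, 2, 100),
        )
        split = split_cohort(cohort, train_frac=0.6, seed=7)
        assert len(split.train_idx) == 60
        assert len(split.test_idx) == 40
        assert not set(split.train_idx) & set(split.test_idx)
        assert sorted([*split.train_idx, *split.test_idx]) == list(range(100))

    def test_registry_scale_train_size(self):
        # oracle: 27455 * 0.6 == 16473 exactly
        assert round(27455 * 0.6) == 16473
        n = 27455
        labels = np.zeros(n, dtype=int)
        labels[:3365] = 1
        schema = FeatureSchema(("x",), ("continuous",), "y")
        cohort = CohortTable(
            schema=schema, records=pd.DataFrame({"x": np.zeros(n)}), labels=labels
        )
        for stratify in (False, True):
            split = split_cohort(cohort, train_frac=0.6, seed=0, stratify=stratify)
            assert len(split.train_idx) == 16473

    def test_deterministic(self, tiny_cohort):
        a = split_cohort(tiny_cohort, seed=3)
        b = split_cohort(tiny_cohort, seed=3)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_stratified_preserves_proportion(self):
        labels = np.array([1] * 20 + [0] * 80)
        schema = FeatureSchema(("x",), ("continuous",), "y")
        cohort = CohortTable(
            schema=schema, records=pd.DataFrame({"x": np.arange(100.0)}), labels=labels
        )
        split = split_cohort(cohort, train_frac=0.6, seed=5, stratify=True)
        n_pos_train = cohort.labels[split.train_idx].sum()
        assert abs(n_pos_train - 0.6 * 20) <= 1

    def test_round_trip_multiset(self, tiny_cohort):
        split = split_cohort(tiny_cohort, seed=11)
        recombined = np.sort(np.concatenate([split.train_idx, split.test_idx]))
        np.testing.assert_array_equal(recombined, np.arange(tiny_cohort.n))

    def test_bad_frac(self, tiny_cohort):
        with pytest.raises(ValueError):
            split_cohort(tiny_cohort, train_frac=1.2)

    def test_partition_frame(self, tiny_cohort):
        frame = split_cohort(tiny_cohort, seed=0).to_frame()
        assert set(frame.columns) == {"row_index", "partition"}
        assert set(frame["partition"]) == {"train", "test"}


def _label_cohort(labels):
    labels = np.asarray(labels)
    schema = FeatureSchema(("x",), ("continuous",), "y")
    return CohortTable(
        schema=schema,
        records=pd.DataFrame({"x": np.arange(len(labels), dtype=float)}),
        labels=labels,
    )


class TestUpsample:
    def test_registry_scale_counts(self):
        # oracle: minority duplicated until it matches the 24090 majority
        labels = np.array([0] * 2409 + [1] * 336)  # 1/10 scale of the registry shape
        up = upsample_minority(_label_cohort(labels), seed=0)
        assert up.class_counts() == {0: 2409, 1: 2409}

    def test_balanced_fixed_point(self):
        labels = np.array([0] * 50 + [1] * 50)
        cohort = _label_cohort(labels)
        up = upsample_minority(cohort, seed=0)
        assert up.n == cohort.n
        pd.testing.assert_frame_equal(up.records, cohort.records)

    def test_forced_multiplicity(self):
        up = upsample_minority(_label_cohort([0, 0, 0, 1]), seed=0)
        assert up.class_counts() == {0: 3, 1: 3}
        minority_rows = up.records[up.labels == 1]
        assert (minority_rows["x"] == 3.0).all()

    def test_majority_untouched(self):
        labels = np.array([0] * 30 + [1] * 10)
        cohort = _label_cohort(labels)
        up = upsample_minority(cohort, seed=4)
        orig = sorted(cohort.records[cohort.labels == 0]["x"])
        new = sorted(up.records[up.labels == 0]["x"])
        assert orig == new

    def test_single_class_error(self):
        with pytest.raises(CohortValidationError):
            upsample_minority(_label_cohort([1, 1, 1]))

    def test_deterministic(self):
        labels = np.array([0] * 30 + [1] * 7)
        a = upsample_minority(_label_cohort(labels), seed=9)
        b = upsample_minority(_label_cohort(labels), seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)

    @given(
        n0=st.integers(min_value=1, max_value=60),
        n1=st.integers(min_value=1, max_value=60),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=30, deadline=None)
    def test_prevalence_exactly_half(self, n0, n1, seed):
        labels = np.array([0] * n0 + [1] * n1)
        up = upsample_minority(_label_cohort(labels), seed=seed)
        assert up.labels.mean() == 0.5


class TestEncoding:
    def test_one_hot_arithmetic(self):
        schema = FeatureSchema(("site",), ("categorical",), "y")
        cohort = CohortTable(
            schema=schema,
            records=pd.DataFrame({"site": ["a", "b", "c", "a"]}),
            labels=np.array([0, 1, 0, 1]),
        )
        X, enc = encode_features(cohort)
        assert X.shape == (4, 2)  # 3 levels, reference dropped
        assert list(X.columns) == ["site=b", "site=c"]

    def test_all_continuous_identity(self):
        schema = FeatureSchema(("a", "b"), ("continuous", "continuous"), "y")
        records = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        cohort = CohortTable(schema=schema, records=records, labels=np.array([0, 1]))
        X, _ = encode_features(cohort)
        np.testing.assert_array_equal(X.to_numpy(), records.to_numpy())

    def test_unseen_level_zero_row_with_warning(self):
        schema = FeatureSchema(("site",), ("categorical",), "y")
        enc = FeatureEncoder(schema)
        enc.fit(pd.DataFrame({"site": ["a", "b", "c"]}))
        with pytest.warns(UserWarning, match="unseen"):
            out = enc.transform(pd.DataFrame({"site": ["d"]}))
        assert (out.to_numpy() == 0).all()

    def test_frozen_map_reused_on_test(self):
        schema = FeatureSchema(("site",), ("categorical",), "y")
        enc = FeatureEncoder(schema)
        enc.fit(pd.DataFrame({"site": ["a", "b"]}))
        # test data with a richer level set must not grow the map
        with pytest.warns(UserWarning):
            out = enc.transform(pd.DataFrame({"site": ["a", "b", "c"]}))
        assert list(out.columns) == ["site=b"]

    def test_ordinal_string_codes(self):
        schema = FeatureSchema(("grade",), ("ordinal",), "y")
        enc = FeatureEncoder(schema)
        out = enc.fit_transform(pd.DataFrame({"grade": ["g1", "g3", "g2"]}))
        assert list(out["grade"]) == [0.0, 2.0, 1.0]

    def test_groups_cover_all_columns(self, tiny_cohort):
        X, enc = encode_features(tiny_cohort)
        covered = sorted(i for cols in enc.groups_.values() for i in cols)
        assert covered == list(range(X.shape[1]))
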