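"""Encoding: dictionary/one-hot expansion, standardization, label maps."""

import numpy as np
import pandas as pd
import pytest

from grainrisk import (
    EncodingSchema,
    decode_labels,
    encode,
    encode_labels,
    fit_schema,
    index_to_level,
    level_area,
    level_to_index,
)
from grainrisk.encoding import SchemaError


def frame(**cols):
    return pd.DataFrame(cols)


class TestSchema:
    def test_vocabulary_size_sets_one_hot_width(self):
        df = frame(grain=["rice", "wheat", "corn", "rice"])
        schema = fit_schema(df)
        assert schema.vocabularies["grain"] == ["corn", "rice", "wheat"]  # lexicographic
        assert schema.width == 3

    def test_distinct_category_count_sets_encoded_width(self):
        # a single column with n distinct types contributes an n-wide block
        df = frame(c=[f"t{i}" for i in range(5)] * 4)
        X = encode(df, fit_schema(df))
        assert X.shape == (20, 5)

    def test_population_std_convention(self):
        df = frame(x=[2.0, 4.0, 6.0])
        schema = fit_schema(df)
        assert schema.numeric_mean["x"] == pytest.approx(4.0)
        assert schema.numeric_std["x"] == pytest.approx(1.632993, abs=1e-6)

    def test_all_missing_column_rejected(self):
        df = frame(x=[np.nan, np.nan], c=["a", "b"])
        with pytest.raises(SchemaError, match="x"):
            fit_schema(df)

    def test_constant_column_flagged_and_encoded_as_zeros(self):
        df = frame(x=[3.0, 3.0, 3.0], y=[1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="constant"):
            schema = fit_schema(df)
        assert "x" in schema.constant_columns
        X = encode(df, schema)
        assert np.all(X[:, schema.feature_names.index("x")] == 0.0)

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(SchemaError):
            fit_schema(frame(x=[1.0]))

    def test_json_round_trip(self, tmp_path):
        df = frame(c=["a", "b", "a"], x=[1.0, 2.0, 3.0])
        schema = fit_schema(df)
        path = tmp_path / "schema.json"
        schema.save(path)
        loaded = EncodingSchema.load(path)
        assert loaded.vocabularies == schema.vocabularies
        assert loaded.numeric_mean == schema.numeric_mean
        np.testing.assert_array_equal(encode(df, loaded), encode(df, schema))


class TestEncode:
    def test_standardized_training_columns_have_zero_mean_unit_std(self, small_dataset):
        records, _ = small_dataset
        schema = fit_schema(records)
        X = encode(records, schema)
        n_cat = sum(len(schema.vocabularies[c]) for c in schema.categorical_columns)
        numeric = X[:, n_cat:]
        keep = [i for i, c in enumerate(schema.numeric_columns) if c not in schema.constant_columns]
        assert np.all(np.abs(numeric[:, keep].mean(axis=0)) < 1e-9)
        assert np.all(np.abs(numeric[:, keep].std(axis=0) - 1.0) < 1e-9)

    def test_value_at_training_mean_standardizes_to_zero(self):
        df = frame(x=[2.0, 4.0, 6.0])
        schema = fit_schema(df)
        assert encode(frame(x=[4.0]), schema)[0, 0] == pytest.approx(0.0)

    def test_standardized_example_column(self):
        df = frame(x=[2.0, 4.0, 6.0])
        X = encode(df, fit_schema(df))
        np.testing.assert_allclose(X[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_one_hot_codes_are_equidistant(self):
        df = frame(c=["a", "b", "c", "a"])
        X = encode(df, fit_schema(df))
        # any two distinct one-hot codes sit at Euclidean distance sqrt(2)
        assert np.linalg.norm(X[0] - X[1]) == pytest.approx(np.sqrt(2))
        assert np.linalg.norm(X[1] - X[2]) == pytest.approx(np.sqrt(2))

    def test_one_hot_round_trip_recovers_vocabulary_index(self, small_dataset):
        records, _ = small_dataset
        schema = fit_schema(records)
        X = encode(records, schema)
        offset = 0
        for col in schema.categorical_columns:
            width = len(schema.vocabularies[col])
            block = X[:, offset : offset + width]
            assert set(np.unique(block)) <= {0.0, 1.0}
            sums = block.sum(axis=1)
            assert np.all((sums == 0) | (sums == 1))
            recovered = np.asarray(schema.vocabularies[col])[block.argmax(axis=1)]
            known = records[col].astype(str).isin(schema.vocabularies[col]).to_numpy()
            np.testing.assert_array_equal(
                recovered[known], records[col].astype(str).to_numpy()[known]
            )
            offset += width

    def test_unknown_category_maps_to_zero_block(self):
        train = frame(c=["a", "b", "a"])
        schema = fit_schema(train)
        X = encode(frame(c=["zzz"]), schema)
        assert np.all(X == 0.0)

    def test_missing_numeric_imputed_to_zero_score(self):
        schema = fit_schema(frame(x=[1.0, 2.0, 3.0]))
        assert encode(frame(x=[np.nan]), schema)[0, 0] == pytest.approx(0.0)

    def test_no_leakage_from_held_out_rows(self):
        train = frame(x=[0.0, 1.0, 2.0])
        shifted_test = frame(x=[100.0, 101.0, 102.0])
        schema = fit_schema(train)
        X_test = encode(shifted_test, schema)
        # encoded with training statistics: far from zero mean
        assert X_test.mean() > 10
        refit = fit_schema(pd.concat([train, shifted_test], ignore_index=True))
        assert refit.numeric_mean["x"] != schema.numeric_mean["x"]

    def test_hazard_quotient_derived_from_guidance_value(self):
        df = frame(
            content=[1.0, 2.0, 10.0],
            health_guidance_value=[2.0, 2.0, 2.0],
        )
        schema = fit_schema(df)
        assert "hazard_quotient_log" in schema.numeric_columns
        raw = np.log1p(np.array([0.5, 1.0, 5.0]))
        expected = (raw - raw.mean()) / raw.std()
        j = schema.feature_names.index("hazard_quotient_log")
        np.testing.assert_allclose(encode(df, schema)[:, j], expected, atol=1e-9)

    def test_content_unit_conversion(self):
        df = frame(
            content=[1000.0, 1.0, 100.0],
            content_unit=["μg/kg", "mg/kg", "CFU/g"],
        )
        schema = fit_schema(df)
        # 1000 ug/kg == 1 mg/kg; the count unit contributes zero mass
        mass = dict(zip(schema.numeric_columns, range(len(schema.numeric_columns))))
        assert schema.numeric_mean["content_mass_mgkg"] == pytest.approx((1.0 + 1.0 + 0.0) / 3)
        assert schema.numeric_mean["content_count_log10"] == pytest.approx(
            np.log10(101.0) / 3
        )
        assert mass is not None


class TestLabels:
    @pytest.mark.parametrize(
        "index, level, area",
        [(0, "I", "safe"), (1, "II", "safe"), (2, "III", "warning"), (7, "VIII", "danger")],
    )
    def test_level_area_map(self, index, level, area):
        assert index_to_level(index) == level
        assert level_area(level) == area
        assert decode_labels([index]) == [(level, area)]

    def test_round_trip_identity(self):
        for i in range(8):
            assert level_to_index(index_to_level(i)) == i

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            index_to_level(8)
        with pytest.raises(ValueError):
            level_to_index("IX")

    def test_encode_labels_vector(self):
        np.testing.assert_array_equal(encode_labels(["I", "VIII", "III"]), [0, 7, 2])
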