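import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hccdx.io import (TabularDataset, load_table, save_table,
                      missingness_summary, validate_against_schema)
from hccdx.schema import (DatasetSchema, FeatureSpec, builtin_hcc_schema,
                          load_schema, save_schema, normalize_name)
from hccdx.synthetic import hcc_like


class TestBuiltinSchema:
    def test_table_shape_and_scale_counts(self):
        schema = builtin_hcc_schema()
        assert len(schema) == 49
        assert schema.n_qualitative() == 26
        assert schema.n_quantitative() == 23

    def test_age_at_diagnosis_entry(self):
        spec = builtin_hcc_schema().features[23]
        assert spec.name == "Age at diagnosis"
        assert spec.kind == "ratio"
        assert (spec.low, spec.high) == (20, 93)
        assert spec.mean == pytest.approx(64.691)
        assert spec.sd == pytest.approx(13.32)
        assert spec.missing_rate == 0.0

    def test_gender_is_dichotomous(self):
        spec = builtin_hcc_schema().features[0]
        assert spec.name == "Gender"
        assert spec.kind == "dichotomous"
        assert (spec.low, spec.high) == (0, 1)

    def test_mean_missingness_matches_overall_rate(self):
        # per-feature rates average to the table's overall missing fraction
        rates = [f.missing_rate for f in builtin_hcc_schema().features]
        assert np.mean(rates) * 100 == pytest.approx(10.22, abs=0.01)

    def test_every_spec_satisfies_its_invariants(self):
        # FeatureSpec validates on construction; also spot-check ordering
        schema = builtin_hcc_schema()
        for f in schema.features:
            assert f.low <= f.mean <= f.high
            assert f.sd >= 0
            assert 0 <= f.missing_rate <= 1


class TestFeatureSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(kind="nominal"),
        dict(mean=99.0),
        dict(sd=-1.0),
        dict(missing_rate=1.5),
    ])
    def test_invalid_spec_rejected(self, kwargs):
        base = dict(name="x", kind="ratio", low=0.0, high=10.0, mean=5.0, sd=1.0)
        with pytest.raises(ValueError):
            FeatureSpec(**{**base, **kwargs})

    def test_dichotomous_range_enforced(self):
        with pytest.raises(ValueError):
            FeatureSpec(name="x", kind="dichotomous", low=0, high=2, mean=1, sd=0.5)

    def test_duplicate_names_rejected(self):
        f = FeatureSpec(name="x", kind="ratio", low=0, high=1, mean=0.5, sd=0.1)
        g = FeatureSpec(name=" X ", kind="ratio", low=0, high=1, mean=0.5, sd=0.1)
        with pytest.raises(ValueError):
            DatasetSchema(features=[f, g])


class TestLoadTable:
    def _write(self, tmp_path, text):
        p = tmp_path / "t.csv"
        p.write_text(text)
        return p

    def test_missing_markers_masked(self, tmp_path):
        p = self._write(tmp_path, "a,b,c,d,Class\n1,?,3,4,0\n?,6,7,8,1\n9,10,?,12,1\n")
        ds = load_table(p)
        assert (ds.n_samples, ds.n_features) == (3, 4)
        assert ds.missing.sum() == 3
        assert np.isnan(ds.values[ds.missing]).all()

    def test_label_outside_binary_rejected(self, tmp_path):
        p = self._write(tmp_path, "a,Class\n1,2\n")
        with pytest.raises(ValueError, match="not in"):
            load_table(p)

    def test_unparseable_cell_names_row_and_column(self, tmp_path):
        p = self._write(tmp_path, "a,b,Class\n1,oops,0\n")
        with pytest.raises(ValueError, match="'b'.*'oops'"):
            load_table(p)

    def test_missing_label_rejected(self, tmp_path):
        p = self._write(tmp_path, "a,Class\n1,?\n")
        with pytest.raises(ValueError, match="missing label"):
            load_table(p)

    def test_label_column_matched_case_insensitively(self, tmp_path):
        p = self._write(tmp_path, "a,  class \n1,1\n")
        ds = load_table(p, label_column="Class")
        assert ds.labels.tolist() == [1]


class TestRoundTrip:
    def test_save_load_bit_exact(self, tmp_path, tiny_missing):
        path = tmp_path / "rt.csv"
        save_table(tiny_missing, path)
        back = load_table(path)
        np.testing.assert_array_equal(back.missing, tiny_missing.missing)
        np.testing.assert_array_equal(back.labels, tiny_missing.labels)
        obs = ~tiny_missing.missing
        np.testing.assert_array_equal(back.values[obs], tiny_missing.values[obs])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(allow_nan=False, allow_infinity=False,
                              width=64), min_size=4, max_size=4))
    def test_round_trip_arbitrary_floats(self, tmp_path_factory, row):
        values = np.array([row, row])
        ds = TabularDataset(values, np.zeros_like(values, dtype=bool),
                            np.array([0, 1]))
        path = tmp_path_factory.mktemp("rt") / "x.csv"
        save_table(ds, path)
        back = load_table(path)
        np.testing.assert_array_equal(back.values, ds.values)


class TestMissingnessSummary:
    def test_three_masked_cells_are_a_quarter(self, tiny_missing):
        s = missingness_summary(tiny_missing)
        assert s.overall == pytest.approx(3 / 12)
        assert s.n_complete_rows == 1

    def test_complete_table(self):
        ds = TabularDataset(np.ones((4, 3)), np.zeros((4, 3), bool),
                            np.array([0, 1, 0, 1]))
        s = missingness_summary(ds)
        assert s.overall == 0.0
        assert s.n_complete_rows == 4

    def test_overall_is_mean_of_per_feature(self, tiny_missing):
        s = missingness_summary(tiny_missing)
        assert s.overall == pytest.approx(float(np.mean(s.per_feature)))

    def test_hcc_like_synthetic_matches_schema_rates(self):
        # with the built-in schema's rates the synthetic table lands near
        # the published overall missingness and has very few complete rows
        overall = [missingness_summary(hcc_like(seed=s)).overall
                   for s in range(5)]
        assert np.mean(overall) * 100 == pytest.approx(10.22, abs=0.6)


class TestValidation:
    def test_clean_synthetic_table_is_clean(self):
        ds = hcc_like(seed=1, with_missingness=False)
        assert validate_against_schema(ds, ds.schema) == []

    def test_out_of_range_and_fractional_category_flagged(self, wide_schema):
        feats = [FeatureSpec(name="Gender", kind="dichotomous", low=0, high=1,
                             mean=0.5, sd=0.5),
                 FeatureSpec(name="Age", kind="ratio", low=20, high=93,
                             mean=60, sd=10)]
        schema = DatasetSchema(features=feats)
        values = np.array([[2.0, 50.0], [0.5, 10.0], [1.0, 50.0]])
        ds = TabularDataset(values, np.zeros_like(values, bool),
                            np.array([0, 1, 0]))
        v = validate_against_schema(ds, schema)
        reasons = {(x.feature, x.row) for x in v}
        assert ("Gender", 0) in reasons          # category code 2
        assert ("Gender", 1) in reasons          # fractional code 0.5
        assert ("Age", 1) in reasons             # below printed range
        assert len(v) == 3

    def test_column_count_mismatch_is_structural(self, wide_schema):
        ds = TabularDataset(np.ones((2, 2)), np.zeros((2, 2), bool),
                            np.array([0, 1]))
        with pytest.raises(ValueError, match="schema"):
            validate_against_schema(ds, wide_schema)


def test_schema_document_round_trip(tmp_path):
    schema = builtin_hcc_schema()
    p = tmp_path / "schema.yaml"
    save_schema(schema, p)
    back = load_schema(p)
    assert back.label_name == schema.label_name
    assert back.features == schema.features


def test_name_normalization():
    assert normalize_name("  Age   at  Diagnosis ") == "age at diagnosis"
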