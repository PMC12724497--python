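"""Feature-table ingestion, QC rules, z-scoring, views and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathstrat.features import (FeatureMatrix, FormatError,
                                InsufficientDataError, asymmetry_index,
                                load_feature_table, parse_feature_name,
                                row_col_normalize, select_view, strip_clinical,
                                zscore_columns, _qc_frame)
from pathstrat.schema import canonical_view_map


def _frame(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestColumnQC:
    def test_std_and_text_columns_dropped(self):
        raw = _frame({
            "subject_id": ["a", "b", "c"],
            "putamen_VOL_L": [1.0, 2.0, 3.0],
            "putamen_FA_L-std": [0.1, 0.2, 0.3],
            "notes": ["x", "y", "z"],
        })
        fm = _qc_frame(raw)
        assert fm.feature_names == ["putamen_VOL_L"]
        reasons = set(zip(fm.qc_ledger["id"], fm.qc_ledger["reason"]))
        assert ("putamen_FA_L-std", "std_suffix") in reasons
        assert ("notes", "non_numeric") in reasons

    def test_row_with_inf_dropped_and_ledgered(self):
        raw = _frame({
            "subject_id": ["a", "b", "c"],
            "putamen_VOL_L": [1.0, np.inf, 3.0],
            "caudate_FA_R": [0.5, 0.6, 0.7],
        })
        fm = _qc_frame(raw)
        assert fm.subject_ids == ["a", "c"]
        rows = fm.qc_ledger[fm.qc_ledger.kind == "row"]
        assert len(rows) == 1 and rows.iloc[0]["reason"] == "nonfinite"

    def test_clean_table_passes_through_with_empty_ledger(self):
        raw = _frame({
            "subject_id": [f"s{i}" for i in range(5)],
            "putamen_VOL_L": np.arange(5.0) + 1,
            "putamen_VOL_R": np.arange(5.0) + 2,
            "caudate_FA_L": np.linspace(0.1, 1, 5),
        })
        fm = _qc_frame(raw)
        assert fm.values.shape == (5, 3)
        assert fm.qc_ledger.empty

    def test_all_zero_modality_row_dropped(self):
        raw = _frame({
            "subject_id": ["a", "b"],
            "putamen_SBR_L": [0.0, 1.2],
            "caudate_SBR_R": [0.0, 0.9],
            "putamen_VOL_L": [5.0, 6.0],
        })
        fm = _qc_frame(raw)
        assert fm.subject_ids == ["b"]
        assert fm.qc_ledger.iloc[0]["reason"] == "all_zero_SBR"

    def test_missing_subject_id_is_format_error(self):
        with pytest.raises(FormatError):
            _qc_frame(_frame({"putamen_VOL_L": [1.0]}))

    def test_qc_ledger_conserves_rows_and_columns(self):
        raw = _frame({
            "subject_id": ["a", "b", "c", "d"],
            "putamen_VOL_L": [1.0, np.nan, 3.0, 4.0],
            "caudate_FA_R-std": [1, 2, 3, 4],
            "meta": list("wxyz"),
            "caudate_FA_R": [0.1, 0.2, 0.3, 0.4],
        })
        fm = _qc_frame(raw)
        dropped_rows = (fm.qc_ledger.kind == "row").sum()
        dropped_cols = (fm.qc_ledger.kind == "column").sum()
        assert fm.n_subjects + dropped_rows == 4
        assert fm.n_features + dropped_cols == 4  # subject_id not counted


class TestZScore:
    def test_simple_column(self):
        fm = FeatureMatrix(["a", "b", "c"], np.array([[1.0], [2.0], [3.0]]),
                           [parse_feature_name("putamen_VOL_L")])
        out = zscore_columns(fm)
        assert np.allclose(out.values[:, 0], [-1, 0, 1])

    def test_constant_column_excluded_and_logged(self):
        fm = FeatureMatrix(["a", "b", "c"],
                           np.array([[7.0, 1.0], [7.0, 2.0], [7.0, 3.0]]),
                           [parse_feature_name("putamen_VOL_L"),
                            parse_feature_name("putamen_VOL_R")])
        out = zscore_columns(fm)
        assert out.feature_names == ["putamen_VOL_R"]
        assert (out.qc_ledger["reason"] == "zero_variance").any()

    def test_hand_computed_values(self):
        # mean 70/3, sample SD sqrt(466.666/2) = 15.27525
        fm = FeatureMatrix(["a", "b", "c"], np.array([[10.0], [20.0], [40.0]]),
                           [parse_feature_name("putamen_VOL_L")])
        out = zscore_columns(fm)
        assert np.allclose(out.values[:, 0], [-0.8728716, -0.2182179, 1.0910895],
                           atol=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix([f"s{i}" for i in range(20)],
                           rng.normal(5, 3, (20, 4)),
                           [parse_feature_name(n) for n in
                            ("a_VOL_L", "b_FA_R", "c_MD_L", "d_SBR_R")])
        once = zscore_columns(fm)
        twice = zscore_columns(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_single_subject_rejected(self):
        fm = FeatureMatrix(["a"], np.array([[1.0]]),
                           [parse_feature_name("putamen_VOL_L")])
        with pytest.raises(InsufficientDataError):
            zscore_columns(fm)


class TestAsymmetry:
    @pytest.mark.parametrize("r,l,expected", [(2, 2, 0.0), (3, 1, 0.5)])
    def test_values(self, r, l, expected):
        assert asymmetry_index(r, l) == pytest.approx(expected)

    def test_zero_denominator_gives_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(asymmetry_index(0, 0))

    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
    @settings(deadline=None, max_examples=50)
    def test_bounded(self, r, l):
        assert -1 <= asymmetry_index(r, l) <= 1


@pytest.fixture(scope="module")
def std_fm(small_cohort):
    # run through QC (drops -std columns) as the pipeline does
    _, fm, _, _ = small_cohort
    return zscore_columns(_qc_frame(fm.to_frame(), view_map=canonical_view_map()))


class TestViews:
    @pytest.mark.parametrize("view,n", [("V1", 4), ("V2", 48), ("V3", 112), ("V4", 144)])
    def test_canonical_view_sizes(self, std_fm, view, n):
        assert select_view(std_fm, view).n_features == n

    def test_view_nesting(self, std_fm):
        sets = {v: set(select_view(std_fm, v).feature_names)
                for v in ("V1", "V2", "V3", "V4")}
        assert sets["V1"] <= sets["V2"] <= sets["V3"]
        assert sets["V2"] <= sets["V4"]

    def test_unknown_view_rejected(self, std_fm):
        with pytest.raises(ValueError):
            select_view(std_fm, "V9")

    def test_strip_clinical_removes_only_clin(self, std_fm):
        v1 = select_view(std_fm, "V1")
        assert strip_clinical(v1).n_features == 0
        v4 = select_view(std_fm, "V4")
        assert strip_clinical(v4).n_features == 140


class TestRowColNormalize:
    def test_two_by_two_fixed_point(self):
        fm = FeatureMatrix(["a", "b"], np.array([[1.0, -1.0], [-1.0, 1.0]]),
                           [parse_feature_name("x_VOL_L"),
                            parse_feature_name("x_VOL_R")], standardized=True)
        out = row_col_normalize(fm)
        assert np.allclose(out.values, fm.values, atol=1e-12)

    def test_doubly_normalized_matrix_unchanged(self):
        rng = np.random.default_rng(3)
        fm = FeatureMatrix([f"s{i}" for i in range(12)],
                           rng.normal(size=(12, 6)),
                           [parse_feature_name(f"r{i}_FA_L") for i in range(6)],
                           standardized=True)
        # iterate to a joint fixed point, then one more application is identity
        for _ in range(200):
            fm = row_col_normalize(fm)
        again = row_col_normalize(fm)
        assert np.allclose(again.values, fm.values, atol=1e-9)

    def test_output_rows_standardized(self):
        rng = np.random.default_rng(4)
        fm = FeatureMatrix([f"s{i}" for i in range(10)],
                           rng.normal(2, 5, (10, 6)),
                           [parse_feature_name(f"r{i}_MD_R") for i in range(6)],
                           standardized=True)
        out = row_col_normalize(fm)
        assert np.allclose(out.values.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(out.values.std(axis=1, ddof=0), 1, atol=1e-9)


def test_csv_round_trip(tmp_path, small_cohort):
    """Written cohort CSVs reload into the same retained matrix."""
    cfg, fm, clinical, _ = small_cohort
    fpath, cpath = tmp_path / "f.csv", tmp_path / "c.csv"
    fm.to_frame().to_csv(fpath, index=False)
    clinical.data.to_csv(cpath, index=False)
    loaded, clin = load_feature_table(fpath, cpath, view_map=canonical_view_map())
    kept = [n for n in fm.feature_names if not n.endswith("-std")]
    assert loaded.feature_names == kept
    orig = fm.to_frame()[kept].to_numpy(dtype=float)
    assert np.allclose(loaded.values, orig)
    assert clin.subject_ids == list(fm.subject_ids)
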