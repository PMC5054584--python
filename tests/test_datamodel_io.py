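"""Containers, validation and text round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from gaclock import (
    BetaMatrix,
    ClockModel,
    SampleSheet,
    ValidationError,
    effective_ga,
)
from gaclock.io import (
    read_beta_matrix,
    read_clock_model,
    read_sample_sheet,
    write_beta_matrix,
    write_clock_model,
    write_sample_sheet,
)
from conftest import random_beta_matrix


class TestBetaMatrix:
    def test_rejects_out_of_range_value_naming_cell(self):
        df = pd.DataFrame([[0.1, 0.9], [0.5, 1.2]], index=["cgA", "cgB"],
                          columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="cgB.*s2"):
            BetaMatrix(df)

    def test_rejects_duplicate_probe_ids(self):
        df = pd.DataFrame([[0.1], [0.2]], index=["cgA", "cgA"], columns=["s1"])
        with pytest.raises(ValidationError, match="duplicate probe"):
            BetaMatrix(df)

    def test_missing_state_is_nan(self):
        df = pd.DataFrame([[0.1, np.nan]], index=["cgA"], columns=["s1", "s2"])
        bm = BetaMatrix(df)
        assert bm.missing_mask.sum() == 1
        assert bm.missing_fraction("probe").loc["cgA"] == 0.5


class TestMatrixIO:
    def test_parse_with_missing_cell(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("probe_id\ts1\ts2\ncgA\t0.1\t0.9\ncgB\t0.5\t\n")
        bm = read_beta_matrix(path)
        assert bm.shape == (2, 2)
        assert np.isnan(bm.data.loc["cgB", "s2"])
        assert bm.data.loc["cgA", "s2"] == 0.9

    def test_out_of_range_file_raises(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("probe_id\ts1\ncgA\t1.2\n")
        with pytest.raises(ValidationError):
            read_beta_matrix(path)

    def test_na_sentinels(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("probe_id,s1,s2\ncgA,NA,NaN\n")
        bm = read_beta_matrix(path)
        assert bm.missing_mask.all()

    def test_round_trip_exact(self, tmp_path, rng):
        bm = random_beta_matrix(rng, 50, 10, missing_frac=0.1)
        # values with <= 6 decimals survive text round trip bit for bit
        bm = BetaMatrix(bm.data.round(6))
        path = tmp_path / "rt.tsv"
        write_beta_matrix(bm, path)
        back = read_beta_matrix(path)
        pd.testing.assert_frame_equal(back.data, bm.data)


class TestClockModelIO:
    def test_basic_parse(self, tmp_path):
        path = tmp_path / "clock.csv"
        path.write_text("term,coefficient\n(Intercept),38.0\ncg000001,-2.5\n")
        model = read_clock_model(path)
        assert model.intercept == 38.0
        assert len(model) == 1
        assert model.coefficients["cg000001"] == -2.5

    def test_missing_intercept_raises(self, tmp_path):
        path = tmp_path / "clock.csv"
        path.write_text("term,coefficient\ncg000001,-2.5\n")
        with pytest.raises(ValidationError, match="Intercept"):
            read_clock_model(path)

    def test_duplicate_probe_raises(self, tmp_path):
        path = tmp_path / "clock.csv"
        path.write_text("term,coefficient\n(Intercept),38\ncgA,1\ncgA,2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_clock_model(path)

    @settings(max_examples=20, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(coefs=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=30),
           intercept=st.floats(20, 46, allow_nan=False))
    def test_round_trip_preserves_coefficients_exactly(self, tmp_path, coefs, intercept):
        model = ClockModel(
            intercept=intercept,
            coefficients=pd.Series(coefs, index=[f"cg{i:06d}" for i in range(len(coefs))]),
        )
        path = tmp_path / "m.csv"
        write_clock_model(model, path)
        back = read_clock_model(path)
        assert back.intercept == model.intercept
        pd.testing.assert_series_equal(
            back.coefficients, model.coefficients, check_names=False
        )


class TestSampleSheet:
    def _sheet(self, **over):
        row = {"sample_id": "s1", "clinical_ga_weeks": 39.0, "tissue": "cord"}
        row.update(over)
        return pd.DataFrame([row])

    def test_cord_identity(self):
        assert effective_ga({"tissue": "cord", "clinical_ga_weeks": 39.0}) == 39.0

    def test_spot_adds_days_over_seven(self):
        row = {"tissue": "spot", "clinical_ga_weeks": 30.0, "days_to_sampling": 7}
        assert effective_ga(row) == 31.0

    def test_spot_maximum_observed_delay(self):
        row = {"tissue": "spot", "clinical_ga_weeks": 40.0, "days_to_sampling": 39}
        assert effective_ga(row) == pytest.approx(40 + 39 / 7)

    def test_spot_without_days_raises(self):
        with pytest.raises(ValidationError):
            effective_ga({"tissue": "spot", "clinical_ga_weeks": 30.0,
                          "days_to_sampling": float("nan")})

    def test_ga_window_enforced(self):
        with pytest.raises(ValidationError, match="clinical_ga_weeks"):
            SampleSheet(self._sheet(clinical_ga_weeks=50.0))

    def test_days_only_for_spot(self):
        with pytest.raises(ValidationError, match="non-spot"):
            SampleSheet(self._sheet(days_to_sampling=3))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 60), st.integers(0, 60))
    def test_effective_ga_monotone_in_days(self, d1, d2):
        ga = 30.0
        e1 = effective_ga({"tissue": "spot", "clinical_ga_weeks": ga, "days_to_sampling": d1})
        e2 = effective_ga({"tissue": "spot", "clinical_ga_weeks": ga, "days_to_sampling": d2})
        assert (e1 <= e2) == (d1 <= d2)

    def test_sheet_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "sample_id": ["a", "b"],
            "clinical_ga_weeks": [39.0, 30.0],
            "tissue": ["cord", "spot"],
            "days_to_sampling": [np.nan, 14],
            "birthweight": [3300.0, 1500.0],
            "insurance": ["private", "medicaid"],
        })
        sheet = SampleSheet(df)
        path = tmp_path / "sheet.csv"
        write_sample_sheet(sheet, path)
        back = read_sample_sheet(path)
        assert list(back.sample_ids) == ["a", "b"]
        assert back.effective_ga().loc["b"] == pytest.approx(32.0)
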