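import warnings

import pytest
import yaml

from rmragree.cohort import Gender, Subject
from rmragree.equations import (
    DispatchError,
    EquationConfigError,
    default_equations,
    load_equation_config,
    predict,
    predict_all,
)


def spec_by_name(specs, name):
    return next(s for s in specs if s.name == name)


def subj(gender, age=30, weight=70.0, height=1.70):
    return Subject("t", gender, age, weight, height)


class TestPredict:
    def test_owen_extremes_match_published_cells(self, specs):
        owen = spec_by_name(specs, "Owen")
        assert predict(subj(Gender.MALE, weight=177.0), owen) == pytest.approx(2684.4)
        assert predict(subj(Gender.FEMALE, weight=42.7), owen) == pytest.approx(1101.586)

    def test_hb_abbreviated_extremes(self, specs):
        abbr = spec_by_name(specs, "H-B_Abbr")
        assert predict(subj(Gender.MALE, weight=177.0), abbr) == pytest.approx(4248.0)
        assert predict(subj(Gender.FEMALE, weight=42.7), abbr) == pytest.approx(973.56)

    def test_harris_benedict_hand_value(self, specs):
        hb = spec_by_name(specs, "H-B")
        # 66.4730 + 13.7516*80 + 5.0033*180 - 6.7550*40 = 1800.795
        got = predict(subj(Gender.MALE, age=40, weight=80.0, height=1.80), hb)
        assert got == pytest.approx(66.4730 + 13.7516 * 80 + 5.0033 * 180 - 6.755 * 40)

    def test_mifflin_fixed_gender_offset(self, specs):
        mifflin = spec_by_name(specs, "Mifflin")
        male = predict(subj(Gender.MALE, age=35, weight=75, height=1.72), mifflin)
        female = predict(subj(Gender.FEMALE, age=35, weight=75, height=1.72), mifflin)
        assert male - female == pytest.approx(166.0)

    @pytest.mark.parametrize("name", ["Schofield", "F-W-U_1", "F-W-U_2"])
    @pytest.mark.parametrize("age,expected_bracket", [(18, (10, 18)), (30, (18, 30))])
    def test_lower_bracket_wins_shared_boundary(self, specs, name, age, expected_bracket):
        spec = spec_by_name(specs, name)
        row = spec.dispatch(Gender.MALE, age)
        assert (row.age_min, row.age_max) == expected_bracket

    def test_placeholder_equation_cannot_predict(self, specs):
        harrington = spec_by_name(specs, "Harrington")
        assert harrington.placeholder
        with pytest.raises(EquationConfigError):
            predict(subj(Gender.MALE), harrington)

    @pytest.mark.parametrize(
        "name", ["H-B", "H-B_Rev", "Mifflin", "F-W-U_1", "F-W-U_2", "Schofield",
                 "Owen", "H-B_Abbr"]
    )
    @pytest.mark.parametrize("gender", list(Gender))
    def test_nondecreasing_in_weight(self, specs, name, gender):
        spec = spec_by_name(specs, name)
        for age in (15, 25, 45, 70):
            lo = predict(subj(gender, age=age, weight=50.0), spec)
            hi = predict(subj(gender, age=age, weight=140.0), spec)
            assert hi >= lo


class TestPredictAll:
    def test_matrix_shape_and_finiteness(self, prediction_matrix):
        est = prediction_matrix.estimates
        assert est.shape == (383, 8)  # placeholder slot skipped
        assert est.notna().all().all()
        assert (est > 0).all().all()

    def test_excluded_subjects_still_predicted(self, prediction_matrix):
        excl = prediction_matrix.excluded
        if excl.any():
            assert prediction_matrix.estimates.loc[excl].notna().all().all()

    def test_full_config_yields_3447_values(self, cohort, specs):
        # Fill the placeholder slot with synthetic category-5 coefficients
        # (BMI, age, gender) so all nine equations predict: 383 x 9 = 3447.
        filled = []
        for s in specs:
            if s.placeholder:
                import dataclasses

                from rmragree.equations import CoefficientRow

                rows = tuple(
                    CoefficientRow(gender=g, age_min=10, age_max=120,
                                   intercept=1500.0, bmi=10.0, age=-4.0)
                    for g in Gender
                )
                s = dataclasses.replace(s, placeholder=False, rows=rows)
            filled.append(s)
        matrix = predict_all(cohort, filled)
        assert matrix.estimates.size == 3447
        assert matrix.estimates.notna().all().all()

    def test_empty_spec_list_warns(self, cohort):
        with pytest.warns(UserWarning, match="no active"):
            matrix = predict_all(cohort, [])
        assert matrix.estimates.empty

    def test_repredicting_is_bit_identical(self, cohort, specs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = predict_all(cohort, default_equations()).estimates
            b = predict_all(cohort, default_equations()).estimates
        assert a.equals(b)

    def test_dispatch_error_names_subject(self, specs):
        schofield = spec_by_name(specs, "Schofield")
        nine = Subject("kid", Gender.MALE, 9, 30.0, 1.35)
        with pytest.raises(DispatchError, match="kid"):
            predict_all([nine], [schofield])


class TestConfigValidation:
    def test_default_config_has_nine_specs(self, specs):
        assert len(specs) == 9
        assert sorted(s.category for s in specs) == [1, 1, 1, 2, 3, 3, 4, 4, 5]

    def _load(self, tmp_path, blocks):
        path = tmp_path / "eq.yaml"
        path.write_text(yaml.safe_dump(blocks))
        return load_equation_config(path)

    def test_overlapping_brackets_rejected(self, tmp_path):
        blocks = [
            {
                "name": "bad",
                "category": 3,
                "covariates": ["weight", "gender"],
                "rows": [
                    {"gender": g, "age_min": a, "age_max": b,
                     "intercept": 500, "weight": 10}
                    for g in ("male", "female")
                    for a, b in ((10, 30), (25, 120))
                ],
            }
        ]
        with pytest.raises(EquationConfigError, match="overlap"):
            self._load(tmp_path, blocks)

    def test_bracket_gap_rejected(self, tmp_path):
        blocks = [
            {
                "name": "bad",
                "category": 3,
                "covariates": ["weight", "gender"],
                "rows": [
                    {"gender": g, "age_min": a, "age_max": b,
                     "intercept": 500, "weight": 10}
                    for g in ("male", "female")
                    for a, b in ((10, 30), (40, 120))
                ],
            }
        ]
        with pytest.raises(EquationConfigError, match="gap"):
            self._load(tmp_path, blocks)

    def test_missing_gender_row_rejected(self, tmp_path):
        blocks = [
            {
                "name": "bad",
                "category": 4,
                "covariates": ["weight", "gender"],
                "rows": [{"gender": "male", "age_min": 10, "age_max": 120,
                          "intercept": 879, "weight": 10.2}],
            }
        ]
        with pytest.raises(EquationConfigError, match="female"):
            self._load(tmp_path, blocks)

    def test_unknown_covariate_rejected(self, tmp_path):
        blocks = [
            {"name": "bad", "category": 1, "covariates": ["weight", "girth"],
             "rows": []}
        ]
        with pytest.raises(EquationConfigError, match="girth"):
            self._load(tmp_path, blocks)
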