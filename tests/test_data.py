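import numpy as np
import pytest

from vpapk.data import (
    Covariates,
    DatasetError,
    DoseEvent,
    ObservationEvent,
    PKDataset,
    SubjectRecord,
    read_dataset,
    validate_dataset,
    write_dataset,
)


def _minimal_csv(tmp_path, text):
    path = tmp_path / "ds.csv"
    path.write_text(text)
    return path


HEADER = "ID,TIME,EVID,AMT,DV,MDV,II,SS,TAD,WT,AGE,SEX,ALB,DD,FORM\n"


class TestRead:
    def test_minimal_file_one_subject_two_observations(self, tmp_path):
        path = _minimal_csv(tmp_path, HEADER + (
            "1,0,1,240,,1,12,1,,20,6,0,42,480,syrup\n"
            "1,12,0,,55.0,0,,,12,20,6,0,42,480,syrup\n"
            "1,24,0,,60.0,0,,,12,20,6,0,42,480,syrup\n"))
        ds = read_dataset(path)
        assert len(ds) == 1
        assert ds.n_observations == 2
        s = ds.subjects[0]
        assert s.doses[0].steady_state and s.doses[0].interdose_interval == 12
        assert s.covariates.weight == 20 and s.covariates.formulation == "syrup"

    def test_conflicting_covariate_within_subject_raises(self, tmp_path):
        path = _minimal_csv(tmp_path, HEADER + (
            "1,0,1,240,,1,12,1,,20,6,0,42,480,syrup\n"
            "1,12,0,,55.0,0,,,12,20,6,1,42,480,syrup\n"))
        with pytest.raises(DatasetError, match="conflicting"):
            read_dataset(path)

    def test_subject_missing_required_covariate_is_dropped_and_counted(self, tmp_path):
        path = _minimal_csv(tmp_path, HEADER + (
            "1,0,1,240,,1,12,1,,20,6,0,42,480,syrup\n"
            "1,12,0,,55.0,0,,,12,20,6,0,42,480,syrup\n"
            "2,0,1,240,,1,12,1,,,6,0,42,480,syrup\n"
            "2,12,0,,55.0,0,,,12,,6,0,42,480,syrup\n"))
        ds = read_dataset(path)
        assert len(ds) == 1
        assert "dropped 1 subject" in ds.provenance

    def test_roundtrip_write_read_identity(self, tmp_path, steady_state_subject):
        ds = PKDataset(subjects=(steady_state_subject,), provenance="test")
        out = tmp_path / "rt.csv"
        write_dataset(ds, out)
        ds2 = read_dataset(out)
        s1, s2 = ds.subjects[0], ds2.subjects[0]
        assert s1.covariates == s2.covariates
        assert s1.doses == s2.doses
        assert s1.observations == s2.observations


class TestInvariants:
    def test_observation_without_dose_rejected(self, steady_state_subject):
        with pytest.raises(DatasetError, match="no dose"):
            SubjectRecord(id="x", covariates=steady_state_subject.covariates,
                          doses=(), observations=steady_state_subject.observations)

    def test_duplicate_subject_ids_rejected(self, steady_state_subject):
        with pytest.raises(DatasetError, match="duplicate"):
            PKDataset(subjects=(steady_state_subject, steady_state_subject))

    def test_ddw_consistency_enforced_and_derived(self):
        cov = Covariates(sex="male", age=5, weight=20, albumin=42,
                         daily_dose=480, formulation="syrup")
        assert cov.daily_dose_per_kg == pytest.approx(24.0)
        with pytest.raises(DatasetError, match="inconsistent"):
            Covariates(sex="male", age=5, weight=20, albumin=42,
                       daily_dose=480, formulation="syrup",
                       daily_dose_per_kg=30.0)

    def test_pma_derived_as_postnatal_plus_term(self):
        cov = Covariates(sex="female", age=2.0, weight=12, albumin=42,
                         daily_dose=300, formulation="syrup")
        assert cov.pma == pytest.approx(2.0 * 365.25 / 7 + 40.0)
        assert cov.pma_derived

    @pytest.mark.parametrize("kwargs", [
        {"age": -1}, {"weight": -3}, {"albumin": 0}, {"daily_dose": 0},
        {"sex": "other"}, {"formulation": "patch"},
    ])
    def test_covariate_domain_violations(self, kwargs):
        base = dict(sex="male", age=5, weight=20, albumin=42,
                    daily_dose=480, formulation="syrup")
        base.update(kwargs)
        with pytest.raises(DatasetError):
            Covariates(**base)

    def test_dose_and_observation_events_validated(self):
        with pytest.raises(DatasetError):
            DoseEvent(time=0, amount=-5)
        with pytest.raises(DatasetError):
            DoseEvent(time=0, amount=100, steady_state=True)  # missing II
        with pytest.raises(DatasetError):
            ObservationEvent(time=1, concentration=0.0, time_after_dose=1)


class TestValidate:
    def _ds(self, **cov_kwargs):
        base = dict(sex="male", age=5, weight=19.0, albumin=42,
                    daily_dose=480, formulation="syrup")
        base.update(cov_kwargs)
        s = SubjectRecord(
            id="a", covariates=Covariates(**base),
            doses=(DoseEvent(0, 240, 12, True),),
            observations=(ObservationEvent(12, 50, 12),))
        return PKDataset(subjects=(s,))

    def test_median_weight_child_passes(self):
        assert validate_dataset(self._ds(weight=19.0)) == []

    def test_adult_age_flagged_against_pediatric_bound(self):
        violations = validate_dataset(self._ds(age=40.0))
        assert [v.field for v in violations] == ["age"]
        assert violations[0].upper == 15.0

    def test_violations_monotone_as_bounds_widen(self):
        ds = self._ds(age=40.0, weight=3.0)
        narrow = validate_dataset(ds, {"age": (0, 15), "weight": (4, 70)})
        wide = validate_dataset(ds, {"age": (0, 100), "weight": (1, 100)})
        assert len(wide) <= len(narrow)
        assert len(narrow) == 2 and len(wide) == 0

    def test_validation_does_not_mutate(self):
        ds = self._ds(age=40.0)
        before = ds.subjects[0].covariates
        validate_dataset(ds)
        assert ds.subjects[0].covariates == before
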