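"""The synthetic trial and case-cohort generators and their invariants."""

import numpy as np
import pandas as pd
import pytest

from lipidfa.aggregation import parse_panel, within_class_fa
from lipidfa.casecohort import fit_prentice_cox, validate_records
from lipidfa.preprocess import missingness_filter
from lipidfa.synthetic import (
    ArmEffect,
    CohortSpec,
    PanelSpec,
    SpeciesSpec,
    TrialSpec,
    default_panel,
    default_trial,
    gen_casecohort,
    gen_trial,
)


class TestTrialGenerator:
    def test_shapes_and_reproducibility(self):
        t1 = gen_trial(seed=3)
        t2 = gen_trial(seed=3)
        pd.testing.assert_frame_equal(t1.week0, t2.week0)
        pd.testing.assert_frame_equal(t1.markers, t2.markers)
        assert len(t1.metadata) == 113
        assert t1.metadata["arm"].value_counts().to_dict() == {
            "MUFA": 39, "SFA": 38, "MUFA_PUFA": 36,
        }
        t3 = gen_trial(seed=4)
        assert not t3.week0.equals(t1.week0)

    def test_panel_parses_and_spans_all_classes(self):
        panel = default_panel()
        parsed = parse_panel([sp.name for sp in panel.species])
        codes = {sp.lipid_class.code for sp in parsed.values()}
        assert len(codes) == 16

    def test_censoring_fraction_matches_detection_quantile(self):
        t = gen_trial(seed=1)
        panel = default_panel()
        n = 2 * len(t.metadata)
        for sp in panel.species:
            q = sp.detection_quantile
            observed_missing = t.week0[sp.name].isna().sum() + t.week16[sp.name].isna().sum()
            if q == 0:
                assert observed_missing == 0
            else:
                # empirical pooled-quantile thresholding: binomial-error band
                se = np.sqrt(q * (1 - q) * n)
                assert abs(observed_missing - q * n) <= 3 * se + 2

    def test_heavily_censored_species_trips_exclusion(self):
        excluded = 0
        for s in range(6):
            t = gen_trial(seed=s)
            pooled = pd.concat([t.week0, t.week16])
            _, report = missingness_filter(pooled)
            excluded += any(sp for sp in report.excluded_species)
        assert excluded >= 4  # the 0.8-quantile species goes most seeds

    def test_null_design_arms_indistinguishable(self):
        spec = TrialSpec(arm_effects=[], markers=[])
        panel = PanelSpec(
            species=[SpeciesSpec("CE(18:0)", 1.0), SpeciesSpec("DAG(16:0/18:1)", 0.5)],
            rho=0.0,
        )
        diffs = []
        for s in range(20):
            t = gen_trial(spec, panel, seed=s)
            fa = within_class_fa(t.week16)
            g = np.log(fa["CE[18:0]"]).groupby(t.metadata["arm"]).mean()
            diffs.append(g["MUFA"] - g["SFA"])
        # arm means coincide up to Monte-Carlo error
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.05

    def test_unknown_effect_target_rejected(self):
        spec = TrialSpec(arm_effects=[ArmEffect("PI[24:1]", "MUFA", -1.0)])
        with pytest.raises(ValueError, match="no species"):
            gen_trial(spec, default_panel(), seed=0)

    def test_markers_track_their_generating_predictors(self):
        t = gen_trial(seed=2)
        fa0 = within_class_fa(t.week0.fillna(t.week0.min() / 2))
        # LDL responds to CE[18:0] change with beta 0.20 per SD
        d_marker = t.markers["LDL_C_week16"] - t.markers["LDL_C_week0"]
        assert d_marker.std() > 0


class TestCaseCohortGenerator:
    def test_output_satisfies_reader_invariants(self):
        table, truth = gen_casecohort(seed=9)
        validate_records(table)
        assert truth["n_cases"] == int(table["event"].sum())
        assert (table["in_subcohort"] | table["is_case"]).all()

    def test_case_count_near_design_target(self):
        counts = [gen_casecohort(seed=s)[1]["n_cases"] for s in range(5)]
        assert 120 <= np.mean(counts) <= 260  # ~180 expected at the scaled design

    def test_null_hazard_ratio_recovered(self):
        spec = CohortSpec(log_hr_exposure=0.0, baseline_hazard=0.004)
        est = []
        for s in range(10):
            table, _ = gen_casecohort(spec, seed=s)
            fit = fit_prentice_cox(table, ["exposure", "class_total", "sex", "conf"])
            est.append(fit.params["exposure"])
        assert abs(np.mean(est)) < 0.08

    def test_subcohort_equals_cohort_gives_full_cohort(self):
        spec = CohortSpec(cohort_size=400, subcohort_size=400, baseline_hazard=0.01)
        table, truth = gen_casecohort(spec, seed=2)
        assert len(table) == 400
        assert table["in_subcohort"].all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(cohort_size=100, subcohort_size=200)
        with pytest.raises(ValueError):
            CohortSpec(baseline_hazard=0.0)
        with pytest.raises(ValueError, match="zero cases"):
            gen_casecohort(CohortSpec(cohort_size=50, subcohort_size=10,
                                      baseline_hazard=1e-9), seed=1)
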