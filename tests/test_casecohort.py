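"""Prentice risk sets, the weighted Cox fit, FDR, and Schoenfeld diagnostics."""

import numpy as np
import pandas as pd
import pytest

from lipidfa.casecohort import (
    SeparationError,
    fdr_bh,
    fit_prentice_cox,
    prentice_riskset,
    schoenfeld_check,
    validate_records,
)
from lipidfa.synthetic import CohortSpec, gen_casecohort

COVS = ["exposure", "class_total", "sex", "conf"]


def _toy_records():
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4],
            "in_subcohort": [True, True, True, False],
            "is_case": [False, True, False, True],
            "entry_age": [50.0, 45.0, 40.0, 42.0],
            "exit_age": [70.0, 55.0, 65.0, 60.0],
            "event": [0, 1, 0, 1],
            "exposure": [0.1, -0.2, 0.5, 1.0],
        }
    )


class TestPrenticeRiskset:
    def test_nonsubcohort_case_only_at_own_failure(self):
        r = _toy_records()
        assert 4 in prentice_riskset(r, 60.0)
        assert 4 not in prentice_riskset(r, 55.0)
        assert 4 not in prentice_riskset(r, 59.0)

    def test_subcohort_member_spans_window(self):
        r = _toy_records()
        for t in (50.5, 60.0, 70.0):
            assert 1 in prentice_riskset(r, t)
        assert 1 not in prentice_riskset(r, 50.0)  # left truncation: entry < t
        assert 1 not in prentice_riskset(r, 71.0)

    def test_age_outside_all_windows_is_empty(self):
        assert prentice_riskset(_toy_records(), 20.0) == set()

    def test_full_cohort_reduces_to_standard_at_risk(self):
        r = _toy_records()
        r["in_subcohort"] = True
        assert prentice_riskset(r, 60.0) == {1, 3, 4}


def test_record_invariants_enforced():
    r = _toy_records()
    r.loc[0, "exit_age"] = 40.0  # entry >= exit
    with pytest.raises(ValueError, match="entry_age"):
        validate_records(r)
    r = _toy_records()
    r.loc[2, "in_subcohort"] = False  # non-subcohort non-case
    with pytest.raises(ValueError, match="non-subcohort"):
        validate_records(r)


def test_full_cohort_equals_lifelines_oracle():
    """With everyone in the subcohort the fit is a standard Cox model."""
    from lifelines import CoxPHFitter

    spec = CohortSpec(cohort_size=600, subcohort_size=600, baseline_hazard=0.01)
    records, _ = gen_casecohort(spec, seed=5)
    fit = fit_prentice_cox(records, COVS)
    cph = CoxPHFitter()
    cph.fit(
        records[["entry_age", "exit_age", "event"] + COVS],
        duration_col="exit_age",
        event_col="event",
        entry_col="entry_age",
        fit_options={"precision": 1e-11},
    )
    np.testing.assert_allclose(fit.params.to_numpy(), cph.params_.to_numpy(), atol=1e-6)


def test_two_subject_separation_flagged():
    r = pd.DataFrame(
        {
            "id": [1, 2],
            "in_subcohort": [True, True],
            "is_case": [True, False],
            "entry_age": [40.0, 40.0],
            "exit_age": [50.0, 60.0],
            "event": [1, 0],
            "x": [1.0, 0.0],
        }
    )
    with pytest.raises(SeparationError):
        fit_prentice_cox(r, ["x"])


def test_hr_equivariance_under_exposure_rescaling():
    records, _ = gen_casecohort(seed=12)
    fit = fit_prentice_cox(records, COVS)
    r2 = records.assign(exposure=records["exposure"] * 2.0)
    fit2 = fit_prentice_cox(r2, COVS)
    assert fit2.params["exposure"] == pytest.approx(fit.params["exposure"] / 2.0, rel=1e-5)


def test_zero_events_rejected():
    r = _toy_records()
    r["event"] = 0
    r["is_case"] = False
    r["in_subcohort"] = True
    with pytest.raises(ValueError, match="zero events"):
        fit_prentice_cox(r, ["exposure"])


class TestFdrBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_and_single(self):
        np.testing.assert_allclose(fdr_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(fdr_bh([0.07]), [0.07])

    def test_adjusted_at_least_raw_and_order_preserving(self, rng):
        p = rng.uniform(size=25)
        adj = fdr_bh(p)
        assert (adj >= p - 1e-12).all()
        assert ((np.argsort(p) == np.argsort(adj)) | (np.diff(np.sort(adj)) >= -1e-12).all()).all()


class TestSchoenfeld:
    def test_null_proportional_hazards_uncorrelated(self):
        flagged = 0
        runs = 20
        for s in range(runs):
            spec = CohortSpec(cohort_size=700, subcohort_size=700, baseline_hazard=0.01)
            records, _ = gen_casecohort(spec, seed=100 + s)
            fit = fit_prentice_cox(records, ["exposure"])
            diag = schoenfeld_check(fit, records)
            flagged += (diag["p"] < 0.05).any()
        assert flagged / runs <= 0.25  # near-nominal false-positive rate

    def test_too_few_events_skipped(self):
        # single event with an interior exposure value: the fit converges but
        # the proportional-hazards diagnostic cannot run
        r = pd.DataFrame(
            {
                "id": [1, 2, 3],
                "in_subcohort": True,
                "is_case": [True, False, False],
                "entry_age": [40.0, 40.0, 40.0],
                "exit_age": [50.0, 60.0, 61.0],
                "event": [1, 0, 0],
                "x": [0.2, 0.5, -0.3],
            }
        )
        fit = fit_prentice_cox(r, ["x"])
        diag = schoenfeld_check(fit, r)
        assert diag.empty
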