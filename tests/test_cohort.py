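"""Synthetic cohort generation, summarization, and 1:k matched pairing."""

import numpy as np
import pytest

from slnbcost.cohort import (
    CohortSpec,
    MatchingError,
    PatientRecord,
    TABLE_COHORT_SPECS,
    frame_to_records,
    generate_cohort,
    pair_cohorts,
    records_to_frame,
    summarize_cohort,
)


def _record(pid, gender="female", cT=1, age=50.0, cohort="upfront_snd"):
    return PatientRecord(
        patient_id=pid, cohort=cohort, age=age, gender=gender, cT=cT,
        total_cost=1000.0, length_of_stay=1, theatre_minutes=90.0, visits_60d=2,
    )


class TestGenerate:
    def test_zero_patients(self):
        assert generate_cohort(TABLE_COHORT_SPECS["slnb"], n=0, seed=1) == []

    def test_determinism_full_record_equality(self):
        spec = TABLE_COHORT_SPECS["delayed_snd"]
        a = generate_cohort(spec, n=200, seed=99)
        b = generate_cohort(spec, n=200, seed=99)
        assert a == b

    def test_different_seeds_differ(self):
        spec = TABLE_COHORT_SPECS["slnb"]
        assert generate_cohort(spec, n=50, seed=1) != generate_cohort(spec, n=50, seed=2)

    def test_cost_mean_recovery_upfront(self):
        """At n = 10,000 the sample cost mean is within 4 standard errors."""
        spec = TABLE_COHORT_SPECS["upfront_snd"]
        records = generate_cohort(spec, n=10_000, seed=5)
        costs = np.array([r.total_cost for r in records])
        assert abs(costs.mean() - spec.cost_mean) < 4 * spec.cost_sd / 100.0

    def test_utilization_medians_match_printed_values(self):
        for name, spec in TABLE_COHORT_SPECS.items():
            records = generate_cohort(spec, n=3000, seed=11)
            s = summarize_cohort(records)
            assert s.los_median == spec.los_median, name
            assert s.visits_median == spec.visits_median, name
            assert s.theatre_median == pytest.approx(spec.theatre_median, rel=0.03), name

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(cohort="slnb", n=10, cost_mean=-1.0, cost_sd=1.0,
                       los_median=1, theatre_median=90, visits_median=2,
                       cT1_fraction=0.5)
        with pytest.raises(ValueError):
            CohortSpec(cohort="slnb", n=10, cost_mean=100.0, cost_sd=1.0,
                       los_median=1, theatre_median=90, visits_median=2,
                       cT1_fraction=1.5)

    def test_correlated_utilization_preserves_marginals(self):
        spec_uncorr = TABLE_COHORT_SPECS["slnb"]
        spec_corr = CohortSpec(**{**spec_uncorr.__dict__, "cost_utilization_corr": 0.6})
        records = generate_cohort(spec_corr, n=4000, seed=3)
        s = summarize_cohort(records)
        assert s.los_median == spec_corr.los_median
        costs = np.array([r.total_cost for r in records])
        los = np.array([r.length_of_stay for r in records])
        # coupling produces a clearly positive rank correlation
        from scipy.stats import spearmanr
        assert spearmanr(costs, los).statistic > 0.3


class TestSummarize:
    def test_empty_cohort_flags_undefined_moments(self):
        s = summarize_cohort([])
        assert s.n == 0
        assert s.cost_mean is None and s.cost_sd is None

    def test_single_record_sd_undefined(self):
        s = summarize_cohort([_record(0)])
        assert s.n == 1
        assert s.cost_mean == 1000.0
        assert s.cost_sd is None

    def test_median_and_mean_small_sample(self):
        recs = [
            PatientRecord(i, "slnb", 50.0, "female", 1, float(c), 1, 90.0, 2)
            for i, c in enumerate([1, 2, 3])
        ]
        s = summarize_cohort(recs)
        assert s.cost_mean == pytest.approx(2.0)
        assert np.median([r.total_cost for r in recs]) == 2.0
        # SD uses the n-1 denominator
        assert s.cost_sd == pytest.approx(1.0)

    def test_generate_summarize_recovers_spec(self):
        """Brute-force recomputation agrees with configured parameters."""
        spec = TABLE_COHORT_SPECS["slnb"]
        records = generate_cohort(spec, n=10_000, seed=21)
        s = summarize_cohort(records)
        se_mean = spec.cost_sd / 100.0
        se_sd = spec.cost_sd / np.sqrt(2 * (10_000 - 1))
        assert abs(s.cost_mean - spec.cost_mean) < 4 * se_mean
        assert abs(s.cost_sd - spec.cost_sd) < 4 * se_sd


class TestPairing:
    def test_exact_small_case(self):
        slnb = [_record(0, cohort="slnb")]
        comps = [_record(i) for i in (10, 11, 12)]
        matches = pair_cohorts(slnb, comps, ratio=3)
        assert sorted(matches[0]) == [10, 11, 12]

    def test_infeasible_raises_with_strata(self):
        slnb = [_record(0, cohort="slnb")]
        comps = [_record(10), _record(11)]
        with pytest.raises(MatchingError, match="female"):
            pair_cohorts(slnb, comps, ratio=3)

    def test_exact_match_fields_respected_and_no_reuse(self):
        rng = np.random.default_rng(8)
        slnb = [
            _record(i, gender=("female" if i % 2 else "male"), cT=1 + i % 2,
                    age=float(rng.uniform(40, 70)), cohort="slnb")
            for i in range(12)
        ]
        comps = []
        pid = 100
        for rec in slnb:
            for _ in range(3):  # guarantee feasibility per stratum
                comps.append(_record(pid, gender=rec.gender, cT=rec.cT,
                                     age=float(rng.uniform(40, 70))))
                pid += 1
        matches = pair_cohorts(slnb, comps, ratio=3)
        used = [c for ids in matches.values() for c in ids]
        assert len(used) == 36 and len(set(used)) == 36
        by_id = {c.patient_id: c for c in comps}
        for rec in slnb:
            for cid in matches[rec.patient_id]:
                assert by_id[cid].gender == rec.gender
                assert by_id[cid].cT == rec.cT

    def test_nearest_age_with_stable_tie_break(self):
        slnb = [_record(0, age=50.0, cohort="slnb")]
        comps = [
            _record(10, age=60.0),
            _record(11, age=51.0),
            _record(12, age=49.0),  # same |diff| as 11 -> lower id wins first
        ]
        matches = pair_cohorts(slnb, comps, ratio=2)
        assert matches[0] == [11, 12]


def test_csv_roundtrip(tmp_path):
    records = generate_cohort(TABLE_COHORT_SPECS["slnb"], n=25, seed=4)
    path = tmp_path / "cohort.csv"
    records_to_frame(records).to_csv(path, index=False)
    import pandas as pd

    back = frame_to_records(pd.read_csv(path))
    assert [r.patient_id for r in back] == [r.patient_id for r in records]
    assert np.allclose([r.total_cost for r in back], [r.total_cost for r in records])
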