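import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from fluidresp.changes import baseline_return_check
from fluidresp.cohort import (
    CohortSpec,
    generate_cohort,
    paper_default_spec,
    truncnorm_moment_params,
)
from fluidresp.datamodel import TimePoint, ValidationError, VARIABLES


class TestMomentMatchedTruncnorm:
    @pytest.mark.parametrize(
        "mean,sd,lo,hi",
        [
            (55.23, 17.82, -50.0, 100.0),
            (95.9, 102.5, -90.0, 600.0),
            (2.30, 1.98, 0.0, math.inf),
            (9.53, 6.00, 0.0, math.inf),
        ],
    )
    def test_truncated_moments_match_targets(self, mean, sd, lo, hi):
        mu, sig = truncnorm_moment_params(mean, sd, lo, hi)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        assert float(m) == pytest.approx(mean, abs=1e-6)
        assert math.sqrt(float(v)) == pytest.approx(sd, abs=1e-6)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValidationError):
            truncnorm_moment_params(5.0, 1.0, 10.0, 20.0)  # mean outside
        with pytest.raises(ValidationError):
            truncnorm_moment_params(5.0, 100.0, 0.0, 10.0)  # sd too large


class TestPaperDefaults:
    def test_responder_fraction(self):
        assert paper_default_spec().responder_fraction == 0.406

    def test_responder_ve_sv_change_from_printed_means(self):
        eff = paper_default_spec().effects.responders["sv"]
        assert eff.ve_mean == pytest.approx(22.07, abs=0.01)

    def test_nonresponder_ppv_lrm_change(self):
        eff = paper_default_spec().effects.nonresponders["ppv"]
        assert eff.lrm_mean == 95.9

    def test_baseline_tables(self):
        r = paper_default_spec().effects.responders
        assert (r["pi"].t1_mean, r["pi"].t1_sd) == (2.30, 1.98)
        assert (r["sv"].t1_mean, r["sv"].t1_sd) == (60.3, 25.4)
        assert (r["pi"].lrm_mean, r["pi"].lrm_sd) == (55.23, 17.82)


class TestGeneration:
    def test_seeded_determinism(self):
        spec = paper_default_spec(n_patients=32, seed=7)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for ra, rb in zip(a, b):
            assert ra.patient_id == rb.patient_id
            for tp in TimePoint:
                for var in VARIABLES:
                    assert ra.value(var, tp) == rb.value(var, tp)

    def test_label_consistency(self, big_cohort):
        records, _ = big_cohort
        for rec in records:
            assert rec.responder == (rec.changes.delta_sv_ve >= 10.0)

    def test_realized_group_summary_near_targets(self, big_cohort):
        # responder-group LRM change of the perfusion index, by realized label
        records, _ = big_cohort
        dpi = np.array([r.changes.delta_pi_lrm for r in records])
        resp = np.array([r.responder for r in records])
        assert dpi[resp].mean() == pytest.approx(55.23, abs=0.5)
        assert dpi[resp].std(ddof=1) == pytest.approx(17.82, abs=0.5)

    def test_copula_correlation_matches_mc_adjusted_target(self):
        # Monte-Carlo oracle at n = 10^6 (truncation-adjusted Pearson
        # correlation for a latent rho of 0.9): 0.8996 in responders,
        # 0.8998 in non-responders.
        spec = replace(paper_default_spec(), n_patients=5000, seed=3,
                       rho_pi_sv=0.9)
        _, draws = generate_cohort(spec, return_draws=True)
        for group, target in (("responder", 0.8996), ("nonresponder", 0.8998)):
            sub = draws[draws.drawn_group == group]
            r = np.corrcoef(sub.lrm_pi, sub.lrm_sv)[0, 1]
            assert r == pytest.approx(target, abs=0.03)

    def test_pooled_pi_sv_correlation_near_published_r2(self, big_cohort):
        records, _ = big_cohort
        dpi = np.array([r.changes.delta_pi_lrm for r in records])
        dsv = np.array([r.changes.delta_sv_lrm for r in records])
        r2 = np.corrcoef(dpi, dsv)[0, 1] ** 2
        assert r2 == pytest.approx(0.16, abs=0.04)

    def test_baseline_return_rule_holds(self, paper_cohort_32):
        for rec in paper_cohort_32:
            for var in ("pi", "sv"):
                t1 = rec.value(var, TimePoint.T1)
                t3 = rec.value(var, TimePoint.T3)
                assert baseline_return_check(t1, t3)

    def test_variation_indices_absent_at_t3(self, paper_cohort_32):
        for rec in paper_cohort_32:
            for var in ("ppv", "svv", "pvi"):
                assert rec.value(var, TimePoint.T3) is None
                assert rec.value(var, TimePoint.T4) is not None

    def test_svv_missingness_flag(self):
        spec = replace(paper_default_spec(n_patients=32, seed=5),
                       svv_missing_nonresponders=2)
        records = generate_cohort(spec)
        blanked = [r for r in records
                   if all(r.value("svv", tp) is None for tp in TimePoint)]
        assert len(blanked) == 2
        assert all(not r.responder for r in blanked)

    def test_panels_validate_everywhere(self, paper_cohort_32):
        # construction would have raised otherwise; spot-check pressures
        for rec in paper_cohort_32:
            for tp in TimePoint:
                p = rec.panel(tp)
                if p.map_mmhg is not None:
                    assert p.dbp_mmhg - 1 <= p.map_mmhg <= p.sbp_mmhg + 1


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 1},
            {"responder_fraction": 0.0},
            {"responder_fraction": 1.0},
            {"rho_pi_sv": 1.0},
            {"svv_missing_nonresponders": 33},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        base = paper_default_spec()
        with pytest.raises(ValidationError):
            replace(base, **kwargs)
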