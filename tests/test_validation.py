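"""Back-generation cross-validation: holdout, signed MAPE, banding, pipeline."""

import warnings

import numpy as np
import pytest

import gripref as g
from gripref import published as pub
from gripref.validation import (
    backgen_test,
    mape_interpret,
    run_backgeneration,
    stratified_holdout,
)


class TestStratifiedHoldout:
    def test_balanced_strata_contribute_exact_fraction(self):
        recs = []
        for sex in ("boys", "girls"):
            for age in pub.AGES:
                for i in range(300):
                    recs.append(g.CohortRecord(
                        id=f"{sex}{age}{i}", sex=sex, age=age, height=160,
                        weight=45, bmi=17.6, hgs_left=20, hgs_right=20,
                        hgs_abs=20.0))
        full, holdout = stratified_holdout(recs, 0.2, seed=7)
        assert len(full) == 3000 and len(holdout) == 600
        for sex in ("boys", "girls"):
            for age in pub.AGES:
                k = sum(1 for r in holdout if r.sex == sex and r.age == age)
                assert k == 60

    def test_same_seed_reproduces_identical_subset(self, default_cohort):
        _, h1 = stratified_holdout(default_cohort, 0.2, seed=7)
        _, h2 = stratified_holdout(default_cohort, 0.2, seed=7)
        assert [r.id for r in h1] == [r.id for r in h2]
        _, h3 = stratified_holdout(default_cohort, 0.2, seed=8)
        assert [r.id for r in h1] != [r.id for r in h3]

    def test_small_stratum_rounds_half_up_and_warns(self):
        recs = [g.CohortRecord(id=str(i), sex="boys", age=13, height=160,
                               weight=45, bmi=17.6, hgs_left=20, hgs_right=20,
                               hgs_abs=20.0) for i in range(11)]
        with pytest.warns(UserWarning, match="holdout"):
            _, holdout = stratified_holdout(recs, 0.2, seed=1)
        assert len(holdout) == 2  # round(0.2 * 11) half-up

    def test_invalid_fraction_rejected(self, default_cohort):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                stratified_holdout(default_cohort, bad, seed=1)


class TestBackgenTest:
    def test_published_male_block(self):
        block = backgen_test(pub.BACKGEN_ACTUAL["boys"], pub.BACKGEN_FITTED["boys"])
        got = [r.row_mape_display for r in block.rows]
        assert got == [-0.03, 0.03, -0.02, 0.04, -0.05]
        assert block.average_mape_display == -0.007

    def test_published_female_block(self):
        block = backgen_test(pub.BACKGEN_ACTUAL["girls"], pub.BACKGEN_FITTED["girls"])
        got = {r.age: r.row_mape_display for r in block.rows}
        assert got == {12.0: 0.01, 13.0: 0.04, 14.0: 0.10, 15.0: -0.05, 16.0: -0.04}
        assert block.average_mape_display == 0.012

    def test_sign_convention_overprediction_is_negative(self):
        block = backgen_test({12: 22.53}, {12: 23.20})
        assert block.rows[0].row_mape < 0

    def test_actual_denominator_variant(self):
        block = backgen_test({15: 18.16}, {15: 19.10}, convention="actual")
        assert block.rows[0].row_mape == pytest.approx((18.16 - 19.10) / 18.16)

    def test_scale_invariance(self):
        a = {12: 20.0, 13: 25.0}
        f = {12: 21.0, 13: 24.0}
        b1 = backgen_test(a, f)
        b2 = backgen_test({k: 7 * v for k, v in a.items()},
                          {k: 7 * v for k, v in f.items()})
        assert b1.average_mape == pytest.approx(b2.average_mape, abs=1e-12)

    def test_perfect_agreement_is_zero_and_highly_accurate(self):
        vals = {a: float(a) + 10 for a in pub.AGES}
        block = backgen_test(vals, dict(vals))
        assert all(r.row_mape == 0.0 for r in block.rows)
        assert block.average_mape == 0.0
        assert block.accuracy_band == "highly accurate"

    def test_mismatched_age_keys_rejected(self):
        with pytest.raises(ValueError, match="keys"):
            backgen_test({12: 20.0}, {13: 20.0})


class TestMapeInterpret:
    @pytest.mark.parametrize(
        "value,band",
        [
            (-0.007, "highly accurate"),
            (0.099, "highly accurate"),
            (0.10, "good"),        # boundary goes to the band starting there
            (0.15, "good"),
            (0.20, "reasonable"),
            (0.50, "reasonable"),
            (0.51, "inaccurate"),
            (-0.6, "inaccurate"),  # banding uses the absolute value
        ],
    )
    def test_bands(self, value, band):
        assert mape_interpret(value) == band


class TestRunBackgeneration:
    def test_average_mape_small_on_study_design_cohorts(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_backgeneration(default_cohort, fraction=0.2, seed=11)
        for sex, block in report.blocks.items():
            assert abs(block.average_mape) < 0.05, sex
            assert block.accuracy_band == "highly accurate"

    def test_identical_holdout_gives_zero_mape(self, boys):
        # bypass the sampler: score the full-sample fit against itself
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = g.fit_lms(boys)
        p50 = {a: g.predict_lms(model, a).mu for a in (12.0, 13.0, 14.0, 15.0, 16.0)}
        block = backgen_test(p50, dict(p50))
        assert block.average_mape == 0.0

    def test_different_seeds_same_band(self, default_cohort):
        rows = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in (1, 2):
                rep = run_backgeneration(default_cohort, fraction=0.2, seed=seed,
                                         p50_mode="raw")
                rows[seed] = [r.row_mape for r in rep.blocks["boys"].rows]
                assert rep.blocks["boys"].accuracy_band == "highly accurate"
        assert rows[1] != rows[2]

    def test_raw_median_mode_uses_sample_medians(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_backgeneration(default_cohort, fraction=0.2, seed=3,
                                     p50_mode="raw")
        boys_recs = [r for r in default_cohort if r.sex == "boys" and r.age == 12]
        expected = float(np.median([r.hgs_abs for r in boys_recs]))
        actual_row = next(r for r in rep.blocks["boys"].rows if r.age == 12.0)
        assert actual_row.actual_p50 == pytest.approx(expected, abs=1e-12)

    def test_provenance_recorded(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_backgeneration(default_cohort, fraction=0.25, seed=5,
                                     p50_mode="raw")
        assert rep.holdout_fraction == 0.25
        assert rep.seed == 5
        assert rep.convention == "fitted"
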