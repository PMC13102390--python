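import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antnest import demography as dg
from antnest import excavation as ex
from conftest import make_cohort_timeline


class TestTargetArea:
    @pytest.mark.parametrize("age,expected", [(0.0, 11.22),
                                              (40.0, 9.94),
                                              (400.0, 0.0)])
    def test_line_with_zero_clamp(self, age, expected):
        assert ex.target_area(age, ex.TargetAreaLine()) == pytest.approx(expected)

    def test_null_model_ignores_age(self):
        t = ex.ConstantTarget(11.6)
        assert ex.target_area(3.0, t) == ex.target_area(300.0, t) == 11.6

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            ex.target_area(-1.0, ex.TargetAreaLine())


class TestPerAntRate:
    def test_empty_nest_rate_is_basal(self, params):
        assert ex.per_ant_rate(0.0, 40.0, params) == pytest.approx(2.2)

    def test_zero_at_target(self, params):
        a_age = float(params.target.target(40.0))
        assert ex.per_ant_rate(a_age, 40.0, params) == 0.0

    def test_rectified_above_target(self, params):
        a_age = float(params.target.target(40.0))
        assert ex.per_ant_rate(2 * a_age, 40.0, params) == 0.0

    def test_maturation_delay_gates_digging(self, params):
        assert ex.per_ant_rate(0.0, 5.0, params) == 0.0

    def test_zero_target_means_no_digging(self, params):
        assert ex.per_ant_rate(0.0, 365.0, params) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.floats(0.0, 50.0), age=st.floats(0.0, 500.0))
    def test_rate_bounded_by_basal_ceiling(self, a, age):
        p = ex.ModelParams()
        rate = ex.per_ant_rate(a, age, p)
        assert 0.0 <= rate <= p.r


class TestColonyRate:
    def test_identical_cohort_sums_basal_rates(self, params):
        ants = [(40.0, dg.WORKER)] * 10
        assert ex.colony_rate(0.0, ants, params) == pytest.approx(22.0)

    def test_zero_above_every_target(self, params):
        ants = [(40.0, dg.WORKER), (100.0, dg.WORKER)]
        assert ex.colony_rate(2 * 11.22, ants, params) == 0.0

    def test_mixed_ages_term_by_term(self, params):
        # A/N sits between the 200 d and 40 d targets: only the young ant digs
        ants = [(40.0, dg.WORKER), (200.0, dg.WORKER)]
        A = 2 * 8.0  # a = 8.0; target(40)=9.94, target(200)=4.82
        expected = ex.per_ant_rate(8.0, 40.0, params)
        assert ex.colony_rate(A, ants, params) == pytest.approx(expected)

    def test_empty_colony_rejected(self, params):
        with pytest.raises(ValueError):
            ex.colony_rate(1.0, [], params)


class TestClosedForm:
    def test_initial_and_asymptotic_values(self, params):
        assert ex.closed_form_single_cohort(0.0, 15, 40.0, 0.5, params) == \
            pytest.approx(15 * 0.5)
        assert ex.closed_form_single_cohort(1e6, 15, 40.0, 0.0, params) == \
            pytest.approx(15 * 9.94)

    def test_half_saturation_time(self, params):
        a_age = 9.94
        t_half = (a_age / params.r) * np.log(2.0)
        val = ex.closed_form_single_cohort(t_half, 15, 40.0, 0.0, params)
        assert val == pytest.approx(15 * a_age / 2)

    def test_zero_target_is_constant(self, params):
        assert ex.closed_form_single_cohort(10.0, 5, 400.0, 1.0, params) == \
            pytest.approx(5.0)


class TestSimulate:
    def test_matches_closed_form_oracle(self, params):
        tl = make_cohort_timeline(15, 40.0, duration=30.0)
        res = ex.simulate(tl, params, dt=0.1)
        oracle = ex.closed_form_single_cohort(res.days, 15, 40.0, 0.0, params)
        rel = np.abs(res.total_area[1:] - oracle[1:]) / oracle[1:]
        assert rel.max() < 1e-3

    def test_euler_error_decreases_with_dt(self, params):
        tl = make_cohort_timeline(10, 40.0, duration=20.0)
        errs = []
        for dt in (0.2, 0.1, 0.05):
            res = ex.simulate(tl, params, dt=dt, method="euler")
            oracle = ex.closed_form_single_cohort(res.days, 10, 40.0, 0.0, params)
            errs.append(np.max(np.abs(res.total_area[1:] - oracle[1:]) / oracle[1:]))
        assert errs[0] > errs[1] > errs[2]

    def test_lone_old_queen_digs_nothing(self, params):
        ants = [dg.AntRecord("queen", dg.QUEEN, -365.0),
                dg.AntRecord("w1", dg.WORKER, -365.0)]
        tl = dg.ColonyTimeline(ants, 30.0, "fixed")
        res = ex.simulate(tl, params)
        assert res.final_area == pytest.approx(0.0)

    def test_area_nondecreasing_between_events(self, params):
        cfg = dg.GeneratorConfig(seed=4)
        tl = dg.synth_maturation_colony(cfg)
        res = ex.simulate(tl, params)
        assert np.all(np.diff(res.total_area) >= -1e-12)

    def test_queen_founding_area_at_first_emergence(self, params):
        cfg = dg.GeneratorConfig(seed=4)
        tl = dg.synth_maturation_colony(cfg)
        res = ex.simulate(tl, params)
        k = int(round(tl.first_worker_day / 0.1))
        assert res.total_area[k] == pytest.approx(params.queen_area_mean)
        assert res.ledger["queen"] == pytest.approx(params.queen_area_mean)

    def test_ledger_sums_to_area_plus_losses(self, params):
        cfg = dg.GeneratorConfig(seed=8)
        tl = dg.synth_maturation_colony(cfg)
        ev = ex.CollapseEvent(150.0, 0.28)
        res = ex.simulate(tl, params, events=[ev])
        total = sum(res.ledger.values())
        assert total == pytest.approx(res.final_area + res.collapse_losses(), rel=1e-9)
        assert np.all(res.increments >= 0)

    def test_collapse_drops_area_by_fraction(self, params):
        tl = make_cohort_timeline(10, 40.0, duration=60.0)
        ev = ex.CollapseEvent(40.0, 0.30)
        res = ex.simulate(tl, params, events=[ev])
        i = int(round(40.0 / 0.1))
        before = res.total_area[i]
        after = res.total_area[i + 1]
        # one integration step of renewed digging happens within the same step
        assert after / before == pytest.approx(0.70, abs=0.01)

    def test_event_beyond_duration_rejected(self, params):
        tl = make_cohort_timeline(5, 40.0, duration=30.0)
        with pytest.raises(ValueError):
            ex.simulate(tl, params, events=[ex.CollapseEvent(99.0, 0.25)])

    def test_frozen_vs_dynamic_age_modes_differ(self, params):
        tl = make_cohort_timeline(10, 150.0, duration=45.0)
        frozen = ex.simulate(tl, params, age_mode="frozen")
        dynamic = ex.simulate(tl, params, age_mode="dynamic")
        # aging lowers the target during the run
        assert dynamic.final_area < frozen.final_area


class TestSaturationArea:
    def test_single_cohort_plateau(self, params):
        tl = make_cohort_timeline(15, 40.0, duration=45.0)
        res = ex.simulate(tl, params)
        assert ex.saturation_area(res) == pytest.approx(15 * 9.94, rel=5e-3)

    def test_constant_series_returns_constant(self, params):
        tl = make_cohort_timeline(2, 365.0, duration=30.0)  # zero target
        res = ex.simulate(tl, params)
        assert ex.saturation_area(res) == pytest.approx(0.0, abs=1e-9)

    def test_null_model_plateau_is_constant_target(self):
        p = ex.ModelParams(target=ex.ConstantTarget(11.6))
        tl = make_cohort_timeline(10, 40.0, duration=60.0)
        res = ex.simulate(tl, p)
        assert ex.saturation_area(res) == pytest.approx(116.0, rel=5e-3)

    def test_no_plateau_signalled(self, params):
        tl = make_cohort_timeline(15, 40.0, duration=10.0)
        res = ex.simulate(tl, params)
        with pytest.raises(ex.NoPlateauError):
            ex.saturation_area(res)


class TestNullModelEquivalence:
    def test_zero_slope_line_equals_constant_target(self):
        line = ex.ModelParams(target=ex.TargetAreaLine(slope=0.0, intercept=11.6))
        null = ex.ModelParams(target=ex.ConstantTarget(11.6))
        tl = make_cohort_timeline(8, 40.0, duration=40.0)
        a = ex.simulate(tl, line).total_area
        b = ex.simulate(tl, null).total_area
        assert np.allclose(a, b)


class TestAttribution:
    def test_single_young_cohort_has_no_old_share(self, params):
        tl = make_cohort_timeline(10, 40.0, duration=45.0)
        res = ex.simulate(tl, params)
        att = ex.attribute_by_group(res, threshold=56.0)
        assert att["old"] == 0.0 and att["young"] > 0

    def test_queen_share_is_founding_area(self, params):
        cfg = dg.GeneratorConfig(seed=12)
        tl = dg.synth_maturation_colony(cfg)
        res = ex.simulate(tl, params)
        att = ex.attribute_by_group(res, threshold=56.0)
        assert att["queen"] == pytest.approx(params.queen_area_mean)

    def test_partition_sums_to_area_plus_losses(self, params):
        cfg = dg.GeneratorConfig(seed=13)
        tl = dg.synth_maturation_colony(cfg)
        ev = ex.CollapseEvent(120.0, 0.25)
        res = ex.simulate(tl, params, events=[ev])
        att = ex.attribute_by_group(res)
        assert sum(att.values()) == pytest.approx(
            res.final_area + res.collapse_losses(), rel=1e-9)

    def test_old_share_minor_in_maturation_ensemble(self, params, maturation_ensemble):
        fracs = []
        for tl, res, _ in maturation_ensemble:
            att = ex.attribute_by_group(res, threshold=56.0)
            fracs.append(att["old"] / (att["young"] + att["old"]))
        assert np.mean(fracs) < 0.10  # old ants dig almost nothing normally


class TestPerAntStats:
    def test_uniform_diggers(self):
        res = _fake_result([8.0, 8.0, 8.0])
        out = ex.per_ant_stats(res, exclude_queen=False)
        assert out["mean"] == pytest.approx(8.0)
        assert out["sd"] == 0.0
        assert out["band_area_fraction"] == 1.0

    def test_band_fraction_area_weighted(self):
        res = _fake_result([2.0, 8.0, 10.0])
        out = ex.per_ant_stats(res, exclude_queen=False)
        assert out["band_area_fraction"] == pytest.approx(18.0 / 20.0)

    def test_empty_worker_set_rejected(self, params):
        ants = [dg.AntRecord("queen", dg.QUEEN, -365.0),
                dg.AntRecord("w", dg.WORKER, -365.0)]
        tl = dg.ColonyTimeline(ants, 20.0, "fixed")
        res = ex.simulate(tl, params)
        with pytest.raises(ValueError):
            ex.per_ant_stats(res)  # everyone dug zero


def _fake_result(amounts):
    n = len(amounts)
    return ex.SimResult(days=np.array([0.0, 1.0]),
                        total_area=np.array([0.0, float(sum(amounts))]),
                        ant_ids=[f"w{i}" for i in range(n)],
                        castes=[dg.WORKER] * n,
                        eclosion_days=np.zeros(n),
                        increments=np.array(amounts)[None, :])


def test_induce_collapse_examples():
    assert ex.induce_collapse(100.0, 0.30) == pytest.approx(70.0)
    assert ex.induce_collapse(100.0, 0.25) == pytest.approx(75.0)
    assert ex.induce_collapse(0.0, 0.27) == 0.0
    with pytest.raises(ValueError):
        ex.induce_collapse(10.0, 1.5)
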