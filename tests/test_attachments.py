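"""Attachment lifecycle: motor program, formation rules, stability, bonds."""

import numpy as np
import pytest

import spindlesim.attachments as at
from spindlesim import CENPE, DYNEIN, ParameterSet, ST_NONE, ST_STABLE, ST_UNSTABLE
from spindlesim.state import Chromosome, Microtubule, SimulationState
from spindlesim.testing import TINY, biorientable_pair, centred_chromosome, mt_towards


def make_state(mts, chroms, params=None, seed=0):
    return SimulationState.from_records(params or TINY, mts, chroms, seed=seed)


class TestMotorProgram:
    @pytest.mark.parametrize("radius_frac,expected", [
        (0.30, CENPE),   # inside the 0.45a shell
        (0.60, DYNEIN),  # peripheral
    ])
    def test_initial_assignment_by_shell(self, radius_frac, expected):
        ch = Chromosome(position=np.array([radius_frac * 15.0, 0, 0]))
        st = make_state([], [ch])
        at.init_motor_program(st)
        assert st.ch_motor[0] == expected

    def test_dynein_switches_at_the_pole_and_never_reverts(self):
        p = TINY.replace(delta_pole=0.5)
        ch = Chromosome(position=np.array([-7.5 + 0.4, 0, 0]), motor=DYNEIN)
        st = make_state([], [ch], params=p)
        at.update_motor_program(st)
        assert st.ch_motor[0] == CENPE
        st.ch_pos[0] = np.zeros(3)   # far from any pole
        at.update_motor_program(st)
        assert st.ch_motor[0] == CENPE

    def test_no_switch_outside_the_pole_zone(self):
        p = TINY.replace(delta_pole=0.5)
        ch = Chromosome(position=np.array([-6.0, 0, 0]), motor=DYNEIN)
        st = make_state([], [ch], params=p)
        at.update_motor_program(st)
        assert st.ch_motor[0] == DYNEIN

    def test_cenpe_knockdown_disables_the_replacement(self):
        p = TINY.replace(delta_pole=0.5, f_cenpe=0.0)
        ch = Chromosome(position=np.array([-7.5 + 0.1, 0, 0]), motor=DYNEIN)
        st = make_state([], [ch], params=p)
        at.update_motor_program(st)
        assert st.ch_motor[0] == DYNEIN


class TestLateralFormation:
    def test_cenpe_rejects_young_rails(self):
        ch = centred_chromosome(CENPE)
        mt = mt_towards([0, 0.2, 0], overshoot=2.0, birth_time=0.0)
        st = make_state([mt], [ch], params=TINY.replace(
            cenpe_rails="aged_interpolar"))
        st.t = 30.0   # rail age 30 s < tau
        assert at.form_lateral(st) == 0

    def test_default_rule_restricts_cenpe_to_the_scaffold(self):
        # an old, centre-pointing dynamic rail is not enough by default
        ch = centred_chromosome(CENPE)
        mt = mt_towards([0, 0.2, 0], overshoot=2.0, birth_time=-100.0)
        st = make_state([mt], [ch])
        assert at.form_lateral(st) == 0

    def test_aged_interpolar_option_accepts_old_centre_pointing_rails(self):
        ch = centred_chromosome(CENPE)
        mt = mt_towards([0, 0.2, 0], overshoot=2.0, birth_time=-100.0)
        st = make_state([mt], [ch], params=TINY.replace(
            cenpe_rails="aged_interpolar"))
        st.t = 0.0
        assert at.form_lateral(st) == 1
        assert st.ch_lateral[0] == 0

    def test_cenpe_accepts_scaffold_regardless_of_clock(self):
        ch = centred_chromosome(CENPE)
        mt = mt_towards([0, 0.2, 0], overshoot=2.0, scaffold=True,
                        birth_time=-np.inf)
        st = make_state([mt], [ch])
        assert at.form_lateral(st) == 1

    def test_cenpe_rejects_old_rails_pointing_away_from_centre(self):
        ch = Chromosome(position=np.array([-7.4, 2.0, 0.0]), motor=CENPE)
        # old MT from pole 0 aimed at the near cortex (not interpolar)
        mt = Microtubule(pole=0, direction=np.array([-0.05, 1.0, 0.0]),
                        length=5.0, birth_time=-1e3)
        st = make_state([mt], [ch], params=TINY.replace(
            cenpe_rails="aged_interpolar"))
        d = st.mt_dir[0]
        assert not st.mt_interpolar[0]
        assert at.form_lateral(st) == 0

    def test_dynein_rides_young_rails_without_age_filter(self):
        ch = centred_chromosome(DYNEIN)
        mt = mt_towards([0, 0.2, 0], overshoot=2.0, birth_time=0.0)
        st = make_state([mt], [ch])
        st.t = 5.0
        assert at.form_lateral(st) == 1

    def test_nearest_rail_wins(self):
        ch = centred_chromosome(DYNEIN)
        far = mt_towards([0, 0.25, 0], overshoot=2.0)
        near = mt_towards([0, 0.05, 0], overshoot=2.0)
        st = make_state([far, near], [ch])
        at.form_lateral(st)
        assert st.ch_lateral[0] == 1

    def test_out_of_range_rail_ignored(self):
        ch = centred_chromosome(DYNEIN)
        mt = mt_towards([0, 0.5, 0], overshoot=2.0)   # 0.5 > r_k
        st = make_state([mt], [ch])
        assert at.form_lateral(st) == 0

    def test_stably_bioriented_chromosomes_do_not_ride(self):
        mts, chroms = biorientable_pair()
        rail = mt_towards([0, 0.1, 0], overshoot=2.0, birth_time=-1e3)
        st = make_state(mts + [rail], chroms)
        at.form_end_on(st)
        assert at.classify_stability(st)[0] == ST_STABLE
        assert at.form_lateral(st) == 0


class TestEndOnFormation:
    def test_dynein_chromosomes_never_form_end_on(self):
        ch = centred_chromosome(DYNEIN)
        mt = mt_towards([0.1, 0, 0], pole=0)
        st = make_state([mt], [ch])
        assert at.form_end_on(st) == 0
        assert np.all(st.mt_attach_ch < 0)

    def test_tip_in_contact_attaches_to_the_touched_hemisphere(self):
        ch = centred_chromosome(CENPE)
        mt = mt_towards([-0.1, 0, 0], pole=0)
        st = make_state([mt], [ch])
        assert at.form_end_on(st) == 1
        assert st.mt_attach_ch[0] == 0
        assert st.mt_attach_side[0] == 0   # left hemisphere (negative x offset)

    def test_capacity_respected_at_the_last_slot(self):
        p = TINY.replace(n_k=25)
        ch = centred_chromosome(CENPE)
        # 24 occupied + 2 candidates: only one may enter
        mts = [mt_towards([-0.1, 0, 0], pole=0, end_on_chrom=0, end_on_side=0)
               for _ in range(24)]
        mts += [mt_towards([-0.15, 0.05, 0], pole=0),
                mt_towards([-0.15, -0.05, 0], pole=0)]
        st = make_state(mts, [ch], params=p)
        assert at.form_end_on(st) == 1
        assert st.slot_occupancy()[0, 0] == 25

    def test_full_kinetochore_accepts_nothing(self):
        p = TINY.replace(n_k=2)
        ch = centred_chromosome(CENPE)
        mts = [mt_towards([-0.1, 0, 0], pole=0, end_on_chrom=0, end_on_side=0)
               for _ in range(2)]
        mts.append(mt_towards([-0.2, 0, 0], pole=0))
        st = make_state(mts, [ch], params=p)
        assert at.form_end_on(st) == 0

    def test_refractory_tips_are_not_recaptured(self):
        ch = centred_chromosome(CENPE)
        mt = mt_towards([-0.1, 0, 0], pole=0)
        st = make_state([mt], [ch])
        st.mt_refract_until[0] = st.t + 5.0
        assert at.form_end_on(st) == 0
        st.t += 6.0
        assert at.form_end_on(st) == 1


class TestStability:
    def test_amphitelic_is_stable(self):
        mts, chroms = biorientable_pair()
        st = make_state(mts, chroms)
        at.form_end_on(st)
        assert at.classify_stability(st)[0] == ST_STABLE

    def test_monotelic_is_unstable(self):
        ch = centred_chromosome(CENPE)
        mt = mt_towards([-0.1, 0, 0], pole=0, end_on_chrom=0, end_on_side=0)
        st = make_state([mt], [ch])
        assert at.classify_stability(st)[0] == ST_UNSTABLE

    def test_syntelic_is_unstable(self):
        # both kinetochores occupied, all MTs from pole 0
        ch = centred_chromosome(CENPE)
        m1 = mt_towards([-0.1, 0, 0], pole=0, end_on_chrom=0, end_on_side=0)
        m2 = mt_towards([0.1, 0, 0], pole=0, end_on_chrom=0, end_on_side=1)
        st = make_state([m1, m2], [ch])
        assert at.classify_stability(st)[0] == ST_UNSTABLE

    def test_no_attachment_is_none(self):
        st = make_state([], [centred_chromosome()])
        assert at.classify_stability(st)[0] == ST_NONE


class TestDetachmentKinetics:
    def test_slip_bond_example(self, params):
        # unstable at F = F_detach_u: rate = 0.1 * e
        rate = at.detachment_rate(4.0, ST_UNSTABLE, params)
        assert rate == pytest.approx(0.1 * np.e)

    def test_catch_bond_unloaded_rate(self, params):
        assert at.detachment_rate(0.0, ST_STABLE, params) == pytest.approx(0.001)

    def test_catch_bond_monotone_decreasing(self, params):
        F = np.linspace(0, 20, 50)
        pr = at.detachment_probability(F, np.full(50, ST_STABLE), params, 0.1)
        assert np.all(np.diff(pr) <= 0)
        assert pr[-1] < pr[0]

    def test_slip_bond_monotone_increasing(self, params):
        F = np.linspace(0, 20, 50)
        pr = at.detachment_probability(F, np.full(50, ST_UNSTABLE), params, 0.1)
        assert np.all(np.diff(pr) >= 0)

    def test_rate_undefined_without_attachment(self, params):
        with pytest.raises(ValueError):
            at.detachment_rate(1.0, ST_NONE, params)


class TestSpringForces:
    def test_zero_rest_length(self):
        ch = centred_chromosome(CENPE)
        mt = mt_towards([0, 0, 0], pole=0, end_on_chrom=0, end_on_side=0)
        st = make_state([mt], [ch])
        np.testing.assert_allclose(at.end_on_spring_forces(st)[0], 0.0, atol=1e-12)

    def test_stretch_gives_k_times_displacement(self):
        ch = centred_chromosome(CENPE)
        mt = mt_towards([0.1, 0, 0], pole=0, end_on_chrom=0, end_on_side=1)
        st = make_state([mt], [ch])
        f = at.end_on_spring_forces(st)[0]
        np.testing.assert_allclose(f, [10.0, 0, 0], atol=1e-9)  # k_k = 100
        assert at.end_on_tip_forces(st)[0] == pytest.approx(10.0)

    def test_symmetric_biorientation_balances(self):
        mts, chroms = biorientable_pair(offset=0.1)
        st = make_state(mts, chroms)
        at.form_end_on(st)
        f = at.end_on_spring_forces(st)[0]
        assert abs(f[0]) < 1e-9


class TestStochasticEventPass:
    def test_rail_collapse_clears_the_lateral_link_in_the_same_step(self):
        p = TINY.replace(p_sc=0.0)
        ch = centred_chromosome(DYNEIN)
        rail = mt_towards([0, 0.2, 0], overshoot=0.02)
        st = make_state([rail], [ch], params=p)
        at.form_lateral(st)
        assert st.ch_lateral[0] == 0
        # force the rail to shrink to zero within one step
        st.mt_len[0] = 0.001
        st.mt_growing[0] = False
        from spindlesim.mt_dynamics import advance_lengths, handle_collapses
        collapsed = advance_lengths(st, np.zeros(1), np.zeros(1, bool), p.dt)
        handle_collapses(st, collapsed)
        assert st.ch_lateral[0] == -1

    def test_stable_release_is_depolymerisation_coupled(self):
        mts, chroms = biorientable_pair()
        for m in mts:
            m.end_on_chrom = 0
        mts[0].end_on_side = 0
        mts[1].end_on_side = 1
        p = TINY.replace(p_detach_s0=1e6)   # stable pair detaches this step
        st = make_state(mts, chroms, params=p)
        assert at.classify_stability(st)[0] == 2
        at.process_stochastic_events(st, 0.1)
        assert np.all(st.mt_attach_ch < 0)
        assert not st.mt_growing[:2].any()
        assert np.all(st.mt_refract_until[:2] > st.t)

    def test_unstable_release_keeps_rebinding(self):
        ch = centred_chromosome(CENPE)
        mt = mt_towards([-0.1, 0, 0], pole=0, end_on_chrom=0, end_on_side=0,
                        birth_time=-1e3)
        p = TINY.replace(p_detach_u0=1e6)   # detach certainly this step
        st = make_state([mt], [ch], params=p)
        at.process_stochastic_events(st, 0.1)
        # the slip-bond release leaves the tip free to rebind at once, so the
        # attachment-formation pass of the same step recaptures it
        assert st.mt_attach_ch[0] == 0
        assert st.mt_growing[0]

    def test_seeded_event_pass_is_reproducible(self):
        logs = []
        for _ in range(2):
            p = ParameterSet(n_mt=100, n_c=2, p_sc=0.1, warmup=10.0)
            from spindlesim import RunConfig, Simulation
            sim = Simulation(RunConfig(params=p, seed=77, record_events=True))
            for _ in range(100):
                sim.step()
            logs.append(list(sim.state.events.records))
        assert logs[0] == logs[1]

    def test_no_end_on_ever_appears_on_dynein_chromosomes(self):
        from spindlesim import RunConfig, Simulation
        p = ParameterSet(n_mt=400, n_c=6, warmup=50.0)
        sim = Simulation(RunConfig(params=p, scenario="ko_cenpe", seed=5))
        st = sim.state
        for _ in range(300):
            sim.step()
            dyn = st.ch_motor == DYNEIN
            att = st.mt_attach_ch[st.mt_attach_ch >= 0]
            assert not np.any(dyn[att])

    def test_slot_capacity_never_exceeded_during_a_run(self):
        from spindlesim import RunConfig, Simulation
        p = ParameterSet(n_mt=600, n_c=4, n_k=3, warmup=100.0)
        sim = Simulation(RunConfig(params=p, scenario="wt_interpolar", seed=8))
        for _ in range(400):
            sim.step()
            assert sim.state.slot_occupancy().max() <= 3
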