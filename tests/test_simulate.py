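"""Virtual-mouse generative model: determinism, validity, and the behavioral
phenomena the analyses assume (habituation, detection-gated dis-habituation,
valence, operant learning)."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from nosepoke import (
    VirtualMouseParams,
    build_cross_habituation,
    build_gonogo_session,
    build_two_choice_session,
    compute_session_metrics,
    pair_events,
    parse_event_log,
    simulate_cohort,
    simulate_gonogo,
    simulate_habituation_assay,
    simulate_two_choice,
    success_rate_gonogo,
    success_rate_two_choice,
    write_event_log,
)


class TestDeterminism:
    def test_same_master_seed_gives_identical_logs(self, threshold_schedule):
        a = simulate_cohort(3, threshold_schedule, seed=5)
        b = simulate_cohort(3, threshold_schedule, seed=5)
        assert [write_event_log(x) for x in a] == [write_event_log(x) for x in b]

    def test_growing_the_cohort_preserves_existing_animals(self, threshold_schedule):
        small = simulate_cohort(2, threshold_schedule, seed=9)
        large = simulate_cohort(5, threshold_schedule, seed=9)
        for s, l in zip(small, large):
            assert write_event_log(s) == write_event_log(l)

    def test_animals_differ_in_basal_activity(self, threshold_schedule):
        logs = simulate_cohort(8, threshold_schedule, seed=2)
        basals = []
        for log in logs:
            m = compute_session_metrics(log, threshold_schedule)
            basals.append(np.mean([x.investigation_ms for x in m[:8]]))
        assert np.std(basals) > 0


class TestLogValidity:
    def test_logs_round_trip_and_pair_cleanly(self, threshold_schedule):
        for log in simulate_cohort(3, threshold_schedule, seed=11):
            text = write_event_log(log)
            back = parse_event_log(text)
            assert back.events == log.events
            with warnings.catch_warnings():
                warnings.simplefilter("error")  # any discard warning fails
                result = pair_events(log, "odor_port_ir")
            assert result.n_discarded == 0
            assert all(iv.duration_ms >= 1 for iv in result)

    def test_timestamps_are_integer_milliseconds(self, threshold_schedule):
        log = simulate_habituation_assay(
            VirtualMouseParams(seed=4), threshold_schedule
        )
        assert all(isinstance(e.time_ms, int) for e in log.events)


class TestHabituationPhenomena:
    def test_null_model_odor_sessions_match_air(self):
        """With novelty gain off, odor sessions are statistically identical
        to air: pooled mean NPI of odor sessions stays at ~100%."""
        params = replace(VirtualMouseParams(), eta=0.0)
        sched = build_cross_habituation("HXH", n_air=8, n_s1=5)
        diffs, odor_npi = [], []
        for rep in range(200):
            logs = simulate_cohort(1, sched, base_params=params, seed=20_000 + rep)
            m = compute_session_metrics(logs[0], sched)
            odor_inv = [x.investigation_ms for x in m if x.concentration_sv > 0]
            air_inv = [x.investigation_ms for x in m if x.concentration_sv == 0]
            diffs.append(np.mean(odor_inv) - np.mean(air_inv))
            odor_npi.extend(x.npi_percent for x in m if x.concentration_sv > 0)
        # within-animal odor-vs-air difference is exactly mean-zero under the null
        sem = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * sem + 1e-9
        # NPI itself sits near 100%, up to small-sample normalization bias
        assert abs(np.mean(odor_npi) - 100.0) < 15.0

    def test_indistinguishable_odors_do_not_dishabituate(self):
        """Full cross-habituation (D = 0) transfers habituation to the second
        odor, so the switch produces no dis-habituation; a distinct pair
        (D = 1) produces a clear positive dNPI jump."""
        base = VirtualMouseParams()
        sched = build_cross_habituation("HXH", "HXO", conc_s1=2.5e-4, conc_s2=2.5e-4)
        switch_idx = 13  # first HXO session (8 air + 5 HXH before it)
        jumps = {}
        for d_value in (0.0, 1.0):
            params = replace(base, similarity={frozenset(("HXH", "HXO")): d_value})
            deltas = []
            for rep in range(150):
                logs = simulate_cohort(1, sched, base_params=params, seed=30_000 + rep)
                m = compute_session_metrics(logs[0], sched)
                deltas.append(m[switch_idx].npi_percent - m[switch_idx - 1].npi_percent)
            jumps[d_value] = np.mean(deltas)
        assert abs(jumps[0.0]) < 15.0  # no dis-habituation for identical percepts
        assert jumps[1.0] > 100.0  # strong dis-habituation for distinct odors

    def test_first_probe_response_scales_with_novelty_gain(self):
        sched = build_cross_habituation("HXH", n_air=8, n_s1=3, conc_s1=2.5e-4)
        means = {}
        for eta in (1.0, 3.0):
            params = replace(VirtualMouseParams(), eta=eta)
            deltas = []
            for rep in range(150):
                logs = simulate_cohort(1, sched, base_params=params, seed=40_000 + rep)
                m = compute_session_metrics(logs[0], sched)
                deltas.append(m[8].npi_percent - m[7].npi_percent)
            means[eta] = np.mean(deltas)
        assert means[1.0] > 30.0  # well-detected odor drives dis-habituation
        assert means[3.0] > 1.8 * means[1.0]

    def test_undetectable_concentration_elicits_nothing(self):
        params = VirtualMouseParams()
        weak = params.detect.a * 1e-4
        sched = build_cross_habituation("HXH", n_air=8, n_s1=3, conc_s1=weak)
        deltas = []
        for rep in range(150):
            logs = simulate_cohort(1, sched, base_params=params, seed=50_000 + rep)
            m = compute_session_metrics(logs[0], sched)
            deltas.append(m[8].npi_percent - m[7].npi_percent)
        assert abs(np.mean(deltas)) < 15.0

    def test_investigation_declines_over_repeated_stimulation(self):
        """Habituation: expected investigation is non-increasing across
        repeated identical odor sessions (session means over replicates)."""
        sched = build_cross_habituation("HXH", n_air=2, n_s1=5, conc_s1=2.5e-4)
        per_session = np.zeros((400, 5))
        for rep in range(400):
            logs = simulate_cohort(1, sched, seed=60_000 + rep)
            m = compute_session_metrics(logs[0], sched)
            per_session[rep] = [x.investigation_ms for x in m[2:]]
        means = per_session.mean(axis=0)
        sem = per_session.std(axis=0, ddof=1).max() / np.sqrt(400)
        assert np.all(np.diff(means) <= 3 * sem)
        assert means[0] > means[-1]  # net decline is unambiguous

    def test_aversive_odor_suppresses_investigation_below_neutral(self):
        """From the second exposure on, an aversive odor multiplies the poke
        rate by (1 + v) < 1: its sessions fall well below a matched
        neutral-valence odor's and below the habituated air level."""
        sched = build_cross_habituation("2MBA", n_air=8, n_s1=3, conc_s1=1e-4)
        means = {}
        for v in (0.0, -0.6):
            params = replace(VirtualMouseParams(), valence={"2MBA": v})
            second_odor_npi = []
            for rep in range(150):
                logs = simulate_cohort(1, sched, base_params=params, seed=70_000 + rep)
                m = compute_session_metrics(logs[0], sched)
                second_odor_npi.append(m[9].npi_percent)
            means[v] = np.mean(second_odor_npi)
        assert means[-0.6] < 0.55 * means[0.0]  # (1 + v) = 0.4 rate factor
        air_floor_npi = 100.0 * (1 + 3 * 0.3**8) / (1 + 3 * np.mean(0.3 ** np.arange(8)))
        assert means[-0.6] < air_floor_npi  # below the habituated background

    def test_attraction_and_aversion_have_opposite_signs(self):
        from nosepoke import attraction_index, aversion_index

        sched = build_cross_habituation("odor", n_air=8, n_s1=3, conc_s1=1e-4)
        index_means = {}
        for v in (0.6, -0.6):
            params = replace(VirtualMouseParams(), valence={"odor": v})
            att, ave = [], []
            for rep in range(150):
                logs = simulate_cohort(1, sched, base_params=params, seed=80_000 + rep)
                npis = [
                    x.npi_percent for x in compute_session_metrics(logs[0], sched)
                ]
                att.append(attraction_index(npis, 8))
                ave.append(aversion_index(npis, 9))
            index_means[v] = (np.mean(att), np.mean(ave))
        # an attractive odor: positive attraction index, negative aversion index
        assert index_means[0.6][0] > 0
        assert index_means[0.6][1] < 0
        # an aversive odor: positive aversion index (port approach suppressed);
        # its first presentation still draws salience-driven investigation
        assert index_means[-0.6][1] > 0
        assert index_means[-0.6][0] > 0
        # the aversion index flips sign between matched +v and -v
        assert index_means[-0.6][1] > index_means[0.6][1]


class TestOperantBehavior:
    def test_undetectable_odor_means_chance_performance(self):
        params = VirtualMouseParams()
        rng = np.random.default_rng(0)
        correct = total = 0
        for i in range(10):
            trials = build_two_choice_session("AA", "HPH", seed=i)
            c = simulate_two_choice(params, trials, 1e-12, rng=rng, n_prior_trials=10_000)
            correct += c.p_aa + c.p_bb
            total += c.p_total
        sr = correct / total  # 600 trials: 3 sigma ~ 0.06 around 0.5
        assert abs(sr - 0.5) < 0.07

    def test_trained_agent_approaches_asymptote(self):
        params = VirtualMouseParams()
        rng = np.random.default_rng(1)
        correct = total = 0
        for i in range(10):
            trials = build_two_choice_session("AA", "HPH", seed=100 + i)
            c = simulate_two_choice(params, trials, 1e-2, rng=rng, n_prior_trials=10_000)
            correct += c.p_aa + c.p_bb
            total += c.p_total
        assert correct / total == pytest.approx(0.95, abs=0.05)

    def test_success_rate_declines_with_concentration(self):
        params = VirtualMouseParams()
        rng = np.random.default_rng(2)
        srs = []
        for c in [1e-3, 2e-6, 1e-8]:  # far above, at, far below threshold
            correct = total = 0
            for i in range(20):
                trials = build_two_choice_session("AA", "HPH", seed=200 + i)
                counts = simulate_two_choice(params, trials, c, rng=rng, n_prior_trials=10_000)
                correct += counts.p_aa + counts.p_bb
                total += counts.p_total
            srs.append(correct / total)
        assert srs[0] > srs[1] > srs[2]
        assert srs[2] == pytest.approx(0.5, abs=0.05)

    def test_untrained_gonogo_agent_is_at_chance(self):
        """A naive agent's very first trials sit at the 50% chance floor,
        even for an easily detected odor."""
        params = VirtualMouseParams()
        rng = np.random.default_rng(3)
        correct = total = 0
        for i in range(200):  # many fresh agents, 4 trials each
            trials = build_gonogo_session("AA", "MO", n_per_odor=2, seed=i)
            c = simulate_gonogo(params, trials, 1e-2, rng=rng, n_prior_trials=0)
            correct += c.p_cs_plus + c.np_cs_minus
            total += c.n_trials
        assert correct / total == pytest.approx(0.5, abs=0.08)

    def test_trained_gonogo_agent_exceeds_90_percent(self):
        params = VirtualMouseParams()
        rng = np.random.default_rng(4)
        correct = total = 0
        for i in range(10):
            trials = build_gonogo_session("AA", "MO", seed=300 + i)
            c = simulate_gonogo(params, trials, 1e-2, rng=rng, n_prior_trials=10_000)
            correct += c.p_cs_plus + c.np_cs_minus
            total += c.n_trials
        assert correct / total > 0.9

    def test_two_choice_counts_are_consistent(self):
        params = VirtualMouseParams()
        trials = build_two_choice_session("AA", "HPH", seed=1)
        c = simulate_two_choice(params, trials, 1e-3, rng=np.random.default_rng(5))
        assert c.p_total == 60
        assert 0 <= c.p_aa <= 30 and 0 <= c.p_bb <= 30


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho": 0.0},
            {"rho": 1.5},
            {"eta": -1.0},
            {"lambda_base": 0.0},
            {"learn_asymptote": 0.4},
            {"valence": {"x": 2.0}},
            {"similarity": {frozenset(("a", "b")): 1.5}},
        ],
    )
    def test_out_of_range_parameters_are_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VirtualMouseParams(**kwargs)
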