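"""Circuit assembly, episode simulation, lesion and clamp behavior."""

from dataclasses import replace

import numpy as np
import pytest

import swimcpg as s
import swimcpg.analysis as an
import swimcpg.circuit as ci
import swimcpg.cohort as co


def bursts_of(rec):
    return an.detect_bursts(rec.spike_times["VSI_soma"], rec.stim_window).n_bursts


class TestBuildCircuit:
    def test_direct_synapse_scaled_to_animal(self, default_animal):
        circ = ci.build_circuit(default_animal)
        edge = next(
            e for e in circ.edges if e.source == "C2" and e.target == "VSI_proximal"
        )
        fast, slow = edge.sub_weights_ns
        assert slow / fast == pytest.approx(default_animal.h_mv / default_animal.d_mv)

    def test_zero_h_zeroes_hyperpolarizing_subconductance(self, default_animal):
        a = replace(default_animal, h_mv=0.0)
        circ = ci.build_circuit(a)
        edge = next(
            e for e in circ.edges if e.source == "C2" and e.target == "VSI_proximal"
        )
        assert edge.sub_weights_ns[1] == 0.0

    def test_negative_amplitudes_rejected(self, default_animal):
        with pytest.raises(ValueError):
            ci.build_circuit(replace(default_animal, h_mv=-1.0))

    def test_hi_di_silences_recruited_pool(self, default_animal):
        circ = ci.build_circuit(default_animal, hi_di=True)
        pool = next(e for e in circ.edges if e.source == "RecruitedPool")
        assert pool.weight_ns == 0.0
        rec = ci.simulate_episode(circ, ci.PdN3Stim(), seed=0)
        assert all(v.size == 0 for v in rec.spike_times.values())

    def test_invalid_edge_definitions_rejected(self):
        with pytest.raises(ValueError):
            ci.SynapseEdge("C2", "VSI_proximal", "sideways", 10.0)
        with pytest.raises(ValueError):
            ci.SynapseEdge("C2", "VSI_proximal", "excitatory", -5.0)
        with pytest.raises(ValueError):
            ci.SynapseEdge("C2", "VSI_proximal", "excitatory", 5.0, delay_ms=-1.0)


class TestSimulateEpisode:
    def test_deterministic_given_seed(self, default_animal):
        circ = ci.build_circuit(default_animal)
        r1 = ci.simulate_episode(circ, ci.PdN3Stim(), seed=42)
        r2 = ci.simulate_episode(circ, ci.PdN3Stim(), seed=42)
        np.testing.assert_array_equal(
            r1.spike_times["VSI_soma"], r2.spike_times["VSI_soma"]
        )
        np.testing.assert_array_equal(r1.nerve_impulse_times, r2.nerve_impulse_times)
        np.testing.assert_array_equal(r1.channels["VSI_soma"], r2.channels["VSI_soma"])

    def test_no_stimulation_no_bursts(self, default_animal):
        rec = ci.simulate_episode(ci.build_circuit(default_animal), None, seed=0)
        assert bursts_of(rec) == 0

    def test_default_animal_burst_range(self, default_animal):
        counts = [
            bursts_of(ci.simulate_episode(ci.build_circuit(default_animal), ci.PdN3Stim(), seed=k))
            for k in range(10)
        ]
        assert all(5 <= c <= 7 for c in counts)

    def test_voltages_physiological(self, default_animal):
        circ = ci.attach_dynamic_clamp(
            ci.build_circuit(default_animal), s.SynapseKinetics(), "add"
        )
        rec = ci.simulate_episode(circ, ci.PdN3Stim(), seed=1)
        for name in ("DSI", "C2", "VSI_soma"):
            v = rec.channels[name]
            assert v.min() >= -120.0 and v.max() <= 60.0

    def test_duration_and_dt_contracts(self, default_animal):
        circ = ci.build_circuit(default_animal)
        with pytest.raises(ValueError):
            ci.simulate_episode(circ, ci.PdN3Stim(), duration_s=30.0)
        with pytest.raises(ValueError):
            ci.simulate_episode(circ, ci.PdN3Stim(), dt_ms=1.0)

    def test_late_bursts_antidromic_in_default_animal(self, default_animal):
        # spike initiation shifts distally late in the motor pattern
        rec = ci.simulate_episode(ci.build_circuit(default_animal), ci.PdN3Stim(), seed=3)
        soma = rec.spike_times["VSI_soma"]
        bursts = an.detect_bursts(soma, rec.stim_window)
        lab = an.match_and_classify(soma, rec.nerve_impulse_times, bursts=bursts)
        assert lab.burst_labels[-1] == "antidromic"


class TestLesion:
    def test_idempotent(self, default_animal):
        circ = ci.build_circuit(default_animal)
        once = ci.apply_lesion(circ)
        twice = ci.apply_lesion(once)
        assert once == twice
        assert not once.pdn6_intact

    def test_no_nerve_impulses_after_lesion(self, default_animal):
        circ = ci.apply_lesion(ci.build_circuit(default_animal))
        rec = ci.simulate_episode(circ, ci.PdN3Stim(), seed=2)
        assert rec.nerve_impulse_times.size == 0

    def test_lesioned_count_never_exceeds_intact(self, default_animal):
        circ = ci.build_circuit(default_animal)
        for seed in range(8):
            n_i = bursts_of(ci.simulate_episode(circ, ci.PdN3Stim(), seed=seed))
            n_l = bursts_of(ci.simulate_episode(ci.apply_lesion(circ), ci.PdN3Stim(), seed=seed))
            assert n_l <= n_i

    def test_strongly_inhibited_animal_severely_impaired(self, default_animal):
        a = replace(default_animal, h_mv=2.9 + 2 * 1.3, epsilon=0.0)
        circ = ci.apply_lesion(ci.build_circuit(a))
        counts = [
            bursts_of(ci.simulate_episode(circ, ci.PdN3Stim(), seed=k)) for k in range(25)
        ]
        assert np.median(counts) <= 2

    def test_zero_h_animal_unimpaired(self, default_animal):
        a = replace(default_animal, h_mv=0.0, epsilon=0.0)
        circ = ci.build_circuit(a)
        for seed in range(6):
            n_i = bursts_of(ci.simulate_episode(circ, ci.PdN3Stim(), seed=seed))
            n_l = bursts_of(ci.simulate_episode(ci.apply_lesion(circ), ci.PdN3Stim(), seed=seed))
            assert abs(n_i - n_l) <= 1


class TestHiddenPhenotype:
    def test_intact_insensitive_lesioned_monotone_in_h(self, default_animal):
        # the core claim: across the population range of h the intact
        # pattern is unchanged while post-lesion impairment grades with h
        h_grid = [0.5, 1.5, 2.5, 3.5, 4.5, 5.5]
        seeds = range(6)
        intact_means, lesioned_means = [], []
        for h in h_grid:
            a = replace(default_animal, h_mv=h, epsilon=0.0)
            circ = ci.build_circuit(a)
            ii = [bursts_of(ci.simulate_episode(circ, ci.PdN3Stim(), seed=k)) for k in seeds]
            ll = [
                bursts_of(ci.simulate_episode(ci.apply_lesion(circ), ci.PdN3Stim(), seed=k))
                for k in seeds
            ]
            intact_means.append(np.mean(ii))
            lesioned_means.append(np.mean(ll))
        assert max(intact_means) - min(intact_means) <= 1.0
        assert all(b <= a + 1e-9 for a, b in zip(lesioned_means, lesioned_means[1:]))


class TestDynamicClamp:
    def test_mode_validation_and_hidi_warning(self, default_animal):
        circ = ci.build_circuit(default_animal)
        with pytest.raises(ValueError):
            ci.attach_dynamic_clamp(circ, s.SynapseKinetics(), "sideways")
        with pytest.warns(UserWarning):
            ci.attach_dynamic_clamp(
                ci.build_circuit(default_animal, hi_di=True), s.SynapseKinetics(), "add"
            )

    def test_addition_hidden_when_intact(self, default_animal):
        circ = ci.build_circuit(default_animal)
        clamped = ci.attach_dynamic_clamp(circ, s.SynapseKinetics(), "add")
        for seed in range(4):
            off = ci.simulate_episode(circ, ci.PdN3Stim(), seed=seed)
            on = ci.simulate_episode(clamped, ci.PdN3Stim(), seed=seed)
            assert bursts_of(on) == bursts_of(off)
            # but every spike becomes antidromic
            lab = an.match_and_classify(
                on.spike_times["VSI_soma"],
                on.nerve_impulse_times,
                bursts=an.detect_bursts(on.spike_times["VSI_soma"], on.stim_window),
            )
            assert all(b == "antidromic" for b in lab.burst_labels)

    def test_subtraction_never_shortens_intact_pattern(self, default_animal):
        circ = ci.build_circuit(default_animal)
        clamped = ci.attach_dynamic_clamp(circ, s.SynapseKinetics(), "subtract")
        for seed in range(6):
            off = ci.simulate_episode(circ, ci.PdN3Stim(), seed=seed)
            on = ci.simulate_episode(clamped, ci.PdN3Stim(), seed=seed)
            assert bursts_of(on) >= bursts_of(off)

    def test_lesioned_count_monotone_in_added_conductance(self, default_animal):
        lesioned = ci.apply_lesion(ci.build_circuit(default_animal))
        means = []
        for g in (0.0, 500.0, 1000.0, 1500.0):
            if g == 0.0:
                circ = lesioned
            else:
                circ = ci.attach_dynamic_clamp(
                    lesioned, s.SynapseKinetics(g_syn_ns=g), "add"
                )
            counts = [
                bursts_of(ci.simulate_episode(circ, ci.PdN3Stim(), seed=k))
                for k in range(6)
            ]
            means.append(np.mean(counts))
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))

    def test_clamp_current_channel_recorded(self, default_animal):
        circ = ci.attach_dynamic_clamp(
            ci.build_circuit(default_animal), s.SynapseKinetics(), "add"
        )
        rec = ci.simulate_episode(circ, ci.PdN3Stim(), seed=0)
        i = rec.channels["I_clamp_pA"]
        assert i.min() < -1000.0  # hyperpolarizing current flows on C2 bursts
        assert i.max() <= 1e-9


class TestHiDiPspCalibration:
    @pytest.mark.parametrize("h", [0.5, 2.9, 5.5])
    def test_simulated_hi_di_psp_matches_h(self, default_animal, h):
        a = replace(default_animal, h_mv=h)
        circ = ci.build_circuit(a, hi_di=True)
        rec = ci.simulate_episode(
            circ, ci.C2TrainStim(start_s=1.0), duration_s=16.0, dt_ms=0.5, seed=0
        )
        m = co.measure_hi_di_psp(rec.time_s, rec.channels["VSI_soma"], 0.5)
        assert m.hyperpolarization_mv == pytest.approx(h, rel=0.05)


class TestCalibration:
    def test_deterministic_and_reaches_defaults(self):
        rep1 = ci.calibrate_population_model(seed=0, n_mc=3000)
        rep2 = ci.calibrate_population_model(seed=0, n_mc=3000)
        assert rep1.chosen == rep2.chosen
        assert rep1.ok

    def test_failure_reported_not_raised(self):
        grid = (np.array([5.0]), np.array([0.0]), np.array([0.1]))
        rep = ci.calibrate_population_model(seed=0, n_mc=500, grid=grid)
        assert not rep.ok
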