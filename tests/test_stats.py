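import numpy as np
import pytest

from udsnet.intervals import StateSequence, EpochSet, UP, DOWN
from udsnet.stats import (assign_transitions, spa_spi_rates,
                          quantized_durations, continuous_cycle_durations,
                          transition_delays, xcorr_lag,
                          history_probabilities, sequence_summaries,
                          comb_concentration)


def alternating(n_cycles, up_s=1.0, down_s=1.0, t0=0.0, first=UP):
    iv = []
    t = t0
    labels = (first, DOWN if first == UP else UP)
    for _ in range(n_cycles):
        iv.append((t, t + up_s, labels[0]))
        iv.append((t + up_s, t + up_s + down_s, labels[1]))
        t += up_s + down_s
    return StateSequence(iv)


@pytest.fixture
def spa_pair():
    """Efferent Up (1, 5) spans the afferent cycle Up-Down-Up."""
    eff = StateSequence([(0, 1, DOWN), (1, 5, UP), (5, 6, DOWN), (6, 7, UP),
                         (7, 8, DOWN), (8, 9, UP), (9, 10, DOWN)])
    aff = StateSequence([(0, 1, DOWN), (1, 3, UP), (3, 4, DOWN), (4, 5, UP),
                         (5, 6, DOWN), (6, 7, UP), (7, 8, DOWN), (8, 9, UP),
                         (9, 10, DOWN)])
    return eff, aff


class TestAssignment:
    def test_identical_sequences_map_one_to_one(self):
        a = alternating(8)
        asn = assign_transitions(a, a)
        assert all(s.delay == 0.0 for s in asn.interior())
        assert all(s.trigger_count == 1 for s in asn.interior())

    def test_shifted_copy_has_uniform_delays(self):
        a = alternating(8)
        b = StateSequence([(s + 0.1, e + 0.1, lab)
                           for s, e, lab in a.intervals])
        asn = assign_transitions(b, a)
        du, ud = transition_delays(asn)
        assert np.allclose(du, 0.1)
        assert np.allclose(ud, 0.1)

    def test_persistent_up_collects_three_triggers(self, spa_pair):
        eff, aff = spa_pair
        asn = assign_transitions(eff, aff)
        persistent = [s for s in asn.interior() if s.trigger_count == 3]
        assert len(persistent) == 1
        assert persistent[0].label == UP

    def test_empty_sequence_raises(self):
        a = alternating(3)
        with pytest.raises(ValueError):
            assign_transitions(StateSequence([]), a)

    def test_trigger_counts_are_odd(self, spa_pair):
        eff, aff = spa_pair
        asn = assign_transitions(eff, aff)
        for s in asn.interior():
            assert s.trigger_count % 2 == 1


class TestRates:
    def test_phase_locked_rates_are_zero(self):
        a = alternating(10)
        s = spa_spi_rates(assign_transitions(a, a))
        assert s.phi_SPA == 0.0
        assert s.phi_SPI == 0.0

    def test_one_in_four_persistent(self, spa_pair):
        eff, aff = spa_pair
        s = spa_spi_rates(assign_transitions(eff, aff))
        # interior efferent Ups: (1,5) persistent, (6,7), (8,9) not
        assert s.phi_SPA == pytest.approx(1 / 3)
        assert s.phi_SPI == 0.0

    def test_label_swap_maps_spa_to_spi(self, spa_pair):
        eff, aff = spa_pair
        s = spa_spi_rates(assign_transitions(eff, aff))
        s_sw = spa_spi_rates(assign_transitions(eff.swap_labels(),
                                                aff.swap_labels()))
        assert s_sw.phi_SPI == pytest.approx(s.phi_SPA)
        assert s_sw.phi_SPA == pytest.approx(s.phi_SPI)

    def test_spa_equals_quantized_definition(self, spa_pair):
        """Trigger-set SPA coincides with counting durations >= 1.5."""
        eff, aff = spa_pair
        asn = assign_transitions(eff, aff)
        s = spa_spi_rates(asn)
        qd_up = quantized_durations(asn, label=UP)
        assert s.phi_SPA == pytest.approx((qd_up >= 1.5).mean())


class TestQuantizedDurations:
    def test_values_are_half_integers_at_least_half(self, spa_pair):
        eff, aff = spa_pair
        qd = quantized_durations(assign_transitions(eff, aff))
        assert np.all(qd >= 0.5)
        assert np.allclose(qd * 2, np.round(qd * 2))

    def test_spa_duration_is_three_halves(self, spa_pair):
        eff, aff = spa_pair
        qd = quantized_durations(assign_transitions(eff, aff), label=UP)
        assert 1.5 in qd

    def test_continuous_durations_near_comb_when_locked(self):
        a = alternating(20, up_s=0.8, down_s=1.2)
        asn = assign_transitions(a, a)
        cd = continuous_cycle_durations(asn)
        assert comb_concentration(cd) == pytest.approx(1.0)


class TestDelaysAndXcorr:
    def test_xcorr_lag_of_shifted_signal(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 0.5 * t)
        shift = int(0.1 * fs)
        y = np.roll(x, shift)   # y lags x by 0.1 s
        assert xcorr_lag(y, x, fs) == pytest.approx(0.1, abs=1 / fs)

    def test_xcorr_requires_common_grid(self):
        with pytest.raises(ValueError):
            xcorr_lag(np.zeros(10), np.zeros(11), 10.0)


class TestHistory:
    def test_caption_arithmetic(self):
        d = [0.5] * 80 + [1.5] * 15 + [2.5] * 5
        h = history_probabilities(d)
        assert h.p1 == pytest.approx(0.2)
        assert h.p2 == pytest.approx(0.25)

    def test_memoryless_geometric_recovers_equal_probabilities(self):
        # quantized durations of a geometric persistence process: a state
        # spans k extra cycles with probability p^k (1-p)
        rng = np.random.default_rng(0)
        p = 0.3
        k = rng.geometric(1 - p, size=1000) - 1
        durations = 0.5 + k  # half-integer comb
        h = history_probabilities(durations)
        assert h.p1 == pytest.approx(p, abs=0.05)
        assert h.p2 == pytest.approx(p, abs=0.05)
        assert h.p1 == pytest.approx(h.p2, abs=0.05)

    def test_no_persistence_flags_p2(self):
        h = history_probabilities([0.5] * 30)
        assert h.p1 == 0.0
        assert h.p2_undefined

    def test_too_few_states_raises(self):
        with pytest.raises(ValueError):
            history_probabilities([0.5] * 5)


class TestSequenceSummaries:
    def test_square_alternation(self):
        duty, freq = sequence_summaries(alternating(10, 1.0, 1.0))
        assert duty == pytest.approx(0.5)
        assert freq == pytest.approx(0.5)

    def test_all_up_flags_frequency(self):
        seq = StateSequence([(0, 10, UP)])
        duty, freq = sequence_summaries(seq)
        assert duty == 1.0
        assert np.isnan(freq)

    def test_asymmetric_duty(self):
        duty, _ = sequence_summaries(alternating(10, 1.0, 3.0))
        assert duty == pytest.approx(0.25)


class TestEpochSet:
    def test_complement_covers_gaps(self):
        eps = EpochSet([(10, 20), (50, 60)])
        comp = eps.complement(0, 100)
        assert comp.intervals == [(0, 10), (20, 50), (60, 100)]
        assert comp.label == "synchronized"

    def test_overlap(self):
        eps = EpochSet([(10, 20)])
        assert eps.overlap(15, 30) == pytest.approx(5.0)

    def test_invalid_epochs_raise(self):
        with pytest.raises(ValueError):
            EpochSet([(5, 2)])
        with pytest.raises(ValueError):
            EpochSet([(0, 10), (5, 15)])
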