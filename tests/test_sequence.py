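import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baroseq import (
    BeatSeries,
    SequenceParams,
    SyntheticConfig,
    bei_peak_spacings,
    delay_sweep,
    detect_ramps,
    find_sequences,
    generate,
    length_sweep,
    sweep_frame,
)
from oracles import brute_ramps, brute_sequences


def _series(values, gap_indices=(), label="SAP", units="mmHg"):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) * 0.17
    gap = np.zeros(len(values), dtype=bool)
    gap[list(gap_indices)] = True
    return BeatSeries(t, values, label=label, units=units, gap_after=gap)


class TestDetectRamps:
    def test_single_monotone_run(self):
        ramps = detect_ramps(_series([100, 101, 102, 103]), min_len=3)
        assert len(ramps) == 1
        r = ramps[0]
        assert (r.start, r.length, r.direction) == (0, 4, 1)

    def test_alternating_series_has_no_ramps(self):
        assert detect_ramps(_series([100, 101, 100, 101, 100]), min_len=3) == []

    def test_ties_break_ramps(self):
        # equal consecutive values never extend a run (strict threshold)
        ramps = detect_ramps(_series([100, 101, 101, 102, 103, 104]), min_len=3)
        assert [(r.start, r.length) for r in ramps] == [(2, 4)]

    def test_gap_breaks_a_run(self):
        ramps = detect_ramps(_series([100, 101, 102, 103, 104, 105], gap_indices=(2,)), min_len=3)
        assert {(r.start, r.length) for r in ramps} == {(0, 3), (3, 3)}

    def test_matches_brute_force_on_random_walk(self):
        rng = np.random.default_rng(0)
        s = _series(120 + np.cumsum(rng.normal(0, 1, 200)), gap_indices=(50, 130))
        got = {(r.start, r.length, r.direction) for r in detect_ramps(s, 3)}
        assert got == brute_ramps(s.values, s.gap_after, 3, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000), st.integers(10, 60), st.sampled_from([0.0, 0.5]))
    def test_brute_force_equivalence_property(self, seed, n, threshold):
        rng = np.random.default_rng(seed)
        s = _series(120 + np.cumsum(rng.normal(0, 1, n)))
        got = {(r.start, r.length, r.direction) for r in detect_ramps(s, 3, threshold)}
        assert got == brute_ramps(s.values, s.gap_after, 3, threshold)


class TestFindSequences:
    def test_exact_affine_coupling_recovers_slope(self):
        rng = np.random.default_rng(4)
        sap_vals = 120 + np.cumsum(rng.normal(0, 1, 300))
        sap = _series(sap_vals)
        pi = _series(30 + 2.0 * sap_vals, label="PI", units="ms")
        res = find_sequences(sap, pi, SequenceParams(delay=0))
        assert res.n_ramps_evaluable > 10
        assert res.bei == 1.0
        for m in res.matches:
            assert m.slope == pytest.approx(2.0, abs=1e-9)
            assert m.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_on_independent_noise(self):
        rng = np.random.default_rng(12)
        sap = _series(120 + np.cumsum(rng.normal(0, 1, 2000)))
        pi = _series(170 + rng.normal(0, 5, 2000), label="PI", units="ms")
        for delay in (0, 1, 3):
            res = find_sequences(sap, pi, SequenceParams(delay=delay))
            n_eval, accepted = brute_sequences(
                sap.values, pi.values, sap.gap_after, 3, 0.8, delay
            )
            assert res.n_ramps_evaluable == n_eval
            got = {
                (m.ramp.start, m.ramp.length, m.ramp.direction): (m.slope, m.pearson_r)
                for m in res.matches
            }
            assert set(got) == set(accepted)
            for key, (slope, r) in accepted.items():
                assert got[key][0] == pytest.approx(slope, abs=1e-9)
                assert got[key][1] == pytest.approx(r, abs=1e-9)

    def test_truncated_ramp_at_series_end_is_unevaluable(self):
        sap = _series([120, 120, 120, 120, 121, 122, 123])
        pi = _series(np.full(7, 170.0), label="PI", units="ms")
        res = find_sequences(sap, pi, SequenceParams(delay=5))
        assert res.n_ramps_evaluable == 0
        assert res.bei is None

    def test_flat_pi_segment_counts_in_denominator_only(self):
        sap = _series([120, 121, 122, 123])
        pi = _series(np.full(4, 170.0), label="PI", units="ms")
        res = find_sequences(sap, pi, SequenceParams(delay=0))
        assert res.n_ramps_evaluable == 1
        assert res.n_sequences == 0
        assert res.bei == 0.0

    def test_negation_symmetry(self):
        rng = np.random.default_rng(8)
        sap_vals = 120 + np.cumsum(rng.normal(0, 1, 500))
        pi_vals = 170 + 1.5 * np.cumsum(rng.normal(0, 1, 500))
        sap, pi = _series(sap_vals), _series(pi_vals, label="PI", units="ms")
        sap_n = _series(-sap_vals)
        pi_n = _series(-pi_vals, label="PI", units="ms")
        a = find_sequences(sap, pi, SequenceParams(delay=1))
        b = find_sequences(sap_n, pi_n, SequenceParams(delay=1))
        assert a.n_sequences == b.n_sequences
        assert a.bei == b.bei
        got_a = sorted(m.slope for m in a.matches)
        got_b = sorted(m.slope for m in b.matches)
        np.testing.assert_allclose(got_a, got_b, atol=1e-12)
        # up ramps map to down ramps
        assert sorted((m.ramp.start, -m.ramp.direction) for m in a.matches) == sorted(
            (m.ramp.start, m.ramp.direction) for m in b.matches
        )


class TestSweeps:
    def test_shifted_affine_coupling_peaks_at_true_delay(self):
        rng = np.random.default_rng(2)
        sap_vals = 120 + np.cumsum(rng.normal(0, 1, 400))
        pi_vals = np.empty(400)
        pi_vals[2:] = 30 + 2.0 * sap_vals[:-2]
        pi_vals[:2] = 170.0
        sap = _series(sap_vals)
        pi = _series(pi_vals, label="PI", units="ms")
        results = delay_sweep(sap, pi, SequenceParams())
        assert len(results) == 13
        bei = [np.nan if r.bei is None else r.bei for r in results]
        assert bei[2] == 1.0
        assert bei[2] == max(b for b in bei if np.isfinite(b))

    def test_respiratory_coupling_gives_3_to_4_beat_bei_oscillation(self):
        sap, pi, _ = generate(SyntheticConfig(n_beats=3000, seed=5))
        results = delay_sweep(sap, pi)
        bei = [np.nan if r.bei is None else r.bei for r in results]
        spacings = bei_peak_spacings(bei)
        assert len(spacings) >= 1
        assert set(spacings) <= {3, 4}

    def test_sequence_counts_non_increasing_in_n(self, synthetic_pair):
        sap, pi, _ = synthetic_pair
        results = length_sweep(sap, pi, SequenceParams(delay=1), n_values=range(3, 10))
        n_seq = [r.n_sequences for r in results]
        n_ramps = [r.n_ramps_total for r in results]
        assert all(a >= b for a, b in zip(n_seq, n_seq[1:]))
        assert all(a >= b for a, b in zip(n_ramps, n_ramps[1:]))

    def test_bei_decreases_with_n_on_lowpass_series(self):
        # longer SAP ramps are less likely to find a matching PI course when
        # the slow coupling is weak relative to uncoupled PI variability
        from baroseq import PreprocessConfig, band_split

        pc = PreprocessConfig()
        bei_3, bei_9 = [], []
        for seed in range(5):
            sap, pi, _ = generate(
                SyntheticConfig(n_beats=4000, noise_mode="band", gain_lf=0.3,
                                sap_noise_sd=0.4, pi_noise_sd=2.5, seed=seed)
            )
            sap_lp = band_split(sap, pc, "low")
            pi_lp = band_split(pi, pc, "low")
            results = length_sweep(
                sap_lp, pi_lp, SequenceParams(delay=3), n_values=[3, 9]
            )
            bei_3.append(results[0].bei)
            bei_9.append(results[1].bei)
        assert np.mean(bei_3) > np.mean(bei_9)

    def test_sweep_frame_shape(self, synthetic_pair):
        sap, pi, _ = synthetic_pair
        frame = sweep_frame(delay_sweep(sap, pi))
        assert list(frame["delay"]) == list(range(13))
        assert {"bei", "brs_mean", "n_sequences"} <= set(frame.columns)


class TestParams:
    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            SequenceParams(n=1)

    def test_n_two_warns(self):
        with pytest.warns(UserWarning, match="below the recommended"):
            SequenceParams(n=2)

    @pytest.mark.parametrize("kwargs", [{"r_min": 0.0}, {"r_min": 1.5}, {"delay": -1},
                                        {"sap_threshold": -0.1}])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SequenceParams(**kwargs)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000), st.integers(30, 120), st.integers(0, 4))
def test_bei_bounds_and_count_invariants(seed, n, delay):
    rng = np.random.default_rng(seed)
    sap = _series(120 + np.cumsum(rng.normal(0, 1, n)))
    pi = _series(170 + rng.normal(0, 3, n), label="PI", units="ms")
    res = find_sequences(sap, pi, SequenceParams(delay=delay))
    assert res.n_sequences <= res.n_ramps_evaluable <= res.n_ramps_total
    if res.bei is not None:
        assert 0.0 <= res.bei <= 1.0
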