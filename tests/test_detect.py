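"""IED detection, spike/sharp-transient classification, peak contact."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thalied.detect import (Candidate, DetectionParams, classify_event,
                            detect_candidates, detect_site,
                            fast_component_duration_ms, ied_rate,
                            match_events, peak_contact,
                            preprocess_recording)
from thalied.recording import (DBS_LEFT, Recording, make_bipolar,
                               make_monopolar)
from thalied.synth import SimulationConfig, SpikeTemplate, one_over_f_noise, \
    simulate_recording
from conftest import insert_template


def balanced(fast_ms, fast_amp=100.0, slow_ms=150.0, **kw):
    """Template whose slow-wave area balances the fast lobe (no recovery
    tail), so noise-free insertions contain exactly one deflection pair."""
    slow_amp = fast_amp * 2 * fast_ms / slow_ms
    return SpikeTemplate(fast_duration_ms=fast_ms, fast_amplitude_uv=fast_amp,
                         slow_duration_ms=slow_ms,
                         slow_amplitude_uv=slow_amp, **kw)


def spread_insert(rec, chain, primary_idx, t, template, weights=(1.0, 0.5)):
    insert_template(rec, chain[primary_idx], t, template, weights[0])
    for k, w in enumerate(weights[1:], start=1):
        for j in (primary_idx - k, primary_idx + k):
            if 0 <= j < len(chain):
                insert_template(rec, chain[j], t, template, w)
    return rec


class TestDetectCandidates:
    def test_noise_free_insertion_single_candidate(self, lead_recording):
        rec = spread_insert(lead_recording, DBS_LEFT, 1, 30.0, balanced(30.0))
        view = make_bipolar(rec, "dbs-adjacent")
        cands = detect_candidates(view)
        assert len(cands) == 1
        assert cands[0].time_s == pytest.approx(30.0, abs=0.005)

    def test_two_close_insertions_merge(self, lead_recording):
        tpl = balanced(30.0)
        rec = spread_insert(lead_recording, DBS_LEFT, 1, 30.0, tpl)
        rec = spread_insert(rec, DBS_LEFT, 1, 30.030, tpl)
        view = make_bipolar(rec, "dbs-adjacent")
        cands = detect_candidates(
            view, params=DetectionParams(min_separation_ms=200.0))
        assert len(cands) == 1

    def test_empty_segment_empty_list(self, lead_recording):
        view = make_bipolar(lead_recording, "dbs-adjacent")
        assert detect_candidates(view, segment=(10.0, 10.0)) == []

    def test_threshold_monotonicity(self):
        """Raising the prominence threshold never increases the candidate
        count."""
        cfg = SimulationConfig(segment_minutes=1.0, fs=256.0, seed=21,
                               rates={("thal-left", "sleep"): 3.0,
                                      ("thal-left", "awake"): 3.0})
        rec, _ = simulate_recording(cfg)
        rec = preprocess_recording(rec)
        view = make_bipolar(rec, "dbs-adjacent")
        counts = [len(detect_candidates(
            view, params=DetectionParams(prominence_threshold=thr)))
            for thr in (3.0, 4.0, 5.0, 6.0, 8.0, 12.0)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > 0

    def test_false_positive_rate_on_pure_background(self):
        """6x robust-SD threshold on band-passed 1/f background: on average
        fewer than one false detection per 20-minute segment."""
        fs, minutes = 128.0, 20.0
        n = int(minutes * 60 * fs)
        total = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            data = np.vstack([one_over_f_noise(n, fs, 10.0, 1.5, rng)
                              for _ in range(4)])
            rec = Recording(labels=DBS_LEFT, data=data, fs=fs)
            rec = preprocess_recording(rec)
            view = make_bipolar(rec, "dbs-adjacent")
            total += len(detect_candidates(view))
        assert total / n_seeds < 1.0


class TestClassification:
    def _views(self, rec):
        return (make_bipolar(rec, "dbs-adjacent"),
                make_monopolar(rec, labels=DBS_LEFT))

    def _classify_first(self, rec, **params):
        bip, mono = self._views(rec)
        p = DetectionParams(**params)
        cands = detect_candidates(bip, params=p)
        assert cands, "no candidate detected"
        cand = max(cands, key=lambda c: c.prominence)
        return classify_event(cand, bip, mono, p)

    def test_canonical_spike(self, lead_recording):
        rec = spread_insert(lead_recording, DBS_LEFT, 1, 30.0, balanced(30.0))
        ev = self._classify_first(rec)
        assert ev.klass == "spike"
        assert ev.has_phase_reversal and ev.has_slow_wave
        assert ev.fast_duration_ms < 50.0

    def test_common_mode_without_reversal_is_sharp_transient(
            self, lead_recording):
        """A monotone far-field gradient on all contacts: outstanding in
        bipolar but no phase reversal -> sharp transient."""
        tpl = balanced(30.0)
        for lb, w in zip(DBS_LEFT, (1.0, 0.5, 0.2, 0.05)):
            insert_template(lead_recording, lb, 30.0, tpl, w)
        ev = self._classify_first(lead_recording)
        assert ev.klass == "sharp_transient"
        assert not ev.has_phase_reversal

    def test_slow_fast_component_is_sharp_transient_despite_reversal(
            self, lead_recording):
        """Fast component of 80 ms with phase reversal and prominence is
        still a sharp transient (duration does not rescue it)."""
        rec = spread_insert(lead_recording, DBS_LEFT, 1, 30.0,
                            balanced(80.0, slow_ms=200.0))
        ev = self._classify_first(rec)
        assert ev.klass == "sharp_transient"
        assert ev.has_phase_reversal
        assert ev.fast_duration_ms >= 50.0

    @pytest.mark.parametrize("fast_ms,expected", [(49.0, "spike"),
                                                  (51.0, "sharp_transient")])
    def test_duration_boundary(self, fast_ms, expected):
        """Templates straddling the 50 ms boundary classify as spike vs
        sharp transient at matched amplitude (full 2048 Hz sampling, so the
        rendered width is within half a sample of nominal)."""
        fs = 2048.0
        rec = Recording(labels=DBS_LEFT, data=np.zeros((4, int(20 * fs))),
                        fs=fs)
        rec = spread_insert(rec, DBS_LEFT, 1, 10.0, balanced(fast_ms))
        assert self._classify_first(rec).klass == expected

    def test_missing_slow_wave_blocks_spike(self, lead_recording):
        """Fast deflection without a following slow wave cannot be a
        spike."""
        fs = lead_recording.fs
        n = int(round(2 * 30.0 / 1000.0 * fs))
        lobe = -100.0 * np.sin(np.pi * np.arange(n) / (n - 1)) ** 2
        i0 = int(30.0 * fs) - (n - 1) // 2
        for idx, w in zip((1, 0, 2), (1.0, 0.5, 0.5)):
            row = lead_recording.index(DBS_LEFT[idx])
            lead_recording.data[row, i0:i0 + n] += w * lobe
        ev = self._classify_first(lead_recording)
        assert ev.klass == "sharp_transient"
        assert not ev.has_slow_wave

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(fast_ms=st.floats(15.0, 85.0), amp=st.floats(50.0, 300.0),
           common_mode=st.booleans())
    def test_spike_label_respects_invariant(self, fast_ms, amp, common_mode):
        """Property: whenever the classifier says spike, the defining
        criteria all hold (duration < 50 ms, slow wave, reversal, monopolar
        prominence)."""
        fs = 512.0
        n = int(90 * fs)
        rec = Recording(labels=DBS_LEFT, data=np.zeros((4, n)), fs=fs)
        tpl = balanced(fast_ms, fast_amp=amp)
        if common_mode:
            for lb, w in zip(DBS_LEFT, (1.0, 0.5, 0.2, 0.05)):
                insert_template(rec, lb, 45.0, tpl, w)
        else:
            spread_insert(rec, DBS_LEFT, 2, 45.0, tpl)
        bip, mono = self._views(rec)
        p = DetectionParams()
        cands = detect_candidates(bip, params=p)
        for cand in cands:
            ev = classify_event(cand, bip, mono, p)
            if ev is not None and ev.klass == "spike":
                assert ev.fast_duration_ms < p.fast_max_ms
                assert ev.has_slow_wave
                assert ev.has_phase_reversal


class TestPeakContact:
    def test_insertion_contact_identified(self, lead_recording):
        rec = spread_insert(lead_recording, DBS_LEFT, 1, 30.0, balanced(30.0))
        mono = make_monopolar(rec, labels=DBS_LEFT)
        assert peak_contact(30.0, mono) == "LTh1"

    def test_tie_broken_toward_deepest(self, lead_recording):
        tpl = balanced(30.0)
        insert_template(lead_recording, "LTh1", 30.0, tpl, 1.0)
        insert_template(lead_recording, "LTh2", 30.0, tpl, 1.0)
        mono = make_monopolar(lead_recording, labels=DBS_LEFT)
        assert peak_contact(30.0, mono) == "LTh1"

    def test_amplitude_gradient_argmax(self, lead_recording):
        tpl = balanced(30.0)
        for lb, w in zip(("LTh0", "LTh1", "LTh2"), (0.3, 0.6, 1.0)):
            insert_template(lead_recording, lb, 30.0, tpl, w)
        mono = make_monopolar(lead_recording, labels=DBS_LEFT)
        assert peak_contact(30.0, mono) == "LTh2"


class TestRates:
    def test_rate_arithmetic(self):
        assert ied_rate([1] * 5, 20.0) == pytest.approx(0.25)
        assert ied_rate([], 20.0) == 0.0
        with pytest.raises(ValueError):
            ied_rate([], 0.0)

    def test_simulated_rate_recovered(self):
        """Detected thalamic sleep rate agrees with the configured 0.33/min
        within 3 SE of the realized event count."""
        rate, n_sims = 0.33, 6
        n_det = n_true = 0
        minutes = 0.0
        for seed in range(n_sims):
            cfg = SimulationConfig(rates={("thal-left", "sleep"): rate,
                                          ("thal-left", "awake"): rate},
                                   segment_minutes=2.5, fs=256.0, seed=seed)
            rec, gt = simulate_recording(cfg)
            rec = preprocess_recording(rec)
            bip = make_bipolar(rec, "dbs-adjacent")
            mono = make_monopolar(rec, labels=DBS_LEFT)
            for state in ("sleep", "awake"):
                segs = rec.state_intervals(state)
                evs = detect_site(bip, mono, segs, "thal-left", state)
                n_det += len(evs)
                minutes += sum(e - s for s, e in segs) / 60.0
            n_true += len(gt)
        se = np.sqrt(max(n_true, 1))
        assert abs(n_det - n_true) <= 3 * se
        assert n_det / minutes == pytest.approx(rate, abs=3 * se / minutes)


def test_match_events_greedy():
    m, d, t = match_events([1.0, 2.0, 5.0], [1.01, 2.2, 4.99], tol_s=0.05)
    assert (m, d, t) == (2, 3, 3)
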