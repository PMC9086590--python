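"""Wavelet phase extraction and PLV maps: analytic phase checks,
zero-jitter and null behaviour, invariances, and the construction
oracle (pipeline PLV vs the generator's own jitter draws)."""

import dataclasses

import numpy as np
import pytest

from ecogplv import (
    AnalysisConfig,
    CouplingSpec,
    EventTable,
    pairwise_plv,
    resultant_length,
    seed_channels,
    tf_phase,
    write_bundle,
    read_bundle,
)
from ecogplv.preprocess import notch, rereference_connector
from ecogplv.simulate import (
    ScheduleSpec,
    _group_couplings,
    _session_rng,
    gen_background,
    inject_coupling,
    make_schedule,
    reduced_session_config,
    simulate_session,
)

from conftest import make_bundle


@pytest.fixture(scope="module")
def config():
    return AnalysisConfig()


def _tone_bundle(freq=10.0, fs=1000.0, seconds=20.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return make_bundle(amp * np.cos(2 * np.pi * freq * t)[None, :], fs=fs)


class TestTfPhase:
    def test_pure_tone_phase_slope(self, config):
        b = _tone_bundle(10.0)
        ev = EventTable([5000.0, 9000.0], ["tone", "tone"])
        tp = tf_phase(b, ev, "c00", config)
        fi = np.argmin(np.abs(tp.freqs_hz - 10.0))
        ph = np.unwrap(tp.phase[0, fi].astype(float))
        slope = np.polyfit(tp.times_ms / 1000.0, ph, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_phase_zero_at_cosine_peak(self, config):
        # onset at 5000 ms: an integer number of 10 Hz cycles -> peak
        b = _tone_bundle(10.0)
        ev = EventTable([5000.0], ["tone"])
        tp = tf_phase(b, ev, "c00", config)
        fi = np.argmin(np.abs(tp.freqs_hz - 10.0))
        ti = np.argmin(np.abs(tp.times_ms - 0.0))
        assert tp.phase[0, fi, ti] == pytest.approx(0.0, abs=1e-6)

    def test_phase_invariant_to_amplitude_scaling(self, config):
        ev = EventTable([5000.0], ["tone"])
        t1 = tf_phase(_tone_bundle(amp=1.0), ev, "c00", config)
        t2 = tf_phase(_tone_bundle(amp=7.5), ev, "c00", config)
        # compare where the wavelet response is non-negligible; far from
        # 10 Hz a pure tone leaves only numerical noise, whose "phase"
        # is arbitrary
        from ecogplv.circstats import circular_distance

        sel = np.abs(t1.freqs_hz - 10.0) <= 5.0
        d = circular_distance(t1.phase[:, sel].astype(float),
                              t2.phase[:, sel].astype(float))
        assert np.max(d) < 1e-4

    def test_edge_events_dropped(self, config):
        b = _tone_bundle(seconds=6.0)
        # first event's epoch reaches into the 4 Hz wavelet edge region
        ev = EventTable([600.0, 3000.0], ["tone", "tone"])
        tp = tf_phase(b, ev, "c00", config)
        assert list(tp.event_index) == [1]

    def test_grid_shape(self, config):
        ev = EventTable([5000.0], ["tone"])
        tp = tf_phase(_tone_bundle(), ev, "c00", config)
        assert tp.phase.shape == (1, 57, 160)
        assert tp.times_ms[0] == -200.0 and tp.times_ms[-1] == 595.0


@pytest.fixture(scope="module")
def coupled_session():
    cfg = reduced_session_config(
        session_id="plv-inf", n_slots=220, channels_per_region=8,
        couplings=[CouplingSpec("at00", "fp01", "both", 18.0,
                                (100.0, 300.0), 1e7, 40.0)],
    )
    bundle, events, _ = simulate_session(cfg, 31)
    conditioned = notch(rereference_connector(bundle))
    config = AnalysisConfig()
    sp = tf_phase(conditioned, events, "at00", config)
    return config, events, conditioned, sp


class TestPairwisePlv:

    def test_zero_jitter_coupling_gives_high_plv(self, coupled_session):
        config, events, conditioned, sp = coupled_session
        tp = tf_phase(conditioned, events, "fp01", config)
        m = pairwise_plv(sp, tp, "tone", config.alpha_plv)
        fi = np.argmin(np.abs(m.freqs_hz - 18.0))
        ti = np.argmin(np.abs(m.times_ms - 200.0))
        assert m.plv[fi, ti] >= 0.9
        assert m.significant[fi, ti]

    def test_null_plv_magnitude(self, config):
        """Uncoupled channels, ~200 trials: PLV across bins sits near
        the uniform-resultant expectation with a bounded upper tail."""
        cfg = reduced_session_config(session_id="plv-null", n_slots=220,
                                     channels_per_region=2)
        bundle, events, _ = simulate_session(cfg, 32)
        conditioned = notch(rereference_connector(bundle))
        sp = tf_phase(conditioned, events, "at00", config)
        tp = tf_phase(conditioned, events, "fp00", config)
        m = pairwise_plv(sp, tp, "tone", config.alpha_plv)
        n = m.n_trials
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
        # high-frequency bins are nearly independent across trials;
        # low-frequency bins inherit some trial-to-trial dependence
        assert np.median(m.plv) == pytest.approx(expected, rel=0.35)
        assert np.quantile(m.plv, 0.95) < 2 * 1.92 * expected

    def test_global_phase_rotation_invariance(self, coupled_session):
        config, events, conditioned, sp = coupled_session
        tp = tf_phase(conditioned, events, "fp01", config)
        m1 = pairwise_plv(sp, tp, "tone", config.alpha_plv)
        from ecogplv.circstats import wrap_angle

        tp2 = dataclasses.replace(
            tp, phase=wrap_angle(tp.phase + 1.234).astype(np.float32)
        )
        m2 = pairwise_plv(sp, tp2, "tone", config.alpha_plv)
        assert np.allclose(m1.plv, m2.plv, atol=1e-5)

    def test_shuffled_trials_kill_significance(self, coupled_session):
        config, events, conditioned, sp = coupled_session
        tp = tf_phase(conditioned, events, "fp01", config)
        perm = np.random.default_rng(0).permutation(tp.n_trials)
        tp_sh = dataclasses.replace(tp, phase=tp.phase[perm])
        m = pairwise_plv(sp, tp_sh, "tone", config.alpha_plv)
        assert m.significant.mean() <= config.alpha_plv

    def test_mismatched_trials_rejected(self, coupled_session):
        config, events, conditioned, sp = coupled_session
        tp = tf_phase(conditioned, events, "fp01", config)
        tp_cut = tp.restrict(tp.event_index[:-5])
        with pytest.raises(ValueError):
            pairwise_plv(sp, tp_cut, "tone", config.alpha_plv)

    def test_pipeline_plv_matches_injected_jitter_resultant(self, config):
        """End-to-end vs construction oracle: the PLV measured through
        signal synthesis + wavelet phase extraction agrees with the
        resultant of the generator's own von Mises draws."""
        cfg = reduced_session_config(
            session_id="plv-oracle", n_slots=100, channels_per_region=8,
            couplings=[CouplingSpec("at00", "fp00", "tone", 18.0,
                                    (100.0, 300.0), 5.0, 40.0)],
        )
        cfg.schedule = ScheduleSpec(n_slots=100, p_omit=0.0)
        bundle, events, _ = simulate_session(cfg, 33)

        # replay the generator's draw sequence to recover the deltas
        rng = _session_rng(33, cfg.session_id)
        schedule = make_schedule(cfg.schedule, rng)
        ev = EventTable(schedule.onsets_ms + cfg.lead_pad_ms, schedule.kinds)
        chans = cfg.montage()
        gen_background(len(chans), bundle.n_samples, cfg.fs_hz, cfg.noise, rng)
        log = []
        scratch = np.zeros((len(chans), bundle.n_samples))
        for group in _group_couplings(cfg.couplings):
            inject_coupling(scratch, cfg.fs_hz, ev, group, rng,
                            [c.channel_id for c in chans], phase_log=log)
        oracle = resultant_length([e["deltas"]["fp00"] for e in log])

        conditioned = notch(rereference_connector(bundle))
        sp = tf_phase(conditioned, events, "at00", config)
        tp = tf_phase(conditioned, events, "fp00", config)
        m = pairwise_plv(sp, tp, "tone", config.alpha_plv)
        fi = np.argmin(np.abs(m.freqs_hz - 18.0))
        ti = np.argmin(np.abs(m.times_ms - 200.0))
        assert m.plv[fi, ti] == pytest.approx(oracle, abs=0.05)


class TestSeedChannels:
    def test_default_simulation_has_two_seeds(self):
        cfg = reduced_session_config(n_slots=10)
        bundle, _, _ = simulate_session(cfg, 1)
        assert seed_channels(bundle) == ["at00"]
        from ecogplv import default_session_config

        b80, _, _ = simulate_session(
            dataclasses.replace(default_session_config(), schedule=ScheduleSpec(n_slots=10)), 1
        )
        assert sorted(seed_channels(b80)) == ["at08", "pt08"]

    def test_no_flags_errors(self, rng):
        b = make_bundle(rng.standard_normal((2, 100)))
        with pytest.raises(ValueError):
            seed_channels(b)

    def test_flags_roundtrip_bundle_io(self, tmp_path, rng):
        b = make_bundle(rng.standard_normal((2, 100)), seeds=("c01",))
        write_bundle(b, tmp_path / "b")
        assert seed_channels(read_bundle(tmp_path / "b")) == ["c01"]
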