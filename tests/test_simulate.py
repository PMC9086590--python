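"""Synthetic-session generator: schedule statistics, noise spectra,
template and coupling injection, and whole-session determinism."""

import numpy as np
import pytest

from ecogplv import (
    ConfigError,
    CouplingSpec,
    ErpTemplateSpec,
    EventTable,
    NoiseSpec,
    ScheduleSpec,
    default_session_config,
    gen_background,
    inject_coupling,
    inject_erp,
    make_schedule,
    reduced_session_config,
    resultant_length,
    simulate_session,
)
from ecogplv.simulate import _group_couplings, _session_rng


class TestSchedule:
    def test_exact_count_matches_session_design(self, rng):
        """1000 slots at 10% omission: exactly 900 tones, 100 omissions."""
        ev = make_schedule(ScheduleSpec(n_slots=1000, p_omit=0.10), rng)
        assert ev.counts() == {"tone": 900, "omission": 100}
        assert np.array_equal(ev.onsets_ms, 500.0 * np.arange(1000))

    def test_zero_probability_gives_all_tones(self, rng):
        ev = make_schedule(ScheduleSpec(n_slots=50, p_omit=0.0), rng)
        assert ev.counts() == {"tone": 50, "omission": 0}

    def test_bernoulli_fraction(self, rng):
        ev = make_schedule(
            ScheduleSpec(n_slots=100_000, p_omit=0.10, mode="bernoulli"), rng
        )
        frac = ev.counts()["omission"] / 100_000
        assert frac == pytest.approx(0.10, abs=0.003)  # ~3 binomial SEs

    def test_invalid_specs(self):
        with pytest.raises(ConfigError):
            ScheduleSpec(n_slots=0)
        with pytest.raises(ConfigError):
            ScheduleSpec(p_omit=1.5)
        with pytest.raises(ConfigError):
            ScheduleSpec(mode="sometimes")


class TestBackground:
    @staticmethod
    def _loglog_slope(x, fs):
        freqs = np.fft.rfftfreq(x.size, 1 / fs)
        psd = np.abs(np.fft.rfft(x)) ** 2
        sel = (freqs >= 2) & (freqs <= 100)
        return np.polyfit(np.log(freqs[sel]), np.log(psd[sel]), 1)[0]

    def test_white_noise_has_flat_spectrum(self, rng):
        x = gen_background(
            1, 2**16, 1000.0, NoiseSpec(one_over_f_exponent=0.0, line_amp_uv=0.0),
            rng,
        )[0]
        assert self._loglog_slope(x, 1000.0) == pytest.approx(0.0, abs=0.1)

    def test_pink_noise_slope_and_rms(self, rng):
        spec = NoiseSpec(one_over_f_exponent=1.0, rms_uv=20.0, line_amp_uv=0.0)
        x = gen_background(2, 2**16, 1000.0, spec, rng)
        rms = np.sqrt(np.mean(x**2, axis=1))
        assert rms == pytest.approx([20.0, 20.0], rel=0.05)
        assert self._loglog_slope(x[0], 1000.0) == pytest.approx(-1.0, abs=0.15)

    def test_line_component_present(self, rng):
        spec = NoiseSpec(one_over_f_exponent=0.0, rms_uv=1.0, line_amp_uv=50.0)
        x = gen_background(1, 10_000, 1000.0, spec, rng)[0]
        freqs = np.fft.rfftfreq(x.size, 1 / 1000.0)
        amp = 2 * np.abs(np.fft.rfft(x)) / x.size
        assert amp[np.argmin(np.abs(freqs - 50.0))] == pytest.approx(50.0, rel=0.05)

    def test_deterministic_under_fixed_seed(self):
        a = gen_background(3, 1000, 1000.0, NoiseSpec(), np.random.default_rng(5))
        b = gen_background(3, 1000, 1000.0, NoiseSpec(), np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_negative_exponent_rejected(self):
        with pytest.raises(ConfigError):
            NoiseSpec(one_over_f_exponent=-0.5)


class TestInjectErp:
    def test_single_component_peak(self):
        sig = np.zeros((2, 2000))
        ev = EventTable([500.0], ["tone"])
        t = ErpTemplateSpec("frontal_pole", "tone", [(90.0, 10.0, 30.0)])
        inject_erp(sig, 1000.0, ev, [t], ["frontal_pole", "ofc"])
        assert sig[0, 590] == pytest.approx(30.0)
        assert np.argmax(sig[0]) == 590
        assert np.all(sig[1] == 0.0)  # other region untouched

    def test_omission_template_skips_tone_events(self):
        sig = np.zeros((1, 2000))
        ev = EventTable([500.0], ["tone"])
        t = ErpTemplateSpec("ofc", "omission", [(90.0, 10.0, 30.0)])
        inject_erp(sig, 1000.0, ev, [t], ["ofc"])
        assert np.all(sig == 0.0)

    def test_overlapping_components_sum_pointwise(self):
        ev = EventTable([500.0], ["tone"])
        args = (1000.0, ev)
        one = np.zeros((1, 2000))
        two = np.zeros((1, 2000))
        both = np.zeros((1, 2000))
        inject_erp(one, *args, [ErpTemplateSpec("ofc", "both", [(80, 15, 10)])], ["ofc"])
        inject_erp(two, *args, [ErpTemplateSpec("ofc", "both", [(100, 20, -5)])], ["ofc"])
        inject_erp(
            both, *args,
            [ErpTemplateSpec("ofc", "both", [(80, 15, 10), (100, 20, -5)])],
            ["ofc"],
        )
        # equal up to the 5-sigma Gaussian tail truncation of the kernels
        assert np.allclose(both, one + two, atol=1e-3)

    def test_unknown_region_rejected(self):
        with pytest.raises(ConfigError):
            inject_erp(
                np.zeros((1, 100)), 1000.0, EventTable([10.0], ["tone"]),
                [ErpTemplateSpec("vlpfc", "tone", [(5, 2, 1)])], ["ofc"],
            )


class TestInjectCoupling:
    def _events(self, n=20):
        return EventTable(500.0 * np.arange(1, n + 1), ["tone"] * n)

    def test_infinite_kappa_makes_target_copy_seed(self, rng):
        sig = np.zeros((2, 12_000))
        spec = CouplingSpec("s", "t", "tone", 18.0, (100.0, 300.0), 1e7, 10.0)
        inject_coupling(sig, 1000.0, self._events(), spec, rng, ["s", "t"])
        assert np.array_equal(sig[0], sig[1])  # zero jitter: identical bursts
        assert np.max(np.abs(sig)) > 0

    def test_kappa_zero_phase_differences_uniform(self, rng):
        """With kappa=0 the per-event jitter is uniform, so the mean
        resultant of the seed-target phase differences matches the
        uniform-sample expectation sqrt(pi/2)/sqrt(n)."""
        n = 100
        reps = 50
        rs = []
        for _ in range(reps):
            log = []
            sig = np.zeros((2, 60_000))
            spec = CouplingSpec("s", "t", "tone", 18.0, (100.0, 300.0), 0.0, 10.0)
            inject_coupling(
                sig, 1000.0, self._events(n), spec, rng, ["s", "t"], phase_log=log
            )
            deltas = [e["deltas"]["t"] for e in log]
            rs.append(resultant_length(deltas))
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)  # E[R] for n uniform phases
        assert np.mean(rs) == pytest.approx(expected, abs=0.02)

    def test_zero_amplitude_leaves_signal_unchanged(self, rng):
        sig = np.zeros((2, 12_000))
        spec = CouplingSpec("s", "t", "tone", 18.0, (100.0, 300.0), 2.0, 0.0)
        inject_coupling(sig, 1000.0, self._events(), spec, rng, ["s", "t"])
        assert np.all(sig == 0.0)

    def test_grouped_specs_share_event_phase(self, rng):
        log = []
        sig = np.zeros((3, 12_000))
        specs = [
            CouplingSpec("s", "t1", "tone", 10.0, (0.0, 200.0), 1e7, 5.0),
            CouplingSpec("s", "t2", "tone", 10.0, (0.0, 200.0), 1e7, 5.0),
        ]
        inject_coupling(
            sig, 1000.0, self._events(5), specs, rng, ["s", "t1", "t2"], phase_log=log
        )
        assert np.array_equal(sig[1], sig[2])
        assert len(log) == 5 and set(log[0]["deltas"]) == {"t1", "t2"}

    def test_mixed_group_rejected(self, rng):
        specs = [
            CouplingSpec("s", "t1", "tone", 10.0, (0.0, 200.0), 2.0, 5.0),
            CouplingSpec("s", "t2", "omission", 10.0, (0.0, 200.0), 2.0, 5.0),
        ]
        with pytest.raises(ConfigError):
            inject_coupling(
                np.zeros((3, 12_000)), 1000.0, self._events(5), specs,
                rng, ["s", "t1", "t2"],
            )

    def test_window_outside_epoch_rejected(self):
        from ecogplv import SessionConfig

        with pytest.raises(ConfigError):
            SessionConfig(
                couplings=[
                    CouplingSpec("at08", "fp00", "tone", 10.0, (500.0, 700.0), 2.0, 5.0)
                ]
            )


class TestSimulateSession:
    def test_default_session_dimensions(self):
        bundle, events, truth = simulate_session(default_session_config(), 0)
        assert bundle.n_channels == 80
        assert len(events) == 1000
        assert bundle.n_samples >= 500_000
        assert bundle.fs == 1000.0
        groups = [c.connector_group for c in bundle.channels]
        assert groups == [i // 32 for i in range(80)]
        assert bundle.seed_channel_ids() == ["pt08", "at08"]

    def test_same_seed_reproduces_bundle(self):
        cfg = reduced_session_config(n_slots=30)
        b1, e1, _ = simulate_session(cfg, 42)
        b2, e2, _ = simulate_session(cfg, 42)
        assert np.array_equal(b1.signals, b2.signals)
        assert np.array_equal(e1.onsets_ms, e2.onsets_ms)

    def test_truth_record_replays_exactly(self):
        cfg = reduced_session_config(
            n_slots=30,
            couplings=[CouplingSpec("at00", "fp00", "both", 12.0, (0.0, 300.0), 3.0, 8.0)],
            templates=[ErpTemplateSpec("frontal_pole", "tone", [(90.0, 10.0, 20.0)])],
        )
        b1, _, truth = simulate_session(cfg, 7)
        b2, _, _ = truth.replay()
        assert np.array_equal(b1.signals, b2.signals)

    def test_truth_json_roundtrip(self, tmp_path):
        from ecogplv.simulate import SimulationTruth

        cfg = reduced_session_config(
            n_slots=20,
            couplings=[CouplingSpec("at00", "fp00", "both", 12.0, (0.0, 300.0), 3.0, 8.0)],
        )
        _, _, truth = simulate_session(cfg, 3)
        truth.to_json(tmp_path / "truth.json")
        truth2 = SimulationTruth.from_json(tmp_path / "truth.json")
        b1, _, _ = truth.replay()
        b2, _, _ = truth2.replay()
        assert np.array_equal(b1.signals, b2.signals)

    def test_signal_is_sum_of_its_parts(self):
        """Replaying the generator's draw sequence stage by stage, the
        session equals background + templates + couplings exactly."""
        cfg = reduced_session_config(
            n_slots=40,
            templates=[ErpTemplateSpec("frontal_pole", "tone", [(90.0, 10.0, 20.0)])],
            couplings=[CouplingSpec("at00", "fp00", "both", 12.0, (0.0, 300.0), 3.0, 8.0)],
        )
        bundle, events, _ = simulate_session(cfg, 11)

        rng = _session_rng(11, cfg.session_id)
        schedule = make_schedule(cfg.schedule, rng)
        ev = EventTable(schedule.onsets_ms + cfg.lead_pad_ms, schedule.kinds)
        n = bundle.n_samples
        chans = cfg.montage()
        noise = gen_background(len(chans), n, cfg.fs_hz, cfg.noise, rng)
        erp_part = np.zeros_like(noise)
        inject_erp(erp_part, cfg.fs_hz, ev, cfg.templates, [c.region for c in chans])
        coup_part = np.zeros_like(noise)
        for group in _group_couplings(cfg.couplings):
            inject_coupling(coup_part, cfg.fs_hz, ev, group, rng,
                            [c.channel_id for c in chans])
        total = (noise + erp_part + coup_part).astype(np.float32)
        assert np.array_equal(bundle.signals, total)
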