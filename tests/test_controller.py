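"""Level-of-automation decisions, schedules and session summaries."""

import numpy as np
import pytest

import vac
from vac.classifier import VigilanceTrace
from vac.controller import (LEVEL0, LEVEL2, build_schedule, decide_loa,
                            summarize_session)
from vac.errors import PreconditionError


def make_trace(states: np.ndarray, step: float = 0.125,
               artifact: np.ndarray | None = None) -> VigilanceTrace:
    """Trace whose V_SCORE is 1 for High epochs, 0 for Low."""
    n = len(states)
    t = np.arange(1, n + 1) * step
    v = states.astype(float)
    art = np.zeros(n, bool) if artifact is None else artifact
    return VigilanceTrace(t=t, y=v, v_score=v, state=states.astype(bool),
                          artifact=art, threshold=0.5)


def states_for(duration: float, low_after: float, step: float = 0.125):
    t = np.arange(1, int(duration / step) + 1) * step
    return (t < low_after), t


class TestDecideLoa:
    def test_mainly_low_lowers_automation(self):
        states = np.zeros(2400, dtype=bool)  # 300 s of epochs
        states[:480] = True  # 20% High
        assert decide_loa(make_trace(states), 300.0) == LEVEL0

    def test_mainly_high_restores_automation(self):
        states = np.ones(2400, dtype=bool)
        states[:480] = False
        assert decide_loa(make_trace(states), 300.0) == LEVEL2

    def test_exact_split_is_not_mainly_low(self):
        states = np.zeros(2400, dtype=bool)
        states[:1200] = True
        assert decide_loa(make_trace(states), 300.0) == LEVEL2

    def test_before_first_period_rejected(self):
        states = np.ones(2400, dtype=bool)
        with pytest.raises(PreconditionError):
            decide_loa(make_trace(states), 200.0, period=300.0)

    def test_empty_window_keeps_previous(self):
        states = np.ones(2400, dtype=bool)
        art = np.ones(2400, bool)
        tr = make_trace(states, artifact=art)
        assert decide_loa(tr, 300.0, prev_level=LEVEL0) == LEVEL0


class TestSchedule:
    def test_low_onset_triggers_at_next_boundary(self):
        # latent Low from minute 10 on: the 900 s decision sees a mainly-Low
        # window and lowers automation at the first boundary >= minute 15
        high, t = states_for(2700.0, low_after=600.0)
        sched = build_schedule(make_trace(high), period=300.0)
        assert sched.levels[:2] == [LEVEL2, LEVEL2]
        # decision at 600 s: window (300, 600] is High -> Level2
        assert sched.level_at(650.0) == LEVEL2
        # decision at 900 s: window (600, 900] fully Low -> Level0
        assert sched.level_at(900.0) == LEVEL0
        assert sched.decision_times[2] == 900.0

    def test_constant_high_never_switches(self):
        high, _ = states_for(2700.0, low_after=1e9)
        sched = build_schedule(make_trace(~(~high)), period=300.0)
        assert sched.switch_count() == 0
        assert all(l == LEVEL2 for l in sched.levels)

    def test_first_interval_is_level2(self):
        high, _ = states_for(900.0, low_after=0.0)
        # even an immediately-Low session starts at the nominal high level
        sched = build_schedule(make_trace(np.zeros_like(high, bool)), 300.0)
        assert sched.levels[0] == LEVEL2
        assert sched.level_at(10.0) == LEVEL2

    def test_monotone_response(self, rng):
        """Raising every y (hence state) in a window cannot flip L2 -> L0."""
        states = rng.random(2400) < 0.5
        base = decide_loa(make_trace(states), 300.0)
        raised = states.copy()
        raised[rng.integers(0, 2400, 200)] = True
        after = decide_loa(make_trace(raised), 300.0)
        assert not (base == LEVEL2 and after == LEVEL0)

    def test_non_adaptive_constant(self):
        high, _ = states_for(1800.0, low_after=100.0)
        sched = build_schedule(make_trace(high), 300.0, adaptive=False)
        assert all(l == LEVEL2 for l in sched.levels)
        assert sched.switch_count() == 0


class TestSummaries:
    def _log(self, states, artifact=None):
        tr = make_trace(states, artifact=artifact)
        sched = build_schedule(tr, 300.0)
        cfg = vac.PipelineConfig()
        return vac.SessionLog(trace=tr, schedule=sched, adaptive=True,
                              config=cfg)

    def test_all_high(self):
        states = np.ones(2400 * 3, dtype=bool)
        s = summarize_session(self._log(states))
        assert s.low_fraction == 0.0
        assert s.relative_change == 0.0
        assert s.loa_switches == 0

    def test_epoch_level_low_fraction(self):
        states = np.ones(2400, dtype=bool)
        states[:960] = False  # 40% Low
        s = summarize_session(self._log(states))
        assert s.low_fraction == pytest.approx(0.4)

    def test_window_means_on_controller_grid(self):
        high, _ = states_for(900.0, low_after=450.0)
        s = summarize_session(self._log(high))
        assert len(s.window_means) == 3
        assert s.window_means[0] == pytest.approx(1.0)
        assert s.window_means[2] == pytest.approx(0.0)
        assert s.first_window_mean == s.window_means[0]
        assert s.relative_change == pytest.approx(1.0)  # full decline

    def test_artifacts_excluded(self):
        states = np.ones(2400, dtype=bool)
        art = np.zeros(2400, bool)
        art[:1200] = True
        states[:1200] = False  # Low but all artifactual
        s = summarize_session(self._log(states, artifact=art))
        assert s.low_fraction == 0.0


@pytest.fixture(scope="module")
def trained():
    timeline = vac.LatentTimeline.calibration(420.0)
    spec = vac.EEGGenSpec(seed=31, artifact_rate_per_min=1.0)
    rec, _ = vac.simulate_eeg_session(spec, timeline, 420.0)
    ec = vac.simulate_eyes_closed(spec.iaf, 60.0, seed=32)
    bands = vac.estimate_iaf(ec)
    epochs = vac.drop_artifacts(vac.preprocess(rec))
    psd = vac.compute_psd(epochs)
    feats, imap = vac.extract_features(psd, bands)
    calib = vac.CalibrationSet.from_protocol(
        feats, epochs.starts, rec.duration, index_map=imap,
        high_window=180.0, low_window=180.0)
    return vac.train_asswlda(calib, bands=bands)


@pytest.fixture(scope="module")
def session():
    timeline = vac.LatentTimeline.from_segments(
        [(0.0, "High"), (180.0, "Low")], 360.0)
    spec = vac.EEGGenSpec(seed=33, artifact_rate_per_min=1.0)
    rec, gt = vac.simulate_eeg_session(spec, timeline, 360.0)
    return rec, gt


class TestRunSession:
    def test_adaptive_flag_does_not_change_trace(self, trained, session):
        rec, _ = session
        cfg = vac.PipelineConfig()
        cfg.controller.period_s = 120.0
        log_a = vac.run_session(rec, trained, cfg, adaptive=True)
        log_b = vac.run_session(rec, trained, cfg, adaptive=False)
        assert np.array_equal(log_a.trace.v_score, log_b.trace.v_score)
        assert all(l == LEVEL2 for l in log_b.schedule.levels)
        assert log_a.schedule.levels != log_b.schedule.levels  # Low onset acts

    def test_determinism(self, trained, session):
        rec, _ = session
        log1 = vac.run_session(rec, trained, adaptive=False)
        log2 = vac.run_session(rec, trained, adaptive=False)
        assert np.array_equal(log1.trace.y, log2.trace.y)
        assert np.array_equal(log1.trace.v_score, log2.trace.v_score)

    def test_causality(self, trained, session):
        """Truncating the future does not change the past of the trace."""
        rec, _ = session
        cut = vac.EEGRecording(rec.channel_names,
                               rec.data[:, :int(300 * rec.fs)], rec.fs)
        full = vac.run_session(rec, trained, adaptive=False).trace
        part = vac.run_session(cut, trained, adaptive=False).trace
        # epochs whose window reaches within a few seconds of the cut may
        # see a clipped blink interval; everything earlier must be identical
        margin_s = 5.0
        keep = part.t + 2.0 < 300.0 - margin_s
        assert np.allclose(full.y[:len(part.t)][keep], part.y[keep], atol=1e-6)
        assert np.allclose(full.v_score[:len(part.t)][keep],
                           part.v_score[keep], atol=1e-6)

    def test_too_short_for_adaptive(self, trained):
        rec = vac.simulate_eyes_closed(10.0, 60.0, seed=34)
        with pytest.raises(PreconditionError):
            vac.run_session(rec, trained, adaptive=True)
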