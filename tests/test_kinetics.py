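import numpy as np
import pytest

import ribofret as rf
from ribofret.errors import EmptyDatasetError, FitError, ValidationError
from ribofret.idealize import IdealizedPath, dwell_segments
from ribofret.kinetics import (
    _arrival_model,
    classify_events,
    cumulative_arrival,
    estimate_bleach_rate,
    fit_arrival,
    kcat_km,
)


def make_path(states, tid="t"):
    states = np.asarray(states, dtype=int)
    model = rf.builtin_model("selection4")
    return IdealizedPath(
        trace_id=tid,
        states=states,
        fret=model.means[states],
        dwells=dwell_segments(states),
        log_likelihood=0.0,
    )


class TestClassification:
    def test_stepwise_progression_is_productive(self):
        path = make_path([0, 0, 1, 1, 2, 3, 3, 3, 3])
        model = rf.builtin_model("selection4")
        (c,) = classify_events({"t": path}, model)
        assert c.event_class == "productive"
        assert c.arrival_frame == 5

    def test_excursion_returning_to_zero_is_non_productive(self):
        path = make_path([0, 1, 2, 1, 0, 0])
        model = rf.builtin_model("selection4")
        (c,) = classify_events({"t": path}, model)
        assert c.event_class == "non-productive"

    def test_flat_zero_trace_is_no_event(self):
        (c,) = classify_events({"t": make_path([0] * 8)}, rf.builtin_model("selection4"))
        assert c.event_class == "no-event"

    def test_single_frame_spike_is_not_stable_accommodation(self):
        path = make_path([0, 1, 3, 1, 0, 0])
        (c,) = classify_events({"t": path}, rf.builtin_model("selection4"))
        assert c.event_class == "non-productive"

    def test_wrong_model_variant_rejected(self):
        with pytest.raises(ValidationError):
            classify_events({}, rf.builtin_model("pretrans3"))

    def test_simulated_arrivals_recovered_within_two_frames(self, small_selection):
        import pandas as pd

        ts, gt = small_selection
        analysis = rf.analyze_selection(ts, seed=0, n_boot=0)
        truth = gt.set_index("trace_id")["arrival_frame"]
        errs = []
        for c in analysis.classifications:
            if c.event_class == "productive" and pd.notna(truth.get(c.trace_id)):
                errs.append(abs(c.arrival_frame - int(truth[c.trace_id])))
        assert len(errs) > 10
        assert np.median(errs) <= 2
        assert np.mean(np.array(errs) <= 2) > 0.9


class TestCumulativeArrival:
    def test_hand_enumerated_curve(self):
        cls = [
            rf.EventClassification("a", "productive", arrival_frame=2),
            rf.EventClassification("b", "productive", arrival_frame=2),
            rf.EventClassification("c", "productive", arrival_frame=5),
            rf.EventClassification("d", "no-event"),
        ]
        curve, _ = cumulative_arrival(cls, n_frames=6, n_total=4)
        np.testing.assert_allclose(curve, [0, 0, 0.5, 0.5, 0.5, 0.75])

    def test_no_productive_traces_gives_zero_curve(self):
        curve, _ = cumulative_arrival(
            [rf.EventClassification("a", "no-event")], n_frames=4, n_total=3
        )
        np.testing.assert_array_equal(curve, 0.0)

    def test_all_arrive_at_zero_gives_constant_one(self):
        cls = [rf.EventClassification(str(i), "productive", arrival_frame=0) for i in range(5)]
        curve, _ = cumulative_arrival(cls, n_frames=4, n_total=5)
        np.testing.assert_array_equal(curve, 1.0)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        cls = [
            rf.EventClassification(str(i), "productive", arrival_frame=int(f))
            for i, f in enumerate(rng.integers(0, 200, size=57))
        ]
        curve, sem = cumulative_arrival(cls, 200, n_total=80, n_boot=50, seed=1)
        assert np.all(np.diff(curve) >= 0)
        assert curve.max() <= 1.0
        assert sem.shape == curve.shape and np.all(sem >= 0)

    def test_zero_traces_rejected(self):
        with pytest.raises(EmptyDatasetError):
            cumulative_arrival([], 10, n_total=0)


class TestArrivalFit:
    def test_recovers_closed_form_curve(self):
        """Exact double-exponential curve on the 15 ms grid is recovered."""
        t = np.arange(3000) * 0.015
        y = _arrival_model(t, 0.8, 0.6, 0.1, 0.05, 0.25)
        f = fit_arrival(t, y)
        assert f.A1 == pytest.approx(0.8, rel=1e-3)
        assert f.k1 == pytest.approx(0.6, rel=1e-3)
        assert f.A2 == pytest.approx(0.1, rel=1e-3)
        assert f.k2 == pytest.approx(0.05, rel=1e-3)
        assert f.t0 == pytest.approx(0.25, rel=1e-3)

    def test_single_exponential_yields_negligible_slow_amplitude(self):
        t = np.arange(3000) * 0.015
        y = _arrival_model(t, 0.8, 0.6, 0.0, 0.05, 0.25)
        f = fit_arrival(t, y)
        assert f.A2 < 0.02
        assert f.k1 == pytest.approx(0.6, rel=1e-3)

    def test_fixed_slow_rate_variant(self):
        t = np.arange(3000) * 0.015
        y = _arrival_model(t, 0.75, 0.6, 0.033, 0.15, 0.25)
        f = fit_arrival(t, y, slow_rate=0.15)
        assert f.k2 == 0.15
        assert f.k1 == pytest.approx(0.6, rel=0.02)
        assert f.fast_amplitude_fraction == pytest.approx(0.75 / 0.783, abs=0.02)

    def test_zero_curve_is_an_error(self):
        t = np.arange(100) * 0.015
        with pytest.raises(FitError):
            fit_arrival(t, np.zeros(100))

    def test_ordering_invariant(self):
        t = np.arange(3000) * 0.015
        y = _arrival_model(t, 0.7, 0.8, 0.2, 0.08, 0.1)
        f = fit_arrival(t, y)
        assert f.k1 > f.k2 >= 0
        assert f.A1 >= 0 and f.A2 >= 0 and f.A1 + f.A2 <= 1 + 1e-6


class TestBleachRate:
    def test_identical_times_give_inverse_mean(self):
        times = np.full(50, 8.0)
        assert estimate_bleach_rate(times) == pytest.approx(1 / 8.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 200)
        assert estimate_bleach_rate(2 * times) == pytest.approx(
            estimate_bleach_rate(times) / 2
        )

    def test_censoring_removes_conditioning_bias(self):
        rng = np.random.default_rng(3)
        true_rate, t_end = 0.1, 45.0
        all_times = rng.exponential(1 / true_rate, 400)
        events = all_times[all_times < t_end]
        censored = np.full((all_times >= t_end).sum(), t_end)
        est = estimate_bleach_rate(events, censored)
        assert est == pytest.approx(true_rate, rel=0.1)

    def test_simulated_dataset_rate_recovered(self, small_selection):
        ts, gt = small_selection
        dt = ts.meta.frame_interval_s
        events = (gt["bleach_frame"].dropna().astype(int).to_numpy() + 0.5) * dt
        n_frames = ts.frames.groupby("trace_id")["frame"].size().max()
        censored = np.full(gt["bleach_frame"].isna().sum(), n_frames * dt)
        est = estimate_bleach_rate(events, censored)
        assert est == pytest.approx(0.1, rel=0.25)  # 60 traces: wide but unbiased

    def test_no_events_rejected(self):
        with pytest.raises(EmptyDatasetError):
            estimate_bleach_rate(np.array([]))


class TestKcatKm:
    def test_arithmetic(self):
        assert kcat_km(0.6, 0.1, 0.01) == pytest.approx(50.0)

    def test_no_bleach_limit(self):
        assert kcat_km(0.6, 0.0, 0.01) == pytest.approx(60.0)

    def test_rate_below_bleach_rejected(self):
        with pytest.raises(ValidationError):
            kcat_km(0.05, 0.1, 0.01)
        with pytest.raises(ValidationError):
            kcat_km(0.6, 0.1, 0.0)
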