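import numpy as np
import pytest
from scipy import stats

import ribofret as rf
from ribofret.errors import ValidationError
from ribofret.schemes import PhotophysicsParams


class TestStatePathSampling:
    def test_zero_rates_give_constant_path(self):
        s = rf.KineticScheme(
            state_names=("a", "b"),
            fret_mean=[0.2, 0.7],
            fret_sd=[0.05, 0.05],
            rate_matrix=np.zeros((2, 2)),
            initial_distribution=[0.0, 1.0],
        )
        path = rf.sample_state_path(s, duration=3.0, dt=0.015, seed=0)
        assert np.all(path == 1)

    def test_symmetric_two_state_occupancy_is_half(self, two_state_scheme):
        rng = np.random.default_rng(1)
        frac = np.mean(
            [
                rf.sample_state_path(two_state_scheme, 15.0, 0.015, rng=rng).mean()
                for _ in range(60)
            ]
        )
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_three_state_occupancy_matches_analytic_stationary(self):
        """Long-run state occupancy equals the solution of pi Q = 0."""
        target = np.array([0.20, 0.40, 0.40])
        s = rf.exchange_scheme(
            ("x", "y", "z"), [0.22, 0.42, 0.72], [0.075] * 3, target, exchange_rate=2.0
        )
        np.testing.assert_allclose(s.stationary_distribution(), target, atol=1e-10)
        rng = np.random.default_rng(2)
        counts = np.zeros(3)
        for _ in range(500):
            path = rf.sample_state_path(s, 15.0, 0.015, rng=rng)
            counts += np.bincount(path, minlength=3)
        np.testing.assert_allclose(counts / counts.sum(), target, atol=0.02)

    def test_absorbing_state_is_never_left(self):
        s = rf.KineticScheme(
            state_names=("live", "dead"),
            fret_mean=[0.5, 0.0],
            fret_sd=[0.05, 0.05],
            rate_matrix=np.array([[0.0, 5.0], [0.0, 0.0]]),
            initial_distribution=[1.0, 0.0],
            absorbing_states=("dead",),
        )
        path = rf.sample_state_path(s, 10.0, 0.015, seed=3)
        entered = np.flatnonzero(path == 1)
        assert entered.size and np.all(path[entered[0] :] == 1)

    def test_invalid_grid_rejected(self, two_state_scheme):
        with pytest.raises(ValidationError):
            rf.sample_state_path(two_state_scheme, 1.0, 0.0, seed=0)
        with pytest.raises(ValidationError):
            rf.sample_state_path(two_state_scheme, 0.001, 0.015, seed=0)


class TestRenderTrace:
    def test_noiseless_limit_reproduces_state_means(self, two_state_scheme):
        import dataclasses

        quiet = PhotophysicsParams(
            channel_noise_sd=0.0, donor_bleach_rate=0.0, blink_rate=0.0
        )
        sharp = dataclasses.replace(
            two_state_scheme, fret_sd=np.array([1e-9, 1e-9])
        )
        path = rf.sample_state_path(sharp, 3.0, 0.015, seed=4)
        tr = rf.render_trace(path, sharp, quiet, seed=4)
        E = (tr.acceptor - quiet.background_level) / (
            tr.donor + tr.acceptor - 2 * quiet.background_level
        )
        np.testing.assert_allclose(E, sharp.fret_mean[path], atol=1e-6)

    def test_bleach_fraction_follows_exponential_law(self, two_state_scheme):
        pp = PhotophysicsParams(donor_bleach_rate=0.2, blink_rate=0.0)
        rng = np.random.default_rng(5)
        path = np.zeros(400, dtype=int)  # 6 s
        n = 400
        bleached_by_3s = 0
        for _ in range(n):
            tr = rf.render_trace(path, two_state_scheme, pp, rng=rng)
            if tr.bleach_frame is not None and tr.bleach_frame * 0.015 < 3.0:
                bleached_by_3s += 1
        expected = 1 - np.exp(-0.2 * 3.0)
        sem = np.sqrt(expected * (1 - expected) / n)
        assert bleached_by_3s / n == pytest.approx(expected, abs=4 * sem)

    def test_heavy_bleaching_hits_early_frames(self, two_state_scheme):
        pp = PhotophysicsParams(donor_bleach_rate=20.0, blink_rate=0.0)
        rng = np.random.default_rng(6)
        frames = [
            rf.render_trace(np.zeros(100, int), two_state_scheme, pp, rng=rng).bleach_frame
            for _ in range(50)
        ]
        assert all(f is not None and f < 20 for f in frames)


class TestDatasets:
    def test_determinism_same_seed_same_tables(self, tmp_path):
        a, gta = rf.simulate_dataset("ctrl-phe", 5, seed=9)
        b, gtb = rf.simulate_dataset("ctrl-phe", 5, seed=9)
        pa = rf.write_traces(a, tmp_path / "a.tsv")
        pb = rf.write_traces(b, tmp_path / "b.tsv")
        assert pa.read_bytes() == pb.read_bytes()
        assert gta.equals(gtb)

    def test_selection_preset_encodes_lambda_from_kcat_km(self):
        for name, kcat in [("ctrl-phe", 50.0), ("sg24-phe", 71.0),
                           ("ctrl-lys", 27.0), ("sg24-lys", 36.0)]:
            p = rf.get_preset(name)
            assert p.ground_truth["lambda_prod"] == pytest.approx(
                kcat * p.ternary_concentration_uM
            )

    def test_pretrans_presets_encode_printed_classical_fractions(self):
        low = rf.get_preset("pretrans-low").ground_truth
        high = rf.get_preset("pretrans-high").ground_truth
        assert low["classical_occupancy"] == pytest.approx(0.15)
        assert high["classical_occupancy"] == pytest.approx(0.20)
        for gt in (low, high):
            assert (
                gt["classical_occupancy"] + gt["hybrid1_occupancy"] + gt["hybrid2_occupancy"]
            ) == pytest.approx(1.0)

    def test_unknown_preset(self):
        with pytest.raises(ValidationError):
            rf.simulate_dataset("nope", 3, seed=0)

    def test_productive_arrival_times_are_two_phase_exponential(self):
        """KS test of fast-phase arrival times against Exp(lambda_prod)."""
        preset = rf.get_preset("ctrl-phe")
        ts, gt = rf.simulate_dataset(preset, 2500, seed=12)
        lam = preset.ground_truth["lambda_prod"]
        kb = preset.photophysics.donor_bleach_rate
        g = gt[(gt["phase"] == "fast") & gt["arrival_frame"].notna()]
        x = g["arrival_frame"].astype(int).to_numpy() * 0.015 - preset.photophysics.dead_time
        x = x[x > 0]
        assert len(x) > 1000
        # observed fast-phase arrivals compete with bleach: rate lam + kb,
        # truncated at the movie end
        t_end = preset.n_frames * 0.015 - preset.photophysics.dead_time
        rate = lam + kb
        cdf = lambda v: (1 - np.exp(-rate * v)) / (1 - np.exp(-rate * t_end))
        stat = stats.kstest(x, cdf)
        assert stat.pvalue > 0.01

    def test_mean_snr_exceeds_acceptance_gate_by_construction(self, small_selection):
        ts, _ = small_selection
        pp = rf.get_preset("ctrl-phe").photophysics
        totals = []
        for _, sub in ts.iter_traces():
            tot = sub["donor"].to_numpy() + sub["acceptor"].to_numpy()
            totals.append(tot[:20].mean())  # early frames are pre-bleach
        mean_signal = np.mean(totals) - 2 * pp.background_level
        assert mean_signal / (np.sqrt(2) * pp.background_noise_sd) > 8.0
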