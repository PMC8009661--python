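"""Onset detection, lags, rates, fractions, group statistics, cohorts."""

import itertools

import numpy as np
import pytest

from na_dynamics import events as ev, synthetic as syn, tracking


def _bg(n, sd=1.0, seed=0):
    return np.random.default_rng(seed).normal(0, sd, n)


class TestDetectOnset:
    def test_flat_series_none(self):
        assert ev.detect_onset(_bg(50, seed=1), _bg(50, seed=2), 2.0) is None

    def test_step_detected_at_step_frame(self):
        sig = np.zeros(100)
        sig[50:] = 10.0  # 10 background sd
        t = ev.detect_onset(sig + _bg(100, seed=3), _bg(100, seed=4), 2.0)
        assert t == pytest.approx(100.0, abs=2.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ev.detect_onset(np.zeros(5), np.zeros(5), 2.0)

    def test_zero_background_sd_warns(self):
        sig = np.zeros(40)
        sig[20:] = 5.0
        with pytest.warns(UserWarning, match="zero background"):
            ev.detect_onset(sig, np.zeros(40), 2.0)

    @pytest.mark.parametrize("snr", [5.0, 10.0])
    def test_ramp_onset_median_error(self, snr):
        """Planted ramps with onset at 30 s: median onset error <= 1 frame
        at SNR >= 5; error shrinks with SNR."""
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(500):
            t = np.arange(100) * 2.0
            sig = np.clip((t - 30.0) * snr / 10.0, 0, snr)  # peak snr sd in 10 s
            noise = rng.normal(0, 1.0, 100)
            bg = rng.normal(0, 1.0, 100)
            onset = ev.detect_onset(sig + noise, bg, 2.0)
            if onset is not None:
                errs.append(onset - 30.0)
        assert abs(np.median(errs)) <= 2.0

    def test_error_decreases_with_snr(self):
        rng = np.random.default_rng(12)
        med = {}
        for snr in (3.0, 5.0, 10.0):
            errs = []
            for _ in range(300):
                t = np.arange(100) * 2.0
                sig = np.clip((t - 30.0) * snr / 10.0, 0, snr)
                onset = ev.detect_onset(sig + rng.normal(0, 1, 100),
                                        rng.normal(0, 1, 100), 2.0)
                if onset is not None:
                    errs.append(abs(onset - 30.0))
            med[snr] = np.median(errs)
        assert med[10.0] <= med[5.0] <= med[3.0]


class TestLags:
    def test_identical_onsets_zero_lag(self):
        # clean steps with identical onsets in both channels
        sig = np.zeros(60)
        sig[30:] = 20.0
        rng = np.random.default_rng(5)
        ann = ev.annotate_events(sig, rng.normal(0, 1, 60),
                                 sig, rng.normal(0, 1, 60), 2.0)
        assert ann.lag_s == 0.0

    @pytest.mark.parametrize("cls,protein,expected", [
        ("G1", "talin", -18.0),
        ("G1", "vinculin", -8.0),
        ("G1", "paxillin", -4.0),
        ("G2", "vinculin", -4.0),
    ])
    def test_preset_lag_recovery(self, cls, protein, expected):
        """Median recovered FII−FTI lag within one 2-s frame of the planted
        lead, 200 traces per preset at SNR 5."""
        traces = syn.simulate_event_traces(cls, protein, 200, snr=5.0,
                                           seed=7)
        anns = [ev.annotate_events(t.intensity, t.intensity_background,
                                   t.traction, t.traction_background,
                                   t.frame_interval_s) for t in traces]
        lags = [a.lag_s for a in anns if a.lag_s is not None]
        assert len(lags) >= 150
        assert np.median(lags) == pytest.approx(expected, abs=2.0)

    def test_lag_distribution_summary(self):
        traces = {g: syn.simulate_event_traces(g, "vinculin", 40, seed=1)
                  for g in ("G1", "G2")}
        anns = {g: [ev.annotate_events(t.intensity, t.intensity_background,
                                       t.traction, t.traction_background,
                                       t.frame_interval_s) for t in tr]
                for g, tr in traces.items()}
        samples, comps = ev.lag_distribution(anns)
        assert set(samples.group) == {"G1", "G2"}
        assert len(comps) == 1
        assert comps.iloc[0].p < 0.05  # -8 vs -4 s distributions differ


class TestRates:
    def test_linear_ramp_exact(self):
        amp = 2.0 * np.arange(20) * 2.0  # 2 AU/s at 2 s/frame
        rate, truncated = ev.assembly_rate(amp, 2.0, 10.0)
        assert rate == pytest.approx(2.0)
        assert not truncated

    def test_constant_zero(self):
        rate, _ = ev.assembly_rate(np.full(20, 5.0), 2.0, 10.0)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_window_truncation_flagged(self):
        rate, truncated = ev.assembly_rate(np.arange(3) * 2.0, 2.0, 10.0)
        assert truncated

    def test_traction_ramp(self):
        tr = 1.0 * np.arange(100) * 2.0  # 1 Pa/s
        rate, _ = ev.traction_growth_rate(tr, 2.0, 120.0)
        assert rate == pytest.approx(1.0)

    def test_g2_over_g1_vinculin_ratio(self, config, edge):
        """Detection-aligned assembly rates: maturing/non-maturing vinculin
        median ratio ~ 5."""
        truth = syn.plant_tracks({"G1": 150, "G2": 150}, edge, config,
                                 seed=21, n_frames=600, protein="vinculin",
                                 bead_density_per_um2=0.2)
        tracks = syn.tracks_from_truth(truth, config, snr=5.0, seed=22)
        g1 = [ev.assembly_rate(t.amplitude, 2.0, 10.0)[0]
              for t in tracks if t.label == "G1"]
        g2 = [ev.assembly_rate(t.amplitude, 2.0, 10.0)[0]
              for t in tracks if t.label == "G2"]
        ratio = np.median(g2) / np.median(g1)
        assert ratio == pytest.approx(5.0, abs=0.75)

    def test_g3_traction_below_noise_floor(self, config):
        """Trackable but force-free adhesions: traction growth stays at the
        noise level and FTI detection is rare."""
        traces = syn.simulate_event_traces("G3", "vinculin", 100, snr=5.0,
                                           seed=9)
        n_fti = 0
        for t in traces:
            # G3 plants zero traction; series is pure noise
            assert np.abs(t.traction).max() < 200.0
            ann = ev.annotate_events(t.intensity, t.intensity_background,
                                     t.traction, t.traction_background,
                                     t.frame_interval_s)
            n_fti += ann.has_traction_increase
        assert n_fti / len(traces) <= 0.1


class TestFractions:
    def test_all_planted_fti(self):
        anns = {"g": [ev.EventAnnotation(0.0, 5.0)] * 10}
        assert ev.traction_increase_fraction(anns)["g"] == 1.0

    def test_mixed_fraction(self):
        anns = {"g": [ev.EventAnnotation(0.0, 5.0)] * 3
                + [ev.EventAnnotation(0.0, None)] * 7}
        assert ev.traction_increase_fraction(anns)["g"] == pytest.approx(0.3)

    def test_empty_group_warns_nan(self):
        with pytest.warns(UserWarning, match="empty"):
            out = ev.traction_increase_fraction({"g": []})
        assert np.isnan(out["g"])

    def test_g2_matures_to_fc(self, planted_tracks):
        g2 = [t for t in planted_tracks if t.label == "G2"]
        frac = ev.maturation_fractions(g2)
        assert frac["na_to_fc_pct"] == pytest.approx(100.0)
        assert 10.0 <= frac["na_to_fa_pct"] <= 60.0  # ~32% planted


def _bruteforce_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumeration of all arrangements."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    def ustat(idx):
        aa = pooled[list(idx)]
        bb = np.delete(pooled, list(idx))
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
    u_obs = ustat(range(n1))
    us = [ustat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    us = np.array(us)
    n = len(us)
    p = 2 * min((us <= u_obs).sum() / n, (us >= u_obs).sum() / n)
    return min(p, 1.0)


class TestGroupStats:
    def test_mw_example_enumeration(self):
        u, p = ev.compare_groups([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(4))
    def test_mw_matches_bruteforce_small_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(2, 6))
        b = rng.normal(0.5, 1, rng.integers(2, 6))
        _, p = ev.compare_groups(a, b)
        assert p == pytest.approx(_bruteforce_mw_p(a, b), abs=1e-10)

    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = ev.compare_groups([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_large_shift_extreme_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 5000)
        b = rng.normal(3, 1, 5000)
        _, p = ev.compare_groups(a, b)
        assert p < 1e-30

    def test_normality_pvalues(self):
        rng = np.random.default_rng(1)
        assert ev.normality_test(rng.normal(0, 1, 500)) > 0.01
        assert ev.normality_test(rng.exponential(1, 500)) < 1e-6


class TestCohorts:
    def _track(self, amp, tid=0):
        n = len(amp)
        return tracking.AdhesionTrack(tid, 0, np.zeros(n), np.zeros(n),
                                      np.asarray(amp, float))

    def test_identical_tracks_mean_equals_track(self):
        amp = np.array([1.0, 3.0, 2.0, 0.5])
        cohorts = ev.cohort_average([self._track(amp, 0),
                                     self._track(amp, 1)],
                                    [0, 100], 2.0)
        (key, c), = cohorts.items()
        assert np.allclose(c["mean"], amp)
        assert np.allclose(c["sd"], 0.0)

    def test_offset_tracks_midline(self):
        a = np.array([1.0, 2.0, 3.0])
        cohorts = ev.cohort_average([self._track(a, 0),
                                     self._track(a + 4, 1)], [0, 100], 2.0)
        (key, c), = cohorts.items()
        assert np.allclose(c["mean"], a + 2)

    def test_empty_bin_omitted(self):
        cohorts = ev.cohort_average([self._track(np.ones(5))],
                                    [0, 4, 1000], 2.0)
        assert list(cohorts) == [(4.0, 1000.0)]

    def test_g1_cohort_rise_then_fall(self, config, edge):
        truth = syn.plant_tracks({"G1": 60}, edge, config, seed=31,
                                 n_frames=600, bead_density_per_um2=0.2)
        tracks = syn.tracks_from_truth(truth, config, snr=10.0, seed=32)
        cohorts = ev.cohort_average(tracks, [240, 420], 2.0)
        (key, c), = cohorts.items()
        m = c["mean"][~np.isnan(c["mean"])]
        peak = np.nanargmax(c["mean"])
        assert 0 < peak < len(m) - 1  # peak strictly inside the lifetime
        assert m[-1] < m[peak]
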