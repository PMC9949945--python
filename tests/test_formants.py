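import numpy as np
import pytest
from scipy import signal
from scipy.signal.windows import hamming

from snorevol import formants as F
from snorevol import synthetic
from tests.conftest import as_clip, preprocessed_minute

RATE = 5000.0


def ar_process(rng, poles, n):
    """Drive an all-pole filter with white noise; poles given as (freq, radius)."""
    a = np.array([1.0])
    for f, r in poles:
        theta = 2 * np.pi * f / RATE
        a = np.convolve(a, [1.0, -2 * r * np.cos(theta), r * r])
    return signal.lfilter([1.0], a, rng.standard_normal(n)), a


class TestLevinsonDurbin:
    def test_recovers_ar2_coefficients(self):
        rng = np.random.default_rng(0)
        theta = 2 * np.pi * 500 / RATE
        r = 0.95
        true_a = np.array([1.0, -2 * r * np.cos(theta), r * r])
        x = signal.lfilter([1.0], true_a, rng.standard_normal(200_000))
        rr = F.autocorrelation(x, 2)
        a, _ = F.levinson_durbin(rr, 2)
        np.testing.assert_allclose(a[1:], true_a[1:], rtol=0.05)

    def test_white_noise_coefficients_small(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(4096)
            a = F.lpc_coefficients(x, 14)
            assert np.all(np.abs(a[1:]) < 0.2)

    def test_matches_direct_yule_walker_solve(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.standard_normal(256)
            order = 8
            r = F.autocorrelation(x, order)
            a, _ = F.levinson_durbin(r, order)
            # independent oracle: solve the Toeplitz system directly
            from scipy.linalg import toeplitz

            R = toeplitz(r[:order])
            coeffs = np.linalg.solve(R, -r[1 : order + 1])
            np.testing.assert_allclose(a[1:], coeffs, atol=1e-8)

    def test_error_nonincreasing_with_order(self):
        rng = np.random.default_rng(2)
        x, _ = ar_process(rng, [(400.0, 0.95)], 4096)
        r = F.autocorrelation(x, 14)
        errs = [F.levinson_durbin(r, p)[1] for p in range(1, 15)]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_zero_energy_frame_flagged(self):
        assert F.lpc_coefficients(np.zeros(100), 14) is None

    def test_short_frame_rejected(self):
        with pytest.raises(ValueError):
            F.lpc_coefficients(np.zeros(10), 14)


class TestFormantsFromLpc:
    def test_single_resonator_400(self):
        rng = np.random.default_rng(3)
        x, _ = ar_process(rng, [(400.0, 0.97)], 8192)
        a = F.lpc_coefficients(x * hamming(len(x), sym=False), 4)
        f1, _, _ = F.formants_from_lpc(a, RATE)
        assert f1 == pytest.approx(400.0, abs=30.0)

    def test_two_resonators(self):
        rng = np.random.default_rng(4)
        x, _ = ar_process(rng, [(400.0, 0.97), (1200.0, 0.97)], 8192)
        a = F.lpc_coefficients(x * hamming(len(x), sym=False), 6)
        f1, f2, _ = F.formants_from_lpc(a, RATE)
        assert f1 == pytest.approx(400.0, abs=30.0)
        assert f2 == pytest.approx(1200.0, abs=30.0)

    def test_real_roots_give_no_formants(self):
        # (1 - 0.5 z^-1)(1 - 0.2 z^-1): both roots real
        a = np.convolve([1.0, -0.5], [1.0, -0.2])
        assert F.formants_from_lpc(a, RATE) == (None, None, None)

    def test_recovery_over_100_seeded_trials(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x, _ = ar_process(rng, [(600.0, 0.97)], 4096)
            a = F.lpc_coefficients(x * hamming(len(x), sym=False), 4)
            f1, _, _ = F.formants_from_lpc(a, RATE)
            if f1 is not None and abs(f1 - 600.0) <= 30.0:
                hits += 1
        assert hits == 100


class TestDetectSnoreEpisodes:
    def test_burst_count_and_onsets(self):
        rng = np.random.default_rng(5)
        n = int(60 * RATE)
        x = 2e-3 * rng.standard_normal(n)
        onsets = np.arange(10) * 5.5 + 1.0
        for t in onsets:
            lo = int(t * RATE)
            burst = synthetic._snore_burst(rng, RATE, 500.0)
            x[lo : lo + len(burst)] += burst
        eps = F.detect_snore_episodes(as_clip(x))
        assert len(eps) == 10
        for e, t in zip(eps, onsets):
            assert e.onset_s == pytest.approx(t, abs=0.2)

    def test_silent_clip_empty(self):
        eps = F.detect_snore_episodes(as_clip(np.zeros(int(60 * RATE))))
        assert eps == []

    def test_continuous_tone_single_episode(self):
        t = np.arange(int(60 * RATE)) / RATE
        x = np.sin(2 * np.pi * 400 * t)
        eps = F.detect_snore_episodes(as_clip(x))
        assert len(eps) == 1
        assert eps[0].onset_s == pytest.approx(0.0, abs=0.3)
        assert eps[0].offset_s == pytest.approx(60.0, abs=0.3)

    def test_episode_f1_tracks_resonator(self, simple_snore_clip):
        eps = F.detect_snore_episodes(simple_snore_clip)
        f1s = [e.f1_hz for e in eps if e.f1_hz is not None]
        assert len(f1s) >= 10
        assert np.median(f1s) == pytest.approx(400.0, abs=30.0)


class TestSnoreFeatures:
    def test_constant_episodes_zero_features(self):
        eps = [
            F.SnoreEpisode(onset_s=o, offset_s=o + 1, f1_hz=400.0)
            for o in (0.0, 4.0, 8.0)
        ]
        sf = F.snore_features(eps)
        assert (sf.std_f1_hz, sf.std_f1_interval_s) == (0.0, 0.0)
        assert not sf.low_evidence

    def test_two_episodes_low_evidence(self):
        eps = [
            F.SnoreEpisode(onset_s=0.0, offset_s=1.0, f1_hz=400.0),
            F.SnoreEpisode(onset_s=4.0, offset_s=5.0, f1_hz=500.0),
        ]
        sf = F.snore_features(eps)
        assert (sf.std_f1_hz, sf.std_f1_interval_s) == (0.0, 0.0)
        assert sf.low_evidence

    def test_interval_std_population(self):
        eps = [
            F.SnoreEpisode(onset_s=o, offset_s=o + 1, f1_hz=450.0)
            for o in (0.0, 4.0, 12.0)
        ]
        sf = F.snore_features(eps)
        # population std of intervals {4, 8} = 2.0
        assert sf.std_f1_interval_s == pytest.approx(2.0, abs=1e-12)
        assert sf.std_f1_hz == 0.0


class TestClassifySnoreType:
    def _blob_features(self, rng, n, f1_std, int_std):
        return [
            F.SnoreFeatures(
                std_f1_hz=max(0.0, f1_std + 5.0 * rng.standard_normal()),
                std_f1_interval_s=max(0.0, int_std + 0.05 * rng.standard_normal()),
            )
            for _ in range(n)
        ]

    def test_two_blobs_separated(self):
        rng = np.random.default_rng(6)
        simple = self._blob_features(rng, 20, 20.0, 0.3)
        apneic = self._blob_features(rng, 20, 120.0, 4.0)
        labels = F.classify_snore_type(simple + apneic)
        assert labels[:20] == ["simple"] * 20
        assert labels[20:] == ["apneic"] * 20

    def test_identical_features_all_simple(self):
        feats = [F.SnoreFeatures(10.0, 1.0)] * 6
        assert F.classify_snore_type(feats) == ["simple"] * 6

    def test_single_clip_degenerate(self):
        assert F.classify_snore_type([F.SnoreFeatures(10.0, 1.0)]) == ["simple"]

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        feats = self._blob_features(rng, 10, 20.0, 0.3) + self._blob_features(
            rng, 10, 120.0, 4.0
        )
        labels = F.classify_snore_type(feats)
        perm = list(range(len(feats)))[::-1]
        labels_perm = F.classify_snore_type([feats[i] for i in perm])
        assert [labels_perm[perm.index(i)] for i in range(len(feats))] == labels

    def test_end_to_end_synthetic_separation(self):
        # 25 simple + 25 apneic synthetic clips, >= 95% agreement
        feats = []
        truth = []
        for s in range(25):
            clip = preprocessed_minute(
                synthetic.gen_simple_snore_minute(1000 + s, RATE)
            )
            feats.append(F.snore_features(F.detect_snore_episodes(clip)))
            truth.append("simple")
        rng = np.random.default_rng(42)
        for s in range(25):
            clip = preprocessed_minute(
                synthetic.gen_apneic_snore_minute(
                    2000 + s, RATE, pause_s=float(rng.uniform(5, 20))
                )
            )
            feats.append(F.snore_features(F.detect_snore_episodes(clip)))
            truth.append("apneic")
        labels = F.classify_snore_type(feats)
        agree = sum(a == b for a, b in zip(labels, truth)) / len(truth)
        assert agree >= 0.95

    def test_f1_threshold_baseline(self):
        assert F.classify_snore_type_f1_threshold([450.0, 480.0]) == [
            "simple",
            "apneic",
        ]
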