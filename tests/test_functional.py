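"""Connectivity features against brute-force formula evaluations.

The oracles below re-evaluate each printed formula directly (loops, or an
independently hand-written Welch average for coherence) and the matrix
assembly is checked against the per-pair functions.
"""

import cmath
import math

import numpy as np
import pytest

import dualeeg as dg
from dualeeg.functional import (FunctionalFeatureConfig, coherence_pair,
                                functional_feature_matrix,
                                instantaneous_phase, pearson_pair, pli_pair,
                                plv_pair)
from tests.conftest import make_window


# ---------------------------------------------------------------- oracles
def brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)
                    * sum((b - my) ** 2 for b in y))
    return num / den


def brute_plv(pi, pj):
    s = sum(cmath.exp(1j * (a - b)) for a, b in zip(pi, pj))
    return abs(s) / len(pi)


def brute_pli_printed(pi, pj):
    d = [a - b for a, b in zip(pi, pj)]
    num = abs(sum(np.sign(math.sin(v)) for v in d) / len(d))
    den = sum(abs(math.sin(v)) for v in d) / len(d)
    return 0.0 if den < 1e-12 else num / den


def brute_pli_standard(pi, pj):
    d = [a - b for a, b in zip(pi, pj)]
    return abs(sum(np.sign(math.sin(v)) for v in d) / len(d))


def brute_wpli(pi, pj):
    d = [a - b for a, b in zip(pi, pj)]
    num = abs(sum(math.sin(v) for v in d) / len(d))
    den = sum(abs(math.sin(v)) for v in d) / len(d)
    return 0.0 if den < 1e-12 else num / den


def brute_coherence(x, y, fs, band, nperseg, noverlap):
    """Hand-written Welch cross/auto spectra and band-mean coherence."""
    step = nperseg - noverlap
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nperseg) / nperseg)
    segs = range(0, len(x) - nperseg + 1, step)
    sxx = syy = sxy = 0
    for s in segs:
        xs = x[s:s + nperseg] - np.mean(x[s:s + nperseg])
        ys = y[s:s + nperseg] - np.mean(y[s:s + nperseg])
        fx = np.fft.rfft(win * xs)
        fy = np.fft.rfft(win * ys)
        sxx = sxx + np.abs(fx) ** 2
        syy = syy + np.abs(fy) ** 2
        sxy = sxy + np.conj(fx) * fy
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    c = np.abs(sxy) ** 2 / (sxx * syy)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(c[sel].mean())


def test_pairwise_features_match_brute_force(rng):
    fs = 64.0
    for _ in range(10):
        n = int(rng.integers(48, 64))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        pi = rng.uniform(-np.pi, np.pi, n)
        pj = rng.uniform(-np.pi, np.pi, n)
        assert pearson_pair(x, y) == pytest.approx(brute_pearson(x, y), abs=1e-10)
        assert plv_pair(pi, pj) == pytest.approx(brute_plv(pi, pj), abs=1e-10)
        assert pli_pair(pi, pj, "printed") == pytest.approx(
            brute_pli_printed(pi, pj), abs=1e-10)
        assert pli_pair(pi, pj, "standard") == pytest.approx(
            brute_pli_standard(pi, pj), abs=1e-10)
        assert pli_pair(pi, pj, "wpli") == pytest.approx(
            brute_wpli(pi, pj), abs=1e-10)
        assert coherence_pair(x, y, fs, band=(2.0, 20.0), welch_seconds=0.25,
                              welch_overlap=0.5) == pytest.approx(
            brute_coherence(x, y, fs, (2.0, 20.0), 16, 8), abs=1e-10)


# ------------------------------------------------------------------ phase
class TestPhase:
    def test_sinusoid_phase_ramp(self):
        fs, f = 500.0, 10.0
        t = np.arange(5000) / fs
        w = make_window(np.sin(2 * np.pi * f * t)[None, :], fs=fs)
        phi = np.unwrap(instantaneous_phase(w).phi[0])
        inc = np.diff(phi)[500:-500]
        assert np.abs(inc - 2 * np.pi * f / fs).max() < 1e-2

    def test_cos_vs_sin_quarter_period_offset(self):
        fs, f = 500.0, 8.0
        t = np.arange(5000) / fs
        data = np.vstack([np.cos(2 * np.pi * f * t),
                          np.sin(2 * np.pi * f * t)])
        phi = instantaneous_phase(make_window(data, fs=fs)).phi
        d = np.angle(np.exp(1j * (phi[0] - phi[1])))[500:-500]
        assert np.abs(d - np.pi / 2).max() < 1e-2

    def test_positive_scaling_leaves_phase_unchanged(self, rng):
        x = rng.standard_normal((1, 400))
        p1 = instantaneous_phase(make_window(x)).phi
        p2 = instantaneous_phase(make_window(4.2 * x)).phi
        assert np.allclose(p1, p2, atol=1e-12)


# ----------------------------------------------------------- trivial cases
class TestTrivialCases:
    def test_pearson_self_and_negation(self, rng):
        x = rng.standard_normal(100)
        assert pearson_pair(x, x) == pytest.approx(1.0, abs=1e-12)
        assert pearson_pair(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_sin_cos_orthogonal(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 5 * t)
        y = np.cos(2 * np.pi * 5 * t)
        assert pearson_pair(x, y) == pytest.approx(0.0, abs=1e-9)

    def test_pearson_constant_input_warns_zero(self):
        with pytest.warns(UserWarning):
            assert pearson_pair(np.ones(10), np.arange(10.0)) == 0.0

    def test_plv_constant_offset_is_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 500)
        assert plv_pair(phi, phi + 0.7) == pytest.approx(1.0, abs=1e-12)

    def test_plv_cancelling_phasors_is_zero(self):
        d = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2] * 25)
        assert plv_pair(d, np.zeros_like(d)) == pytest.approx(0.0, abs=1e-12)

    def test_plv_random_phases_small(self, rng):
        # Rayleigh: resultant of T unit phasors is O(1/sqrt(T))
        pi = rng.uniform(-np.pi, np.pi, 12_500)
        pj = rng.uniform(-np.pi, np.pi, 12_500)
        assert plv_pair(pi, pj) < 0.03

    @pytest.mark.parametrize("variant", ["printed", "standard", "wpli"])
    def test_pli_quarter_lag_is_one(self, variant):
        phi = np.linspace(0, 20 * np.pi, 400)
        assert pli_pair(phi + np.pi / 2, phi, variant) == pytest.approx(
            1.0, abs=1e-12)

    @pytest.mark.parametrize("variant", ["printed", "standard", "wpli"])
    def test_pli_zero_lag_is_zero(self, variant):
        phi = np.linspace(0, 20 * np.pi, 400)
        assert pli_pair(phi, phi, variant) == 0.0

    @pytest.mark.parametrize("variant", ["printed", "standard", "wpli"])
    def test_pli_alternating_lag_cancels(self, variant):
        d = np.array([np.pi / 3, -np.pi / 3] * 50)
        assert pli_pair(d, np.zeros_like(d), variant) == pytest.approx(
            0.0, abs=1e-12)

    def test_printed_pli_exceeds_one_for_small_constant_lag(self):
        # the ratio form is unbounded for constant small nonzero lags
        phi = np.linspace(0, 20 * np.pi, 400)
        assert pli_pair(phi + 0.1, phi, "printed") > 1.0
        assert pli_pair(phi + 0.1, phi, "wpli") == pytest.approx(1.0, abs=1e-12)

    def test_coherence_self_is_one(self, rng):
        x = rng.standard_normal(2000)
        assert coherence_pair(x, x, 100.0, band=(1.0, 30.0)) == pytest.approx(
            1.0, abs=1e-9)

    def test_coherence_pure_delay_near_one(self):
        # short delay relative to the Welch segment keeps edge loss < 1%
        rng = np.random.default_rng(8)
        x = rng.standard_normal(4000)
        y = np.roll(x, 2)
        assert coherence_pair(x, y, 100.0, band=(1.0, 30.0)) > 0.99

    def test_coherence_independent_noise_small(self):
        rng = np.random.default_rng(9)
        fs = 500.0
        x = rng.standard_normal(12_500)
        y = rng.standard_normal(12_500)
        # ~24 Welch segments -> bias is O(1/L)
        assert coherence_pair(x, y, fs, band=(1.0, 30.0)) < 0.15

    def test_coherence_single_segment_rejected(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(ValueError, match="segments"):
            coherence_pair(x, x, 100.0, welch_seconds=1.0, welch_overlap=0.0)


# ------------------------------------------------------------- properties
class TestProperties:
    def test_symmetry_of_all_pair_features(self, rng):
        fs = 64.0
        x = rng.standard_normal(64)
        y = rng.standard_normal(64)
        pi = rng.uniform(-np.pi, np.pi, 64)
        pj = rng.uniform(-np.pi, np.pi, 64)
        assert pearson_pair(x, y) == pytest.approx(pearson_pair(y, x), abs=1e-12)
        assert plv_pair(pi, pj) == pytest.approx(plv_pair(pj, pi), abs=1e-12)
        for variant in ("printed", "standard", "wpli"):
            assert pli_pair(pi, pj, variant) == pytest.approx(
                pli_pair(pj, pi, variant), abs=1e-12)
        assert coherence_pair(x, y, fs, welch_seconds=0.25) == pytest.approx(
            coherence_pair(y, x, fs, welch_seconds=0.25), abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            x = rng.standard_normal(64)
            y = rng.standard_normal(64)
            pi = rng.uniform(-np.pi, np.pi, 64)
            pj = rng.uniform(-np.pi, np.pi, 64)
            assert -1.0 <= pearson_pair(x, y) <= 1.0
            assert 0.0 <= plv_pair(pi, pj) <= 1.0
            assert 0.0 <= pli_pair(pi, pj, "standard") <= 1.0
            assert 0.0 <= pli_pair(pi, pj, "wpli") <= 1.0
            assert 0.0 <= coherence_pair(x, y, 64.0, welch_seconds=0.25) <= 1.0
            # printed >= standard whenever the denominator (<= 1) is positive
            assert (pli_pair(pi, pj, "printed")
                    >= pli_pair(pi, pj, "standard") - 1e-12)

    def test_amplitude_invariance(self, rng):
        """Per-channel positive rescaling leaves phase/correlation features
        unchanged (exactly) and coherence unchanged within tolerance."""
        data = rng.standard_normal((4, 512))
        scales = np.array([0.2, 3.0, 17.0, 1e-3])[:, None]
        w1 = make_window(data, fs=64.0)
        w2 = make_window(data * scales, fs=64.0)
        cfg = FunctionalFeatureConfig(
            features=("pearson", "coherence", "plv", "pli"),
            band=(2.0, 20.0), welch_seconds=1.0)
        m1 = functional_feature_matrix(w1, cfg)
        m2 = functional_feature_matrix(w2, cfg)
        for j, name in enumerate(cfg.features):
            # phase/correlation features cancel the scale analytically; the
            # float evaluation leaves only rounding noise
            tol = 1e-9 if name == "coherence" else 1e-12
            assert np.abs(m1.values[:, j] - m2.values[:, j]).max() <= tol


# ---------------------------------------------------------------- matrix
class TestMatrix:
    def test_31_channels_default_features_give_465x3(self, rng):
        w = make_window(rng.standard_normal((31, 250)), fs=125.0,
                        labels=dg.MONTAGE_31)
        m = functional_feature_matrix(
            w, FunctionalFeatureConfig(features=("pli", "plv", "pearson")))
        assert m.values.shape == (465, 3)
        assert m.feature_names == ("pli", "plv", "pearson")
        assert m.pair_labels[0] == ("FP1", "FP2")
        assert m.pair_labels[-1] == ("Oz", "O2")

    def test_three_channels_canonical_pair_order(self, rng):
        w = make_window(rng.standard_normal((3, 256)), fs=64.0,
                        labels=("x", "y", "z"))
        m = functional_feature_matrix(w)
        assert m.pair_labels == [("x", "y"), ("x", "z"), ("y", "z")]

    def test_matrix_matches_pair_functions(self, rng):
        """Vectorized assembly equals the per-pair functions."""
        fs = 64.0
        data = rng.standard_normal((4, 64))
        w = make_window(data, fs=fs, labels=("a", "b", "c", "d"))
        cfg = FunctionalFeatureConfig(
            features=("pearson", "coherence", "plv", "pli"),
            band=(2.0, 20.0), welch_seconds=0.25)
        m = functional_feature_matrix(w, cfg)
        phi = instantaneous_phase(w).phi
        row = 0
        for i in range(4):
            for j in range(i + 1, 4):
                expected = [
                    pearson_pair(data[i], data[j]),
                    coherence_pair(data[i], data[j], fs, band=(2.0, 20.0),
                                   welch_seconds=0.25),
                    plv_pair(phi[i], phi[j]),
                    pli_pair(phi[i], phi[j], "printed"),
                ]
                assert m.values[row] == pytest.approx(expected, abs=1e-10)
                row += 1

    def test_channel_relabeling_permutes_rows_consistently(self, rng):
        data = rng.standard_normal((4, 256))
        labels = ("a", "b", "c", "d")
        w = make_window(data, fs=64.0, labels=labels)
        perm = [2, 0, 3, 1]
        w_p = make_window(data[perm], fs=64.0,
                          labels=tuple(labels[i] for i in perm))
        cfg = FunctionalFeatureConfig(features=("plv", "pearson"))
        m = functional_feature_matrix(w, cfg)
        m_p = functional_feature_matrix(w_p, cfg)
        lookup = {frozenset(p): v for p, v in zip(m.pair_labels, m.values)}
        for pair, vals in zip(m_p.pair_labels, m_p.values):
            assert vals == pytest.approx(lookup[frozenset(pair)], abs=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(features=()),
        dict(features=("plv", "plv")),
        dict(features=("nope",)),
        dict(pli_variant="bogus"),
        dict(band=(30.0, 1.0)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            FunctionalFeatureConfig(**bad)
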