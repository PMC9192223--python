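import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimodes import (
    DegenerateInputError,
    EmdConfig,
    EnvelopeError,
    Signal,
    emd,
    extract_imf,
    find_extrema,
    is_imf,
    mean_envelope,
    sd_criterion,
)
from mimodes.emd import count_zero_crossings


def brute_force_extrema(x):
    """Independent oracle: direct neighbor comparison with plateau collapse."""
    maxima, minima = [], []
    n = len(x)
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and x[j + 1] == x[j]:
            j += 1
        if j == n - 1:
            break
        left, right = x[i - 1], x[j + 1]
        if x[i] > left and x[i] > right:
            maxima.append(i)
        elif x[i] < left and x[i] < right:
            minima.append(i)
        i = j + 1
    return maxima, minima


class TestFindExtrema:
    def test_sine_against_brute_force(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 5 * t)
        mx, mn = find_extrema(x)
        bmx, bmn = brute_force_extrema(x)
        assert list(mx) == bmx
        assert list(mn) == bmn
        assert abs(len(mx) - 5) <= 1
        assert abs(len(mn) - 5) <= 1

    def test_constant_signal(self):
        mx, mn = find_extrema(np.ones(50))
        assert mx.size == 0 and mn.size == 0

    def test_flat_run_first_index(self):
        mx, mn = find_extrema(np.array([0.0, 1.0, 1.0, 0.0]))
        assert list(mx) == [1]
        assert mn.size == 0

    def test_too_short_raises(self):
        with pytest.raises(DegenerateInputError):
            find_extrema(np.array([1.0, 2.0, 1.0]))

    def test_endpoints_never_extrema(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.standard_normal(64)
            mx, mn = find_extrema(x)
            for idx in (*mx, *mn):
                assert 0 < idx < 63

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_oracle_on_random_signals(self, seed):
        x = np.round(np.random.default_rng(seed).standard_normal(40), 1)
        mx, mn = find_extrema(x)
        bmx, bmn = brute_force_extrema(x)
        assert list(mx) == bmx
        assert list(mn) == bmn


class TestMeanEnvelope:
    def test_sine_mean_near_zero(self):
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        a = 2.0
        m = mean_envelope(Signal(a * np.sin(2 * np.pi * 5 * t), fs))
        margin = len(t) // 20
        assert np.max(np.abs(m[margin:-margin])) < 0.05 * a

    def test_constant_offset_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        c = 7.5
        m0 = mean_envelope(x)
        m1 = mean_envelope(x + c)
        assert np.allclose(m1 - m0, c, atol=1e-9)

    def test_tracks_slow_tone(self):
        fs = 1000.0
        t = np.arange(int(2 * fs)) / fs
        slow = np.sin(2 * np.pi * 1 * t)
        x = slow + 0.5 * np.sin(2 * np.pi * 10 * t)
        m = mean_envelope(x)
        assert np.corrcoef(m, slow)[0, 1] > 0.9

    def test_too_few_extrema_raises(self):
        with pytest.raises(EnvelopeError):
            mean_envelope(np.linspace(0, 1, 50))

    def test_clamp_mode_runs(self):
        fs = 250.0
        t = np.arange(500) / fs
        x = np.sin(2 * np.pi * 5 * t)
        m = mean_envelope(x, boundary_mode="clamp")
        assert m.shape == x.shape


class TestSdCriterion:
    def test_identical_is_zero(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert sd_criterion(x, x) == 0.0

    def test_doubling_is_one(self):
        x = np.random.default_rng(1).standard_normal(100)
        assert sd_criterion(2 * x, x) == pytest.approx(1.0)

    def test_known_perturbation(self):
        rng = np.random.default_rng(2)
        prev = rng.standard_normal(256)
        eps = rng.standard_normal(256)
        eps *= 0.2 * np.linalg.norm(prev) / np.linalg.norm(eps)  # ||eps||^2/||prev||^2 = 0.04
        assert sd_criterion(prev + eps, prev) == pytest.approx(0.04)

    def test_zero_reference_raises(self):
        with pytest.raises(DegenerateInputError):
            sd_criterion(np.ones(10), np.zeros(10))

    def test_length_mismatch_raises(self):
        with pytest.raises(DegenerateInputError):
            sd_criterion(np.ones(10), np.ones(11))

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 32))
        assert sd_criterion(a, b) >= 0.0


class TestExtractImf:
    def test_pure_tone_is_its_own_imf(self):
        fs = 1000.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 8 * t)
        imf, trace = extract_imf(Signal(x, fs))
        assert trace.converged
        assert 1 <= trace.n_iterations <= 3
        assert np.linalg.norm(imf - x) / np.linalg.norm(x) < 1e-3

    def test_terminal_sd_below_threshold_when_converged(self):
        cfg = EmdConfig()
        rng = np.random.default_rng(4)
        x = rng.standard_normal(512)
        imf, trace = extract_imf(x, cfg)
        if trace.converged:
            assert trace.terminal_sd < cfg.sd_threshold

    def test_first_imf_matches_fast_tone(self, two_tone_signal, two_tone_parts):
        imf, trace = extract_imf(two_tone_signal)
        assert abs(np.corrcoef(imf, two_tone_parts["fast"])[0, 1]) > 0.95


class TestEmd:
    def test_monotone_ramp_no_imfs(self):
        dec = emd(np.linspace(0.0, 1.0, 100))
        assert dec.n_imfs == 0
        assert np.array_equal(dec.residual, np.linspace(0.0, 1.0, 100))

    def test_two_tone_plus_trend_components(self):
        fs = 250.0
        t = np.arange(2000) / fs
        fast = 0.5 * np.sin(2 * np.pi * 12 * t)
        slow = np.sin(2 * np.pi * 1 * t)
        x = slow + fast + t / 10
        dec = emd(Signal(x, fs))
        assert dec.n_imfs >= 2
        assert abs(np.corrcoef(dec.imfs[0], fast)[0, 1]) > 0.9
        assert abs(np.corrcoef(dec.imfs[1], slow)[0, 1]) > 0.9

    def test_reconstruction_identity_random_signals(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(64, 512))
            x = rng.standard_normal(n)
            dec = emd(x)
            err = np.max(np.abs(x - dec.reconstruct()))
            assert err < 1e-10 * np.max(np.abs(x))

    def test_imf_condition_holds(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            x = rng.standard_normal(256)
            dec = emd(x)
            for c in dec.imfs:
                assert is_imf(c)

    def test_imfs_have_near_zero_local_mean(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(512).cumsum()  # smooth-ish random walk
        dec = emd(x)
        from mimodes import mean_envelope

        for c in dec.imfs:
            amp = np.max(np.abs(c))
            if amp == 0:
                continue
            try:
                m = mean_envelope(c)
            except EnvelopeError:
                continue
            margin = max(1, len(c) // 20)
            assert np.max(np.abs(m[margin:-margin])) < 0.1 * amp

    def test_shift_scale_completeness(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(300)
        a, b = 2.5, 4.0
        base = emd(x)
        shifted = emd(a * x + b)
        assert base.n_imfs == shifted.n_imfs
        scale = max(np.max(np.abs(a * c)) for c in base.imfs)
        for c0, c1 in zip(base.imfs, shifted.imfs):
            assert np.max(np.abs(c1 - a * c0)) < 1e-8 * scale
        assert np.max(np.abs(shifted.residual - (a * base.residual + b))) < 1e-8 * scale

    def test_max_imfs_cap(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(512)
        dec = emd(x, EmdConfig(max_imfs=2))
        assert dec.n_imfs <= 2

    def test_zero_crossings_counter(self):
        assert count_zero_crossings(np.array([1.0, -1.0, 1.0, -1.0])) == 3
        assert count_zero_crossings(np.array([1.0, 0.0, 1.0, 2.0])) == 0


class TestEmdConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sd_threshold": 0.0},
            {"sd_threshold": 1.5},
            {"max_sift_iterations": 0},
            {"boundary_mode": "wrap"},
            {"max_imfs": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        from mimodes import ConfigurationError

        with pytest.raises(ConfigurationError):
            EmdConfig(**kwargs)
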