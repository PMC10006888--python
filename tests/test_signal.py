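"""Signal processing: interpolation, stride period, cycle averaging, powers."""

import numpy as np
import pytest

import gaitfreq as gf
from gaitfreq.signal import (
    CycleSegmentation,
    estimate_stride_period,
    extract_and_average_cycles,
    fourier_features,
    fourier_interpolate,
)
from conftest import make_trial, single_harmonic_config

FS = 12.5


class TestFourierInterpolate:
    def test_identity_at_sample_points(self):
        rng = np.random.default_rng(0)
        t = np.arange(100) / FS
        x = rng.normal(size=100)
        np.testing.assert_allclose(fourier_interpolate(t, x, t), x, atol=1e-10)

    def test_band_limited_cosine_at_midpoints(self):
        # 1 Hz is periodic in the 30 s implied extension window
        t = np.arange(375) / FS
        x = np.cos(2 * np.pi * t)
        tq = t[:-1] + 0.5 / FS
        np.testing.assert_allclose(
            fourier_interpolate(t, x, tq), np.cos(2 * np.pi * tq), atol=1e-6
        )

    def test_rejects_nonuniform_grid(self):
        t = np.array([0.0, 0.08, 0.17, 0.24])
        with pytest.raises(ValueError, match="uniform"):
            fourier_interpolate(t, np.ones(4), [0.1])

    def test_rejects_query_outside_span(self):
        t = np.arange(50) / FS
        with pytest.raises(ValueError, match="span"):
            fourier_interpolate(t, np.ones(50), [t[-1] + 1.0])


class TestStridePeriod:
    def test_pure_cosine_known_period(self):
        t = np.arange(int(30 * FS)) / FS
        trial = make_trial(np.cos(2 * np.pi * t / 1.0))
        assert estimate_stride_period(trial) == pytest.approx(1.0, abs=0.02)

    def test_noisy_two_harmonic_within_half_sample(self):
        # planted period 1.10 s, SNR ~10
        rng = np.random.default_rng(5)
        t = np.arange(int(30 * FS)) / FS
        clean = np.cos(2 * np.pi * t / 1.1) + 0.6 * np.cos(4 * np.pi * t / 1.1 + 1.0)
        noise = rng.normal(0, np.sqrt(np.var(clean) / 10), t.size)
        trial = make_trial(clean + noise)
        assert estimate_stride_period(trial) == pytest.approx(1.1, abs=0.04)

    def test_white_noise_is_aperiodic(self):
        rng = np.random.default_rng(1)
        trial = make_trial(rng.normal(size=int(30 * FS)))
        with pytest.raises(ValueError, match="aperiodic"):
            estimate_stride_period(trial)

    def test_constant_signal_rejected(self):
        trial = make_trial(np.full(int(30 * FS), 3.3))
        with pytest.raises(ValueError, match="constant"):
            estimate_stride_period(trial)


class TestCycleAveraging:
    def test_noiseless_periodic_average_equals_single_cycle(self):
        cfg = single_harmonic_config(4)
        cfg.harmonic_power_profile["control"]["cc"] = np.array(
            [1.0, 0.4, 0.2, 0.0, 0.1, 0.0]
        )
        _, trials = gf.generate_cohort(cfg)
        tr = trials[0]
        T = tr.truth["stride_period"]
        seg10 = extract_and_average_cycles(tr, T, n_cycles=10)
        seg1 = extract_and_average_cycles(tr, T, n_cycles=1)
        # both grids have the same phase only up to a cycle offset; compare
        # by aligning the single cycle circularly
        a, b = seg10.averaged_cycle[:, 0], seg1.averaged_cycle[:, 0]
        shifts = [np.abs(a - np.roll(b, s)).max() for s in range(len(b))]
        assert min(shifts) < 1e-8

    def test_averaging_suppresses_noise_like_sqrt_n(self):
        # RMS deviation of the averaged cycle ~ sigma / sqrt(10)
        sigma = 0.3
        devs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = np.arange(int(18 * FS)) / FS
            clean_fn = lambda tt: np.cos(2 * np.pi * tt / 1.04) + 0.5 * np.sin(
                4 * np.pi * tt / 1.04
            )
            trial = make_trial(clean_fn(t) + rng.normal(0, sigma, t.size))
            seg = extract_and_average_cycles(trial, 1.04)
            start = seg.cycle_boundaries[0][0]
            grid = start + 1.04 * np.arange(seg.m_points) / seg.m_points
            clean = clean_fn(grid) - clean_fn(t).mean()
            devs.append(np.sqrt(np.mean((seg.averaged_cycle[:, 0] - clean) ** 2)))
        expected = sigma / np.sqrt(10)
        assert np.mean(devs) == pytest.approx(expected, rel=0.3)

    def test_too_short_trial_errors_with_required_duration(self):
        t = np.arange(int(12 * FS)) / FS  # ~12 strides of 1 s
        trial = make_trial(np.cos(2 * np.pi * t))
        with pytest.raises(ValueError, match="required"):
            extract_and_average_cycles(trial, 1.0, n_cycles=10)


def _seg_from_cycle(cycle, period=1.0):
    cyc = np.asarray(cycle, dtype=float)
    if cyc.ndim == 1:
        cyc = np.column_stack([cyc, np.zeros_like(cyc), np.zeros_like(cyc)])
    return CycleSegmentation(period, ((0.0, period),), cyc)


class TestFourierFeatures:
    def test_single_harmonic_unit_power(self):
        k = np.arange(64)
        seg = _seg_from_cycle(np.cos(2 * np.pi * k / 64))
        ff = fourier_features(seg)
        assert ff.coefficients["cc"][0, 0] == pytest.approx(1.0, abs=1e-10)
        assert ff.coefficients["cc"][0, 1] == pytest.approx(0.0, abs=1e-10)
        assert ff.powers["cc"][0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(ff.powers["cc"][1:], 0, atol=1e-10)

    def test_second_harmonic_scaling(self):
        k = np.arange(64)
        seg = _seg_from_cycle(2.0 * np.sin(2 * np.pi * 2 * k / 64))
        ff = fourier_features(seg)
        assert ff.powers["cc"][1] == pytest.approx(4.0, abs=1e-10)
        np.testing.assert_allclose(np.delete(ff.powers["cc"], 1), 0, atol=1e-10)

    def test_matches_dft_oracle_and_parseval(self):
        rng = np.random.default_rng(9)
        M = 64
        k = np.arange(M)
        cycle = np.zeros(M)
        for i in range(1, 11):  # band-limited random periodic cycle
            cycle += rng.normal() * np.cos(2 * np.pi * i * k / M)
            cycle += rng.normal() * np.sin(2 * np.pi * i * k / M)
        seg = _seg_from_cycle(cycle)
        ff = fourier_features(seg, n_harmonics=12)
        # independent direct-sum DFT oracle
        for i in range(1, 13):
            a = 2 / M * np.sum(cycle * np.cos(2 * np.pi * i * k / M))
            b = 2 / M * np.sum(cycle * np.sin(2 * np.pi * i * k / M))
            assert ff.coefficients["cc"][i - 1, 0] == pytest.approx(a, abs=1e-10)
            assert ff.coefficients["cc"][i - 1, 1] == pytest.approx(b, abs=1e-10)
        total = (ff.powers["cc"] / 2).sum()
        assert total == pytest.approx(np.var(cycle), abs=1e-10)

    def test_powers_equal_sum_of_squared_coefficients(self):
        rng = np.random.default_rng(2)
        seg = _seg_from_cycle(rng.normal(size=64))
        ff = fourier_features(seg)
        for ax in ("cc", "ap", "ml"):
            np.testing.assert_array_equal(
                ff.powers[ax], (ff.coefficients[ax] ** 2).sum(axis=1)
            )

    def test_insufficient_bandwidth_rejected(self):
        seg = _seg_from_cycle(np.ones(12))
        with pytest.raises(ValueError, match="insufficient bandwidth"):
            fourier_features(seg)


@pytest.fixture(scope="module")
def noiseless_trial():
    cfg = single_harmonic_config(6)
    cfg.harmonic_power_profile["control"]["cc"] = np.array(
        [0.8, 0.3, 0.15, 0.1, 0.05, 0.04]
    )
    _, trials = gf.generate_cohort(cfg)
    return trials[0]


class TestSpectralInvariances:

    def test_reconstruction_at_grid_points(self, noiseless_trial):
        tr = noiseless_trial
        seg = extract_and_average_cycles(tr, tr.truth["stride_period"])
        M = seg.m_points
        ff = fourier_features(seg, n_harmonics=M // 2 - 1)
        k = np.arange(M)
        recon = np.full(M, seg.averaged_cycle[:, 0].mean())
        for i in range(1, M // 2):
            a, b = ff.coefficients["cc"][i - 1]
            recon += a * np.cos(2 * np.pi * i * k / M) + b * np.sin(
                2 * np.pi * i * k / M
            )
        np.testing.assert_allclose(recon, seg.averaged_cycle[:, 0], atol=1e-8)

    def test_scale_equivariance(self, noiseless_trial):
        tr = noiseless_trial
        c = 3.7
        scaled = gf.AccelTrial(
            "s", tr.sampling_rate,
            np.column_stack([tr.t, *[c * tr.axis(a) for a in ("cc", "ap", "ml")]]),
        )
        T = tr.truth["stride_period"]
        p1 = fourier_features(extract_and_average_cycles(tr, T)).powers["cc"]
        p2 = fourier_features(extract_and_average_cycles(scaled, T)).powers["cc"]
        np.testing.assert_allclose(p2, c**2 * p1, rtol=1e-9)

    def test_shift_invariance(self, noiseless_trial):
        tr = noiseless_trial
        shifted = gf.AccelTrial(
            "s", tr.sampling_rate,
            np.column_stack(
                [tr.t, *[tr.axis(a) + 5.0 for a in ("cc", "ap", "ml")]]
            ),
        )
        T = tr.truth["stride_period"]
        p1 = fourier_features(extract_and_average_cycles(tr, T)).powers["cc"]
        p2 = fourier_features(extract_and_average_cycles(shifted, T)).powers["cc"]
        np.testing.assert_allclose(p2, p1, atol=1e-10)

    def test_phase_invariance_of_powers(self):
        rng = np.random.default_rng(3)
        cycle = np.zeros(64)
        k = np.arange(64)
        for i in range(1, 7):
            cycle += rng.normal() * np.cos(2 * np.pi * i * k / 64 + rng.uniform())
        p0 = fourier_features(_seg_from_cycle(cycle)).powers["cc"]
        for shift in (1, 7, 31):
            p = fourier_features(_seg_from_cycle(np.roll(cycle, shift))).powers["cc"]
            np.testing.assert_allclose(p, p0, atol=1e-10)

    def test_noiseless_planted_power_recovery(self):
        cfg = single_harmonic_config(8)
        cfg.harmonic_power_profile["control"]["ap"] = np.array(
            [0.2, 0.35, 0.1, 0.12, 0.07, 0.05]
        )
        _, trials = gf.generate_cohort(cfg)
        tr = trials[0]
        ff = gf.extract_features(tr)
        np.testing.assert_allclose(
            ff.powers["ap"], tr.truth["powers"]["ap"], atol=1e-6
        )
        np.testing.assert_allclose(ff.powers["cc"][0], 1.0, atol=1e-6)

    def test_omega_recovery_across_seeds(self):
        # extracted omega within 2% of 2*pi/stride_period_mean over seeds
        for seed in range(20):
            cfg = single_harmonic_config(
                100 + seed, stride_period_sd={"control": 0.0, "patient": 0.0}
            )
            cfg.noise_sd = 0.02
            _, trials = gf.generate_cohort(cfg)
            ff = gf.extract_features(trials[0])
            expected = 2 * np.pi / cfg.stride_period_mean["control"]
            assert abs(ff.omega - expected) / expected < 0.02
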