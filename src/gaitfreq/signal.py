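"""Stride-frequency estimation and Fourier harmonic-power feature extraction.

Pipeline per trial: band-limited (trigonometric) interpolation of the
uniformly sampled signal, autocorrelation-based stride-period estimation,
extraction and averaging of ten gait cycles from the middle of the walking
bout, then the first six Fourier coefficient pairs of the averaged cycle.
The harmonic power is P(f_i) = a_i^2 + b_i^2 — the sum of squares of the
i-th coefficient pair, with no 1/2 factor; any constant factor cancels
after downstream standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cohort import AXES, AccelTrial

FEATURE_AXES = ("CC", "AP", "ML")  # column-name casing


def feature_names(n_harmonics: int = 6) -> list[str]:
    """Feature column order: omega then P_f1_CC..P_f6_CC, AP, ML."""
    return ["omega"] + [
        f"P_f{i}_{AX}" for AX in FEATURE_AXES for i in range(1, n_harmonics + 1)
    ]


@dataclass(frozen=True)
class CycleSegmentation:
    """Ten contiguous gait cycles from the middle of a trial, averaged.

    ``averaged_cycle`` is an (m_points, 3) array (columns cc/ap/ml) on a
    uniform grid spanning one stride; per-axis means were removed from the
    raw trial before segmentation.
    """

    stride_period: float
    cycle_boundaries: tuple  # ((start, end), ...) in trial time
    averaged_cycle: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_boundaries)

    @property
    def m_points(self) -> int:
        return self.averaged_cycle.shape[0]


@dataclass(frozen=True)
class FourierFeatures:
    """Fundamental frequency plus per-axis Fourier coefficients and powers.

    ``coefficients[axis]`` holds (a_i, b_i) pairs for i = 1..6 as an (6, 2)
    array; ``powers[axis][i-1] = a_i^2 + b_i^2``.
    """

    omega: float
    coefficients: dict
    powers: dict

    def as_row(self) -> dict:
        row = {"omega": self.omega}
        for ax, AX in zip(AXES, FEATURE_AXES):
            for i, p in enumerate(self.powers[ax], start=1):
                row[f"P_f{i}_{AX}"] = float(p)
        return row


# ---------------------------------------------------------------------------
# Band-limited interpolation


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if t.size < 2:
        raise ValueError("need at least two samples")
    if not np.allclose(dt, dt[0], rtol=1e-7, atol=1e-12):
        raise ValueError("input grid is not uniform")
    return float(dt[0])


def fourier_interpolate(t: np.ndarray, x: np.ndarray, t_query) -> np.ndarray:
    """Evaluate the trigonometric interpolant of a uniform series.

    Reproduces the samples exactly at their own grid points and is the
    band-limited extension in between.  ``x`` may be 1-D or (n, c) with one
    column per channel; queries outside the sampled span raise.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    tq = np.atleast_1d(np.asarray(t_query, dtype=float))
    dt = _check_uniform(t)
    eps = 1e-9 * dt
    if tq.min() < t[0] - eps or tq.max() > t[-1] + eps:
        raise ValueError("query times outside the sampled span")

    squeeze = x.ndim == 1
    X = np.fft.rfft(x, axis=0)  # (K, c) spectrum
    n = t.size
    k = np.arange(X.shape[0])
    weights = np.full(k.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0  # Nyquist bin is not doubled
    tau = (tq - t[0]) / dt
    # (q, K) phase matrix; memory fine for the short trials this handles
    phase = np.exp(2j * np.pi * np.outer(tau, k) / n)
    out = (phase * weights) @ X
    out = out.real / n
    return out[:, 0] if (squeeze and out.ndim > 1) else out


# ---------------------------------------------------------------------------
# Stride-period estimation


def _parabolic_refine(r: np.ndarray, p: int) -> float:
    if p <= 0 or p >= r.size - 1:
        return float(p)
    denom = r[p - 1] - 2 * r[p] + r[p + 1]
    if denom == 0:
        return float(p)
    return p + 0.5 * (r[p - 1] - r[p + 1]) / denom


def _phase_drift_refine(t, x, period, n_harmonics=6, n_iter=8):
    """Refine the period by tracking the phase drift of the strongest harmonic.

    If the trial frequency estimate w is off by dw, the demodulated phase of
    harmonic i drifts at rate i*dw; comparing early and late window phases
    yields a correction that converges quadratically on periodic signals.
    Hann tapers on the demodulation windows suppress the interference of the
    negative-frequency component, which would otherwise bias the estimate.
    """
    n = t.size
    half = n // 2
    w1 = np.hanning(half)
    w2 = np.hanning(n - half)
    t1, t2 = t[:half], t[half:]
    x1, x2 = x[:half], x[half:]
    dt_c = (w2 @ t2) / w2.sum() - (w1 @ t1) / w1.sum()
    h_full = np.hanning(n)
    for _ in range(n_iter):
        w = 2 * np.pi / period
        harmonics = np.arange(1, n_harmonics + 1)
        z = np.exp(-1j * np.outer(harmonics, w * t)) @ (h_full * x)
        i_star = int(np.argmax(np.abs(z)))
        k = i_star + 1
        z1 = np.exp(-1j * k * w * t1) @ (w1 * x1)
        z2 = np.exp(-1j * k * w * t2) @ (w2 * x2)
        if abs(z1) == 0 or abs(z2) == 0:
            break
        dphi = np.angle(z2 * np.conj(z1))
        w_new = w + dphi / (k * dt_c)
        if w_new <= 0:
            break
        new_period = 2 * np.pi / w_new
        if abs(new_period - period) < 1e-13:
            period = new_period
            break
        period = new_period
    return period


def estimate_stride_period(
    trial: AccelTrial,
    axis: str = "cc",
    search_range: tuple = (0.4, 2.0),
    min_peak: float = 0.2,
    refine: bool = True,
) -> float:
    """Stride period from the normalized autocorrelation of one axis.

    The discrete autocorrelation peak inside ``search_range`` is refined by
    parabolic interpolation and (by default) a phase-drift step that brings
    the estimate to near machine precision on noiseless periodic signals.
    Raises on constant input and on signals without a clear periodicity
    (peak below ``min_peak``).
    """
    fs = trial.sampling_rate
    dt = 1.0 / fs
    lo, hi = search_range
    if trial.duration < 2.0 * hi:
        raise ValueError(
            f"trial must span at least twice the maximum search lag ({2 * hi:.1f} s)"
        )
    x = trial.axis(axis) - trial.axis(axis).mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("constant signal: stride period undefined")
    r = np.correlate(x, x, mode="full")[x.size - 1 :] / denom

    l_lo = max(1, int(np.ceil(lo * fs)))
    l_hi = min(r.size - 2, int(np.floor(hi * fs)))
    if l_hi <= l_lo:
        raise ValueError("search range too narrow for the sampling rate")
    seg = r[l_lo : l_hi + 1]
    p = l_lo + int(np.argmax(seg))
    if r[p] < min_peak:
        raise ValueError(
            f"aperiodic signal: autocorrelation peak {r[p]:.3f} below {min_peak}"
        )
    period = _parabolic_refine(r, p) * dt

    def r_at(tau):  # quadratic interpolation of the discrete autocorrelation
        j = int(round(tau * fs))
        if j < 1 or j > r.size - 2:
            return -np.inf
        denom = r[j - 1] - 2 * r[j] + r[j + 1]
        d = tau * fs - j
        return r[j] + 0.5 * (r[j + 1] - r[j - 1]) * d + 0.5 * denom * d * d

    # octave-error guard: a sharp multi-harmonic peak can fall between lag
    # samples while an integer multiple lands on one; prefer the smallest
    # sub-multiple whose interpolated autocorrelation is comparably high
    base = r_at(period)
    for k in (4, 3, 2):
        tau = period / k
        if tau >= lo and r_at(tau) >= 0.8 * base and r_at(tau) >= min_peak:
            period = tau
            break
    if refine:
        refined = _phase_drift_refine(trial.t, x, period)
        # keep the refinement only if it stayed near the discrete peak
        if abs(refined - period) <= 2 * dt:
            period = refined
    if not period > 2.0 / fs:
        raise ValueError("estimated stride period at or below two samples")
    return float(period)


# ---------------------------------------------------------------------------
# Cycle extraction and harmonic powers


def _harmonic_design(t: np.ndarray, period: float, n_harm: int) -> np.ndarray:
    ang = 2.0 * np.pi * np.outer(t, np.arange(1, n_harm + 1)) / period
    return np.hstack([np.cos(ang), np.sin(ang)])


def extract_and_average_cycles(
    trial: AccelTrial,
    period: float,
    n_cycles: int = 10,
    m_points: int = 64,
) -> CycleSegmentation:
    """Average ``n_cycles`` contiguous cycles centred on the trial midpoint.

    Each cycle is resampled onto ``m_points`` equally spaced points over one
    period via trigonometric interpolation; the averaged cycle is the
    pointwise mean.  Per-axis means (gravity + DC) are subtracted first.

    The full-window trigonometric interpolant leaks at the window wrap when
    the stride period is incommensurate with the recording length, so the
    stride-periodic component (a least-squares harmonic series at the given
    period) is removed before interpolation and added back analytically at
    the query times.  The periodic part is thereby resampled exactly — even
    for harmonics near the Nyquist limit — while cycle-to-cycle variability
    survives in the interpolated residual and is genuinely averaged.
    """
    required = (n_cycles + 4) * period
    if trial.duration < required:
        raise ValueError(
            f"trial too short: {trial.duration:.2f} s < required "
            f"{required:.2f} s ({n_cycles} cycles + 4 stride margin)"
        )
    t = trial.t
    xs = trial.samples[:, 1:4] - trial.samples[:, 1:4].mean(axis=0)
    t_mid = 0.5 * (t[0] + t[-1])
    start = t_mid - 0.5 * n_cycles * period
    # query all cycles at once: cycle c, point j -> start + (c + j/m) * period
    offsets = np.arange(m_points) / m_points
    q = (start + (np.arange(n_cycles)[:, None] + offsets[None, :]) * period).ravel()

    # periodic-trend removal: highest harmonic must stay under Nyquist
    dt = 1.0 / trial.sampling_rate
    n_harm = max(1, min(8, int(np.ceil(period / (2.0 * dt) - 1e-9)) - 1))
    design = _harmonic_design(t, period, n_harm)
    coef, *_ = np.linalg.lstsq(design, xs, rcond=None)
    resid = xs - design @ coef
    vals = fourier_interpolate(t, resid, q) + _harmonic_design(q, period, n_harm) @ coef
    vals = vals.reshape(n_cycles, m_points, 3)
    averaged = vals.mean(axis=0)
    bounds = tuple(
        (start + c * period, start + (c + 1) * period) for c in range(n_cycles)
    )
    return CycleSegmentation(float(period), bounds, averaged)


def fourier_features(seg: CycleSegmentation, n_harmonics: int = 6) -> FourierFeatures:
    """Fourier coefficient pairs and powers of the averaged cycle, per axis.

    a_i = (2/M) sum_k x_k cos(2 pi i k / M), b_i likewise with sin, and
    P(f_i) = a_i^2 + b_i^2 for i = 1..n_harmonics.
    """
    M = seg.m_points
    if M < 2 * n_harmonics + 2:
        raise ValueError(
            f"insufficient bandwidth for {n_harmonics} harmonics: "
            f"m_points={M} < {2 * n_harmonics + 2}"
        )
    X = np.fft.rfft(seg.averaged_cycle, axis=0)  # (K, 3)
    a = 2.0 * X.real[1 : n_harmonics + 1] / M
    b = -2.0 * X.imag[1 : n_harmonics + 1] / M
    coefficients = {}
    powers = {}
    for c, ax in enumerate(AXES):
        coefficients[ax] = np.column_stack([a[:, c], b[:, c]])
        powers[ax] = a[:, c] ** 2 + b[:, c] ** 2
    return FourierFeatures(2.0 * np.pi / seg.stride_period, coefficients, powers)


def extract_features(
    trial: AccelTrial,
    axis: str = "cc",
    search_range: tuple = (0.4, 2.0),
    n_cycles: int = 10,
    m_points: int = 64,
) -> FourierFeatures:
    """Full per-trial pipeline: period -> averaged cycle -> harmonic powers."""
    period = estimate_stride_period(trial, axis=axis, search_range=search_range)
    seg = extract_and_average_cycles(trial, period, n_cycles, m_points)
    return fourier_features(seg)


def cohort_feature_frame(trials, **kwargs) -> pd.DataFrame:
    """Feature rows (omega + 18 powers) for many trials, indexed by id."""
    rows = {}
    for tr in trials:
        rows[tr.participant_id] = extract_features(tr, **kwargs).as_row()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df[feature_names()]
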