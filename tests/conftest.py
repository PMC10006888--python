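import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import gaitfreq as gf
from gaitfreq.features import FeatureTable
from gaitfreq.signal import cohort_feature_frame


@pytest.fixture(scope="session")
def default_cohort():
    cfg = gf.default_config(seed=11)
    participants, trials = gf.generate_cohort(cfg)
    return cfg, participants, trials


@pytest.fixture(scope="session")
def default_table(default_cohort):
    _, participants, trials = default_cohort
    fdf = cohort_feature_frame(trials)
    return gf.build_feature_table(participants, fdf), fdf


def single_harmonic_config(seed, axis="cc", harmonic=1, power=1.0, **overrides):
    """Noiseless, jitter-free single-subject config with one planted harmonic.

    A unit fundamental is also planted on the CC axis (unless that is the
    axis under test) so the stride period remains identifiable.
    """
    cfg = gf.default_config(
        seed=seed,
        n_patients=0,
        n_controls=1,
        noise_sd=0.0,
        phase_jitter_sd=0.0,
        power_log_sd=0.0,
        **overrides,
    )
    profile = {ax: np.zeros(6) for ax in ("cc", "ap", "ml")}
    profile[axis][harmonic - 1] = power
    if axis != "cc" or harmonic != 1:
        profile["cc"][0] = max(profile["cc"][0], 1.0)
    cfg.harmonic_power_profile["control"] = profile
    cfg.harmonic_power_profile["patient"] = {
        ax: v.copy() for ax, v in profile.items()
    }
    return cfg


def random_problem(seed, n=40, p=3, signal=1.0):
    """Small standardized design with a logistic outcome; returns FeatureTable."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = signal * rng.normal(size=p)
    prob = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.uniform(size=n) < prob).astype(int)
    if y.min() == y.max():  # both classes required
        y[0] = 1 - y[0]
    cols = [f"x{j}" for j in range(p)]
    return FeatureTable(
        pd.DataFrame(X, columns=cols), pd.Series(y, name="knee_oa")
    )


def lbfgs_objective_oracle(X, y, lam):
    """Direct minimization of the penalized logistic objective by a generic
    smooth-convex solver.

    The l1 term is handled by the standard split beta = b+ - b- with
    nonnegativity bounds, leaving a smooth convex problem for L-BFGS-B;
    entirely independent of the coordinate-descent path code.
    """
    n, p = X.shape
    yt = 2.0 * y - 1.0

    def fun(params):
        b0, bp, bm = params[0], params[1 : p + 1], params[p + 1 :]
        beta = bp - bm
        eta = b0 + X @ beta
        val = np.mean(np.logaddexp(0.0, -yt * eta)) + lam * (bp.sum() + bm.sum())
        d = -yt * (1 / (1 + np.exp(yt * eta))) / n
        gb = X.T @ d
        grad = np.concatenate([[d.sum()], gb + lam, -gb + lam])
        return val, grad

    x0 = np.zeros(2 * p + 1)
    bounds = [(None, None)] + [(0, None)] * (2 * p)
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return res.fun


def make_trial(x_cc, fs=12.5, pid="t1", x_ap=None, x_ml=None):
    """AccelTrial from a raw CC-axis array (AP/ML default to zeros)."""
    n = len(x_cc)
    t = np.arange(n) / fs
    zero = np.zeros(n)
    cols = np.column_stack(
        [t, x_cc, zero if x_ap is None else x_ap, zero if x_ml is None else x_ml]
    )
    return gf.AccelTrial(pid, fs, cols)
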