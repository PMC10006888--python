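"""Post-selection inference for the logistic LASSO at a fixed penalty.

Conditional ("selective") confidence intervals and p-values for the active
coefficients, valid conditional on the LASSO having selected that active
set with those signs.  The binomial fit is mapped to its Gaussian one-step
approximation (working response and weights at the solution, dispersion
fixed at 1); the selection event {sign(beta_E) = s_E} is a polyhedron in
the one-step estimator, and the polyhedral lemma yields truncated-Gaussian
pivots for each active coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .features import FeatureTable
from .lasso import FitAtLambda, _sigmoid


@dataclass
class SelectiveCI:
    """Per-active-feature estimates, truncated-Gaussian CIs and p-values."""

    lam: float
    table: pd.DataFrame  # index: feature; columns: coefficient, estimate,
    # lower, upper, p_value, flagged


def _norm_logsf(x):
    return log_ndtr(-np.asarray(x, dtype=float))


def _truncnorm_cdf(x, mu, sigma, a, b) -> float:
    """P(Z <= x | a <= Z <= b) for Z ~ N(mu, sigma^2), tail-stable."""
    xa, xb, xx = (a - mu) / sigma, (b - mu) / sigma, (x - mu) / sigma
    xx = min(max(xx, xa), xb)
    if xa == xb:
        return np.nan
    if xa + xb > 0:
        # right tail: work with survival functions in log space
        la, lb, lx = _norm_logsf([xa, xb, xx])
        num = -np.exp(la) * np.expm1(lx - la)
        den = -np.exp(la) * np.expm1(lb - la)
    else:
        la, lb, lx = log_ndtr([xa, xb, xx])
        num = -np.exp(lx) * np.expm1(la - lx)
        den = -np.exp(lb) * np.expm1(la - lb)
    if den <= 0 or not np.isfinite(den):
        return np.nan
    return float(np.clip(num / den, 0.0, 1.0))


def _ci_from_pivot(x, sigma, a, b, alpha=0.05):
    """Invert the truncated-Gaussian pivot over mu; returns (lo, hi, ok).

    F(x; mu) is monotone decreasing in mu, so each bound is a bisection.
    Falls back over a widened grid when the pivot is numerically flat.
    """

    def pivot(mu):
        return _truncnorm_cdf(x, mu, sigma, a, b)

    def solve(target):
        lo, hi = x - 30.0 * sigma, x + 30.0 * sigma
        plo, phi = pivot(lo), pivot(hi)
        if np.isnan(plo) or np.isnan(phi) or not (phi <= target <= plo):
            return None
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            pm = pivot(mid)
            if np.isnan(pm):
                return None
            if pm > target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lo = solve(1.0 - alpha / 2.0)
    hi = solve(alpha / 2.0)
    if lo is not None and hi is not None:
        return lo, hi, True
    # grid fallback: scan a wide mu range for where the pivot crosses
    grid = x + sigma * np.linspace(-50, 50, 4001)
    vals = np.array([pivot(m) for m in grid])
    ok = np.isfinite(vals)
    inside = grid[ok & (vals >= alpha / 2.0) & (vals <= 1.0 - alpha / 2.0)]
    if inside.size:
        return float(inside.min()), float(inside.max()), False
    z = 1.959963984540054
    return x - z * sigma, x + z * sigma, False


def selective_inference(
    fit: FitAtLambda, table: FeatureTable, alpha: float = 0.05
) -> SelectiveCI:
    """Selective 95% CIs and p-values for the active set at ``fit.lam``.

    Conditions on the active set and its signs via the polyhedral lemma
    applied to the one-step (debiased) estimator of the active submodel.
    Raises when nothing is selected; degenerate truncation intervals fall
    back to a widened grid / unconditional interval and are flagged.
    """
    beta = fit.coefficients
    active = list(beta.index[beta != 0])
    if not active:
        raise ValueError("nothing selected: active set is empty")
    Xs = table.standardized().to_numpy(dtype=float)
    y = table.y.to_numpy(dtype=float)
    n = len(y)
    idx = [list(beta.index).index(a) for a in active]
    signs = np.sign(beta.to_numpy()[idx])

    M = np.column_stack([np.ones(n), Xs[:, idx]])
    eta = fit.intercept + Xs @ beta.to_numpy()
    prob = np.clip(_sigmoid(eta), 1e-9, 1 - 1e-9)
    w = prob * (1.0 - prob)
    info = M.T @ (M * w[:, None])
    Sigma = np.linalg.inv(info)
    bhat = np.concatenate([[fit.intercept], beta.to_numpy()[idx]])
    bbar = bhat + Sigma @ (M.T @ (y - prob))

    lam_u = fit.lam * n  # penalty in unscaled-gradient units
    s_tilde = np.concatenate([[0.0], signs])
    offset = lam_u * Sigma @ s_tilde
    # sign constraints: s_r * (bbar - offset)_{r+1} >= 0   =>   A bbar <= b
    k = len(active)
    A = np.zeros((k, k + 1))
    A[np.arange(k), np.arange(1, k + 1)] = -signs
    b = -signs * offset[1:]

    rows = []
    for r, name in enumerate(active):
        j = r + 1
        sigma_j = float(np.sqrt(Sigma[j, j]))
        c = Sigma[:, j] / Sigma[j, j]
        x_obs = float(bbar[j])
        z0 = bbar - c * x_obs
        rho = A @ c
        resid = b - A @ z0
        with np.errstate(divide="ignore"):
            lower_set = resid[rho < 0] / rho[rho < 0]
            upper_set = resid[rho > 0] / rho[rho > 0]
        vminus = float(lower_set.max()) if lower_set.size else -np.inf
        vplus = float(upper_set.min()) if upper_set.size else np.inf

        flagged = False
        if not vminus < vplus:
            # numerically degenerate truncation: widen to the whole line
            vminus, vplus, flagged = -np.inf, np.inf, True
        F0 = _truncnorm_cdf(x_obs, 0.0, sigma_j, vminus, vplus)
        if np.isnan(F0):
            p = np.nan
            flagged = True
        else:
            p = 2.0 * min(F0, 1.0 - F0)
        lo, hi, ok = _ci_from_pivot(x_obs, sigma_j, vminus, vplus, alpha)
        rows.append(
            {
                "feature": name,
                "coefficient": float(beta[name]),
                "estimate": x_obs,
                "lower": lo,
                "upper": hi,
                "p_value": p,
                "flagged": flagged or not ok,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    return SelectiveCI(fit.lam, out)
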