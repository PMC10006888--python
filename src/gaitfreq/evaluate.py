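"""Classification performance by repeated stratified 75/25 splits.

Per repeat: stratified split, train-only standardization, penalty selection
by internal 10-fold CV (1-SE rule) on the training set, fit at that
penalty, and held-out prediction at threshold 0.5.  Accuracy and Cohen's
kappa are recorded per repeat; means carry normal-approximation 95% CIs
(mean +/- 1.96 * sd / sqrt(n_repeats)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .features import FeatureTable, Scaler
from .lasso import _path_arrays, _sigmoid, cv_select_lambda, lambda_grid

_Z95 = 1.959963984540054


def cohen_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from the marginals."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    n = len(y_true)
    po = float(np.mean(y_true == y_pred))
    pe = 0.0
    for c in (0, 1):
        pe += np.mean(y_true == c) * np.mean(y_pred == c)
    if pe >= 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


@dataclass
class EvalResult:
    """Per-repeat accuracies and kappas with summary CIs and protocol metadata."""

    accuracies: np.ndarray
    kappas: np.ndarray
    lambdas_used: np.ndarray
    n_repeats: int
    train_frac: float
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_kappa(self) -> float:
        return float(self.kappas.mean())

    def _ci(self, x):
        half = _Z95 * x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
        return (float(x.mean() - half), float(x.mean() + half))

    @property
    def accuracy_ci(self):
        return self._ci(self.accuracies)

    @property
    def kappa_ci(self):
        return self._ci(self.kappas)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "mean_kappa": self.mean_kappa,
            "kappa_ci": list(self.kappa_ci),
            "accuracies": self.accuracies.tolist(),
            "kappas": self.kappas.tolist(),
            "lambdas_used": self.lambdas_used.tolist(),
            "n_repeats": self.n_repeats,
            "train_frac": self.train_frac,
            "seed": self.seed,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _split_seeds(seed: int, n_repeats: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_repeats)]


def evaluate(
    table: FeatureTable,
    n_repeats: int = 10,
    train_frac: float = 0.75,
    seed: int = 0,
    k_inner: int = 10,
    lambda_fixed: float | None = None,
    _seeds: list | None = None,
) -> EvalResult:
    """Repeated stratified hold-out evaluation of the LASSO classifier.

    ``lambda_fixed`` bypasses per-split penalty re-selection (both modes are
    supported; re-selection inside each training set is the default and
    avoids selection leakage).
    """
    y = table.y
    n_val = int(round(table.n * (1 - train_frac)))
    if n_val < 4:
        raise ValueError("validation set would have fewer than 4 observations")
    if y.nunique() < 2:
        raise ValueError("both classes must be present")
    seeds = _seeds if _seeds is not None else _split_seeds(seed, n_repeats)

    accs, kaps, lams = [], [], []
    for rs in seeds:
        for attempt in range(20):
            tr_idx, te_idx = train_test_split(
                table.X.index,
                test_size=1 - train_frac,
                stratify=y,
                random_state=rs + attempt,
            )
            if y.loc[te_idx].nunique() == 2 and y.loc[tr_idx].nunique() == 2:
                break
        else:
            raise ValueError("could not draw a split with both classes")
        train = table.subset_rows(tr_idx)
        if lambda_fixed is None:
            lam = cv_select_lambda(train, k=k_inner, seed=rs).lambda_1se
        else:
            lam = float(lambda_fixed)
        scaler = Scaler.fit(train.X, train.continuous)
        Xtr = scaler.transform(train.X).to_numpy(dtype=float)
        Xte = scaler.transform(table.X.loc[te_idx]).to_numpy(dtype=float)
        grid = np.append(lambda_grid()[lambda_grid() > lam], lam)
        b0s, coefs, _, _ = _path_arrays(
            Xtr, y.loc[tr_idx].to_numpy(dtype=float), grid, train.columns,
            check=False,
        )
        prob = _sigmoid(b0s[-1] + Xte @ coefs[-1])
        pred = (prob > 0.5).astype(int)
        truth = y.loc[te_idx].to_numpy()
        accs.append(float(np.mean(pred == truth)))
        kaps.append(cohen_kappa(truth, pred))
        lams.append(lam)
    return EvalResult(
        np.array(accs), np.array(kaps), np.array(lams),
        n_repeats, train_frac, seed,
    )


def compare_models(
    table: FeatureTable,
    seed: int = 0,
    n_repeats: int = 10,
    train_frac: float = 0.75,
    k_inner: int = 10,
):
    """Evaluate the full table and its confounder-only (age, BMI, omega)
    subset on identical splits; returns ``(full, confounders)``."""
    seeds = _split_seeds(seed, n_repeats)
    full = evaluate(
        table, n_repeats, train_frac, seed, k_inner, _seeds=seeds
    )
    conf = evaluate(
        table.confounder_subset(), n_repeats, train_frac, seed, k_inner,
        _seeds=seeds,
    )
    return full, conf
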