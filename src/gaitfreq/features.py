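"""Assembly and standardization of the 22-variable explanatory table.

Explanatory variables: age, sex, BMI, the fundamental angular stride
frequency omega, and 18 harmonic powers (P(f_1..6) on each of the CC, AP
and ML axes).  Outcome: knee-OA status (1 = patient, 0 = control).
Continuous columns are standardized to zero mean / unit variance; sex is a
0/1 code (female = 1) and is left unscaled.  Scaling parameters are kept so
held-out rows can be standardized with training-set statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import feature_names

CONFOUNDERS = ("age", "bmi", "omega")


def explanatory_columns() -> list[str]:
    return ["age", "sex", "bmi"] + feature_names()


@dataclass
class Scaler:
    """Per-column means/SDs of the continuous variables."""

    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame, continuous: list[str]) -> "Scaler":
        mu = X[continuous].mean()
        sd = X[continuous].std(ddof=0)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(f"zero-variance column(s): {list(zero.index)}")
        return cls(mu, sd)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        cols = self.means.index
        out[cols] = (X[cols] - self.means) / self.sds
        return out


class FeatureTable:
    """Raw explanatory table + outcome + standardization parameters.

    ``X`` holds raw (unstandardized) values so cross-validation folds can be
    re-standardized with train-only statistics; ``standardized()`` applies
    the stored whole-table scaling.
    """

    def __init__(self, X: pd.DataFrame, y: pd.Series, continuous=None):
        if X.isna().any().any() or y.isna().any():
            raise ValueError("missing values in feature table")
        if "sex" in X.columns and not set(X["sex"].unique()) <= {0, 1}:
            raise ValueError("sex column must be coded 0/1")
        self.X = X
        self.y = y.astype(int)
        self.continuous = list(
            continuous
            if continuous is not None
            else [c for c in X.columns if c != "sex"]
        )
        self.scaler = Scaler.fit(X, self.continuous)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def standardized(self) -> pd.DataFrame:
        return self.scaler.transform(self.X)

    def standardize_rows(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Apply this table's scaling to held-out raw rows."""
        return self.scaler.transform(rows)

    def subset_rows(self, index) -> "FeatureTable":
        """New table (with re-fit scaling) on a row subset."""
        return FeatureTable(
            self.X.loc[index].copy(), self.y.loc[index].copy(), self.continuous
        )

    def confounder_subset(self) -> "FeatureTable":
        """Only the potential confounders age, BMI and omega (sex excluded)."""
        cols = [c for c in CONFOUNDERS if c in self.X.columns]
        return FeatureTable(self.X[cols].copy(), self.y.copy(), cols)

    # -- persistence --------------------------------------------------------

    def to_csv(self, path):
        df = self.X.copy()
        df["knee_oa"] = self.y
        df.to_csv(path)
        side = Path(str(path)).with_suffix(".scaling.json")
        side.write_text(
            json.dumps(
                {
                    "means": self.scaler.means.to_dict(),
                    "sds": self.scaler.sds.to_dict(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col=0)
        y = df.pop("knee_oa")
        return cls(df, y)


def build_feature_table(participants, features) -> FeatureTable:
    """Join metadata and per-participant Fourier features into a FeatureTable.

    ``features`` maps participant id -> FourierFeatures, or is a DataFrame
    indexed by id with columns omega, P_f1_CC ... P_f6_ML.  Raises when any
    participant lacks features (or vice versa), listing the offending ids.
    """
    if isinstance(features, pd.DataFrame):
        fdf = features.copy()
    else:
        fdf = pd.DataFrame.from_dict(
            {pid: ff.as_row() for pid, ff in features.items()}, orient="index"
        )
    pids = [p.id for p in participants]
    missing = sorted(set(pids) - set(fdf.index))
    extra = sorted(set(fdf.index) - set(pids))
    if missing or extra:
        raise ValueError(
            f"metadata/feature mismatch: missing features for {missing}, "
            f"features without metadata for {extra}"
        )
    meta = pd.DataFrame(
        {
            "age": [p.age for p in participants],
            "sex": [1 if p.sex == "female" else 0 for p in participants],
            "bmi": [p.bmi for p in participants],
        },
        index=pids,
    )
    X = meta.join(fdf.loc[pids])[explanatory_columns()]
    y = pd.Series(
        [1 if p.group == "patient" else 0 for p in participants], index=pids,
        name="knee_oa",
    )
    return FeatureTable(X, y)
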