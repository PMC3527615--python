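"""Splitting, scaling and log transforms for the modelling protocol.

The training protocol holds 80% of the seasonal samples for parameter
adjustment and 20% as a test set used only to monitor generalisation at
each training iteration.  All variables are standardised to zero mean and
unit variance; the scaler is fitted on the full seasonal table and reused
unchanged on the spatial evaluation data, and predictions are mapped back
to abundance units through its inverse.  For conventional statistics the
skewed variables (depth, Chl-a, abundances) are natural-log transformed
while temperature, salinity and day length stay on their native scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import ABUNDANCE_COLUMNS

__all__ = ["Scaler", "SplitSpec", "split_train_test", "fit_scaler", "log_policy",
           "LOG_COLUMNS"]

#: Columns the log-transform policy applies to.
LOG_COLUMNS = [
    "depth_m",
    "chl_a_ug_l",
    *ABUNDANCE_COLUMNS.values(),
    "prokaryotes_1e5_ml",
    "viruses_1e6_ml",
]


@dataclass
class SplitSpec:
    fraction_train: float = 0.8
    seed: int = 0
    stratify_by: str | None = "date"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_train < 1.0:
            raise ValueError("fraction_train must be in (0, 1)")


def split_train_test(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint 80/20 partition, stratified so every level of
    ``stratify_by`` contributes to both subsets where possible.

    Train size is ``round(fraction * n)`` overall; within strata the
    train share is apportioned by largest remainder so the global count
    is exact.
    """
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.fraction_train * n))
    idx = np.arange(n)
    if spec.stratify_by is None:
        perm = rng.permutation(idx)
        train_idx = np.sort(perm[:n_train])
    else:
        strata = table[spec.stratify_by].to_numpy()
        order = []  # (stratum, shuffled members)
        for key in pd.unique(strata):
            members = idx[strata == key]
            order.append(rng.permutation(members))
        quotas = np.array([len(m) * spec.fraction_train for m in order])
        base = np.floor(quotas).astype(int)
        short = n_train - base.sum()
        # largest fractional remainders get the extra slots
        frac_order = np.argsort(-(quotas - base), kind="stable")
        for j in frac_order[:short]:
            base[j] += 1
        train_idx = np.sort(np.concatenate([m[:k] for m, k in zip(order, base)]))
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return table.iloc[mask].copy(), table.iloc[~mask].copy()


@dataclass
class Scaler:
    """Per-column standardisation to zero mean, unit variance (ddof=1)."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.means)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.means:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out

    def transform_matrix(self, table: pd.DataFrame, columns: list[str]) -> np.ndarray:
        X = np.empty((len(table), len(columns)))
        for j, c in enumerate(columns):
            X[:, j] = (table[c].to_numpy(dtype=float) - self.means[c]) / self.sds[c]
        return X

    def inverse(self, values: np.ndarray, column: str) -> np.ndarray:
        return np.asarray(values) * self.sds[column] + self.means[column]

    def to_json(self) -> str:
        return json.dumps({"means": self.means, "sds": self.sds})

    @classmethod
    def from_json(cls, text: str) -> "Scaler":
        d = json.loads(text)
        return cls(means=d["means"], sds=d["sds"])


def fit_scaler(table: pd.DataFrame, columns: list[str]) -> Scaler:
    means, sds = {}, {}
    for c in columns:
        x = table[c].to_numpy(dtype=float)
        sd = float(x.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"column {c!r} has zero variance; cannot scale")
        means[c] = float(x.mean())
        sds[c] = sd
    return Scaler(means=means, sds=sds)


def log_policy(table: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform of depth, Chl-a and all abundance columns;
    temperature, salinity and day length are left untouched."""
    out = table.copy()
    for c in LOG_COLUMNS:
        if c not in out.columns:
            continue
        x = out[c].to_numpy(dtype=float)
        if np.any(x <= 0):
            raise ValueError(f"non-positive value in column {c!r}; cannot log")
        out[c] = np.log(x)
    return out
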