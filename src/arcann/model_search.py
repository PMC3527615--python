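"""Two-phase random-restart architecture screening and model selection.

For each output population, every candidate architecture — an input
subset of 1-3 of the five covariates, 2-15 hidden units, FFW or RBF —
is trained from many random initialisations (phase 1, default 100
restarts); the survivors are re-screened with an order of magnitude more
restarts (phase 2, default 1000).  A candidate's score is its combined
train+test RMSE at the early-stopping iteration, minimised over
restarts.  Final selection regresses observed on predicted abundance on
the independent spatial survey and keeps, among candidates with spatial
r^2 > 0.5, the one whose slope is closest to 1.

All randomness derives from a single master seed: the restart ``i`` of
architecture ``s`` uses ``SeedSequence([master, crc32(s), i])``, so a
phase-2 run with more restarts extends the phase-1 restart stream and
can only improve on it.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_prep import Scaler, SplitSpec, fit_scaler, split_train_test
from .networks import ArchitectureSpec, init_network
from .stats import RegressionFit, linfit
from .synthetic_data import ABUNDANCE_COLUMNS, COVARIATE_COLUMNS
from .training import reconstitute, train_lm

__all__ = [
    "ModelingData",
    "CandidateResult",
    "SelectionRule",
    "NoAdmissibleModelError",
    "prepare_modeling_data",
    "enumerate_candidates",
    "phase1",
    "phase2",
    "evaluate_spatial",
    "evaluate_seasonal",
    "select_best",
    "total_abundance",
    "leaderboard",
]


@dataclass
class ModelingData:
    """Scaled, split data shared by every candidate."""

    seasonal: pd.DataFrame
    spatial: pd.DataFrame
    train: pd.DataFrame
    test: pd.DataFrame
    scaler: Scaler


def prepare_modeling_data(
    seasonal: pd.DataFrame, spatial: pd.DataFrame, split_seed: int = 0
) -> ModelingData:
    """Fit the scaler on the full seasonal table (covariates and targets),
    then split seasonal 80/20 stratified by date."""
    cols = COVARIATE_COLUMNS + list(ABUNDANCE_COLUMNS.values())
    scaler = fit_scaler(seasonal, cols)
    train, test = split_train_test(seasonal, SplitSpec(seed=split_seed))
    return ModelingData(seasonal, spatial, train, test, scaler)


@dataclass
class CandidateResult:
    spec: ArchitectureSpec
    combined_rmse: float
    restart_index: int
    params: np.ndarray
    record_converged_iteration: int
    seasonal_fit: RegressionFit | None = None
    spatial_fit: RegressionFit | None = None
    failed: bool = False

    def network(self):
        from .networks import FFWNetwork, RBFNetwork

        h, d = self.spec.n_hidden, len(self.spec.inputs)
        proto = (
            FFWNetwork(np.zeros((h, d)), np.zeros(h), np.zeros(h), 0.0)
            if self.spec.net_type == "FFW"
            else RBFNetwork(np.zeros((h, d)), np.ones(h), np.zeros(h), 0.0)
        )
        return proto.from_vector(self.params)


@dataclass
class SelectionRule:
    r2_threshold: float = 0.5
    slope_target: float = 1.0


class NoAdmissibleModelError(RuntimeError):
    """No candidate passed the spatial r^2 gate."""


def enumerate_candidates(
    output: str,
    parameters: list[str] | None = None,
    subsets: list[tuple] | None = None,
    hidden_range: tuple[int, int] = (2, 15),
    net_types: tuple[str, ...] = ("FFW", "RBF"),
) -> list[ArchitectureSpec]:
    """All (subset, hidden count, type) candidates for one output.

    Defaults enumerate every subset of 1-3 of the five covariates with
    2-15 hidden units for both families: 25 x 14 x 2 = 700 specs.
    ``subsets`` restricts to an explicit list of input combinations.
    """
    params = sorted(parameters or COVARIATE_COLUMNS)
    if subsets is None:
        subsets = [
            combo
            for k in (1, 2, 3)
            for combo in itertools.combinations(params, k)
        ]
    return [
        ArchitectureSpec(t, tuple(subset), h, output)
        for subset in subsets
        for h in range(hidden_range[0], hidden_range[1] + 1)
        for t in net_types
    ]


def _restart_seed(master: int, spec: ArchitectureSpec, restart: int):
    return np.random.SeedSequence([master, zlib.crc32(spec.spec_id.encode()), restart])


def _train_one_spec(
    spec: ArchitectureSpec,
    data: ModelingData,
    restarts: int,
    master_seed: int,
    max_iter: int,
) -> CandidateResult:
    cols = list(spec.inputs)
    ycol = ABUNDANCE_COLUMNS[spec.output]
    X_tr = data.scaler.transform_matrix(data.train, cols)
    X_te = data.scaler.transform_matrix(data.test, cols)
    y_tr = data.scaler.transform_matrix(data.train, [ycol])[:, 0]
    y_te = data.scaler.transform_matrix(data.test, [ycol])[:, 0]
    best = None
    for i in range(restarts):
        rng = np.random.default_rng(_restart_seed(master_seed, spec, i))
        net = init_network(spec, X_tr, rng)
        record = train_lm(net, (X_tr, y_tr), (X_te, y_te), max_iter=max_iter)
        k = record.converged_iteration
        combined = float(record.combined[k])
        if not np.isfinite(combined):
            continue
        if best is None or combined < best.combined_rmse:
            best = CandidateResult(
                spec=spec,
                combined_rmse=combined,
                restart_index=i,
                params=reconstitute(record),
                record_converged_iteration=k,
            )
    if best is None:
        return CandidateResult(spec, np.inf, -1, np.empty(0), -1, failed=True)
    return best


def phase1(
    specs: list[ArchitectureSpec],
    data: ModelingData,
    restarts: int = 100,
    master_seed: int = 0,
    max_iter: int = 100,
) -> list[CandidateResult]:
    """Best-of-restarts screening; failed specs are flagged and excluded."""
    results = []
    for spec in specs:
        res = _train_one_spec(spec, data, restarts, master_seed, max_iter)
        if not res.failed:
            results.append(res)
    return results


def phase2(
    shortlist: list[ArchitectureSpec],
    data: ModelingData,
    restarts: int = 1000,
    master_seed: int = 0,
    max_iter: int = 100,
) -> list[CandidateResult]:
    """Re-screen a shortlist with more restarts drawn from the same
    per-spec stream (a superset of phase 1's when restarts is larger)."""
    if not shortlist:
        raise ValueError("empty shortlist")
    out = []
    for spec in shortlist:
        res = _train_one_spec(spec, data, restarts, master_seed, max_iter)
        res.seasonal_fit = evaluate_seasonal(res, data)
        res.spatial_fit = evaluate_spatial(res, data)
        out.append(res)
    return out


def _predict_abundance(result: CandidateResult, table: pd.DataFrame,
                       scaler: Scaler) -> np.ndarray:
    X = scaler.transform_matrix(table, list(result.spec.inputs))
    yhat_scaled = result.network().forward(X)
    return scaler.inverse(yhat_scaled, ABUNDANCE_COLUMNS[result.spec.output])


def evaluate_spatial(result: CandidateResult, data: ModelingData) -> RegressionFit:
    """Observed-vs-predicted regression on the spatial survey, in
    abundance units (observed on y, predicted on x)."""
    if len(data.spatial) < 3:
        raise ValueError("need at least 3 spatial rows")
    pred = _predict_abundance(result, data.spatial, data.scaler)
    obs = data.spatial[ABUNDANCE_COLUMNS[result.spec.output]].to_numpy(float)
    return linfit(pred, obs)


def evaluate_seasonal(result: CandidateResult, data: ModelingData) -> RegressionFit:
    """Observed-vs-predicted regression on the combined train+test data."""
    pred = _predict_abundance(result, data.seasonal, data.scaler)
    obs = data.seasonal[ABUNDANCE_COLUMNS[result.spec.output]].to_numpy(float)
    return linfit(pred, obs)


def select_best(
    results: list[CandidateResult], rule: SelectionRule | None = None
) -> CandidateResult:
    """Among candidates with spatial r^2 above the gate, pick the slope
    closest to the target (1); break ties by smaller combined RMSE."""
    rule = rule or SelectionRule()
    if not results:
        raise ValueError("no candidate results")
    admissible = [
        r for r in results
        if r.spatial_fit is not None and r.spatial_fit.r2 > rule.r2_threshold
    ]
    if not admissible:
        raise NoAdmissibleModelError(
            f"no candidate exceeded spatial r^2 {rule.r2_threshold}"
        )
    return min(
        admissible,
        key=lambda r: (abs(r.spatial_fit.slope - rule.slope_target), r.combined_rmse),
    )


def total_abundance(pred_a: np.ndarray, pred_b: np.ndarray) -> np.ndarray:
    """Element-wise sum of two aligned component predictions."""
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("predictions are not aligned")
    return a + b


def predict_abundance(result: CandidateResult, table: pd.DataFrame,
                      scaler: Scaler) -> np.ndarray:
    """Public helper: model predictions for a table, in abundance units."""
    return _predict_abundance(result, table, scaler)


def leaderboard(results: list[CandidateResult]) -> pd.DataFrame:
    """Candidate summary table (one row per architecture)."""
    rows = []
    for r in sorted(results, key=lambda r: r.combined_rmse):
        row = {
            "inputs": ",".join(r.spec.inputs),
            "output": r.spec.output,
            "type": r.spec.net_type,
            "units": r.spec.n_hidden,
            "rmse": r.combined_rmse,
        }
        if r.seasonal_fit is not None:
            row.update(
                r2=r.seasonal_fit.r2,
                intercept=r.seasonal_fit.intercept,
                k=r.seasonal_fit.slope,
            )
        if r.spatial_fit is not None:
            row.update(
                r2_spatial=r.spatial_fit.r2,
                intercept_spatial=r.spatial_fit.intercept,
                k_spatial=r.spatial_fit.slope,
            )
        rows.append(row)
    return pd.DataFrame(rows)
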