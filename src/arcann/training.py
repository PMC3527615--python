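"""Levenberg-Marquardt training with an early-stopping training record.

The trainer runs a fixed number of outer LM iterations (default 100) on
the training data and, at every iteration, records a snapshot of the
parameter vector together with the RMSE on the training set and on a
held-out test set.  The test set never influences the parameter update;
it exists only so that "convergence" can be defined after the fact as
the iteration minimising RMSE_train + RMSE_test.  Reconstitution restores
the snapshot at that minimum, which guards against over-training in
oversized networks.

Each outer iteration proposes the damped Gauss-Newton step
``delta = -(J'J + mu*I)^-1 J'r``; an accepted step (training SSE
decreased) divides the damping ``mu`` by 10, a rejected one multiplies it
by 10 and retries, up to 10 inner attempts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrainingRecord", "rmse", "train_lm", "reconstitute"]

_MU_INIT = 1e-2
_MU_MIN, _MU_MAX = 1e-12, 1e12
_MAX_INNER = 10


def rmse(predictions: np.ndarray, observations: np.ndarray) -> float:
    """Root-mean-squared error between two equal-length vectors."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predictions and observations must be same non-zero length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


@dataclass
class TrainingRecord:
    """Per-iteration snapshots and error trajectories (index 0 = initial)."""

    snapshots: list = field(default_factory=list)  # parameter vectors
    rmse_train: list = field(default_factory=list)
    rmse_test: list = field(default_factory=list)
    mu_trajectory: list = field(default_factory=list)
    failed: bool = False

    @property
    def combined(self) -> np.ndarray:
        return np.asarray(self.rmse_train) + np.asarray(self.rmse_test)

    @property
    def converged_iteration(self) -> int:
        """Index of the combined-RMSE minimum; ties go to the earliest."""
        return int(np.argmin(self.combined))


def reconstitute(record: TrainingRecord) -> np.ndarray:
    """Parameter snapshot at the combined-RMSE minimum."""
    if not record.snapshots:
        raise ValueError("empty training record")
    return np.asarray(record.snapshots[record.converged_iteration])


def train_lm(net, train, test, max_iter: int = 100) -> TrainingRecord:
    """Train ``net`` in place-free style for exactly ``max_iter`` outer
    LM iterations, recording train/test RMSE at every iteration.

    Parameters
    ----------
    net:
        FFW or RBF network providing ``forward``, ``residual_jacobian``,
        ``to_vector`` and ``from_vector``.
    train, test:
        ``(X, y)`` pairs of scaled covariates and scaled targets.
    """
    X_tr, y_tr = train
    X_te, y_te = test
    if X_tr.shape[0] == 0:
        raise ValueError("empty training set")
    record = TrainingRecord()
    theta = net.to_vector()
    current = net.from_vector(theta)
    r = current.forward(X_tr) - y_tr
    sse = float(r @ r)

    def log_state(model):
        record.snapshots.append(model.to_vector())
        record.rmse_train.append(rmse(model.forward(X_tr), y_tr))
        record.rmse_test.append(rmse(model.forward(X_te), y_te))

    log_state(current)
    mu = _MU_INIT
    record.mu_trajectory.append(mu)
    eye = np.eye(theta.size)
    for _ in range(max_iter):
        J = current.residual_jacobian(X_tr)
        g = J.T @ r
        H = J.T @ J
        accepted = False
        for _attempt in range(_MAX_INNER):
            try:
                delta = np.linalg.solve(H + mu * eye, -g)
            except np.linalg.LinAlgError:
                mu = min(mu * 10.0, _MU_MAX)
                continue
            if not np.all(np.isfinite(delta)):
                mu = min(mu * 10.0, _MU_MAX)
                continue
            candidate = current.from_vector(current.to_vector() + delta)
            r_new = candidate.forward(X_tr) - y_tr
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                current, r, sse = candidate, r_new, sse_new
                mu = max(mu / 10.0, _MU_MIN)
                accepted = True
                break
            mu = min(mu * 10.0, _MU_MAX)
        if not accepted and mu >= _MU_MAX:
            record.failed = True
        log_state(current)
        record.mu_trajectory.append(mu)
    return record
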