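"""Feed-forward and radial-basis-function regression networks.

Both families map a small covariate vector (1-3 standardised inputs) to a
single unconstrained output:

* FFW: one sigmoid hidden layer, ``y = sum_j w_out_j * sigmoid(w_j.x + b_j)
  + b_out``; bias units (fixed input 1) feed both the hidden and the
  output layer, so the parameter count is ``h(d+1) + (h+1)``.
* RBF: a weighted sum of isotropic Gaussian bumps,
  ``y = sum_j w_j * exp(-|x - c_j|^2 / (2 lam_j^2)) + b_out``; the only
  bias sits in the output layer, giving ``h(d+2) + 1`` parameters.

Parameters flatten to/from a single vector (for the Levenberg-Marquardt
trainer) and each family supplies the analytic Jacobian of its residuals
with respect to that vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FFWNetwork",
    "RBFNetwork",
    "ArchitectureSpec",
    "init_network",
    "network_from_json",
]

_HIDDEN_RANGE = (2, 15)


@dataclass
class ArchitectureSpec:
    """(network family, input subset, hidden-unit count, output)."""

    net_type: str  # "FFW" | "RBF"
    inputs: tuple  # 1-3 covariate column names
    n_hidden: int  # 2..15
    output: str  # "hna" | "lna" | "v1" | "v2"

    def __post_init__(self) -> None:
        if self.net_type not in ("FFW", "RBF"):
            raise ValueError(f"unknown network type {self.net_type!r}")
        self.inputs = tuple(self.inputs)
        if not 1 <= len(self.inputs) <= 3:
            raise ValueError("input subset must have 1-3 covariates")
        if not _HIDDEN_RANGE[0] <= self.n_hidden <= _HIDDEN_RANGE[1]:
            raise ValueError(f"hidden count must be in {_HIDDEN_RANGE}")

    @property
    def spec_id(self) -> str:
        return f"{self.output}:{self.net_type}:{self.n_hidden}:{','.join(self.inputs)}"


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class FFWNetwork:
    """Single-hidden-layer sigmoid network with hidden and output biases."""

    w_hidden: np.ndarray  # (h, d)
    b_hidden: np.ndarray  # (h,)
    w_out: np.ndarray  # (h,)
    b_out: float

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def n_params(self) -> int:
        h, d = self.w_hidden.shape
        return h * (d + 1) + (h + 1)

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.w_hidden.ravel(), self.b_hidden, self.w_out, [self.b_out]]
        )

    def from_vector(self, v: np.ndarray) -> "FFWNetwork":
        h, d = self.w_hidden.shape
        v = np.asarray(v, dtype=float)
        return FFWNetwork(
            w_hidden=v[: h * d].reshape(h, d).copy(),
            b_hidden=v[h * d : h * d + h].copy(),
            w_out=v[h * d + h : h * d + 2 * h].copy(),
            b_out=float(v[-1]),
        )

    def forward(self, X: np.ndarray) -> np.ndarray:
        act = _sigmoid(X @ self.w_hidden.T + self.b_hidden)
        return act @ self.w_out + self.b_out

    def residual_jacobian(self, X: np.ndarray) -> np.ndarray:
        """d(prediction)/d(theta), shape (n, n_params); residual r = yhat - y
        shares this Jacobian since y is constant."""
        n = X.shape[0]
        h, d = self.w_hidden.shape
        act = _sigmoid(X @ self.w_hidden.T + self.b_hidden)  # (n, h)
        dact = act * (1.0 - act)
        J = np.empty((n, self.n_params))
        # hidden weights: w_out_j * act'_j * x_k
        J[:, : h * d] = ((self.w_out * dact)[:, :, None] * X[:, None, :]).reshape(
            n, h * d
        )
        J[:, h * d : h * d + h] = self.w_out * dact  # hidden biases
        J[:, h * d + h : h * d + 2 * h] = act  # output weights
        J[:, -1] = 1.0  # output bias
        return J


@dataclass
class RBFNetwork:
    """Gaussian radial-basis network; bias in the output layer only."""

    centers: np.ndarray  # (h, d)
    widths: np.ndarray  # (h,) > 0
    w_out: np.ndarray  # (h,)
    b_out: float

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.centers.shape[0]

    @property
    def n_params(self) -> int:
        h, d = self.centers.shape
        return h * (d + 2) + 1

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.centers.ravel(), self.widths, self.w_out, [self.b_out]]
        )

    def from_vector(self, v: np.ndarray) -> "RBFNetwork":
        h, d = self.centers.shape
        v = np.asarray(v, dtype=float)
        return RBFNetwork(
            centers=v[: h * d].reshape(h, d).copy(),
            widths=v[h * d : h * d + h].copy(),
            w_out=v[h * d + h : h * d + 2 * h].copy(),
            b_out=float(v[-1]),
        )

    def _basis(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        diff = X[:, None, :] - self.centers[None, :, :]  # (n, h, d)
        sq = np.einsum("nhd,nhd->nh", diff, diff)
        phi = np.exp(-sq / (2.0 * self.widths**2))
        return phi, diff

    def forward(self, X: np.ndarray) -> np.ndarray:
        phi, _ = self._basis(X)
        return phi @ self.w_out + self.b_out

    def residual_jacobian(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        h, d = self.centers.shape
        phi, diff = self._basis(X)
        sq = np.einsum("nhd,nhd->nh", diff, diff)
        J = np.empty((n, self.n_params))
        # centers: w_j * phi_j * (x - c_j) / lam_j^2
        J[:, : h * d] = (
            (self.w_out * phi / self.widths**2)[:, :, None] * diff
        ).reshape(n, h * d)
        # widths: w_j * phi_j * |x - c_j|^2 / lam_j^3
        J[:, h * d : h * d + h] = self.w_out * phi * sq / self.widths**3
        J[:, h * d + h : h * d + 2 * h] = phi  # output weights
        J[:, -1] = 1.0
        return J


def init_network(
    spec: ArchitectureSpec, train_X: np.ndarray, rng: np.random.Generator
):
    """Random initialisation tied to the data range.

    Non-linear parameters are placed inside the per-dimension range of
    the (scaled) training inputs: FFW sigmoid inflection points fall on a
    random in-range point, RBF centers are uniform in-range with widths
    0.2-2x the per-dimension spread.  Linear parameters (output weights
    and bias) are iid Uniform(-1, 1).
    """
    X = np.asarray(train_X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("train_X must be a non-empty 2-D array")
    d = X.shape[1]
    if d != len(spec.inputs):
        raise ValueError("train_X width does not match the input subset")
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate (zero-range) input column")
    h = spec.n_hidden
    if spec.net_type == "FFW":
        w = rng.uniform(-1.0, 1.0, size=(h, d))
        # anchor each unit's inflection hyperplane at an in-range point
        anchor = rng.uniform(lo, hi, size=(h, d))
        b = -np.einsum("hd,hd->h", w, anchor)
        return FFWNetwork(
            w_hidden=w,
            b_hidden=b,
            w_out=rng.uniform(-1.0, 1.0, size=h),
            b_out=float(rng.uniform(-1.0, 1.0)),
        )
    centers = rng.uniform(lo, hi, size=(h, d))
    spread = float((hi - lo).mean())
    widths = rng.uniform(0.2 * spread, 2.0 * spread, size=h)
    return RBFNetwork(
        centers=centers,
        widths=widths,
        w_out=rng.uniform(-1.0, 1.0, size=h),
        b_out=float(rng.uniform(-1.0, 1.0)),
    )


def network_to_json(net, spec: ArchitectureSpec) -> str:
    return json.dumps(
        {
            "net_type": spec.net_type,
            "inputs": list(spec.inputs),
            "n_hidden": spec.n_hidden,
            "output": spec.output,
            "params": net.to_vector().tolist(),
        }
    )


def network_from_json(text: str):
    d = json.loads(text)
    spec = ArchitectureSpec(d["net_type"], tuple(d["inputs"]), d["n_hidden"], d["output"])
    h, dim = spec.n_hidden, len(spec.inputs)
    if spec.net_type == "FFW":
        proto = FFWNetwork(
            np.zeros((h, dim)), np.zeros(h), np.zeros(h), 0.0
        )
    else:
        proto = RBFNetwork(np.zeros((h, dim)), np.ones(h), np.zeros(h), 0.0)
    return proto.from_vector(np.array(d["params"])), spec
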