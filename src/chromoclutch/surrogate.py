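"""Force-matched surrogate free-energy model over inter-nucleosome distances.

A small multilayer perceptron maps the vector of pairwise nucleosome center
distances (z-scored with training statistics) to a scalar free energy in
kcal/mol.  Its parameters are fitted by *force matching*: minimizing the mean
squared deviation between the model's negative center-coordinate gradients
and reference mean forces supplied with each training configuration.

The network is trained on small oligonucleosomes (tetranucleosomes by
default); energies of longer arrays are composed as a sum of sliding-window
evaluations over consecutive 4-mers — a documented composition choice, not a
uniquely determined transfer rule.  Exhaustive Monte Carlo sampling of the
surrogate under umbrella biases proposes the most probable configurations at
a given bias, which the package uses only to *initialize* toy-simulator
sampling; all reported free energies come from the simulator plus WHAM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _autodiff as ad
from .constants import kt
from .structures import ChromatinConfig, NucleosomeFrame

__all__ = [
    "featurize",
    "feature_jacobian",
    "SurrogateModel",
    "train_force_matching",
    "mc_most_probable",
]


def _centers_of(config_or_centers) -> np.ndarray:
    if isinstance(config_or_centers, ChromatinConfig):
        return config_or_centers.all_centers()
    return np.asarray(config_or_centers, dtype=float)


def featurize(config_or_centers) -> np.ndarray:
    """Pairwise center distances in fixed (i < j) lexicographic order.

    A 12mer yields 66 features, a tetranucleosome 6.  Distances are
    invariant under any rigid motion of the configuration.
    """
    centers = _centers_of(config_or_centers)
    i, j = np.triu_indices(len(centers), 1)
    return np.linalg.norm(centers[i] - centers[j], axis=1)


def feature_jacobian(config_or_centers) -> np.ndarray:
    """d(distance_f)/d(center coordinates): shape (3n, n(n-1)/2)."""
    centers = _centers_of(config_or_centers)
    n = len(centers)
    ii, jj = np.triu_indices(n, 1)
    d = centers[ii] - centers[jj]
    r = np.linalg.norm(d, axis=1)
    if np.any(r <= 0):
        raise ValueError("coincident centers: distance gradient undefined")
    u = d / r[:, None]
    G = np.zeros((3 * n, len(ii)))
    for f, (a, b) in enumerate(zip(ii, jj)):
        G[3 * a:3 * a + 3, f] = u[f]
        G[3 * b:3 * b + 3, f] = -u[f]
    return G


def _init_params(m: int, hidden: tuple[int, int], rng: np.random.Generator):
    h1, h2 = hidden
    return {
        "W1": rng.normal(0, math.sqrt(1.0 / m), (m, h1)),
        "b1": np.zeros(h1),
        "W2": rng.normal(0, math.sqrt(1.0 / h1), (h1, h2)),
        "b2": np.zeros(h2),
        "w3": rng.normal(0, math.sqrt(1.0 / h2), h2),
        "b3": np.zeros(()),
    }


@dataclass
class SurrogateModel:
    """Trained surrogate: standardized distances -> free energy (kcal/mol)."""

    n_body: int
    hidden: tuple[int, int]
    mean: np.ndarray            # feature standardization, training statistics
    std: np.ndarray
    params: dict
    training: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.n_body * (self.n_body - 1) // 2

    # -- forward / gradients -------------------------------------------------

    def _energy_grad_window(self, centers: np.ndarray) -> tuple[float, np.ndarray]:
        """Energy and its gradient w.r.t. one window's center coordinates."""
        d = featurize(centers)
        if len(d) != self.n_features:
            raise ValueError("feature length mismatch with model spec")
        x = (d - self.mean) / self.std
        p = self.params
        a1 = x @ p["W1"] + p["b1"]
        h1 = np.tanh(a1)
        a2 = h1 @ p["W2"] + p["b2"]
        h2 = np.tanh(a2)
        E = float(h2 @ p["w3"] + p["b3"])
        u2 = (1 - h2**2) * p["w3"]
        u1 = (1 - h1**2) * (p["W2"] @ u2)
        dE_dx = p["W1"] @ u1
        dE_dd = dE_dx / self.std
        G = feature_jacobian(centers)
        return E, (G @ dE_dd).reshape(-1, 3)

    def energy(self, config_or_centers) -> float:
        """Surrogate free energy; longer arrays sum sliding n_body windows."""
        centers = _centers_of(config_or_centers)
        n = len(centers)
        if n < self.n_body:
            raise ValueError(f"need >= {self.n_body} nucleosomes")
        return sum(
            self._energy_grad_window(centers[i:i + self.n_body])[0]
            for i in range(n - self.n_body + 1)
        )

    def forces(self, config_or_centers) -> np.ndarray:
        """Negative energy gradient on every center, kcal/(mol nm)."""
        centers = _centers_of(config_or_centers)
        n = len(centers)
        grad = np.zeros((n, 3))
        for i in range(n - self.n_body + 1):
            _, g = self._energy_grad_window(centers[i:i + self.n_body])
            grad[i:i + self.n_body] += g
        return -grad

    # -- serialization (single JSON file, text only) -------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_body": self.n_body,
            "hidden": list(self.hidden),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "params": {k: np.asarray(v).tolist() for k, v in self.params.items()},
            "training": {k: v for k, v in self.training.items()
                         if k != "loss_curve"} |
                        {"loss_curve": [float(x) for x in
                                        self.training.get("loss_curve", [])]},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_body=d["n_body"],
            hidden=tuple(d["hidden"]),
            mean=np.array(d["mean"]),
            std=np.array(d["std"]),
            params={k: np.array(v) for k, v in d["params"].items()},
            training=d.get("training", {}),
        )


def _force_loss_graph(params: dict[str, ad.Var], X: np.ndarray,
                      Gs_neg: np.ndarray, F_ref: np.ndarray) -> ad.Var:
    """Autodiff graph of the force-matching loss for one batch.

    ``X`` standardized features (B, m); ``Gs_neg`` = -(dd/dc)/std, shape
    (B, 3n, m); ``F_ref`` reference forces flattened to (B, 3n).
    """
    one = ad.Var(1.0)
    Xv = ad.Var(X)
    a1 = ad.add(ad.matmul(Xv, params["W1"]), params["b1"])
    h1 = ad.tanh(a1)
    a2 = ad.add(ad.matmul(h1, params["W2"]), params["b2"])
    h2 = ad.tanh(a2)
    D1 = ad.sub(one, ad.square(h1))
    D2 = ad.sub(one, ad.square(h2))
    u2 = ad.mul(D2, params["w3"])                      # (B, H2)
    u1 = ad.mul(D1, ad.matmul(u2, _transpose(params["W2"])))
    Jx = ad.matmul(u1, _transpose(params["W1"]))       # (B, m) = dE/dx
    F_pred = ad.contract_bcm(Gs_neg, Jx)               # (B, 3n)
    return ad.mean_all(ad.square(ad.sub(F_pred, ad.Var(F_ref))))


def _transpose(a: ad.Var) -> ad.Var:
    out = ad.Var(a.value.T, (a,))
    out._backward = lambda g: ad._acc(a, g.T)
    return out


def train_force_matching(
    configs: Sequence,
    forces: Sequence[np.ndarray],
    hidden: tuple[int, int] = (64, 64),
    lr: float = 1e-2,
    epochs: int = 2000,
    val_frac: float = 0.1,
    seed: int = 0,
) -> SurrogateModel:
    """Fit the surrogate so -grad(NN) matches reference mean forces.

    Full-batch Adam with an exponentially decayed learning rate (``lr`` down
    to ``lr/10``) on a 90/10 train/validation split (every 10th example
    validates).  Deterministic for a given seed, and duplicating every
    training example leaves the mean-gradient loss, and hence the fit,
    unchanged.  Returns the model with its loss curve and held-out force
    RMSE recorded in ``model.training``.
    """
    if len(configs) < 100:
        raise ValueError("need >= 100 training configurations")
    if len(configs) != len(forces):
        raise ValueError("configs and forces must align")
    centers = np.stack([_centers_of(c) for c in configs])   # (B, n, 3)
    F_ref = np.stack([np.asarray(f, float) for f in forces])
    if F_ref.shape != centers.shape:
        raise ValueError("forces must be per-center 3-vectors")
    if not np.all(np.isfinite(F_ref)):
        raise ValueError("non-finite reference forces")
    B, n_body, _ = centers.shape
    m = n_body * (n_body - 1) // 2

    feats = np.stack([featurize(c) for c in centers])
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std = np.where(std > 1e-12, std, 1.0)
    X = (feats - mean) / std
    Gs_neg = np.stack([-feature_jacobian(c) / std[None, :] for c in centers])
    F_flat = F_ref.reshape(B, -1)

    # deterministic stride split: every k-th example validates; duplicating
    # the whole data set (with B a multiple of k) then reproduces the exact
    # same full-batch mean gradients and hence the same fit
    k_stride = max(2, int(round(1 / val_frac)))
    idx = np.arange(B)
    val_idx = idx[idx % k_stride == 0]
    train_idx = idx[idx % k_stride != 0]
    n_val = len(val_idx)

    rng = np.random.default_rng(seed)
    raw = _init_params(m, hidden, rng)
    params = {k: ad.Var(v, requires_grad=True) for k, v in raw.items()
              if k != "b3"}
    # Adam state
    mom = {k: np.zeros_like(v.value) for k, v in params.items()}
    vel = {k: np.zeros_like(v.value) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    loss_curve = []
    Xt, Gt, Ft = X[train_idx], Gs_neg[train_idx], F_flat[train_idx]
    for t in range(1, epochs + 1):
        lr_t = lr * (0.1 ** (t / epochs))  # exponential decay to lr/10
        loss = _force_loss_graph(params, Xt, Gt, Ft)
        loss.backward()
        loss_curve.append(float(loss.value))
        for k, v in params.items():
            g = v.grad
            mom[k] = beta1 * mom[k] + (1 - beta1) * g
            vel[k] = beta2 * vel[k] + (1 - beta2) * g * g
            mhat = mom[k] / (1 - beta1**t)
            vhat = vel[k] / (1 - beta2**t)
            v.value = v.value - lr_t * mhat / (np.sqrt(vhat) + eps)

    model = SurrogateModel(
        n_body=n_body,
        hidden=hidden,
        mean=mean,
        std=std,
        params={k: v.value for k, v in params.items()} | {"b3": raw["b3"]},
    )
    # held-out force RMSE
    pred = np.stack([model.forces(c) for c in centers[val_idx]])
    resid = pred - F_ref[val_idx]
    rmse = float(np.sqrt(np.mean(resid**2)))
    rms_ref = float(np.sqrt(np.mean(F_ref[val_idx] ** 2)))
    model.training = {
        "seed": seed,
        "epochs": epochs,
        "lr": lr,
        "n_train": int(len(train_idx)),
        "n_val": int(n_val),
        "loss_curve": loss_curve,
        "holdout_force_rmse": rmse,
        "holdout_force_rms_ref": rms_ref,
    }
    return model


_MC_BIASABLE = ("d_stack", "q_wrap")


def mc_most_probable(
    model: SurrogateModel | None,
    n_nucleosomes: int,
    biases: Sequence = (),
    steps: int = 20000,
    seed: int = 0,
    start: np.ndarray | None = None,
    min_separation: float = 4.0,
    temperature_K: float = 300.0,
    trans_sigma: float = 0.6,
) -> ChromatinConfig:
    """Most probable configuration of surrogate + bias energy, by Metropolis MC.

    Samples nucleosome centers (and wrap fractions when a q_wrap umbrella is
    present; the surrogate itself is wrap-blind) and returns the
    lowest-energy configuration visited.  Moves creating center pairs closer
    than ``min_separation`` nm are rejected to keep features inside the
    training domain.  ``model=None`` means a zero-energy network: the
    returned structure minimizes the bias alone.
    """
    for b in biases:
        if b.kind == "umbrella" and b.cv not in _MC_BIASABLE:
            raise ValueError(
                f"surrogate MC cannot bias CV {b.cv!r}; supported: {_MC_BIASABLE}"
            )
    rng = np.random.default_rng(seed)
    n = n_nucleosomes
    if start is None:
        centers = np.column_stack(
            [np.zeros(n), np.zeros(n), 5.0 * np.arange(n, dtype=float)]
        )
    else:
        centers = np.asarray(start, float).copy()
    wraps = np.ones(n)
    kT = kt(temperature_K)
    wrap_moves = any(b.kind == "umbrella" and b.cv == "q_wrap" for b in biases)

    def bias_energy(c, w):
        e = 0.0
        for b in biases:
            if b.kind != "umbrella":
                continue
            if b.cv == "d_stack":
                x = float(np.mean(np.linalg.norm(c[2:] - c[:-2], axis=1)))
            else:
                x = float(w.mean())
            e += 0.5 * b.spring_k * (x - b.center) ** 2
        return e

    def surrogate_energy(c):
        return model.energy(c) if model is not None else 0.0

    def min_sep_ok(c, k):
        d = np.linalg.norm(c - c[k], axis=1)
        d[k] = np.inf
        return d.min() >= min_separation

    e_sur = surrogate_energy(centers)
    e_bias = bias_energy(centers, wraps)
    best = (e_sur + e_bias, centers.copy(), wraps.copy())
    for _ in range(steps):
        k = int(rng.integers(n))
        if wrap_moves and rng.random() < 0.25:
            w_old = wraps[k]
            w_new = min(1.0, max(0.5, w_old + rng.uniform(-0.05, 0.05)))
            wraps[k] = w_new
            e_bias_new = bias_energy(centers, wraps)
            dE = e_bias_new - e_bias
            if dE <= 0 or rng.random() < math.exp(-dE / kT):
                e_bias = e_bias_new
            else:
                wraps[k] = w_old
        else:
            delta = rng.normal(0, trans_sigma, 3)
            centers[k] += delta
            if not min_sep_ok(centers, k):
                centers[k] -= delta
                continue
            e_sur_new = surrogate_energy(centers)
            e_bias_new = bias_energy(centers, wraps)
            dE = (e_sur_new + e_bias_new) - (e_sur + e_bias)
            if dE <= 0 or rng.random() < math.exp(-dE / kT):
                e_sur, e_bias = e_sur_new, e_bias_new
            else:
                centers[k] -= delta
        if e_sur + e_bias < best[0]:
            best = (e_sur + e_bias, centers.copy(), wraps.copy())

    _, c_best, w_best = best
    frames = [
        NucleosomeFrame(0, i, c_best[i], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0],
                        float(w_best[i]))
        for i in range(n)
    ]
    return ChromatinConfig([frames])
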