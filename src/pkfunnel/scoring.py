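"""Graph-convolutional scoring heads for (pocket graph, ligand graph) pairs.

Two model kinds share one architecture and differ only in the output head:

* ``BC`` — binary binder/non-binder classifier; logistic output in [0, 1],
  values near 1 meaning high binding probability;
* ``RG`` — affinity regressor on the pKa scale, where
  ``pKa = -log10(Kx)`` and ``Kx`` is a molar IC50, Ki or Kd
  (so pKa 9 corresponds to 1 nM).

Each input graph passes through its own stack of graph-convolution layers
(symmetric-normalized adjacency with self-loops, ReLU), is pooled to a
fixed-length vector by concatenated global mean and max pooling (both
permutation-invariant), and the two pooled embeddings feed a small dense
combiner.  The implementation is plain NumPy with hand-written reverse-mode
gradients and an Adam optimizer; a numerical-gradient test in the suite
pins the backward pass to the forward definition.

Everything is deterministic given (weights, inputs); weight initialization
is a pure function of the model seed.  A schema fingerprint (feature layout
+ layer shapes) travels with every checkpoint so that a trained model
refuses graphs featurized under a different schema instead of silently
mis-scoring them.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .graphs import EMBEDDING_DIM, LIGAND_FEATURE_DIM, LIGAND_FEATURE_NAMES, LigandGraph, PocketGraph

__all__ = [
    "Affinity",
    "GCNScoringModel",
    "SchemaMismatchError",
    "TrainConfig",
    "pka_from_affinity",
    "affinity_from_pka",
    "bc_score",
    "rg_score",
    "train",
]


class SchemaMismatchError(ValueError):
    """Graph feature layout does not match the model's schema fingerprint."""


def pka_from_affinity(kx_molar: float) -> float:
    """pKa = -log10(Kx) for a molar affinity Kx (IC50, Ki or Kd).

    Raises for non-positive affinities (log undefined).
    """
    if kx_molar <= 0:
        raise ValueError(f"affinity must be positive molar, got {kx_molar}")
    return -math.log10(kx_molar)


def affinity_from_pka(pka: float) -> float:
    """Inverse transform: Kx = 10**(-pKa), molar."""
    return 10.0 ** (-pka)


@dataclass
class Affinity:
    """A molar affinity and its pKa, kept consistent by construction."""

    kx: float

    def __post_init__(self) -> None:
        if self.kx <= 0:
            raise ValueError("Kx must be positive")

    @property
    def pka(self) -> float:
        return pka_from_affinity(self.kx)


def _normalized_adjacency(adj: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^-1/2 (A + I) D^-1/2 with self-loops."""
    a = adj + np.eye(adj.shape[0])
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 0.01
    seed: int = 0


@dataclass
class GCNScoringModel:
    kind: str                       # "BC" or "RG"
    pocket_dim: int = EMBEDDING_DIM
    ligand_dim: int = LIGAND_FEATURE_DIM
    hidden: int = 16
    combiner_hidden: int = 32
    seed: int = 0
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("BC", "RG"):
            raise ValueError(f"model kind must be 'BC' or 'RG', got {self.kind!r}")
        if not self.params:
            self.params = self._init_params()

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        h, c = self.hidden, self.combiner_hidden

        def dense(fan_in: int, fan_out: int) -> np.ndarray:
            return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)

        return {
            "p_W1": dense(self.pocket_dim, h), "p_b1": np.zeros(h),
            "p_W2": dense(h, h), "p_b2": np.zeros(h),
            "l_W1": dense(self.ligand_dim, h), "l_b1": np.zeros(h),
            "l_W2": dense(h, h), "l_b2": np.zeros(h),
            "W3": dense(4 * h, c), "b3": np.zeros(c),
            "w4": dense(c, 1)[:, 0], "b4": np.zeros(1),
        }

    def schema_fingerprint(self) -> str:
        payload = json.dumps(
            {
                "kind": self.kind,
                "pocket_dim": self.pocket_dim,
                "ligand_dim": self.ligand_dim,
                "hidden": self.hidden,
                "combiner_hidden": self.combiner_hidden,
                "pocket_embedding_dim": EMBEDDING_DIM,
                "ligand_feature_names": LIGAND_FEATURE_NAMES[: self.ligand_dim],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def copy(self) -> "GCNScoringModel":
        return GCNScoringModel(
            kind=self.kind,
            pocket_dim=self.pocket_dim,
            ligand_dim=self.ligand_dim,
            hidden=self.hidden,
            combiner_hidden=self.combiner_hidden,
            seed=self.seed,
            params={k: v.copy() for k, v in self.params.items()},
        )

    # -- checkpointing (text JSON; adequate at the scales this runs at) -----

    def to_json(self) -> str:
        return json.dumps(
            {
                "fingerprint": self.schema_fingerprint(),
                "kind": self.kind,
                "pocket_dim": self.pocket_dim,
                "ligand_dim": self.ligand_dim,
                "hidden": self.hidden,
                "combiner_hidden": self.combiner_hidden,
                "seed": self.seed,
                "params": {k: v.tolist() for k, v in self.params.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GCNScoringModel":
        payload = json.loads(text)
        model = cls(
            kind=payload["kind"],
            pocket_dim=payload["pocket_dim"],
            ligand_dim=payload["ligand_dim"],
            hidden=payload["hidden"],
            combiner_hidden=payload["combiner_hidden"],
            seed=payload["seed"],
            params={k: np.asarray(v, dtype=float) for k, v in payload["params"].items()},
        )
        if model.schema_fingerprint() != payload["fingerprint"]:
            raise SchemaMismatchError(
                "checkpoint fingerprint does not match the current feature schema"
            )
        return model

    # -- forward ------------------------------------------------------------

    def _check_schema(self, pocket: PocketGraph, ligand: LigandGraph) -> None:
        if pocket.node_features.shape[1] != self.pocket_dim:
            raise SchemaMismatchError(
                f"pocket features have dim {pocket.node_features.shape[1]}, "
                f"model expects {self.pocket_dim}"
            )
        if ligand.node_features.shape[1] != self.ligand_dim:
            raise SchemaMismatchError(
                f"ligand features have dim {ligand.node_features.shape[1]}, "
                f"model expects {self.ligand_dim}"
            )

    def _branch_forward(self, prefix: str, x: np.ndarray, a_hat: np.ndarray) -> dict:
        p = self.params
        m1 = a_hat @ x
        z1 = m1 @ p[f"{prefix}_W1"] + p[f"{prefix}_b1"]
        h1 = np.maximum(z1, 0.0)
        m2 = a_hat @ h1
        z2 = m2 @ p[f"{prefix}_W2"] + p[f"{prefix}_b2"]
        h2 = np.maximum(z2, 0.0)
        argmax = h2.argmax(axis=0)
        pooled = np.concatenate([h2.mean(axis=0), h2[argmax, np.arange(h2.shape[1])]])
        return {
            "a_hat": a_hat, "m1": m1, "z1": z1, "h1": h1,
            "m2": m2, "z2": z2, "h2": h2, "argmax": argmax, "pooled": pooled,
        }

    def forward(self, pocket: PocketGraph, ligand: LigandGraph) -> tuple[float, dict]:
        """Raw head output (pre-squash) plus the cache needed for backprop."""
        self._check_schema(pocket, ligand)
        p = self.params
        cp = self._branch_forward("p", pocket.node_features, _normalized_adjacency(pocket.adjacency()))
        cl = self._branch_forward("l", ligand.node_features, _normalized_adjacency(ligand.adjacency()))
        u = np.concatenate([cp["pooled"], cl["pooled"]])
        z3 = u @ p["W3"] + p["b3"]
        h3 = np.maximum(z3, 0.0)
        y = float(h3 @ p["w4"] + p["b4"][0])
        return y, {"p": cp, "l": cl, "u": u, "z3": z3, "h3": h3}

    def _branch_backward(
        self, prefix: str, x: np.ndarray, cache: dict, d_pooled: np.ndarray,
        grads: dict[str, np.ndarray],
    ) -> None:
        p = self.params
        h = self.hidden
        n = cache["h2"].shape[0]
        d_mean, d_max = d_pooled[:h], d_pooled[h:]
        d_h2 = np.tile(d_mean / n, (n, 1))
        d_h2[cache["argmax"], np.arange(h)] += d_max
        d_z2 = d_h2 * (cache["z2"] > 0)
        grads[f"{prefix}_W2"] += cache["m2"].T @ d_z2
        grads[f"{prefix}_b2"] += d_z2.sum(axis=0)
        d_h1 = cache["a_hat"].T @ (d_z2 @ p[f"{prefix}_W2"].T)
        d_z1 = d_h1 * (cache["z1"] > 0)
        grads[f"{prefix}_W1"] += cache["m1"].T @ d_z1
        grads[f"{prefix}_b1"] += d_z1.sum(axis=0)

    def backward(
        self, pocket: PocketGraph, ligand: LigandGraph, cache: dict, d_y: float,
        grads: dict[str, np.ndarray],
    ) -> None:
        """Accumulate d(loss)/d(params) into ``grads`` given d(loss)/d(head)."""
        p = self.params
        grads["b4"] += np.array([d_y])
        grads["w4"] += cache["h3"] * d_y
        d_h3 = p["w4"] * d_y
        d_z3 = d_h3 * (cache["z3"] > 0)
        grads["W3"] += np.outer(cache["u"], d_z3)
        grads["b3"] += d_z3
        d_u = p["W3"] @ d_z3
        half = 2 * self.hidden
        self._branch_backward("p", pocket.node_features, cache["p"], d_u[:half], grads)
        self._branch_backward("l", ligand.node_features, cache["l"], d_u[half:], grads)

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}


def _sigmoid(y: float) -> float:
    if y >= 0:
        return 1.0 / (1.0 + math.exp(-y))
    e = math.exp(y)
    return e / (1.0 + e)


def bc_score(model: GCNScoringModel, pocket: PocketGraph, ligand: LigandGraph) -> float:
    """Binder probability in [0, 1] (logistic squash of the head output)."""
    if model.kind != "BC":
        raise ValueError("bc_score requires a BC-kind model")
    y, _ = model.forward(pocket, ligand)
    return _sigmoid(y)


def rg_score(model: GCNScoringModel, pocket: PocketGraph, ligand: LigandGraph) -> float:
    """Predicted binding affinity on the pKa scale (unbounded real)."""
    if model.kind != "RG":
        raise ValueError("rg_score requires an RG-kind model")
    y, _ = model.forward(pocket, ligand)
    return y


def loss_and_grads(
    model: GCNScoringModel,
    dataset: list[tuple[PocketGraph, LigandGraph, float]],
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean loss over the batch and its parameter gradients.

    BC uses binary cross-entropy on the logistic output; RG uses squared
    error on the raw (pKa-scale) output.
    """
    grads = model.zero_grads()
    total = 0.0
    m = len(dataset)
    for pocket, ligand, label in dataset:
        y, cache = model.forward(pocket, ligand)
        if model.kind == "BC":
            p = _sigmoid(y)
            eps = 1e-12
            total += -(label * math.log(p + eps) + (1 - label) * math.log(1 - p + eps))
            d_y = (p - label) / m
        else:
            total += (y - label) ** 2
            d_y = 2.0 * (y - label) / m
        model.backward(pocket, ligand, cache, d_y, grads)
    return total / m, grads


def train(
    model: GCNScoringModel,
    dataset: list[tuple[PocketGraph, LigandGraph, float]],
    config: TrainConfig | None = None,
) -> tuple[GCNScoringModel, list[float]]:
    """Full-batch Adam training; returns (updated model copy, loss trace).

    The input model is not mutated.  Given identical (model, dataset,
    config) the returned weights are bit-identical across runs: weight
    init is seeded and the optimization has no sampling.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    if config is None:
        config = TrainConfig()
    if model.kind == "BC":
        for _, _, label in dataset:
            if not 0.0 <= label <= 1.0:
                raise ValueError("BC labels must lie in [0, 1]")

    out = model.copy()
    trace: list[float] = []
    m1 = {k: np.zeros_like(v) for k, v in out.params.items()}
    m2 = {k: np.zeros_like(v) for k, v in out.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for step in range(1, config.epochs + 1):
        loss, grads = loss_and_grads(out, dataset)
        trace.append(loss)
        for k in out.params:
            m1[k] = beta1 * m1[k] + (1 - beta1) * grads[k]
            m2[k] = beta2 * m2[k] + (1 - beta2) * grads[k] ** 2
            m1_hat = m1[k] / (1 - beta1**step)
            m2_hat = m2[k] / (1 - beta2**step)
            out.params[k] -= config.learning_rate * m1_hat / (np.sqrt(m2_hat) + eps)
    return out, trace
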