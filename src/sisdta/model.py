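"""Affinity regression network.

Architecture (per drug–target pair):

1. Per-entity encoders: each feature view flagged ``propagate`` passes
   through a two-layer graph convolution over the entity's similarity graph,
   ``X' = act(D̂^{-1/2} Â D̂^{-1/2} X Θ)``; raw views are passed through
   unchanged.  The per-view outputs are concatenated column-wise.
2. The drug and protein embeddings of a pair are concatenated into the pair
   feature H^I.
3. An autoencoder reduces H^I to a latent code; the decoder reconstructs
   H^D, and a small fully connected head maps the latent code to the
   predicted affinity ŷ.
4. Joint loss: mean squared prediction error plus mean squared
   reconstruction error, equally weighted,

       loss = (1/q) Σ (Y_k − Ŷ_k)² + (1/q) Σ mean_dims (H_k^I − H_k^D)².

Everything is plain NumPy: forward and backward passes are written out for
this fixed computation graph and verified against finite differences in the
test suite.  Training is full-batch Adam; all randomness flows from a single
integer seed, so identical seeds give bitwise-identical loss histories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, DomainError, InputError
from .featurize import FeatureView
from .graphs import NormalizedAdjacency

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GCNLayerParams:
    """One graph-convolution layer: learnable Θ plus a named activation."""

    theta: np.ndarray  # (d, k)
    activation: str = "relu"  # "relu" or "identity"


def _activate(Z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(Z, 0.0)
    if activation == "identity":
        return Z
    raise ConfigError(f"unknown activation {activation!r}")


def gcn_layer(X: np.ndarray, A_norm: NormalizedAdjacency | np.ndarray, params: GCNLayerParams) -> np.ndarray:
    """activation(Â_norm · X · Θ) — one propagation step."""
    A = A_norm.matrix if isinstance(A_norm, NormalizedAdjacency) else np.asarray(A_norm)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != A.shape[0]:
        raise InputError(f"node count mismatch: X has {X.shape[0]} rows, graph has {A.shape[0]}")
    if X.shape[1] != params.theta.shape[0]:
        raise InputError(
            f"width mismatch: X has {X.shape[1]} columns, theta expects {params.theta.shape[0]}"
        )
    return _activate(A @ X @ params.theta, params.activation)


@dataclass
class ModelConfig:
    """Widths and view wiring; defaults sized for desk-scale data."""

    gcn_hidden: int = 64
    gcn_out: int = 32
    latent_dim: int = 32
    head_hidden: int = 32
    recon_weight: float = 1.0  # Eq-form default: both loss terms weighted 1


@dataclass
class OptimizerConfig:
    lr: float = 1e-2
    epochs: int = 200
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def pair_feature(drug_vec: np.ndarray, protein_vec: np.ndarray) -> np.ndarray:
    """Concatenate drug then protein embedding into H^I."""
    return np.concatenate([np.asarray(drug_vec, float), np.asarray(protein_vec, float)])


def joint_loss(
    Y: Sequence[float],
    Y_hat: Sequence[float],
    H_I: np.ndarray,
    H_D: np.ndarray,
    recon_weight: float = 1.0,
) -> float:
    """Prediction MSE plus reconstruction MSE over q pairs.

    Vector residuals (H^I − H^D) reduce by the mean over components so the
    two terms share scale.
    """
    Y = np.asarray(Y, float)
    Y_hat = np.asarray(Y_hat, float)
    H_I = np.atleast_2d(np.asarray(H_I, float))
    H_D = np.atleast_2d(np.asarray(H_D, float))
    q = len(Y)
    if not (len(Y_hat) == H_I.shape[0] == H_D.shape[0] == q) or q < 1:
        raise InputError("Y, Y_hat, H_I, H_D must all have the same positive length")
    mse_term = float(np.mean((Y - Y_hat) ** 2))
    recon_term = float(np.mean((H_I - H_D) ** 2))
    return mse_term + recon_weight * recon_term


# ---------------------------------------------------------------------------
# parameter container and forward/backward


def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


class AffinityModel:
    """Full model state: views, graphs, parameters, and configuration.

    The forward pass is a pure function of (parameters, inputs); training
    mutates parameters only through Adam steps driven by the seeded
    initialization, so runs are reproducible.
    """

    def __init__(
        self,
        drug_views: list[FeatureView],
        protein_views: list[FeatureView],
        drug_adj: NormalizedAdjacency,
        protein_adj: NormalizedAdjacency,
        config: ModelConfig,
        seed: int = 0,
    ):
        self.drug_views = drug_views
        self.protein_views = protein_views
        self.A_d = drug_adj.matrix
        self.A_p = protein_adj.matrix
        self.config = config
        self.seed = seed
        self.drug_ids = list(drug_views[0].entity_ids)
        self.protein_ids = list(protein_views[0].entity_ids)
        for v in drug_views:
            if v.entity_ids != self.drug_ids:
                raise InputError(f"drug view {v.name!r}: entity ordering mismatch")
        for v in protein_views:
            if v.entity_ids != self.protein_ids:
                raise InputError(f"protein view {v.name!r}: entity ordering mismatch")
        if len(self.drug_ids) != self.A_d.shape[0]:
            raise InputError("drug graph size does not match drug views")
        if len(self.protein_ids) != self.A_p.shape[0]:
            raise InputError("protein graph size does not match protein views")

        c = config
        self._drug_idx = {d: i for i, d in enumerate(self.drug_ids)}
        self._prot_idx = {p: i for i, p in enumerate(self.protein_ids)}

        def entity_width(views: list[FeatureView]) -> int:
            return sum(c.gcn_out if v.propagate else v.dims for v in views)

        self.pair_width = entity_width(drug_views) + entity_width(protein_views)
        if c.latent_dim >= self.pair_width:
            raise ConfigError(
                f"latent_dim {c.latent_dim} must be smaller than pair width {self.pair_width}"
            )

        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for tag, views in (("d", drug_views), ("p", protein_views)):
            for v in views:
                if v.propagate:
                    self.params[f"{tag}:{v.name}:W1"] = _glorot(rng, v.dims, c.gcn_hidden)
                    self.params[f"{tag}:{v.name}:W2"] = _glorot(rng, c.gcn_hidden, c.gcn_out)
        D = self.pair_width
        self.params["We"] = _glorot(rng, D, c.latent_dim)
        self.params["be"] = np.zeros(c.latent_dim)
        self.params["Wd"] = _glorot(rng, c.latent_dim, D)
        self.params["bd"] = np.zeros(D)
        self.params["Wh1"] = _glorot(rng, c.latent_dim, c.head_hidden)
        self.params["bh1"] = np.zeros(c.head_hidden)
        self.params["Wh2"] = _glorot(rng, c.head_hidden, 1)
        self.params["bh2"] = np.zeros(1)

    # -- forward pieces ----------------------------------------------------

    def _encode_entities(self, tag: str, views: list[FeatureView], A: np.ndarray, cache: dict | None = None):
        blocks = []
        for v in views:
            if v.propagate:
                pre1 = A @ v.matrix @ self.params[f"{tag}:{v.name}:W1"]
                h1 = np.maximum(pre1, 0.0)
                z = A @ h1 @ self.params[f"{tag}:{v.name}:W2"]
                if cache is not None:
                    cache[f"{tag}:{v.name}"] = (pre1, h1)
                blocks.append(z)
            else:
                blocks.append(v.matrix)
        return np.concatenate(blocks, axis=1)

    def encode_entity(self, which: str) -> np.ndarray:
        """Entity embedding matrix for 'drug' or 'protein' under current parameters."""
        if which == "drug":
            return self._encode_entities("d", self.drug_views, self.A_d)
        if which == "protein":
            return self._encode_entities("p", self.protein_views, self.A_p)
        raise ConfigError(f"unknown entity type {which!r}")

    def autoencode(self, H_I: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(latent, reconstruction) of pair features; both pure in parameters."""
        H_I = np.atleast_2d(np.asarray(H_I, float))
        U = H_I @ self.params["We"] + self.params["be"]
        L = np.maximum(U, 0.0)
        H_D = L @ self.params["Wd"] + self.params["bd"]
        return L, H_D

    def _forward(self, di: np.ndarray, pi: np.ndarray, cache: dict | None = None):
        E_d = self._encode_entities("d", self.drug_views, self.A_d, cache)
        E_p = self._encode_entities("p", self.protein_views, self.A_p, cache)
        H_I = np.concatenate([E_d[di], E_p[pi]], axis=1)
        U = H_I @ self.params["We"] + self.params["be"]
        L = np.maximum(U, 0.0)
        H_D = L @ self.params["Wd"] + self.params["bd"]
        preV = L @ self.params["Wh1"] + self.params["bh1"]
        V = np.maximum(preV, 0.0)
        y_hat = (V @ self.params["Wh2"] + self.params["bh2"])[:, 0]
        if cache is not None:
            cache.update(E_d=E_d, E_p=E_p, H_I=H_I, U=U, L=L, H_D=H_D, preV=preV, V=V)
        return y_hat, H_I, H_D

    def predict_pairs(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        """Predicted affinity for each (drug id, protein id) pair, input order preserved."""
        unknown = [p for p in pairs if p[0] not in self._drug_idx or p[1] not in self._prot_idx]
        if unknown:
            raise InputError(f"unknown entity ids in pairs: {unknown[:5]}")
        di = np.array([self._drug_idx[d] for d, _ in pairs], dtype=int)
        pi = np.array([self._prot_idx[p] for _, p in pairs], dtype=int)
        y_hat, _, _ = self._forward(di, pi)
        return y_hat

    # -- backward ----------------------------------------------------------

    def _backward(self, di, pi, y, cache) -> dict[str, np.ndarray]:
        P = self.params
        c = self.config
        q = len(y)
        D = self.pair_width
        H_I, H_D, L, U, preV, V = (
            cache["H_I"], cache["H_D"], cache["L"], cache["U"], cache["preV"], cache["V"],
        )
        y_hat = (V @ P["Wh2"] + P["bh2"])[:, 0]
        g: dict[str, np.ndarray] = {}

        d_yhat = 2.0 * (y_hat - y) / q  # (q,)
        g["Wh2"] = V.T @ d_yhat[:, None]
        g["bh2"] = np.array([d_yhat.sum()])
        dV = d_yhat[:, None] @ P["Wh2"].T
        dpreV = dV * (preV > 0)
        g["Wh1"] = L.T @ dpreV
        g["bh1"] = dpreV.sum(axis=0)
        dL = dpreV @ P["Wh1"].T

        R = 2.0 * c.recon_weight * (H_D - H_I) / (q * D)  # d loss / d H_D
        g["Wd"] = L.T @ R
        g["bd"] = R.sum(axis=0)
        dL += R @ P["Wd"].T

        dU = dL * (U > 0)
        g["We"] = H_I.T @ dU
        g["be"] = dU.sum(axis=0)
        dH_I = dU @ P["We"].T - R  # -R: H^I is also the reconstruction target

        # scatter pair gradients back to entity embeddings
        wd = sum(c.gcn_out if v.propagate else v.dims for v in self.drug_views)
        dEd_pairs, dEp_pairs = dH_I[:, :wd], dH_I[:, wd:]
        dE_d = np.zeros_like(cache["E_d"])
        dE_p = np.zeros_like(cache["E_p"])
        np.add.at(dE_d, di, dEd_pairs)
        np.add.at(dE_p, pi, dEp_pairs)

        for tag, views, A, dE in (
            ("d", self.drug_views, self.A_d, dE_d),
            ("p", self.protein_views, self.A_p, dE_p),
        ):
            col = 0
            for v in views:
                width = c.gcn_out if v.propagate else v.dims
                dZ = dE[:, col : col + width]
                col += width
                if not v.propagate:
                    continue
                pre1, h1 = cache[f"{tag}:{v.name}"]
                Ah1 = A @ h1
                g[f"{tag}:{v.name}:W2"] = Ah1.T @ dZ
                dh1 = A.T @ dZ @ P[f"{tag}:{v.name}:W2"].T
                dpre1 = dh1 * (pre1 > 0)
                g[f"{tag}:{v.name}:W1"] = (A @ v.matrix).T @ dpre1
        return g

    def loss_and_grads(self, di, pi, y) -> tuple[float, dict[str, np.ndarray]]:
        cache: dict = {}
        y_hat, H_I, H_D = self._forward(di, pi, cache)
        loss = joint_loss(y, y_hat, H_I, H_D, self.config.recon_weight)
        return loss, self._backward(di, pi, y, cache)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single .npz archive with config JSON and all parameter tensors."""
        meta = {
            "config": asdict(self.config),
            "seed": self.seed,
            "drug_ids": self.drug_ids,
            "protein_ids": self.protein_ids,
            "drug_views": [
                {"name": v.name, "propagate": v.propagate} for v in self.drug_views
            ],
            "protein_views": [
                {"name": v.name, "propagate": v.propagate} for v in self.protein_views
            ],
        }
        arrays = {f"param:{k}": v for k, v in self.params.items()}
        arrays["A_d"] = self.A_d
        arrays["A_p"] = self.A_p
        for i, v in enumerate(self.drug_views):
            arrays[f"dview:{i}"] = v.matrix
        for i, v in enumerate(self.protein_views):
            arrays[f"pview:{i}"] = v.matrix
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AffinityModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            drug_views = [
                FeatureView(
                    name=dv["name"], entity_ids=meta["drug_ids"],
                    matrix=z[f"dview:{i}"], propagate=dv["propagate"],
                )
                for i, dv in enumerate(meta["drug_views"])
            ]
            protein_views = [
                FeatureView(
                    name=pv["name"], entity_ids=meta["protein_ids"],
                    matrix=z[f"pview:{i}"], propagate=pv["propagate"],
                )
                for i, pv in enumerate(meta["protein_views"])
            ]
            from .graphs import WeightedDigraph

            A_d = NormalizedAdjacency(z["A_d"], WeightedDigraph(meta["drug_ids"], np.eye(len(meta["drug_ids"]))))
            A_p = NormalizedAdjacency(z["A_p"], WeightedDigraph(meta["protein_ids"], np.eye(len(meta["protein_ids"]))))
            model = cls(
                drug_views, protein_views, A_d, A_p,
                ModelConfig(**meta["config"]), seed=meta["seed"],
            )
            for k in model.params:
                model.params[k] = z[f"param:{k}"]
        return model


def encode_entity(views: list[FeatureView], A_norm: NormalizedAdjacency, layers: list[GCNLayerParams]) -> np.ndarray:
    """Standalone entity encoder: propagated views go through the GCN stack,
    raw views pass through; outputs concatenated in declared view order.

    ``layers`` lists one stack shared by all propagated views and is applied
    per view (the trained model keeps per-view stacks; this free function
    serves single-view and inspection use)."""
    blocks = []
    for v in views:
        if v.propagate:
            X = v.matrix
            for lp in layers:
                X = gcn_layer(X, A_norm, lp)
            blocks.append(X)
        else:
            blocks.append(v.matrix)
    return np.concatenate(blocks, axis=1)


def train(
    dataset,
    drug_views: list[FeatureView],
    protein_views: list[FeatureView],
    drug_adj: NormalizedAdjacency,
    protein_adj: NormalizedAdjacency,
    model_config: ModelConfig | None = None,
    optimizer_config: OptimizerConfig | None = None,
    seed: int = 0,
) -> tuple[AffinityModel, list[float]]:
    """Fit the model on the dataset's training pairs with full-batch Adam.

    Returns the fitted model and the per-epoch joint-loss history.  The
    output bias is initialized to the mean training label so the prediction
    term starts at the label variance rather than the raw second moment.
    """
    mc = model_config or ModelConfig()
    oc = optimizer_config or OptimizerConfig()
    pairs, y = dataset.training_pairs()
    if len(pairs) < 1:
        raise InputError("dataset has no labeled training pairs")
    model = AffinityModel(drug_views, protein_views, drug_adj, protein_adj, mc, seed=seed)
    model.params["bh2"] = np.array([float(np.mean(y))])
    di = np.array([model._drug_idx[d] for d, _ in pairs], dtype=int)
    pi = np.array([model._prot_idx[p] for _, p in pairs], dtype=int)
    y = np.asarray(y, float)

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v2 = {k: np.zeros_like(v) for k, v in model.params.items()}
    history: list[float] = []
    for epoch in range(1, oc.epochs + 1):
        loss, grads = model.loss_and_grads(di, pi, y)
        if not np.isfinite(loss):
            raise DomainError(f"non-finite loss at epoch {epoch}")
        history.append(loss)
        for k, gk in grads.items():
            m[k] = oc.beta1 * m[k] + (1 - oc.beta1) * gk
            v2[k] = oc.beta2 * v2[k] + (1 - oc.beta2) * gk**2
            mhat = m[k] / (1 - oc.beta1**epoch)
            vhat = v2[k] / (1 - oc.beta2**epoch)
            model.params[k] = model.params[k] - oc.lr * mhat / (np.sqrt(vhat) + oc.eps)
    return model, history


def predict(model: AffinityModel, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    """Module-level alias for :meth:`AffinityModel.predict_pairs`."""
    return model.predict_pairs(pairs)
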