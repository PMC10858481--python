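"""Latent-variable model coupling a microbiome encoder to a low-rank
linear metabolite decoder.

The model embeds preprocessed (log, z-scored) microbiome profiles ``Mi``
into a low-dimensional representation ``Z`` with a 3-layer fully connected
encoder, then decodes the preprocessed metabolite matrix ``Me`` linearly:

* ``A = Z^+ Me`` — the relation matrix, with ``Z^+ = (Z'Z)^{-1} Z'`` the
  Moore-Penrose pseudo-inverse (a tiny ridge jitter keeps the normal
  equations well-posed);
* ``A* = SVD_r(A)`` — the best rank-r approximation of ``A``, which
  regularizes the decoder against overfitting;
* ``Me_hat = Z A*`` with a mean-squared-error loss.

Everything is trained at once: gradients of the loss flow through the
low-rank truncation and the pseudo-inverse into the encoder (Adam, full
batch).  After training, ``A*`` is frozen from the final (or best) epoch
and prediction for new microbiome-only samples is ``encoder(Mi) A*``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import (Adam, Encoder, lstsq_backward, lstsq_forward,
                  svd_truncate_backward, svd_truncate_forward)

SCHEMA_VERSION = 1


@dataclass
class LatentConfig:
    """Hyperparameters of the latent model.

    The defaults are the shipped fixed setting: a 128->64 hidden encoder
    with elu activations, dropout 0.2, L2 weight penalty 1e-4, Adam at
    1e-3 for 200 full-batch epochs, a 10-dimensional representation and a
    rank-6 decoder truncation.
    """

    latent_dim: int = 10
    hidden_sizes: tuple[int, int] = (128, 64)
    activation: str = "elu"
    dropout_rate: float = 0.2
    l2_weight: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 200
    lowrank_rank: int = 6
    seed: int = 0
    ridge_jitter: float = 1e-8
    use_best_epoch: bool = False

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.lowrank_rank < 1:
            raise ValueError("latent_dim and lowrank_rank must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate must be > 0 and epochs >= 1")
        if self.activation not in {"relu", "elu", "tanh"}:
            raise ValueError("activation must be relu, elu or tanh")


@dataclass
class LatentRepresentation:
    """Latent embedding of a set of samples (rows of ``Z``)."""

    sample_ids: list
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape[0] != len(self.sample_ids):
            raise ValueError("Z row count must match sample_ids")
        if not np.isfinite(self.Z).all():
            raise ValueError("Z contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"z{i}" for i in range(self.Z.shape[1])]
        return pd.DataFrame(self.Z, index=self.sample_ids, columns=cols)


def compute_relation_matrix(Z: np.ndarray, Me: np.ndarray,
                            jitter: float = 0.0) -> np.ndarray:
    """Least-squares relation matrix ``A`` with ``Z A ~= Me``.

    Equivalent to applying the Moore-Penrose pseudo-inverse of ``Z`` to
    ``Me``; a rank-deficient ``Z`` yields the minimum-norm solution with a
    warning.
    """
    Z = np.asarray(Z, dtype=float)
    Me = np.asarray(Me, dtype=float)
    if Z.shape[0] != Me.shape[0]:
        raise ValueError("Z and Me must share the sample axis")
    if Z.shape[0] < Z.shape[1]:
        raise ValueError("need at least latent_dim samples")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        warnings.warn("rank-deficient Z: returning the minimum-norm solution")
        if jitter == 0.0:
            A, *_ = np.linalg.lstsq(Z, Me, rcond=None)
            return A
    if jitter > 0.0:
        A, _ = lstsq_forward(Z, Me, jitter)
        return A
    A, *_ = np.linalg.lstsq(Z, Me, rcond=None)
    return A


def low_rank_approx(A: np.ndarray, rank: int) -> np.ndarray:
    """Best rank-``rank`` approximation of ``A`` (exact truncated SVD)."""
    A = np.asarray(A, dtype=float)
    A_star, _ = svd_truncate_forward(A, rank)
    return A_star


def _as_matrix(X) -> tuple[np.ndarray, list, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[0])), None


class LatentMetaboliteModel:
    """Encoder + pseudo-inverse low-rank decoder, trained end to end.

    ``fit`` expects *preprocessed* matrices (the z-scored log chains); the
    higher-level :class:`~mimelat.pipelines.LatentPipeline` wires the
    preprocessing in front.  Inputs may be DataFrames (feature names are
    then checked at predict time) or plain arrays.
    """

    def __init__(self, config: LatentConfig | None = None, **kwargs):
        if config is None:
            config = LatentConfig(**kwargs)
        elif kwargs:
            raise ValueError("pass either a config or keyword fields")
        self.config = config

    # -- training ---------------------------------------------------------

    def fit(self, Mi, Me) -> "LatentMetaboliteModel":
        cfg = self.config
        X, sample_ids, feat_names = _as_matrix(Mi)
        Y, y_ids, met_names = _as_matrix(Me)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("Mi and Me must have the same number of samples")
        if X.shape[0] < cfg.latent_dim:
            raise ValueError(
                f"need at least latent_dim={cfg.latent_dim} samples, got {X.shape[0]}"
            )
        if cfg.latent_dim >= X.shape[1]:
            raise ValueError("latent_dim must be smaller than the number of features")
        self.feature_names_ = feat_names
        self.metabolite_ids_ = met_names

        rng = np.random.default_rng(cfg.seed)
        enc = Encoder(X.shape[1], cfg.hidden_sizes, cfg.latent_dim,
                      activation=cfg.activation, dropout=cfg.dropout_rate,
                      rng=rng)
        adam = Adam(enc.params, lr=cfg.learning_rate)
        n, m = Y.shape
        size = n * m
        trace = []
        best = (np.inf, None, -1)
        for epoch in range(cfg.epochs):
            Z, cache = enc.forward(X, rng=rng, train=True)
            A, c_ls = lstsq_forward(Z, Y, cfg.ridge_jitter)
            A_star, c_svd = svd_truncate_forward(A, cfg.lowrank_rank)
            R = Z @ A_star - Y
            data_loss = float(np.sum(R * R) / size)
            penalty = cfg.l2_weight * float(sum(np.sum(w * w) for w in enc.weights))
            loss = data_loss + penalty
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: data={data_loss}, "
                    f"penalty={penalty}; try a smaller learning rate"
                )
            # backward
            G_hat = (2.0 / size) * R
            G_Astar = Z.T @ G_hat
            G_Z = G_hat @ A_star.T
            G_A = svd_truncate_backward(G_Astar, c_svd, A.shape)
            G_Z_ls, _ = lstsq_backward(G_A, c_ls)
            G_Z = G_Z + G_Z_ls
            grads = enc.backward(G_Z, cache)
            for i in range(len(enc.weights)):
                grads[i] = grads[i] + 2.0 * cfg.l2_weight * enc.weights[i]
            enc.set_params(adam.step(enc.params, grads))

            # deterministic (dropout-free) loss for the trace / best-epoch
            Z_eval, _ = enc.forward(X, train=False)
            A_eval, _ = lstsq_forward(Z_eval, Y, cfg.ridge_jitter)
            A_star_eval, _ = svd_truncate_forward(A_eval, cfg.lowrank_rank)
            eval_loss = float(np.mean((Z_eval @ A_star_eval - Y) ** 2))
            trace.append(eval_loss)
            if eval_loss < best[0]:
                best = (eval_loss, [p.copy() for p in enc.params], epoch)

        if cfg.use_best_epoch and best[1] is not None:
            enc.set_params(best[1])
        self.encoder_ = enc
        self.loss_trace_ = np.asarray(trace)
        self.best_epoch_ = best[2]
        # freeze Z, A, A* from the final encoder on the full training set
        Z_fin, _ = enc.forward(X, train=False)
        self.Z_ = Z_fin
        self.A_, _ = lstsq_forward(Z_fin, Y, cfg.ridge_jitter)
        self.A_star_, _ = svd_truncate_forward(self.A_, cfg.lowrank_rank)
        self.train_sample_ids_ = sample_ids
        self.final_train_loss_ = float(np.mean((Z_fin @ self.A_star_ - Y) ** 2))
        return self

    # -- inference --------------------------------------------------------

    def _check_input(self, Mi) -> np.ndarray:
        X, ids, names = _as_matrix(Mi)
        if names is not None and self.feature_names_ is not None:
            if names != self.feature_names_:
                missing = [f for f in self.feature_names_ if f not in names]
                extra = [f for f in names if f not in self.feature_names_]
                if missing or extra:
                    raise ValueError(
                        f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}"
                    )
                X = Mi[self.feature_names_].to_numpy(dtype=float)
        if X.shape[1] != self.encoder_.weights[0].shape[0]:
            raise ValueError(
                f"expected {self.encoder_.weights[0].shape[0]} features, got {X.shape[1]}"
            )
        return X

    def embed(self, Mi) -> LatentRepresentation:
        """Latent representation of (preprocessed) microbiome-only samples."""
        X = self._check_input(Mi)
        _, ids, _ = _as_matrix(Mi)
        Z, _ = self.encoder_.forward(X, train=False)
        return LatentRepresentation(sample_ids=ids, Z=Z)

    def predict(self, Mi):
        """Predicted metabolites (z-scored log scale): ``encoder(Mi) A*``."""
        rep = self.embed(Mi)
        Y = rep.Z @ self.A_star_
        if self.metabolite_ids_ is not None:
            return pd.DataFrame(Y, index=rep.sample_ids,
                                columns=self.metabolite_ids_)
        return Y

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize config, encoder weights and ``A*`` to one JSON file."""
        enc = self.encoder_
        payload = {
            "schema_version": SCHEMA_VERSION,
            "config": asdict(self.config),
            "weights": [w.tolist() for w in enc.weights],
            "biases": [b.tolist() for b in enc.biases],
            "A_star": self.A_star_.tolist(),
            "feature_names": self.feature_names_,
            "metabolite_ids": self.metabolite_ids_,
            "final_train_loss": self.final_train_loss_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "LatentMetaboliteModel":
        obj = json.loads(Path(path).read_text())
        if obj["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {obj['schema_version']}")
        cfg = obj["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        model = cls(LatentConfig(**cfg))
        weights = [np.asarray(w) for w in obj["weights"]]
        biases = [np.asarray(b) for b in obj["biases"]]
        enc = Encoder(weights[0].shape[0],
                      (weights[0].shape[1], weights[1].shape[1]),
                      weights[2].shape[1],
                      activation=model.config.activation,
                      dropout=model.config.dropout_rate)
        enc.set_params(weights + biases)
        model.encoder_ = enc
        model.A_star_ = np.asarray(obj["A_star"])
        model.feature_names_ = obj["feature_names"]
        model.metabolite_ids_ = obj["metabolite_ids"]
        model.final_train_loss_ = obj["final_train_loss"]
        return model


def train_locate(Mi, Me, config: LatentConfig | None = None,
                 **kwargs) -> LatentMetaboliteModel:
    """Convenience wrapper: build a model from config/kwargs and fit it."""
    return LatentMetaboliteModel(config, **kwargs).fit(Mi, Me)
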