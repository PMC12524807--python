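"""Transformer encoder over tokenized gene-expression vectors.

Architecture: the full feature vector is layer-normalized and linearly
projected into ``num_tokens = floor(n_features / token_dim)`` tokens of width
``token_dim`` (one dense map, so every token can draw on every gene and no
feature is discarded when ``n_features`` is not a multiple of the token
width).  A learnable CLS token is prepended; the sequence passes through
``num_blocks`` encoder blocks (multi-head self-attention + position-wise
feed-forward, each with layer normalization, a residual connection and
dropout).  The prediction head normalizes the CLS output and maps it
linearly to a scalar Prognosis Index (PI); higher PI = worse predicted
prognosis.  No positional encodings: tokens carry no order semantics.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, stack_rows

__all__ = ["ModelConfig", "ZZFormer", "scaled_dot_product_attention",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the selected configuration for the liver-cancer signature:
    token width 64, 8 heads, 2 encoder blocks, dropout 0.1.
    """

    n_features: int
    token_dim: int = 64
    num_heads: int = 8
    num_blocks: int = 2
    dropout: float = 0.1
    ffn_mult: int = 4
    pre_norm: bool = True

    def __post_init__(self):
        if self.n_features < self.token_dim:
            raise ValueError(
                f"n_features={self.n_features} < token_dim={self.token_dim}: "
                "num_tokens would be 0"
            )
        if self.token_dim % self.num_heads:
            raise ValueError("token_dim must be divisible by num_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.num_blocks < 0:
            raise ValueError("num_blocks must be >= 0")

    @property
    def num_tokens(self) -> int:
        return self.n_features // self.token_dim

    @property
    def seq_len(self) -> int:
        return self.num_tokens + 1  # CLS prepended

    @property
    def d_k(self) -> int:
        return self.token_dim // self.num_heads


def scaled_dot_product_attention(Q, K, V):
    """softmax(Q K^T / sqrt(d_k)) V with row-stochastic weights.

    Accepts arrays with any leading batch dimensions; the last two axes are
    (sequence, channel).  Returns ``(output, weights)``.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    d_k = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V, w


def _uniform(rng, fan_in, shape):
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class ZZFormer:
    """The survival transformer; one scalar risk score per sample."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        G, D, H, B = cfg.n_features, cfg.token_dim, cfg.num_heads, cfg.num_blocks
        T = cfg.num_tokens
        p: dict[str, Tensor] = {}

        def param(name, data):
            p[name] = Tensor(data, requires_grad=True)

        param("ln_in.g", np.ones(G))
        param("ln_in.b", np.zeros(G))
        param("embed.W", _uniform(rng, G, (G, T * D)))
        param("embed.b", _uniform(rng, G, (T * D,)))
        param("cls", 0.02 * rng.standard_normal((1, D)))
        for i in range(B):
            for nm in ("q", "k", "v", "o"):
                param(f"blk{i}.W{nm}", _uniform(rng, D, (D, D)))
                param(f"blk{i}.b{nm}", np.zeros(D))
            param(f"blk{i}.ln1.g", np.ones(D))
            param(f"blk{i}.ln1.b", np.zeros(D))
            param(f"blk{i}.ln2.g", np.ones(D))
            param(f"blk{i}.ln2.b", np.zeros(D))
            Dh = cfg.ffn_mult * D
            param(f"blk{i}.ffn.W1", _uniform(rng, D, (D, Dh)))
            param(f"blk{i}.ffn.b1", _uniform(rng, D, (Dh,)))
            param(f"blk{i}.ffn.W2", _uniform(rng, Dh, (Dh, D)))
            param(f"blk{i}.ffn.b2", _uniform(rng, Dh, (D,)))
        param("ln_out.g", np.ones(D))
        param("ln_out.b", np.zeros(D))
        param("head.w", _uniform(rng, D, (D, 1)))
        param("head.b", np.zeros(1))
        self.params = p
        self.last_attention: list[np.ndarray] = []

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def decay_mask(self) -> list[bool]:
        """L2 decay applies to weight matrices only, not norms/biases/CLS."""
        return [k != "cls" and v.data.ndim >= 2 for k, v in self.params.items()]

    def count_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    # -- forward pieces -------------------------------------------------------
    def embed_features(self, X) -> Tensor:
        """LayerNorm the features, project to tokens, prepend CLS."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.cfg.n_features:
            raise ValueError(
                f"expected {self.cfg.n_features} features, got {X.shape[1]}"
            )
        p = self.params
        n, (T, D) = X.shape[0], (self.cfg.num_tokens, self.cfg.token_dim)
        h = Tensor(X).layernorm(axis=-1) * p["ln_in.g"] + p["ln_in.b"]
        tokens = (h @ p["embed.W"] + p["embed.b"]).reshape(n, T, D)
        cls = stack_rows(p["cls"], n)  # (n, 1, D)
        return concat([cls, tokens], axis=1)

    def _mha(self, u: Tensor, i: int, capture: bool) -> Tensor:
        p, cfg = self.params, self.cfg
        n, m = u.shape[0], u.shape[1]
        H, dk = cfg.num_heads, cfg.d_k

        def heads(t):  # (n, m, D) -> (n, H, m, dk)
            return t.reshape(n, m, H, dk).swapaxes(1, 2)

        q = heads(u @ p[f"blk{i}.Wq"] + p[f"blk{i}.bq"])
        k = heads(u @ p[f"blk{i}.Wk"] + p[f"blk{i}.bk"])
        v = heads(u @ p[f"blk{i}.Wv"] + p[f"blk{i}.bv"])
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dk))
        w = scores.softmax(axis=-1)
        if capture:
            self.last_attention.append(w.data.copy())
        out = (w @ v).swapaxes(1, 2).reshape(n, m, cfg.token_dim)
        return out @ p[f"blk{i}.Wo"] + p[f"blk{i}.bo"]

    def _ffn(self, u: Tensor, i: int) -> Tensor:
        p = self.params
        return (u @ p[f"blk{i}.ffn.W1"] + p[f"blk{i}.ffn.b1"]).gelu() \
            @ p[f"blk{i}.ffn.W2"] + p[f"blk{i}.ffn.b2"]

    def forward(self, X, training: bool = False, rng: np.random.Generator | None = None,
                capture_attention: bool = False) -> Tensor:
        """Full forward pass; dropout only when ``training`` (needs ``rng``)."""
        p, cfg = self.params, self.cfg
        rate = cfg.dropout if training else 0.0
        if rate > 0 and rng is None:
            raise ValueError("training-mode forward requires an rng for dropout")
        if capture_attention:
            self.last_attention = []
        x = self.embed_features(X)

        def ln(t, name):
            return t.layernorm(axis=-1) * p[f"{name}.g"] + p[f"{name}.b"]

        for i in range(cfg.num_blocks):
            if cfg.pre_norm:
                x = x + self._mha(ln(x, f"blk{i}.ln1"), i, capture_attention).dropout(rate, rng)
                x = x + self._ffn(ln(x, f"blk{i}.ln2"), i).dropout(rate, rng)
            else:
                x = ln(x + self._mha(x, i, capture_attention).dropout(rate, rng), f"blk{i}.ln1")
                x = ln(x + self._ffn(x, i).dropout(rate, rng), f"blk{i}.ln2")
        c = ln(x[:, 0, :], "ln_out")
        pi = (c @ p["head.w"]).reshape(x.shape[0]) + p["head.b"]
        return pi

    def predict_risk(self, X) -> np.ndarray:
        """Evaluation-mode Prognosis Index, one scalar per sample."""
        return self.forward(X, training=False).data.copy()


def save_checkpoint(path: str | Path, model: ZZFormer, standardizer=None,
                    genes: list[str] | None = None) -> None:
    """Bundle weights, config, standardizer and gene list into one .npz file."""
    meta = {
        "config": asdict(model.cfg),
        "genes": genes,
        "has_standardizer": standardizer is not None,
    }
    arrays = {f"w::{k}": v for k, v in model.state_dict().items()}
    if standardizer is not None:
        arrays["std::mean"] = standardizer.mean
        arrays["std::scale"] = standardizer.scale
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path):
    """Inverse of :func:`save_checkpoint`; returns (model, standardizer, genes)."""
    from .data_io import Standardizer

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = ZZFormer(ModelConfig(**meta["config"]))
        model.load_state_dict(
            {k[3:]: z[k] for k in z.files if k.startswith("w::")}
        )
        std = None
        if meta["has_standardizer"]:
            std = Standardizer(mean=z["std::mean"].copy(), scale=z["std::scale"].copy())
    return model, std, meta["genes"]
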