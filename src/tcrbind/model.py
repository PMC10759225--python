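"""The cross-attention binding-prediction network.

Architecture: per-side token + learned positional embeddings -> per-side
Transformer self-attention encoders -> one cross-attention layer with four
heads per side -> length-averaged pooling of the concatenated cross-attention
outputs -> MLP -> sigmoid confidence in [0, 1].

The cross-attention layer is the interpretable heart of the model.  Writing
the learned hidden values of the TCR side as

    H_TCR = softmax(Q_peptide K_TCR^T / d) V_TCR,

each peptide position distributes one unit of attention over the TCR
residues (rows of the weight matrix sum to 1), and symmetrically for
H_Peptide.  These weight matrices are exposed per head for downstream
residue-level analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .autodiff import Tensor, softmax as t_softmax, concatenate, embedding
from .encoding import TokenBatch, Vocabulary

__all__ = [
    "ModelConfig", "AttentionMap", "ForwardOutputs", "CrossAttentionModel",
    "attention", "bce_loss", "save_checkpoint", "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyperparameters and fixed padded lengths of the network.

    ``embed_dim`` must be divisible by ``heads_per_side``; the attention
    scaling factor is sqrt(embed_dim / heads_per_side).  The ``max_len_*``
    fields are the training-set sequence maxima and fix the padded widths
    (TCR side: max_len_cdr3a + 1 + max_len_cdr3b, the +1 for the colon).
    """

    max_len_cdr3a: int
    max_len_cdr3b: int
    max_len_peptide: int
    embed_dim: int = 64
    heads_per_side: int = 4
    encoder_layers: int = 2
    mlp_hidden: int = 128
    dropout: float = 0.1
    mask_pads: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.heads_per_side:
            raise ValueError("embed_dim must be divisible by heads_per_side")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads_per_side

    @property
    def scaling(self) -> float:
        return float(np.sqrt(self.head_dim))

    @property
    def L_tcr(self) -> int:
        return self.max_len_cdr3a + 1 + self.max_len_cdr3b

    @property
    def L_pep(self) -> int:
        return self.max_len_peptide


@dataclass
class AttentionMap:
    """One head's cross-attention weights with explicit axis semantics.

    ``side='tcr_given_peptide'``: queries are peptide positions (query_axis),
    keys are TCR positions; each query row sums to 1 over the key axis, so a
    column maximum picks out how strongly a TCR residue is ever attended.
    ``side='peptide_given_tcr'`` is the mirror image.
    """

    head: int
    side: Literal["tcr_given_peptide", "peptide_given_tcr"]
    values: np.ndarray              # (query_len, key_len)
    query_axis: list[str] = field(default_factory=list)   # residue labels
    key_axis: list[str] = field(default_factory=list)


@dataclass
class ForwardOutputs:
    """Per-batch outputs of a forward pass (numpy views; detached)."""

    confidence: np.ndarray                 # (B,) in [0,1]
    h_tcr: np.ndarray                      # (B, L_pep, D) pooled TCR hidden values
    h_peptide: np.ndarray                  # (B, L_tcr, D)
    attention_tcr_side: np.ndarray         # (B, H, L_pep, L_tcr) rows sum to 1
    attention_peptide_side: np.ndarray     # (B, H, L_tcr, L_pep)
    confidence_t: Tensor | None = None     # tape-attached, for training


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
              d: float) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention on plain arrays.

    ``weights = row_softmax(Q K^T / d)``; returns (weights @ V, weights).
    """
    Q, K, V = np.asarray(Q, float), np.asarray(K, float), np.asarray(V, float)
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError(f"shape mismatch: Q{Q.shape} K{K.shape} V{V.shape}")
    if d <= 0:
        raise ValueError("scaling factor d must be positive")
    scores = Q @ np.swapaxes(K, -1, -2) / d
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ V, weights


def bce_loss(confidences, labels, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy; confidences clipped into (0, 1)."""
    c = np.clip(np.asarray(confidences, float), eps, 1.0 - eps)
    y = np.asarray(labels, float)
    if c.shape != y.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {y.shape}")
    return float(-(y * np.log(c) + (1 - y) * np.log(1 - c)).mean())


# ---------------------------------------------------------------------------
# parameter initialisation helpers

def _xavier(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class _Linear:
    def __init__(self, params, name, rng, din, dout):
        self.W = params.setdefault(f"{name}.W", Tensor(_xavier(rng, din, dout), True))
        self.b = params.setdefault(f"{name}.b", Tensor(np.zeros(dout), True))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class _LayerNorm:
    def __init__(self, params, name, dim):
        self.g = params.setdefault(f"{name}.g", Tensor(np.ones(dim), True))
        self.b = params.setdefault(f"{name}.b", Tensor(np.zeros(dim), True))

    def __call__(self, x: Tensor, eps: float = 1e-5) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        centered = x - m
        v = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (v + eps) ** -0.5 * self.g + self.b


def _split_heads(x: Tensor, H: int):
    B, L, D = x.shape
    return x.reshape(B, L, H, D // H).transpose(0, 2, 1, 3)   # (B,H,L,Dh)


def _merge_heads(x: Tensor):
    B, H, L, Dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, L, H * Dh)


def _dropout(x: Tensor, rate: float, rng, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * keep


class CrossAttentionModel:
    """Sequence-only CDR3ab-peptide binding predictor.

    Deterministic in eval mode; dropout is applied only when ``training=True``
    and an RNG is supplied by the training loop.
    """

    def __init__(self, cfg: ModelConfig, vocab: Vocabulary | None = None):
        self.cfg = cfg
        self.vocab = vocab or Vocabulary()
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(cfg.seed)
        D, H = cfg.embed_dim, cfg.heads_per_side
        p = self.params

        p["embed.tok"] = Tensor(rng.normal(0, 0.02, (len(self.vocab), D)), True)
        p["embed.pos_tcr"] = Tensor(rng.normal(0, 0.02, (cfg.L_tcr, D)), True)
        p["embed.pos_pep"] = Tensor(rng.normal(0, 0.02, (cfg.L_pep, D)), True)

        self.enc = {}
        for side in ("tcr", "pep"):
            for l in range(cfg.encoder_layers):
                base = f"enc.{side}.{l}"
                self.enc[base] = {
                    "q": _Linear(p, base + ".q", rng, D, D),
                    "k": _Linear(p, base + ".k", rng, D, D),
                    "v": _Linear(p, base + ".v", rng, D, D),
                    "o": _Linear(p, base + ".o", rng, D, D),
                    "ln1": _LayerNorm(p, base + ".ln1", D),
                    "ff1": _Linear(p, base + ".ff1", rng, D, 2 * D),
                    "ff2": _Linear(p, base + ".ff2", rng, 2 * D, D),
                    "ln2": _LayerNorm(p, base + ".ln2", D),
                }
        # cross-attention projections: queries from the opposite side
        self.cross = {}
        for side in ("tcr", "pep"):
            base = f"cross.{side}"
            self.cross[side] = {
                "q": _Linear(p, base + ".q", rng, D, D),   # queries (opposite side input)
                "k": _Linear(p, base + ".k", rng, D, D),
                "v": _Linear(p, base + ".v", rng, D, D),
            }
        self.mlp1 = _Linear(p, "mlp.1", rng, D, cfg.mlp_hidden)
        self.mlp2 = _Linear(p, "mlp.2", rng, cfg.mlp_hidden, 1)

    # -- building blocks -------------------------------------------------

    def _self_attention_block(self, x: Tensor, layer, key_mask, rng, training):
        cfg = self.cfg
        H = cfg.heads_per_side
        q = _split_heads(layer["q"](x), H)
        k = _split_heads(layer["k"](x), H)
        v = _split_heads(layer["v"](x), H)
        scores = q @ k.swapaxes(-1, -2) * (1.0 / cfg.scaling)
        mask = None
        if key_mask is not None:
            mask = key_mask[:, None, None, :]
        w = t_softmax(scores, axis=-1, mask=mask)
        attn = _merge_heads(w @ v)
        x = layer["ln1"](x + _dropout(layer["o"](attn), cfg.dropout, rng, training))
        ff = layer["ff2"](layer["ff1"](x).relu())
        return layer["ln2"](x + _dropout(ff, cfg.dropout, rng, training))

    def _encode_side(self, tokens, pos_name, side, rng, training):
        cfg = self.cfg
        x = embedding(self.params["embed.tok"], tokens) + self.params[pos_name]
        key_mask = (tokens != self.vocab.pad_index) if cfg.mask_pads else None
        for l in range(cfg.encoder_layers):
            x = self._self_attention_block(
                x, self.enc[f"enc.{side}.{l}"], key_mask, rng, training)
        return x, key_mask

    def _cross_side(self, q_input, kv_input, side, kv_mask):
        """One direction of the cross-attention layer.

        ``side`` names the key/value sequence: side='tcr' computes
        H_TCR = softmax(Q_pep K_tcr^T / d) V_tcr with peptide-derived queries.
        Returns (heads-concatenated hidden values, per-head weights Tensor).
        """
        cfg = self.cfg
        H = cfg.heads_per_side
        proj = self.cross[side]
        q = _split_heads(proj["q"](q_input), H)
        k = _split_heads(proj["k"](kv_input), H)
        v = _split_heads(proj["v"](kv_input), H)
        scores = q @ k.swapaxes(-1, -2) * (1.0 / cfg.scaling)
        mask = kv_mask[:, None, None, :] if kv_mask is not None else None
        w = t_softmax(scores, axis=-1, mask=mask)     # (B,H,Lq,Lkv)
        return _merge_heads(w @ v), w

    # -- forward ----------------------------------------------------------

    def forward(self, batch: TokenBatch, training: bool = False,
                rng: np.random.Generator | None = None) -> ForwardOutputs:
        cfg = self.cfg
        if batch.L_tcr != cfg.L_tcr or batch.L_pep != cfg.L_pep:
            raise ValueError(
                f"batch padded widths ({batch.L_tcr},{batch.L_pep}) do not match "
                f"model ({cfg.L_tcr},{cfg.L_pep}); re-encode with the model's limits")
        if np.any(batch.tcr_tokens >= len(self.vocab)) or \
           np.any(batch.peptide_tokens >= len(self.vocab)):
            raise ValueError("token indices outside the model vocabulary")
        if len(batch) == 0:
            empty = np.zeros((0, cfg.heads_per_side, 0, 0))
            return ForwardOutputs(np.zeros(0), np.zeros((0, cfg.L_pep, cfg.embed_dim)),
                                  np.zeros((0, cfg.L_tcr, cfg.embed_dim)), empty, empty)
        if training and rng is None:
            rng = np.random.default_rng(cfg.seed)

        tcr_h, tcr_mask = self._encode_side(batch.tcr_tokens, "embed.pos_tcr",
                                            "tcr", rng, training)
        pep_h, pep_mask = self._encode_side(batch.peptide_tokens, "embed.pos_pep",
                                            "pep", rng, training)

        # H_TCR: peptide queries over TCR keys/values; H_Peptide: the mirror.
        h_tcr, w_tcr = self._cross_side(pep_h, tcr_h, "tcr", tcr_mask)
        h_pep, w_pep = self._cross_side(tcr_h, pep_h, "pep", pep_mask)

        # pool over the length direction of [H_Peptide ; H_TCR], skipping
        # padded query positions (TCR positions for H_Peptide, peptide
        # positions for H_TCR)
        pooled_in = concatenate([h_pep, h_tcr], axis=1)       # (B, Lt+Lp, D)
        valid = np.concatenate([
            np.arange(cfg.L_tcr)[None, :] < batch.tcr_lengths[:, None],
            np.arange(cfg.L_pep)[None, :] < batch.peptide_lengths[:, None],
        ], axis=1).astype(float)
        valid /= valid.sum(axis=1, keepdims=True)
        pooled = (pooled_in * valid[:, :, None]).sum(axis=1)   # (B, D)

        hidden = _dropout(self.mlp1(pooled).relu(), cfg.dropout, rng, training)
        conf_t = self.mlp2(hidden).sigmoid().reshape(-1)
        return ForwardOutputs(
            confidence=conf_t.data.copy(),
            h_tcr=h_tcr.data.copy(),
            h_peptide=h_pep.data.copy(),
            attention_tcr_side=w_tcr.data.copy(),
            attention_peptide_side=w_pep.data.copy(),
            confidence_t=conf_t,
        )

    def predict(self, batch: TokenBatch) -> np.ndarray:
        return self.forward(batch).confidence

    # -- training-loss tensor ---------------------------------------------

    def loss(self, batch: TokenBatch, labels: np.ndarray,
             training: bool = True, rng=None) -> Tensor:
        out = self.forward(batch, training=training, rng=rng)
        c = out.confidence_t
        eps = 1e-9
        c = c * (1.0 - 2 * eps) + eps  # clip into (0,1) smoothly, keeps gradient
        y = np.asarray(labels, float)
        return -(Tensor(y) * c.log() + Tensor(1.0 - y) * (1.0 - c).log()).mean()

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(model: CrossAttentionModel, path) -> None:
    """Serialize weights + ModelConfig + Vocabulary into a single .npz."""
    arrays = {f"param/{k}": v.data for k, v in model.params.items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8)
    arrays["vocab_json"] = np.frombuffer(
        model.vocab.to_json().encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> CrossAttentionModel:
    with np.load(path) as z:
        cfg = ModelConfig(**json.loads(bytes(z["config_json"]).decode()))
        vocab = Vocabulary.from_json(bytes(z["vocab_json"]).decode())
        model = CrossAttentionModel(cfg, vocab)
        for k, t in model.params.items():
            t.data = z[f"param/{k}"].astype(np.float64)
    return model
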