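"""BERT-style transformer encoder with bottleneck adapters, in NumPy.

The encoder follows the standard BERT layout: summed word / learned-position
/ token-type embeddings with layer norm, then per layer multi-head
self-attention (post-norm residual) and a feed-forward block (post-norm
residual).  A Pfeiffer-style bottleneck adapter — ``h + Up(relu(Down(h)))``
— is applied after each feed-forward block.  Task heads (classifier or
regressor) read the class-token hidden state through
``dense(d→d) + tanh + dense(d→out)``.

Two presets matter: ``PROTBERT_BFD`` (30 layers / 16 heads / d 1024 / ff
4096), used only by the closed-form parameter accountant, and ``TINY``
(2 layers / 2 heads / d 16 / ff 32), the trainable desk-scale model.

The backbone pooler (dense + tanh over the class token) is part of the
published encoder and is counted in parameter totals, but task heads read
the class-token state directly; with adapters enabled the pooler stays
frozen along with the rest of the backbone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .autodiff import Tensor, cross_entropy_logits, embedding, mse
from .seqio import PAD_ID, TokenizedSequence, tokenize

CLASSIFIER = "classifier"
REGRESSOR = "regressor"


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters of the backbone encoder."""

    n_layers: int
    n_heads: int
    d_model: int
    d_ff: int
    vocab_size: int = 30
    max_positions: int = 512
    type_vocab: int = 2
    layer_norm_eps: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("n_layers", "n_heads", "d_model", "d_ff", "vocab_size",
                     "max_positions", "type_vocab"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass(frozen=True)
class AdapterConfig:
    """Bottleneck adapter hyperparameters (one adapter per layer, placed
    after the feed-forward block)."""

    reduction_factor: int = 16
    nonlinearity: str = "relu"

    def bottleneck(self, d_model: int) -> int:
        if d_model % self.reduction_factor:
            raise ValueError("d_model must be divisible by reduction_factor")
        return d_model // self.reduction_factor


@dataclass(frozen=True)
class HeadConfig:
    """Task head: ``dense(d→hidden) + tanh + dense(hidden→out)``."""

    kind: str = CLASSIFIER
    hidden: int | None = None  # defaults to d_model

    def __post_init__(self) -> None:
        if self.kind not in (CLASSIFIER, REGRESSOR):
            raise ValueError(f"unknown head kind {self.kind!r}")

    @property
    def n_outputs(self) -> int:
        return 2 if self.kind == CLASSIFIER else 1


#: protBERT-BFD-sized preset (used for parameter accounting only).
PROTBERT_BFD = EncoderConfig(
    n_layers=30, n_heads=16, d_model=1024, d_ff=4096,
    vocab_size=30, max_positions=40000, type_vocab=2,
)

#: Desk-scale preset used for every trained model in the test suite.
TINY = EncoderConfig(n_layers=2, n_heads=2, d_model=16, d_ff=32,
                     vocab_size=30, max_positions=512, type_vocab=2)


# -- closed-form parameter accountant ---------------------------------------


def count_parameters(
    cfg: EncoderConfig,
    adapters: AdapterConfig | None = None,
    head: HeadConfig | None = None,
    trainable_only: bool = False,
) -> int:
    """Closed-form parameter count of the configured model.

    With ``trainable_only`` and adapters present, the backbone (embeddings,
    attention, feed-forward, layer norms, pooler) is frozen and only adapter
    and head parameters count.  Without adapters every parameter is
    trainable.
    """
    d, ff = cfg.d_model, cfg.d_ff
    adapter_count = 0
    if adapters is not None:
        b = adapters.bottleneck(d)
        adapter_count = cfg.n_layers * ((d * b + b) + (b * d + d))
    head_count = 0
    if head is not None:
        hidden = head.hidden or d
        head_count = (d * hidden + hidden) + (hidden * head.n_outputs + head.n_outputs)
    if trainable_only and adapters is not None:
        return adapter_count + head_count
    embeddings = (cfg.vocab_size + cfg.max_positions + cfg.type_vocab) * d + 2 * d
    per_layer = (
        4 * (d * d + d)      # Q, K, V, attention output projections
        + 2 * d              # attention layer norm
        + (d * ff + ff)      # feed-forward in
        + (ff * d + d)       # feed-forward out
        + 2 * d              # feed-forward layer norm
    )
    pooler = d * d + d
    return embeddings + cfg.n_layers * per_layer + pooler + adapter_count + head_count


# -- runnable model ----------------------------------------------------------


def adapter_forward(h: Tensor, down_w: Tensor, down_b: Tensor,
                    up_w: Tensor, up_b: Tensor) -> Tensor:
    """Bottleneck adapter: ``h + Up(relu(Down(h)))`` (residual preserved)."""
    if h.shape[-1] != down_w.shape[0] or up_w.shape[1] != h.shape[-1]:
        raise ValueError("adapter width does not match hidden width")
    z = (h @ down_w + down_b).relu()
    return h + (z @ up_w + up_b)


class EncoderModel:
    """Instantiated transformer with optional adapters and task head.

    Parameters are held in a flat ``name -> Tensor`` dict.  With adapters
    enabled the backbone is frozen: only adapter and head tensors have
    ``requires_grad`` set.
    """

    def __init__(
        self,
        cfg: EncoderConfig = TINY,
        adapters: AdapterConfig | None = None,
        head: HeadConfig | None = None,
        seed: int = 0,
        init_scale: float = 0.3,
    ):
        self.cfg = cfg
        self.adapters = adapters
        self.head = head
        self.seed = seed
        self.target_stats: tuple[float, float] | None = None  # (mean, sd) °C
        rng = np.random.default_rng(seed)
        d, ff = cfg.d_model, cfg.d_ff
        p: dict[str, Tensor] = {}

        def par(name: str, shape, zero: bool = False) -> None:
            if zero or init_scale == 0.0:
                data = np.zeros(shape)
            else:
                data = rng.normal(0.0, init_scale, shape)
            p[name] = Tensor(data, requires_grad=True, name=name)

        par("emb.word", (cfg.vocab_size, d))
        par("emb.pos", (cfg.max_positions, d))
        par("emb.type", (cfg.type_vocab, d))
        par("emb.ln.g", (d,)); p["emb.ln.g"].data[:] = 1.0
        par("emb.ln.b", (d,), zero=True)
        for i in range(cfg.n_layers):
            for proj in ("q", "k", "v", "o"):
                par(f"layer{i}.attn.{proj}.w", (d, d))
                par(f"layer{i}.attn.{proj}.b", (d,), zero=True)
            par(f"layer{i}.attn.ln.g", (d,)); p[f"layer{i}.attn.ln.g"].data[:] = 1.0
            par(f"layer{i}.attn.ln.b", (d,), zero=True)
            par(f"layer{i}.ffn.w1", (d, ff))
            par(f"layer{i}.ffn.b1", (ff,), zero=True)
            par(f"layer{i}.ffn.w2", (ff, d))
            par(f"layer{i}.ffn.b2", (d,), zero=True)
            par(f"layer{i}.ffn.ln.g", (d,)); p[f"layer{i}.ffn.ln.g"].data[:] = 1.0
            par(f"layer{i}.ffn.ln.b", (d,), zero=True)
            if adapters is not None:
                b = adapters.bottleneck(d)
                par(f"layer{i}.adapter.down.w", (d, b))
                par(f"layer{i}.adapter.down.b", (b,), zero=True)
                # zero-init up-projection: the adapted layer starts as the
                # identity map over the frozen backbone
                par(f"layer{i}.adapter.up.w", (b, d), zero=True)
                par(f"layer{i}.adapter.up.b", (d,), zero=True)
        par("pooler.w", (d, d))
        par("pooler.b", (d,), zero=True)
        if head is not None:
            hidden = head.hidden or d
            par("head.dense1.w", (d, hidden))
            par("head.dense1.b", (hidden,), zero=True)
            par("head.dense2.w", (hidden, head.n_outputs))
            par("head.dense2.b", (head.n_outputs,), zero=True)
        self.params = p
        if adapters is not None:
            self.freeze_backbone()

    # -- parameter bookkeeping ----------------------------------------------

    @staticmethod
    def _is_trainable_name(name: str) -> bool:
        return ".adapter." in name or name.startswith("head.")

    def freeze_backbone(self) -> None:
        """Freeze everything except adapters and head."""
        for name, t in self.params.items():
            t.requires_grad = self._is_trainable_name(name)

    def named_parameters(self, trainable_only: bool = False) -> Iterator[tuple[str, Tensor]]:
        for name, t in self.params.items():
            if trainable_only and not t.requires_grad:
                continue
            yield name, t

    def num_parameters(self, trainable_only: bool = False) -> int:
        return sum(t.size for _, t in self.named_parameters(trainable_only))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.params.items():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            if state[name].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            t.data = np.array(state[name], dtype=np.float64)

    def adapter_state(self) -> dict[str, np.ndarray]:
        return {n: t.data.copy() for n, t in self.params.items() if ".adapter." in n}

    def load_adapter_state(self, state: dict[str, np.ndarray]) -> None:
        own = [n for n in self.params if ".adapter." in n]
        if set(own) != set(state):
            raise ValueError("adapter state incompatible with this architecture")
        for n in own:
            if state[n].shape != self.params[n].data.shape:
                raise ValueError(f"adapter shape mismatch for {n!r}")
            self.params[n].data = np.array(state[n], dtype=np.float64)

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        token_ids: np.ndarray,
        attention_mask: np.ndarray | None = None,
        capture_attention: bool = False,
    ) -> tuple[Tensor, list[np.ndarray]]:
        """Run the encoder on a (B, T) int array of token ids.

        Returns the (B, T, d) hidden states and, when requested, the list of
        per-layer (B, H, T, T) row-stochastic attention matrices.
        """
        token_ids = np.asarray(token_ids)
        if token_ids.ndim != 2:
            raise ValueError("token_ids must be (batch, tokens)")
        if token_ids.min() < 0 or token_ids.max() >= self.cfg.vocab_size:
            raise ValueError("token id outside vocabulary")
        B, T = token_ids.shape
        if attention_mask is None:
            attention_mask = (token_ids != PAD_ID).astype(np.float64)
        p = self.params
        cfg = self.cfg
        d, H = cfg.d_model, cfg.n_heads
        dk = d // H

        x = (
            embedding(p["emb.word"], token_ids)
            + embedding(p["emb.pos"], np.broadcast_to(np.arange(T), (B, T)))
            + embedding(p["emb.type"], np.zeros((B, T), dtype=np.intp))
        )
        x = x.layer_norm(p["emb.ln.g"], p["emb.ln.b"], cfg.layer_norm_eps)

        # additive key mask: 0 for real tokens, -1e9 for padding
        key_mask = (1.0 - attention_mask[:, None, None, :]) * -1e9
        attn_maps: list[np.ndarray] = []
        for i in range(cfg.n_layers):
            def split_heads(t: Tensor) -> Tensor:
                return t.reshape(B, T, H, dk).transpose(0, 2, 1, 3)

            q = split_heads(x @ p[f"layer{i}.attn.q.w"] + p[f"layer{i}.attn.q.b"])
            k = split_heads(x @ p[f"layer{i}.attn.k.w"] + p[f"layer{i}.attn.k.b"])
            v = split_heads(x @ p[f"layer{i}.attn.v.w"] + p[f"layer{i}.attn.v.b"])
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
            scores = scores + Tensor(key_mask)
            attn = scores.softmax(axis=-1)
            if capture_attention:
                attn_maps.append(attn.data.copy())
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
            attn_out = ctx @ p[f"layer{i}.attn.o.w"] + p[f"layer{i}.attn.o.b"]
            x = (x + attn_out).layer_norm(
                p[f"layer{i}.attn.ln.g"], p[f"layer{i}.attn.ln.b"], cfg.layer_norm_eps
            )
            h = (x @ p[f"layer{i}.ffn.w1"] + p[f"layer{i}.ffn.b1"]).gelu()
            h = h @ p[f"layer{i}.ffn.w2"] + p[f"layer{i}.ffn.b2"]
            x = (x + h).layer_norm(
                p[f"layer{i}.ffn.ln.g"], p[f"layer{i}.ffn.ln.b"], cfg.layer_norm_eps
            )
            if self.adapters is not None:
                x = adapter_forward(
                    x,
                    p[f"layer{i}.adapter.down.w"], p[f"layer{i}.adapter.down.b"],
                    p[f"layer{i}.adapter.up.w"], p[f"layer{i}.adapter.up.b"],
                )
        return x, attn_maps

    def head_logits(self, hidden: Tensor) -> Tensor:
        """Apply the task head to the class-token hidden state."""
        if self.head is None:
            raise ValueError("model has no head")
        p = self.params
        cls = hidden[:, 0]
        z = (cls @ p["head.dense1.w"] + p["head.dense1.b"]).tanh()
        return z @ p["head.dense2.w"] + p["head.dense2.b"]

    # -- inference-mode entry points -----------------------------------------

    def _batch_ids(self, tokens: Sequence[TokenizedSequence]) -> tuple[np.ndarray, np.ndarray]:
        T = max(len(t) for t in tokens)
        ids = np.full((len(tokens), T), PAD_ID, dtype=np.intp)
        mask = np.zeros((len(tokens), T))
        for i, t in enumerate(tokens):
            ids[i, : len(t)] = t.token_ids
            mask[i, : len(t)] = 1.0
        return ids, mask

    def forward_classify(self, tokens: TokenizedSequence | Sequence[TokenizedSequence]) -> np.ndarray:
        """Probability of the thermophilic class (logit index 1)."""
        if self.head is None or self.head.kind != CLASSIFIER:
            raise ValueError("model has no classifier head")
        single = isinstance(tokens, TokenizedSequence)
        batch = [tokens] if single else list(tokens)
        ids, mask = self._batch_ids(batch)
        hidden, _ = self.forward(ids, mask)
        logits = self.head_logits(hidden)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        probs = (e / e.sum(axis=-1, keepdims=True))[:, 1]
        return probs[0] if single else probs

    def forward_regress(self, tokens: TokenizedSequence | Sequence[TokenizedSequence]) -> np.ndarray:
        """Predicted melting temperature in °C (de-normalized)."""
        if self.head is None or self.head.kind != REGRESSOR:
            raise ValueError("model has no regressor head")
        if self.target_stats is None:
            raise ValueError("model has no target normalization statistics")
        single = isinstance(tokens, TokenizedSequence)
        batch = [tokens] if single else list(tokens)
        ids, mask = self._batch_ids(batch)
        hidden, _ = self.forward(ids, mask)
        y = self.head_logits(hidden).data[:, 0]
        mean, sd = self.target_stats
        out = y * sd + mean
        return out[0] if single else out

    def capture_attention(self, tokens: TokenizedSequence) -> "AttentionTensorSet":
        """Forward one sequence and return every layer/head attention map."""
        ids, mask = self._batch_ids([tokens])
        _, maps = self.forward(ids, mask, capture_attention=True)
        stacked = np.stack([m[0] for m in maps])  # (L, H, T, T)
        return AttentionTensorSet(matrices=stacked, tokens=tokens)

    # -- training losses (differentiable) ------------------------------------

    def classification_loss(self, ids: np.ndarray, mask: np.ndarray, labels: np.ndarray) -> Tensor:
        hidden, _ = self.forward(ids, mask)
        return cross_entropy_logits(self.head_logits(hidden), labels)

    def regression_loss(self, ids: np.ndarray, mask: np.ndarray, targets_norm: np.ndarray) -> Tensor:
        hidden, _ = self.forward(ids, mask)
        return mse(self.head_logits(hidden)[:, 0], targets_norm)

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.state_dict())
        config = {
            "encoder": asdict(self.cfg),
            "adapters": asdict(self.adapters) if self.adapters else None,
            "head": asdict(self.head) if self.head else None,
            "seed": self.seed,
            "target_stats": list(self.target_stats) if self.target_stats else None,
        }
        (directory / "config.json").write_text(json.dumps(config, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "EncoderModel":
        directory = Path(directory)
        config = json.loads((directory / "config.json").read_text())
        model = cls(
            cfg=EncoderConfig(**config["encoder"]),
            adapters=AdapterConfig(**config["adapters"]) if config["adapters"] else None,
            head=HeadConfig(**config["head"]) if config["head"] else None,
            seed=config["seed"],
        )
        with np.load(directory / "weights.npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        if config["target_stats"]:
            model.target_stats = tuple(config["target_stats"])
        return model


@dataclass
class AttentionTensorSet:
    """All layers' and heads' attention matrices for one tokenized sequence.

    ``matrices`` has shape (n_layers, n_heads, T, T); every row is a
    probability distribution over token positions.  ``tokens`` carries the
    token-index → residue-index map needed to excise special tokens.
    """

    matrices: np.ndarray
    tokens: TokenizedSequence

    @property
    def n_matrices(self) -> int:
        return self.matrices.shape[0] * self.matrices.shape[1]


def tokenize_records(sequences: Sequence[str], max_len: int = 512) -> list[TokenizedSequence]:
    """Tokenize a batch of raw sequences."""
    return [tokenize(s, max_len) for s in sequences]
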