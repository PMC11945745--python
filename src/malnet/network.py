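"""The MAL-Net architecture.

A patient's encoded feature vector x ∈ [0,1]^d is turned into a length-d
token sequence (token_j = x_j · E_j with a learned embedding E_j per
encoded column), consumed by a single-layer LSTM:

    i_t = σ(W_i x_t + U_i h_{t-1} + b_i)
    f_t = σ(W_f x_t + U_f h_{t-1} + b_f)
    c̃_t = tanh(W_c x_t + U_c h_{t-1} + b_c)
    c_t = f_t ⊙ c_{t-1} + i_t ⊙ c̃_t
    o_t = σ(W_o x_t + U_o h_{t-1} + b_o)
    h_t = o_t ⊙ tanh(c_t)

The hidden-state sequence passes through (inverted) dropout, then
multi-head self-attention:

    Attention(Q, K, V) = softmax(QKᵀ/√d_k) V
    head_h = Attention(Q W_Q^h, K W_K^h, V W_V^h)
    MHA(Q, K, V) = Concat(head_1, …, head_H) W_O

Each head projects the full hidden width (no per-head width split); W_O
maps H·hidden_dim back to hidden_dim.  The attended sequence is
mean-aggregated, passed through a ReLU fully-connected layer and a
linear output layer, and per-subtype probabilities are σ(z_i) —
independent per label (multi-label).

Everything is built on the package's autodiff tensors, so one code path
serves both inference and training; the public operations below return
plain numpy arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, stack

__all__ = [
    "ModelConfig", "ModelParams", "init_params", "tokenize", "lstm_step",
    "lstm_forward", "dropout", "attention", "multi_head_attention",
    "forward", "predict_labels", "count_parameters",
    "save_checkpoint", "load_checkpoint", "NetworkError",
]


class NetworkError(ValueError):
    """Shape/configuration errors in the network."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and inference settings.

    Defaults follow the published configuration: 32-unit hidden layer,
    four attention heads, dropout 0.4 (the swept optimum; 0.2 is the
    other published setting), decision threshold 0.5.
    """

    token_dim: int = 32
    hidden_dim: int = 32
    n_heads: int = 4
    dropout_p: float = 0.4
    n_labels: int = 5
    fc_dim: int = 32
    decision_threshold: float = 0.5
    use_mha: bool = True          # False = LSTM-only ablation baseline
    aggregation: str = "mean"     # mean | sum | last

    def __post_init__(self):
        if not 0 <= self.dropout_p < 1:
            raise NetworkError("dropout_p must lie in [0, 1)")
        if not 0 < self.decision_threshold < 1:
            raise NetworkError("decision_threshold must lie in (0, 1)")
        if self.n_heads < 1:
            raise NetworkError("n_heads must be >= 1")
        if self.aggregation not in ("mean", "sum", "last"):
            raise NetworkError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class ModelParams:
    """All learnable arrays, stored as autodiff leaf tensors."""

    E: Tensor                       # d x token_dim embeddings
    W: dict[str, Tensor]            # LSTM input weights  (i, f, c, o)
    U: dict[str, Tensor]            # LSTM recurrent weights
    b: dict[str, Tensor]            # LSTM biases
    WQ: list[Tensor]                # per-head query projections
    WK: list[Tensor]
    WV: list[Tensor]
    WO: Tensor                      # (H*hidden) x hidden output proj
    fc_W: Tensor
    fc_b: Tensor
    out_W: Tensor
    out_b: Tensor

    def tensors(self) -> list[Tensor]:
        out = [self.E]
        for gate in "ifco":
            out += [self.W[gate], self.U[gate], self.b[gate]]
        out += self.WQ + self.WK + self.WV + [self.WO]
        out += [self.fc_W, self.fc_b, self.out_W, self.out_b]
        return out

    def names(self) -> list[str]:
        out = ["E"]
        for gate in "ifco":
            out += [f"W_{gate}", f"U_{gate}", f"b_{gate}"]
        H = len(self.WQ)
        for kind in ("WQ", "WK", "WV"):
            out += [f"{kind}_{h}" for h in range(H)]
        out += ["WO", "fc_W", "fc_b", "out_W", "out_b"]
        return out

    def zero_grad(self) -> None:
        for t in self.tensors():
            t.zero_grad()


def init_params(config: ModelConfig, d: int,
                seed: int | np.random.Generator = 0) -> ModelParams:
    """Uniform(±1/√fan_in) weights, zero biases, forget-gate bias 1."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    def uniform(fan_in, *shape):
        lim = 1.0 / np.sqrt(fan_in)
        return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

    td, hd, fc, H = (config.token_dim, config.hidden_dim, config.fc_dim,
                     config.n_heads)
    params = ModelParams(
        E=uniform(1, d, td),
        W={g: uniform(td, td, hd) for g in "ifco"},
        U={g: uniform(hd, hd, hd) for g in "ifco"},
        b={g: Tensor(np.full(hd, 1.0 if g == "f" else 0.0),
                     requires_grad=True) for g in "ifco"},
        WQ=[uniform(hd, hd, hd) for _ in range(H)],
        WK=[uniform(hd, hd, hd) for _ in range(H)],
        WV=[uniform(hd, hd, hd) for _ in range(H)],
        WO=uniform(H * hd, H * hd, hd),
        fc_W=uniform(hd, hd, fc),
        fc_b=Tensor(np.zeros(fc), requires_grad=True),
        out_W=uniform(fc, fc, config.n_labels),
        out_b=Tensor(np.zeros(config.n_labels), requires_grad=True),
    )
    return params


# -- graph builders (autodiff path) ----------------------------------------

def _tokenize_graph(X: Tensor, E: Tensor) -> Tensor:
    """(n, d) values x (d, token_dim) embeddings -> (n, d, token_dim)."""
    if X.shape[-1] != E.shape[0]:
        raise NetworkError(
            f"feature width {X.shape[-1]} != embedding rows {E.shape[0]}")
    return X.reshape(*X.shape, 1) * E


def _lstm_step_graph(x_t: Tensor, h: Tensor, c: Tensor,
                     params: ModelParams) -> tuple[Tensor, Tensor]:
    W, U, b = params.W, params.U, params.b
    i = (x_t @ W["i"] + h @ U["i"] + b["i"]).sigmoid()
    f = (x_t @ W["f"] + h @ U["f"] + b["f"]).sigmoid()
    c_tilde = (x_t @ W["c"] + h @ U["c"] + b["c"]).tanh()
    c_new = f * c + i * c_tilde
    o = (x_t @ W["o"] + h @ U["o"] + b["o"]).sigmoid()
    h_new = o * c_new.tanh()
    return h_new, c_new


def _lstm_forward_graph(tokens: Tensor, params: ModelParams,
                        hidden_dim: int) -> Tensor:
    """(n, d, token_dim) -> (n, d, hidden_dim); zero initial state.

    Input-side gate projections for every time step are computed in one
    batched product per gate before the recurrence."""
    n, d = tokens.shape[0], tokens.shape[1]
    if d == 0:
        raise NetworkError("empty token sequence")
    x_proj = {g: tokens @ params.W[g] + params.b[g] for g in "ifco"}
    h = Tensor(np.zeros((n, hidden_dim)))
    c = Tensor(np.zeros((n, hidden_dim)))
    U = params.U
    states = []
    for t in range(d):
        i = (x_proj["i"][:, t, :] + h @ U["i"]).sigmoid()
        f = (x_proj["f"][:, t, :] + h @ U["f"]).sigmoid()
        c_tilde = (x_proj["c"][:, t, :] + h @ U["c"]).tanh()
        c = f * c + i * c_tilde
        o = (x_proj["o"][:, t, :] + h @ U["o"]).sigmoid()
        h = o * c.tanh()
        states.append(h)
    return stack(states, axis=1)


def _attention_graph(Q: Tensor, K: Tensor, V: Tensor
                     ) -> tuple[Tensor, Tensor]:
    d_k = Q.shape[-1]
    if d_k == 0:
        raise NetworkError("d_k must be positive")
    scores = (Q @ K.transpose_last()) * (1.0 / np.sqrt(d_k))
    weights = scores.softmax_last()
    return weights @ V, weights


def _mha_graph(Hseq: Tensor, params: ModelParams) -> Tensor:
    heads = []
    for WQ, WK, WV in zip(params.WQ, params.WK, params.WV):
        out, _ = _attention_graph(Hseq @ WQ, Hseq @ WK, Hseq @ WV)
        heads.append(out)
    return concat(heads, axis=-1) @ params.WO


def _dropout_graph(M: Tensor, p: float, train: bool,
                   rng: np.random.Generator | None) -> Tensor:
    if not 0 <= p < 1:
        raise NetworkError("dropout probability must lie in [0, 1)")
    if not train or p == 0:
        return M
    if rng is None:
        raise NetworkError("train-mode dropout needs a random generator")
    mask = (rng.random(M.shape) >= p) / (1.0 - p)
    return M * Tensor(mask)


def forward_graph(X: Tensor, params: ModelParams, config: ModelConfig,
                  train: bool = False,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Full forward pass on a batch; returns the (n, n_labels) logits."""
    tokens = _tokenize_graph(X, params.E)
    Hseq = _lstm_forward_graph(tokens, params, config.hidden_dim)
    Hseq = _dropout_graph(Hseq, config.dropout_p, train, rng)
    if config.use_mha:
        Hseq = _mha_graph(Hseq, params)
    if config.aggregation == "mean":
        agg = Hseq.mean(axis=1)
    elif config.aggregation == "sum":
        agg = Hseq.mean(axis=1) * Hseq.shape[1]
    else:  # last
        agg = Hseq[:, -1, :]
    hidden = (agg @ params.fc_W + params.fc_b).relu()
    logits = hidden @ params.out_W + params.out_b
    if not np.isfinite(logits.data).all():
        raise NetworkError("non-finite logits in forward pass")
    return logits


# -- public numpy-facing operations ----------------------------------------

def tokenize(x: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Value-scaled token sequence: token_j = x_j * E_j."""
    x = np.asarray(x, dtype=float)
    E = np.asarray(E, dtype=float)
    if x.shape[-1] != E.shape[0]:
        raise NetworkError(
            f"feature width {x.shape[-1]} != embedding rows {E.shape[0]}")
    return x[..., None] * E


def lstm_step(x_t: np.ndarray, state: tuple[np.ndarray, np.ndarray],
              params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM gate update; returns (h_t, c_t)."""
    x_t = np.asarray(x_t, dtype=float)
    h0, c0 = state
    if not (np.isfinite(x_t).all() and np.isfinite(h0).all()
            and np.isfinite(c0).all()):
        raise NetworkError("non-finite input to lstm_step")
    h, c = _lstm_step_graph(Tensor(x_t), Tensor(np.asarray(h0, float)),
                            Tensor(np.asarray(c0, float)), params)
    return h.data, c.data


def lstm_forward(tokens: np.ndarray, params: ModelParams) -> np.ndarray:
    """Run the LSTM from the zero state; returns all hidden states."""
    tokens = np.asarray(tokens, dtype=float)
    squeeze = tokens.ndim == 2
    if squeeze:
        tokens = tokens[None]
    if tokens.shape[1] == 0:
        raise NetworkError("empty token sequence")
    hidden_dim = params.U["i"].shape[0]
    out = _lstm_forward_graph(Tensor(tokens), params, hidden_dim).data
    return out[0] if squeeze else out


def dropout(M: np.ndarray, p: float, mode: str = "train",
            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Inverted dropout: train mode zeroes entries w.p. p and rescales
    survivors by 1/(1-p); eval mode is the identity."""
    if mode not in ("train", "eval"):
        raise NetworkError(f"unknown dropout mode {mode!r}")
    M = np.asarray(M, dtype=float)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return _dropout_graph(Tensor(M), p, mode == "train", rng).data


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention; returns (output, weights)."""
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if K.shape[-2] != V.shape[-2]:
        raise NetworkError("K and V must have equal row counts")
    if Q.shape[-1] != K.shape[-1]:
        raise NetworkError("Q and K must share their column dimension")
    out, w = _attention_graph(Tensor(Q), Tensor(K), Tensor(V))
    return out.data, w.data


def multi_head_attention(Hseq: np.ndarray, params: ModelParams) -> np.ndarray:
    """Multi-head self-attention over a hidden-state sequence."""
    Hseq = np.asarray(Hseq, dtype=float)
    if Hseq.shape[-2] == 0:
        raise NetworkError("empty sequence")
    if not params.WQ:
        raise NetworkError("head count must be >= 1")
    return _mha_graph(Tensor(Hseq), params).data


def forward(x: np.ndarray, params: ModelParams, config: ModelConfig,
            mode: str = "eval", seed: int | np.random.Generator = 0
            ) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and logits for one encoded vector or a batch.

    Eval mode is fully deterministic (dropout is the identity).
    """
    if mode not in ("train", "eval"):
        raise NetworkError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise NetworkError("non-finite input features")
    squeeze = x.ndim == 1
    X = x[None] if squeeze else x
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    logits = forward_graph(Tensor(X), params, config,
                           train=(mode == "train"), rng=rng).data
    probs = 0.5 * (1.0 + np.tanh(0.5 * logits))
    if squeeze:
        return probs[0], logits[0]
    return probs, logits


def predict_labels(probabilities: np.ndarray,
                   threshold: float = 0.5) -> np.ndarray:
    """label_i = 1 iff p_i > threshold (strict); multi-label allowed."""
    p = np.asarray(probabilities, dtype=float)
    return (p > threshold).astype(int)


def count_parameters(config: ModelConfig, d: int = 0,
                     scope: str = "full") -> int:
    """Exact trainable-parameter count.

    ``lstm_only`` counts the recurrent layer alone:
    4 * ((token_dim + hidden_dim) * hidden_dim + hidden_dim).
    ``full`` adds embeddings, attention projections, and the FC/output
    layers.
    """
    td, hd, fc, H, L = (config.token_dim, config.hidden_dim, config.fc_dim,
                        config.n_heads, config.n_labels)
    lstm = 4 * ((td + hd) * hd + hd)
    if scope == "lstm_only":
        return lstm
    if scope != "full":
        raise NetworkError(f"unknown scope {scope!r}")
    total = lstm + d * td
    if config.use_mha:
        total += H * 3 * hd * hd + (H * hd) * hd
    total += hd * fc + fc + fc * L + L
    return total


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(path: str | Path, params: ModelParams,
                    config: ModelConfig, schema_fingerprint: str) -> None:
    """Serialize config + parameters + schema fingerprint (JSON)."""
    payload = {
        "schema_fingerprint": schema_fingerprint,
        "config": asdict(config),
        "params": {name: t.data.tolist()
                   for name, t in zip(params.names(), params.tensors())},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path, schema_fingerprint: str
                    ) -> tuple[ModelParams, ModelConfig]:
    """Load a checkpoint; refuses a mismatched schema fingerprint."""
    payload = json.loads(Path(path).read_text())
    if payload["schema_fingerprint"] != schema_fingerprint:
        raise NetworkError(
            "checkpoint was trained under a different schema "
            f"(fingerprint {payload['schema_fingerprint']} != "
            f"{schema_fingerprint})")
    config = ModelConfig(**payload["config"])
    arrays = {k: np.asarray(v, dtype=float)
              for k, v in payload["params"].items()}
    d = arrays["E"].shape[0]
    params = init_params(config, d, seed=0)
    for name, tensor in zip(params.names(), params.tensors()):
        if tensor.data.shape != arrays[name].shape:
            raise NetworkError(f"checkpoint array {name} has shape "
                               f"{arrays[name].shape}, expected "
                               f"{tensor.data.shape}")
        tensor.data = arrays[name]
    return params, config
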