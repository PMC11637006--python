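"""BiGRU + structured self-attention encoder with a topic-posterior head.

A weighted feature matrix FW (k tokens x T_emb dims) is read left-to-right
and right-to-left by two GRU chains; the per-token hidden states are
concatenated into H (k x 2u).  A structured self-attention layer turns H
into a fixed number of attention-weighted summaries (softmax over the k
token positions), which a two-layer projection maps to the text
representation M (length r_rep).  A separate two-layer head maps M through a
ReLU and a softmax to a posterior over r_topics topics — the quantity the
topic KL loss compares against the frozen LDA target.

The GRU update follows the convention in which the update gate weights the
candidate state: h_t = (1 - z_t) * h_{t-1} + z_t * h~_t.  No bias terms are
used anywhere; all layers are pure linear maps plus their nonlinearity.

Two equivalent forward paths exist: per-document numpy functions
(`gru_step`, `bigru_encode`, `self_attend`, `topic_head`) used for
inspection and testing, and a batched autodiff path (`encode_batch`) used
for training.  They compute the same function; a test pins them together.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "EncoderConfig", "GRUCellParams", "EncoderParams", "init_params",
    "gru_step", "bigru_encode", "self_attend", "topic_head",
    "encode_document", "encode_batch", "save_checkpoint", "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class EncoderConfig:
    """Shapes of the encoder; defaults follow the reference setting
    (512-dim BiGRU state, 64-dim text vector, one attention hop)."""

    emb_dim: int
    hidden_units: int = 256          # u, per direction; BiGRU state is 2u
    attn_dim: int = 64               # width of the attention tanh layer
    attn_hops: int = 1               # number of attention summaries
    proj_dim: int = 64               # width of the projection tanh layer
    r_rep: int = 64                  # length of the text representation M
    head_dim: int = 64               # width of the topic head ReLU layer
    r_topics: int = 12               # length of the topic posterior
    init_std: float = 0.02


@dataclass
class GRUCellParams:
    """One direction's gate weights, each mapping [h_prev, x] -> u."""

    W_r: np.ndarray
    W_z: np.ndarray
    W_h: np.ndarray


@dataclass
class EncoderParams:
    """All learnable arrays plus the config that fixes their shapes."""

    config: EncoderConfig
    gru_fw: GRUCellParams
    gru_bw: GRUCellParams
    attn_W1: np.ndarray              # (attn_dim, 2u)
    attn_W2: np.ndarray              # (hops, attn_dim)
    proj_W1: np.ndarray              # (hops*2u, proj_dim)
    proj_W2: np.ndarray              # (r_rep, proj_dim)
    head_W1: np.ndarray              # (r_rep, head_dim)
    head_W2: np.ndarray              # (r_topics, head_dim)

    def named_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for d, cell in (("fw", self.gru_fw), ("bw", self.gru_bw)):
            out[f"gru_{d}.W_r"] = cell.W_r
            out[f"gru_{d}.W_z"] = cell.W_z
            out[f"gru_{d}.W_h"] = cell.W_h
        out.update(attn_W1=self.attn_W1, attn_W2=self.attn_W2,
                   proj_W1=self.proj_W1, proj_W2=self.proj_W2,
                   head_W1=self.head_W1, head_W2=self.head_W2)
        return out

    def set_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for d, cell in (("fw", self.gru_fw), ("bw", self.gru_bw)):
            cell.W_r = arrays[f"gru_{d}.W_r"]
            cell.W_z = arrays[f"gru_{d}.W_z"]
            cell.W_h = arrays[f"gru_{d}.W_h"]
        self.attn_W1 = arrays["attn_W1"]
        self.attn_W2 = arrays["attn_W2"]
        self.proj_W1 = arrays["proj_W1"]
        self.proj_W2 = arrays["proj_W2"]
        self.head_W1 = arrays["head_W1"]
        self.head_W2 = arrays["head_W2"]


def init_params(config: EncoderConfig, seed: int = 0) -> EncoderParams:
    """Draw every weight from N(0, init_std^2) with a dedicated generator."""
    rng = np.random.default_rng(seed)
    u, e, s = config.hidden_units, config.emb_dim, config.init_std

    def w(*shape):
        return rng.normal(0.0, s, size=shape)

    def cell():
        return GRUCellParams(W_r=w(u, u + e), W_z=w(u, u + e), W_h=w(u, u + e))

    return EncoderParams(
        config=config,
        gru_fw=cell(), gru_bw=cell(),
        attn_W1=w(config.attn_dim, 2 * u),
        attn_W2=w(config.attn_hops, config.attn_dim),
        proj_W1=w(config.attn_hops * 2 * u, config.proj_dim),
        proj_W2=w(config.r_rep, config.proj_dim),
        head_W1=w(config.r_rep, config.head_dim),
        head_W2=w(config.r_topics, config.head_dim),
    )


# ---------------------------------------------------------------------------
# per-document forward (plain numpy)
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, cell: GRUCellParams) -> np.ndarray:
    """One gated-recurrent update: reset gate, update gate, candidate, blend."""
    hx = np.concatenate([h_prev, x_t])
    if cell.W_r.shape[1] != hx.shape[0]:
        raise ValueError(f"gate expects input of {cell.W_r.shape[1]}, got {hx.shape[0]}")
    r = _sigmoid(cell.W_r @ hx)
    z = _sigmoid(cell.W_z @ hx)
    h_tilde = np.tanh(cell.W_h @ np.concatenate([r * h_prev, x_t]))
    return (1.0 - z) * h_prev + z * h_tilde


def bigru_encode(fw: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Run both directions from zero states; H row t = [h_fwd_t ; h_bwd_t]."""
    k = fw.shape[0]
    if k < 1:
        raise ValueError("cannot encode an empty sequence")
    u = params.config.hidden_units
    hf = np.zeros(u)
    fwd = []
    for t in range(k):
        hf = gru_step(fw[t], hf, params.gru_fw)
        fwd.append(hf)
    hb = np.zeros(u)
    bwd = [np.zeros(u)] * k
    for t in range(k - 1, -1, -1):
        hb = gru_step(fw[t], hb, params.gru_bw)
        bwd[t] = hb
    return np.stack([np.concatenate([f, b]) for f, b in zip(fwd, bwd)])


def self_attend(H: np.ndarray, params: EncoderParams) -> tuple[np.ndarray, np.ndarray]:
    """Attention matrix A (hops x k, rows on the simplex) and representation M."""
    if H.shape[0] < 1:
        raise ValueError("empty hidden-state matrix")
    Z = params.attn_W2 @ np.tanh(params.attn_W1 @ H.T)          # (hops, k)
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    A = E / E.sum(axis=1, keepdims=True)                        # softmax over words
    Z_hat = (A @ H).reshape(-1)                                 # (hops*2u,)
    M = params.proj_W2 @ np.tanh(params.proj_W1.T @ Z_hat)      # (r_rep,)
    return A, M


def topic_head(M: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Topic posterior: softmax(W2 @ relu(W1^T @ M)); strictly positive simplex."""
    logits = params.head_W2 @ np.maximum(params.head_W1.T @ M, 0.0)
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def encode_document(fw: np.ndarray, params: EncoderParams) -> tuple[np.ndarray, np.ndarray]:
    """FW -> (M, topic posterior) through the full per-document path."""
    H = bigru_encode(fw, params)
    _, M = self_attend(H, params)
    return M, topic_head(M, params)


# ---------------------------------------------------------------------------
# batched autodiff forward (training path)
# ---------------------------------------------------------------------------

def params_as_tensors(params: EncoderParams) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=True) for k, v in params.named_arrays().items()}


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, True, (t,))
    out._backward = lambda g: t._accumulate(g.T)
    return out


def encode_batch(fw_list: list[np.ndarray], pt: dict[str, Tensor],
                 config: EncoderConfig) -> tuple[Tensor, Tensor]:
    """Encode a batch of variable-length FW matrices in one padded graph.

    Sequences are right-padded to the batch maximum; pad positions are frozen
    out of the recurrences and masked out of the attention softmax, so the
    result per document is identical to the per-document path.
    Returns (M: m x r_rep, D: m x r_topics) tensors.
    """
    m = len(fw_list)
    u, e = config.hidden_units, config.emb_dim
    lens = np.array([fw.shape[0] for fw in fw_list])
    kmax = int(lens.max())

    X = np.zeros((kmax, m, e))
    for i, fw in enumerate(fw_list):
        X[: fw.shape[0], i, :] = fw
    masks = [Tensor((lens > t).astype(float).reshape(m, 1)) for t in range(kmax)]
    xs = [Tensor(X[t]) for t in range(kmax)]

    WT = {k: _transpose(v) for k, v in pt.items()
          if k.startswith("gru_") or k in ("attn_W1", "attn_W2", "proj_W2", "head_W2")}

    def run_direction(prefix: str, order: range) -> list[Tensor | None]:
        h = Tensor(np.zeros((m, u)))
        states: list[Tensor | None] = [None] * kmax
        for t in order:
            hx = concat([h, xs[t]], axis=1)
            r = (hx @ WT[f"{prefix}.W_r"]).sigmoid()
            z = (hx @ WT[f"{prefix}.W_z"]).sigmoid()
            h_tilde = (concat([r * h, xs[t]], axis=1) @ WT[f"{prefix}.W_h"]).tanh()
            h_new = (1.0 - z) * h + z * h_tilde
            h = masks[t] * h_new + (1.0 - masks[t]) * h
            states[t] = h
        return states

    fwd = run_direction("gru_fw", range(kmax))
    bwd = run_direction("gru_bw", range(kmax - 1, -1, -1))
    Hs = [concat([fwd[t], bwd[t]], axis=1) for t in range(kmax)]   # each (m, 2u)

    # structured self-attention with masked softmax over token positions
    scores = []                                                    # per t: (m, hops)
    for t in range(kmax):
        s = (Hs[t] @ WT["attn_W1"]).tanh()
        scores.append(s @ WT["attn_W2"])
    score_max = np.max(np.stack([s.data for s in scores]), axis=0)  # constant shift
    exps = [(s - score_max).exp() * masks[t] for t, s in enumerate(scores)]
    total = exps[0]
    for e_t in exps[1:]:
        total = total + e_t
    hop_summaries = []
    for hop in range(config.attn_hops):
        hop_col = np.zeros((config.attn_hops, 1))
        hop_col[hop, 0] = 1.0
        pick = Tensor(hop_col)
        z_hat = None
        for t in range(kmax):
            a_t = (exps[t] @ pick) / (total @ pick)                # (m, 1)
            term = a_t * Hs[t]
            z_hat = term if z_hat is None else z_hat + term
        hop_summaries.append(z_hat)
    Z_hat = concat(hop_summaries, axis=1)                          # (m, hops*2u)

    M = (Z_hat @ pt["proj_W1"]).tanh() @ WT["proj_W2"]             # (m, r_rep)
    logits = (M @ pt["head_W1"]).relu() @ WT["head_W2"]            # (m, r_topics)
    return M, logits.softmax_rows()


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(params: EncoderParams, path) -> None:
    """Serialize all weights plus the embedded config; round-trips bit-exactly."""
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(params.config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode("utf-8"), dtype=np.uint8),
             **params.named_arrays())


def load_checkpoint(path) -> EncoderParams:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        config = EncoderConfig(**meta["config"])
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    params = init_params(config, seed=0)
    params.set_arrays(arrays)
    return params
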