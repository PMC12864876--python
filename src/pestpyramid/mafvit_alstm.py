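"""Pest classification: multi-attention fusion transformer + adaptive LSTM.

Detected pest crops are embedded as patch tokens at several input scales.
Each scale passes through a multi-head self-attention block; the per-scale
sequences are weighted by softmax-normalized learned scalars, concatenated
along the token axis, and fused by one cross-scale attention block. The fused
tokens are then consumed sequentially by an adaptive LSTM whose cell follows

    forget    h = sigmoid(M_hy y_s + M_hf f_{s-1} + a_h)
    candidate c = tanh(M_jy y_s + M_jf f_{s-1} + a_j)
    input     t = sigmoid(M_ty y_s + M_tf f_{s-1} + a_t + logit(significance))
    output    k = sigmoid(M_ky y_s + M_kf f_{s-1} + a_k)
    cell      d_s = h (*) d_{s-1} + t (*) c
    hidden    f_s = k (*) tanh(d_s)

where (*) is the Hadamard product. The adaptive element is the logit shift of
the input gate by a per-token significance score (the mean attention the token
receives in the fusion block), so salient tokens write more to memory;
significance 0.5 shifts by zero and recovers the textbook LSTM step exactly.

The tunable hyperparameters exposed to the optimizer are the LSTM hidden
width (integer in [5, 255]) and the learning-rate gene (real in [0.01, 0.99],
applied multiplicatively onto a 0.01 base rate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn

__all__ = ["ClassifierConfig", "LSTMParams", "LSTMState", "lstm_step",
           "patch_embed_tokens", "MAFViTALSTM", "train_classifier", "classify",
           "crop_detection", "prepare_crop"]

_GATES = ("forget", "input", "output", "candidate")


# -- standalone adaptive-LSTM cell (plain numpy; the reference semantics) -----

@dataclass
class LSTMParams:
    """Per-gate input/recurrent weights and biases.

    ``weights[g] = (M_gy, M_gf, a_g)`` with M_gy: (hidden, d_in),
    M_gf: (hidden, hidden), a_g: (hidden,).
    """

    weights: dict
    hidden_width: int
    learning_rate: float = 0.3

    def __post_init__(self):
        if not 5 <= self.hidden_width <= 255:
            raise ValueError("hidden_width must lie in [5, 255]")
        if not 0.01 <= self.learning_rate <= 0.99:
            raise ValueError("learning_rate gene must lie in [0.01, 0.99]")

    @classmethod
    def zeros(cls, d_in: int, hidden_width: int, **kw) -> "LSTMParams":
        w = {g: (np.zeros((hidden_width, d_in)), np.zeros((hidden_width, hidden_width)),
                 np.zeros(hidden_width)) for g in _GATES}
        return cls(weights=w, hidden_width=hidden_width, **kw)

    @classmethod
    def init(cls, d_in: int, hidden_width: int, rng: np.random.Generator,
             **kw) -> "LSTMParams":
        sc_in = 1.0 / np.sqrt(d_in)
        sc_h = 1.0 / np.sqrt(hidden_width)
        w = {g: (rng.normal(0, sc_in, (hidden_width, d_in)),
                 rng.normal(0, sc_h, (hidden_width, hidden_width)),
                 np.zeros(hidden_width)) for g in _GATES}
        return cls(weights=w, hidden_width=hidden_width, **kw)


@dataclass
class LSTMState:
    hidden: np.ndarray
    cell: np.ndarray
    step: int = 0


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def lstm_step(y_s: np.ndarray, prev: LSTMState, params: LSTMParams,
              significance: float = 0.5) -> LSTMState:
    """One adaptive-LSTM step on a single input vector."""
    y_s = np.asarray(y_s, dtype=float)
    if not (np.all(np.isfinite(y_s)) and np.all(np.isfinite(prev.hidden))
            and np.all(np.isfinite(prev.cell))):
        raise FloatingPointError("non-finite input to lstm_step")
    if not 0.0 <= significance <= 1.0:
        raise ValueError("significance must lie in [0, 1]")

    def pre(gate):
        my, mf, a = params.weights[gate]
        return my @ y_s + mf @ prev.hidden + a

    forget = _sigmoid(pre("forget"))
    candidate = np.tanh(pre("candidate"))
    inp = _sigmoid(pre("input") + _logit(significance))
    outp = _sigmoid(pre("output"))
    cell = forget * prev.cell + inp * candidate
    hidden = outp * np.tanh(cell)
    return LSTMState(hidden=hidden, cell=cell, step=prev.step + 1)


# -- patch embedding ----------------------------------------------------------

def extract_patches(crops: np.ndarray, patch_size: int) -> np.ndarray:
    """(N, S, S, 3) crops -> (N, T, patch_size^2*3) row-major flattened patches."""
    n, s, s2, c = crops.shape
    if s != s2:
        raise ValueError("crops must be square")
    if s % patch_size:
        raise ValueError(f"crop side {s} not divisible by patch size {patch_size}")
    g = s // patch_size
    p = crops.reshape(n, g, patch_size, g, patch_size, c)
    return p.transpose(0, 1, 3, 2, 4, 5).reshape(n, g * g, patch_size * patch_size * c)


def patch_embed_tokens(patches: np.ndarray, proj_w: nn.Tensor, proj_b: nn.Tensor,
                       pos: nn.Tensor) -> nn.Tensor:
    """Linear projection of flattened patches plus additive positional encoding."""
    x = nn.Tensor(patches)
    return x @ proj_w + proj_b + pos


# -- attention blocks ---------------------------------------------------------

def _layer_norm(x: nn.Tensor, gamma: nn.Tensor, beta: nn.Tensor,
                eps: float = 1e-5) -> nn.Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * gamma + beta


class AttentionBlock:
    """Pre-norm multi-head self-attention with residual connection."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError(f"embed dim {d} not divisible by n_heads {n_heads}")
        self.d, self.n_heads = d, n_heads
        self.p = {k: nn.glorot(rng, d, d) for k in ("wq", "wk", "wv", "wo")}
        self.p["gamma"] = nn.Tensor(np.ones(d), requires_grad=True)
        self.p["beta"] = nn.Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: nn.Tensor) -> tuple[nn.Tensor, np.ndarray]:
        """x: (N, T, d) -> (output (N, T, d), attention (N, heads, T, T))."""
        n, t, d = x.shape
        hd = d // self.n_heads
        xn = _layer_norm(x, self.p["gamma"], self.p["beta"])

        def heads(w):
            return (xn @ w).reshape(n, t, self.n_heads, hd).transpose(0, 2, 1, 3)

        q, k, v = heads(self.p["wq"]), heads(self.p["wk"]), heads(self.p["wv"])
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = nn.softmax(scores, axis=-1)                 # (N, h, T, T)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        out = x + ctx @ self.p["wo"]
        return out, attn.data

    def parameters(self):
        return list(self.p.values())


# -- full classifier ----------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    n_classes: int = 3
    hidden_width: int = 48        # LSTM hidden size; tunable gene in [5, 255]
    learning_rate: float = 0.3    # gene in [0.01, 0.99]; effective = gene * 0.01
    epochs: int = 30
    batch_size: int = 32
    crop_size: int = 32
    scales: tuple[int, ...] = (32, 16)
    patch_size: int = 8
    embed_dim: int = 32
    n_heads: int = 4
    seed: int = 0
    # ablation switches
    use_attention: bool = True
    use_adaptive: bool = True
    use_lstm: bool = True

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 5 <= self.hidden_width <= 255:
            raise ValueError("hidden_width must lie in [5, 255]")
        if not 0.01 <= self.learning_rate <= 0.99:
            raise ValueError("learning_rate gene must lie in [0.01, 0.99]")
        if not 1 <= self.epochs <= 250:
            raise ValueError("epochs must lie in [1, 250]")
        for s in self.scales:
            if s % self.patch_size:
                raise ValueError(f"scale {s} not divisible by patch {self.patch_size}")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")

    @property
    def effective_lr(self) -> float:
        return self.learning_rate * 0.01


class MAFViTALSTM:
    """Multi-scale token embedding + attention fusion + adaptive LSTM head."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self.trained = False
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 41)))
        d = config.embed_dim
        pdim = config.patch_size ** 2 * 3
        self.embed = []
        for s in config.scales:
            t = (s // config.patch_size) ** 2
            self.embed.append({
                "proj_w": nn.glorot(rng, pdim, d),
                "proj_b": nn.Tensor(np.zeros(d), requires_grad=True),
                "pos": nn.Tensor(rng.normal(0, 0.02, (t, d)), requires_grad=True),
            })
        self.scale_attn = [AttentionBlock(d, config.n_heads, rng)
                           for _ in config.scales]
        self.fusion_weights = nn.Tensor(np.zeros(len(config.scales)),
                                        requires_grad=True)
        self.fusion_attn = AttentionBlock(d, config.n_heads, rng)
        h = config.hidden_width
        sc_in, sc_h = 1.0 / np.sqrt(d), 1.0 / np.sqrt(h)
        self.lstm = {}
        for g in _GATES:
            self.lstm[f"{g}_y"] = nn.Tensor(rng.normal(0, sc_in, (d, h)),
                                            requires_grad=True)
            self.lstm[f"{g}_f"] = nn.Tensor(rng.normal(0, sc_h, (h, h)),
                                            requires_grad=True)
            self.lstm[f"{g}_b"] = nn.Tensor(np.zeros(h), requires_grad=True)
        head_in = h if config.use_lstm else d
        self.head_w = nn.glorot(rng, head_in, config.n_classes)
        self.head_b = nn.Tensor(np.zeros(config.n_classes), requires_grad=True)

    # - forward -
    def fuse_tokens(self, crops: np.ndarray) -> tuple[nn.Tensor, np.ndarray]:
        """Crops (N, S, S, 3) -> fused token sequence (N, T_total, d) and
        per-token significance (N, T_total) from the fusion attention."""
        cfg = self.config
        seqs = []
        for si, s in enumerate(cfg.scales):
            arr = crops if s == cfg.crop_size else _resize_batch(crops, s)
            patches = extract_patches(arr, cfg.patch_size)
            tok = patch_embed_tokens(patches, self.embed[si]["proj_w"],
                                     self.embed[si]["proj_b"], self.embed[si]["pos"])
            if cfg.use_attention:
                tok, _ = self.scale_attn[si](tok)
            seqs.append(tok)
        w = nn.softmax(self.fusion_weights, axis=0)
        seqs = [seq * w[si].reshape(1, 1, 1) for si, seq in enumerate(seqs)]
        fused = nn.concat(seqs, axis=1)
        if cfg.use_attention:
            fused, attn = self.fusion_attn(fused)
            # significance: mean attention received by each token (column mean
            # over heads and query positions), renormalized to mean 0.5 per
            # sequence so the logit shift is centered
            sig = attn.mean(axis=(1, 2))
            sig = sig / (2.0 * sig.mean(axis=1, keepdims=True))
        else:
            sig = np.full(fused.shape[:2], 0.5)
        return fused, np.clip(sig, 1e-6, 1 - 1e-6)

    def _lstm_forward(self, fused: nn.Tensor, sig: np.ndarray) -> nn.Tensor:
        cfg = self.config
        n, t, _ = fused.shape
        h = cfg.hidden_width
        f_prev = nn.Tensor(np.zeros((n, h)))
        d_prev = nn.Tensor(np.zeros((n, h)))
        if cfg.use_adaptive:
            shift = np.log(sig / (1 - sig))        # logit, (N, T)
        else:
            shift = np.zeros((n, t))
        for s in range(t):
            y = fused[:, s]
            pre = {g: y @ self.lstm[f"{g}_y"] + f_prev @ self.lstm[f"{g}_f"]
                   + self.lstm[f"{g}_b"] for g in _GATES}
            forget = nn.sigmoid(pre["forget"])
            cand = nn.tanh(pre["candidate"])
            inp = nn.sigmoid(pre["input"] + shift[:, s:s + 1])
            outp = nn.sigmoid(pre["output"])
            d_prev = forget * d_prev + inp * cand
            f_prev = outp * nn.tanh(d_prev)
        return f_prev

    def forward_logits(self, crops: np.ndarray) -> nn.Tensor:
        fused, sig = self.fuse_tokens(crops)
        if self.config.use_lstm:
            feat = self._lstm_forward(fused, sig)
        else:
            feat = fused.mean(axis=1)
        return feat @ self.head_w + self.head_b

    def predict_proba(self, crops: np.ndarray) -> np.ndarray:
        logits = self.forward_logits(crops).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def parameters(self) -> list[nn.Tensor]:
        ps: list[nn.Tensor] = []
        for e in self.embed:
            ps += list(e.values())
        for blk in self.scale_attn:
            ps += blk.parameters()
        ps.append(self.fusion_weights)
        ps += self.fusion_attn.parameters()
        ps += list(self.lstm.values())
        ps += [self.head_w, self.head_b]
        return ps

    # - persistence -
    def _named_params(self) -> dict:
        named = {}
        for i, e in enumerate(self.embed):
            for k, v in e.items():
                named[f"embed{i}_{k}"] = v
        for i, blk in enumerate(self.scale_attn):
            for k, v in blk.p.items():
                named[f"sattn{i}_{k}"] = v
        named["fusion_weights"] = self.fusion_weights
        for k, v in self.fusion_attn.p.items():
            named[f"fattn_{k}"] = v
        for k, v in self.lstm.items():
            named[f"lstm_{k}"] = v
        named["head_w"] = self.head_w
        named["head_b"] = self.head_b
        return named

    def save(self, path: str | Path) -> None:
        cfg = dict(self.config.__dict__)
        cfg["scales"] = list(cfg["scales"])
        with open(Path(path), "wb") as fh:
            np.savez(fh, **{k: v.data for k, v in self._named_params().items()},
                     __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path: str | Path) -> "MAFViTALSTM":
        with np.load(Path(path)) as z:
            cfg = json.loads(z["__config__"].tobytes().decode())
            cfg["scales"] = tuple(cfg["scales"])
            model = cls(ClassifierConfig(**cfg))
            for k, v in model._named_params().items():
                v.data = z[k].astype(np.float64)
        model.trained = True
        return model


# -- crop preparation ---------------------------------------------------------

def _resize_batch(crops: np.ndarray, side: int) -> np.ndarray:
    out = np.empty((crops.shape[0], side, side, 3))
    for i, c in enumerate(crops):
        im = Image.fromarray((np.clip(c, 0, 1) * 255).astype(np.uint8))
        out[i] = np.asarray(im.resize((side, side), Image.BILINEAR)) / 255.0
    return out


def crop_detection(image: np.ndarray, box, pad_frac: float = 0.1) -> np.ndarray:
    """Cut a detection box out of the scene with fractional context padding."""
    h, w = image.shape[:2]
    x0, y0, x1, y1 = box
    px = (x1 - x0) * pad_frac
    py = (y1 - y0) * pad_frac
    xi0 = max(0, int(np.floor(x0 - px)))
    yi0 = max(0, int(np.floor(y0 - py)))
    xi1 = min(w, int(np.ceil(x1 + px)))
    yi1 = min(h, int(np.ceil(y1 + py)))
    if xi1 <= xi0 or yi1 <= yi0:
        raise ValueError(f"empty crop from box {box}")
    return image[yi0:yi1, xi0:xi1]


def prepare_crop(image: np.ndarray, box, crop_size: int = 32,
                 pad_frac: float = 0.1) -> np.ndarray:
    """Crop + bilinear resize to the classifier's square input."""
    c = crop_detection(image, box, pad_frac)
    return _resize_batch(c[None], crop_size)[0]


# -- training / inference -----------------------------------------------------

def train_classifier(crops: np.ndarray, labels: np.ndarray,
                     config: ClassifierConfig) -> tuple[MAFViTALSTM, list[float]]:
    """Cross-entropy training; returns the model and the per-epoch cost trace."""
    crops = np.asarray(crops, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if crops.shape[1] != config.crop_size:
        raise ValueError(f"crops must be {config.crop_size}x{config.crop_size}")
    model = MAFViTALSTM(config)
    opt = nn.Adam(model.parameters(), lr=config.effective_lr)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 43)))
    n = len(crops)
    costs: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        tot, nb = 0.0, 0
        for start in range(0, n, config.batch_size):
            b = order[start:start + config.batch_size]
            logits = model.forward_logits(crops[b])
            ls = nn.log_softmax(logits, axis=-1)
            loss = -(ls[np.arange(len(b)), labels[b]]).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"classifier training diverged (non-finite loss) at epoch "
                    f"{_epoch}, lr gene {config.learning_rate}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += float(loss.data)
            nb += 1
        costs.append(tot / nb)
    model.trained = True
    return model, costs


def classify(crop: np.ndarray, model: MAFViTALSTM) -> np.ndarray:
    """Class probability vector for one prepared crop (S, S, 3)."""
    if not model.trained:
        raise RuntimeError("model is untrained; call train_classifier first")
    return model.predict_proba(crop[None])[0]
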