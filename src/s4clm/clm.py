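"""Autoregressive chemical language model built on S4 layers.

Architecture: token embedding -> ``n_blocks`` pre-norm residual blocks, each
``LayerNorm -> per-channel S4 convolution (+ skip term D·u) -> GELU ->
pointwise channel mixing`` -> final LayerNorm -> projection to the
vocabulary.  Every channel carries an independent SISO state-space system;
channels communicate only through the pointwise mixing layers.

The model is deliberately small enough to train on one CPU: all forward and
backward passes are explicit NumPy, with the convolution executed by FFT.
The state matrices (HiPPO-LegS spectrum) and step sizes Δ are frozen at
initialization; the input/output maps B and C, the skip weights D and all
non-SSM parameters are trained.  With the state matrix fixed, the
convolution kernel ``K_l = Cbar Abar^l Bbar`` is bilinear in (B, C), so its
gradients are exact short recurrences — no autodiff framework is needed.

Training runs in convolutional mode (whole sequence at once); generation
runs the identical parameters as a linear recurrence, one token at a time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .chem_io import Vocabulary
from .s4_core import discretize, init_state_space_bank

__all__ = ["CLMConfig", "CLM", "RecurrentModelState", "clm_forward"]

_LN_EPS = 1e-5


@dataclass(frozen=True)
class CLMConfig:
    """Model shape.

    ``content_length`` is the number of content tokens per sequence
    (padded layout adds BOS and EOS, so encoded sequences have
    ``content_length + 2`` positions).  Desk-scale default: 2 blocks,
    width 128, state size 32; a full-scale setting would be 4 blocks,
    width 256, state size 64.
    """

    vocab_size: int
    n_blocks: int = 2
    model_width: int = 128
    state_size: int = 32
    dropout: float = 0.0
    content_length: int = 100
    delta_range: tuple[float, float] = (1e-3, 1e-1)

    def __post_init__(self) -> None:
        if min(self.vocab_size, self.n_blocks, self.model_width,
               self.state_size, self.content_length) < 1:
            raise ValueError("all size fields must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


_GELU_C = np.sqrt(2.0 / np.pi)


def _gelu(x: np.ndarray):
    """Tanh-form GELU; returns (value, tanh term) so backward reuses it."""
    x2 = x * x
    t = np.tanh(_GELU_C * x * (1.0 + 0.044715 * x2))
    return 0.5 * x * (1.0 + t), t


def _gelu_grad(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    x2 = x * x
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * _GELU_C * (
        1.0 + 3 * 0.044715 * x2)


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


class CLM:
    """S4 chemical language model with explicit forward/backward passes."""

    def __init__(self, config: CLMConfig, seed: int = 0,
                 dtype: np.dtype = np.float64):
        self.config = config
        rng = np.random.default_rng(seed)
        d, N, V = config.model_width, config.state_size, config.vocab_size
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.params["emb"] = rng.standard_normal((V, d)) / np.sqrt(d)
        for i in range(config.n_blocks):
            bank = [discretize(p) for p in
                    init_state_space_bank(N, d, rng, config.delta_range)]
            self.buffers[f"blk{i}.A_bar"] = np.stack([p.A_bar for p in bank])
            # Bbar = T_B @ B with T_B = (I - Δ/2 A)^{-1} Δ  (fixed per channel)
            TB = np.stack([
                np.linalg.solve(np.eye(N) - p.delta / 2.0 * p.A, p.delta * np.eye(N))
                for p in bank
            ])
            self.buffers[f"blk{i}.TB"] = TB
            self.params[f"blk{i}.B"] = np.stack([p.B for p in bank])
            self.params[f"blk{i}.C"] = np.stack([p.C for p in bank])
            self.params[f"blk{i}.D"] = np.ones(d)
            self.params[f"blk{i}.ln_g"] = np.ones(d)
            self.params[f"blk{i}.ln_b"] = np.zeros(d)
            self.params[f"blk{i}.Wm"] = rng.standard_normal((d, d)) / np.sqrt(d)
            self.params[f"blk{i}.bm"] = np.zeros(d)
        self.params["lnf_g"] = np.ones(d)
        self.params["lnf_b"] = np.zeros(d)
        self.params["Wout"] = 0.01 * rng.standard_normal((d, V))
        self.params["bout"] = np.zeros(V)
        if np.dtype(dtype) != np.float64:
            # single precision roughly halves CPU training time; the dual
            # formulation and all contracts hold at correspondingly looser
            # floating-point tolerances
            self.params = {k: v.astype(dtype) for k, v in self.params.items()}
            self.buffers = {k: v.astype(dtype) for k, v in self.buffers.items()}

    # ---------------------------------------------------------------- kernels

    def _apow(self, i: int, L: int) -> np.ndarray:
        """Cached per-channel matrix-power stack ``P[l] = Abar^l`` (L, d, N, N).

        The state matrices are frozen, so the stack is computed once per
        (block, length) and reused by every forward/backward pass.
        """
        if not hasattr(self, "_apow_cache"):
            self._apow_cache: dict[tuple[int, int], tuple] = {}
        key = (i, L)
        if key not in self._apow_cache:
            A_bar = self.buffers[f"blk{i}.A_bar"]
            d, N = A_bar.shape[0], A_bar.shape[1]
            P = np.empty((L, d, N, N), dtype=A_bar.dtype)
            P[0] = np.eye(N, dtype=A_bar.dtype)
            for l in range(1, L):
                P[l] = A_bar @ P[l - 1]
            # two BLAS-friendly layouts: (d, L·N, N) for powers·Bbar and
            # (d, N, L·N) for C·powers
            PB = np.ascontiguousarray(
                P.transpose(1, 0, 2, 3).reshape(d, L * N, N))
            PC = np.ascontiguousarray(
                P.transpose(1, 2, 0, 3).reshape(d, N, L * N))
            if len(self._apow_cache) >= 4:  # bound the cache
                self._apow_cache.pop(next(iter(self._apow_cache)))
            self._apow_cache[key] = (PB, PC)
        return self._apow_cache[key]

    def _block_kernels(self, i: int, L: int):
        """Per-channel kernels K (d, L) plus the power stack ``G``.

        ``G[c, l] = Abar^l Bbar`` (shape d, L, N); ``K[c, l] = C[c]·G[c, l]``.
        """
        PB, _ = self._apow(i, L)
        d, N = self.params[f"blk{i}.B"].shape
        B_bar = np.einsum("cnm,cm->cn", self.buffers[f"blk{i}.TB"],
                          self.params[f"blk{i}.B"])
        G = (PB @ B_bar[:, :, None]).reshape(d, L, N)
        K = (G @ self.params[f"blk{i}.C"][:, :, None])[..., 0]  # (d, L)
        return K, G, B_bar

    # ---------------------------------------------------------------- forward

    def forward(self, ids: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Convolutional-mode forward pass.

        ``ids``: (batch, T) int array of encoded sequences.  Returns logits
        of shape (batch, T, vocab) where position k predicts token k+1 and
        conditions only on positions <= k (strict causality: the causal FFT
        convolution and pointwise layers never look ahead).
        """
        ids = np.atleast_2d(ids)
        Bt, L = ids.shape
        n = next_fast_len(2 * L, real=True)
        X = self.params["emb"][ids]
        if cache is not None:
            cache["ids"], cache["n"] = ids, n
            cache["blocks"] = []
        for i in range(self.config.n_blocks):
            Z, ln_cache = _layernorm_fwd(
                X, self.params[f"blk{i}.ln_g"], self.params[f"blk{i}.ln_b"])
            K, G, _ = self._block_kernels(i, L)
            Kf = rfft(K, n, axis=-1)
            # FFT along a contiguous last axis: (batch, d, L) layout
            Zf = rfft(np.ascontiguousarray(Z.transpose(0, 2, 1)), n, axis=-1)
            Y = irfft(Zf * Kf[None], n, axis=-1)[..., :L].transpose(0, 2, 1)
            Y = Y + self.params[f"blk{i}.D"] * Z
            H, tanh_t = _gelu(Y)
            M = H @ self.params[f"blk{i}.Wm"] + self.params[f"blk{i}.bm"]
            if cache is not None:
                cache["blocks"].append(dict(Z=Z, ln=ln_cache, G=G, Zf=Zf,
                                            Kf=Kf, Y=Y, H=H, t=tanh_t))
            X = X + M
        Xf, lnf_cache = _layernorm_fwd(X, self.params["lnf_g"], self.params["lnf_b"])
        if cache is not None:
            cache["Xf"], cache["lnf"] = Xf, lnf_cache
        return Xf @ self.params["Wout"] + self.params["bout"]

    def log_probs(self, ids: np.ndarray) -> np.ndarray:
        """Log-softmax of the conv-mode logits, shape (batch, T, vocab)."""
        logits = self.forward(np.atleast_2d(ids))
        z = logits - logits.max(axis=-1, keepdims=True)
        return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))

    # --------------------------------------------------------------- backward

    def loss_and_grads(self, ids: np.ndarray, pad_id: int):
        """Teacher-forced next-token cross-entropy and exact gradients.

        Inputs are ``ids[:, :-1]``, targets ``ids[:, 1:]``; PAD targets are
        masked out (EOS is scored).  Returns ``(loss, accuracy, grads)``.
        """
        ids = np.atleast_2d(ids)
        inputs, targets = ids[:, :-1], ids[:, 1:]
        mask = targets != pad_id
        n_tok = int(mask.sum())
        if n_tok == 0:
            raise ValueError("no unmasked target positions")
        cache: dict = {}
        logits = self.forward(inputs, cache)
        z = logits - logits.max(axis=-1, keepdims=True)
        logZ = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        logp = z - logZ
        Bt, L = inputs.shape
        tgt_lp = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
        loss = -(tgt_lp * mask).sum() / n_tok
        if not np.isfinite(loss):
            raise FloatingPointError("training loss diverged (non-finite)")
        acc = float(((logits.argmax(-1) == targets) & mask).sum() / n_tok)

        dlogits = np.exp(logp)
        flat = dlogits.reshape(-1, dlogits.shape[-1])
        flat[np.arange(Bt * L), targets.reshape(-1)] -= 1.0
        dlogits *= (mask[..., None] / n_tok)

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        Xf = cache["Xf"]
        grads["Wout"] = np.einsum("btd,btv->dv", Xf, dlogits)
        grads["bout"] = dlogits.sum(axis=(0, 1))
        dXf = dlogits @ self.params["Wout"].T
        dX, grads["lnf_g"], grads["lnf_b"] = _layernorm_bwd(dXf, cache["lnf"])

        n = cache["n"]
        for i in reversed(range(self.config.n_blocks)):
            blk = cache["blocks"][i]
            dM = dX  # residual: dX flows both into the block and around it
            grads[f"blk{i}.Wm"] = np.einsum("btd,bte->de", blk["H"], dM)
            grads[f"blk{i}.bm"] = dM.sum(axis=(0, 1))
            dH = dM @ self.params[f"blk{i}.Wm"].T
            dY = dH * _gelu_grad(blk["Y"], blk["t"])
            grads[f"blk{i}.D"] = (dY * blk["Z"]).sum(axis=(0, 1))
            dZ = dY * self.params[f"blk{i}.D"]
            # conv backward: dZ_t += sum_{s>=t} K_{s-t} dY_s  (correlation)
            dYf = rfft(np.ascontiguousarray(dY.transpose(0, 2, 1)), n, axis=-1)
            dZ = dZ + irfft(dYf * np.conj(blk["Kf"])[None], n,
                            axis=-1)[..., :L].transpose(0, 2, 1)
            # dK_l = sum_{b, t>=l} dY_{b,t} Z_{b,t-l}
            E = (dYf * np.conj(blk["Zf"])).sum(axis=0)
            dK = irfft(E, n, axis=-1)[:, :L]  # (d, L)
            grads[f"blk{i}.C"] = (blk["G"].transpose(0, 2, 1)
                                  @ dK[:, :, None])[..., 0]
            # dBbar = sum_l dK_l · (C Abar^l)
            _, PC = self._apow(i, L)
            d, N = self.params[f"blk{i}.C"].shape
            H_rows = (self.params[f"blk{i}.C"][:, None, :]
                      @ PC).reshape(d, L, N)
            dB_bar = (H_rows.transpose(0, 2, 1) @ dK[:, :, None])[..., 0]
            grads[f"blk{i}.B"] = np.einsum(
                "cnm,cn->cm", self.buffers[f"blk{i}.TB"], dB_bar)
            dZ_in, grads[f"blk{i}.ln_g"], grads[f"blk{i}.ln_b"] = \
                _layernorm_bwd(dZ, blk["ln"])
            dX = dX + dZ_in
        # embedding scatter as a one-hot matmul (faster than ufunc.at)
        onehot = (cache["ids"].reshape(-1, 1)
                  == np.arange(self.config.vocab_size)).astype(dX.dtype)
        grads["emb"] = onehot.T @ dX.reshape(-1, dX.shape[-1])
        return float(loss), acc, grads

    def loss(self, ids: np.ndarray, pad_id: int) -> tuple[float, float]:
        """Forward-only loss and next-token accuracy (for validation)."""
        ids = np.atleast_2d(ids)
        inputs, targets = ids[:, :-1], ids[:, 1:]
        mask = targets != pad_id
        logp = self.log_probs(inputs)
        tgt_lp = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
        n_tok = int(mask.sum())
        loss = float(-(tgt_lp * mask).sum() / n_tok)
        acc = float(((logp.argmax(-1) == targets) & mask).sum() / n_tok)
        return loss, acc

    # -------------------------------------------------------------- recurrent

    def init_recurrent_state(self, batch: int) -> "RecurrentModelState":
        return RecurrentModelState(self, batch)

    def copy(self) -> "CLM":
        clone = CLM.__new__(CLM)
        clone.config = self.config
        clone.params = {k: v.copy() for k, v in self.params.items()}
        clone.buffers = self.buffers  # fixed, shareable
        return clone

    # ------------------------------------------------------------ persistence

    def save(self, directory: str | Path, vocab: Vocabulary,
             metadata: dict | None = None) -> None:
        """Write weights, config, vocabulary and metadata to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params,
                 **{f"buf__{k}": v for k, v in self.buffers.items()})
        meta = dict(metadata or {})
        meta["vocab_hash"] = vocab.content_hash()
        cfg = asdict(self.config)
        cfg["delta_range"] = list(cfg["delta_range"])
        (directory / "config.json").write_text(
            json.dumps({"config": cfg, "metadata": meta}, indent=2))
        vocab.save(directory / "vocab.txt")

    @classmethod
    def load(cls, directory: str | Path) -> tuple["CLM", Vocabulary, dict]:
        """Load a checkpoint; verifies the stored vocabulary hash."""
        directory = Path(directory)
        blob = json.loads((directory / "config.json").read_text())
        cfg = blob["config"]
        cfg["delta_range"] = tuple(cfg["delta_range"])
        vocab = Vocabulary.load(directory / "vocab.txt")
        if vocab.content_hash() != blob["metadata"]["vocab_hash"]:
            raise ValueError("vocabulary file does not match checkpoint hash")
        model = cls.__new__(cls)
        model.config = CLMConfig(**cfg)
        data = np.load(directory / "weights.npz")
        model.params = {k: data[k] for k in data.files if not k.startswith("buf__")}
        model.buffers = {k[len("buf__"):]: data[k]
                         for k in data.files if k.startswith("buf__")}
        return model, vocab, blob["metadata"]


class RecurrentModelState:
    """Per-sequence hidden states for recurrent (generation-time) execution.

    Holds one state vector of size N per (sequence, channel, block), all
    initialized to zero at sequence start.
    """

    def __init__(self, model: CLM, batch: int):
        self.model = model
        cfg = model.config
        self.S = [np.zeros((batch, cfg.model_width, cfg.state_size))
                  for _ in range(cfg.n_blocks)]
        self._B_bar = [
            np.einsum("cnm,cm->cn", model.buffers[f"blk{i}.TB"],
                      model.params[f"blk{i}.B"])
            for i in range(cfg.n_blocks)
        ]

    def step(self, token_ids: np.ndarray) -> np.ndarray:
        """Advance one position; returns next-token logits (batch, vocab)."""
        m = self.model
        x = m.params["emb"][np.asarray(token_ids)]
        for i in range(m.config.n_blocks):
            z, _ = _layernorm_fwd(x, m.params[f"blk{i}.ln_g"],
                                  m.params[f"blk{i}.ln_b"])
            A_bar = m.buffers[f"blk{i}.A_bar"]
            self.S[i] = (np.einsum("cnm,bcm->bcn", A_bar, self.S[i])
                         + self._B_bar[i][None] * z[..., None])
            y = (np.einsum("bcn,cn->bc", self.S[i], m.params[f"blk{i}.C"])
                 + m.params[f"blk{i}.D"] * z)
            h, _ = _gelu(y)
            x = x + h @ m.params[f"blk{i}.Wm"] + m.params[f"blk{i}.bm"]
        xf, _ = _layernorm_fwd(x, m.params["lnf_g"], m.params["lnf_b"])
        return xf @ m.params["Wout"] + m.params["bout"]


def clm_forward(ids: np.ndarray, model: CLM, mode: str = "convolutional"
                ) -> np.ndarray:
    """Per-position next-token logits in either execution mode.

    Both modes use the same parameters and must agree within floating-point
    tolerance; the convolutional mode processes the whole sequence at once,
    the recurrent mode replays it token by token.
    """
    ids = np.atleast_2d(ids)
    if mode == "convolutional":
        return model.forward(ids)
    if mode == "recurrent":
        state = model.init_recurrent_state(ids.shape[0])
        out = np.stack([state.step(ids[:, t]) for t in range(ids.shape[1])],
                       axis=1)
        return out
    raise ValueError(f"unknown mode {mode!r}")
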