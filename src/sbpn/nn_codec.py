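"""Feed-forward bottleneck neural transform coder.

An autoassociative single-hidden-layer network maps length-n input chunks
through a k-unit bottleneck (k < n for compression) and back:

    h = tansig(W_enc x),     y = W_dec h

The encoder weights are initialised from the data's outer-product (Gram)
matrix: its top-k unit eigenvectors form W_enc and their transpose W_dec --
the implementable reading of the Hebbian-style weight formulas, equivalent
to principal-component initialisation.  Backpropagation (full-batch
least-mean-square descent on reconstruction error) then refines both weight
matrices, stopping at an error goal of 0.1 or a fixed epoch budget of 50.

The hidden activations are the compressed representation; for storage they
are uniformly quantized to 8 bits over the tansig range (-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cosimilar import FlatSequence
from .errors import ScaleError, TrainingError

__all__ = [
    "NNModel",
    "HiddenCode",
    "chunk_and_normalize",
    "denormalize",
    "init_weights_hebbian",
    "train",
    "encode",
    "decode",
    "quantize_hidden",
    "dequantize_hidden",
]


@dataclass
class NNModel:
    """Bottleneck transform coder state.

    Parameters
    ----------
    n : chunk length (input/output width)
    k : hidden size; k <= n, and k < n gives compression
    w_enc : (k, n) encoder weights
    w_dec : (n, k) decoder weights
    hidden_activation : "tansig" (default) or "linear"
    scale : normalization scale s_max the chunks were divided by
    signed : whether chunks used the signed map x/s_max (True) or the
        nonnegative map 2x/s_max - 1 (False)
    goal : mean-squared-error training target (normalized units)
    max_epochs : epoch budget
    seed : recorded for reproducibility of the full codec path
    """

    n: int
    k: int
    w_enc: np.ndarray
    w_dec: np.ndarray
    hidden_activation: str = "tansig"
    scale: float = 1.0
    signed: bool = False
    goal: float = 0.1
    max_epochs: int = 50
    seed: int = 0
    initial_mse: float | None = None
    final_mse: float | None = None
    epochs_run: int = 0

    def __post_init__(self):
        if not 1 <= self.k <= self.n:
            raise ValueError(f"hidden size k={self.k} must satisfy 1 <= k <= n={self.n}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.hidden_activation not in ("tansig", "linear"):
            raise ValueError(f"unknown activation {self.hidden_activation!r}")
        for w, shape in ((self.w_enc, (self.k, self.n)), (self.w_dec, (self.n, self.k))):
            if w.shape != shape:
                raise ValueError(f"weight shape {w.shape} != {shape}")
            if not np.all(np.isfinite(w)):
                raise ValueError("weights must be finite")


@dataclass
class HiddenCode:
    """Per-chunk hidden vectors -- the compressed representation."""

    h: np.ndarray  # (n_chunks, k)
    pad: int  # zero-pad count of the final chunk

    @property
    def n_chunks(self) -> int:
        return self.h.shape[0]

    @property
    def k(self) -> int:
        return self.h.shape[1]


def _as_array(s) -> np.ndarray:
    if isinstance(s, FlatSequence):
        return s.values.astype(np.float64)
    return np.asarray(s, dtype=np.float64)


def chunk_and_normalize(s, n: int, s_max: float,
                        signed: bool = False) -> tuple[np.ndarray, int]:
    """Normalize a sequence into [-1, 1] and cut it into length-n chunks.

    Nonnegative streams use the affine map x -> 2x/s_max - 1 (so 0 and s_max
    land on the interval endpoints); signed streams use x -> x/s_max.  The
    final chunk is zero-padded and the pad count returned.

    Raises :class:`ScaleError` if any normalized value leaves [-1, 1].
    """
    if n < 2:
        raise ValueError("chunk length must be >= 2")
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    x = _as_array(s)
    norm = x / s_max if signed else 2.0 * x / s_max - 1.0
    if np.any(np.abs(norm) > 1.0 + 1e-12):
        raise ScaleError(
            f"normalization scale {s_max} too small: max |normalized| = "
            f"{np.abs(norm).max():.6g}"
        )
    pad = (-len(norm)) % n
    if pad:
        norm = np.concatenate((norm, np.zeros(pad)))
    return norm.reshape(-1, n), pad


def denormalize(y: np.ndarray, s_max: float, signed: bool = False) -> np.ndarray:
    """Inverse of the normalization map."""
    return y * s_max if signed else (y + 1.0) * s_max / 2.0


def init_weights_hebbian(chunks: np.ndarray, k: int, seed: int = 0,
                         hidden_activation: str = "tansig",
                         goal: float = 0.1, max_epochs: int = 50) -> NNModel:
    """Build encode/decode weights from the chunk Gram matrix.

    The Gram matrix G = sum_c x_c x_c^T is accumulated over all chunks; its
    top-k eigenvectors (deterministic sign: largest-magnitude entry positive)
    become the rows of W_enc, and W_dec is their transpose.
    """
    chunks = np.asarray(chunks, dtype=np.float64)
    if chunks.ndim != 2 or chunks.shape[0] < 1:
        raise ValueError("need at least one chunk")
    n = chunks.shape[1]
    if not 1 <= k <= n:
        raise ValueError(f"hidden size k={k} must satisfy 1 <= k <= n={n}")
    gram = chunks.T @ chunks  # sum of outer products x x^T
    eigvals, eigvecs = np.linalg.eigh(gram)
    top = np.argsort(eigvals)[::-1][:k]
    w_enc = eigvecs[:, top].T.copy()  # (k, n)
    # deterministic sign convention: largest-|entry| coordinate positive
    for row in w_enc:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return NNModel(
        n=n, k=k, w_enc=w_enc, w_dec=w_enc.T.copy(),
        hidden_activation=hidden_activation, goal=goal,
        max_epochs=max_epochs, seed=seed,
    )


def _forward(model: NNModel, chunks: np.ndarray):
    with np.errstate(over="ignore", invalid="ignore"):
        a = chunks @ model.w_enc.T
        h = np.tanh(a) if model.hidden_activation == "tansig" else a
        y = h @ model.w_dec.T
    return h, y


def _mse(model: NNModel, chunks: np.ndarray) -> float:
    _, y = _forward(model, chunks)
    return float(np.mean((y - chunks) ** 2))


def train(model: NNModel, chunks: np.ndarray,
          learning_rate: float = 0.2) -> NNModel:
    """Refine the weights by full-batch gradient descent on reconstruction MSE.

    One epoch is one full-batch step.  A backtracking rule (halve the step
    when the error would rise, modestly grow it after an accepted step)
    makes the reported error non-increasing epoch over epoch.  Training
    stops when the error reaches ``model.goal`` or after ``model.max_epochs``
    epochs; the whole procedure is deterministic.
    """
    chunks = np.asarray(chunks, dtype=np.float64)
    if chunks.ndim != 2 or chunks.shape[0] < 1:
        raise ValueError("chunks must be a nonempty (N, n) array")
    if chunks.shape[1] != model.n:
        raise ValueError(f"chunk length {chunks.shape[1]} != model n {model.n}")
    n_el = chunks.size
    w_enc = model.w_enc.copy()
    w_dec = model.w_dec.copy()
    cur = NNModel(**{**model.__dict__, "w_enc": w_enc, "w_dec": w_dec})
    err = _mse(cur, chunks)
    if not np.isfinite(err):
        raise TrainingError("reconstruction error not finite", epoch=0)
    initial = err
    lr = learning_rate
    epochs = 0
    for epoch in range(1, model.max_epochs + 1):
        if err <= model.goal:
            break
        h, y = _forward(cur, chunks)
        e = y - chunks
        d_y = 2.0 * e / n_el
        g_dec = d_y.T @ h  # (n, k)
        d_h = d_y @ cur.w_dec  # (N, k)
        d_a = d_h * (1.0 - h ** 2) if cur.hidden_activation == "tansig" else d_h
        g_enc = d_a.T @ chunks  # (k, n)
        # backtracking: accept only error-decreasing steps
        accepted = False
        for _ in range(30):
            trial_enc = cur.w_enc - lr * g_enc
            trial_dec = cur.w_dec - lr * g_dec
            trial = replace(cur, w_enc=trial_enc, w_dec=trial_dec)
            trial_err = _mse(trial, chunks)
            if not np.isfinite(trial_err):
                raise TrainingError("training diverged", epoch=epoch)
            if trial_err <= err:
                cur, err = trial, trial_err
                lr *= 1.1
                accepted = True
                break
            lr *= 0.5
        epochs = epoch
        if not accepted:  # no descent direction at working precision
            break
    return replace(cur, initial_mse=initial, final_mse=err, epochs_run=epochs)


def encode(model: NNModel, chunks: np.ndarray, pad: int = 0) -> HiddenCode:
    """Hidden-layer codes h = activation(W_enc x) for every chunk."""
    chunks = np.asarray(chunks, dtype=np.float64)
    if chunks.ndim != 2 or chunks.shape[1] != model.n:
        raise ValueError(
            f"chunks must have shape (N, {model.n}), got {chunks.shape}"
        )
    h, _ = _forward(model, chunks)
    return HiddenCode(h=h, pad=pad)


def decode(model: NNModel, code: HiddenCode, clip: tuple[int, int] | None = None,
           round_int: bool = False) -> np.ndarray:
    """Reconstruct the flat sequence from hidden codes.

    y = W_dec h per chunk (linear output), concatenated, padding stripped,
    denormalized by the model's scale.  For integer-valued streams pass
    ``round_int=True`` and a ``clip`` range for the coded values.
    """
    if code.h.ndim != 2 or code.h.shape[1] != model.k:
        raise ValueError(f"hidden code width {code.h.shape} != k={model.k}")
    if not 0 <= code.pad < model.n:
        raise ValueError(f"pad count {code.pad} must be in [0, n)")
    y = code.h @ model.w_dec.T
    flat = y.reshape(-1)
    if code.pad:
        flat = flat[: -code.pad]
    out = denormalize(flat, model.scale, model.signed)
    if round_int:
        out = np.sign(out) * np.floor(np.abs(out) + 0.5)
    if clip is not None:
        out = np.clip(out, clip[0], clip[1])
    if round_int:
        out = out.astype(np.int64)
    return out


def quantize_hidden(h: np.ndarray) -> np.ndarray:
    """Uniform 8-bit quantization of hidden activations over [-1, 1]."""
    return np.clip(np.rint((h + 1.0) * 127.5), 0, 255).astype(np.uint8)


def dequantize_hidden(q: np.ndarray) -> np.ndarray:
    return q.astype(np.float64) / 127.5 - 1.0
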