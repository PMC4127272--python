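"""The cosimilar pair-value coder.

Runs of equal adjacent values ("cosimilar" coefficients -- the image's
redundant pixels) are segregated into (U, V) pairs of value and occurrence
count, exactly as in run-length coding.  The ordered pair list can be
flattened into the interleaved sequence S = U1, V1, U2, V2, ... which is the
neural coder's input representation.  All four mappings are exact inverses
on their domains.

Real-valued wavelet coefficients are bridged to the integer pair coder by
uniform scalar quantization: two coefficients are cosimilar when they fall
in the same quantizer bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CorruptStreamError

__all__ = [
    "PairSequence",
    "FlatSequence",
    "encode_pairs",
    "decode_pairs",
    "flatten",
    "unflatten",
    "split_runs",
    "quantize_plane",
    "dequantize_plane",
]


@dataclass
class PairSequence:
    """Ordered (value, count) run pairs of a scanned integer matrix.

    ``values[i]`` occurred ``counts[i]`` times; runs emitted by
    :func:`encode_pairs` are maximal (consecutive values differ) and counts
    sum to the number of scanned elements.
    """

    values: np.ndarray  # int64, the U_i
    counts: np.ndarray  # int64, the V_i (each >= 1)
    order: str = "raster"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.values.shape != self.counts.shape or self.values.ndim != 1:
            raise ValueError("values and counts must be 1-D and equal length")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PairSequence):
            return NotImplemented
        return (
            self.order == other.order
            and bool(np.array_equal(self.values, other.values))
            and bool(np.array_equal(self.counts, other.counts))
        )


@dataclass
class FlatSequence:
    """The interleaved sequence order S = U1, V1, U2, V2, ...

    Even positions (0-based) hold values, odd positions hold counts >= 1;
    the length is twice the pair count.
    """

    values: np.ndarray
    order: str = "raster"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1:
            raise ValueError("flat sequence must be 1-D")

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FlatSequence):
            return NotImplemented
        return self.order == other.order and bool(
            np.array_equal(self.values, other.values)
        )


def encode_pairs(matrix, order: str = "raster") -> PairSequence:
    """Run-length encode an integer matrix into maximal (U, V) pairs.

    The default (and only built-in) scan order is row-major raster.
    """
    if order != "raster":
        raise ValueError(f"unknown scan order {order!r}")
    mat = np.asarray(matrix)
    if mat.size == 0:
        raise ValueError("matrix must be nonempty")
    if not np.issubdtype(mat.dtype, np.integer):
        raise ValueError("matrix entries must be integers")
    flat = mat.reshape(-1).astype(np.int64)
    # boundaries of maximal runs
    starts = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate(([0], starts))
    values = flat[starts]
    counts = np.diff(np.concatenate((starts, [flat.size])))
    return PairSequence(values=values, counts=counts, order=order)


def decode_pairs(p: PairSequence, dims: tuple[int, int]):
    """Expand a pair sequence back to an (m, n) integer matrix.

    Exact inverse of :func:`encode_pairs` for the same scan order; a count
    sum that does not match ``m * n`` raises :class:`CorruptStreamError`.
    """
    m, n = dims
    if np.any(p.counts < 1):
        raise CorruptStreamError("run counts must be >= 1")
    if p.total != m * n:
        raise CorruptStreamError(
            f"pair counts sum to {p.total}, but dims {m}x{n} need {m * n}"
        )
    return np.repeat(p.values, p.counts).reshape(m, n)


def flatten(p: PairSequence) -> FlatSequence:
    """Interleave pairs into the flat sequence order S."""
    flat = np.empty(2 * len(p), dtype=np.int64)
    flat[0::2] = p.values
    flat[1::2] = p.counts
    return FlatSequence(values=flat, order=p.order)


def unflatten(s: FlatSequence) -> PairSequence:
    """Rebuild (U, V) pairs from the flat sequence; inverse of :func:`flatten`."""
    if len(s) % 2 != 0:
        raise CorruptStreamError(f"flat sequence length {len(s)} is odd")
    values = s.values[0::2]
    counts = s.values[1::2]
    if np.any(counts < 1):
        raise CorruptStreamError("flat sequence has a count < 1")
    return PairSequence(values=values, counts=counts, order=s.order)


def split_runs(p: PairSequence, cap: int = 255) -> PairSequence:
    """Split runs longer than ``cap`` into repeated pairs.

    Used before neural coding so every count fits the normalization range;
    the result is intentionally *not* maximal (repeated pairs share a value)
    and expands identically through :func:`decode_pairs`'s repeat logic.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if np.all(p.counts <= cap):
        return PairSequence(p.values.copy(), p.counts.copy(), order=p.order)
    reps = (p.counts + cap - 1) // cap  # pairs each run expands to
    values = np.repeat(p.values, reps)
    counts = np.full(int(reps.sum()), cap, dtype=np.int64)
    # last pair of each run carries the remainder
    last_idx = np.cumsum(reps) - 1
    rem = p.counts - (reps - 1) * cap
    counts[last_idx] = rem
    return PairSequence(values=values, counts=counts, order=p.order)


def quantize_plane(plane, step: float) -> np.ndarray:
    """Uniform scalar quantization: round-to-nearest of value/step, ties away
    from zero.  Bridges real DWT coefficients to the integer pair coder."""
    if step <= 0:
        raise ValueError("quantizer step must be > 0")
    vals = np.asarray(getattr(plane, "values", plane), dtype=np.float64)
    scaled = vals / step
    return (np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)).astype(np.int64)


def dequantize_plane(q, step: float) -> np.ndarray:
    """Midpoint reconstruction q * step; error is at most step/2 per entry."""
    if step <= 0:
        raise ValueError("quantizer step must be > 0")
    return np.asarray(q, dtype=np.float64) * step
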