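"""Grayscale image I/O and the ``.sbpn`` compressed container.

The codec operates on 8-bit grayscale matrices (:class:`GrayImage`).  Multi
channel inputs are reduced to luminance with the ITU-R BT.601 weights; deeper
bit depths are rejected rather than rescaled so that rate/distortion
accounting stays on the 8-bit pixel scale.

The compressed container is a bespoke little-endian binary format (magic
``SBPN``).  It is self-describing: the header fully determines how the
payload parses, and its serialized byte length is the codec's "compressed
size" for all compression-ratio metrics.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import CorruptContainerError, UnsupportedFormatError

__all__ = [
    "GrayImage",
    "StreamRecord",
    "CompressedArtifact",
    "read_image",
    "write_image",
    "serialize_artifact",
    "deserialize_artifact",
    "encode_varints",
    "decode_varints",
    "zigzag_encode",
    "zigzag_decode",
]

# BT.601 luma weights for RGB -> gray reduction.
_LUMA = np.array([0.299, 0.587, 0.114])

MAGIC = b"SBPN"
VERSION = 1

#: artifact mode tags <-> wire bytes
MODES = {"lossless": 0, "direct": 1, "spectral": 2}
_MODE_NAMES = {v: k for k, v in MODES.items()}


@dataclass
class GrayImage:
    """An m x n 8-bit intensity matrix, the codec's input/output unit.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (m, n)
    dpi : int, optional
        Resolution metadata carried through read/write when present.
    """

    pixels: np.ndarray
    dpi: int | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a 2-D matrix, got shape {px.shape}")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValueError("pixel values must be integers")
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )


def read_image(path) -> GrayImage:
    """Read a PNG or TIFF file into a :class:`GrayImage`.

    Multi-channel images are converted to luminance with the BT.601 weights
    (0.299 R + 0.587 G + 0.114 B) and rounded.  Bit depths above 8 raise
    :class:`UnsupportedFormatError` -- no silent rescale.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            dpi = im.info.get("dpi")
            if mode in ("I", "I;16", "I;16B", "I;16L", "I;16N", "F"):
                raise UnsupportedFormatError(
                    f"{path}: bit depth > 8 is not supported (mode {mode!r})"
                )
            if mode == "1":
                arr = (np.asarray(im, dtype=np.uint8) * 255).astype(np.uint8)
            elif mode == "L":
                arr = np.asarray(im, dtype=np.uint8)
            else:
                rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
                arr = np.rint(rgb @ _LUMA).clip(0, 255).astype(np.uint8)
    except FileNotFoundError:
        raise IOError(f"cannot read image: {path} (file not found)")
    except UnidentifiedImageError:
        raise IOError(f"cannot read image: {path} (not a recognised raster format)")
    dpi_val = int(round(dpi[0])) if dpi else None
    return GrayImage(arr, dpi=dpi_val)


def write_image(img: GrayImage, path) -> None:
    """Write an image losslessly as PNG or TIFF (by file extension).

    TIFF output uses deflate compression; both formats round-trip bit-exact
    through :func:`read_image`.
    """
    path = Path(path)
    pil = Image.fromarray(img.pixels, mode="L")
    kwargs = {}
    if img.dpi is not None:
        kwargs["dpi"] = (img.dpi, img.dpi)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            pil.save(path, format="TIFF", compression="tiff_deflate", **kwargs)
        else:
            pil.save(path, format="PNG", **kwargs)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot write image: {path} ({exc})")


# ---------------------------------------------------------------------------
# varints


def encode_varints(values) -> bytes:
    """LEB128-style unsigned varint encoding of an integer sequence."""
    out = bytearray()
    for v in values:
        v = int(v)
        if v < 0:
            raise ValueError("varints encode nonnegative integers only")
        while True:
            b = v & 0x7F
            v >>= 7
            if v:
                out.append(b | 0x80)
            else:
                out.append(b)
                break
    return bytes(out)


def decode_varints(buf: bytes, count: int, offset: int = 0) -> tuple[np.ndarray, int]:
    """Decode ``count`` varints from ``buf`` starting at ``offset``.

    Returns ``(values, next_offset)``.
    """
    values = np.empty(count, dtype=np.int64)
    pos = offset
    n = len(buf)
    for i in range(count):
        result = 0
        shift = 0
        while True:
            if pos >= n:
                raise CorruptContainerError("varint stream truncated", offset=pos)
            b = buf[pos]
            pos += 1
            result |= (b & 0x7F) << shift
            if not b & 0x80:
                break
            shift += 7
        values[i] = result
    return values, pos


def zigzag_encode(values: np.ndarray) -> np.ndarray:
    """Map signed integers onto nonnegative ones (0,-1,1,-2 -> 0,1,2,3)."""
    v = np.asarray(values, dtype=np.int64)
    return np.where(v >= 0, 2 * v, -2 * v - 1)


def zigzag_decode(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=np.int64)
    return np.where(v % 2 == 0, v // 2, -(v + 1) // 2)


# ---------------------------------------------------------------------------
# container


@dataclass
class StreamRecord:
    """One coded coefficient stream (whole image, or one subband plane).

    ``blocks`` maps block names to raw payload bytes; which blocks are
    present depends on the mode (``pairs`` for lossless streams; ``counts``,
    ``w_dec`` and ``hidden`` for neural-coded streams).
    """

    label: str
    rows: int
    cols: int
    qstep: float = 1.0
    signed: bool = False
    s_max: float = 255.0
    u_lo: int = 0
    u_hi: int = 255
    chunk_n: int = 0
    k: int = 0
    pad: int = 0
    n_chunks: int = 0
    n_pairs: int = 0
    flat_len: int = 0
    blocks: dict[str, bytes] = field(default_factory=dict)


@dataclass
class CompressedArtifact:
    """Self-describing compressed representation of one image."""

    mode: str
    m: int
    n: int
    levels: int = 0
    wavelet: str = ""
    pad_mode: str = ""
    streams: list[StreamRecord] = field(default_factory=list)

    @property
    def nbytes(self) -> int:
        """Serialized container length in bytes (the codec's compressed size)."""
        return len(serialize_artifact(self))


def _pack_str(s: str) -> bytes:
    b = s.encode("utf-8")
    if len(b) > 255:
        raise ValueError("tag too long")
    return struct.pack("<B", len(b)) + b


_STREAM_FIXED = struct.Struct("<IIdBdiiHHHIII")


def serialize_artifact(a: CompressedArtifact) -> bytes:
    """Serialize to the ``.sbpn`` wire format (deterministic byte layout)."""
    if a.mode not in MODES:
        raise ValueError(f"unknown mode {a.mode!r}")
    out = bytearray()
    out += MAGIC
    out += struct.pack("<BB", VERSION, MODES[a.mode])
    out += struct.pack("<IIB", a.m, a.n, a.levels)
    out += _pack_str(a.wavelet)
    out += _pack_str(a.pad_mode)
    out += struct.pack("<H", len(a.streams))
    for s in a.streams:
        out += _pack_str(s.label)
        out += _STREAM_FIXED.pack(
            s.rows, s.cols, s.qstep, int(s.signed), s.s_max, s.u_lo, s.u_hi,
            s.chunk_n, s.k, s.pad, s.n_chunks, s.n_pairs, s.flat_len,
        )
        out += struct.pack("<B", len(s.blocks))
        for name, blob in s.blocks.items():
            out += _pack_str(name)
            out += struct.pack("<I", len(blob))
            out += blob
    return bytes(out)


class _Reader:
    def __init__(self, buf: bytes):
        self.buf = buf
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise CorruptContainerError(
                f"container truncated: need {n} more bytes", offset=self.pos
            )
        b = self.buf[self.pos : self.pos + n]
        self.pos += n
        return b

    def unpack(self, st: struct.Struct):
        return st.unpack(self.take(st.size))

    def read_str(self) -> str:
        (ln,) = struct.unpack("<B", self.take(1))
        return self.take(ln).decode("utf-8")


def deserialize_artifact(buf: bytes) -> CompressedArtifact:
    """Parse a ``.sbpn`` byte string; exact inverse of :func:`serialize_artifact`.

    Raises :class:`CorruptContainerError` (with the failing byte offset) on
    bad magic, unknown version, truncation, or trailing bytes.
    """
    r = _Reader(buf)
    if r.take(4) != MAGIC:
        raise CorruptContainerError("bad magic bytes (not an .sbpn container)", offset=0)
    version, mode_b = struct.unpack("<BB", r.take(2))
    if version != VERSION:
        raise CorruptContainerError(f"unsupported container version {version}", offset=4)
    if mode_b not in _MODE_NAMES:
        raise CorruptContainerError(f"unknown mode byte {mode_b}", offset=5)
    m, n, levels = struct.unpack("<IIB", r.take(9))
    wavelet = r.read_str()
    pad_mode = r.read_str()
    (n_streams,) = struct.unpack("<H", r.take(2))
    streams = []
    for _ in range(n_streams):
        label = r.read_str()
        (rows, cols, qstep, signed, s_max, u_lo, u_hi,
         chunk_n, k, pad, n_chunks, n_pairs, flat_len) = r.unpack(_STREAM_FIXED)
        (n_blocks,) = struct.unpack("<B", r.take(1))
        blocks: dict[str, bytes] = {}
        for _ in range(n_blocks):
            name = r.read_str()
            (ln,) = struct.unpack("<I", r.take(4))
            blocks[name] = r.take(ln)
        streams.append(
            StreamRecord(
                label=label, rows=rows, cols=cols, qstep=qstep,
                signed=bool(signed), s_max=s_max, u_lo=u_lo, u_hi=u_hi,
                chunk_n=chunk_n, k=k, pad=pad, n_chunks=n_chunks,
                n_pairs=n_pairs, flat_len=flat_len, blocks=blocks,
            )
        )
    if r.pos != len(buf):
        raise CorruptContainerError(
            f"{len(buf) - r.pos} trailing bytes after payload", offset=r.pos
        )
    return CompressedArtifact(
        mode=_MODE_NAMES[mode_b], m=m, n=n, levels=levels,
        wavelet=wavelet, pad_mode=pad_mode, streams=streams,
    )
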