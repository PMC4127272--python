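"""Rate/distortion/timing metrics and the codec comparison harness.

Metrics follow the usual image-codec conventions: compression ratio is
original bytes over compressed bytes (original size of an m x n 8-bit image
is m*n bytes), and PSNR is 10*log10(255^2 / MSE) dB, infinite for exact
reconstruction.  ``run_suite`` evaluates every (image, codec) cell, records
failures without aborting the suite, and can render the comparison as a
text table, CSV, or grouped bar plots.

External baselines (e.g. JPEG 2000) plug in through the same two-method
codec interface and are entirely optional.
"""

from __future__ import annotations

import csv
import io
import math
import time
from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage
from .pipeline import CodecConfig, compress_bytes, decompress_bytes

__all__ = ["MetricsRecord", "psnr", "compression_ratio", "run_suite",
           "SbpnCodec", "RawCodec", "Jpeg2000Codec", "records_to_csv",
           "comparison_table", "plot_metric"]

PEAK = 255.0  # 8-bit pipeline


def psnr(a: GrayImage, b: GrayImage) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the images are equal."""
    if a.shape != b.shape:
        raise ValueError(f"image dims differ: {a.shape} vs {b.shape}")
    diff = a.pixels.astype(np.float64) - b.pixels.astype(np.float64)
    mse = float(np.mean(diff * diff))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(PEAK * PEAK / mse)


def compression_ratio(original_bytes: float, compressed_bytes: float) -> float:
    """CR = original size / compressed size; > 1 means the artifact shrank."""
    if original_bytes <= 0 or compressed_bytes <= 0:
        raise ValueError("byte sizes must be positive")
    return original_bytes / compressed_bytes


@dataclass
class MetricsRecord:
    """One (sample, codec) evaluation cell."""

    sample_id: str
    codec_id: str
    original_bytes: int
    compressed_bytes: int | None = None
    ratio: float | None = None
    psnr_db: float | None = None
    encode_ms: float | None = None
    decode_ms: float | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


# ---------------------------------------------------------------------------
# codec plug-ins: anything with compress(img)->bytes and decompress(bytes)->GrayImage


class SbpnCodec:
    """This package's codec under one configuration."""

    def __init__(self, cfg: CodecConfig | None = None, codec_id: str | None = None):
        self.cfg = cfg or CodecConfig()
        self.codec_id = codec_id or f"sbpn-{self.cfg.mode}"

    def compress(self, img: GrayImage) -> bytes:
        return compress_bytes(img, self.cfg)

    def decompress(self, buf: bytes) -> GrayImage:
        return decompress_bytes(buf)


class RawCodec:
    """Identity codec (stores the raster verbatim); a sanity baseline."""

    codec_id = "raw"

    def compress(self, img: GrayImage) -> bytes:
        m, n = img.shape
        return m.to_bytes(4, "little") + n.to_bytes(4, "little") + img.pixels.tobytes()

    def decompress(self, buf: bytes) -> GrayImage:
        m = int.from_bytes(buf[:4], "little")
        n = int.from_bytes(buf[4:8], "little")
        return GrayImage(np.frombuffer(buf[8:], dtype=np.uint8).reshape(m, n))


class Jpeg2000Codec:
    """External JPEG 2000 baseline via Pillow's OpenJPEG bindings.

    Optional: construction fails with a clear error where Pillow lacks
    JPEG 2000 support, and ``run_suite`` records the failure and moves on.
    """

    codec_id = "jpeg2000"

    def __init__(self, quality_db: float = 40.0):
        self.quality_db = quality_db

    def compress(self, img: GrayImage) -> bytes:
        from PIL import Image

        buf = io.BytesIO()
        Image.fromarray(img.pixels, mode="L").save(
            buf, format="JPEG2000", quality_mode="dB",
            quality_layers=[self.quality_db], irreversible=True,
        )
        return buf.getvalue()

    def decompress(self, buf: bytes) -> GrayImage:
        from PIL import Image

        with Image.open(io.BytesIO(buf)) as im:
            return GrayImage(np.asarray(im.convert("L"), dtype=np.uint8))


# ---------------------------------------------------------------------------


def evaluate_one(img: GrayImage, codec, sample_id: str = "sample") -> MetricsRecord:
    """Compress/decompress one image with one codec and measure everything."""
    m, n = img.shape
    rec = MetricsRecord(sample_id=sample_id,
                        codec_id=getattr(codec, "codec_id", type(codec).__name__),
                        original_bytes=m * n)
    try:
        t0 = time.perf_counter()
        blob = codec.compress(img)
        t1 = time.perf_counter()
        out = codec.decompress(blob)
        t2 = time.perf_counter()
        rec.compressed_bytes = len(blob)
        rec.ratio = compression_ratio(rec.original_bytes, len(blob))
        rec.psnr_db = psnr(img, out)
        rec.encode_ms = (t1 - t0) * 1e3
        rec.decode_ms = (t2 - t1) * 1e3
    except Exception as exc:  # a failed cell must not sink the suite
        rec.error = f"{type(exc).__name__}: {exc}"
    return rec


def run_suite(images, codecs, sample_ids=None) -> list[MetricsRecord]:
    """Evaluate every codec on every image; one record per cell.

    CR and PSNR are deterministic given the codec seeds; only the timing
    fields vary between runs.
    """
    images = list(images)
    codecs = list(codecs)
    if not images or not codecs:
        raise ValueError("need at least one image and one codec")
    if sample_ids is None:
        sample_ids = [f"Q{i + 1}" for i in range(len(images))]
    records = []
    for sid, img in zip(sample_ids, images):
        for codec in codecs:
            records.append(evaluate_one(img, codec, sample_id=sid))
    return records


def records_to_csv(records, path) -> None:
    """Export suite results as CSV, one row per record."""
    fields = ["sample_id", "codec_id", "original_bytes", "compressed_bytes",
              "ratio", "psnr_db", "encode_ms", "decode_ms", "error"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for r in records:
            w.writerow({f: getattr(r, f) for f in fields})


def comparison_table(records) -> str:
    """Plain-text per-metric comparison table (samples x codecs)."""
    samples = sorted({r.sample_id for r in records})
    codecs = sorted({r.codec_id for r in records})
    cell = {(r.sample_id, r.codec_id): r for r in records}
    lines = []
    for metric, fmt in (("ratio", "{:.3f}"), ("psnr_db", "{:.2f}"),
                        ("encode_ms", "{:.1f}")):
        lines.append(f"== {metric} ==")
        header = "sample".ljust(10) + "".join(c.rjust(16) for c in codecs)
        lines.append(header)
        for s in samples:
            row = s.ljust(10)
            for c in codecs:
                r = cell.get((s, c))
                if r is None or r.failed or getattr(r, metric) is None:
                    row += "failed".rjust(16)
                else:
                    row += fmt.format(getattr(r, metric)).rjust(16)
            lines.append(row)
        lines.append("")
    return "\n".join(lines)


def plot_metric(records, metric: str, path) -> None:
    """Grouped bar plot of one metric (samples on x, one bar per codec)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = sorted({r.sample_id for r in records})
    codecs = sorted({r.codec_id for r in records})
    cell = {(r.sample_id, r.codec_id): r for r in records}
    x = np.arange(len(samples))
    width = 0.8 / len(codecs)
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(samples), 4))
    for i, c in enumerate(codecs):
        vals = []
        for s in samples:
            r = cell.get((s, c))
            v = getattr(r, metric) if r is not None and not r.failed else np.nan
            vals.append(np.nan if v is None or math.isinf(v) else v)
        ax.bar(x + (i - (len(codecs) - 1) / 2) * width, vals, width, label=c)
    ax.set_xticks(x, samples)
    ax.set_ylabel(metric)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
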