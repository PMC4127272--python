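"""Pyramidal 2-D DWT decomposition and exact inverse reconstruction.

One decomposition level splits an image into four coefficient planes:
horizontal detail (C1), vertical detail (C2), diagonal detail (C3) and the
approximate low-pass plane (C4).  The filter bank is recursive: deeper
levels re-decompose the approximate plane, halving resolution each time.

The default wavelet is the orthonormal Haar pair; odd dimensions are handled
by symmetric half-sample extension with the original shape recorded so the
inverse transform crops exactly.  Coefficients stay in floating point --
quantization is the coder's job, not the transform's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .image_io import GrayImage

__all__ = ["CoefficientPlane", "SubbandSet", "decompose", "reconstruct"]

#: orientation labels in paper order C1..C4
LABELS = ("horizontal", "vertical", "diagonal", "approximate")


@dataclass
class CoefficientPlane:
    """One subband plane at one level of the pyramid."""

    values: np.ndarray
    label: str  # horizontal | vertical | diagonal | approximate
    level: int

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown subband label {self.label!r}")
        if self.level < 1:
            raise ValueError("level must be >= 1")


@dataclass
class SubbandSet:
    """Full multiresolution pyramid of an image.

    ``details[i]`` holds the (horizontal, vertical, diagonal) planes of level
    ``i + 1``; ``approx`` is the approximate plane at the deepest level.
    """

    levels: int
    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    shape: tuple[int, int]
    wavelet: str
    pad_mode: str

    def plane(self, label: str, level: int) -> CoefficientPlane:
        """Fetch one plane by orientation label and level."""
        if not 1 <= level <= self.levels:
            raise ValueError(f"level must be in [1, {self.levels}]")
        if label == "approximate":
            if level != self.levels:
                raise ValueError("approximate plane exists only at the deepest level")
            return CoefficientPlane(self.approx, label, level)
        h, v, d = self.details[level - 1]
        values = {"horizontal": h, "vertical": v, "diagonal": d}[label]
        return CoefficientPlane(values, label, level)

    def iter_planes(self):
        """Yield every plane, approximate first then details shallow-to-deep."""
        yield self.plane("approximate", self.levels)
        for level in range(1, self.levels + 1):
            for label in ("horizontal", "vertical", "diagonal"):
                yield self.plane(label, level)


def decompose(img, levels: int = 1, wavelet: str = "haar",
              pad_mode: str = "symmetric") -> SubbandSet:
    """Pyramidal DWT of an image (or real matrix) into subband planes.

    Parameters
    ----------
    img : GrayImage or ndarray
    levels : int
        Pyramid depth L >= 1; requires 2**L <= min(m, n).
    wavelet : str
        Any discrete wavelet known to PyWavelets; default orthonormal Haar.
    pad_mode : str
        Boundary extension; default symmetric half-sample.
    """
    mat = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    mat = mat.astype(np.float64)
    m, n = mat.shape
    if levels < 1:
        raise ValueError("levels must be >= 1")
    max_level = int(np.floor(np.log2(min(m, n)))) if min(m, n) >= 2 else 0
    if 2 ** levels > min(m, n):
        raise ValueError(
            f"levels={levels} too deep for a {m}x{n} image; "
            f"max admissible level is {max_level}"
        )
    coeffs = pywt.wavedec2(mat, wavelet=wavelet, mode=pad_mode, level=levels)
    approx = coeffs[0]
    # pywt orders detail tuples coarsest-first; store shallow-first (level 1..L)
    details = [tuple(t) for t in reversed(coeffs[1:])]
    return SubbandSet(levels=levels, approx=approx, details=details,
                      shape=(m, n), wavelet=wavelet, pad_mode=pad_mode)


def reconstruct(sb: SubbandSet) -> np.ndarray:
    """Inverse DWT back to an (m, n) real matrix.

    ``reconstruct(decompose(img))`` is the identity within floating-point
    tolerance; the result is cropped to the shape recorded at decomposition.
    """
    if len(sb.details) != sb.levels:
        raise ValueError(
            f"structure error: {sb.levels} levels declared but "
            f"{len(sb.details)} detail triples present"
        )
    expected = _plane_shapes(sb.shape, sb.levels, sb.wavelet, sb.pad_mode)
    for lvl, triple in enumerate(sb.details, start=1):
        for plane in triple:
            if plane.shape != expected[lvl - 1]:
                raise ValueError(
                    f"structure error: level {lvl} detail plane has shape "
                    f"{plane.shape}, expected {expected[lvl - 1]}"
                )
    if sb.approx.shape != expected[sb.levels - 1]:
        raise ValueError(
            f"structure error: approximate plane has shape {sb.approx.shape}, "
            f"expected {expected[sb.levels - 1]}"
        )
    coeffs = [sb.approx] + [tuple(t) for t in reversed(sb.details)]
    rec = pywt.waverec2(coeffs, wavelet=sb.wavelet, mode=sb.pad_mode)
    m, n = sb.shape
    return rec[:m, :n]


def _plane_shapes(shape: tuple[int, int], levels: int, wavelet: str,
                  pad_mode: str) -> list[tuple[int, int]]:
    """Subband plane shape at each level (ceil-halving for two-tap filters)."""
    flen = pywt.Wavelet(wavelet).dec_len
    shapes = []
    m, n = shape
    for _ in range(levels):
        m = pywt.dwt_coeff_len(m, flen, pad_mode)
        n = pywt.dwt_coeff_len(n, flen, pad_mode)
        shapes.append((m, n))
    return shapes
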