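import numpy as np
import pytest
from PIL import Image

from sbpn import (CompressedArtifact, CorruptContainerError, GrayImage,
                  StreamRecord, UnsupportedFormatError, deserialize_artifact,
                  read_image, serialize_artifact, write_image)
from sbpn.image_io import (decode_varints, encode_varints, zigzag_decode,
                           zigzag_encode)

from .conftest import random_gray


class TestGrayImage:
    def test_rejects_out_of_range_and_bad_shape(self):
        with pytest.raises(ValueError):
            GrayImage(np.array([[300, 0]]))
        with pytest.raises(ValueError):
            GrayImage(np.array([1, 2, 3]))
        with pytest.raises(ValueError):
            GrayImage(np.array([[0.5]]))

    def test_accepts_int_matrix_and_coerces_dtype(self):
        img = GrayImage(np.array([[0, 255], [17, 4]]))
        assert img.pixels.dtype == np.uint8
        assert img.shape == (2, 2)


class TestReadWrite:
    def test_constant_gray_png_reads_identically(self, tmp_path):
        path = tmp_path / "c.png"
        Image.fromarray(np.full((2, 2), 128, dtype=np.uint8), "L").save(path)
        assert np.array_equal(read_image(path).pixels, np.full((2, 2), 128))

    def test_gray_rgb_collapses_to_its_value(self, tmp_path):
        # BT.601 luminance of an (v, v, v) pixel is exactly v
        path = tmp_path / "rgb.png"
        rgb = np.full((3, 4, 3), 77, dtype=np.uint8)
        Image.fromarray(rgb, "RGB").save(path)
        assert np.array_equal(read_image(path).pixels, np.full((3, 4), 77))

    @pytest.mark.parametrize("suffix", [".png", ".tiff"])
    @pytest.mark.parametrize("dims", [(1, 1), (5, 7), (64, 64)])
    def test_roundtrip_bit_exact(self, tmp_path, rng, suffix, dims):
        for trial in range(10):
            img = GrayImage(random_gray(rng, *dims))
            path = tmp_path / f"t{trial}{suffix}"
            write_image(img, path)
            assert read_image(path) == img

    def test_roundtrip_512(self, tmp_path, rng):
        img = GrayImage(random_gray(rng, 512, 512))
        path = tmp_path / "big.png"
        write_image(img, path)
        assert read_image(path) == img

    def test_constant_zero_roundtrip(self, tmp_path):
        img = GrayImage(np.zeros((4, 4), dtype=np.uint8))
        write_image(img, tmp_path / "z.tiff")
        assert read_image(tmp_path / "z.tiff") == img

    def test_sixteen_bit_rejected_not_rescaled(self, tmp_path):
        path = tmp_path / "deep.png"
        Image.fromarray(np.full((2, 2), 1000, dtype=np.uint16)).save(path)
        with pytest.raises(UnsupportedFormatError):
            read_image(path)

    def test_missing_file_error_names_path(self, tmp_path):
        with pytest.raises(IOError, match="nope.png"):
            read_image(tmp_path / "nope.png")

    def test_dpi_metadata_carried(self, tmp_path):
        img = GrayImage(np.zeros((4, 4), dtype=np.uint8), dpi=500)
        path = tmp_path / "d.tiff"
        write_image(img, path)
        assert read_image(path).dpi == 500


class TestVarints:
    def test_roundtrip_mixed_magnitudes(self, rng):
        vals = np.concatenate([
            [0, 1, 127, 128, 255, 300, 2 ** 20, 2 ** 31],
            rng.integers(0, 2 ** 24, size=200),
        ])
        buf = encode_varints(vals)
        out, pos = decode_varints(buf, len(vals))
        assert pos == len(buf)
        assert np.array_equal(out, vals)

    def test_zigzag_roundtrip_and_order(self):
        vals = np.array([0, -1, 1, -2, 2, -1000, 1000])
        assert np.array_equal(zigzag_encode(vals)[:5], [0, 1, 2, 3, 4])
        assert np.array_equal(zigzag_decode(zigzag_encode(vals)), vals)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            encode_varints([-1])

    def test_truncated_stream(self):
        buf = encode_varints([2 ** 20])[:-1]
        with pytest.raises(CorruptContainerError):
            decode_varints(buf, 1)


def _sample_artifact(rng):
    streams = [
        StreamRecord(label="a1", rows=32, cols=32, qstep=0.5, signed=True,
                     s_max=904.0, u_lo=-12, u_hi=1008, chunk_n=16, k=8,
                     pad=3, n_chunks=40, n_pairs=300, flat_len=600,
                     blocks={"counts": rng.bytes(120), "w_dec": rng.bytes(512),
                             "hidden": rng.bytes(320)}),
        StreamRecord(label="h1", rows=32, cols=32,
                     blocks={"pairs": rng.bytes(64)}),
    ]
    return CompressedArtifact(mode="spectral", m=64, n=64, levels=1,
                              wavelet="haar", pad_mode="symmetric",
                              streams=streams)


class TestContainer:
    def test_empty_payload_header_only(self):
        a = CompressedArtifact(mode="lossless", m=4, n=4)
        assert deserialize_artifact(serialize_artifact(a)) == a

    def test_roundtrip_structural_equality(self, rng):
        a = _sample_artifact(rng)
        buf = serialize_artifact(a)
        assert deserialize_artifact(buf) == a
        # byte-identical re-serialization: no timestamps, no random padding
        assert serialize_artifact(deserialize_artifact(buf)) == buf

    def test_phantom_artifact_roundtrips_byte_identically(self):
        from sbpn import CodecConfig, PhantomSpec, compress, generate_phantom

        img = generate_phantom(PhantomSpec(dims=(64, 64), seed=5))
        buf = serialize_artifact(compress(img, CodecConfig(mode="spectral")))
        assert serialize_artifact(deserialize_artifact(buf)) == buf

    def test_truncation_by_one_byte(self, rng):
        buf = serialize_artifact(_sample_artifact(rng))
        with pytest.raises(CorruptContainerError):
            deserialize_artifact(buf[:-1])

    def test_trailing_bytes_rejected(self, rng):
        buf = serialize_artifact(_sample_artifact(rng))
        with pytest.raises(CorruptContainerError, match="trailing"):
            deserialize_artifact(buf + b"\x00")

    def test_bad_magic_reports_offset_zero(self):
        with pytest.raises(CorruptContainerError) as exc:
            deserialize_artifact(b"JUNKJUNKJUNK")
        assert exc.value.offset == 0

    def test_bad_version(self, rng):
        buf = bytearray(serialize_artifact(_sample_artifact(rng)))
        buf[4] = 99
        with pytest.raises(CorruptContainerError, match="version"):
            deserialize_artifact(bytes(buf))
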