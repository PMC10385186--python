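"""Preprocessing: unit rescaling, resampling, slicing, splitting, pairing."""

import numpy as np
import pytest

from tracergan.pet_io import (CorruptDataError, InsufficientDataError,
                              InvalidMetadataError, RawSeries, Tracer,
                              pair_subsets, rescale_to_unit, resample_volume,
                              slice_axial, split_participants)


def _raw(pixels, bits=8, tracer=Tracer.FBB):
    return RawSeries(pixels=np.asarray(pixels), bits_stored=bits,
                     tracer=tracer, participant_id="P0")


class TestRescaleToUnit:
    @pytest.mark.parametrize("bits,pixel,expected", [
        (8, 255, 1.0),                # top code maps exactly to 1
        (8, 0, 0.0),
        (12, 819, 819 / 4095),        # = 0.2 by independent division
    ])
    def test_known_values(self, bits, pixel, expected):
        raw = _raw(np.full((2, 2, 2), pixel, dtype=np.uint16), bits=bits)
        out = rescale_to_unit(raw)
        assert out.shape == (2, 2, 2)
        assert np.allclose(out, expected, atol=0, rtol=1e-15)

    def test_range_and_monotonicity(self):
        vals = np.arange(0, 4096, dtype=np.uint16).reshape(16, 16, 16)
        out = rescale_to_unit(_raw(vals, bits=12))
        assert out.min() == 0.0 and out.max() == 1.0
        flat = out.ravel()
        assert np.all(np.diff(flat) > 0)  # strictly monotone in pixel value

    def test_invalid_bits_stored(self):
        with pytest.raises(InvalidMetadataError):
            _raw(np.zeros((2, 2, 2), dtype=np.uint16), bits=17)
        with pytest.raises(InvalidMetadataError):
            _raw(np.zeros((2, 2, 2), dtype=np.uint16), bits=0)

    def test_pixel_exceeding_bit_depth(self):
        with pytest.raises(CorruptDataError):
            _raw(np.full((2, 2, 2), 256, dtype=np.uint16), bits=8)


def _trilinear_oracle(vol, point):
    """Brute-force trilinear interpolation at a fractional coordinate."""
    out = 0.0
    base = [int(np.floor(c)) for c in point]
    frac = [c - b for c, b in zip(point, base)]
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                i = min(base[0] + di, vol.shape[0] - 1)
                j = min(base[1] + dj, vol.shape[1] - 1)
                k = min(base[2] + dk, vol.shape[2] - 1)
                w = ((frac[0] if di else 1 - frac[0])
                     * (frac[1] if dj else 1 - frac[1])
                     * (frac[2] if dk else 1 - frac[2]))
                out += w * vol[i, j, k]
    return out


class TestResampleVolume:
    def test_constant_volume_is_invariant(self):
        vol = np.full((128, 128, 90), 0.5)
        out = resample_volume(vol, (64, 64, 64))
        assert out.shape == (64, 64, 64)
        assert np.allclose(out, 0.5)

    def test_output_shape_contract(self, rng):
        out = resample_volume(rng.random((30, 50, 17)), (64, 64, 64))
        assert out.shape == (64, 64, 64)

    def test_ramp_matches_trilinear_oracle(self, rng):
        vol = rng.random((20, 24, 18))
        target = (64, 64, 64)
        out = resample_volume(vol, target)
        # probe 10 output voxels against a brute-force oracle
        probes = rng.integers(0, 64, size=(10, 3))
        for p in probes:
            point = [p[ax] * (vol.shape[ax] - 1) / (target[ax] - 1)
                     for ax in range(3)]
            assert out[tuple(p)] == pytest.approx(
                _trilinear_oracle(vol, point), abs=1e-6)

    def test_monotone_ramp_stays_in_range(self):
        ramp = np.tile(np.linspace(0, 1, 100)[:, None, None], (1, 8, 8))
        out = resample_volume(ramp, (64, 64, 64))
        line = out[:, 4, 4]
        assert np.all(np.diff(line) >= 0)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_idempotent_at_target_shape(self, rng):
        vol = rng.random((16, 16, 16))
        out = resample_volume(vol, (16, 16, 16))
        assert np.allclose(out, vol, atol=1e-9)

    def test_invalid_target(self, rng):
        with pytest.raises(ValueError):
            resample_volume(rng.random((8, 8, 8)), (0, 8, 8))


class TestSliceAxial:
    def test_one_slice_per_axial_plane(self, rng):
        vol = rng.random((64, 64, 64))
        slices = slice_axial(vol)
        assert len(slices) == 64
        assert all(s.values.shape == (64, 64) for s in slices)

    def test_plane_extraction_and_order(self, rng):
        vol = rng.random((8, 8, 12))
        vol[:, :, 10] = 0.3
        slices = slice_axial(vol, participant_id="P1", subset_index=2)
        assert np.allclose(slices[10].values, 0.3)
        assert [s.slice_index for s in slices] == list(range(12))
        assert slices[5].participant_id == "P1"
        for k, s in enumerate(slices):
            assert np.array_equal(s.values, vol[:, :, k])


class TestSplitParticipants:
    def test_110_participants_give_82_28(self):
        ids = [f"P{i:03d}" for i in range(110)]
        split = split_participants(ids, 0.75, seed=3)
        assert len(split.train_ids) == 82
        assert len(split.val_ids) == 28

    def test_floor_rule_small(self):
        split = split_participants(["a", "b", "c", "d"], 0.75, seed=0)
        assert len(split.train_ids) == 3 and len(split.val_ids) == 1

    def test_deterministic_per_seed(self):
        ids = [f"P{i}" for i in range(20)]
        s1 = split_participants(ids, 0.6, seed=42)
        s2 = split_participants(ids, 0.6, seed=42)
        assert s1.train_ids == s2.train_ids and s1.val_ids == s2.val_ids

    def test_partition_property_many_seeds(self):
        ids = [f"P{i}" for i in range(37)]
        for seed in range(1000):
            s = split_participants(ids, 0.75, seed=seed)
            assert s.train_ids | s.val_ids == set(ids)
            assert not (s.train_ids & s.val_ids)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            split_participants(["a", "a", "b"], 0.5, seed=0)


class TestPairSubsets:
    def _volumes(self, n):
        return [np.full((4, 4, 4), i / 10) for i in range(n)]

    def test_cardinality_and_distinctness(self):
        pairs = pair_subsets(self._volumes(4), self._volumes(6), 3, seed=1)
        assert len(pairs) == 3
        idx = {(p.fbb_subset_index, p.fdg_subset_index) for p in pairs}
        assert len(idx) == 3

    def test_exhaustive_case(self):
        pairs = pair_subsets(self._volumes(4), self._volumes(6), 24, seed=1)
        idx = {(p.fbb_subset_index, p.fdg_subset_index) for p in pairs}
        assert idx == {(i, j) for i in range(4) for j in range(6)}

    def test_deterministic_per_seed(self):
        a, b = self._volumes(4), self._volumes(6)
        p1 = pair_subsets(a, b, 5, seed=9)
        p2 = pair_subsets(a, b, 5, seed=9)
        assert ([(p.fbb_subset_index, p.fdg_subset_index) for p in p1]
                == [(p.fbb_subset_index, p.fdg_subset_index) for p in p2])

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            pair_subsets(self._volumes(2), self._volumes(2), 5, seed=0)


def test_png_preview_round_trip(tmp_path, rng):
    from PIL import Image

    from tracergan.pet_io import UnitSlice, write_png_preview

    img = rng.random((16, 16))
    path = tmp_path / "preview.png"
    write_png_preview(UnitSlice(img), path)
    back = np.asarray(Image.open(path), dtype=np.float64) / 255.0
    assert back.shape == (16, 16)
    assert np.abs(back - img).max() <= 0.5 / 255 + 1e-12


def test_read_dicom_series(tmp_path, rng):
    """A synthetic DICOM series stacks in InstanceNumber order and carries
    Bits Stored through to the rescaling divisor."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    from tracergan.pet_io import read_dicom_series

    planes = (rng.random((8, 8)) * 4095).astype(np.uint16)
    planes = [planes, (planes // 2).astype(np.uint16)]
    for k, plane in enumerate(planes):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(tmp_path / f"s{k}.dcm"), {}, file_meta=meta,
                         preamble=b"\0" * 128)
        ds.PatientID = "P42"
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = 8, 8
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = plane.tobytes()
        ds.save_as(str(tmp_path / f"s{k}.dcm"), enforce_file_format=True)

    raw = read_dicom_series(tmp_path, tracer=Tracer.FBB)
    assert raw.bits_stored == 12
    assert raw.participant_id == "P42"
    assert raw.pixels.shape == (8, 8, 2)
    assert np.array_equal(raw.pixels[:, :, 0], planes[0])
    assert np.array_equal(raw.pixels[:, :, 1], planes[1])
    out = rescale_to_unit(raw)
    assert out.max() <= 1.0
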