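"""PET series I/O and preprocessing.

Reads DICOM or NIfTI PET volumes, rescales unsigned-integer pixel data to
the unit range using the DICOM Bits Stored attribute, resamples to the
64x64x64 working matrix, slices volumes into 2-D axial images, and performs
the participant-level train/validation split and subset pairing that feed
the translation models.

Array convention: volumes are (row, column, axial-slice), 0-based,
row-major; the axial slice index is the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Tracer", "RawSeries", "UnitSlice", "DatasetSplit", "SubsetPair",
    "WORKING_MATRIX", "rescale_to_unit", "resample_volume", "slice_axial",
    "split_participants", "pair_subsets", "read_dicom_series", "read_nifti",
    "write_nifti", "InvalidMetadataError", "CorruptDataError",
    "InsufficientDataError",
]

WORKING_MATRIX = (64, 64, 64)


class Tracer(str, Enum):
    FBB = "FBB"   # amyloid tracer, domain A
    FDG = "FDG"   # glucose tracer, domain B


class InvalidMetadataError(ValueError):
    """Series metadata (e.g. Bits Stored) outside its legal range."""


class CorruptDataError(ValueError):
    """Pixel data inconsistent with the declared bit depth."""


class InsufficientDataError(ValueError):
    """Not enough source data for the requested sampling."""


@dataclass
class RawSeries:
    """An unsigned-integer PET volume plus acquisition metadata.

    ``pixels`` is (height, width, depth); every value must fit in
    ``bits_stored`` bits. One RawSeries corresponds to one subset frame of
    one tracer for one participant.
    """

    pixels: np.ndarray
    bits_stored: int
    tracer: Tracer
    participant_id: str
    subset_index: int = 0
    frame_minutes: float = 5.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if not (1 <= int(self.bits_stored) <= 16):
            raise InvalidMetadataError(
                f"bits_stored={self.bits_stored} outside 1..16")
        if self.pixels.ndim != 3 or self.pixels.shape[2] < 1:
            raise CorruptDataError("pixel array must be 3-D with depth >= 1")
        if np.issubdtype(self.pixels.dtype, np.signedinteger) and self.pixels.min() < 0:
            raise CorruptDataError("negative pixel values in unsigned series")
        if self.pixels.max(initial=0) >= 2 ** int(self.bits_stored):
            raise CorruptDataError(
                f"pixel value >= 2^{self.bits_stored}; data corrupt or "
                "bits_stored wrong")
        self.tracer = Tracer(self.tracer)


@dataclass
class UnitSlice:
    """A single 64x64 unit-range axial image with its provenance."""

    values: np.ndarray
    participant_id: str = ""
    subset_index: int = 0
    slice_index: int = 0
    tracer: Tracer | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("UnitSlice values must be 2-D")


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: frozenset
    val_ids: frozenset
    train_fraction: float
    seed: int


@dataclass
class SubsetPair:
    fbb: np.ndarray
    fdg: np.ndarray
    participant_id: str
    fbb_subset_index: int
    fdg_subset_index: int


def rescale_to_unit(raw: RawSeries) -> np.ndarray:
    """Convert unsigned-integer pixels to floats in [0, 1].

    The divisor is 2**bits_stored - 1 so the top code of the declared bit
    depth maps exactly to 1.0.
    """
    divisor = float(2 ** int(raw.bits_stored) - 1)
    return raw.pixels.astype(np.float64) / divisor


def resample_volume(vol: np.ndarray,
                    target_shape: tuple[int, int, int] = WORKING_MATRIX,
                    method: str = "trilinear") -> np.ndarray:
    """Resample a volume to ``target_shape`` (trilinear by default).

    Uses the align-corners convention: output index i samples input
    coordinate i*(n_in-1)/(n_out-1), so resampling to the input's own shape
    is the identity and output values never leave the input's range.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if vol.ndim != 3 or vol.size == 0:
        raise ValueError("input volume must be non-empty and 3-D")
    if any(int(t) < 1 for t in target_shape):
        raise ValueError(f"invalid target shape {target_shape}")
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    axes = [np.linspace(0.0, n_in - 1.0, int(n_out)) if n_out > 1
            else np.array([(n_in - 1) / 2.0])
            for n_in, n_out in zip(vol.shape, target_shape)]
    grid = np.meshgrid(*axes, indexing="ij")
    order = 1 if method == "trilinear" else 0
    out = ndimage.map_coordinates(vol, np.stack(grid), order=order,
                                  mode="nearest")
    return out.reshape(tuple(int(t) for t in target_shape))


def slice_axial(vol: np.ndarray, participant_id: str = "",
                subset_index: int = 0,
                tracer: Tracer | None = None) -> list[UnitSlice]:
    """Split a working-matrix volume into its ordered axial planes."""
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D volume")
    return [UnitSlice(vol[:, :, k], participant_id=participant_id,
                      subset_index=subset_index, slice_index=k, tracer=tracer)
            for k in range(vol.shape[2])]


def split_participants(ids, train_fraction: float = 0.75,
                       seed: int = 0) -> DatasetSplit:
    """Participant-level train/validation split.

    Exactly floor(train_fraction * n) participants go to training; the
    assignment is a seeded uniform shuffle, so no participant's data can
    appear in both partitions.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("empty id list")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * len(ids)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.asarray(sorted(ids), dtype=object)).tolist()
    return DatasetSplit(train_ids=frozenset(order[:n_train]),
                        val_ids=frozenset(order[n_train:]),
                        train_fraction=train_fraction, seed=seed)


def pair_subsets(fbb_volumes: list, fdg_volumes: list, n_pairs: int,
                 seed: int = 0, participant_id: str = "") -> list[SubsetPair]:
    """Sample (FBB, FDG) subset pairs without replacement.

    Pairs are drawn uniformly from the cartesian product of the two subset
    lists of one participant; determinism is governed by ``seed``.
    """
    if not fbb_volumes or not fdg_volumes:
        raise ValueError("both subset lists must be non-empty")
    n_total = len(fbb_volumes) * len(fdg_volumes)
    if n_pairs > n_total:
        raise InsufficientDataError(
            f"requested {n_pairs} pairs but only {n_total} distinct "
            "(fbb, fdg) combinations exist")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_total, size=n_pairs, replace=False)
    pairs = []
    for idx in flat:
        i, j = divmod(int(idx), len(fdg_volumes))
        pairs.append(SubsetPair(fbb=fbb_volumes[i], fdg=fdg_volumes[j],
                                participant_id=participant_id,
                                fbb_subset_index=i, fdg_subset_index=j))
    return pairs


def read_dicom_series(directory: str | Path, tracer: Tracer,
                      participant_id: str = "",
                      subset_index: int = 0) -> RawSeries:
    """Read one DICOM series (a directory of .dcm slices) into a RawSeries.

    Slices are stacked along the last axis in InstanceNumber order; the
    Bits Stored attribute (0028,0101) is taken from the first slice.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files under {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    first = datasets[0]
    bits = int(first.BitsStored)
    planes = [d.pixel_array for d in datasets]
    pixels = np.stack(planes, axis=-1)
    frame = float(getattr(first, "ActualFrameDuration", 300000)) / 60000.0
    pid = participant_id or str(getattr(first, "PatientID", ""))
    return RawSeries(pixels=pixels, bits_stored=bits, tracer=tracer,
                     participant_id=pid, subset_index=subset_index,
                     frame_minutes=frame)


def read_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)


def write_nifti(vol: np.ndarray, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine=np.eye(4))
    nib.save(img, str(path))


def write_png_preview(image: np.ndarray | UnitSlice, path: str | Path) -> None:
    """Write a unit-range 2-D image as an 8-bit grayscale PNG preview."""
    from PIL import Image

    arr = np.asarray(getattr(image, "values", image), dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("preview expects a 2-D image")
    Image.fromarray(np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8),
                    mode="L").save(str(path))
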