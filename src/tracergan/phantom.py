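"""Synthetic dual-tracer brain phantom generator.

Produces paired amyloid-like (FBB) and glucose-metabolism-like (FDG) PET
volumes with the statistical structure the translation task relies on:

* regional uptake of the two tracers is anticorrelated inside the brain
  (noise-free FDG = clip(a - b * FBB)),
* the amyloid images carry more noise (lower SNR) than the FDG images,
* an optional ellipsoidal hypometabolic region depresses FDG uptake,
  mimicking the regional hypometabolism of neurodegeneration,
* volumes are stored as unsigned integers at a declared bit depth, like
  DICOM PET pixel data, and optionally rigidly misaligned to exercise the
  unpaired-training regime.

The anatomy of each synthetic participant is one smooth random uptake field
inside a spherical brain mask with a central ventricle-like cavity; each
subset frame is an independent noise realisation of that anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .pet_io import RawSeries, Tracer

__all__ = ["Ellipsoid", "PhantomParams", "PhantomPair", "make_phantom_pair",
           "make_dataset", "write_dataset", "load_dataset", "quantize"]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in fractional volume coordinates.

    ``centre`` and ``radii`` are fractions of the matrix dimensions;
    ``multiplier`` scales uptake inside the region (in (0,1) it depresses).
    """

    centre: tuple[float, float, float] = (0.35, 0.65, 0.5)
    radii: tuple[float, float, float] = (0.12, 0.12, 0.12)
    multiplier: float = 0.7


@dataclass(frozen=True)
class PhantomParams:
    matrix: tuple[int, int, int] = (64, 64, 64)
    brain_radius_frac: float = 0.42
    ventricle_radius_frac: float = 0.12
    cortex_uptake_fbb: float = 0.9
    anticorrelation_gain: float = 0.9    # b in fdg = a - b*fbb
    anticorrelation_offset: float = 0.95  # a
    hypometabolic_region: Ellipsoid | None = None
    noise_sd_fbb: float = 0.06
    noise_sd_fdg: float = 0.03
    smoothing_sigma_voxels: float = 1.0
    misalignment_max_voxels: float = 0.0
    bits_stored: int = 12
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.cortex_uptake_fbb <= 1.0:
            raise ValueError("cortex_uptake_fbb must be in (0, 1]")
        if not 0.0 < self.anticorrelation_offset <= 1.0:
            raise ValueError("anticorrelation_offset must be in (0, 1]")
        if self.anticorrelation_gain < 0:
            raise ValueError("anticorrelation_gain must be >= 0")
        if self.noise_sd_fbb < 0 or self.noise_sd_fdg < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.smoothing_sigma_voxels < 0 or self.misalignment_max_voxels < 0:
            raise ValueError("sigma/misalignment must be >= 0")
        if not 1 <= self.bits_stored <= 16:
            raise ValueError("bits_stored must be in 1..16")
        if self.hypometabolic_region is not None:
            m = self.hypometabolic_region.multiplier
            if not 0.0 < m < 1.0:
                raise ValueError("hypometabolic multiplier must be in (0, 1)")


@dataclass
class PhantomPair:
    fbb: RawSeries
    fdg: RawSeries
    truth_fdg: np.ndarray   # noise-free unit-range FDG ground truth
    brain_mask: np.ndarray


def quantize(vol: np.ndarray, bits_stored: int) -> np.ndarray:
    """Round a unit-range volume to unsigned integers at the given depth."""
    top = 2 ** int(bits_stored) - 1
    return np.round(np.clip(vol, 0.0, 1.0) * top).astype(np.uint16)


def _fractional_grid(matrix):
    axes = [(np.arange(n) - (n - 1) / 2.0) / n for n in matrix]
    return np.meshgrid(*axes, indexing="ij")


def _brain_mask(params: PhantomParams) -> np.ndarray:
    gx, gy, gz = _fractional_grid(params.matrix)
    r2 = gx ** 2 + gy ** 2 + gz ** 2
    brain = r2 <= params.brain_radius_frac ** 2
    ventricle = r2 <= params.ventricle_radius_frac ** 2
    return brain & ~ventricle


def _ellipsoid_mask(matrix, ell: Ellipsoid) -> np.ndarray:
    idx = np.indices(matrix, dtype=np.float64)
    acc = np.zeros(matrix)
    for ax in range(3):
        c = ell.centre[ax] * (matrix[ax] - 1)
        r = max(ell.radii[ax] * matrix[ax], 1e-9)
        acc += ((idx[ax] - c) / r) ** 2
    return acc <= 1.0


def _anatomy(params: PhantomParams, rng: np.random.Generator):
    """Noise-free masked FBB/FDG volumes for one participant."""
    mask = _brain_mask(params)
    field3d = ndimage.gaussian_filter(rng.standard_normal(params.matrix), 4.0)
    lo, hi = field3d.min(), field3d.max()
    # smooth uptake field spanning [0.15, cortex_uptake_fbb]
    fbb = 0.15 + (params.cortex_uptake_fbb - 0.15) * (field3d - lo) / (hi - lo)
    if params.smoothing_sigma_voxels > 0:
        fbb = ndimage.gaussian_filter(fbb, params.smoothing_sigma_voxels)
    a, b = params.anticorrelation_offset, params.anticorrelation_gain
    fdg = np.clip(a - b * fbb, 0.0, 1.0)
    if params.hypometabolic_region is not None:
        region = _ellipsoid_mask(params.matrix, params.hypometabolic_region)
        fdg = np.where(region, fdg * params.hypometabolic_region.multiplier, fdg)
    return fbb * mask, fdg * mask, mask


def _noisy(vol, sd, rng):
    if sd > 0:
        vol = vol + rng.normal(0.0, sd, size=vol.shape)
    return np.clip(vol, 0.0, 1.0)


def _misalign(vol, max_vox, rng):
    if max_vox <= 0:
        return vol
    shift = rng.uniform(-max_vox, max_vox, size=3)
    return ndimage.shift(vol, shift, order=1, mode="constant", cval=0.0)


def make_phantom_pair(params: PhantomParams | None = None) -> PhantomPair:
    """Generate one paired (FBB, FDG) phantom volume set.

    Deterministic for a given ``params.seed``. The returned ``truth_fdg``
    is the noise-free unit-range FDG volume before noise, misalignment and
    quantization — the ground truth for evaluating translated images.
    """
    params = params or PhantomParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    fbb0, fdg0, mask = _anatomy(params, rng)
    fbb = _noisy(fbb0, params.noise_sd_fbb, rng)
    fdg = _noisy(fdg0, params.noise_sd_fdg, rng)
    fbb = _misalign(fbb, params.misalignment_max_voxels, rng)
    pid = f"phantom-{params.seed:06d}"
    fbb_raw = RawSeries(pixels=quantize(fbb, params.bits_stored),
                        bits_stored=params.bits_stored, tracer=Tracer.FBB,
                        participant_id=pid)
    fdg_raw = RawSeries(pixels=quantize(fdg, params.bits_stored),
                        bits_stored=params.bits_stored, tracer=Tracer.FDG,
                        participant_id=pid)
    return PhantomPair(fbb=fbb_raw, fdg=fdg_raw, truth_fdg=fdg0,
                       brain_mask=mask)


def make_dataset(n_participants: int, fbb_subsets: int = 4,
                 fdg_subsets: int = 6,
                 params: PhantomParams | None = None,
                 inter_subset_noise: float = 0.02,
                 seed: int = 0) -> dict:
    """Generate a participant -> tracer -> subset-frame dataset tree.

    Each participant receives one anatomy realisation (plus one shared
    tracer-noise realisation, so the tracer SNR difference is preserved);
    each subset frame adds independent noise of SD ``inter_subset_noise``.
    With ``inter_subset_noise = 0`` all subsets of a participant/tracer are
    identical.
    """
    if n_participants < 1 or fbb_subsets < 1 or fdg_subsets < 1:
        raise ValueError("counts must be >= 1")
    params = params or PhantomParams()
    params.validate()
    tree: dict = {}
    for p in range(n_participants):
        pid = f"P{p:04d}"
        pseed = int(np.random.SeedSequence([seed, p]).generate_state(1)[0]
                    % (2 ** 31))
        pp = replace(params, seed=pseed)
        rng = np.random.default_rng(pseed)
        fbb0, fdg0, mask = _anatomy(pp, rng)
        fbb_base = _noisy(fbb0, pp.noise_sd_fbb, rng)
        fdg_base = _noisy(fdg0, pp.noise_sd_fdg, rng)
        fbb_base = _misalign(fbb_base, pp.misalignment_max_voxels, rng)
        tree[pid] = {Tracer.FBB: [], Tracer.FDG: []}
        for tracer, base, count in ((Tracer.FBB, fbb_base, fbb_subsets),
                                    (Tracer.FDG, fdg_base, fdg_subsets)):
            for s in range(count):
                frame = _noisy(base, inter_subset_noise, rng)
                tree[pid][tracer].append(RawSeries(
                    pixels=quantize(frame, pp.bits_stored),
                    bits_stored=pp.bits_stored, tracer=tracer,
                    participant_id=pid, subset_index=s, frame_minutes=5.0))
        tree[pid]["truth_fdg"] = fdg0
        tree[pid]["brain_mask"] = mask
    return tree


def inversion_benchmark_slices(n_slices: int = 200, seed: int = 0,
                               misalignment_max_voxels: float = 0.0,
                               central_slices: int = 24):
    """Aligned zero-noise slice pairs where FDG = 1 - FBB voxelwise.

    The canonical toy task: with anticorrelation offset a = 1 and gain
    b = 1 and no noise or smoothing, the FBB -> FDG map is an exact affine
    inversion that a small generator can recover in minutes on one CPU.

    The phantom radius is enlarged (0.75) and only the central axial planes
    are kept, so every slice is anticorrelated texture with no dark
    background: global SSIM between an input slice and its ground-truth
    target is then strongly negative, and any recovery of the inversion
    raises it. (With the standard geometry the shared brain-vs-background
    silhouette dominates global image statistics and masks the mapping.)
    Returns (fbb_slices, fdg_slices, truth_fdg_slices); slices are drawn
    from as many phantom participants as needed.
    """
    from .pet_io import rescale_to_unit, slice_axial

    fbb_slices, fdg_slices, truth_slices = [], [], []
    p = 0
    while len(fbb_slices) < n_slices:
        params = PhantomParams(
            brain_radius_frac=0.75, ventricle_radius_frac=0.0,
            noise_sd_fbb=0.0, noise_sd_fdg=0.0,
            anticorrelation_gain=1.0, anticorrelation_offset=1.0,
            smoothing_sigma_voxels=0.0,
            misalignment_max_voxels=misalignment_max_voxels,
            seed=int(np.random.SeedSequence([seed, p]).generate_state(1)[0]
                     % (2 ** 31)))
        pair = make_phantom_pair(params)
        depth = params.matrix[2]
        lo = (depth - central_slices) // 2
        sl = slice(lo, lo + central_slices)
        fbb_vol = rescale_to_unit(pair.fbb)
        fdg_vol = rescale_to_unit(pair.fdg)
        pid = pair.fbb.participant_id
        fbb_slices.extend(slice_axial(fbb_vol, pid, tracer=Tracer.FBB)[sl])
        fdg_slices.extend(slice_axial(fdg_vol, pid, tracer=Tracer.FDG)[sl])
        truth_slices.extend(slice_axial(pair.truth_fdg, pid,
                                        tracer=Tracer.FDG)[sl])
        p += 1
    return (fbb_slices[:n_slices], fdg_slices[:n_slices],
            truth_slices[:n_slices])


def write_dataset(tree: dict, out_dir: str | Path) -> Path:
    """Write a phantom dataset as a NIfTI tree plus a manifest CSV."""
    import pandas as pd

    from .pet_io import write_nifti

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, node in tree.items():
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        for tracer in (Tracer.FBB, Tracer.FDG):
            for raw in node[tracer]:
                name = f"{tracer.value}_subset{raw.subset_index}.nii.gz"
                write_nifti(raw.pixels.astype(np.float32), pdir / name)
                rows.append({"participant_id": pid, "tracer": tracer.value,
                             "subset": raw.subset_index,
                             "bits_stored": raw.bits_stored,
                             "file": str(Path(pid) / name)})
        write_nifti(node["truth_fdg"], pdir / "truth_FDG.nii.gz")
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(in_dir: str | Path) -> dict:
    """Load a written phantom dataset tree back from its manifest CSV."""
    import pandas as pd

    from .pet_io import read_nifti

    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "manifest.csv")
    tree: dict = {}
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        node = tree.setdefault(pid, {Tracer.FBB: [], Tracer.FDG: []})
        tracer = Tracer(row["tracer"])
        pixels = read_nifti(in_dir / row["file"]).astype(np.uint16)
        node[tracer].append(RawSeries(
            pixels=pixels, bits_stored=int(row["bits_stored"]),
            tracer=tracer, participant_id=pid,
            subset_index=int(row["subset"])))
    for pid in tree:
        truth = in_dir / pid / "truth_FDG.nii.gz"
        if truth.exists():
            tree[pid]["truth_fdg"] = read_nifti(truth)
    return tree
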