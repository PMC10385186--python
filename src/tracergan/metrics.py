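"""Image-similarity metrics: SSIM (global-statistics form), MSE, PSNR.

SSIM here uses *global* per-image statistics —

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
                 / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

with C1 = (k1 L)^2, C2 = (k2 L)^2 and population (n-denominator) variance
and cross-covariance, so identical images score exactly 1 and strongly
anticorrelated images approach -1. A sliding-window variant (the common
library form) is available behind ``windowed=True`` for comparability, but
the global form is the default. PSNR is 20 log10(MAX) - 10 log10(MSE) in
dB; aggregates report mean and sample (n-1) standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SsimConstants", "ssim", "mse", "psnr", "aggregate",
           "SimilarityReport", "evaluate_pairs", "InsufficientDataError"]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class SsimConstants:
    L: float = 1.0
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("dynamic range L must be > 0")

    @property
    def c1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.L) ** 2


def ssim(x: np.ndarray, y: np.ndarray,
         constants: SsimConstants | None = None,
         windowed: bool = False) -> float:
    """Structural similarity between two images of equal shape."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    c = constants or SsimConstants()
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(
            x, y, data_range=c.L, gaussian_weights=True, win_size=11,
            K1=c.k1, K2=c.k2, use_sample_covariance=False))
    mx, my = x.mean(), y.mean()
    vx = x.var()           # population variance
    vy = y.var()
    cov = ((x - mx) * (y - my)).mean()   # population cross-covariance
    num = (2 * mx * my + c.c1) * (2 * cov + c.c2)
    den = (mx ** 2 + my ** 2 + c.c1) * (vx + vy + c.c2)
    return float(num / den)


def mse(I: np.ndarray, K: np.ndarray) -> float:
    """Mean squared error over all pixels."""
    I = np.asarray(I, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    if I.shape != K.shape:
        raise ValueError(f"shape mismatch {I.shape} vs {K.shape}")
    return float(((I - K) ** 2).mean())


def psnr(I: np.ndarray, K: np.ndarray, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    if max_i <= 0:
        raise ValueError("max_i must be > 0")
    m = mse(I, K)
    if m == 0.0:
        return math.inf
    return float(20.0 * np.log10(max_i) - 10.0 * np.log10(m))


def aggregate(records: pd.DataFrame | list) -> dict:
    """Per-model mean and sample SD of SSIM and PSNR.

    ``records`` has columns image_id, ssim, mse, psnr_db (a list of dicts is
    accepted). Infinite-PSNR records (identical images) are excluded from
    the PSNR aggregate and counted; at least two finite records per metric
    are required.
    """
    df = pd.DataFrame(records)
    out: dict = {}
    finite = df[np.isfinite(df["psnr_db"])]
    n_excluded = int(len(df) - len(finite))
    if n_excluded:
        warnings.warn(f"{n_excluded} record(s) with infinite PSNR excluded "
                      "from aggregates")
    if len(df) < 2 or len(finite) < 2:
        raise InsufficientDataError("need >= 2 finite records per metric")
    out["ssim_mean"] = float(df["ssim"].mean())
    out["ssim_sd"] = float(df["ssim"].std(ddof=1))
    out["psnr_mean"] = float(finite["psnr_db"].mean())
    out["psnr_sd"] = float(finite["psnr_db"].std(ddof=1))
    out["n"] = int(len(df))
    out["n_psnr_excluded"] = n_excluded
    return out


@dataclass
class SimilarityReport:
    """Per-image metric records for one model plus their aggregates."""

    model: str
    records: pd.DataFrame

    @property
    def aggregates(self) -> dict:
        return aggregate(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model: str = "") -> "SimilarityReport":
        return cls(model=model, records=pd.read_csv(path))


def evaluate_pairs(generated, reference, model: str = "",
                   constants: SsimConstants | None = None,
                   ids=None) -> SimilarityReport:
    """Score each (generated, reference) image pair with SSIM/MSE/PSNR."""
    c = constants or SsimConstants()
    rows = []
    for k, (g, r) in enumerate(zip(generated, reference)):
        g = getattr(g, "values", g)
        r = getattr(r, "values", r)
        rows.append({
            "image_id": ids[k] if ids is not None else k,
            "ssim": ssim(g, r, c),
            "mse": mse(g, r),
            "psnr_db": psnr(g, r, max_i=c.L),
        })
    return SimilarityReport(model=model, records=pd.DataFrame(rows))
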