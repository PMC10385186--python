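"""Statistical comparison of model metric distributions and demographics.

Two-sided independent Student's t-test (pooled variance by default, Welch
by flag) compares the SSIM/PSNR distributions of two models; the
Mann-Whitney U test (exact for small samples, tie-corrected normal
approximation otherwise) compares categorical demographics coded as
integers. Significance is declared at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "students_t_independent", "mann_whitney_u",
           "compare_models", "compare_demographics", "ALPHA"]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    direction: str  # "a_higher", "b_higher" or "equal"
    degenerate: bool = False


def _finite(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    return a[np.isfinite(a)]


def students_t_independent(a, b, variant: str = "pooled",
                           metric: str = "") -> ComparisonResult:
    """Two-sided independent-samples Student's t-test.

    ``pooled`` uses the classic pooled-variance statistic with
    df = n1 + n2 - 2; ``welch`` uses the Welch-Satterthwaite correction.
    Two identical zero-variance samples are degenerate: t = 0, p = 1.
    """
    a, b = _finite(a), _finite(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 finite values")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    degenerate = False
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
            df = len(a) + len(b) - 2
            degenerate = True
        else:
            t, p, df = np.inf * np.sign(a.mean() - b.mean()), 0.0, \
                len(a) + len(b) - 2
            degenerate = True
    else:
        res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    diff = a.mean() - b.mean()
    direction = "a_higher" if diff > 0 else ("b_higher" if diff < 0 else "equal")
    return ComparisonResult(
        metric=metric, mean_a=float(a.mean()), sd_a=float(np.std(a, ddof=1)),
        mean_b=float(b.mean()), sd_b=float(np.std(b, ddof=1)),
        t_statistic=float(t), degrees_of_freedom=float(df),
        p_value=float(p), significant=bool(p <= ALPHA),
        direction=direction, degenerate=degenerate)


def mann_whitney_u(a, b, exact_max_product: int = 400) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p value).

    Uses the exact null distribution when n1*n2 <= ``exact_max_product``
    and there are no ties, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) * len(b) <= exact_max_product and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_models(report_a, report_b, variant: str = "pooled",
                   label_a: str = "cyclegan",
                   label_b: str = "pix2pix") -> pd.DataFrame:
    """Compare two models' SSIM and PSNR distributions (one row each)."""
    ra, rb = report_a.records, report_b.records
    for r, name in ((ra, label_a), (rb, label_b)):
        if len(r) < 2:
            raise ValueError(f"report {name} has < 2 records")
    if set(ra["image_id"]) != set(rb["image_id"]):
        warnings.warn("image-id sets differ between reports; proceeding "
                      "with the independent test (paired analysis refused)")
    rows = []
    for metric, col in (("ssim", "ssim"), ("psnr", "psnr_db")):
        res = students_t_independent(ra[col], rb[col], variant=variant,
                                     metric=metric)
        d = res.__dict__.copy()
        d["higher"] = {"a_higher": label_a, "b_higher": label_b,
                       "equal": "equal"}[res.direction]
        rows.append(d)
    return pd.DataFrame(rows)


def compare_demographics(table: pd.DataFrame, split_col: str = "split",
                         continuous=("age",),
                         categorical=("sex", "diagnosis")) -> pd.DataFrame:
    """Train-vs-validation demographic comparison.

    Continuous variables use the independent t-test; categorical variables
    are integer-coded and compared with the Mann-Whitney U test (a
    chi-squared alternative is reported alongside for reference).
    """
    groups = table.groupby(split_col)
    if len(groups) != 2:
        raise ValueError("split column must define exactly two groups")
    (ga, da), (gb, db) = groups
    rows = []
    for col in continuous:
        res = students_t_independent(da[col], db[col], metric=col)
        rows.append({"variable": col, "test": "t", "p_value": res.p_value,
                     "significant": res.significant})
    for col in categorical:
        codes = pd.Categorical(table[col]).codes
        ca = codes[table[split_col] == ga]
        cb = codes[table[split_col] == gb]
        _, p = mann_whitney_u(ca, cb)
        ct = pd.crosstab(table[split_col], table[col])
        chi_p = float(sps.chi2_contingency(ct).pvalue) if ct.shape[1] > 1 else 1.0
        rows.append({"variable": col, "test": "mannwhitney", "p_value": p,
                     "significant": p <= ALPHA, "chi2_p_value": chi_p})
    return pd.DataFrame(rows)
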