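"""Adversarial and reconstruction loss terms for the translation GANs.

The full objective is an additive combination of six terms: two
least-squares adversarial terms (forward and backward), two cycle-
consistency L1 terms and two identity L1 terms. All weights default to 1
(an unweighted sum); they are exposed because common practice up-weights
the cycle terms. In pix2pix (paired, forward-only) mode the graph contains
only the forward adversarial term and a forward reconstruction L1 against
the paired target; the backward and identity slots are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LossBreakdown", "l1_term", "l1_grad", "adversarial_mse",
           "adversarial_mse_grad", "total_loss", "ConfigurationError",
           "DEFAULT_WEIGHTS"]

DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

_TERMS = ("adv_forward", "adv_backward", "cycle_A", "cycle_B",
          "identity_B", "identity_A")


class ConfigurationError(ValueError):
    """Mode flag inconsistent with the provided networks."""


@dataclass
class LossBreakdown:
    """The six additive loss terms and their weighted total.

    In pix2pix mode ``cycle_A`` holds the forward reconstruction term
    |G_A(A) - B| (the paired L1 against the target image); the backward
    and identity slots are zero.
    """

    adv_forward: float = 0.0
    adv_backward: float = 0.0
    cycle_A: float = 0.0
    cycle_B: float = 0.0
    identity_B: float = 0.0
    identity_A: float = 0.0
    weights: tuple = DEFAULT_WEIGHTS

    @property
    def terms(self) -> tuple:
        return tuple(getattr(self, t) for t in _TERMS)

    @property
    def total(self) -> float:
        return float(sum(w * t for w, t in zip(self.weights, self.terms)))

    def as_dict(self) -> dict:
        d = {t: getattr(self, t) for t in _TERMS}
        d["total"] = self.total
        return d


def l1_term(x: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute difference over all elements."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(np.abs(x - y).mean())


def l1_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of l1_term w.r.t. x."""
    return (np.sign(x - y) / x.size).astype(x.dtype)


def adversarial_mse(disc_scores: np.ndarray, target_label: float) -> float:
    """Least-squares adversarial loss: mean of (score - label)^2."""
    s = np.asarray(disc_scores, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite discriminator scores")
    return float(((s - target_label) ** 2).mean())


def adversarial_mse_grad(disc_scores: np.ndarray,
                         target_label: float) -> np.ndarray:
    """Gradient of adversarial_mse w.r.t. the scores."""
    s = np.asarray(disc_scores)
    return (2.0 * (s - target_label) / s.size).astype(s.dtype)


def total_loss(A: np.ndarray, B: np.ndarray, G_A, G_B=None, D_A=None,
               D_B=None, weights=DEFAULT_WEIGHTS,
               mode: str = "cyclegan") -> LossBreakdown:
    """Evaluate the full generator objective on batches A and B (no grad).

    cyclegan mode populates all six terms; pix2pix mode populates the
    forward adversarial term and the forward reconstruction |G_A(A) - B|
    (stored in the cycle_A slot), requiring paired A/B batches and no
    backward networks.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if mode == "cyclegan":
        if G_B is None or D_A is None or D_B is None:
            raise ConfigurationError("cyclegan mode needs G_A, G_B, D_A, D_B")
        fake_b = G_A(A)
        fake_a = G_B(B)
        return LossBreakdown(
            adv_forward=adversarial_mse(D_A(fake_b), 1.0),
            adv_backward=adversarial_mse(D_B(fake_a), 1.0),
            cycle_A=l1_term(G_B(fake_b), A),
            cycle_B=l1_term(G_A(fake_a), B),
            identity_B=l1_term(G_A(B), B),
            identity_A=l1_term(G_B(A), A),
            weights=tuple(weights))
    if mode == "pix2pix":
        if G_B is not None or D_B is not None:
            raise ConfigurationError("pix2pix mode takes only G_A and D_A")
        if D_A is None:
            raise ConfigurationError("pix2pix mode needs D_A")
        if A.shape != B.shape:
            raise ConfigurationError("pix2pix mode requires paired batches")
        fake_b = G_A(A)
        return LossBreakdown(
            adv_forward=adversarial_mse(D_A(fake_b), 1.0),
            cycle_A=l1_term(fake_b, B),
            weights=tuple(weights))
    raise ConfigurationError(f"unknown mode {mode!r}")
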