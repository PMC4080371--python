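"""Attractor score functions for a cancer/normal network pair.

The cancer-cell score rewards active (ON) genes, ``h = sum_i alpha_i (1-w_i)
v_i``, while the normal-cell score rewards inactive (OFF) genes in its
objective form, ``sum_i gamma_i (1-w_i) (1-v_i)`` with ``gamma_i = -beta_i``.
Controlled nodes (``w_i = 1``) contribute zero to either score: an externally
clamped gene says nothing about the cell's own stable state.

Both coefficient vectors are non-negative.  The signed normal-cell score
``g = sum_i beta_i (1-w_i) v_i`` differs from the objective form only by the
constant ``sum_{i not controlled} gamma_i``, so the two agree on which
attractor is best once the control set is fixed; the objective form is
canonical here because the control thresholds are calibrated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ControlAssignment, State

__all__ = ["ScoreConfig", "score_cancer", "score_normal", "score_combined"]


@dataclass(frozen=True)
class ScoreConfig:
    """Score coefficients for a network pair.

    ``alpha``: cancer-cell coefficients (reward per ON free node).
    ``gamma``: normal-cell coefficients (reward per OFF free node),
    ``gamma_i = -beta_i`` for the signed coefficients ``beta_i <= 0``.
    """

    alpha: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        if a.ndim != 1 or g.ndim != 1 or a.shape != g.shape:
            raise ValueError("alpha and gamma must be 1-D vectors of equal length")
        if (a < 0).any() or (g < 0).any():
            raise ValueError("score coefficients must be non-negative")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "gamma", g)

    @classmethod
    def uniform(cls, n: int, alpha: float = 1.0, gamma: float = 1.0) -> "ScoreConfig":
        return cls(np.full(n, float(alpha)), np.full(n, float(gamma)))

    @property
    def n(self) -> int:
        return self.alpha.shape[0]


def _free_mask(n: int, c: ControlAssignment) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    for i in c.controlled:
        mask[i] = False
    return mask


def score_cancer(cfg: ScoreConfig, s: State, c: ControlAssignment) -> float:
    """``sum_i alpha_i (1-w_i) v_i``: total alpha over ON, non-controlled nodes."""
    if len(s) != cfg.n:
        raise ValueError("state length does not match coefficient length")
    bits = np.asarray(s.bits, dtype=float)
    return float(np.sum(cfg.alpha * _free_mask(cfg.n, c) * bits))


def score_normal(cfg: ScoreConfig, s: State, c: ControlAssignment) -> float:
    """``sum_i gamma_i (1-w_i) (1-v_i)``: total gamma over OFF, non-controlled nodes."""
    if len(s) != cfg.n:
        raise ValueError("state length does not match coefficient length")
    bits = np.asarray(s.bits, dtype=float)
    return float(np.sum(cfg.gamma * _free_mask(cfg.n, c) * (1.0 - bits)))


def score_combined(
    cfg: ScoreConfig, s1: State, s2: State, c: ControlAssignment
) -> float:
    """Joint score ``G`` of a cancer attractor ``s1`` and normal attractor ``s2``."""
    return score_cancer(cfg, s1, c) + score_normal(cfg, s2, c)
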