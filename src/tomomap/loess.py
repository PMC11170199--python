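"""LOESS smoothing of serial-section expression profiles.

Sections sit on an integer grid 1..S, so the local tricube-weighted
polynomial fit at each section is a fixed linear combination of the
observations.  We therefore precompute an S x S smoother matrix once
per (S, span, degree) and smooth whole gene x section matrices by a
single matrix product.

Neighborhood size is q = max(degree + 2, ceil(span * S)); distances are
scaled by the q-th nearest distance, so the farthest neighbor carries
zero tricube weight (standard LOESS behavior).  Boundary sections use
their one-sided neighborhood — no reflection or padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LoessConfig", "loess_smoother_matrix", "loess_smooth_matrix"]


@dataclass(frozen=True)
class LoessConfig:
    """Span and degree of the local regression.

    span_alpha is the fraction of sections in each local neighborhood
    (0 < alpha <= 1); degree 0 (local mean) or 1 (local line);
    robustness_iters is accepted for interface completeness but only 0
    is implemented.
    """

    span_alpha: float = 0.15
    degree: int = 1
    robustness_iters: int = 0

    def __post_init__(self):
        if not 0 < self.span_alpha <= 1:
            raise ValueError(f"span_alpha must be in (0, 1], got {self.span_alpha}")
        if self.degree not in (0, 1):
            raise ValueError(f"degree must be 0 or 1, got {self.degree}")
        if self.robustness_iters < 0:
            raise ValueError("robustness_iters must be >= 0")
        if self.robustness_iters > 0:
            raise NotImplementedError("robust refitting is not implemented")

    def neighborhood(self, n_sections: int) -> int:
        q = max(self.degree + 2, math.ceil(self.span_alpha * n_sections))
        if q > n_sections:
            raise ValueError(
                f"neighborhood of {q} points exceeds {n_sections} sections; "
                "increase the number of sections or the span"
            )
        return q


def tricube(u: np.ndarray) -> np.ndarray:
    """Tricube kernel (1 - u^3)^3 on [0, 1), zero beyond."""
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u**3) ** 3


def loess_smoother_matrix(n_sections: int, cfg: LoessConfig | None = None) -> np.ndarray:
    """S x S matrix L with smoothed = counts @ L.T for gene-row matrices."""
    cfg = cfg or LoessConfig()
    q = cfg.neighborhood(n_sections)
    x = np.arange(1, n_sections + 1, dtype=float)
    L = np.zeros((n_sections, n_sections))
    for i, x0 in enumerate(x):
        d = np.abs(x - x0)
        order = np.argsort(d, kind="stable")
        # distance ties at the neighborhood edge carry zero tricube
        # weight; widen the window until the fit is determined
        # (equivalent to including tied points, the standard treatment)
        q_eff = q
        while True:
            nbr = order[:q_eff]
            dmax = d[nbr].max()
            w = tricube(d[nbr] / dmax)
            if (w > 0).sum() >= cfg.degree + 1 or q_eff >= n_sections:
                break
            q_eff += 1
        # weighted least squares at x0; prediction is the intercept of
        # the fit in centered coordinates t = x - x0
        t = x[nbr] - x0
        if cfg.degree == 0:
            L[i, nbr] = w / w.sum()
        else:
            X = np.column_stack([np.ones_like(t), t])
            XtW = X.T * w
            gram = XtW @ X
            if np.linalg.matrix_rank(gram) < gram.shape[0]:
                beta_row = (np.linalg.pinv(gram) @ XtW)[0]
            else:
                beta_row = np.linalg.solve(gram, XtW)[0]
            L[i, nbr] = beta_row
    return L


def loess_smooth_matrix(counts: np.ndarray, cfg: LoessConfig | None = None,
                        clamp_negative: bool = True) -> np.ndarray:
    """Smooth each row of a gene x section matrix along sections.

    Negative local-linear predictions are clamped to 0 so downstream
    fold changes stay non-negative.
    """
    counts = np.asarray(counts, dtype=float)
    L = loess_smoother_matrix(counts.shape[1], cfg)
    smoothed = counts @ L.T
    if clamp_negative:
        np.maximum(smoothed, 0.0, out=smoothed)
    return smoothed
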