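"""Multi-instance statistic kernel between gene bags.

Each gene is observed as a bag of one or more feature vectors (one per
surviving image).  Bag similarity is computed by first summarizing each bag
with per-dimension order statistics (mean by default; median/min/max for
corpora with different noise characteristics) and then applying a base kernel
between the summary vectors.  The base kernel is the spatial covariance across
the triangle dimensions — the second moment about the mean — so with the mean
statistic the kernel equals the mean pairwise covariance over all image pairs
of the two bags (the normalized set kernel).  The resulting p x p matrix plays
the role of the sample covariance in sparse precision estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import GeneBag

__all__ = [
    "KernelMatrix",
    "bag_statistic",
    "covariance_base_kernel",
    "multi_instance_kernel_matrix",
    "MultiInstanceKernel",
    "clip_psd",
]

_STATISTICS = {
    "mean": lambda v: v.mean(axis=0),
    "median": lambda v: np.median(v, axis=0),
    "min": lambda v: v.min(axis=0),
    "max": lambda v: v.max(axis=0),
}


@dataclass
class KernelMatrix:
    """Symmetric PSD gene-similarity matrix used in place of a sample covariance."""

    values: np.ndarray
    gene_ids: list
    statistic: str | list = "mean"
    base_kernel: str = "covariance"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("kernel matrix must be square")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match kernel size")

    @property
    def n_genes(self) -> int:
        return int(self.values.shape[0])


def bag_statistic(bag: GeneBag | np.ndarray, statistic="mean") -> np.ndarray:
    """Per-dimension order statistic(s) of a bag of feature vectors.

    ``statistic`` may be one of {mean, median, min, max} or an ordered list of
    them; with q statistics the summary has length q*m for m features.
    """
    vectors = bag.vectors if isinstance(bag, GeneBag) else np.atleast_2d(bag)
    if vectors.shape[0] < 1:
        raise ValueError("bag must be non-empty")
    stats = [statistic] if isinstance(statistic, str) else list(statistic)
    parts = []
    for s in stats:
        if s not in _STATISTICS:
            raise ValueError(
                f"unknown statistic {s!r}; expected one of {sorted(_STATISTICS)}"
            )
        parts.append(_STATISTICS[s](vectors))
    return np.concatenate(parts)


def covariance_base_kernel(
    u: np.ndarray, v: np.ndarray, unbiased: bool = False
) -> float:
    """Spatial covariance of two summary vectors across the m feature dims.

    (1/m) * sum_l (u_l - u_bar)(v_l - v_bar); the population 1/m normalization
    matches the second-moment convention, with ``unbiased=True`` switching to
    1/(m-1).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    m = u.size
    if m < 2:
        raise ValueError("covariance requires vectors of length >= 2")
    denom = m - 1 if unbiased else m
    return float((u - u.mean()) @ (v - v.mean()) / denom)


def multi_instance_kernel_matrix(
    bags: list[GeneBag], statistic="mean", unbiased: bool = False
) -> KernelMatrix:
    """p x p statistic kernel between all gene bags.

    K_ij = covariance_base_kernel(s(X_i), s(X_j)) for summary statistic s.
    With the default mean statistic this equals the mean of the pairwise
    covariance kernel over all image pairs of bags i and j (normalized set
    kernel), and the matrix is PSD up to round-off by construction.
    """
    if len(bags) < 2:
        raise ValueError("need at least two gene bags")
    lengths = {b.n_features for b in bags}
    if len(lengths) != 1:
        raise ValueError("all bag vectors must have the same length")
    summaries = np.vstack([bag_statistic(b, statistic) for b in bags])
    centered = summaries - summaries.mean(axis=1, keepdims=True)
    m = summaries.shape[1]
    denom = m - 1 if unbiased else m
    K = centered @ centered.T / denom
    K = (K + K.T) / 2.0
    return KernelMatrix(
        values=K,
        gene_ids=[b.gene_id for b in bags],
        statistic=statistic,
        base_kernel="covariance",
    )


def clip_psd(S: np.ndarray, tol_scale: float = 1e-8) -> np.ndarray:
    """Clip tiny negative eigenvalues (round-off) at zero.

    Eigenvalues below -tol_scale * max_eigenvalue indicate a genuinely
    indefinite input and raise instead of being silently repaired.
    """
    S = np.asarray(S, dtype=float)
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    floor = -tol_scale * max(w.max(), 0.0)
    if w.min() < floor - 1e-15:
        raise ValueError(
            f"matrix is indefinite (min eigenvalue {w.min():.3e}); "
            "not a valid kernel/covariance"
        )
    if w.min() >= 0:
        return S
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


class MultiInstanceKernel(BaseEstimator, TransformerMixin):
    """Transformer from gene bags to the statistic-kernel matrix.

    Parameters
    ----------
    statistic : order statistic(s) summarizing each bag (default "mean",
        robust to noisy images; "median" suits over-stained corpora).
    unbiased : use 1/(m-1) instead of 1/m in the base covariance.
    """

    def __init__(self, statistic="mean", unbiased: bool = False):
        self.statistic = statistic
        self.unbiased = unbiased

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[GeneBag]) -> KernelMatrix:
        K = multi_instance_kernel_matrix(
            X, statistic=self.statistic, unbiased=self.unbiased
        )
        self.gene_ids_ = K.gene_ids
        return K
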