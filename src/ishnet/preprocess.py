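"""Feature normalization, variance-based selection, and per-gene bag assembly.

Triangulated stain features from different images live on different intensity
scales (staining and lighting are not calibrated across experiments), so each
image is first min-max rescaled to the 0-255 color range and log-transformed.
Unstained or ubiquitously stained images carry no spatial information and are
removed, as are triangles whose stain barely varies across the corpus; because
the two removals interact, they are alternated until a fixpoint is reached.
Genes whose images were all rejected are dropped, and each surviving gene is
represented by its bag of per-image feature vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "GeneBag",
    "normalize_features",
    "iterative_variance_selection",
    "assemble_gene_bags",
    "VarianceSelector",
    "DEFAULT_VARIANCE_THRESHOLD",
]

#: default variance threshold tau for image/feature rejection
DEFAULT_VARIANCE_THRESHOLD = 0.1


@dataclass
class FeatureMatrix:
    """Images x triangles table of expression features with row/column metadata."""

    values: np.ndarray
    image_ids: list
    gene_ids: list
    triangle_ids: list
    tau: float = DEFAULT_VARIANCE_THRESHOLD

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (images x triangles)")
        n, m = self.values.shape
        if len(self.image_ids) != n or len(self.gene_ids) != n:
            raise ValueError("row metadata length does not match matrix")
        if len(self.triangle_ids) != m:
            raise ValueError("column metadata length does not match matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.triangle_ids))
        df.insert(0, "gene_id", list(self.gene_ids))
        df.insert(0, "image_id", list(self.image_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tau: float = DEFAULT_VARIANCE_THRESHOLD):
        feature_cols = [c for c in df.columns if c not in ("image_id", "gene_id")]
        return cls(
            values=df[feature_cols].to_numpy(dtype=float),
            image_ids=df["image_id"].tolist(),
            gene_ids=df["gene_id"].tolist(),
            triangle_ids=feature_cols,
            tau=tau,
        )


@dataclass
class GeneBag:
    """A gene with its bag of surviving normalized feature vectors (>= 1)."""

    gene_id: str
    vectors: np.ndarray  # (n_images, n_features)

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.shape[0] < 1:
            raise ValueError(f"bag for gene {self.gene_id!r} is empty")

    @property
    def size(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.vectors.shape[1])


def normalize_features(raw_vector: np.ndarray) -> np.ndarray:
    """Min-max rescale one image's features to [0, 255], then log-transform.

    The log is taken as log(1 + e): the raw logarithm is undefined at zero
    stain, and log1p maps 0 to 0 while matching log at the stained end of the
    scale.  A constant vector (min == max) maps to all zeros; such images are
    removed by the variance filter anyway.
    """
    v = np.asarray(raw_vector, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("feature vector contains non-finite entries")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return np.log1p((v - lo) / (hi - lo) * 255.0)


def _population_variance(x: np.ndarray, axis: int) -> np.ndarray:
    # population convention (divide by count), matching the second-moment
    # definition used for the covariance kernel
    return np.var(x, axis=axis, ddof=0)


def iterative_variance_selection(
    F: FeatureMatrix | np.ndarray, tau: float | None = None
) -> tuple[list, list]:
    """Alternately drop low-variance images (rows) and features (columns).

    Removing an uninformative image changes every feature's variance and vice
    versa, so removal alternates — starting with images — until on the
    surviving submatrix every row and column variance strictly exceeds
    ``tau``.  The procedure shrinks monotonically and therefore terminates;
    the fixpoint reached is returned as (kept_triangle_ids, kept_image_ids).

    If everything is removed, empty lists are returned with a warning.
    """
    if isinstance(F, FeatureMatrix):
        values = F.values
        image_ids = list(F.image_ids)
        triangle_ids = list(F.triangle_ids)
        if tau is None:
            tau = F.tau
    else:
        values = np.asarray(F, dtype=float)
        image_ids = list(range(values.shape[0]))
        triangle_ids = list(range(values.shape[1]))
        if tau is None:
            tau = DEFAULT_VARIANCE_THRESHOLD
    if tau <= 0:
        raise ValueError("variance threshold tau must be positive")

    rows = np.arange(values.shape[0])
    cols = np.arange(values.shape[1])
    drop_rows_next = True
    while True:
        if rows.size == 0 or cols.size == 0:
            rows = rows[:0]
            cols = cols[:0]
            break
        sub = values[np.ix_(rows, cols)]
        if drop_rows_next:
            keep = _population_variance(sub, axis=1) > tau
            changed = not keep.all()
            rows = rows[keep]
        else:
            keep = _population_variance(sub, axis=0) > tau
            changed = not keep.all()
            cols = cols[keep]
        if not changed:
            # check the other axis before declaring a fixpoint
            if rows.size and cols.size:
                sub = values[np.ix_(rows, cols)]
                other_ok = (
                    _population_variance(sub, axis=0 if drop_rows_next else 1)
                    > tau
                ).all()
                if other_ok:
                    break
        drop_rows_next = not drop_rows_next

    if rows.size == 0 or cols.size == 0:
        warnings.warn(
            "variance selection removed every image and/or feature",
            RuntimeWarning,
            stacklevel=2,
        )
        return [], []
    kept_triangles = [triangle_ids[c] for c in cols]
    kept_images = [image_ids[r] for r in rows]
    n_img_dropped = len(image_ids) - len(kept_images)
    n_tri_dropped = len(triangle_ids) - len(kept_triangles)
    if n_img_dropped or n_tri_dropped:
        logger.info(
            "variance selection dropped %d image(s) and %d feature(s)",
            n_img_dropped,
            n_tri_dropped,
        )
    return kept_triangles, kept_images


def assemble_gene_bags(F: FeatureMatrix) -> list[GeneBag]:
    """Group a (filtered) feature matrix into one bag per surviving gene.

    Genes with zero surviving images have already disappeared from the row
    metadata; an entirely empty matrix means no network can be estimated and
    raises a ValueError.
    """
    if F.values.shape[0] == 0:
        raise ValueError("no images survive: gene network cannot be estimated")
    bags: dict[str, list] = {}
    order: list[str] = []
    for row, gene in enumerate(F.gene_ids):
        if gene not in bags:
            bags[gene] = []
            order.append(gene)
        bags[gene].append(F.values[row])
    return [GeneBag(gene_id=g, vectors=np.vstack(bags[g])) for g in order]


class VarianceSelector(BaseEstimator, TransformerMixin):
    """Normalize per image, then apply the alternating variance filter.

    Parameters
    ----------
    tau : variance threshold (dimensionless, on log-intensity features).
    normalize : whether to min-max/log1p-normalize each row before filtering.

    Attributes
    ----------
    kept_image_ids_, kept_triangle_ids_ : survivors of the fixpoint filter.
    dropped_genes_ : genes whose images were all rejected.
    """

    def __init__(self, tau: float = DEFAULT_VARIANCE_THRESHOLD, normalize: bool = True):
        self.tau = tau
        self.normalize = normalize

    def fit_transform(self, X: FeatureMatrix, y=None) -> FeatureMatrix:
        values = X.values
        if self.normalize:
            values = np.vstack([normalize_features(r) for r in values])
        F = FeatureMatrix(
            values=values,
            image_ids=list(X.image_ids),
            gene_ids=list(X.gene_ids),
            triangle_ids=list(X.triangle_ids),
            tau=self.tau,
        )
        kept_tri, kept_img = iterative_variance_selection(F, self.tau)
        tri_index = {t: i for i, t in enumerate(F.triangle_ids)}
        img_index = {im: i for i, im in enumerate(F.image_ids)}
        rows = [img_index[i] for i in kept_img]
        cols = [tri_index[t] for t in kept_tri]
        self.kept_image_ids_ = kept_img
        self.kept_triangle_ids_ = kept_tri
        surviving_genes = {F.gene_ids[r] for r in rows}
        self.dropped_genes_ = sorted(set(F.gene_ids) - surviving_genes)
        if self.dropped_genes_:
            logger.info(
                "genes rejected for insufficient information: %s",
                ", ".join(map(str, self.dropped_genes_)),
            )
        return FeatureMatrix(
            values=F.values[np.ix_(rows, cols)],
            image_ids=kept_img,
            gene_ids=[F.gene_ids[r] for r in rows],
            triangle_ids=kept_tri,
            tau=self.tau,
        )

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X: FeatureMatrix) -> FeatureMatrix:
        return self.fit_transform(X)
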