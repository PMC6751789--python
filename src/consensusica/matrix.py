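"""Expression matrices and the preprocessing steps that make heterogeneous
inputs comparable.

Bulk transcriptome deconvolution operates on a single feature-by-sample
matrix ``E`` (genes or miRNAs in rows, samples in columns).  Real studies mix
platforms — RNA-seq counts, microarray intensities, qPCR Ct values — so the
entry points here are (i) soft count filtering, (ii) log2 transformation,
(iii) Ct inversion for qPCR panels, (iv) linear harmonisation of a foreign
matrix onto a reference distribution and (v) column-wise concatenation of
cohorts with batch bookkeeping.

Matrices are stored as :class:`pandas.DataFrame` with a ``scale`` tag so that
downstream code can refuse to decompose raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "filter_features",
    "log_transform",
    "invert_ct",
    "harmonize_to_reference",
    "concat_datasets",
    "read_expression_tsv",
]

#: recognised value scales, roughly "how far from raw counts are we"
SCALES = ("raw_count", "log2", "ct_inverted", "harmonised")
_LOG_LIKE = ("log2", "ct_inverted", "harmonised")


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with a value-scale tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Features in rows (index = feature ids), samples in columns.
    scale : str
        One of ``raw_count``, ``log2``, ``ct_inverted``, ``harmonised``.
    allow_missing : bool
        Ct tables may carry NA values (handled by :func:`invert_ct`); every
        other scale must be finite.
    """

    data: pd.DataFrame
    scale: str = "raw_count"
    allow_missing: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not self.allow_missing and not np.isfinite(values).all():
            raise ValueError(
                "non-finite values in expression matrix; only Ct tables "
                "(allow_missing=True) may contain NA"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def is_log_like(self) -> bool:
        return self.scale in _LOG_LIKE

    def copy(self) -> "ExpressionMatrix":
        return replace(self, data=self.data.copy())

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: first column feature id, header row sample ids."""
        self.data.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read_tsv(cls, path, scale: str = "raw_count",
                 allow_missing: bool = False) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        return cls(df, scale=scale, allow_missing=allow_missing)


def read_expression_tsv(path, scale: str = "raw_count",
                        allow_missing: bool = False) -> ExpressionMatrix:
    """Module-level alias of :meth:`ExpressionMatrix.read_tsv`."""
    return ExpressionMatrix.read_tsv(path, scale=scale, allow_missing=allow_missing)


def filter_features(E: ExpressionMatrix, min_value: float,
                    min_samples: int = 1) -> ExpressionMatrix:
    """Soft count filter: keep features with value strictly greater than
    ``min_value`` in at least ``min_samples`` samples.

    The comparison is strict ("more than" the threshold), so
    ``min_value=0, min_samples=1`` keeps every feature with at least one read.
    Feature order is preserved.  Raises if nothing passes.
    """
    if E.scale != "raw_count":
        raise ValueError(f"filter_features expects raw counts, got scale={E.scale!r}")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    keep = (E.data.to_numpy(dtype=float) > min_value).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            f"no features pass filter (value > {min_value} in >= {min_samples} samples)"
        )
    return ExpressionMatrix(E.data.loc[keep], scale=E.scale)


def log_transform(E: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) on a raw count matrix."""
    if E.scale != "raw_count":
        raise ValueError(f"log_transform expects raw counts, got scale={E.scale!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    values = E.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = pd.DataFrame(np.log2(values + pseudocount),
                       index=E.data.index, columns=E.data.columns)
    return ExpressionMatrix(out, scale="log2")


def invert_ct(Ct: ExpressionMatrix, limit: float = 36.0) -> ExpressionMatrix:
    """Convert qPCR Ct values to an expression-like scale: ``limit - Ct``.

    A Ct above ``limit`` means the amplicon never crossed the detection
    threshold, so missing values and values above the limit are replaced by
    the limit before inversion — both map to expression 0.
    """
    values = Ct.data.to_numpy(dtype=float).copy()
    values[~np.isfinite(values)] = limit
    values[values > limit] = limit
    out = pd.DataFrame(limit - values, index=Ct.data.index, columns=Ct.data.columns)
    return ExpressionMatrix(out, scale="ct_inverted")


def harmonize_to_reference(E_new: ExpressionMatrix,
                           E_ref: ExpressionMatrix,
                           method: str = "robust") -> ExpressionMatrix:
    """Linearly map ``E_new`` onto the value distribution of ``E_ref``.

    Microarray intensities live on a different dynamic range than log RNA-seq
    values; an affine transform ``a*x + b`` fitted on the pooled value
    distributions aligns them.  ``method='robust'`` matches median and MAD of
    the pooled values (insensitive to the heavy tails of expression data);
    ``method='quantile'`` instead regresses the sorted values of ``E_new``
    on the matching quantiles of ``E_ref``.

    Only features shared with the reference are returned.
    """
    if not (E_new.is_log_like and E_ref.is_log_like) and not (
            E_new.scale == E_ref.scale):
        raise ValueError("harmonisation expects both matrices on log-like scales")
    shared = [f for f in E_new.feature_ids if f in set(E_ref.feature_ids)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared features; cannot harmonise")
    x = E_new.data.loc[shared].to_numpy(dtype=float).ravel()
    y = E_ref.data.loc[shared].to_numpy(dtype=float).ravel()
    if method == "robust":
        x_scale = np.median(np.abs(x - np.median(x)))
        y_scale = np.median(np.abs(y - np.median(y)))
        if x_scale == 0:
            raise ValueError("degenerate (constant) input matrix")
        a = y_scale / x_scale
        b = np.median(y) - a * np.median(x)
    elif method == "quantile":
        # regress sorted new values on equally-spaced quantiles of the reference
        qs = np.linspace(0, 1, min(len(x), len(y), 1001))
        xq = np.quantile(x, qs)
        yq = np.quantile(y, qs)
        a, b = np.polyfit(xq, yq, 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame(a * E_new.data.loc[shared].to_numpy(dtype=float) + b,
                       index=shared, columns=E_new.data.columns)
    return ExpressionMatrix(out, scale="harmonised")


def concat_datasets(E_a: ExpressionMatrix, E_b: ExpressionMatrix,
                    batches: tuple[str, str] = ("discovery", "investigation"),
                    ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Column-bind two cohorts on their shared features.

    Returns the combined matrix and a two-column batch table
    (``sample_id``, ``batch``) recording which cohort each column came from.
    Sample id collisions are an error: the decomposition treats columns as
    distinct observations.
    """
    if not (E_a.is_log_like and E_b.is_log_like):
        raise ValueError("concatenation expects both matrices on log-like scales")
    collisions = set(E_a.sample_ids) & set(E_b.sample_ids)
    if collisions:
        raise ValueError(f"duplicate sample ids across datasets: {sorted(collisions)[:5]}")
    shared = [f for f in E_a.feature_ids if f in set(E_b.feature_ids)]
    if not shared:
        raise ValueError("empty feature intersection")
    combined = pd.concat([E_a.data.loc[shared], E_b.data.loc[shared]], axis=1)
    labels = pd.DataFrame({
        "sample_id": E_a.sample_ids + E_b.sample_ids,
        "batch": [batches[0]] * len(E_a.sample_ids) + [batches[1]] * len(E_b.sample_ids),
    })
    scale = E_a.scale if E_a.scale == E_b.scale else "harmonised"
    return ExpressionMatrix(combined, scale=scale), labels
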