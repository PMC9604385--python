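"""Median-of-ratios ("DESeq") normalization and the expressed-gene filter.

The size factor of sample *j* is the median, over reference genes *g*, of
``counts[g, j] / geomean_s(counts[g, s])`` — the classic median-of-ratios
estimator.  Reference genes are the rows with strictly positive counts in
every sample; the geometric mean is computed in log space.  Expression is
then reported as NRC (normalized read count, ``counts / size_factor``) and as
``log2(NRC + 1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix, ValidationError

__all__ = ["normalize_deseq", "filter_expressed", "DEFAULT_NRC_THRESHOLD"]

#: expressed-gene floor used throughout the pipeline (NRC >= 20 in all samples
#: of the relevant scope)
DEFAULT_NRC_THRESHOLD = 20.0


def size_factors_median_of_ratios(
    counts: pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Per-sample size factors by median-of-ratios.

    Parameters
    ----------
    counts
        genes x samples raw counts.
    pseudo_reference
        If True, fall back to including zero-containing rows by computing the
        geometric mean over the strictly positive entries of each row (a
        documented "poscounts"-style fallback for sparse matrices).  The
        default (False) uses only all-positive rows and raises if none exist.
    """
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if all_positive.any() and not pseudo_reference:
        ref_rows = x[all_positive]
        log_geo = np.mean(np.log(ref_rows), axis=1)
        ratios = np.log(ref_rows) - log_geo[:, None]
    else:
        if not pseudo_reference:
            raise ValidationError(
                "no gene has strictly positive counts in every sample; "
                "re-run with pseudo_reference=True to use the positive-count "
                "geometric-mean fallback"
            )
        any_positive = (x > 0).any(axis=1)
        if not any_positive.any():
            raise ValidationError("count matrix is all zero")
        rows = x[any_positive]
        with np.errstate(divide="ignore", invalid="ignore"):
            logx = np.log(rows)
        logx[rows <= 0] = np.nan
        log_geo = np.nanmean(logx, axis=1)
        ratios = logx - log_geo[:, None]  # NaN where count == 0
    # geometric means are formed in log space (overflow-safe); the median of
    # the ratios themselves is taken in linear space (even counts average
    # the two central order statistics)
    sf = np.nanmedian(np.exp(ratios), axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_deseq(
    counts: CountMatrix | pd.DataFrame,
    pseudocount: float = 1.0,
    pseudo_reference: bool = False,
) -> NormalizedMatrix:
    """Normalize a count matrix by median-of-ratios size factors.

    Returns a :class:`NormalizedMatrix` carrying the size factors, the NRC
    matrix and ``log2(NRC + pseudocount)``.
    """
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    sf = size_factors_median_of_ratios(table, pseudo_reference=pseudo_reference)
    nrc = table / sf
    return NormalizedMatrix(size_factors=sf, nrc=nrc, pseudocount=pseudocount)


def filter_expressed(
    norm: NormalizedMatrix,
    threshold: float = DEFAULT_NRC_THRESHOLD,
    samples=None,
) -> pd.Index:
    """Genes with NRC >= ``threshold`` in *every* sample of the scope.

    ``samples`` restricts the scope to one cell/tissue type; the default is
    all samples.  The boundary value (NRC exactly equal to the threshold) is
    retained.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    scope = norm.nrc if samples is None else norm.nrc[list(samples)]
    if scope.shape[1] == 0:
        raise ValidationError("empty sample scope")
    keep = (scope >= threshold).all(axis=1)
    return norm.nrc.index[keep]
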