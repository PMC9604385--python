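"""Core data containers shared by every pipeline stage.

The pipeline's sole biological input is a gene x sample matrix of raw read
counts plus a gene annotation giving each gene's genomic location.  Both are
thin, validated wrappers around pandas objects so that downstream stages can
rely on a handful of invariants (unique identifiers, non-negative counts,
start < end) instead of re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "GeneAnnotation", "NormalizedMatrix"]


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples, with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample.  Values must
        be finite and non-negative.
    sample_metadata
        Optional DataFrame indexed by sample id (group / cell type, strain,
        passage, ...).  Must cover exactly the samples in ``counts``.
    """

    counts: pd.DataFrame
    sample_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if not isinstance(counts, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("counts contain non-finite values")
        if (values < 0).any():
            raise ValidationError("counts contain negative values")
        if self.sample_metadata is not None:
            missing = counts.columns.difference(self.sample_metadata.index)
            if len(missing):
                raise ValidationError(
                    f"sample_metadata missing samples: {list(missing)[:5]}"
                )
            self.sample_metadata = self.sample_metadata.loc[counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def groups(self, column: str = "group") -> pd.Series:
        """Per-sample group labels from the metadata table."""
        if self.sample_metadata is None or column not in self.sample_metadata:
            raise ValidationError(f"no metadata column {column!r}")
        return self.sample_metadata[column]

    def subset_samples(self, samples) -> "CountMatrix":
        meta = None
        if self.sample_metadata is not None:
            meta = self.sample_metadata.loc[list(samples)]
        return CountMatrix(self.counts[list(samples)], meta)


@dataclass
class GeneAnnotation:
    """Gene id -> (chromosome, start, end, strand), 0-based half-open.

    Chromosomes are ordered by first appearance in the input, which defines
    the karyotype order used for genomic sorting (so "chr2" sorts before
    "chr10" whenever the source lists them that way).
    """

    table: pd.DataFrame  # index gene_id; columns chromosome, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        required = {"chromosome", "start", "end"}
        if not required.issubset(t.columns):
            raise ValidationError(f"annotation needs columns {sorted(required)}")
        if "strand" not in t.columns:
            t = t.assign(strand=".")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in annotation: {dups[:5]}")
        bad = t["start"] >= t["end"]
        if bad.any():
            raise ValidationError(
                f"start >= end for genes: {t.index[bad].tolist()[:5]}"
            )
        # freeze karyotype order = order of first appearance
        order = t["chromosome"].astype(str)
        cats = list(dict.fromkeys(order))
        t = t.assign(chromosome=pd.Categorical(order, categories=cats, ordered=True))
        self.table = t

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def chromosomes(self) -> list[str]:
        return list(self.table["chromosome"].cat.categories)

    def genomic_order(self, genes=None) -> pd.DataFrame:
        """Annotation rows sorted by (chromosome, start, gene_id).

        The gene-id tie-break makes the ordering deterministic when two genes
        share a start coordinate.
        """
        t = self.table if genes is None else self.table.loc[
            self.table.index.intersection(genes, sort=False)
        ]
        t = t.assign(_gid=t.index.astype(str))
        t = t.sort_values(["chromosome", "start", "_gid"], kind="stable")
        return t.drop(columns="_gid")


@dataclass
class NormalizedMatrix:
    """Median-of-ratios normalized expression.

    ``nrc`` (normalized read count) is counts divided by the per-sample size
    factor; ``log_expr`` is log2(nrc + pseudocount).
    """

    size_factors: pd.Series
    nrc: pd.DataFrame
    log_expr: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValidationError("size factors must be strictly positive")
        if self.log_expr is None:
            self.log_expr = np.log2(self.nrc + self.pseudocount)

    @property
    def sample_ids(self) -> pd.Index:
        return self.nrc.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.nrc.index
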