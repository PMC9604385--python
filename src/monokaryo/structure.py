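"""Transcriptome structure: concordance, clustering, PCA, lineage markers.

These summaries characterise how samples relate to one another once the
per-gene preprocessing is done: squared Pearson correlation (r^2) between
expressed transcriptomes, hierarchical clustering on Euclidean distances,
variance decomposition of a gene set by SVD, mean marker-set z-scores for
lineage assignment, and the multi-comparison union of upregulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .containers import ValidationError

__all__ = [
    "ConcordanceReport",
    "LineageProfile",
    "pairwise_r2",
    "hcluster",
    "linkage_to_newick",
    "pca_variance",
    "lineage_profile",
    "multiway_upregulated_union",
]


@dataclass
class ConcordanceReport:
    """Pairwise r^2 over samples plus a group mean with 95% t-interval."""

    r2: pd.DataFrame

    def group_summary(self, samples=None) -> tuple[float, float]:
        """Mean r^2 over the distinct pairs of ``samples`` and the 95% CI
        half-width (t-interval over the C(m,2) pairwise values)."""
        cols = list(samples) if samples is not None else list(self.r2.columns)
        if len(cols) < 2:
            raise ValidationError("need >= 2 samples for a pairwise summary")
        vals = [
            self.r2.loc[a, b] for i, a in enumerate(cols) for b in cols[i + 1 :]
        ]
        vals = np.asarray(vals, dtype=float)
        mean = float(vals.mean())
        if len(vals) == 1:
            return mean, 0.0
        half = float(
            stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
        )
        return mean, half


def pairwise_r2(log_expr: pd.DataFrame, samples=None, genes=None) -> ConcordanceReport:
    """Squared Pearson correlation between samples on a gene set.

    Raises if any sample in scope has zero variance (correlation undefined).
    """
    sub = log_expr
    if genes is not None:
        sub = sub.loc[list(genes)]
    if samples is not None:
        sub = sub[list(samples)]
    if sub.shape[1] < 2 or sub.shape[0] < 3:
        raise ValidationError("need >= 2 samples and >= 3 genes")
    sd = sub.std(axis=0, ddof=1)
    flat = sd.index[sd == 0]
    if len(flat):
        raise ValidationError(f"zero-variance sample(s): {list(flat)}")
    r2 = sub.corr(method="pearson") ** 2
    return ConcordanceReport(r2=r2)


def hcluster(log_expr: pd.DataFrame, samples=None, method: str = "average"):
    """Agglomerative clustering of samples on Euclidean distances.

    Returns ``(linkage_matrix, sample_labels)`` in scipy linkage form;
    ``method`` may be any scipy linkage (default average, per the package's
    declared convention).  scipy's agglomeration is deterministic for a
    fixed sample order, which serves as the tie-break.
    """
    sub = log_expr if samples is None else log_expr[list(samples)]
    if sub.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    x = sub.to_numpy(dtype=float).T  # samples x genes
    z = hierarchy.linkage(pdist(x, metric="euclidean"), method=method)
    return z, list(sub.columns)


def distance_matrix(log_expr: pd.DataFrame, samples=None) -> pd.DataFrame:
    sub = log_expr if samples is None else log_expr[list(samples)]
    d = squareform(pdist(sub.to_numpy(dtype=float).T, metric="euclidean"))
    return pd.DataFrame(d, index=sub.columns, columns=sub.columns)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as Newick, branch lengths from
    merge heights (leaf height 0)."""
    tree = hierarchy.to_tree(z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    inner = (
        f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)})"
        if not tree.is_leaf()
        else labels[tree.id]
    )
    return inner + ";"


def pca_variance(log_expr: pd.DataFrame, genes=None):
    """Variance decomposition of a gene set across samples.

    Centers each gene over samples, takes the SVD, and returns
    ``(fractions, scores)``: per-component variance fractions (descending,
    summing to 1) and sample scores (samples x components).
    """
    sub = log_expr if genes is None else log_expr.loc[list(genes)]
    if sub.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    x = sub.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValidationError("gene set has no variance across samples")
    fractions = s**2 / total
    scores = pd.DataFrame(
        (vt * s[:, None]).T,
        index=sub.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return fractions, scores


@dataclass
class LineageProfile:
    """Marker-set scores per sample and the implied lineage assignment."""

    scores: pd.DataFrame  # marker sets x samples
    assignment: pd.Series  # per-sample argmax set
    tie: pd.Series  # per-sample flag: top two scores within 1e-12

    def summary(self) -> str:
        lines = ["Lineage-marker profile", "=" * 22]
        for sample in self.scores.columns:
            flag = " (tie)" if self.tie[sample] else ""
            lines.append(f"  {sample:<20s} -> {self.assignment[sample]}{flag}")
        return "\n".join(lines)


def lineage_profile(log_expr: pd.DataFrame, marker_sets: dict[str, list]) -> LineageProfile:
    """Score each sample against each marker set.

    Per gene, z-scores are computed across samples; a sample's score for a
    set is the mean z over the set's genes present in the matrix with
    nonzero variance.  Raises if a set has no usable gene.
    """
    x = log_expr.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    usable = sd[:, 0] > 0
    z = np.zeros_like(x)
    z[usable] = (x[usable] - mean[usable]) / sd[usable]
    zdf = pd.DataFrame(z, index=log_expr.index, columns=log_expr.columns)

    rows = {}
    for name, genes in marker_sets.items():
        present = log_expr.index.intersection(pd.Index(genes), sort=False)
        present = present[usable[log_expr.index.get_indexer(present)]]
        if len(present) == 0:
            raise ValidationError(
                f"marker set {name!r} has no expressed, variable gene in the matrix"
            )
        rows[name] = zdf.loc[present].mean(axis=0)
    scores = pd.DataFrame(rows).T  # sets x samples
    assignment = scores.idxmax(axis=0)
    sorted_scores = np.sort(scores.to_numpy(), axis=0)
    if scores.shape[0] >= 2:
        tie_vals = sorted_scores[-1] - sorted_scores[-2] < 1e-12
    else:
        tie_vals = np.zeros(scores.shape[1], dtype=bool)
    tie = pd.Series(tie_vals, index=scores.columns)
    return LineageProfile(scores=scores, assignment=assignment, tie=tie)


def multiway_upregulated_union(called_tables: dict[str, pd.DataFrame]):
    """Union of up-called genes across several pairwise comparisons.

    ``called_tables`` maps comparison name -> a flagged DE table (as from
    :meth:`DEResults.call`).  Returns ``(union_index, membership)`` where
    ``membership`` is a boolean genes x comparisons frame — the Venn
    structure of the multi-tissue comparison.
    """
    if not called_tables:
        raise ValidationError("need >= 1 comparison")
    up_sets = {
        name: set(t.index[(t["significant"]) & (t["log2fc"] > 0)])
        for name, t in called_tables.items()
    }
    union = sorted(set().union(*up_sets.values()))
    membership = pd.DataFrame(
        {name: [g in genes for g in union] for name, genes in up_sets.items()},
        index=pd.Index(union, name="gene_id"),
    )
    return pd.Index(union, name="gene_id"), membership
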