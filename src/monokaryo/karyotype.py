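"""Expression-based karyotyping (e-karyotyping).

Chromosomal gains and losses leave a dosage footprint in RNA-seq: the genes
of a trisomic chromosome are, on average, expressed ~1.5x higher than in a
diploid reference.  This module detects such regional expression bias from a
count matrix alone:

1. normalize (median-of-ratios) and keep expressed genes (NRC >= 20),
2. subtract each gene's median log2 expression across the reference samples
   (relative expression),
3. drop the most variable genes (sum-of-squares filter) and winsorize,
4. fit a piecewise-constant model per sample and chromosome by exact
   dynamic-programming least squares with a per-breakpoint penalty,
5. call segments whose mean deviation, length and significance all clear the
   configured floors, and
6. smooth each track with a centered moving average for plotting.

The segmentation penalty is gamma = penalty * sigma^2, with sigma estimated
robustly from lag-1 differences (sigma = 1.4826 * MAD(diff(y)) / sqrt(2)),
which makes the ``penalty`` parameter scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, GeneAnnotation, ValidationError
from .normalize import DEFAULT_NRC_THRESHOLD, filter_expressed, normalize_deseq

__all__ = [
    "EKaryoParams",
    "RelativeTrack",
    "Segment",
    "EKaryotype",
    "EKaryotypeResults",
    "relative_expression",
    "variability_filter",
    "winsorize_track",
    "estimate_noise_sd",
    "pcf_segment",
    "call_aberrations",
    "moving_average",
]


@dataclass(frozen=True)
class EKaryoParams:
    """Tuning parameters of the e-karyotyping chain.

    ``least_allowed_deviation`` is in log2 units (0.25 ~ the shift expected
    from a mosaic single-copy gain); ``least_allowed_aberration_size`` is the
    minimum number of genes a called aberration must span.  ``penalty``
    multiplies the estimated noise variance to give the per-breakpoint cost;
    ``threshold`` is the per-segment significance level of the deviation
    test.  ``min_segment_genes`` is the hard minimum segment length imposed
    on the segmentation itself (kept at 1 so that short deviant runs surface
    as their own segments and are then rejected by the aberration-size
    floor, which is what makes that floor observable).
    """

    variability_removal_fraction: float = 0.10
    least_allowed_deviation: float = 0.25
    least_allowed_aberration_size: int = 50
    winsorize_quantile: float = 0.001
    penalty: float = 12.0
    threshold: float = 0.01
    moving_average_window: int = 200
    nrc_threshold: float = DEFAULT_NRC_THRESHOLD
    pseudocount: float = 1.0
    min_segment_genes: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.variability_removal_fraction < 1:
            raise ValidationError("variability_removal_fraction must be in [0, 1)")
        if not 0 <= self.winsorize_quantile < 0.5:
            raise ValidationError("winsorize_quantile must be in [0, 0.5)")
        if self.least_allowed_deviation <= 0 or self.penalty <= 0:
            raise ValidationError("deviation and penalty must be > 0")
        if not 0 < self.threshold <= 1:
            raise ValidationError("threshold must be in (0, 1]")
        if (
            self.least_allowed_aberration_size < 1
            or self.moving_average_window < 1
            or self.min_segment_genes < 1
        ):
            raise ValidationError("sizes/windows must be >= 1")


@dataclass
class RelativeTrack:
    """Median-centered log2 expression, genes in genomic order.

    ``values`` is genes x samples; ``chromosome`` maps each gene (same
    order) to its chromosome.
    """

    values: pd.DataFrame
    chromosome: pd.Series

    def per_chromosome(self):
        for chrom, idx in self.values.groupby(self.chromosome, observed=True).groups.items():
            yield str(chrom), self.values.loc[idx]


@dataclass(frozen=True)
class Segment:
    start: int  # gene index within chromosome track, inclusive
    end: int  # inclusive
    mean: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def relative_expression(
    log_expr: pd.DataFrame,
    annotation: GeneAnnotation,
    reference_samples=None,
) -> RelativeTrack:
    """Subtract each gene's median log2 expression across the reference.

    The per-gene median over ``reference_samples`` (default: all samples)
    serves as the diploid baseline; genes absent from the annotation are
    excluded with a warning.
    """
    refs = list(reference_samples) if reference_samples is not None else list(log_expr.columns)
    if len(refs) < 2:
        raise ValidationError("need >= 2 reference samples for a median baseline")
    ordered = annotation.genomic_order(log_expr.index)
    n_missing = log_expr.shape[0] - ordered.shape[0]
    if n_missing:
        warnings.warn(f"{n_missing} genes missing from annotation were excluded")
    expr = log_expr.loc[ordered.index]
    baseline = expr[refs].median(axis=1)
    values = expr.sub(baseline, axis=0)
    return RelativeTrack(values=values, chromosome=ordered["chromosome"].astype(str))


def variability_filter(track: RelativeTrack, fraction: float = 0.10) -> RelativeTrack:
    """Remove the ``floor(fraction * n)`` genes with the largest sum of
    squares of relative expression across samples.

    Ties are broken by genomic position, removing later-ordered genes first.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("fraction must be in [0, 1)")
    n = track.values.shape[0]
    k = int(np.floor(fraction * n))
    if k == 0:
        return track
    ss = np.square(track.values.to_numpy()).sum(axis=1)
    pos = np.arange(n)
    order = np.lexsort((-pos, -ss))  # largest SS first; ties: latest position first
    keep = np.ones(n, dtype=bool)
    keep[order[:k]] = False
    return RelativeTrack(track.values.iloc[keep], track.chromosome.iloc[keep])


def winsorize_track(track: RelativeTrack, quantile: float = 0.001) -> RelativeTrack:
    """Clip each sample's values to its [q, 1-q] empirical quantile range.

    The thresholds are order statistics (nearest rank outside the tail), so
    the operation is idempotent.
    """
    if not 0 <= quantile < 0.5:
        raise ValidationError("quantile must be in [0, 0.5)")
    if quantile == 0:
        return track
    values = track.values.to_numpy(dtype=float).copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        lo = np.quantile(col, quantile, method="higher")
        hi = np.quantile(col, 1.0 - quantile, method="lower")
        if lo > hi:  # degenerate tiny-n case: leave untouched
            continue
        values[:, j] = np.clip(col, lo, hi)
    return RelativeTrack(
        pd.DataFrame(values, index=track.values.index, columns=track.values.columns),
        track.chromosome,
    )


def estimate_noise_sd(y: np.ndarray) -> float:
    """Robust noise sd from lag-1 differences.

    For a piecewise-constant signal plus iid noise, diff(y) is noise-driven
    except at the few breakpoints; sigma = 1.4826 * MAD(diff(y)) / sqrt(2).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        return 0.0
    d = np.diff(y)
    return float(stats.median_abs_deviation(d, scale="normal") / np.sqrt(2.0))


def pcf_segment(
    y,
    penalty: float = 12.0,
    min_size: int = 1,
    sigma: float | None = None,
) -> list[Segment]:
    """Exact piecewise-constant least-squares segmentation.

    Minimizes ``sum_seg SSE(seg) + gamma * (n_segments - 1)`` over all
    segmentations with every segment at least ``min_size`` long, by dynamic
    programming over breakpoint positions; ``gamma = penalty * sigma**2``.
    Ties are broken toward fewer segments, then leftmost breakpoints.

    A track shorter than ``min_size`` is returned as a single segment.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        return []
    if sigma is None:
        sigma = estimate_noise_sd(y)
    if n < 2 * min_size:  # no feasible breakpoint
        return [Segment(0, n - 1, float(y.mean()))]
    gamma = float(penalty) * float(sigma) ** 2

    s = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    inf = np.inf
    cost = np.full(n + 1, inf)  # cost[i]: best over prefix of i genes, gamma per segment
    nseg = np.zeros(n + 1, dtype=np.int64)
    prev = np.zeros(n + 1, dtype=np.int64)
    cost[0] = 0.0
    for i in range(min_size, n + 1):
        js = np.arange(0, i - min_size + 1)
        lengths = i - js
        seg_sum = s[i] - s[js]
        sse = (s2[i] - s2[js]) - seg_sum * seg_sum / lengths
        cand = cost[js] + sse + gamma
        best = np.nanmin(cand)
        if not np.isfinite(best):
            continue
        ties = js[cand == best]
        k = nseg[ties] + 1
        ties = ties[k == k.min()]
        j = int(ties[0])
        cost[i] = best
        nseg[i] = nseg[j] + 1
        prev[i] = j

    segments: list[Segment] = []
    i = n
    while i > 0:
        j = int(prev[i])
        mean = (s[i] - s[j]) / (i - j)
        segments.append(Segment(j, i - 1, float(mean)))
        i = j
    segments.reverse()
    return segments


def segmentation_cost(y, segments, gamma: float) -> float:
    """Cost of a given segmentation: sum of SSEs + gamma per breakpoint."""
    y = np.asarray(y, dtype=float)
    sse = sum(float(np.sum((y[s.start : s.end + 1] - np.mean(y[s.start : s.end + 1])) ** 2))
              for s in segments)
    return sse + gamma * (len(segments) - 1)


def call_aberrations(
    segments: list[Segment],
    params: EKaryoParams,
    sigma: float,
) -> pd.DataFrame:
    """Flag segments as gains/losses.

    A segment is called iff |mean| >= least_allowed_deviation, its length
    >= least_allowed_aberration_size, and the two-sided z-test of the
    segment mean against 0 (sd = sigma / sqrt(length)) has p <= threshold.
    """
    rows = []
    for seg in segments:
        mean, length = seg.mean, seg.length
        if sigma > 0:
            z = abs(mean) * np.sqrt(length) / sigma
            p = float(2.0 * stats.norm.sf(z))
        else:
            p = 1.0 if mean == 0 else 0.0
        called = (
            abs(mean) >= params.least_allowed_deviation
            and length >= params.least_allowed_aberration_size
            and p <= params.threshold
        )
        rows.append(
            {
                "start": seg.start,
                "end": seg.end,
                "n_genes": length,
                "mean": mean,
                "direction": "gain" if mean > 0 else ("loss" if mean < 0 else "none"),
                "p_value": p,
                "called": bool(called),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["start", "end", "n_genes", "mean", "direction", "p_value", "called"],
    )


def moving_average(
    values: pd.DataFrame, window: int, chromosome: pd.Series | None = None
) -> pd.DataFrame:
    """Centered moving average, truncated (never wrapped) at chromosome edges.

    With ``chromosome`` given, averaging is done independently within each
    chromosome so windows never straddle a boundary.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")

    def smooth(df: pd.DataFrame) -> pd.DataFrame:
        return df.rolling(window, center=True, min_periods=1).mean()

    if chromosome is None:
        return smooth(values)
    out = values.groupby(chromosome.to_numpy(), sort=False, group_keys=False).apply(smooth)
    return out.loc[values.index]


class EKaryotype:
    """e-karyotyping model over a count matrix.

    Parameters
    ----------
    counts
        Raw counts (genes x samples); needs >= 3 samples so the median
        baseline is meaningful.
    annotation
        Genomic locations defining the gene order along which segments run.
    params
        :class:`EKaryoParams`; defaults are the standard e-karyotyping
        settings.
    reference_samples
        Samples defining the per-gene median baseline (default: all).

    Examples
    --------
    >>> results = EKaryotype(counts, annotation).fit()
    >>> results.called_chromosomes["iPSC_1"]
    ['chr2', 'chr5']
    """

    def __init__(
        self,
        counts: CountMatrix,
        annotation: GeneAnnotation,
        params: EKaryoParams | None = None,
        reference_samples=None,
    ):
        if counts.n_samples < 3:
            raise ValidationError("e-karyotyping needs >= 3 samples")
        self.counts = counts
        self.annotation = annotation
        self.params = params or EKaryoParams()
        self.reference_samples = reference_samples

    def fit(self) -> "EKaryotypeResults":
        p = self.params
        norm = normalize_deseq(self.counts, pseudocount=p.pseudocount)
        expressed = filter_expressed(norm, p.nrc_threshold)
        if len(expressed) == 0:
            raise ValidationError("no gene passes the expressed-gene filter")
        log_expr = norm.log_expr.loc[expressed]
        track = relative_expression(log_expr, self.annotation, self.reference_samples)
        track = variability_filter(track, p.variability_removal_fraction)
        track = winsorize_track(track, p.winsorize_quantile)

        seg_rows = []
        sigmas = {}
        ordered_chroms = list(dict.fromkeys(track.chromosome))
        chrom_blocks = {
            chrom: track.values[track.chromosome.to_numpy() == chrom]
            for chrom in ordered_chroms
        }
        for sample in track.values.columns:
            diffs = [
                np.diff(block[sample].to_numpy())
                for block in chrom_blocks.values()
                if block.shape[0] >= 2
            ]
            d = np.concatenate(diffs) if diffs else np.array([])
            sigma = (
                float(stats.median_abs_deviation(d, scale="normal") / np.sqrt(2.0))
                if d.size
                else 0.0
            )
            sigmas[sample] = sigma
            for chrom in ordered_chroms:
                block = chrom_blocks[chrom]
                if block.shape[0] == 0:
                    continue
                y = block[sample].to_numpy()
                segments = pcf_segment(
                    y, penalty=p.penalty, min_size=p.min_segment_genes, sigma=sigma
                )
                calls = call_aberrations(segments, p, sigma)
                starts = self.annotation.table.loc[block.index, "start"].to_numpy()
                ends = self.annotation.table.loc[block.index, "end"].to_numpy()
                for _, row in calls.iterrows():
                    seg_rows.append(
                        {
                            "sample": sample,
                            "chromosome": chrom,
                            "start_idx": int(row["start"]),
                            "end_idx": int(row["end"]),
                            "start_bp": int(starts[int(row["start"])]),
                            "end_bp": int(ends[int(row["end"])]),
                            "n_genes": int(row["n_genes"]),
                            "mean": row["mean"],
                            "direction": row["direction"],
                            "p_value": row["p_value"],
                            "called": row["called"],
                        }
                    )
        segments_df = pd.DataFrame(
            seg_rows,
            columns=[
                "sample", "chromosome", "start_idx", "end_idx", "start_bp",
                "end_bp", "n_genes", "mean", "direction", "p_value", "called",
            ],
        )
        smoothed = moving_average(track.values, p.moving_average_window, track.chromosome)
        return EKaryotypeResults(
            model=self,
            track=track,
            segments=segments_df,
            smoothed=smoothed,
            noise_sd=pd.Series(sigmas, name="noise_sd"),
        )


@dataclass
class EKaryotypeResults:
    """Fitted e-karyotype: segments, aberration calls and smoothed tracks."""

    model: EKaryotype
    track: RelativeTrack
    segments: pd.DataFrame
    smoothed: pd.DataFrame
    noise_sd: pd.Series

    @property
    def calls(self) -> pd.DataFrame:
        return self.segments[self.segments["called"]]

    @property
    def called_chromosomes(self) -> dict[str, list[str]]:
        """Per sample, the sorted set of chromosomes with >= 1 call."""
        out: dict[str, list[str]] = {
            s: [] for s in self.track.values.columns
        }
        for sample, grp in self.calls.groupby("sample"):
            out[sample] = sorted(set(grp["chromosome"]))
        return out

    def is_stable(self, sample: str) -> bool:
        return len(self.called_chromosomes[sample]) == 0

    def summary(self) -> str:
        lines = ["e-karyotyping summary", "=" * 21]
        p = self.model.params
        lines.append(
            f"samples: {self.track.values.shape[1]}  genes analysed: "
            f"{self.track.values.shape[0]}"
        )
        lines.append(
            f"params: deviation>={p.least_allowed_deviation}, "
            f"size>={p.least_allowed_aberration_size} genes, "
            f"penalty={p.penalty}, threshold={p.threshold}"
        )
        for sample, chroms in self.called_chromosomes.items():
            verdict = "stable" if not chroms else "aberrant: " + ", ".join(chroms)
            lines.append(f"  {sample:<20s} {verdict}")
        return "\n".join(lines)
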