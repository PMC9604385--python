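"""Synthetic RNA-seq cohorts with known ground truth.

The generator emulates the structure the downstream stages are built to
detect: negative-binomial counts with gene-specific means and dispersions
(variance = mu + phi * mu^2), per-sample library-size factors, two cell-type
groups with a planted fraction of differentially expressed genes, dosage
aberrations (whole-chromosome or segmental, e.g. a 1.5x single-copy gain) in
chosen samples, and lineage-marker gene sets elevated in designated groups.

Randomness is organised as one master seed with per-stage child streams
(gene parameters, DE assignment, size factors, and one stream per
(sample, chromosome) block of counts), so adding an aberration to one block
never perturbs draws anywhere else.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, ValidationError

__all__ = [
    "Aneuploidy",
    "MarkerSet",
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "spike_aneuploidy",
    "chromosome_names",
]

# fixed stage tags for child-seed derivation
_STAGE_GENE_PARAMS = 1
_STAGE_DE = 2
_STAGE_SIZE_FACTORS = 3
_STAGE_COUNTS = 4
_STAGE_SPIKE = 5

_GENE_SPACING = 2_000
_GENE_LENGTH = 1_000


def chromosome_names(n: int) -> list[str]:
    """Default karyotype naming: n-1 autosomes plus X (e.g. chr1..chr8, chrX)."""
    if n == 1:
        return ["chr1"]
    return [f"chr{i}" for i in range(1, n)] + ["chrX"]


@dataclass(frozen=True)
class Aneuploidy:
    """A planted dosage change.

    ``start``/``end`` are gene indices within the chromosome, half-open
    ``[start, end)``; both None means the whole chromosome.  ``dosage`` is
    the multiplier on expected expression (1.5 = single-copy gain of a
    diploid locus, 0.5 = single-copy loss).
    """

    sample: str
    chromosome: str
    dosage: float
    start: int | None = None
    end: int | None = None


@dataclass(frozen=True)
class MarkerSet:
    """A named lineage-marker gene set.

    ``gene_indices`` are global gene indices; ``elevation`` maps group label
    -> log2 elevation of the set's genes in that group's samples.
    """

    name: str
    gene_indices: tuple[int, ...]
    elevation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "gene_indices", tuple(self.gene_indices))


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort.

    Defaults are the package's reference study conditions: a 9-chromosome
    karyotype (8 autosomes + X), 1,200 genes per chromosome, two groups of
    four samples, log-normal baseline means (median mean count ~150),
    moderate bulk-RNA-seq dispersions (phi median 0.05) and library-size
    factors in [0.7, 1.4].
    """

    n_chromosomes: int = 9
    genes_per_chromosome: tuple[int, ...] | int = 1_200
    n_samples_per_group: int = 4
    group_labels: tuple[str, ...] = ("fibroblast", "iPSC")
    baseline_log_mean_distribution: tuple[float, float] = (5.0, 1.5)
    dispersion_distribution: tuple[float, float] = (float(np.log(0.05)), 0.5)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    de_fraction: float = 0.10
    de_log2fc_magnitude: tuple[float, float] = (1.0, 3.0)
    aneuploidies: tuple[Aneuploidy, ...] = ()
    marker_sets: tuple[MarkerSet, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValidationError("n_chromosomes: must be >= 1")
        if isinstance(self.genes_per_chromosome, int):
            self.genes_per_chromosome = (self.genes_per_chromosome,) * self.n_chromosomes
        else:
            self.genes_per_chromosome = tuple(self.genes_per_chromosome)
        if len(self.genes_per_chromosome) != self.n_chromosomes:
            raise ValidationError(
                "genes_per_chromosome: length must equal n_chromosomes"
            )
        if any(g < 1 for g in self.genes_per_chromosome):
            raise ValidationError("genes_per_chromosome: all entries must be >= 1")
        if self.n_samples_per_group < 1:
            raise ValidationError("n_samples_per_group: must be >= 1")
        if len(set(self.group_labels)) != len(self.group_labels) or not self.group_labels:
            raise ValidationError("group_labels: must be non-empty and unique")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction: must be in [0, 1]")
        lo, hi = self.de_log2fc_magnitude
        if lo < 0 or hi < lo:
            raise ValidationError("de_log2fc_magnitude: need 0 <= lo <= hi")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi < lo:
            raise ValidationError("size_factor_range: need 0 < lo <= hi")
        if self.baseline_log_mean_distribution[1] < 0:
            raise ValidationError("baseline_log_mean_distribution: sd must be >= 0")
        if self.dispersion_distribution[1] < 0:
            raise ValidationError("dispersion_distribution: log-sd must be >= 0")
        self.aneuploidies = tuple(self.aneuploidies)
        self.marker_sets = tuple(self.marker_sets)
        chroms = set(self.chromosomes)
        samples = set(self.sample_ids)
        for an in self.aneuploidies:
            if an.sample not in samples:
                raise ValidationError(f"aneuploidies: unknown sample {an.sample!r}")
            if an.chromosome not in chroms:
                raise ValidationError(
                    f"aneuploidies: unknown chromosome {an.chromosome!r}"
                )
            if an.dosage <= 0:
                raise ValidationError("aneuploidies: dosage must be > 0")
        n_genes = self.n_genes
        groups = set(self.group_labels)
        for ms in self.marker_sets:
            if any(not 0 <= g < n_genes for g in ms.gene_indices):
                raise ValidationError(f"marker_sets: {ms.name}: gene index out of range")
            if any(g not in groups for g in ms.elevation):
                raise ValidationError(f"marker_sets: {ms.name}: unknown group label")

    # --- derived layout -------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return chromosome_names(self.n_chromosomes)

    @property
    def n_genes(self) -> int:
        return int(sum(self.genes_per_chromosome))

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{label}_{k + 1}"
            for label in self.group_labels
            for k in range(self.n_samples_per_group)
        ]

    @property
    def sample_groups(self) -> pd.Series:
        return pd.Series(
            [label for label in self.group_labels for _ in range(self.n_samples_per_group)],
            index=self.sample_ids,
            name="group",
        )

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Everything planted into a synthetic cohort.

    ``de_log2fc`` is the signed log2 fold change of the second group relative
    to the first (index = planted DE gene ids).
    """

    de_log2fc: pd.Series
    aneuploidies: tuple[Aneuploidy, ...]
    marker_genes: dict[str, list[str]]
    size_factors: pd.Series
    gene_means: pd.Series
    dispersions: pd.Series
    groups: pd.Series


def _child_rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


def _make_annotation(spec: SyntheticSpec) -> GeneAnnotation:
    width = max(6, len(str(spec.n_genes)))
    rows = []
    gidx = 0
    for chrom, n in zip(spec.chromosomes, spec.genes_per_chromosome):
        for i in range(n):
            rows.append(
                (
                    f"g{gidx:0{width}d}",
                    chrom,
                    i * _GENE_SPACING,
                    i * _GENE_SPACING + _GENE_LENGTH,
                    "+",
                )
            )
            gidx += 1
    df = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    ).set_index("gene_id")
    return GeneAnnotation(df)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[CountMatrix, GeneAnnotation, GroundTruth]:
    """Draw one synthetic cohort; identical spec + seed gives identical output."""
    annotation = _make_annotation(spec)
    gene_ids = annotation.gene_ids
    n_genes, samples = spec.n_genes, spec.sample_ids
    groups = spec.sample_groups

    rng = _child_rng(spec.seed, _STAGE_GENE_PARAMS)
    mu_log_mean, mu_log_sd = spec.baseline_log_mean_distribution
    base_mean = np.exp(rng.normal(mu_log_mean, mu_log_sd, size=n_genes))
    phi_log_mean, phi_log_sd = spec.dispersion_distribution
    dispersion = np.exp(rng.normal(phi_log_mean, phi_log_sd, size=n_genes))

    rng = _child_rng(spec.seed, _STAGE_DE)
    n_de = int(np.floor(spec.de_fraction * n_genes))
    de_idx = np.sort(rng.choice(n_genes, size=n_de, replace=False))
    lo, hi = spec.de_log2fc_magnitude
    de_lfc = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)

    rng = _child_rng(spec.seed, _STAGE_SIZE_FACTORS)
    sf_lo, sf_hi = spec.size_factor_range
    size_factors = rng.uniform(sf_lo, sf_hi, size=len(samples))

    # per-(gene, sample) log2 offsets from DE and marker elevations
    log2_offset = np.zeros((n_genes, len(samples)))
    group_of = groups.to_numpy()
    if n_de and len(spec.group_labels) >= 2:
        second = spec.group_labels[1]
        log2_offset[np.ix_(de_idx, group_of == second)] += de_lfc[:, None]
    for ms in spec.marker_sets:
        for label, elev in ms.elevation.items():
            log2_offset[np.ix_(list(ms.gene_indices), group_of == label)] += elev

    dosage = np.ones((n_genes, len(samples)))
    chrom_offsets = np.cumsum([0, *spec.genes_per_chromosome])
    chrom_index = {c: i for i, c in enumerate(spec.chromosomes)}
    sample_index = {s: j for j, s in enumerate(samples)}
    for an in spec.aneuploidies:
        ci = chrom_index[an.chromosome]
        lo_g, hi_g = chrom_offsets[ci], chrom_offsets[ci + 1]
        start = lo_g + (an.start or 0)
        end = lo_g + (an.end if an.end is not None else hi_g - lo_g)
        start, end = max(lo_g, start), min(hi_g, end)
        dosage[start:end, sample_index[an.sample]] *= an.dosage

    mean = (
        base_mean[:, None] * np.exp2(log2_offset) * dosage * size_factors[None, :]
    )

    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    n_param = 1.0 / dispersion
    for j in range(len(samples)):
        for ci in range(spec.n_chromosomes):
            lo_g, hi_g = chrom_offsets[ci], chrom_offsets[ci + 1]
            block_rng = _child_rng(spec.seed, _STAGE_COUNTS, j, ci)
            mu = mean[lo_g:hi_g, j]
            n = n_param[lo_g:hi_g]
            counts[lo_g:hi_g, j] = block_rng.negative_binomial(n, n / (n + mu))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    metadata = pd.DataFrame({"group": groups, "strain": "synthetic", "passage": 0})
    truth = GroundTruth(
        de_log2fc=pd.Series(de_lfc, index=gene_ids[de_idx], name="log2fc"),
        aneuploidies=spec.aneuploidies,
        marker_genes={
            ms.name: list(gene_ids[list(ms.gene_indices)]) for ms in spec.marker_sets
        },
        size_factors=pd.Series(size_factors, index=samples, name="size_factor"),
        gene_means=pd.Series(base_mean, index=gene_ids, name="mean"),
        dispersions=pd.Series(dispersion, index=gene_ids, name="dispersion"),
        groups=groups,
    )
    return CountMatrix(counts_df, metadata), annotation, truth


def spike_aneuploidy(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    sample: str,
    chromosome: str,
    dosage: float,
    span: tuple[int, int] | None = None,
    mode: str = "deterministic",
    seed: int = 0,
) -> CountMatrix:
    """Scale the expected counts of one chromosome (or span) in one sample.

    ``mode="deterministic"`` multiplies the targeted counts by ``dosage`` and
    rounds half-to-even; ``mode="poisson"`` re-draws each targeted count from
    Poisson(dosage * count), preserving the expectation while adding sampling
    noise.  All other entries are returned unchanged.
    """
    if dosage <= 0:
        raise ValidationError("dosage must be > 0")
    if sample not in counts.sample_ids:
        raise LookupError(f"unknown sample {sample!r}")
    chrom_col = annotation.table["chromosome"].astype(str)
    if chromosome not in set(chrom_col):
        raise LookupError(f"unknown chromosome {chromosome!r}")
    ordered = annotation.genomic_order()
    chrom_genes = ordered.index[ordered["chromosome"].astype(str) == chromosome]
    if span is not None:
        chrom_genes = chrom_genes[span[0] : span[1]]
    target = counts.counts.index.intersection(chrom_genes, sort=False)

    new = counts.counts.copy()
    col = new.loc[target, sample].to_numpy(dtype=float)
    if mode == "deterministic":
        new.loc[target, sample] = np.rint(col * dosage).astype(np.int64)
    elif mode == "poisson":
        rng = _child_rng(seed, _STAGE_SPIKE)
        new.loc[target, sample] = rng.poisson(col * dosage).astype(np.int64)
    else:
        raise ValidationError(f"unknown spike mode {mode!r}")
    return CountMatrix(new, counts.sample_metadata)
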