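"""Readers and writers for the pipeline's on-disk formats.

Counts travel as TSV (``gene_id`` column + one column per sample) or as a
matrix-market triplet with ``.rows`` / ``.cols`` sidecar files carrying the
gene and sample identifiers.  Annotation is accepted as 6-column BED
(0-based, half-open) or GFF3 (1-based inclusive, converted on read to the
internal 0-based half-open convention).  Floats are written with 6
significant digits.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, GeneAnnotation, ValidationError

__all__ = [
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation_bed",
    "read_metadata",
    "write_table",
]

FLOAT_FORMAT = "%.6g"


class ParseError(ValidationError):
    """Malformed input file; message carries the offending line number."""


def read_counts(path: str, fmt: str | None = None, metadata: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV or matrix-market.

    ``fmt`` is inferred from the extension when omitted (``.mtx`` -> sparse
    matrix-market with ``.rows``/``.cols`` sidecars, anything else -> TSV).
    """
    if fmt is None:
        fmt = "mtx" if str(path).endswith(".mtx") else "tsv"
    if fmt == "tsv":
        df = pd.read_table(path, index_col=0)
        df.index.name = "gene_id"
    elif fmt == "mtx":
        mat = scipy.io.mmread(path)
        genes = _read_lines(str(path) + ".rows")
        samples = _read_lines(str(path) + ".cols")
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise ParseError(
                f"matrix-market shape {dense.shape} does not match "
                f"{len(genes)} row ids x {len(samples)} column ids"
            )
        df = pd.DataFrame(dense, index=pd.Index(genes, name="gene_id"), columns=samples)
    else:
        raise ValidationError(f"unknown counts format {fmt!r}")
    meta = read_metadata(metadata) if metadata else None
    return CountMatrix(df, meta)


def write_counts(cm: CountMatrix, path: str, fmt: str | None = None) -> None:
    if fmt is None:
        fmt = "mtx" if str(path).endswith(".mtx") else "tsv"
    if fmt == "tsv":
        cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "mtx":
        sparse = scipy.sparse.coo_matrix(cm.counts.to_numpy())
        scipy.io.mmwrite(path, sparse)
        _write_lines(str(path) + ".rows", cm.gene_ids)
        _write_lines(str(path) + ".cols", cm.sample_ids)
    else:
        raise ValidationError(f"unknown counts format {fmt!r}")


def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_table(path, index_col=0)
    meta.index.name = "sample_id"
    return meta


def read_annotation(path: str, fmt: str | None = None) -> GeneAnnotation:
    """Read gene annotation from BED6 or GFF3.

    GFF3 coordinates (1-based, end-inclusive) are converted to the internal
    0-based half-open convention: ``start -> start - 1``, ``end`` unchanged.
    """
    if fmt is None:
        lower = str(path).lower()
        fmt = "gff3" if lower.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "gff3":
        return _read_gff3(path)
    raise ValidationError(f"unknown annotation format {fmt!r}")


def _read_bed(path: str) -> GeneAnnotation:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: BED line needs >= 4 fields")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            if start_i >= end_i:
                raise ParseError(f"{path}:{lineno}: start >= end ({start_i} >= {end_i})")
            strand = parts[5] if len(parts) >= 6 else "."
            records.append((name, chrom, start_i, end_i, strand))
    if not records:
        raise ParseError(f"{path}: no BED records")
    df = pd.DataFrame(
        records, columns=["gene_id", "chromosome", "start", "end", "strand"]
    ).set_index("gene_id")
    return GeneAnnotation(df)


def _read_gff3(path: str) -> GeneAnnotation:
    import gffutils

    records = []
    for feature in gffutils.DataIterator(path):
        if feature.featuretype not in ("gene", "pseudogene"):
            continue
        attrs = feature.attributes
        gene_id = (
            (attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name") or [None])[0]
        )
        if gene_id is None:
            raise ParseError(f"{path}: gene feature at {feature.seqid}:{feature.start} has no ID")
        start0 = feature.start - 1  # GFF3 is 1-based inclusive
        if start0 >= feature.end:
            raise ParseError(
                f"{path}: gene {gene_id}: start >= end after conversion"
            )
        records.append((gene_id, feature.seqid, start0, feature.end, feature.strand or "."))
    if not records:
        raise ParseError(f"{path}: no gene features found")
    df = pd.DataFrame(
        records, columns=["gene_id", "chromosome", "start", "end", "strand"]
    ).set_index("gene_id")
    return GeneAnnotation(df)


def write_annotation_bed(ann: GeneAnnotation, path: str) -> None:
    t = ann.genomic_order()
    with open(path, "w") as fh:
        for gene_id, row in t.iterrows():
            fh.write(
                f"{row['chromosome']}\t{int(row['start'])}\t{int(row['end'])}"
                f"\t{gene_id}\t0\t{row['strand']}\n"
            )


def write_table(df: pd.DataFrame, path: str, index_label: str | None = None) -> None:
    """Write any result table as TSV with 6-significant-digit floats."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def _read_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path: str, items) -> None:
    with open(path, "w") as fh:
        for item in items:
            fh.write(f"{item}\n")
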