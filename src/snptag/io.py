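"""Readers and writers: VCF and TSV genotype matrices in, TSV reports out."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .attractor import AttractorResult
from .errors import InvalidInputError, ParseError
from .matrix import GenotypeMatrix
from .tagging import TagSNP

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_vcf",
    "write_report",
    "read_tag_table",
]

REPORT_TOP_SNPS = 100


def read_matrix(
    path,
    ploidy_mode: str = "genotype",
    chromosome: str | None = None,
    start: int | None = None,
    end: int | None = None,
    samples=None,
) -> GenotypeMatrix:
    """Read a tab-separated genotype matrix.

    Expected header: ``id  chrom  pos  <sample...>``; entries in
    {0, 1, 2, NA} (genotypes) or {0, 1, NA} (haplotypes).  Rows must be
    sorted by position and belong to one chromosome (use the region filter
    on multi-chromosome files).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.shape[1] < 4:
        raise ParseError(f"{path}: need columns id, chrom, pos and >= 1 sample")
    head = [c.lower() for c in df.columns[:3]]
    if head != ["id", "chrom", "pos"]:
        raise ParseError(f"{path}: header must start with id, chrom, pos (got {head})")
    if df.empty:
        raise ParseError(f"{path}: no variant rows")
    if chromosome is not None:
        df = df[df.iloc[:, 1] == str(chromosome)]
    chroms = df.iloc[:, 1].unique()
    if len(chroms) > 1:
        raise ParseError(
            f"{path}: multiple chromosomes {list(chroms)}; pass a region filter"
        )
    if df.empty:
        raise ParseError(f"{path}: no rows left after region filter")
    pos = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    if pos.isna().any():
        raise ParseError(f"{path}: non-numeric position in row {int(pos.isna().idxmax()) + 2}")
    if start is not None:
        df, pos = df[pos >= start], pos[pos >= start]
    if end is not None:
        df, pos = df[pos <= end], pos[pos <= end]
    if df.empty:
        raise ParseError(f"{path}: no rows left after region filter")
    if np.any(np.diff(pos.to_numpy()) < 0):
        raise ParseError(f"{path}: positions not sorted; sort the file by position")

    sample_cols = list(df.columns[3:])
    if samples is not None:
        missing = set(samples) - set(sample_cols)
        if missing:
            raise ParseError(f"{path}: unknown samples {sorted(missing)}")
        sample_cols = list(samples)
    allowed = {"0", "1", "2", "NA"} if ploidy_mode == "genotype" else {"0", "1", "NA"}
    body = df[sample_cols].to_numpy(dtype=object)
    values = np.empty(body.shape, dtype=np.float64)
    for (r, c), tok in np.ndenumerate(body):
        tok = str(tok).strip()
        if tok not in allowed:
            raise ParseError(
                f"{path}: invalid token {tok!r} at variant {df.iloc[r, 0]!r}, "
                f"sample {sample_cols[c]!r}"
            )
        values[r, c] = np.nan if tok == "NA" else float(tok)
    return GenotypeMatrix(
        values=values,
        ids=df.iloc[:, 0].to_numpy(dtype=object),
        positions=pos.to_numpy(dtype=np.int64),
        chromosome=str(chroms[0]),
        ploidy_mode=ploidy_mode,
        sample_names=np.array(sample_cols, dtype=object),
    )


def write_matrix(g: GenotypeMatrix, path) -> None:
    """Write the TSV matrix format read by :func:`read_matrix`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tchrom\tpos\t" + "\t".join(map(str, g.sample_names)) + "\n")
        for i in range(g.num_variants):
            row = [
                "NA" if np.isnan(v) else str(int(v)) for v in g.values[i]
            ]
            fh.write(f"{g.ids[i]}\t{g.chromosome}\t{g.positions[i]}\t" + "\t".join(row) + "\n")


def read_vcf(
    path,
    ploidy_mode: str = "genotype",
    chromosome: str | None = None,
    start: int | None = None,
    end: int | None = None,
    samples=None,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a genotype or haplotype matrix.

    Genotype mode counts ALT alleles (0/0 -> 0, 0/1 -> 1, 1/1 -> 2); any
    missing or half-called allele gives a missing entry.  Haplotype mode
    splits each phased diploid sample into two {0, 1} columns and requires
    phased genotypes.  Multiallelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=list(samples) if samples is not None else None)
    sample_names = list(vcf.samples)
    rows, ids, positions, chroms = [], [], [], set()
    skipped = 0
    for var in vcf:
        if chromosome is not None and var.CHROM != chromosome:
            continue
        if start is not None and var.POS < start:
            continue
        if end is not None and var.POS > end:
            continue
        if len(var.ALT) != 1:
            skipped += 1
            continue
        chroms.add(var.CHROM)
        if len(chroms) > 1:
            raise ParseError(
                f"{path}: multiple chromosomes; pass chromosome= to select one"
            )
        calls = var.genotypes  # [[a0, a1, phased], ...]
        if ploidy_mode == "genotype":
            row = [
                float(c[0] + c[1]) if c[0] >= 0 and c[1] >= 0 else np.nan
                for c in calls
            ]
        else:
            row = []
            for c in calls:
                if (c[0] >= 0 or c[1] >= 0) and not c[2]:
                    raise ParseError(
                        f"{path}: unphased genotype at {var.CHROM}:{var.POS} — "
                        "haplotype mode requires phased input"
                    )
                row.extend(
                    float(a) if a >= 0 else np.nan for a in (c[0], c[1])
                )
        rows.append(row)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
    if skipped:
        logger.info("%s: skipped %d multiallelic records", path, skipped)
    if not rows:
        raise ParseError(f"{path}: no biallelic records found")
    values = np.asarray(rows, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.int64)
    order = np.argsort(positions, kind="stable")
    if ploidy_mode == "haplotype":
        names = [f"{s}_{h}" for s in sample_names for h in (1, 2)]
    else:
        names = sample_names
    return GenotypeMatrix(
        values=values[order],
        ids=np.asarray(ids, dtype=object)[order],
        positions=positions[order],
        chromosome=next(iter(chroms)),
        ploidy_mode=ploidy_mode,
        sample_names=np.array(names, dtype=object),
    )


def write_tag_table(tags: list[TagSNP], g: GenotypeMatrix, path) -> None:
    """Ranked tag table: rank, id, chromosome, position, strength (bits),
    number of top SNPs listed, and the top-SNP list with weights."""
    with Path(path).open("w") as fh:
        fh.write("rank\tid\tchrom\tpos\tstrength_bits\tn_top_snps\ttop_snps\n")
        for t in tags:
            a = t.source
            order = np.argsort(-a.weights, kind="stable")[:10]
            idx = a.window_range[0] + order
            listed = ";".join(
                f"{g.ids[i]}:{a.weights[j]:.6f}" for i, j in zip(idx, order)
            )
            fh.write(
                f"{t.rank}\t{t.id}\t{g.chromosome}\t{t.position}\t"
                f"{t.strength:.6f}\t{len(order)}\t{listed}\n"
            )


def write_attractor_table(
    a: AttractorResult, g: GenotypeMatrix, path, top: int = REPORT_TOP_SNPS
) -> None:
    """Per-attractor weight table: id, position, weight and the genotype row
    of each of the top-weighted SNPs (at most ``top``), weight-descending."""
    order = np.argsort(-a.weights, kind="stable")[:top]
    with Path(path).open("w") as fh:
        fh.write("id\tpos\tweight\tgenotypes\n")
        for j in order:
            i = a.window_range[0] + int(j)
            geno = ",".join(
                "NA" if np.isnan(v) else str(int(v)) for v in g.values[i]
            )
            fh.write(f"{g.ids[i]}\t{g.positions[i]}\t{a.weights[j]:.9f}\t{geno}\n")


def write_report(tags: list[TagSNP], g: GenotypeMatrix, outdir) -> list[Path]:
    """Write the ranked tag table plus one weight table per attractor.

    Returns the written paths (tags.tsv first).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [outdir / "tags.tsv"]
    write_tag_table(tags, g, paths[0])
    for t in tags:
        p = outdir / f"attractor_rank{t.rank:03d}_{t.id}.tsv"
        write_attractor_table(t.source, g, p)
        paths.append(p)
    return paths


def read_tag_table(path) -> pd.DataFrame:
    """Re-read a written tag table (for coverage evaluation pipelines)."""
    df = pd.read_csv(path, sep="\t")
    required = {"rank", "id", "pos"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: not a tag table (missing {required - set(df.columns)})")
    return df.sort_values("rank")


def resolve_tag_ids(g: GenotypeMatrix, tag_ids) -> list[int]:
    """Map variant identifiers to matrix indices, erroring on unknown ids."""
    lookup = {str(v): i for i, v in enumerate(g.ids)}
    indices = []
    for tid in tag_ids:
        if str(tid) not in lookup:
            raise InvalidInputError(f"unknown tag id {tid!r}")
        indices.append(lookup[str(tid)])
    return indices
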