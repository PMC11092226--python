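"""Readers and writers for the external formats the pipeline consumes.

Coordinates are normalized to the package-wide 1-based closed convention:
VCF and GFF3 are already 1-based; BED's 0-based half-open intervals are
converted at this boundary.  VCF parsing goes through pysam and GFF3
parsing through gffutils; the writers emit the corresponding plain-text
dialects directly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import AlleleCountRecord, GeneModel, Genotype, SampleKey, VariantRecord

logger = logging.getLogger("asel")


class FormatError(ValueError):
    """File-level structural problem (missing column, bad header)."""


class ParseError(ValueError):
    """Row-level problem; the message cites the offending line."""


COUNT_COLUMNS = [
    "gene_id", "snp_id", "chrom", "pos",
    "genotype", "condition", "replicate", "count_p1", "count_p2",
]

_INT_COUNT_COLUMNS = ["pos", "replicate", "count_p1", "count_p2"]


# ---------------------------------------------------------------- counts TSV

def read_allele_counts(path: str | Path) -> list[AlleleCountRecord]:
    """Read a per-SNP allele-count table (TSV) into records, order preserved.

    The header line is line 1; parse errors cite the 1-based file line of
    the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in _INT_COUNT_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.astype("Int64").astype("float"))
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based index
            raise ParseError(
                f"{path}: non-integer value {df[col].iloc[bad.idxmax()]!r} "
                f"in column {col} on line {line}"
            )
        df[col] = converted.astype(int)
    records = []
    for row in df.itertuples(index=False):
        sample = SampleKey(Genotype(row.genotype), row.condition, int(row.replicate))
        records.append(
            AlleleCountRecord(
                gene_id=row.gene_id, snp_id=row.snp_id, chrom=row.chrom,
                pos=int(row.pos), sample=sample,
                count_p1=int(row.count_p1), count_p2=int(row.count_p2),
            )
        )
    return records


def write_allele_counts(records: Iterable[AlleleCountRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id, "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
            "genotype": r.sample.genotype.value, "condition": r.sample.condition,
            "replicate": r.sample.replicate,
            "count_p1": r.count_p1, "count_p2": r.count_p2,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- VCF

def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read VCF 4.x records; multi-allelic sites expand to one record per alt.

    AF and DP are taken from INFO when present (defaults 1.0 / 100, the
    convention for fixed inter-genome differences).
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            af = info.get("AF", 1.0)
            if isinstance(af, tuple):
                af = af[0]
            dp = info.get("DP", 100)
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        allele_frequency=round(float(af), 6),  # htslib stores Float as float32
                        depth=int(dp),
                    )
                )
    return records


def write_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    records = list(records)
    chroms = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"AF={r.allele_frequency:g};DP={r.depth}\n"
            )


# --------------------------------------------------------------------- GFF3

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene features + their CDS children) from GFF3."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        cds = sorted(
            (c.start, c.end)
            for c in db.children(g, featuretype="CDS")
        )
        gene_id = g.attributes.get("ID", [g.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id, chrom=g.seqid, start=g.start, end=g.end,
                strand=g.strand, cds_segments=cds,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tasel\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tasel\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for s, e in g.cds_segments:
                fh.write(
                    f"{g.chrom}\tasel\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )


# -------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------- BED

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals, converting 0-based half-open to 1-based closed.

    Returns (chrom, start, end, name) with name "" when absent.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            start1, end1 = bed_to_internal(start0, end0)
            if end1 < start1:
                raise ParseError(f"{path}: line {lineno}: empty/inverted interval")
            name = fields[3] if len(fields) > 3 else ""
            intervals.append((chrom, start1, end1, name))
    return intervals


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start1, end1, name in intervals:
            start0, end0 = internal_to_bed(start1, end1)
            fh.write(f"{chrom}\t{start0}\t{end0}\t{name}\n")


def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based closed [start0+1, end0]."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    return start1 - 1, end1


# --------------------------------------------------------- ASEG call table

ASEG_COLUMNS = [
    "gene_id", "hybrid", "condition", "is_aseg", "direction",
    "n_supporting_replicates", "n_testable_replicates", "replicate_directions",
]


def write_aseg_calls(calls, path: str | Path) -> None:
    rows = [
        {
            "gene_id": c.gene_id, "hybrid": c.hybrid.value, "condition": c.condition,
            "is_aseg": int(c.is_aseg), "direction": c.direction.value,
            "n_supporting_replicates": c.n_supporting_replicates,
            "n_testable_replicates": c.n_testable_replicates,
            "replicate_directions": ",".join(d.value for d in c.replicate_directions),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=ASEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_aseg_calls(path: str | Path):
    from .calling import ASEGCall
    from .types import Direction

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ASEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            ASEGCall(
                gene_id=row.gene_id, hybrid=Genotype(row.hybrid), condition=row.condition,
                is_aseg=bool(int(row.is_aseg)), direction=Direction(row.direction),
                n_supporting_replicates=int(row.n_supporting_replicates),
                n_testable_replicates=int(row.n_testable_replicates),
                replicate_directions=[
                    Direction(d) for d in row.replicate_directions.split(",") if d
                ],
            )
        )
    return calls


# --------------------------------------------------------- haplotype table

def write_haplotypes(hm, path: str | Path) -> None:
    """Write a HaplotypeMatrix as TSV: metadata comment, positions header,
    one row per haplotype (-1 = missing)."""
    with open(path, "w") as fh:
        fh.write(
            f"#region_start={hm.region_start}\tregion_length={hm.region_length}\t"
            f"population={hm.population}\n"
        )
        fh.write("haplotype\t" + "\t".join(str(p) for p in hm.positions) + "\n")
        for i, row in enumerate(hm.matrix):
            fh.write(f"h{i + 1}\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_haplotypes(path: str | Path):
    """Read a haplotype TSV written by :func:`write_haplotypes`."""
    import numpy as np

    from .diversity import HaplotypeMatrix

    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("#"):
            raise FormatError(f"{path}: missing metadata comment line")
        meta = dict(item.split("=", 1) for item in meta_line[1:].strip().split("\t"))
        header = fh.readline().rstrip("\n").split("\t")
        positions = np.array([int(p) for p in header[1:]], dtype=np.int64)
        rows = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows.append([int(v) for v in fields[1:]])
    return HaplotypeMatrix(
        positions=positions,
        matrix=np.array(rows, dtype=np.int8),
        region_start=int(meta["region_start"]),
        region_length=int(meta["region_length"]),
        population=meta.get("population", ""),
    )


# --------------------------------------------------------------- TPM matrix

def read_tpm(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TPM table; columns parse to (genotype, condition,
    replicate) MultiIndex from 'GENOTYPE:condition:replicate' headers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    keys = [SampleKey.parse(c) for c in df.columns]
    df.columns = pd.MultiIndex.from_tuples(
        [(k.genotype.value, k.condition, k.replicate) for k in keys],
        names=["genotype", "condition", "replicate"],
    )
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative TPM values")
    return df


def write_tpm(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.columns = [f"{g}:{c}:{r}" for g, c, r in matrix.columns]
    out.to_csv(path, sep="\t", index_label="gene_id")
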