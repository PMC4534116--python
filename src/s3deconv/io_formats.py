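"""Readers and writers for the external formats the pipeline touches.

This module converts files (SAM/BAM alignments, refFlat/GTF annotation,
TSV result tables, FASTA/FASTQ sequences) into the package's internal
records and back.  It contains no species-assignment logic.

All internal coordinates are 0-based half-open; conversions to and from
1-based conventions (GTF, SAM text) happen only at the parse/write
boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Sentinel mismatch count for reads with no alignment in a genome.
MISMATCH_SENTINEL = -1

UNIQUENESS_RULES = ("mapq255", "nh_tag")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class AlignmentObservation:
    """A read's best alignment evidence within one genome.

    Multimapping within a genome is collapsed to a single observation:
    ``aligned=True``, ``unique=False`` and ``mismatches`` equal to the
    best (minimum edit distance) alignment's value.  ``mismatches`` is
    taken from the SAM ``NM`` tag, i.e. edit distance including indels,
    which is the only universally available per-alignment proxy for the
    mismatch count.
    """

    read_id: str
    genome_id: str
    aligned: bool
    unique: bool
    mismatches: int = MISMATCH_SENTINEL
    chrom: str = ""
    start: int = -1
    end: int = -1
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.aligned:
            if self.unique:
                raise ValueError(
                    f"read {self.read_id!r}: unaligned observation cannot be unique"
                )
            if self.mismatches != MISMATCH_SENTINEL:
                raise ValueError(
                    f"read {self.read_id!r}: unaligned observation carries a "
                    "mismatch count"
                )
        else:
            if self.mismatches < 0:
                raise ValueError(
                    f"read {self.read_id!r}: aligned observation needs a "
                    "non-negative mismatch count"
                )
            if self.end <= self.start:
                raise ValueError(
                    f"read {self.read_id!r}: aligned observation needs end > start"
                )

    @classmethod
    def unaligned(cls, read_id: str, genome_id: str) -> "AlignmentObservation":
        return cls(read_id=read_id, genome_id=genome_id, aligned=False, unique=False)


@dataclass(frozen=True)
class GeneModel:
    """A gene's exon-union intervals within one genome.

    ``exon_union`` holds ``(chrom, start, end, strand)`` tuples that are
    sorted and pairwise disjoint after merging all isoforms of the gene.
    ``effective_length_bp`` is the total union length; the quantification
    step lowers it when multi-gene (name-overlap) regions are masked out.
    """

    gene_id: str
    genome_id: str
    exon_union: tuple[tuple[str, int, int, str], ...]
    biotype_hint: str = ""
    effective_length_bp: int = -1

    def __post_init__(self) -> None:
        if self.effective_length_bp < 0:
            object.__setattr__(
                self,
                "effective_length_bp",
                sum(e - s for _, s, e, _ in self.exon_union),
            )

    def with_exons(
        self, exons: Sequence[tuple[str, int, int, str]]
    ) -> "GeneModel":
        return replace(self, exon_union=tuple(exons), effective_length_bp=-1)


def merge_intervals(
    intervals: Iterable[tuple[str, int, int, str]]
) -> tuple[tuple[str, int, int, str], ...]:
    """Union of genomic intervals, merged per (chrom, strand).

    Overlapping or bookended intervals are fused; the result is sorted by
    (chrom, start) and independent of the input ordering.
    """
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, start, end, strand in intervals:
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end}) on {chrom}")
        by_key.setdefault((chrom, strand), []).append((start, end))
    merged: list[tuple[str, int, int, str]] = []
    for (chrom, strand), ivs in by_key.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e, strand))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e, strand))
    merged.sort(key=lambda iv: (iv[0], iv[1], iv[2]))
    return tuple(merged)


# ---------------------------------------------------------------------------
# SAM/BAM alignments
# ---------------------------------------------------------------------------

def read_alignments(
    alignment_file: str | Path,
    genome_id: str,
    uniqueness_rule: str = "mapq255",
) -> Iterator[AlignmentObservation]:
    """Collapse a SAM/BAM file into one observation per read.

    ``uniqueness_rule`` selects how single-locus alignment is recognised:
    ``mapq255`` uses the STAR convention of mapping quality 255 for unique
    alignments; ``nh_tag`` requires the ``NH`` (number of hits) tag to be 1.
    Regardless of the rule, a read with more than one mapped record is
    never unique.  Yields observations sorted by read id, so re-reading a
    file produces an identical stream.
    """
    if uniqueness_rule not in UNIQUENESS_RULES:
        raise ValueError(f"unknown uniqueness rule {uniqueness_rule!r}")

    # read_id -> list of (nm, chrom, start, end, strand, rule_unique)
    mapped: dict[str, list[tuple[int, str, int, int, str, bool]]] = {}
    seen: dict[str, None] = {}
    try:
        handle = pysam.AlignmentFile(str(alignment_file), check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse {alignment_file}: {exc}") from exc
    with handle:
        for rec in handle.fetch(until_eof=True):
            name = rec.query_name
            seen.setdefault(name, None)
            if rec.is_unmapped:
                continue
            try:
                nm = int(rec.get_tag("NM"))
            except KeyError:
                raise FormatError(
                    f"aligned record for read {name!r} in {alignment_file} "
                    "is missing the NM (edit distance) tag"
                ) from None
            if uniqueness_rule == "mapq255":
                rule_unique = rec.mapping_quality == 255
            else:
                try:
                    rule_unique = int(rec.get_tag("NH")) == 1
                except KeyError:
                    raise FormatError(
                        f"aligned record for read {name!r} in {alignment_file} "
                        "is missing the NH tag required by uniqueness rule "
                        "'nh_tag'"
                    ) from None
            mapped.setdefault(name, []).append(
                (
                    nm,
                    rec.reference_name or "",
                    rec.reference_start,
                    rec.reference_end or rec.reference_start + 1,
                    "-" if rec.is_reverse else "+",
                    rule_unique,
                )
            )

    for name in sorted(seen):
        records = mapped.get(name)
        if records is None:
            yield AlignmentObservation.unaligned(name, genome_id)
            continue
        records.sort(key=lambda r: (r[0], r[1], r[2], r[4]))
        nm, chrom, start, end, strand, rule_unique = records[0]
        unique = rule_unique if len(records) == 1 else False
        yield AlignmentObservation(
            read_id=name,
            genome_id=genome_id,
            aligned=True,
            unique=unique,
            mismatches=nm,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
        )


def collect_alignments(
    alignment_file: str | Path, genome_id: str, uniqueness_rule: str = "mapq255"
) -> dict[str, AlignmentObservation]:
    """Read a SAM/BAM into a read_id -> observation mapping."""
    return {
        obs.read_id: obs
        for obs in read_alignments(alignment_file, genome_id, uniqueness_rule)
    }


# ---------------------------------------------------------------------------
# Gene annotation (refFlat / GTF)
# ---------------------------------------------------------------------------

_REFFLAT_COLUMNS = 11


def _read_refflat(path: str | Path, genome_id: str) -> list[GeneModel]:
    per_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _REFFLAT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_REFFLAT_COLUMNS} tab-separated "
                    f"refFlat fields, got {len(fields)}"
                )
            gene_name, _tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                n_exons = int(fields[8])
                starts = [int(x) for x in fields[9].rstrip(",").split(",")]
                ends = [int(x) for x in fields[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(starts) != n_exons or len(ends) != n_exons:
                raise FormatError(
                    f"{path}:{lineno}: exonCount disagrees with exonStarts/Ends"
                )
            per_gene.setdefault(gene_name, []).extend(
                (chrom, s, e, strand) for s, e in zip(starts, ends)
            )
    return [
        GeneModel(gene_id=g, genome_id=genome_id, exon_union=merge_intervals(ivs))
        for g, ivs in sorted(per_gene.items())
    ]


def _read_gtf(path: str | Path, genome_id: str) -> list[GeneModel]:
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise FormatError(f"cannot parse GTF {path}: {exc}") from exc
    per_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    biotypes: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        names = feat.attributes.get("gene_id") or feat.attributes.get("gene_name")
        if not names:
            raise FormatError(
                f"{path}: exon at {feat.seqid}:{feat.start} lacks a gene_id"
            )
        gene = names[0]
        # GTF is 1-based closed; convert to 0-based half-open.
        per_gene.setdefault(gene, []).append(
            (feat.seqid, feat.start - 1, feat.end, feat.strand or "+")
        )
        hint = feat.attributes.get("gene_biotype") or feat.attributes.get("gene_type")
        if hint:
            biotypes[gene] = hint[0]
    return [
        GeneModel(
            gene_id=g,
            genome_id=genome_id,
            exon_union=merge_intervals(ivs),
            biotype_hint=biotypes.get(g, ""),
        )
        for g, ivs in sorted(per_gene.items())
    ]


def read_gene_models(
    annotation_file: str | Path, format: str = "refflat", genome_id: str = ""
) -> list[GeneModel]:
    """Parse gene models, merging transcript exons across isoforms per gene.

    ``format`` is ``refflat`` (0-based half-open, UCSC) or ``gtf`` (1-based
    closed, converted internally).  Returns models sorted by gene id.
    """
    if format == "refflat":
        return _read_refflat(annotation_file, genome_id)
    if format == "gtf":
        return _read_gtf(annotation_file, genome_id)
    raise ValueError(f"unknown annotation format {format!r}")


def write_refflat(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as refFlat, one transcript per gene (its exon union)."""
    with open(path, "w") as fh:
        for model in sorted(models, key=lambda m: m.gene_id):
            if not model.exon_union:
                continue
            chrom = model.exon_union[0][0]
            strand = model.exon_union[0][3]
            starts = [s for _, s, _, _ in model.exon_union]
            ends = [e for _, _, e, _ in model.exon_union]
            tx_start, tx_end = min(starts), max(ends)
            fh.write(
                "\t".join(
                    [
                        model.gene_id,
                        model.gene_id,
                        chrom,
                        strand,
                        str(tx_start),
                        str(tx_end),
                        str(tx_start),
                        str(tx_start),
                        str(len(starts)),
                        ",".join(map(str, starts)) + ",",
                        ",".join(map(str, ends)) + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV: header row, rows sorted by the first
    (identifier) column, NaN serialized as "NA"."""
    out = rows.sort_values(list(rows.columns[:1]), kind="mergesort")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False, comment=None
    )


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs with constant quality 'I'."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def file_sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
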