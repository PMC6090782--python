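"""Reading and writing the standard formats.

Covers free-form location strings, GTF in the UCSC-refGene and Ensembl
attribute dialects, circRNA-database tables (circBase-style TSV plus an
optional spliced-sequence FASTA), and random-access genome FASTA.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Union

import pyfaidx

from .models import (
    CircRecord,
    DataError,
    GenomicInterval,
    LocationParseError,
    STRAND_UNKNOWN,
    Transcript,
)

log = logging.getLogger(__name__)

DIALECT_AUTO = "auto"
DIALECT_UCSC = "ucsc_refgene"
DIALECT_ENSEMBL = "ensembl"


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the chr-prefixed UCSC style."""
    name = name.strip()
    if not name:
        raise LocationParseError("empty chromosome name")
    if name in ("MT", "M"):
        return "chrM"
    if not name.startswith("chr"):
        return "chr" + name
    return name


_CHROM_RE = re.compile(r"\s*([A-Za-z0-9_.]+)")
_NUM_RE = re.compile(r"\d+")


def parse_location(text: str) -> GenomicInterval:
    """Parse a display-style location into a :class:`GenomicInterval`.

    Accepts e.g. ``chr1:1735857-1,737,977``, ``chr2 100 200 +`` or an
    en-dash range. Chromosome, coordinates and optional strand may be
    separated by any non-numeric character except ``','``, which is treated
    as a thousands separator and stripped. Coordinates are read as 0-based
    start / exclusive end (the database display convention).
    """
    stripped = text.replace(",", "").strip()
    m = _CHROM_RE.match(stripped)
    if not m:
        raise LocationParseError(f"no chromosome token in {text!r}")
    chrom = normalize_chrom(m.group(1))
    rest = stripped[m.end():]
    nums = list(_NUM_RE.finditer(rest))
    if len(nums) < 2:
        raise LocationParseError(
            f"expected two coordinates after chromosome in {text!r}"
        )
    if len(nums) > 2:
        raise LocationParseError(
            f"too many numeric tokens in {text!r} "
            f"(offending token: {nums[2].group(0)!r})"
        )
    start, end = (int(n.group(0)) for n in nums)
    tail = rest[nums[1].end():]
    if "+" in tail:
        strand = "+"
    elif "-" in tail:
        strand = "-"
    else:
        strand = STRAND_UNKNOWN
    if start >= end:
        raise LocationParseError(
            f"start must be less than end in {text!r} (got {start} >= {end})"
        )
    return GenomicInterval(chrom, start, end, strand)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(
    path: Union[str, Path], dialect: str = DIALECT_AUTO
) -> list[Transcript]:
    """Parse a GTF into transcript models.

    Only ``exon`` features are used. The Ensembl dialect is recognized by
    its ``gene_name`` attribute (and bare chromosome names, normalized to
    chr-prefixed); the UCSC refGene dialect carries the gene symbol in
    ``gene_id``. Records lacking ``transcript_id`` are skipped with a
    warning; a file yielding zero transcripts is an error.
    """
    if dialect not in (DIALECT_AUTO, DIALECT_UCSC, DIALECT_ENSEMBL):
        raise ValueError(f"unknown GTF dialect {dialect!r}")

    rows: list[tuple[str, int, int, str, dict]] = []
    saw_gene_name = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                log.warning("%s:%d: short GTF line skipped", path, lineno)
                continue
            if fields[2] != "exon":
                continue
            attrs = _parse_attributes(fields[8])
            if "gene_name" in attrs:
                saw_gene_name = True
            if "transcript_id" not in attrs:
                log.warning(
                    "%s:%d: exon without transcript_id skipped", path, lineno
                )
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad coordinates") from exc
            rows.append((fields[0], start1 - 1, end1, fields[6], attrs))

    if dialect == DIALECT_AUTO:
        dialect = DIALECT_ENSEMBL if saw_gene_name else DIALECT_UCSC

    by_tx: dict[str, list[tuple[str, int, int, str, dict]]] = {}
    for row in rows:
        by_tx.setdefault(row[4]["transcript_id"], []).append(row)

    transcripts = []
    for tx_id in sorted(by_tx):
        exon_rows = by_tx[tx_id]
        chrom = normalize_chrom(exon_rows[0][0])
        strand = exon_rows[0][3]
        attrs = exon_rows[0][4]
        if dialect == DIALECT_ENSEMBL:
            symbol = attrs.get("gene_name", attrs.get("gene_id", ""))
        else:
            symbol = attrs.get("gene_id", "")
        transcripts.append(
            Transcript.from_exon_coords(
                tx_id,
                symbol,
                chrom,
                strand,
                [(s, e) for _, s, e, _, _ in exon_rows],
                source_dialect=dialect,
            )
        )
    if not transcripts:
        raise DataError(f"{path}: no transcripts parsed (no usable exon records)")
    return transcripts


CIRC_TABLE_COLUMNS = ("circ_id", "chrom", "start", "end", "strand", "gene_symbol")


def read_circ_table(
    path: Union[str, Path], fasta_path: Optional[Union[str, Path]] = None
) -> list[CircRecord]:
    """Read a circRNA database table, optionally attaching spliced sequences.

    The table is TSV with a header naming the columns
    ``circ_id, chrom, start, end, strand, gene_symbol`` (0-based half-open
    coordinates). The companion FASTA is keyed by circ_id; FASTA entries
    without a table row are dropped with a warning.
    """
    import csv

    records: dict[str, CircRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(CIRC_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            cid = row["circ_id"].strip()
            if cid in records:
                raise DataError(f"{path}: duplicate circ_id {cid!r}")
            strand = row["strand"].strip() or STRAND_UNKNOWN
            interval = GenomicInterval(
                normalize_chrom(row["chrom"]),
                int(row["start"]),
                int(row["end"]),
                strand if strand in "+-" else STRAND_UNKNOWN,
            )
            records[cid] = CircRecord(
                cid, interval, gene_symbol=row["gene_symbol"].strip() or None
            )
    if fasta_path is not None:
        for name, seq in read_fasta(fasta_path):
            if name in records:
                rec = records[name]
                if len(seq) > len(rec.interval):
                    raise DataError(
                        f"{fasta_path}: sequence for {name} longer than its "
                        "genomic span"
                    )
                rec.spliced_seq = seq.upper()
            else:
                log.warning(
                    "%s: FASTA id %s has no table row; sequence dropped",
                    fasta_path,
                    name,
                )
    return list(records.values())


def open_genome(path: Union[str, Path]) -> pyfaidx.Fasta:
    """Open a genome FASTA for random access (builds a .fai on first use)."""
    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch_genome_region(
    genome: Union[pyfaidx.Fasta, str, Path], interval: GenomicInterval
) -> str:
    """Return the uppercased plus-strand sequence of ``interval``.

    Strand handling (reverse complementing) is the caller's responsibility.
    """
    if not isinstance(genome, pyfaidx.Fasta):
        genome = open_genome(genome)
    if interval.chrom not in genome:
        raise DataError(f"chromosome {interval.chrom!r} not in genome FASTA")
    chrom_len = len(genome[interval.chrom])
    if interval.end > chrom_len:
        raise DataError(
            f"interval {interval} beyond end of {interval.chrom} ({chrom_len} bp)"
        )
    return str(genome[interval.chrom][interval.start:interval.end]).upper()


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a (small) FASTA file into (id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(
    records: Iterable[tuple[str, str]], path: Union[str, Path], wrap: int = 60
) -> None:
    """Write (id, sequence) pairs as FASTA, wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")
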