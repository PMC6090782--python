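"""Self-contained synthetic test data.

Generates a small genome, matching transcript annotations in both GTF
dialects, a circRNA database table with spliced-sequence FASTA, engineered
primer pairs, and a construction-time ground-truth file — everything the
other modules consume, with no biological downloads. Sequences are uniform
random ACGT; realism is limited to coordinate structure (exons, introns,
strands, backsplice classes), which is what the toolkit's logic acts on.

circRNA classes generated:

* ``both_exact`` — both boundaries on exon edges (score 6),
* ``one_inexact`` — end strictly inside an exon (score 5),
* ``intronic_boundary`` — start inside an intron, end exact (score 3;
  exercises the intron-retention rule),
* ``intron_only`` — entirely inside one intron (score 0; spliced equals
  genomic),
* ``shared_sequence_cluster`` — several database records sharing one
  spliced sequence, the cross-amplification scenario for divergent
  primers.

Every class is produced on a plus- and a minus-strand gene (except the
cluster, generated once). Ground truth (winner transcript, score,
segments, spliced sequence) is written by explicit construction, not by
running the annotation pipeline, so the verify step is a genuine
round-trip.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

from Bio.Seq import reverse_complement

from . import annotation as _annotation
from . import io as _io
from . import splicing as _splicing
from .models import CircRecord, DataError, GenomicInterval, Transcript

ALL_CIRC_CLASSES = (
    "both_exact",
    "one_inexact",
    "intronic_boundary",
    "intron_only",
    "shared_sequence_cluster",
)

MANIFEST_NAME = "manifest.json"


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genes: int = 6
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (60, 180)
    intron_len: tuple[int, int] = (80, 300)
    intergenic_len: tuple[int, int] = (200, 400)
    circ_classes: tuple[str, ...] = ALL_CIRC_CLASSES
    cluster_size: int = 4
    genes_per_chrom: int = 3

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered")
        unknown = set(self.circ_classes) - set(ALL_CIRC_CLASSES)
        if unknown:
            raise ValueError(f"unknown circ classes {sorted(unknown)}")
        if "shared_sequence_cluster" in self.circ_classes and self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")
        if self.exons_per_gene[0] < 3:
            raise ValueError("need at least 3 exons per gene for all circ classes")


@dataclass
class _Gene:
    transcript: Transcript
    exon_coords: list[tuple[int, int]]


def _layout_genes(spec: FixtureSpec, rng: random.Random) -> tuple[list[_Gene], dict[str, int]]:
    genes: list[_Gene] = []
    cursors: dict[str, int] = {}
    for gi in range(spec.n_genes):
        chrom = f"chrT{gi // spec.genes_per_chrom + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        cursor = cursors.get(chrom, 0) + rng.randint(*spec.intergenic_len)
        n_ex = rng.randint(*spec.exons_per_gene)
        coords = []
        pos = cursor
        for ei in range(n_ex):
            if ei:
                pos += rng.randint(*spec.intron_len)
            elen = rng.randint(*spec.exon_len)
            coords.append((pos, pos + elen))
            pos = pos + elen
        cursors[chrom] = pos
        genes.append(
            _Gene(
                Transcript.from_exon_coords(
                    f"TX{gi + 1:03d}", f"GENE{gi + 1:03d}", chrom, strand, coords
                ),
                coords,
            )
        )
    return genes, cursors


def _truth_sequence(
    chrom_seqs: dict[str, str], segments: list[tuple[int, int]], chrom: str, strand: str
) -> str:
    seq = "".join(chrom_seqs[chrom][a:b] for a, b in segments)
    return reverse_complement(seq) if strand == "-" else seq


def make_fixture(spec: FixtureSpec, outdir: Union[str, Path]) -> dict:
    """Write a complete fixture tree; returns the manifest (also on disk).

    Deterministic: the same spec (including seed) yields byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    genes, cursors = _layout_genes(spec, rng)
    chrom_seqs = {
        chrom: "".join(rng.choice("ACGT") for _ in range(cursors[chrom] + 500))
        for chrom in sorted(cursors)
    }

    circs: list[dict] = []  # table rows
    truth: dict[str, dict] = {}
    fasta_records: list[tuple[str, str]] = []
    counter = 0

    def add_circ(cls: str, gene: _Gene, start: int, end: int,
                 segments: list[tuple[int, int]], score: int,
                 circ_id: str | None = None) -> str:
        nonlocal counter
        if circ_id is None:
            counter += 1
            circ_id = f"fix_circ_{counter:04d}"
        tx = gene.transcript
        seq = _truth_sequence(chrom_seqs, segments, tx.chrom, tx.strand)
        circs.append(
            {
                "circ_id": circ_id,
                "chrom": tx.chrom,
                "start": start,
                "end": end,
                "strand": tx.strand,
                "gene_symbol": tx.gene_symbol,
            }
        )
        fasta_records.append((circ_id, seq))
        truth[circ_id] = {
            "class": cls,
            "transcript_id": tx.transcript_id,
            "score": score,
            "segments": [list(s) for s in segments],
            "spliced_seq": seq,
            "strand": tx.strand,
        }
        return circ_id

    plus_genes = [g for g in genes if g.transcript.strand == "+"]
    minus_genes = [g for g in genes if g.transcript.strand == "-"]

    for cls in spec.circ_classes:
        if cls == "shared_sequence_cluster":
            continue
        for gene in (plus_genes[0], minus_genes[0]) if minus_genes else (plus_genes[0],):
            ex = gene.exon_coords
            if cls == "both_exact":
                j = min(2, len(ex) - 1)
                start, end = ex[0][0], ex[j][1]
                add_circ(cls, gene, start, end, ex[: j + 1], 6)
            elif cls == "one_inexact":
                j = min(2, len(ex) - 1)
                start = ex[0][0]
                cut = (ex[j][0] + ex[j][1]) // 2  # strictly inside exon j
                segments = ex[:j] + [(ex[j][0], cut)]
                add_circ(cls, gene, start, cut, segments, 5)
            elif cls == "intronic_boundary":
                # start mid-intron 0, end on exon 2's right edge
                start = (ex[0][1] + ex[1][0]) // 2
                end = ex[2][1]
                segments = [(start, ex[1][0]), ex[1], ex[2]]
                add_circ(cls, gene, start, end, segments, 3)
            elif cls == "intron_only":
                start, end = ex[1][1] + 10, ex[2][0] - 10
                add_circ(cls, gene, start, end, [(start, end)], 0)

    cluster_seq = None
    if "shared_sequence_cluster" in spec.circ_classes:
        gene = plus_genes[-1]
        ex = gene.exon_coords
        start, end = ex[0][0], ex[-1][1]
        for k in range(spec.cluster_size):
            add_circ(
                "shared_sequence_cluster", gene, start, end, list(ex), 6,
                circ_id=f"fix_circ_cl{k + 1:02d}",
            )
        cluster_seq = _truth_sequence(chrom_seqs, list(ex), gene.transcript.chrom,
                                      gene.transcript.strand)

    # --- primers engineered on the cluster sequence (or first circ) ---
    primer_rows: list[tuple[str, str, str]] = []
    s = cluster_seq or truth[circs[0]["circ_id"]]["spliced_seq"]
    length = len(s)
    plen = 20
    if length >= 6 * plen:
        rc = reverse_complement
        # convergent: both interior, reverse downstream of forward
        primer_rows.append(("convergent", s[10:10 + plen], rc(s[90:90 + plen])))
        # divergent: product runs through the seam
        primer_rows.append(
            ("divergent", s[length - 2 * plen:length - plen], rc(s[20:20 + plen]))
        )
        # forward primers crossing the seam with n 3'-bases beyond it
        for n in (4, 5):
            fwd = s[length - (plen - n):] + s[:n]
            primer_rows.append((f"junction_f{n}", fwd, rc(s[60:60 + plen])))

    # --- write everything ---
    files = {
        "genome": "genome.fa",
        "gtf_ucsc": "annotation.ucsc.gtf",
        "gtf_ensembl": "annotation.ensembl.gtf",
        "circ_table": "circs.tsv",
        "circ_fasta": "circs.fa",
        "primers": "primers.tsv",
        "ground_truth": "ground_truth.json",
    }
    _io.write_fasta(sorted(chrom_seqs.items()), outdir / files["genome"])
    _write_gtf(genes, outdir / files["gtf_ucsc"], "ucsc_refgene")
    _write_gtf(genes, outdir / files["gtf_ensembl"], "ensembl")
    with open(outdir / files["circ_table"], "w") as fh:
        fh.write("\t".join(_io.CIRC_TABLE_COLUMNS) + "\n")
        for row in circs:
            fh.write("\t".join(str(row[c]) for c in _io.CIRC_TABLE_COLUMNS) + "\n")
    _io.write_fasta(fasta_records, outdir / files["circ_fasta"])
    with open(outdir / files["primers"], "w") as fh:
        fh.write("name\tforward\treverse\n")
        for name, fwd, rev in primer_rows:
            fh.write(f"{name}\t{fwd}\t{rev}\n")
    with open(outdir / files["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {"spec": asdict(spec), "files": files}
    with open(outdir / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_gtf(genes: list[_Gene], path: Path, dialect: str) -> None:
    with open(path, "w") as fh:
        for gi, gene in enumerate(genes):
            tx = gene.transcript
            chrom = tx.chrom if dialect == "ucsc_refgene" else tx.chrom[3:]
            for s, e in gene.exon_coords:
                if dialect == "ucsc_refgene":
                    attrs = (
                        f'gene_id "{tx.gene_symbol}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    source = "refGene"
                else:
                    attrs = (
                        f'gene_id "FIXG{gi + 1:011d}"; '
                        f'transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{tx.gene_symbol}"; '
                        f'gene_biotype "protein_coding";'
                    )
                    source = "ensembl"
                fh.write(
                    f"{chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


@dataclass
class FixtureReport:
    ok: bool
    n_checked: int
    failures: list[dict] = field(default_factory=list)


def verify_fixture(manifest_path: Union[str, Path]) -> FixtureReport:
    """Re-run annotation and splicing on a fixture against its ground truth.

    Compares winner transcript, score, retained segments and spliced
    sequence field-by-field; the first divergent field of each circRNA is
    reported.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent
    files = manifest["files"]

    genome = _io.open_genome(root / files["genome"])
    transcripts = _io.read_gtf(root / files["gtf_ucsc"])
    circs = _io.read_circ_table(root / files["circ_table"], root / files["circ_fasta"])
    with open(root / files["ground_truth"]) as fh:
        truth = json.load(fh)

    failures = []

    def fail(circ_id: str, fld: str, expected, got) -> None:
        failures.append(
            {"circ_id": circ_id, "field": fld, "expected": expected, "got": got}
        )

    for circ in circs:
        expected = truth.get(circ.circ_id)
        if expected is None:
            fail(circ.circ_id, "ground_truth", "record", None)
            continue
        try:
            ann = _annotation.annotate(circ, transcripts)
            if ann is None:
                fail(circ.circ_id, "transcript_id", expected["transcript_id"], None)
                continue
            if ann.transcript.transcript_id != expected["transcript_id"]:
                fail(circ.circ_id, "transcript_id", expected["transcript_id"],
                     ann.transcript.transcript_id)
                continue
            if ann.score != expected["score"]:
                fail(circ.circ_id, "score", expected["score"], ann.score)
                continue
            got_segments = [[s.start, s.end] for s in ann.segments]
            if got_segments != expected["segments"]:
                fail(circ.circ_id, "segments", expected["segments"], got_segments)
                continue
            spliced = _splicing.spliced_sequence(circ, ann, genome)
            if spliced.sequence != expected["spliced_seq"]:
                fail(circ.circ_id, "spliced_seq", expected["spliced_seq"],
                     spliced.sequence)
        except DataError as exc:
            fail(circ.circ_id, "error", None, str(exc))
    return FixtureReport(ok=not failures, n_checked=len(circs), failures=failures)
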