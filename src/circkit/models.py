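"""Shared domain types.

All genomic coordinates are internal convention: 0-based, half-open
``[start, end)``, chromosome names ``chr``-prefixed. GTF input (1-based
inclusive) is converted on read; circRNA-database tables and display-style
locations are treated as BED-like (0-based start, exclusive end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_UNKNOWN = "."

_VALID_STRANDS = frozenset((STRAND_PLUS, STRAND_MINUS, STRAND_UNKNOWN))


class CircKitError(Exception):
    """Base class for toolkit errors."""


class LocationParseError(CircKitError):
    """A free-form location string could not be parsed."""


class DataError(CircKitError):
    """Input data violates a format or content contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Containment on coordinates only; strand is not compared."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and self.end >= other.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        s = f"{self.chrom}:{self.start}-{self.end}"
        if self.strand != STRAND_UNKNOWN:
            s += f"({self.strand})"
        return s


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    index: int  # ordinal in transcription order (reversed on minus strand)


@dataclass(frozen=True)
class Transcript:
    """One transcript model: ordered exons plus identifiers.

    ``exons`` are sorted by genomic start; ``Exon.index`` carries the
    transcription-order ordinal so minus-strand transcripts keep both views.
    """

    transcript_id: str
    gene_symbol: str
    interval: GenomicInterval
    exons: tuple[Exon, ...]
    source_dialect: str = "ucsc_refgene"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        starts = [e.interval.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError(
                f"transcript {self.transcript_id}: exons not sorted by start"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.interval.end > b.interval.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        for e in self.exons:
            if (
                e.interval.chrom != self.interval.chrom
                or e.interval.strand != self.interval.strand
            ):
                raise ValueError(
                    f"transcript {self.transcript_id}: exon chrom/strand mismatch"
                )
        if (
            self.interval.start != self.exons[0].interval.start
            or self.interval.end != self.exons[-1].interval.end
        ):
            raise ValueError(
                f"transcript {self.transcript_id}: span does not match exons"
            )

    @classmethod
    def from_exon_coords(
        cls,
        transcript_id: str,
        gene_symbol: str,
        chrom: str,
        strand: str,
        exon_coords: list[tuple[int, int]],
        source_dialect: str = "ucsc_refgene",
    ) -> "Transcript":
        coords = sorted(exon_coords)
        n = len(coords)
        exons = tuple(
            Exon(
                GenomicInterval(chrom, s, e, strand),
                index=i if strand != STRAND_MINUS else n - 1 - i,
            )
            for i, (s, e) in enumerate(coords)
        )
        span = GenomicInterval(chrom, coords[0][0], coords[-1][1], strand)
        return cls(transcript_id, gene_symbol, span, exons, source_dialect)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class CircRecord:
    """One circRNA: identifier, backsplice span, optional database sequence."""

    circ_id: str
    interval: GenomicInterval
    gene_symbol: Optional[str] = None
    spliced_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.spliced_seq is not None and len(self.spliced_seq) > len(self.interval):
            raise ValueError(
                f"{self.circ_id or self.interval}: spliced sequence longer than "
                "genomic span"
            )


# --- annotation ---

KIND_EXACT = "exact_exon_boundary"
KIND_INEXACT = "on_exon_inexact"
KIND_INTRONIC = "intronic_or_other"

_KIND_POINTS = {KIND_EXACT: 3, KIND_INEXACT: 2, KIND_INTRONIC: 0}


@dataclass(frozen=True)
class BoundaryMatch:
    """How one circRNA boundary relates to a transcript's exon structure."""

    kind: str
    points: int
    exon_index: Optional[int] = None

    def __post_init__(self) -> None:
        if _KIND_POINTS.get(self.kind) != self.points:
            raise ValueError(f"kind {self.kind!r} incompatible with {self.points} points")


@dataclass
class CircAnnotation:
    circ: CircRecord
    transcript: Transcript
    start_match: BoundaryMatch
    end_match: BoundaryMatch
    score: int
    segments: tuple[GenomicInterval, ...]
    candidates_considered: int

    def __post_init__(self) -> None:
        if self.score != self.start_match.points + self.end_match.points:
            raise ValueError("score must equal the sum of boundary points")


# --- splicing ---

ORIENT_TRANSCRIPT = "transcript"
ORIENT_GENOMIC = "genomic"


@dataclass
class SplicedSequence:
    circ_id: str
    sequence: str
    segments: tuple[GenomicInterval, ...]
    orientation: str

    def __post_init__(self) -> None:
        if len(self.sequence) != sum(len(s) for s in self.segments):
            raise ValueError("sequence length must equal total segment length")


# --- templates ---

MODE_DIVERGENT = "divergent"
MODE_JUNCTION = "junction_spanning"


@dataclass
class TemplateRecord:
    circ_id: str
    template_seq: str
    junction_pos: int  # offset of the first base after the backsplice seam
    mode: str
    constraints: dict

    def __post_init__(self) -> None:
        if not (0 < self.junction_pos < len(self.template_seq)):
            raise ValueError("junction_pos must be interior to the template")
        if self.mode not in (MODE_DIVERGENT, MODE_JUNCTION):
            raise ValueError(f"unknown template mode {self.mode!r}")


# --- specificity ---

PRIMER_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    name: Optional[str] = None
    min_length: int = 10

    def __post_init__(self) -> None:
        for role, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if len(seq) < self.min_length:
                raise ValueError(
                    f"{role} primer shorter than {self.min_length} nt"
                )
            bad = set(seq.upper()) - PRIMER_ALPHABET
            if bad:
                raise ValueError(
                    f"{role} primer contains invalid characters {sorted(bad)}"
                )
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class PrimerHit:
    """One binding site of one primer on one circular target.

    ``start`` is the circle coordinate of the primer's 5'-most matched base
    (for antisense hits this is the highest coordinate of the match).
    ``match_start`` is the lowest circle coordinate of the matched window.
    ``three_prime_junction_overlap`` counts matched bases on the primer's
    3' side of the backsplice seam when the hit crosses it, else 0.
    """

    target_id: str
    primer_role: str  # forward | reverse
    strand_on_target: str  # sense | antisense
    start: int
    three_prime_junction_overlap: int
    match_start: int
    length: int

    @property
    def crosses_junction(self) -> bool:
        return self.three_prime_junction_overlap > 0


@dataclass(frozen=True)
class AmpliconPrediction:
    target_id: str
    product_length: int
    f0r_code: str
    parental_gene_warning: bool
    fwd_hit: PrimerHit
    rev_hit: PrimerHit
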