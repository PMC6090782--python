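"""Spliced- and genomic-sequence reconstruction for circRNAs.

A circRNA's spliced sequence is its genomic span with introns removed,
guided by the parental transcript's exon structure, with one exception:
a boundary that falls inside an intron keeps the intronic run between
that boundary and the nearest retained exon (backsplicing at an intronic
position carries that intron fragment into the circle).
"""

from __future__ import annotations

from typing import Optional, Union

from Bio.Seq import reverse_complement

from . import io as _io
from .models import (
    CircAnnotation,
    CircRecord,
    CircKitError,
    GenomicInterval,
    ORIENT_GENOMIC,
    ORIENT_TRANSCRIPT,
    STRAND_MINUS,
    STRAND_PLUS,
    SplicedSequence,
    Transcript,
)


def segment_interval(
    interval: GenomicInterval, transcript: Transcript
) -> tuple[GenomicInterval, ...]:
    """Split a circRNA span into retained segments, in genomic order.

    Segments are the intersections of the span with the transcript's exons;
    an intronic start boundary additionally retains the run from the start
    to the first intersecting exon, an intronic end boundary the run from
    the last intersecting exon to the end. A span intersecting no exon at
    all (entirely intra-intronic) is retained whole.
    """
    strand = transcript.strand
    chrom = interval.chrom
    clipped = []
    for exon in transcript.exons:
        s = max(exon.interval.start, interval.start)
        e = min(exon.interval.end, interval.end)
        if s < e:
            clipped.append((s, e))
    if not clipped:
        return (GenomicInterval(chrom, interval.start, interval.end, strand),)
    segments = []
    if interval.start < clipped[0][0]:
        segments.append((interval.start, clipped[0][0]))
    segments.extend(clipped)
    if interval.end > clipped[-1][1]:
        segments.append((clipped[-1][1], interval.end))
    return tuple(GenomicInterval(chrom, s, e, strand) for s, e in segments)


def segment_circ(
    circ: CircRecord, annotation: CircAnnotation
) -> tuple[GenomicInterval, ...]:
    """Retained segments of ``circ`` under its annotated parental transcript."""
    return segment_interval(circ.interval, annotation.transcript)


def spliced_sequence(
    circ: CircRecord,
    annotation: Optional[CircAnnotation],
    genome,
) -> SplicedSequence:
    """Reconstruct the spliced (mature) sequence of an annotated circRNA.

    Segments are fetched plus-strand and concatenated in genomic order; for
    minus-strand parental transcripts the concatenation is reverse
    complemented, so the result always reads in transcript orientation.
    """
    if annotation is None:
        raise CircKitError(
            f"{circ.circ_id or circ.interval}: no parental transcript; "
            "use genomic_sequence for an unannotated circRNA"
        )
    segments = annotation.segments or segment_circ(circ, annotation)
    seq = "".join(_io.fetch_genome_region(genome, s) for s in segments)
    if annotation.transcript.strand == STRAND_MINUS:
        seq = reverse_complement(seq)
    return SplicedSequence(
        circ_id=circ.circ_id,
        sequence=seq,
        segments=tuple(segments),
        orientation=ORIENT_TRANSCRIPT,
    )


def genomic_sequence(circ: CircRecord, genome) -> SplicedSequence:
    """The unspliced genomic sequence of the circRNA span.

    Reverse complemented when the record's strand is '-'; with unknown
    strand the plus-strand sequence is returned and flagged as genomic
    orientation.
    """
    seq = _io.fetch_genome_region(genome, circ.interval)
    strand = circ.interval.strand
    if strand == STRAND_MINUS:
        seq = reverse_complement(seq)
    orientation = ORIENT_TRANSCRIPT if strand in (STRAND_PLUS, STRAND_MINUS) else ORIENT_GENOMIC
    return SplicedSequence(
        circ_id=circ.circ_id,
        sequence=seq,
        segments=(circ.interval,),
        orientation=orientation,
    )


def sequence_discrepancy(
    circ: CircRecord, reconstructed: SplicedSequence
) -> Optional[dict]:
    """Compare a database-provided sequence with the reconstruction.

    Returns a warning record when they differ (neither is overridden —
    discrepancies should be resolved experimentally), else None.
    """
    if circ.spliced_seq is None:
        return None
    db = circ.spliced_seq.upper()
    if db == reconstructed.sequence.upper():
        return None
    return {
        "circ_id": circ.circ_id,
        "db_length": len(db),
        "reconstructed_length": len(reconstructed.sequence),
        "identical_length": len(db) == len(reconstructed.sequence),
        "note": (
            "database sequence differs from reconstruction; "
            "confirm experimentally"
        ),
    }
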