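"""Parental-transcript annotation of circRNAs by boundary scoring.

Candidate transcripts are those whose span contains the circRNA's span.
Each circRNA boundary is scored against a candidate's exon structure:

* 3 points — the boundary coincides exactly with an exon edge of the
  matching sense (circ start on an exon start, circ end on an exon end);
* 2 points — the boundary lies on an exon but not on that edge;
* 0 points — otherwise (intronic).

The candidate with the highest total (max 6) is the parental transcript;
ties go to the longest genomic span, then the lexicographically smallest
transcript id so the result is deterministic.

Exon edges are compared in genomic space regardless of strand: backsplice
donor/acceptor sites sit at genomic exon boundaries and database locations
are genomic, so minus-strand scoring stays symmetric with the display
convention.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .models import (
    BoundaryMatch,
    CircAnnotation,
    CircKitError,
    CircRecord,
    KIND_EXACT,
    KIND_INEXACT,
    KIND_INTRONIC,
    STRAND_UNKNOWN,
    Transcript,
)
from .splicing import segment_interval


def candidate_transcripts(
    circ: CircRecord, transcripts: Iterable[Transcript]
) -> list[Transcript]:
    """Transcripts whose genomic span contains the circRNA span.

    When the circRNA's strand is known only same-strand transcripts
    qualify; with unknown strand both strands are considered.
    """
    circ_strand = circ.interval.strand
    out = []
    for t in transcripts:
        if not t.interval.contains(circ.interval):
            continue
        if circ_strand != STRAND_UNKNOWN and t.strand != circ_strand:
            continue
        out.append(t)
    return out


def score_boundary(
    position: int, which: str, transcript: Transcript
) -> BoundaryMatch:
    """Score one circRNA boundary against one transcript.

    ``which='start'`` scores a 0-based start coordinate, ``which='end'`` a
    half-open (exclusive) end coordinate. "On an exon" means the boundary
    base (the base at ``position`` for a start, the base at ``position-1``
    for an end) lies inside an exon.
    """
    if which not in ("start", "end"):
        raise ValueError("which must be 'start' or 'end'")
    span = transcript.interval
    if not (span.start <= position <= span.end):
        raise CircKitError(
            f"boundary {position} outside span of {transcript.transcript_id}"
        )
    for exon in transcript.exons:
        s, e = exon.interval.start, exon.interval.end
        if which == "start" and position == s:
            return BoundaryMatch(KIND_EXACT, 3, exon.index)
        if which == "end" and position == e:
            return BoundaryMatch(KIND_EXACT, 3, exon.index)
    for exon in transcript.exons:
        s, e = exon.interval.start, exon.interval.end
        if s < position < e:
            return BoundaryMatch(KIND_INEXACT, 2, exon.index)
    return BoundaryMatch(KIND_INTRONIC, 0, None)


def score_transcript(circ: CircRecord, transcript: Transcript) -> int:
    """Total boundary score of one candidate (0, 2, 3, 4, 5 or 6)."""
    start = score_boundary(circ.interval.start, "start", transcript)
    end = score_boundary(circ.interval.end, "end", transcript)
    return start.points + end.points


def annotate(
    circ: CircRecord, transcripts: Iterable[Transcript]
) -> Optional[CircAnnotation]:
    """Pick the parental transcript of a circRNA, or None when no candidate.

    The winner maximizes the boundary score; ties are broken by longest
    span, then smallest transcript id.
    """
    candidates = candidate_transcripts(circ, transcripts)
    if not candidates:
        return None

    def sort_key(t: Transcript):
        return (-score_transcript(circ, t), -len(t.interval), t.transcript_id)

    winner = min(candidates, key=sort_key)
    start_match = score_boundary(circ.interval.start, "start", winner)
    end_match = score_boundary(circ.interval.end, "end", winner)
    return CircAnnotation(
        circ=circ,
        transcript=winner,
        start_match=start_match,
        end_match=end_match,
        score=start_match.points + end_match.points,
        segments=segment_interval(circ.interval, winner),
        candidates_considered=len(candidates),
    )


ANNOTATION_REPORT_COLUMNS = (
    "circ_id",
    "location",
    "transcript_id",
    "gene_symbol",
    "score",
    "start_match",
    "end_match",
    "n_candidates",
)


def annotation_report_rows(
    annotations: Iterable[tuple[CircRecord, Optional[CircAnnotation]]],
) -> list[dict]:
    """Flatten (circ, annotation) pairs into report rows (TSV-ready)."""
    rows = []
    for circ, ann in annotations:
        if ann is None:
            rows.append(
                {
                    "circ_id": circ.circ_id,
                    "location": str(circ.interval),
                    "transcript_id": "",
                    "gene_symbol": circ.gene_symbol or "",
                    "score": "",
                    "start_match": "",
                    "end_match": "",
                    "n_candidates": 0,
                }
            )
        else:
            rows.append(
                {
                    "circ_id": circ.circ_id,
                    "location": str(circ.interval),
                    "transcript_id": ann.transcript.transcript_id,
                    "gene_symbol": ann.transcript.gene_symbol,
                    "score": ann.score,
                    "start_match": ann.start_match.kind,
                    "end_match": ann.end_match.kind,
                    "n_candidates": ann.candidates_considered,
                }
            )
    return rows
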