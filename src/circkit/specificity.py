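"""In-silico PCR on circular templates.

A circRNA database sequence is treated as a circle whose backsplice seam
lies between its last and first base (sequences are assumed to start at
the backsplice acceptor). Primer binding sites — including sites crossing
the seam — are found on both strands, every sense-forward/antisense-reverse
hit pairing is turned into a predicted product, and each prediction gets a
geometry code:

* ``"1"``  — convergent pair (product does not cover the seam; such a pair
  also amplifies the linear parental transcript),
* ``"0"``  — divergent pair (product covers the seam; circle-specific),
* ``"F<n>"`` / ``"R<n>"`` — the forward / reverse primer itself crosses the
  seam with n bases on its 3' side beyond it.

A junction-crossing primer with >= 5 bases (configurable) of its 3' end past
the seam behaves like a linear-transcript primer and raises the
parental-gene warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Seq import reverse_complement

from .models import AmpliconPrediction, CircRecord, PrimerHit, PrimerPair

log = logging.getLogger(__name__)

STRAND_SENSE = "sense"
STRAND_ANTISENSE = "antisense"
DEFAULT_WARNING_THRESHOLD = 5


def _match_positions(
    query: str, text: str, n_positions: int, max_mismatches: int, exact_3p: int
) -> list[int]:
    """Start positions (< n_positions) where query matches text.

    Exact substring search when possible; a scanning matcher handles
    N-wildcards and mismatch budgets (the 3'-terminal ``exact_3p`` bases
    must always match exactly; N in the query matches any base).
    """
    qlen = len(query)
    if max_mismatches == 0 and "N" not in query:
        positions = []
        p = text.find(query)
        while p != -1 and p < n_positions:
            positions.append(p)
            p = text.find(query, p + 1)
        return positions
    positions = []
    for p in range(n_positions):
        window = text[p:p + qlen]
        if len(window) < qlen:
            break
        mismatches = 0
        ok = True
        for i, (q, t) in enumerate(zip(query, window)):
            if q == "N" or q == t:
                continue
            if i >= qlen - exact_3p:
                ok = False
                break
            mismatches += 1
            if mismatches > max_mismatches:
                ok = False
                break
        if ok:
            positions.append(p)
    return positions


def find_hits(
    primer: str,
    target: str,
    target_id: str = "",
    role: str = "primer",
    max_mismatches: int = 0,
) -> list[PrimerHit]:
    """All binding sites of one primer on one circular target.

    The search runs over ``target + target[:len(primer)-1]`` so sites
    crossing the seam are found; positions are circle coordinates. For a
    seam-crossing site the 3'-junction overlap counts the matched bases on
    the primer's 3' side of the seam: for a sense hit those lie after the
    seam, for an antisense hit before it (the primer extends toward lower
    coordinates).
    """
    primer = primer.upper()
    target = target.upper()
    plen, length = len(primer), len(target)
    if plen > length:
        log.warning(
            "%s %s longer than target (%d > %d nt); no hits",
            role, primer, plen, length,
        )
        return []
    doubled = target + target[:plen - 1]
    hits = []
    for strand, query in (
        (STRAND_SENSE, primer),
        (STRAND_ANTISENSE, reverse_complement(primer)),
    ):
        # a query matching the whole circle would hit every rotation once
        for p in _match_positions(query, doubled, length, max_mismatches, 5):
            crossing = p + plen > length
            if strand == STRAND_SENSE:
                start = p
                overlap = p + plen - length if crossing else 0
            else:
                start = (p + plen - 1) % length
                overlap = length - p if crossing else 0
            hits.append(
                PrimerHit(
                    target_id=target_id,
                    primer_role=role,
                    strand_on_target=strand,
                    start=start,
                    three_prime_junction_overlap=overlap,
                    match_start=p % length,
                    length=plen,
                )
            )
    return hits


def predict_amplicons(
    pair: PrimerPair,
    target: CircRecord,
    warning_threshold: int = DEFAULT_WARNING_THRESHOLD,
    max_mismatches: int = 0,
) -> list[AmpliconPrediction]:
    """Predicted single-lap products of a primer pair on one circular target.

    Every pairing of a sense forward hit with an antisense reverse hit
    yields a product whose length is the circular walk from the forward
    primer's 5' base to the reverse primer's 5' base, both included, in the
    forward extension direction.
    """
    if target.spliced_seq is None:
        log.warning("%s has no sequence; target skipped", target.circ_id)
        return []
    seq = target.spliced_seq.upper()
    length = len(seq)
    fwd_hits = [
        h
        for h in find_hits(
            pair.forward, seq, target.circ_id, "forward", max_mismatches
        )
        if h.strand_on_target == STRAND_SENSE
    ]
    rev_hits = [
        h
        for h in find_hits(
            pair.reverse, seq, target.circ_id, "reverse", max_mismatches
        )
        if h.strand_on_target == STRAND_ANTISENSE
    ]
    predictions = []
    for fh in fwd_hits:
        for rh in rev_hits:
            product_length = (rh.start - fh.start) % length + 1
            covers_seam = fh.start + product_length > length
            if fh.three_prime_junction_overlap > 0:
                code = f"F{fh.three_prime_junction_overlap}"
            elif rh.three_prime_junction_overlap > 0:
                code = f"R{rh.three_prime_junction_overlap}"
            elif covers_seam:
                code = "0"
            else:
                code = "1"
            warning = (
                fh.three_prime_junction_overlap >= warning_threshold
                or rh.three_prime_junction_overlap >= warning_threshold
            )
            predictions.append(
                AmpliconPrediction(
                    target_id=target.circ_id,
                    product_length=product_length,
                    f0r_code=code,
                    parental_gene_warning=warning,
                    fwd_hit=fh,
                    rev_hit=rh,
                )
            )
    return predictions


@dataclass
class SpecificityReport:
    """All predicted products of one primer pair across a circRNA database."""

    pair: PrimerPair
    predictions: list[AmpliconPrediction] = field(default_factory=list)
    skipped_targets: list[str] = field(default_factory=list)

    @property
    def n_targets_amplified(self) -> int:
        return len({p.target_id for p in self.predictions})

    def to_dataframe(self, database: Optional[Sequence[CircRecord]] = None) -> pd.DataFrame:
        symbols = (
            {c.circ_id: c.gene_symbol or "" for c in database} if database else {}
        )
        rows = [
            {
                "target_id": p.target_id,
                "gene_symbol": symbols.get(p.target_id, ""),
                "product_length": p.product_length,
                "f0r_code": p.f0r_code,
                "parental_gene_warning": p.parental_gene_warning,
                "fwd_pos": p.fwd_hit.start,
                "rev_pos": p.rev_hit.start,
            }
            for p in self.predictions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "target_id",
                "gene_symbol",
                "product_length",
                "f0r_code",
                "parental_gene_warning",
                "fwd_pos",
                "rev_pos",
            ],
        )


def check_specificity(
    pair: PrimerPair,
    database: Iterable[CircRecord],
    genome=None,
    transcripts=None,
    warning_threshold: int = DEFAULT_WARNING_THRESHOLD,
    max_mismatches: int = 0,
) -> SpecificityReport:
    """Run the pair against every database target with a usable sequence.

    Targets without a stored spliced sequence are reconstructed through
    annotation when a genome and transcript set are supplied, otherwise
    skipped. Predictions are sorted by product length, then target id.
    """
    from . import annotation as _annotation
    from . import splicing as _splicing

    report = SpecificityReport(pair=pair)
    for circ in database:
        target = circ
        if circ.spliced_seq is None:
            if genome is not None and transcripts is not None:
                ann = _annotation.annotate(circ, transcripts)
                if ann is None:
                    report.skipped_targets.append(circ.circ_id)
                    continue
                seq = _splicing.spliced_sequence(circ, ann, genome).sequence
                target = CircRecord(
                    circ.circ_id, circ.interval, circ.gene_symbol, seq
                )
            else:
                report.skipped_targets.append(circ.circ_id)
                continue
        report.predictions.extend(
            predict_amplicons(pair, target, warning_threshold, max_mismatches)
        )
    report.predictions.sort(key=lambda p: (p.product_length, p.target_id))
    return report


def slice_circular(seq: str, start: int, length: int) -> str:
    """Slice a circular sequence, wrapping past the seam when needed."""
    n = len(seq)
    if length > n:
        raise ValueError("slice longer than circle")
    start %= n
    end = start + length
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def locate_primers_figure_data(
    pair: PrimerPair,
    target: CircRecord,
    warning_threshold: int = DEFAULT_WARNING_THRESHOLD,
) -> dict:
    """Circle-coordinate spans of each primer plus the seam, for plotting.

    Returns a JSON-serializable record; no graphics are rendered here.
    """
    if target.spliced_seq is None:
        raise ValueError(f"{target.circ_id}: target carries no sequence")
    seq = target.spliced_seq.upper()
    spans = []
    for role, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
        for h in find_hits(primer, seq, target.circ_id, role):
            spans.append(
                {
                    "role": role,
                    "strand": h.strand_on_target,
                    "start": h.match_start,
                    "length": h.length,
                    "crosses_junction": h.crosses_junction,
                    "three_prime_junction_overlap": h.three_prime_junction_overlap,
                }
            )
    predictions = predict_amplicons(pair, target, warning_threshold)
    return {
        "target_id": target.circ_id,
        "circle_length": len(seq),
        "junction": 0,  # seam lies between coordinates len-1 and 0
        "primer_spans": spans,
        "products": [
            {
                "product_length": p.product_length,
                "f0r_code": p.f0r_code,
                "parental_gene_warning": p.parental_gene_warning,
                "arc_start": p.fwd_hit.start,
            }
            for p in predictions
        ],
    }
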