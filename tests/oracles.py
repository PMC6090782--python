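"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own search/scoring code paths:
hit finding enumerates every rotation of the circular target, product
lengths are computed by stepping base-by-base around the circle, boundary
scoring works on coordinate sets, and splice segmentation classifies every
base individually.
"""

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_hits(primer: str, target: str) -> list[tuple[str, int, int]]:
    """All (strand, start_of_5prime_base, 3prime_junction_overlap) sites.

    Scans every rotation of the circular target for a prefix match of the
    primer (sense) or its reverse complement (antisense). The junction
    overlap is counted per base: a matched base lies past the seam on the
    primer's 3' side when its unwrapped coordinate reaches beyond the end
    of the linearized sequence (sense) or when it sits before the seam
    while the primer's 5' end has wrapped past it (antisense).
    """
    L, plen = len(target), len(primer)
    out = []
    if plen > L:
        return out
    for strand, query in (("sense", primer), ("antisense", revcomp(primer))):
        for r in range(L):
            rotated = target[r:] + target[:r]
            if not rotated.startswith(query):
                continue
            window = [(r + j) % L for j in range(plen)]  # circle coords
            wrapped = r + plen > L
            if strand == "sense":
                start = r
                overlap = sum(1 for j in range(plen) if r + j >= L) if wrapped else 0
            else:
                start = window[-1]
                overlap = sum(1 for j in range(plen) if r + j < L) if wrapped else 0
            out.append((strand, start, overlap))
    return sorted(out)


def naive_amplicons(
    fwd: str, rev: str, target: str, warning_threshold: int = 5
) -> list[tuple[int, str, bool, int, int]]:
    """All (product_length, code, warning, fwd_start, rev_start) predictions.

    Product length is found by stepping one base at a time from the
    forward primer's 5' base to the reverse primer's 5' base.
    """
    L = len(target)
    fwd_hits = [h for h in naive_hits(fwd, target) if h[0] == "sense"]
    rev_hits = [h for h in naive_hits(rev, target) if h[0] == "antisense"]
    out = []
    for _, f, f_ov in fwd_hits:
        for _, r, r_ov in rev_hits:
            pos, n, covers = f, 1, False
            while pos != r:
                if pos == L - 1:
                    covers = True
                pos = (pos + 1) % L
                n += 1
            if f_ov:
                code = f"F{f_ov}"
            elif r_ov:
                code = f"R{r_ov}"
            elif covers:
                code = "0"
            else:
                code = "1"
            out.append(
                (n, code, f_ov >= warning_threshold or r_ov >= warning_threshold, f, r)
            )
    return sorted(out)


def naive_boundary_points(position: int, which: str, transcript) -> int:
    """Set-based re-implementation of the 3/2/0 boundary scoring."""
    starts = {e.interval.start for e in transcript.exons}
    ends = {e.interval.end for e in transcript.exons}
    if which == "start" and position in starts:
        return 3
    if which == "end" and position in ends:
        return 3
    if any(
        e.interval.start < position < e.interval.end for e in transcript.exons
    ):
        return 2
    return 0


def naive_score(circ, transcript) -> int:
    return naive_boundary_points(
        circ.interval.start, "start", transcript
    ) + naive_boundary_points(circ.interval.end, "end", transcript)


def naive_winner(circ, transcripts):
    iv = circ.interval
    cands = [
        t
        for t in transcripts
        if t.chrom == iv.chrom
        and t.interval.start <= iv.start
        and t.interval.end >= iv.end
        and (iv.strand == "." or t.strand == iv.strand)
    ]
    if not cands:
        return None
    cands.sort(
        key=lambda t: (
            -naive_score(circ, t),
            -(t.interval.end - t.interval.start),
            t.transcript_id,
        )
    )
    return cands[0]


def naive_retained_bases(interval, transcript) -> set[int]:
    """Per-base classification of the splice/retention rule."""
    all_bases = set(range(interval.start, interval.end))
    exonic = set()
    for e in transcript.exons:
        exonic |= all_bases & set(range(e.interval.start, e.interval.end))
    if not exonic:
        return all_bases
    lo, hi = min(exonic), max(exonic)
    return exonic | {b for b in all_bases if b < lo or b > hi}
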