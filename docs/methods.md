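# Methods

## Problem and model

A circular RNA (circRNA) arises when a downstream splice donor joins an
upstream splice acceptor (backsplicing), producing a covalently closed RNA.
Public catalogues record circRNAs by genomic location; their mature
sequence, parental transcript and junction-safe primers must be inferred.
`circkit` models a circRNA as a genomic interval on a chromosome and treats
its spliced sequence as a circle whose seam (backsplice junction) lies
between the sequence's last and first base — i.e., stored sequences are
assumed to begin at the backsplice acceptor, matching the convention of the
public catalogues this format emulates.

## Coordinate conventions

Internally everything is 0-based, half-open, `chr`-prefixed. GTF input
(1-based inclusive, UCSC-refGene or Ensembl attribute dialect, bare Ensembl
chromosome names normalized) is converted on read. Database tables and
display-style location strings are read BED-like: 0-based start, exclusive
end. Location strings accept any non-alphanumeric separator except `','`
(stripped as a thousands separator); letters cannot serve as separators
because they are indistinguishable from the chromosome token. A trailing
`+`/`-` sets the strand; `-` elsewhere is a range separator.

## Parental-transcript scoring

Candidates are transcripts whose span contains the circRNA span; when the
record's strand is known, only same-strand transcripts compete (records
from the emulated databases carry strand, so this is the common case).
Boundary scores are 3 (boundary exactly on the matching exon edge), 2 (on
an exon but not on that edge) or 0 (intronic); the pair sums to at most 6.
Ties on the score go to the longest genomic span, then to the
lexicographically smallest transcript id — the last step exists purely to
make the winner a total order, hence deterministic.

Two deliberately resolved ambiguities:

* **Genomic-space edges.** "Exon 5' end" is read as the exon's genomic
  start and "exon 3' end" as its genomic end regardless of strand. Database
  locations are genomic and backsplice donor/acceptor sites sit at genomic
  exon boundaries; a strand-aware reading would score minus-strand records
  asymmetrically with their display coordinates. A consequence, tested,
  is that scoring is strand-symmetric.
* **Wrong-edge boundaries.** A circRNA start falling on an exon's *last*
  base (display coordinate equal to the exon end) is "on the exon" and
  scores 2; a start one base further right (the first intron base) scores
  0. Both fall out of the strictly-inside test in half-open coordinates;
  no special casing is applied.

## Spliced-sequence reconstruction

Segments are the intersections of the circRNA span with the winner's
exons. A boundary inside an intron additionally retains the intronic run
from that boundary to the first (genomic-order) intersecting exon — or
from the last intersecting exon to the end — because a backsplice at an
intronic position carries that intron fragment into the circle. A span
intersecting no exon at all is retained whole (spliced equals genomic).
Segments are fetched plus-strand and concatenated in genomic order; for
minus-strand winners the concatenation is reverse complemented, so output
always reads in transcript orientation. Only the dominant isoform is
modelled: alternative splicing within circRNAs (a few percent of cases) is
out of scope, as is any use of RNA-seq evidence.

When a database-supplied sequence disagrees with the reconstruction (a
known failure mode is a catalogue storing the *genomic* rather than the
spliced sequence), the toolkit reports both and emits a discrepancy
warning instead of overriding either; such conflicts need experimental
resolution.

## Primer-design templates

The template is the half-rotation `S[m:] + S[:m]`, `m = ⌊L/2⌋`, of the
spliced sequence `S`, placing the seam at template offset `L − m` — near
the center, which maximizes design freedom on both sides. No layout is
prescribed by upstream conventions; centering is this package's choice.
Serialized Boulder-IO records carry a 2-base target over the seam (so any
product must cover it → divergent primers), plus, in junction-spanning
mode, the junction-overlap tag forcing one primer across the seam. The
design engine itself (e.g. Primer3) is external: `circkit` writes its
input and never re-implements melting-temperature or quality scoring.
Defaults: minimum template length 60 nt (below that, qPCR design on the
rotation is not meaningful; the genomic sequence is suggested instead);
product-size range 70–250 nt, capped at the circle length.

## In-silico PCR on circular templates

Binding sites of a primer (sense) and its reverse complement (antisense)
are located by exact substring search over `target + target[:len(primer)−1]`;
the doubled prefix captures seam-crossing sites, and positions are reported
modulo the circle length. For a seam-crossing site the 3'-junction overlap
counts matched bases on the primer's 3' side of the seam: bases after the
seam for sense hits, before it for antisense hits (the primer extends
toward lower coordinates). Every sense-forward × antisense-reverse pairing
becomes a predicted product; its length is the circular walk from forward
5' base to reverse 5' base, both included (standard product definition).
Only single-lap products exist by construction; rolling-circle multimers
are out of scope. Geometry codes: `F<n>`/`R<n>` when the forward/reverse
hit crosses the seam (primer codes take precedence, with `F` before `R`),
else `0` when the product covers the seam (divergent), else `1`
(convergent). The parental-gene warning fires when any hit of the pair has
3'-junction overlap ≥ 5 bases (configurable): such a primer has enough of
a 3' foothold on one exon to prime on the linear parental transcript.

Numerical/matching choices: matching is exact (0 mismatches) by default —
reproducible and conservative; an optional mismatch budget exists (the
five 3'-terminal bases always match exactly, since 3' mismatches abolish
extension) and `N` in a primer matches any base. Rotating a stored target
sequence moves its seam by definition, so junction-dependent codes can
legitimately change under rotation; what is invariant, and tested, is
hit-position equivariance and product-length invariance.

## Synthetic data generator

The fixture generator emulates the *coordinate structure* the toolkit
reasons about: multi-exon genes (default 6 genes, 3–6 exons of 60–180 nt,
introns of 80–300 nt, alternating strands across genes), the same
annotation in both GTF dialects, a circRNA table with spliced FASTA, and
engineered primer pairs (convergent, divergent, junction-spanning with 4
and 5 overlap bases — straddling the warning threshold). Five circRNA
classes are produced, each on a plus- and a minus-strand gene: both
boundaries exact, one boundary inside an exon, an intronic start boundary,
a fully intra-intronic span, and a 4-member cluster sharing one spliced
sequence (the cross-amplification scenario for divergent primers).
Sequences are uniform random ACGT under a single seeded RNG, so output is
byte-deterministic. Ground truth (winner, score, segments, sequence) is
written by explicit construction, not by running the pipeline, making
`verify_fixture` a genuine closed loop.

What the fixtures do **not** emulate: real base composition, splice-site
motifs, overlapping genes and isoforms, assembly gaps, and genome-scale
data volumes. Passing tests therefore demonstrate the correctness of the
coordinate logic, scoring, reconstruction and circular search — not
robustness to messy real annotations, which should be validated against a
real genome/GTF/catalogue before production use. Problem sizes in the test
suite (fixture genomes of tens of kilobases; oracle comparisons on 20
random targets ≤ 500 nt × 50 primers) were chosen so the brute-force
all-rotations oracles remain exhaustive while the suite runs in seconds.

## Known limitations

* Exact matching only by default; no thermodynamic binding model, so a
  "no hit" verdict does not rule out mispriming with mismatches.
* No genome-wide off-target search against linear transcripts; the ≥ 5-base
  junction rule is the only parental-gene heuristic.
* Dominant-isoform assumption; alternative backsplice isoforms are not
  enumerated.
* The boundary-scoring edge interpretations above are this package's
  documented choices where the underlying convention is ambiguous.
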