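# circkit

Designing qPCR assays for circular RNAs is error-prone: a circRNA's mature
(spliced) sequence is usually not published, only its backsplice junction —
the non-colinear joint between a downstream splice donor and an upstream
splice acceptor — distinguishes it from its parental linear mRNA, and
circRNAs derived from the same gene often share their entire sequence, so a
primer pair designed for one may amplify several. `circkit` is a scriptable
toolkit for molecular biologists working on circRNAs that covers this whole
workflow:

* **annotate** a circRNA (known or novel) against transcript models and pick
  its parental transcript by boundary scoring;
* **reconstruct** its spliced and genomic sequences from a genome FASTA;
* **generate templates** for divergent or junction-spanning primer design,
  ready to paste into a design engine such as Primer3;
* **check primer specificity** by in-silico PCR over a circRNA sequence
  database on a circular topology, including binding sites that cross the
  backsplice junction.

## The method

**Parental-transcript scoring.** Candidate transcripts are those whose
genomic span contains the circRNA span. Each boundary is scored against a
candidate's exons: 3 points if the circRNA start coincides exactly with an
exon start (respectively, the end with an exon end), 2 points if the
boundary lies on an exon but not on that edge, 0 otherwise (intronic). The
candidate with the highest total (max 3 + 3 = 6) is the parental
transcript; ties go to the longest span, then the smallest transcript id.

**Spliced sequence.** Introns are removed from the circRNA's genomic span
according to the winning transcript's exons, except that a boundary falling
inside an intron retains the intronic run between that boundary and the
nearest retained exon. Minus-strand results are reverse complemented. The
dominant-isoform assumption is deliberate: alternative splicing within
circRNAs is rare enough to ignore for primer design.

**In-silico PCR on a circle.** Each database sequence is treated as a
circle whose seam (backsplice junction) lies between its last and first
base. Primer sites are found on both strands of the doubled sequence, so
seam-crossing sites are detected; every sense-forward × antisense-reverse
hit pairing yields a product whose length is the circular walk between the
two 5' ends. Each prediction carries a geometry code — `1` convergent, `0`
divergent (product covers the seam), `F<n>`/`R<n>` forward/reverse primer
crossing the seam with *n* 3'-side bases beyond it — and a **parental-gene
warning** whenever a junction-spanning primer has ≥ 5 bases of its 3' end
past the seam, since such a primer can also prime on the linear transcript.

## Worked example

Everything below runs on a self-contained synthetic fixture (no downloads):

```bash
circkit make-fixtures --outdir fx --seed 11
circkit annotate --gtf fx/annotation.ucsc.gtf --circdb fx/circs.tsv --id fix_circ_0001
circkit check --circdb fx/circs.tsv --circdb-fasta fx/circs.fa --primers-tsv fx/primers.tsv
```

The annotation report (one row per circRNA):

```text
circ_id	location	transcript_id	gene_symbol	score	start_match	end_match	n_candidates
fix_circ_0001	chrT1:315-1125(+)	TX001	GENE001	6	exact_exon_boundary	exact_exon_boundary	1
```

Score 6 means both boundaries sit exactly on exon edges of `TX001` — the
strongest possible support that `TX001` is the parental transcript. The
specificity report for the fixture's engineered divergent pair:

```text
pair	target_id	gene_symbol	product_length	f0r_code	parental_gene_warning	fwd_pos	rev_pos
divergent	fix_circ_cl01	GENE005	80	0	False	491	39
divergent	fix_circ_cl02	GENE005	80	0	False	491	39
divergent	fix_circ_cl03	GENE005	80	0	False	491	39
divergent	fix_circ_cl04	GENE005	80	0	False	491	39
```

Four database circRNAs share one spliced sequence, so the divergent pair
(code `0`: the 80-nt product runs through the backsplice junction) amplifies
all four — exactly the cross-amplification risk the junction-spanning mode
(`circkit template --mode junction`) is there to avoid. A pair whose forward
primer crosses the junction with 5 bases at its 3' end would instead be
coded `F5` with `parental_gene_warning	True`.

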