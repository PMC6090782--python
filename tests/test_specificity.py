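import random

import pytest

from circkit.models import CircRecord, GenomicInterval, PrimerPair
from circkit.specificity import (
    check_specificity,
    find_hits,
    locate_primers_figure_data,
    predict_amplicons,
    slice_circular,
)

from .oracles import naive_amplicons, naive_hits, revcomp


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def circ_with_seq(seq, cid="t1"):
    return CircRecord(cid, GenomicInterval("chr1", 0, len(seq) * 2), None, seq)


class TestFindHits:
    def setup_method(self):
        self.rng = random.Random(42)
        self.target = rand_seq(self.rng, 300)

    def test_interior_sense_hit(self):
        hits = find_hits(self.target[10:30], self.target)
        sense = [h for h in hits if h.strand_on_target == "sense"]
        assert len(sense) == 1
        assert sense[0].start == 10
        assert sense[0].three_prime_junction_overlap == 0

    def test_seam_crossing_sense_hit(self):
        """12 bases before the seam, 8 after: the 3'-junction overlap is 8."""
        t = self.target
        primer = t[-12:] + t[:8]
        hits = [h for h in find_hits(primer, t) if h.strand_on_target == "sense"]
        assert len(hits) == 1
        assert hits[0].start == len(t) - 12
        assert hits[0].three_prime_junction_overlap == 8
        assert hits[0].crosses_junction

    def test_seam_crossing_antisense_hit(self):
        """An antisense primer extends toward lower coordinates, so its
        3'-side junction overlap counts the bases before the seam."""
        t = self.target
        primer = revcomp(t[-7:] + t[:13])  # window crosses with 7 before seam
        hits = [h for h in find_hits(primer, t) if h.strand_on_target == "antisense"]
        assert len(hits) == 1
        assert hits[0].start == 12  # 5' base at the high end of the window
        assert hits[0].three_prime_junction_overlap == 7

    def test_absent_primer_no_hits(self):
        assert find_hits("A" * 25, "CG" * 100) == []

    def test_primer_longer_than_target_warns_empty(self):
        assert find_hits("ACGT" * 10, "ACGTACGT") == []

    def test_n_wildcard_matches_any_base(self):
        t = self.target
        primer = t[50:60] + "N" + t[61:70]
        hits = [h for h in find_hits(primer, t) if h.strand_on_target == "sense"]
        assert any(h.start == 50 for h in hits)

    def test_agrees_with_all_rotations_scan(self):
        """Exhaustive oracle: hits equal a scan over every rotation of the
        circle, for planted and random primers on random targets."""
        rng = random.Random(5)
        for _ in range(20):
            t = rand_seq(rng, rng.randint(40, 500))
            primers = [rand_seq(rng, rng.randint(12, 25)) for _ in range(2)]
            for _ in range(3):  # planted, possibly seam-crossing
                p = rng.randrange(len(t))
                k = rng.randint(12, min(25, len(t)))
                primers.append(slice_circular(t, p, k))
                primers.append(revcomp(slice_circular(t, p, k)))
            for primer in primers:
                got = sorted(
                    (h.strand_on_target, h.start, h.three_prime_junction_overlap)
                    for h in find_hits(primer, t)
                )
                assert got == naive_hits(primer, t)


class TestPredictAmplicons:
    def test_convergent_interior_product(self):
        rng = random.Random(9)
        t = rand_seq(rng, 400)
        fwd = t[30:50]
        rev = revcomp(t[130:150])  # reverse 5' base at coordinate 149
        preds = predict_amplicons(PrimerPair(fwd, rev), circ_with_seq(t))
        assert len(preds) == 1
        assert preds[0].product_length == 120
        assert preds[0].f0r_code == "1"
        assert not preds[0].parental_gene_warning

    def test_divergent_product_covers_seam(self):
        rng = random.Random(10)
        t = rand_seq(rng, 400)
        fwd = t[350:370]
        rev = revcomp(t[40:60])
        preds = predict_amplicons(PrimerPair(fwd, rev), circ_with_seq(t))
        assert len(preds) == 1
        assert preds[0].f0r_code == "0"
        assert preds[0].fwd_hit.start + preds[0].product_length > len(t)

    @pytest.mark.parametrize("overlap", range(1, 9))
    def test_junction_overlap_series(self, overlap):
        """Sweeping a forward primer's 3' overlap past the seam: code F<n>,
        and the parental-gene warning fires first at 5 bases."""
        rng = random.Random(11)
        t = rand_seq(rng, 300)
        plen = 20
        fwd = t[-(plen - overlap):] + t[:overlap]
        rev = revcomp(t[60:80])
        preds = predict_amplicons(PrimerPair(fwd, rev), circ_with_seq(t))
        assert len(preds) == 1
        assert preds[0].f0r_code == f"F{overlap}"
        assert preds[0].parental_gene_warning == (overlap >= 5)

    def test_warning_threshold_configurable(self):
        rng = random.Random(12)
        t = rand_seq(rng, 300)
        fwd = t[-17:] + t[:3]
        rev = revcomp(t[60:80])
        preds = predict_amplicons(PrimerPair(fwd, rev), circ_with_seq(t),
                                  warning_threshold=3)
        assert preds[0].parental_gene_warning

    def test_reverse_junction_code(self):
        rng = random.Random(13)
        t = rand_seq(rng, 300)
        fwd = t[100:120]
        rev = revcomp(t[-6:] + t[:14])  # window crosses seam; 6 bases 3' side
        preds = predict_amplicons(PrimerPair(fwd, rev), circ_with_seq(t))
        assert len(preds) == 1
        assert preds[0].f0r_code == "R6"
        assert preds[0].parental_gene_warning

    def test_directed_walks_sum_to_circle_length(self):
        """For any hit pair, the forward walk plus the reverse walk between
        the two 5' ends closes the circle: d(f->r) + d(r->f) == L."""
        rng = random.Random(14)
        t = rand_seq(rng, 350)
        fwd, rev = t[20:40], revcomp(t[200:220])
        (pred,) = predict_amplicons(PrimerPair(fwd, rev), circ_with_seq(t))
        L = len(t)
        f, r = pred.fwd_hit.start, pred.rev_hit.start
        assert (r - f) % L + (f - r) % L == L

    def test_agrees_with_brute_force(self):
        rng = random.Random(15)
        for _ in range(10):
            t = rand_seq(rng, rng.randint(60, 500))
            p1 = rng.randrange(len(t))
            p2 = rng.randrange(len(t))
            fwd = slice_circular(t, p1, 20)
            rev = revcomp(slice_circular(t, p2, 20))
            got = sorted(
                (p.product_length, p.f0r_code, p.parental_gene_warning,
                 p.fwd_hit.start, p.rev_hit.start)
                for p in predict_amplicons(PrimerPair(fwd, rev), circ_with_seq(t))
            )
            assert got == naive_amplicons(fwd, rev, t)

    def test_rotation_equivariance(self):
        """Rotating the circle shifts every hit by -r (mod L) and leaves
        hit counts, strands and product lengths unchanged."""
        rng = random.Random(16)
        t = rand_seq(rng, 240)
        fwd, rev = t[10:30], revcomp(t[100:120])
        base_hits = find_hits(fwd, t)
        base_preds = predict_amplicons(PrimerPair(fwd, rev), circ_with_seq(t))
        L = len(t)
        for r in (1, 17, 120, 239):
            rot = t[r:] + t[:r]
            hits = find_hits(fwd, rot)
            assert sorted((h.strand_on_target, h.start) for h in hits) == sorted(
                (h.strand_on_target, (h.start - r) % L) for h in base_hits
            )
            preds = predict_amplicons(PrimerPair(fwd, rev), circ_with_seq(rot))
            assert sorted(p.product_length for p in preds) == sorted(
                p.product_length for p in base_preds
            )


class TestCheckSpecificity:
    def test_shared_sequence_cluster_amplifies_all_members(self, circ_db,
                                                           primer_rows):
        """Four database circRNAs share one spliced sequence; a divergent
        pair on it amplifies exactly those four."""
        fwd, rev = primer_rows["divergent"]
        report = check_specificity(PrimerPair(fwd, rev), circ_db)
        assert report.n_targets_amplified == 4
        amplified = {p.target_id for p in report.predictions}
        assert amplified == {f"fix_circ_cl{k:02d}" for k in range(1, 5)}
        assert all(p.f0r_code == "0" for p in report.predictions)

    def test_nonmatching_pair_empty_report(self, circ_db):
        report = check_specificity(PrimerPair("A" * 20, "C" * 20), circ_db)
        assert report.predictions == []
        assert report.n_targets_amplified == 0

    def test_reconstruction_path_matches_database_path(self, fixture_dir, genome,
                                                       transcripts, primer_rows):
        """Targets without stored sequences are rebuilt through annotation;
        the report equals the one computed from database sequences."""
        from circkit import io as cio

        with_seq = cio.read_circ_table(fixture_dir / "circs.tsv",
                                       fixture_dir / "circs.fa")
        without = cio.read_circ_table(fixture_dir / "circs.tsv")
        fwd, rev = primer_rows["convergent"]
        pair = PrimerPair(fwd, rev)
        a = check_specificity(pair, with_seq)
        b = check_specificity(pair, without, genome=genome, transcripts=transcripts)
        key = lambda p: (p.target_id, p.product_length, p.f0r_code)
        assert sorted(map(key, a.predictions)) == sorted(map(key, b.predictions))

    def test_targets_without_sequences_skipped(self, fixture_dir):
        from circkit import io as cio

        db = cio.read_circ_table(fixture_dir / "circs.tsv")
        report = check_specificity(PrimerPair("A" * 20, "C" * 20), db)
        assert len(report.skipped_targets) == len(db)

    def test_report_dataframe_columns_and_order(self, circ_db, primer_rows):
        fwd, rev = primer_rows["junction_f5"]
        report = check_specificity(PrimerPair(fwd, rev), circ_db)
        df = report.to_dataframe(circ_db)
        assert list(df.columns) == [
            "target_id", "gene_symbol", "product_length", "f0r_code",
            "parental_gene_warning", "fwd_pos", "rev_pos",
        ]
        assert list(df.product_length) == sorted(df.product_length)
        assert df.parental_gene_warning.all()


class TestLocalization:
    def test_spans_slice_back_to_primer_sequences(self, circ_db, primer_rows):
        target = next(c for c in circ_db if c.circ_id == "fix_circ_cl01")
        fwd, rev = primer_rows["junction_f5"]
        data = locate_primers_figure_data(PrimerPair(fwd, rev), target)
        assert data["circle_length"] == len(target.spliced_seq)
        assert data["primer_spans"]
        for span in data["primer_spans"]:
            piece = slice_circular(
                target.spliced_seq, span["start"], span["length"]
            )
            primer = fwd if span["role"] == "forward" else rev
            expected = primer if span["strand"] == "sense" else revcomp(primer)
            assert piece == expected

    def test_junction_spanning_forward_span_crosses_seam(self, circ_db, primer_rows):
        target = next(c for c in circ_db if c.circ_id == "fix_circ_cl01")
        fwd, rev = primer_rows["junction_f5"]
        data = locate_primers_figure_data(PrimerPair(fwd, rev), target)
        fwd_spans = [s for s in data["primer_spans"] if s["role"] == "forward"]
        assert any(s["crosses_junction"] for s in fwd_spans)
        assert all(p["f0r_code"] == "F5" for p in data["products"])

    def test_divergent_spans_avoid_seam_product_covers_it(self, circ_db, primer_rows):
        target = next(c for c in circ_db if c.circ_id == "fix_circ_cl01")
        fwd, rev = primer_rows["divergent"]
        data = locate_primers_figure_data(PrimerPair(fwd, rev), target)
        assert not any(s["crosses_junction"] for s in data["primer_spans"])
        L = data["circle_length"]
        for p in data["products"]:
            assert p["f0r_code"] == "0"
            assert p["arc_start"] + p["product_length"] > L
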