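import random

import pytest

from refforge.core_io import GenomeSequence
from refforge.epcr import (
    MarkerHit,
    STSMarker,
    dedupe_hits,
    epcr_scan,
    find_primer_sites,
    read_hits,
    read_markers,
    revcomp,
    write_hits,
)


def brute_primer_sites(text, primer, max_mismatch, three_prime_exact):
    """Naive reference: explicit character loops, no shortcuts.  An N in
    the genome matches no primer base (plain inequality)."""
    out = []
    rc = revcomp(primer)
    for start in range(len(text) - len(primer) + 1):
        window = text[start: start + len(primer)]
        mm_plus = 0
        for a, b in zip(primer, window):
            if a != b:
                mm_plus += 1
        tail_ok = all(
            primer[len(primer) - 1 - i] == window[len(window) - 1 - i]
            for i in range(three_prime_exact)
        )
        if mm_plus <= max_mismatch and tail_ok:
            out.append((start, "+", mm_plus))
        mm_minus = sum(a != b for a, b in zip(rc, window))
        head_ok = all(rc[i] == window[i] for i in range(three_prime_exact))
        if mm_minus <= max_mismatch and head_ok:
            out.append((start, "-", mm_minus))
    return out


def brute_epcr(assembly, markers, max_mismatch=1, three_prime_exact=3,
               default_margin=50):
    """Quadratic oracle: all primer placements x all pairings."""
    hits = []
    for rec in assembly:
        for m in markers:
            lo, hi = m.size_window(default_margin)
            lo = max(lo, len(m.fwd) + len(m.rev))
            fsites = brute_primer_sites(rec.seq, m.fwd, max_mismatch,
                                        three_prime_exact)
            rsites = brute_primer_sites(rec.seq, m.rev, max_mismatch,
                                        three_prime_exact)
            for fs, fstrand, fmm in fsites:
                for rs, rstrand, rmm in rsites:
                    if fstrand == "+" and rstrand == "-":
                        start, end, strand = fs, rs + len(m.rev), "+"
                    elif fstrand == "-" and rstrand == "+":
                        start, end, strand = rs, fs + len(m.fwd), "-"
                    else:
                        continue
                    if lo <= end - start <= hi:
                        hits.append((m.marker_id, rec.name, start, end, strand,
                                     (fmm, rmm)))
    return sorted(hits)


class TestFindPrimerSites:
    def test_exact_plus_strand_site(self):
        seq = GenomeSequence("s", "AAACCGTAAGTAAA")
        primer = "CCGTAAGT"
        assert find_primer_sites(seq, primer, max_mismatch=0) == [(3, "+", 0)]

    def test_reverse_complement_symmetry(self):
        # searching with the reverse complement reports the same genomic
        # interval on the opposite strand
        seq = GenomeSequence("s", "AAACCGTAAGTAAA")
        sites = find_primer_sites(seq, revcomp("CCGTAAGT"), max_mismatch=0)
        assert sites == [(3, "-", 0)]

    def test_internal_mismatch_tolerated(self):
        primer = "CGTAACGTCC"
        site = primer[:4] + "G" + primer[5:]  # mutation outside the 3' window
        seq = GenomeSequence("s", "AAAA" + site + "TTTT")
        sites = find_primer_sites(seq, primer, max_mismatch=1)
        assert sites == [(4, "+", 1)]

    def test_three_prime_mismatch_kills_site(self):
        primer = "CGTAACGTCC"
        site = primer[:-1] + "A"  # mutate the 3'-terminal base
        seq = GenomeSequence("s", "AAAA" + site + "TTTT")
        assert find_primer_sites(seq, primer, max_mismatch=2) == []

    def test_genomic_n_counts_as_mismatch(self):
        seq = GenomeSequence("s", "AAACCGTNAGTAAA")
        assert find_primer_sites(seq, "CCGTAAGT", max_mismatch=0) == []
        assert find_primer_sites(seq, "CCGTAAGT", max_mismatch=1) == [(3, "+", 1)]

    def test_ambiguity_codes_in_primer_rejected(self):
        with pytest.raises(ValueError, match="ACGT"):
            find_primer_sites(GenomeSequence("s", "ACGT" * 10), "CGTNCGTACG")

    def test_primer_shorter_than_exact_window_rejected(self):
        with pytest.raises(ValueError):
            find_primer_sites(GenomeSequence("s", "ACGTACGTACGT"),
                              "ACGTACGTAC", three_prime_exact=11)

    def test_agrees_with_brute_force(self):
        rng = random.Random(7)
        for _ in range(20):
            text = "".join(rng.choice("ACGTN") for _ in range(300))
            primer = "".join(rng.choice("ACGT") for _ in range(12))
            assert find_primer_sites(GenomeSequence("s", text), primer,
                                     max_mismatch=2) == \
                brute_primer_sites(text, primer, 2, 3)


def _scaffold_with_amplicon(fwd, rev, spacer=25, lead=5, tail=10):
    seq = ("A" * lead) + fwd + ("C" * spacer) + revcomp(rev) + ("G" * tail)
    return GenomeSequence("sc1", seq)


class TestEpcrScan:
    FWD = "ATGCGTACTG"
    REV = "CATGCCAGTA"

    def test_constructed_amplicon_found(self):
        sc = _scaffold_with_amplicon(self.FWD, self.REV)
        marker = STSMarker("m1", self.FWD, self.REV, expected_size=45,
                           size_margin=50)
        (hit,) = epcr_scan([sc], [marker])
        assert (hit.start, hit.end, hit.product_size, hit.strand) == (5, 50, 45, "+")
        assert hit.mismatches == (0, 0)

    def test_out_of_window_size_rejected(self):
        sc = _scaffold_with_amplicon(self.FWD, self.REV)
        marker = STSMarker("m1", self.FWD, self.REV, expected_size=200,
                           size_margin=50)
        assert epcr_scan([sc], [marker]) == []

    def test_three_prime_mismatch_rejects_marker(self):
        mutated_fwd = self.FWD[:-1] + ("A" if self.FWD[-1] != "A" else "C")
        sc = _scaffold_with_amplicon(mutated_fwd, self.REV)
        marker = STSMarker("m1", self.FWD, self.REV, expected_size=45,
                           size_margin=50)
        assert epcr_scan([sc], [marker]) == []

    def test_strand_symmetry(self):
        sc = _scaffold_with_amplicon(self.FWD, self.REV)
        flipped = GenomeSequence(sc.name, revcomp(sc.seq))
        marker = STSMarker("m1", self.FWD, self.REV, expected_size=45,
                           size_margin=50)
        fwd_hits = epcr_scan([sc], [marker])
        rev_hits = epcr_scan([flipped], [marker])
        assert len(fwd_hits) == len(rev_hits) == 1
        h, g = fwd_hits[0], rev_hits[0]
        assert g.strand == "-" and h.strand == "+"
        assert (g.start, g.end) == (sc.length - h.end, sc.length - h.start)
        assert g.product_size == h.product_size

    def test_agreement_with_quadratic_oracle(self):
        rng = random.Random(99)
        text = "".join(rng.choice("ACGT") for _ in range(10_000))
        markers = []
        for i in range(5):
            fwd = "".join(rng.choice("ACGT") for _ in range(12))
            rev = "".join(rng.choice("ACGT") for _ in range(12))
            start = rng.randrange(0, 9_000)
            size = rng.randrange(150, 400)
            text = (text[:start] + fwd + text[start + 12: start + size - 12]
                    + revcomp(rev) + text[start + size:])
            markers.append(STSMarker(f"m{i}", fwd, rev, expected_size=size,
                                     size_margin=50))
        assembly = [GenomeSequence("s", text)]
        got = sorted(
            (h.marker_id, h.seq_name, h.start, h.end, h.strand, h.mismatches)
            for h in epcr_scan(assembly, markers)
        )
        assert got == brute_epcr(assembly, markers)

    def test_planted_markers_recovered_exactly_once(self, planted_marker_genome):
        p = planted_marker_genome
        hits = epcr_scan(p.genome, p.markers)
        by_marker = {}
        for h in hits:
            by_marker.setdefault(h.marker_id, []).append(h)
        for marker_id, chrom, start, end in p.truth_loci:
            assert [
                (h.seq_name, h.start, h.end, h.mismatches)
                for h in by_marker[marker_id]
            ] == [(chrom, start, end, (0, 0))]

    def test_hits_tsv_round_trip(self, tmp_path):
        sc = _scaffold_with_amplicon(self.FWD, self.REV)
        marker = STSMarker("m1", self.FWD, self.REV, expected_size=45,
                           size_margin=50)
        hits = epcr_scan([sc], [marker])
        path = tmp_path / "hits.tsv"
        write_hits(hits, path, header_lines=["##refforge_params={}"])
        assert read_hits(path) == hits

    def test_dedupe_prefers_fewest_mismatches(self):
        hits = [
            MarkerHit("m", "s", 0, 100, "+", (1, 0)),
            MarkerHit("m", "s", 500, 600, "+", (0, 0)),
        ]
        assert dedupe_hits(hits) == [hits[1]]


class TestMarkerTable:
    def test_marker_tsv_with_maps(self, tmp_path):
        mk = tmp_path / "markers.tsv"
        mk.write_text(
            "marker_id\tfwd\trev\texpected_size\tsize_margin\n"
            "m1\tATGCGTACTG\tCATGCCAGTA\t300\t\n"
        )
        mp = tmp_path / "maps.tsv"
        mp.write_text(
            "map_name\tmarker_id\tgroup\tposition\n"
            "genethon\tm1\tchr1\t12.5\n"
            "rh_tng\tm1\tchr1\t410\n"
        )
        (m,) = read_markers(mk, mp)
        assert m.expected_size == 300 and m.size_margin is None
        assert m.map_positions == (("genethon", "chr1", 12.5),
                                   ("rh_tng", "chr1", 410.0))

    def test_primer_invariants(self):
        with pytest.raises(ValueError):
            STSMarker("m", "ACGT", "ACGTACGTAC", expected_size=100)
        with pytest.raises(ValueError):
            STSMarker("m", "ACGTACGTAC", "ACGTACGTAC", expected_size=15)
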