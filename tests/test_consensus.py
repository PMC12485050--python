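import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refforge.consensus import (
    VoteTally,
    apply_substitutions,
    build_consensus,
    decide,
    decide_all,
    lift_position,
    normalize_variant,
    tally_sites,
)
from refforge.core_io import GenomeSequence, HaplotypeCallset, Interval, Variant

BB = [GenomeSequence("chr1", "ATTTG")]


def oracle_normalize(backbone: str, v: Variant) -> tuple[int, str, str]:
    """Exhaustively enumerate every (pos, ref, alt) giving the same edited
    sequence; return the parsimonious one at the smallest position."""
    edited = backbone[: v.pos - 1] + v.alt + backbone[v.pos - 1 + len(v.ref):]
    delta = len(edited) - len(backbone)
    candidates = []
    for pos in range(1, len(backbone) + 1):
        for ref_len in range(1, len(backbone) - pos + 2):
            alt_len = ref_len + delta
            if alt_len < 1:
                continue
            ref = backbone[pos - 1: pos - 1 + ref_len]
            alt = edited[pos - 1: pos - 1 + alt_len]
            if backbone[: pos - 1] + alt + backbone[pos - 1 + ref_len:] != edited:
                continue
            if ref == alt:
                continue
            # parsimonious: no shared leading/trailing base is removable
            if len(ref) > 1 and len(alt) > 1 and (
                ref[0] == alt[0] or ref[-1] == alt[-1]
            ):
                continue
            candidates.append((pos, ref, alt))
    return min(candidates, key=lambda c: (c[0], len(c[1])))


def apply_edit(backbone: str, v: Variant) -> str:
    return backbone[: v.start] + v.alt + backbone[v.end:]


class TestNormalize:
    @pytest.mark.parametrize(
        "v, expected",
        [
            (Variant("chr1", 2, "TT", "T"), Variant("chr1", 1, "AT", "A")),
            (Variant("chr1", 3, "T", "G"), Variant("chr1", 3, "T", "G")),
            (Variant("chr1", 3, "T", "TT"), Variant("chr1", 1, "A", "AT")),
        ],
    )
    def test_left_alignment_examples(self, v, expected):
        got = normalize_variant(v, BB)
        assert (got.chrom, got.pos, got.ref, got.alt) == (
            expected.chrom, expected.pos, expected.ref, expected.alt
        )
        # equivalence: both edits give the same sequence
        assert apply_edit(BB[0].seq, got) == apply_edit(BB[0].seq, v)

    def test_agrees_with_enumeration_oracle_on_random_indels(self):
        rng = random.Random(1234)
        bases = "ACGT"
        for _ in range(1000):
            backbone = "".join(rng.choice(bases) for _ in range(50))
            seqs = [GenomeSequence("c", backbone)]
            pos = rng.randrange(1, 48)
            ref = backbone[pos - 1: pos - 1 + rng.randrange(1, 4)]
            alt = "".join(rng.choice(bases) for _ in range(rng.randrange(1, 4)))
            if ref == alt:
                continue
            v = Variant("c", pos, ref, alt)
            got = normalize_variant(v, seqs)
            assert (got.pos, got.ref, got.alt) == oracle_normalize(backbone, v)
            assert apply_edit(backbone, got) == apply_edit(backbone, v)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_idempotent(self, data):
        rng = random.Random(data.draw(st.integers(0, 2**20)))
        backbone = "".join(rng.choice("ACGT") for _ in range(40))
        pos = rng.randrange(1, 38)
        ref = backbone[pos - 1: pos - 1 + rng.randrange(1, 4)]
        alt = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 4)))
        if ref == alt:
            return
        seqs = [GenomeSequence("c", backbone)]
        once = normalize_variant(Variant("c", pos, ref, alt), seqs)
        twice = normalize_variant(once, seqs)
        assert once == twice


def _callsets(allele_by_hap: dict[str, str | None], site=("chr1", 3, "T"),
              uncovered=()):
    """Six-haplotype callsets; None = no variant (votes backbone)."""
    out = []
    chrom, pos, ref = site
    for hap, alt in allele_by_hap.items():
        variants = [] if alt is None else [Variant(chrom, pos, ref, alt)]
        coverage = None
        if hap in uncovered:
            coverage = [Interval(chrom, 10**6, 10**6 + 1)]  # elsewhere
        out.append(HaplotypeCallset(hap, variants, coverage))
    return out


class TestTally:
    def test_four_carriers_two_backbone(self):
        cs = _callsets({"h1": "C", "h2": "C", "h3": "C", "h4": "C",
                        "h5": None, "h6": None})
        (tally,) = tally_sites(cs, BB)
        assert tally.counts == {"C": 4, "T": 2}
        assert tally.total_haplotypes == 6

    def test_variant_free_site_emits_no_tally(self):
        cs = _callsets({f"h{i}": None for i in range(1, 7)})
        assert tally_sites(cs, BB) == []

    def test_uncovered_haplotype_abstains(self):
        cs = _callsets({"h1": "C", "h2": "C", "h3": "C", "h4": "G",
                        "h5": "G", "h6": None}, uncovered={"h6"})
        (tally,) = tally_sites(cs, BB)
        assert tally.counts == {"C": 3, "G": 2, "T": 0}
        assert tally.votes == 5

    def test_unknown_chromosome_rejected(self):
        cs = [HaplotypeCallset("h1", [Variant("chrZ", 1, "A", "C")])]
        with pytest.raises(ValueError, match="chrZ"):
            tally_sites(cs, BB)


class TestDecide:
    def test_strict_majority_substitutes(self):
        t = VoteTally(("chr1", 3, "T"), {"C": 4, "T": 2}, 6)
        d = decide(t)
        assert d.winner == "C" and d.substituted and not d.tie

    def test_tie_is_random_but_reproducible(self):
        t = VoteTally(("chr1", 3, "T"), {"C": 3, "T": 3}, 6)
        draws = {decide(t, seed=s).winner for s in range(40)}
        assert draws == {"C", "T"}  # both outcomes reachable
        for s in (0, 1, 17):
            d1, d2 = decide(t, seed=s), decide(t, seed=s)
            assert d1.tie and d1.winner == d2.winner

    def test_backbone_retained_without_majority(self):
        t = VoteTally(("chr1", 3, "T"), {"C": 2, "G": 1, "T": 3}, 6)
        d = decide(t)
        assert d.winner == "T" and not d.substituted and not d.tie

    def test_plurality_below_half_keeps_backbone(self):
        # 3 of 6 for the alt is not "more than three of six"
        t = VoteTally(("chr1", 3, "T"), {"C": 3, "T": 2}, 6)
        d = decide(t)
        assert not d.substituted and d.winner == "T"

    def test_invalid_h_rejected(self):
        with pytest.raises(ValueError):
            decide(VoteTally(("chr1", 3, "T"), {"T": 0}, 0))

    def test_order_independence_of_tie_draws(self):
        cs = _callsets({"h1": "C", "h2": "C", "h3": "C", "h4": None,
                        "h5": None, "h6": None})
        for perm_seed in range(5):
            shuffled = list(cs)
            random.Random(perm_seed).shuffle(shuffled)
            d, _ = decide_all(tally_sites(shuffled, BB), seed=5)
            d0, _ = decide_all(tally_sites(cs, BB), seed=5)
            assert d == d0


class TestApply:
    def test_snv_identity_liftover(self):
        bb = [GenomeSequence("chr1", "AAAA")]
        cons, lo, rep = apply_substitutions(bb, [Variant("chr1", 2, "A", "C")])
        assert cons[0].seq == "ACAA" and rep.count == 0
        assert [lift_position(lo, "chr1", i) for i in range(4)] == [0, 1, 2, 3]

    def test_deletion(self):
        cons, lo, rep = apply_substitutions(BB, [Variant("chr1", 1, "AT", "A")])
        assert cons[0].seq == "ATTG"
        assert lift_position(lo, "chr1", 4) == 3
        assert lift_position(lo, "chr1", 1) is None  # deleted base

    def test_overlapping_winner_skipped(self):
        winners = [Variant("chr1", 1, "AT", "A"), Variant("chr1", 2, "TT", "T")]
        cons, lo, rep = apply_substitutions(BB, winners)
        assert cons[0].seq == "ATTG"
        assert rep.count == 1 and rep.skipped[0].pos == 2

    def test_length_conservation(self, population_bundle):
        b = population_bundle
        for cs, hap in zip(b.truth_callsets, b.haplotypes):
            cons, _, rep = apply_substitutions(b.backbone, cs.variants)
            assert rep.count == 0
            delta = sum(len(v.alt) - len(v.ref) for v in cs.variants)
            assert sum(c.length for c in cons) == \
                sum(s.length for s in b.backbone) + delta

    def test_single_winner_round_trip(self):
        # consensus vs backbone differ by exactly the applied edit
        bb = [GenomeSequence("chr1", "ACGTACGTAC")]
        v = Variant("chr1", 4, "T", "TGG")
        cons, _, _ = apply_substitutions(bb, [v])
        assert cons[0].seq == apply_edit(bb[0].seq, v)

    def test_liftover_monotonic(self, population_bundle):
        b = population_bundle
        cons, lo, _, _ = build_consensus(b.backbone, b.truth_callsets, seed=3)
        for rec in b.backbone:
            mapped = [lo.lift(rec.name, i) for i in range(rec.length)]
            present = [m for m in mapped if m is not None]
            assert present == sorted(present)
            assert len(set(present)) == len(present)

    def test_stale_winner_rejected(self):
        with pytest.raises(ValueError):
            apply_substitutions(BB, [Variant("chr1", 1, "GG", "G")])


class TestVotingRecovery:
    def test_majority_sites_substituted_exactly(self, population_bundle):
        """Sites carried by >H/2 haplotypes enter the consensus; sites with
        a backbone-held maximum do not; nothing else changes."""
        b = population_bundle
        cons, lo, decisions, report = build_consensus(
            b.backbone, b.truth_callsets, seed=0
        )
        assert report.count == 0
        substituted = {d.site for d in decisions if d.substituted}
        expected = {(v.chrom, v.pos, v.ref) for v, c in b.truth_variants if c > 3}
        assert substituted == expected
        assert not any(d.tie for d in decisions)

    def test_decisions_independent_of_callset_order(self, population_bundle):
        b = population_bundle
        _, _, d1, _ = build_consensus(b.backbone, b.truth_callsets, seed=9)
        _, _, d2, _ = build_consensus(
            b.backbone, list(reversed(b.truth_callsets)), seed=9
        )
        assert d1 == d2
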