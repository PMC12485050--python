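"""Majority-decision consensus across haploid assemblies.

Given a backbone assembly and H per-haplotype variant callsets, this
module (1) normalizes each variant to its left-aligned parsimonious
representation, (2) tallies, at every variant site, which allele each
haplotype carries, (3) substitutes an allele into the backbone when it
is carried by a strict majority (count > H/2), breaking exact ties by a
reproducible per-site random draw, and (4) returns the edited consensus
together with a block liftover from backbone to consensus coordinates.

The strict-majority rule means private and rare variants are dropped and
the consensus carries population-major alleles; with H = 6 haplotypes a
substitution requires the allele in at least 4 of them.
"""

from __future__ import annotations

import hashlib
import random
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from refforge.core_io import (
    GenomeSequence,
    HaplotypeCallset,
    ReferenceMismatchError,
    Variant,
)

Site = tuple[str, int, str]  # (chrom, 1-based normalized pos, ref allele)


class NullVariantError(ValueError):
    """REF equals ALT after trimming: the record encodes no edit."""


@dataclass
class VoteTally:
    """Allele counts at one normalized site across H haplotypes.

    The backbone (reference) allele is always present as a key, possibly
    with zero votes.  ``sum(counts.values())`` can be below H when some
    haplotypes do not cover the site and therefore abstain.
    """

    site: Site
    counts: dict[str, int]
    total_haplotypes: int

    @property
    def backbone_allele(self) -> str:
        return self.site[2]

    @property
    def votes(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Decision:
    site: Site
    winner: str
    substituted: bool
    tie: bool
    rng_draw: int | None = None


@dataclass
class Liftover:
    """Monotone block map from backbone to consensus coordinates.

    ``blocks[chrom]`` is a sorted list of ``(src_start, src_end,
    dst_start, dst_end)`` 0-based half-open tuples of equal src/dst
    width.  Backbone bases falling between blocks were deleted by a
    substitution and have no consensus image.
    """

    blocks: dict[str, list[tuple[int, int, int, int]]] = field(default_factory=dict)

    def lift(self, chrom: str, pos: int) -> int | None:
        """Map a 0-based backbone position to its consensus position.

        Returns ``None`` for bases removed by an applied deletion.
        """
        if chrom not in self.blocks:
            raise KeyError(f"unknown chromosome {chrom!r} in liftover")
        blocks = self.blocks[chrom]
        i = bisect_right(blocks, pos, key=lambda b: b[0]) - 1
        if i < 0:
            return None
        src_start, src_end, dst_start, _ = blocks[i]
        if pos >= src_end:
            return None
        return dst_start + (pos - src_start)

    def write_chain(self, path: str | Path, src_sizes: Mapping[str, int],
                    dst_sizes: Mapping[str, int]) -> None:
        """Write the liftover as a UCSC chain file (backbone → consensus)."""
        with open(path, "wt") as fh:
            chain_id = 0
            for chrom, blocks in sorted(self.blocks.items()):
                if not blocks:
                    continue
                chain_id += 1
                src_size = src_sizes[chrom]
                dst_size = dst_sizes[chrom]
                first, last = blocks[0], blocks[-1]
                fh.write(
                    f"chain 1000 {chrom} {src_size} + {first[0]} {last[1]} "
                    f"{chrom} {dst_size} + {first[2]} {last[3]} {chain_id}\n"
                )
                for i, (s0, s1, d0, d1) in enumerate(blocks):
                    size = s1 - s0
                    if i + 1 < len(blocks):
                        n0, _, nd0, _ = blocks[i + 1]
                        fh.write(f"{size}\t{n0 - s1}\t{nd0 - d1}\n")
                    else:
                        fh.write(f"{size}\n")
                fh.write("\n")


# ---------------------------------------------------------------------------
# normalization


def _verify_ref(v: Variant, seqs: Mapping[str, GenomeSequence]) -> str:
    if v.chrom not in seqs:
        raise ReferenceMismatchError(f"unknown chromosome {v.chrom!r}")
    seq = seqs[v.chrom].seq
    observed = seq[v.start : v.end]
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"REF mismatch at {v.chrom}:{v.pos}: variant says {v.ref!r}, "
            f"backbone has {observed!r}"
        )
    return seq


def normalize_variant(
    v: Variant, backbone: Sequence[GenomeSequence] | Mapping[str, GenomeSequence]
) -> Variant:
    """Left-align and trim a variant to its canonical representation.

    Follows the standard normalization algorithm (as implemented by
    ``bcftools norm`` and ``vt normalize``): shared trailing bases are
    trimmed, extending left over the backbone whenever trimming would
    empty an allele, then shared leading bases are trimmed.  The result
    is the parsimonious representation at the smallest possible
    position; applying it to the backbone yields the same edited
    sequence as applying the input.
    """
    if not isinstance(backbone, Mapping):
        backbone = {s.name: s for s in backbone}
    seq = _verify_ref(v, backbone)

    pos, ref, alt = v.pos, v.ref, v.alt
    if ref == alt:
        raise NullVariantError(f"{v.chrom}:{pos} {ref}->{alt}")

    while True:
        if ref[-1] == alt[-1]:
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
            elif pos > 1:
                # an allele would become empty: extend left instead
                base = seq[pos - 2]
                ref, alt = base + ref[:-1], base + alt[:-1]
                pos -= 1
            else:
                break
        else:
            break
        if ref == alt:
            raise NullVariantError(f"{v.chrom}:{v.pos} {v.ref}->{v.alt}")
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(v.chrom, pos, ref, alt, source=v.source)


def normalize_callset(
    cs: HaplotypeCallset,
    backbone: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
) -> HaplotypeCallset:
    """Normalize every variant of a callset against the backbone."""
    return HaplotypeCallset(
        haplotype_id=cs.haplotype_id,
        variants=[normalize_variant(v, backbone) for v in cs.variants],
        coverage=cs.coverage,
    )


# ---------------------------------------------------------------------------
# voting


def tally_sites(
    callsets: Sequence[HaplotypeCallset],
    backbone: Sequence[GenomeSequence] | Mapping[str, GenomeSequence],
) -> list[VoteTally]:
    """Count, per normalized variant site, the allele each haplotype carries.

    Sites are induced by the variants: a position where no haplotype
    differs from the backbone produces no tally.  At a tallied site a
    haplotype with no variant there votes for the backbone allele if the
    site lies inside its coverage, and abstains otherwise.
    """
    if not isinstance(backbone, Mapping):
        backbone = {s.name: s for s in backbone}
    H = len(callsets)

    # site -> {haplotype -> alt allele}
    alt_votes: dict[Site, dict[str, str]] = {}
    for cs in callsets:
        for v in cs.variants:
            if v.chrom not in backbone:
                raise ReferenceMismatchError(
                    f"callset {cs.haplotype_id!r} references unknown "
                    f"chromosome {v.chrom!r}"
                )
            site = (v.chrom, v.pos, v.ref)
            alt_votes.setdefault(site, {})[cs.haplotype_id] = v.alt

    tallies = []
    for site in sorted(alt_votes):
        chrom, pos, ref = site
        carriers = alt_votes[site]
        counts: dict[str, int] = {ref: 0}
        for cs in callsets:
            if cs.haplotype_id in carriers:
                allele = carriers[cs.haplotype_id]
                counts[allele] = counts.get(allele, 0) + 1
            elif cs.covers(chrom, pos - 1):
                counts[ref] += 1
            # else: abstains (site outside the haplotype's alignment)
        tallies.append(VoteTally(site=site, counts=counts, total_haplotypes=H))
    return tallies


def _site_rng(seed: int, chrom: str, pos: int) -> random.Random:
    """A generator keyed by (seed, site) — reproducible and order-free."""
    key = f"{seed}\x00{chrom}\x00{pos}".encode()
    digest = hashlib.sha256(key).digest()
    return random.Random(int.from_bytes(digest[:8], "big"))


def decide(tally: VoteTally, seed: int = 0) -> Decision:
    """Apply the strict-majority rule to one site.

    A single allele with count > H/2 wins.  When the maximum count is
    shared by two or more alleles (backbone included), the winner is
    drawn uniformly among the tied alleles with a generator seeded from
    (seed, chrom, pos), so the draw is reproducible and independent of
    callset iteration order.  Otherwise the backbone allele is retained.
    """
    H = tally.total_haplotypes
    if H <= 0:
        raise ValueError("total_haplotypes must be positive")
    chrom, pos, ref = tally.site
    max_count = max(tally.counts.values())
    leaders = sorted(a for a, c in tally.counts.items() if c == max_count)

    if len(leaders) > 1:
        rng = _site_rng(seed, chrom, pos)
        draw = rng.randrange(len(leaders))
        winner = leaders[draw]
        return Decision(tally.site, winner, substituted=winner != ref,
                        tie=True, rng_draw=draw)
    winner = leaders[0]
    if max_count > H / 2 and winner != ref:
        return Decision(tally.site, winner, substituted=True, tie=False)
    return Decision(tally.site, ref, substituted=False, tie=False)


def decide_all(
    tallies: Iterable[VoteTally], seed: int = 0
) -> tuple[list[Decision], list[Variant]]:
    """Decide every site; also return the winning substitutions as variants."""
    decisions = []
    winners = []
    for t in tallies:
        d = decide(t, seed=seed)
        decisions.append(d)
        if d.substituted:
            chrom, pos, ref = t.site
            winners.append(Variant(chrom, pos, ref, d.winner))
    return decisions, winners


# ---------------------------------------------------------------------------
# substitution


@dataclass
class SkipReport:
    """Winners skipped because their REF span overlapped an applied one."""

    skipped: list[Variant] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.skipped)


def apply_substitutions(
    backbone: Sequence[GenomeSequence],
    winners: Sequence[Variant],
) -> tuple[list[GenomeSequence], Liftover, SkipReport]:
    """Substitute winning alleles into the backbone, left to right.

    Winners whose REF span overlaps an already-applied winner are
    skipped and reported, never merged.  Besides the edited consensus a
    block :class:`Liftover` is returned; within each applied edit the
    shared-length prefix of REF and ALT keeps its coordinates and any
    excess REF bases (a deletion) map to nothing.
    """
    by_name = {s.name: s for s in backbone}
    by_chrom: dict[str, list[Variant]] = {}
    for w in sorted(winners, key=lambda v: (v.chrom, v.pos, -len(v.ref))):
        by_chrom.setdefault(w.chrom, []).append(w)

    consensus: list[GenomeSequence] = []
    lo = Liftover()
    report = SkipReport()

    for rec in backbone:
        seq = rec.seq
        pieces: list[str] = []
        blocks: list[tuple[int, int, int, int]] = []
        src_cursor = 0  # 0-based backbone position up to which output is built
        dst_cursor = 0
        block_src = 0  # start of the current 1:1 block
        block_dst = 0

        def close_block(src_end: int) -> None:
            nonlocal block_src, block_dst
            if src_end > block_src:
                blocks.append(
                    (block_src, src_end, block_dst, block_dst + (src_end - block_src))
                )

        for w in by_chrom.get(rec.name, []):
            if w.start < src_cursor:
                report.skipped.append(w)
                continue
            _verify_ref(w, by_name)
            pieces.append(seq[src_cursor : w.start])
            dst_cursor += w.start - src_cursor
            pieces.append(w.alt)
            # the shared-length prefix of ref/alt stays coordinate-mapped
            shared = min(len(w.ref), len(w.alt))
            close_block(w.start + shared)
            src_cursor = w.end
            dst_cursor += len(w.alt)
            block_src = src_cursor
            block_dst = dst_cursor
        pieces.append(seq[src_cursor:])
        close_block(len(seq))
        consensus.append(GenomeSequence(name=rec.name, seq="".join(pieces)))
        lo.blocks[rec.name] = blocks
    return consensus, lo, report


def lift_position(lo: Liftover, chrom: str, pos: int) -> int | None:
    """Map a 0-based backbone position through the liftover."""
    return lo.lift(chrom, pos)


def build_consensus(
    backbone: Sequence[GenomeSequence],
    callsets: Sequence[HaplotypeCallset],
    seed: int = 0,
) -> tuple[list[GenomeSequence], Liftover, list[Decision], SkipReport]:
    """Full pipeline: normalize, tally, decide, substitute."""
    normalized = [normalize_callset(cs, backbone) for cs in callsets]
    tallies = tally_sites(normalized, backbone)
    decisions, winners = decide_all(tallies, seed=seed)
    consensus, lo, report = apply_substitutions(backbone, winners)
    return consensus, lo, decisions, report
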