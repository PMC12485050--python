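"""Unplaced-scaffold filtering.

After chromosome anchoring, the leftover contigs/scaffolds are reduced
to a clean unplaced set by a four-stage cascade, applied in this fixed
order with the first matching rule claiming each sequence:

1. *placed* — drop sequences whose aligned fraction to the chromosome
   set reaches a threshold (evidence supplied as a table; the alignment
   itself is upstream of this tool);
2. *short* — drop sequences below a minimum length (default 1 kb);
3. *contained* — drop sequences redundant with a longer kept sequence,
   judged by canonical k-mer containment (a deterministic proxy for
   all-by-all alignment);
4. *gappy* — drop sequences whose N fraction strictly exceeds a cutoff
   (default 80%; a sequence at exactly the cutoff survives).

Survivors keep their input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from refforge.core_io import GenomeSequence
from refforge.epcr import revcomp

DEFAULT_MIN_LENGTH = 1000
DEFAULT_PLACED_FRACTION = 0.5
DEFAULT_CONTAINMENT = 0.95
DEFAULT_K = 21
DEFAULT_MAX_GAP_FRACTION = 0.80


@dataclass
class FilterReport:
    input_count: int = 0
    dropped_placed: int = 0
    dropped_short: int = 0
    dropped_contained: int = 0
    dropped_gappy: int = 0
    survivors: list[str] = field(default_factory=list)
    missing_evidence: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "dropped_placed": self.dropped_placed,
            "dropped_short": self.dropped_short,
            "dropped_contained": self.dropped_contained,
            "dropped_gappy": self.dropped_gappy,
            "survivors": list(self.survivors),
        }


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Distinct canonical k-mers (min of k-mer and its reverse
    complement); k-mers containing N are excluded."""
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        out.add(min(kmer, revcomp(kmer)))
    return out


def kmer_containment(a: GenomeSequence, b: GenomeSequence, k: int = DEFAULT_K) -> float:
    """Fraction of a's distinct canonical k-mers present in b."""
    if a.length < k:
        raise ValueError(
            f"sequence {a.name!r} shorter than k={k}: containment undefined"
        )
    ka = canonical_kmers(a.seq, k)
    if not ka:
        return 0.0
    kb = canonical_kmers(b.seq, k)
    return len(ka & kb) / len(ka)


def filter_unplaced(
    scaffolds: Sequence[GenomeSequence],
    placed_fractions: Mapping[str, float],
    min_length: int = DEFAULT_MIN_LENGTH,
    placed_fraction: float = DEFAULT_PLACED_FRACTION,
    containment: float = DEFAULT_CONTAINMENT,
    k: int = DEFAULT_K,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> tuple[list[GenomeSequence], FilterReport]:
    """Apply the cascade; returns survivors (input order) and the report.

    ``placed_fractions`` maps seq name → fraction aligned to the
    chromosome set; a missing entry counts as 0 and is logged in the
    report.
    """
    report = FilterReport(input_count=len(scaffolds))

    # stage 1: placed
    stage1: list[GenomeSequence] = []
    for s in scaffolds:
        frac = placed_fractions.get(s.name)
        if frac is None:
            report.missing_evidence.append(s.name)
            frac = 0.0
        if frac >= placed_fraction:
            report.dropped_placed += 1
        else:
            stage1.append(s)

    # stage 2: short
    stage2: list[GenomeSequence] = []
    for s in stage1:
        if s.length < min_length:
            report.dropped_short += 1
        else:
            stage2.append(s)

    # stage 3: greedy uniqueness, longest kept first
    kept: list[GenomeSequence] = []
    contained: set[str] = set()
    for s in sorted(stage2, key=lambda s: (-s.length, s.name)):
        # sequences shorter than k cannot be assessed; keep them
        if s.length >= k and any(
            kmer_containment(s, other, k) >= containment for other in kept
        ):
            contained.add(s.name)
            report.dropped_contained += 1
        else:
            kept.append(s)
    stage3 = [s for s in stage2 if s.name not in contained]

    # stage 4: gappy (strictly greater than the cutoff)
    survivors: list[GenomeSequence] = []
    for s in stage3:
        if s.seq.count("N") / s.length > max_gap_fraction:
            report.dropped_gappy += 1
        else:
            survivors.append(s)

    report.survivors = [s.name for s in survivors]
    return survivors, report
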