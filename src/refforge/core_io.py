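"""Domain types and readers/writers for the standard formats.

Coordinate conventions
----------------------
Internally every coordinate is 0-based half-open.  The two exceptions
are dictated by the file formats themselves: VCF positions are 1-based
(converted at the parsing boundary) and BED is already 0-based
half-open.  :class:`Variant.pos` keeps the VCF 1-based convention
because the voting and normalization layers speak VCF.

The sequence alphabet is strictly ``{A, C, G, T, N}``; IUPAC ambiguity
codes other than N are rejected at ingestion because the voting and
substitution logic assumes a 5-letter alphabet.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violates its declared format (bad header, bad characters...)."""


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the backbone sequence."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence; the unit of all assembly operations.

    The sequence is uppercased on construction, so downstream code can
    assume the 5-letter alphabet without re-checking case.
    """

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.name!r} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Variant:
    """A site-level difference versus the backbone, VCF-style.

    ``pos`` is the 1-based position of the first REF base.  ``source``
    names the haploid assembly the call came from (empty when unknown).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("REF and ALT must be non-empty")
        if self.ref == self.alt:
            raise ValueError(
                f"null variant at {self.chrom}:{self.pos} ({self.ref}->{self.alt})"
            )

    @property
    def end(self) -> int:
        """0-based exclusive end of the REF span."""
        return self.pos - 1 + len(self.ref)

    @property
    def start(self) -> int:
        """0-based inclusive start of the REF span."""
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class Interval:
    """A BED-style 0-based half-open interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def contains(self, pos: int) -> bool:
        """True when a 0-based position lies inside the interval."""
        return self.start <= pos < self.end


@dataclass
class HaplotypeCallset:
    """All variants of one haploid assembly versus the backbone.

    ``coverage`` optionally restricts where the haplotype is informative
    (regions of the backbone it aligns to); ``None`` means the haplotype
    covers everything.
    """

    haplotype_id: str
    variants: list[Variant]
    coverage: list[Interval] | None = None

    def __post_init__(self) -> None:
        self.variants = sorted(self.variants, key=lambda v: (v.chrom, v.pos))
        prev: Variant | None = None
        for v in self.variants:
            # records from a multiallelic split share (pos, ref); tolerated
            if (
                prev is not None
                and prev.chrom == v.chrom
                and v.start < prev.end
                and not (v.start == prev.start and v.ref == prev.ref)
            ):
                raise ValueError(
                    f"callset {self.haplotype_id!r}: overlapping REF spans at "
                    f"{v.chrom}:{prev.pos} and {v.chrom}:{v.pos}"
                )
            prev = v

    def covers(self, chrom: str, pos0: int) -> bool:
        """Does this haplotype's alignment cover 0-based ``pos0``?"""
        if self.coverage is None:
            return True
        return any(
            iv.chrom == chrom and iv.contains(pos0) for iv in self.coverage
        )


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (optionally gzipped) FASTA file.

    Sequences are uppercased, record order is preserved, and duplicate
    record names are rejected.  Errors name the offending line so large
    files can be fixed without guesswork.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if name is None:
            return
        if name in seen:
            raise FormatError(
                f"{path}: duplicate sequence name {name!r} (line {header_line})"
            )
        seen.add(name)
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: empty sequence {name!r} (line {header_line})")
        records.append(GenomeSequence(name=name, seq=seq))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                bad = set(line.upper()) - VALID_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}: non-ACGTN characters {sorted(bad)} at line {lineno}"
                    )
                chunks.append(line)
        flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    sequences: Iterable[GenomeSequence], path: str | Path, width: int = 60
) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    with open(path, "wt") as fh:
        for rec in sequences:
            fh.write(f">{rec.name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def _check_ref(
    chrom: str, pos: int, ref: str, backbone: dict[str, GenomeSequence], path
) -> None:
    if chrom not in backbone:
        raise ReferenceMismatchError(
            f"{path}: contig {chrom!r} not present in the backbone assembly"
        )
    seq = backbone[chrom].seq
    observed = seq[pos - 1 : pos - 1 + len(ref)]
    if observed != ref:
        raise ReferenceMismatchError(
            f"{path}: REF mismatch at {chrom}:{pos}: VCF says {ref!r}, "
            f"backbone has {observed!r}"
        )


def read_variants(
    path: str | Path,
    backbone: Sequence[GenomeSequence] | dict[str, GenomeSequence],
    haplotype_id: str | None = None,
) -> list[HaplotypeCallset]:
    """Read a VCF into per-haplotype callsets, verifying REF consistency.

    Two dialects are accepted: a multi-sample VCF (one sample column per
    haploid assembly → one callset per sample) and a site-only VCF with
    no sample columns (the whole file is one haplotype, named by
    ``haplotype_id`` or the file stem).  Multiallelic records are split
    into biallelic variants, each keeping the original position;
    normalization happens downstream.
    """
    from cyvcf2 import VCF

    if not isinstance(backbone, dict):
        backbone = {s.name: s for s in backbone}

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        hap = haplotype_id or Path(path).name.removesuffix(".gz").removesuffix(".vcf")
        buckets: dict[str, list[Variant]] = {hap: []}
        for rec in vcf:
            _check_ref(rec.CHROM, rec.POS, rec.REF, backbone, path)
            for alt in rec.ALT:
                buckets[hap].append(
                    Variant(rec.CHROM, rec.POS, rec.REF, alt, source=hap)
                )
    else:
        buckets = {s: [] for s in samples}
        for rec in vcf:
            _check_ref(rec.CHROM, rec.POS, rec.REF, backbone, path)
            # genotypes: allele indices per sample; haploid assemblies carry
            # a single allele but diploid-style entries are tolerated.
            for sample, gt in zip(samples, rec.genotypes):
                alleles = [a for a in gt[:-1] if isinstance(a, int) and a > 0]
                for ai in sorted(set(alleles)):
                    buckets[sample].append(
                        Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[ai - 1], source=sample)
                    )
    return [
        HaplotypeCallset(haplotype_id=hap, variants=vs) for hap, vs in buckets.items()
    ]


# ---------------------------------------------------------------------------
# BED


def read_intervals(path: str | Path) -> list[Interval]:
    """Read BED3 intervals, returned sorted by (chrom, start)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": "int64", "end": "int64"},
        )
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: malformed BED3 file: {exc}") from exc
    intervals = []
    for row in df.itertuples(index=False):
        if row.start >= row.end:
            raise ValueError(
                f"{path}: empty or inverted interval {row.chrom}:{row.start}-{row.end}"
            )
        intervals.append(Interval(row.chrom, int(row.start), int(row.end)))
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start))


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
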