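"""In-silico PCR: locate STS-marker amplicons on scaffolds.

An STS (sequence-tagged site) marker is a primer pair plus an expected
product size.  A scaffold "amplifies" the marker when the forward
primer matches on one strand, the reverse primer matches on the
opposite strand facing it, and the implied product size falls inside a
size window.  Primer matching allows a configurable number of
mismatches but requires the 3'-terminal bases to match exactly —
polymerase extension starts from the 3' end, so mismatches there
abolish amplification in a real reaction as well.

Ns in the genome never match a primer base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from refforge.core_io import GenomeSequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MAX_MISMATCH = 1
DEFAULT_THREE_PRIME_EXACT = 3
DEFAULT_SIZE_MARGIN = 50
# absolute window used when a marker carries no expected size
DEFAULT_UNKNOWN_SIZE_WINDOW = (100, 1000)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class STSMarker:
    """A primer pair with its expected product size and map positions.

    ``map_positions`` holds (map_name, group, position) triples, the
    marker's location on each genetic (cM) or radiation-hybrid (cR) map
    that carries it.  ``expected_size`` of ``None`` means the size is
    unknown and an absolute window is used instead.
    """

    marker_id: str
    fwd: str
    rev: str
    expected_size: int | None
    size_margin: int | None = None
    map_positions: tuple[tuple[str, str, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.fwd) < 10 or len(self.rev) < 10:
            raise ValueError(f"marker {self.marker_id}: primers must be >= 10 bp")
        if self.expected_size is not None and self.expected_size <= len(
            self.fwd
        ) + len(self.rev):
            raise ValueError(
                f"marker {self.marker_id}: expected size must exceed the "
                "combined primer length"
            )
        if self.size_margin is not None and self.size_margin < 0:
            raise ValueError(f"marker {self.marker_id}: negative size margin")

    def size_window(self, default_margin: int = DEFAULT_SIZE_MARGIN) -> tuple[int, int]:
        if self.expected_size is None:
            return DEFAULT_UNKNOWN_SIZE_WINDOW
        margin = self.size_margin if self.size_margin is not None else default_margin
        return (self.expected_size - margin, self.expected_size + margin)


@dataclass(frozen=True)
class MarkerHit:
    """A located amplicon: [start, end) on ``seq_name``, product = end - start."""

    marker_id: str
    seq_name: str
    start: int
    end: int
    strand: str
    mismatches: tuple[int, int]

    @property
    def product_size(self) -> int:
        return self.end - self.start


def find_primer_sites(
    seq: GenomeSequence | str,
    primer: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    three_prime_exact: int = DEFAULT_THREE_PRIME_EXACT,
) -> list[tuple[int, str, int]]:
    """All footprints of ``primer`` on both strands of ``seq``.

    Returns (start, strand, mismatch_count) triples, ``start`` being the
    0-based leftmost genomic base of the footprint.  On the ``+`` strand
    the primer reads left-to-right; on the ``-`` strand the genomic
    footprint equals the reverse complement of the primer, so the
    primer's 3' end sits at the footprint's left edge.
    """
    import numpy as np

    text = seq.seq if isinstance(seq, GenomeSequence) else seq.upper()
    m = len(primer)
    if three_prime_exact > m:
        raise ValueError("three_prime_exact exceeds the primer length")
    primer = primer.upper()
    if set(primer) - set("ACGT"):
        raise ValueError("primers must be plain ACGT (no ambiguity codes)")
    if len(text) < m:
        return []

    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    # an N in the genome matches nothing, so it simply counts as a mismatch
    # (and fails the exact 3' window) via plain byte inequality
    sites: list[tuple[int, str, int]] = []
    for strand, pat in (("+", primer), ("-", revcomp(primer))):
        p = np.frombuffer(pat.encode("ascii"), dtype=np.uint8)
        neq = windows != p
        mm = neq.sum(axis=1)
        ok = mm <= max_mismatch
        if three_prime_exact > 0:
            # 3' end sits right on '+' (primer read left→right) and left
            # on '-' (the footprint is the primer's reverse complement)
            exact = (
                ~neq[:, -three_prime_exact:].any(axis=1)
                if strand == "+"
                else ~neq[:, :three_prime_exact].any(axis=1)
            )
            ok &= exact
        for start in np.flatnonzero(ok):
            sites.append((int(start), strand, int(mm[start])))
    sites.sort()
    return sites


def epcr_scan(
    assembly: Iterable[GenomeSequence],
    markers: Sequence[STSMarker],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    three_prime_exact: int = DEFAULT_THREE_PRIME_EXACT,
    default_size_margin: int = DEFAULT_SIZE_MARGIN,
) -> list[MarkerHit]:
    """Scan an assembly for amplicons of every marker.

    A hit pairs a forward-primer site on one strand with a
    reverse-primer site on the opposite strand facing it, with the
    implied product size inside the marker's window.  All candidate
    pairings are reported (scanning is lossless); downstream anchoring
    may deduplicate.  A marker may hit several scaffolds.
    """
    hits: list[MarkerHit] = []
    for rec in assembly:
        for marker in markers:
            lo, hi = marker.size_window(default_size_margin)
            fsites = find_primer_sites(rec, marker.fwd, max_mismatch, three_prime_exact)
            rsites = find_primer_sites(rec, marker.rev, max_mismatch, three_prime_exact)
            # + orientation: fwd on +, rev on -, fwd left of rev
            for fs, fstrand, fmm in fsites:
                for rs, rstrand, rmm in rsites:
                    if fstrand == "+" and rstrand == "-":
                        start, end = fs, rs + len(marker.rev)
                        strand = "+"
                    elif fstrand == "-" and rstrand == "+":
                        start, end = rs, fs + len(marker.fwd)
                        strand = "-"
                    else:
                        continue
                    size = end - start
                    if size < max(lo, len(marker.fwd) + len(marker.rev)):
                        continue
                    if size > hi:
                        continue
                    hits.append(
                        MarkerHit(
                            marker_id=marker.marker_id,
                            seq_name=rec.name,
                            start=start,
                            end=end,
                            strand=strand,
                            mismatches=(fmm, rmm),
                        )
                    )
    hits.sort(key=lambda h: (h.seq_name, h.start, h.end, h.marker_id))
    return hits


def read_markers(marker_path, map_path=None) -> list[STSMarker]:
    """Read a marker TSV (marker_id, fwd, rev, expected_size[, size_margin])
    and optionally join a map TSV (map_name, marker_id, group, position)."""
    import pandas as pd

    df = pd.read_csv(marker_path, sep="\t", comment="#", dtype={"marker_id": str})
    positions: dict[str, list[tuple[str, str, float]]] = {}
    if map_path is not None:
        mp = pd.read_csv(map_path, sep="\t", comment="#",
                         dtype={"marker_id": str, "map_name": str, "group": str})
        for row in mp.itertuples(index=False):
            positions.setdefault(row.marker_id, []).append(
                (row.map_name, row.group, float(row.position))
            )
    markers = []
    for row in df.itertuples(index=False):
        size = getattr(row, "expected_size", None)
        size = None if size is None or pd.isna(size) else int(size)
        margin = getattr(row, "size_margin", None)
        margin = None if margin is None or pd.isna(margin) else int(margin)
        markers.append(
            STSMarker(
                marker_id=row.marker_id,
                fwd=str(row.fwd).upper(),
                rev=str(row.rev).upper(),
                expected_size=size,
                size_margin=margin,
                map_positions=tuple(positions.get(row.marker_id, ())),
            )
        )
    return markers


def write_hits(hits: Iterable[MarkerHit], path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("marker_id\tseq_name\tstart\tend\tstrand\tproduct_size\t"
                 "fwd_mismatches\trev_mismatches\n")
        for h in hits:
            fh.write(
                f"{h.marker_id}\t{h.seq_name}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.product_size}\t{h.mismatches[0]}\t{h.mismatches[1]}\n"
            )


def read_hits(path) -> list[MarkerHit]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"marker_id": str, "seq_name": str})
    return [
        MarkerHit(
            marker_id=r.marker_id,
            seq_name=r.seq_name,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            mismatches=(int(r.fwd_mismatches), int(r.rev_mismatches)),
        )
        for r in df.itertuples(index=False)
    ]


def dedupe_hits(hits: Iterable[MarkerHit]) -> list[MarkerHit]:
    """Keep one hit per (marker, scaffold): smallest mismatch total, then
    smallest product size, then leftmost."""
    best: dict[tuple[str, str], MarkerHit] = {}
    for h in hits:
        key = (h.marker_id, h.seq_name)
        cur = best.get(key)
        rank = (sum(h.mismatches), h.product_size, h.start)
        if cur is None or rank < (sum(cur.mismatches), cur.product_size, cur.start):
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.seq_name, h.start))
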