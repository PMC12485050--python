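"""Assembly statistics and population-representativeness evaluation.

Covers four independent measurements used to judge a consensus
reference:

* contiguity and gap statistics (N50, gap runs) of an assembly;
* the allele-frequency spectrum of consensus-vs-reference variants
  joined to a population AF panel, with headline counts at AF == 1.0,
  AF >= 0.99 and AF >= 0.90 — a consensus that carries population-major
  alleles concentrates its variants at high panel AF;
* callable regions from a window x sample depth matrix: a window is
  callable when enough samples have adequate but not excessive depth
  (the depth bound is half-open, ``lo <= DP < hi``; the sample fraction
  threshold is inclusive);
* SNV / indel counting, optionally restricted to regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from refforge.core_io import GenomeSequence, Interval, Variant

DEFAULT_MIN_GAP_RUN = 10
DEFAULT_BIN_WIDTH = 0.05


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_length: int
    n50: int
    gap_count: int
    gap_length: int
    max_length: int

    def as_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "total_length": self.total_length,
            "n50": self.n50,
            "gap_count": self.gap_count,
            "gap_length": self.gap_length,
            "max_length": self.max_length,
        }


def n50(lengths: Sequence[int]) -> int:
    """Length of the shortest sequence in the smallest length-sorted
    prefix whose sum reaches half the total."""
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable for non-empty input")


def assembly_stats(
    sequences: Sequence[GenomeSequence], min_gap_run: int = DEFAULT_MIN_GAP_RUN
) -> AssemblyStats:
    """Contiguity and gap statistics; gaps are maximal N runs of at
    least ``min_gap_run`` bases."""
    if not sequences:
        raise ValueError("empty assembly")
    lengths = [s.length for s in sequences]
    gap_re = re.compile("N{%d,}" % min_gap_run)
    gap_count = 0
    gap_length = 0
    for s in sequences:
        for m in gap_re.finditer(s.seq):
            gap_count += 1
            gap_length += m.end() - m.start()
    return AssemblyStats(
        n_sequences=len(sequences),
        total_length=sum(lengths),
        n50=n50(lengths),
        gap_count=gap_count,
        gap_length=gap_length,
        max_length=max(lengths),
    )


# ---------------------------------------------------------------------------
# AF spectrum


@dataclass
class AFPanel:
    """Population allele frequencies keyed by (chrom, pos, ref, alt)."""

    af: dict[tuple[str, int, str, str], float]

    def __post_init__(self) -> None:
        for key, f in self.af.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"AF out of [0,1] at {key}: {f}")

    def lookup(self, v: Variant) -> float | None:
        return self.af.get((v.chrom, v.pos, v.ref, v.alt))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AFPanel":
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"chrom": str, "pos": "int64",
                                "ref": str, "alt": str, "af": "float64"})
        af: dict[tuple[str, int, str, str], float] = {}
        for r in df.itertuples(index=False):
            key = (r.chrom, int(r.pos), r.ref, r.alt)
            if key in af:
                raise ValueError(f"{path}: duplicate panel key {key}")
            af[key] = float(r.af)
        return cls(af=af)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            fh.write("chrom\tpos\tref\talt\taf\n")
            for (chrom, pos, ref, alt), f in sorted(self.af.items()):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{f:.6f}\n")


@dataclass
class AFSpectrum:
    """Histogram over (0, 1] with right-closed bins plus headline counts."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_af_1: int
    n_af_ge_099: int
    n_af_ge_090: int
    unmatched: int

    @property
    def matched(self) -> int:
        return int(self.counts.sum())


def af_spectrum(
    variants: Iterable[Variant],
    panel: AFPanel,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> AFSpectrum:
    """Join variants to the panel and histogram their population AFs.

    Bins are right-closed on (0, 1] so AF == 1.0 lands in the last bin
    (and is additionally reported as its own headline count).  Variants
    absent from the panel are counted as unmatched and excluded from
    the histogram.
    """
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts = np.zeros(nbins, dtype=np.int64)
    n1 = n99 = n90 = unmatched = 0
    for v in variants:
        f = panel.lookup(v)
        if f is None:
            unmatched += 1
            continue
        if f > 0.0:
            # right-closed bins: (0, w], (w, 2w], ..., (1-w, 1]
            idx = min(int(np.ceil(f / bin_width)) - 1, nbins - 1)
            counts[idx] += 1
        if f == 1.0:
            n1 += 1
        if f >= 0.99:
            n99 += 1
        if f >= 0.90:
            n90 += 1
    return AFSpectrum(
        bin_edges=edges, counts=counts,
        n_af_1=n1, n_af_ge_099=n99, n_af_ge_090=n90, unmatched=unmatched,
    )


def plot_af_spectrum(spec: AFSpectrum, path: str | Path,
                     title: str = "Allele-frequency spectrum") -> None:
    """Bar plot of the AF histogram (non-reference allele frequency on
    the x axis, variant-site count on the y axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (spec.bin_edges[:-1] + spec.bin_edges[1:]) / 2
    width = spec.bin_edges[1] - spec.bin_edges[0]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, spec.counts, width=width * 0.9, color="#3b6ea5")
    ax.set_xlabel("population allele frequency")
    ax.set_ylabel("variant sites")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# callable regions


@dataclass
class DepthMatrix:
    """Per-window per-sample mean depth over fixed-width windows.

    ``windows`` is a list of (chrom, start, end); ``depths`` has shape
    (n_windows, n_samples).
    """

    windows: list[tuple[str, int, int]]
    depths: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 2 or self.depths.shape[0] != len(self.windows):
            raise ValueError("depth matrix shape disagrees with windows")
        if self.depths.shape[1] != len(self.samples) or not self.samples:
            raise ValueError("need at least one sample column")
        if (self.depths < 0).any():
            raise ValueError("negative depth")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DepthMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
        windows = [
            (str(r.chrom), int(r.start), int(r.end))
            for r in df[["chrom", "start", "end"]].itertuples(index=False)
        ]
        return cls(windows=windows, depths=df[samples].to_numpy(), samples=samples)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            fh.write("chrom\tstart\tend\t" + "\t".join(self.samples) + "\n")
            for (chrom, start, end), row in zip(self.windows, self.depths):
                vals = "\t".join(str(int(v)) for v in row)
                fh.write(f"{chrom}\t{start}\t{end}\t{vals}\n")


def callable_regions(
    dm: DepthMatrix, lo: int = 10, hi: int = 100, frac: float = 0.90
) -> list[Interval]:
    """Windows where (lo <= DP < hi) holds in at least ``frac`` of samples,
    with adjacent callable windows merged; BED-sorted output."""
    in_range = (dm.depths >= lo) & (dm.depths < hi)
    ok = in_range.mean(axis=1) >= frac

    merged: list[Interval] = []
    for (chrom, start, end), callable_ in zip(dm.windows, ok):
        if not callable_:
            continue
        if merged and merged[-1].chrom == chrom and merged[-1].end == start:
            merged[-1] = Interval(chrom, merged[-1].start, end)
        else:
            merged.append(Interval(chrom, start, end))
    return sorted(merged, key=lambda iv: (iv.chrom, iv.start))


# ---------------------------------------------------------------------------
# variant counting


def count_variants(
    variants: Iterable[Variant],
    regions: Sequence[Interval] | None = None,
) -> tuple[int, int]:
    """Count SNVs and indels, optionally restricted to regions.

    A variant is an SNV iff both alleles are single bases; anything
    else (after normalization) is an indel.  With regions given, a
    variant is counted when its 0-based start falls inside one.
    """
    snv = indel = 0
    for v in variants:
        if regions is not None:
            if not any(iv.chrom == v.chrom and iv.contains(v.start) for iv in regions):
                continue
        if v.is_snv:
            snv += 1
        else:
            indel += 1
    return snv, indel
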