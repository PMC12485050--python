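"""Deterministic synthetic data: populations, markers, mate pairs, depth.

This module fabricates every input the rest of the toolkit consumes,
with known ground truth:

* a backbone genome plus H haploid genomes carrying variants at exact,
  configured carrier counts (the stand-in for several donors' phased
  haploid assemblies) together with truth callsets and a truth AF
  panel;
* a genome with planted STS markers and per-map marker positions;
* mate-pair insert coordinates from a library with stated mean/SD,
  optionally distorted by one structural edit, for exercising the CE
  statistic;
* per-window per-sample depth matrices with designated dropout windows.

Everything is seeded: the same configuration and seed reproduce the
same bytes.  Carrier counts are assigned deterministically — the first
k haplotypes carry the alternate allele — so voting outcomes are exact;
``sampled=True`` switches to random carrier choice for stochastic
tests.  Haplotype sequences are built here by direct string editing,
independently of the consensus module's substitution engine, so
round-trip agreement between the two is a meaningful cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from refforge.anchoring import MapTable
from refforge.consensus import normalize_variant
from refforge.core_io import GenomeSequence, HaplotypeCallset, Variant
from refforge.epcr import STSMarker, revcomp
from refforge.evaluate import AFPanel, DepthMatrix
from refforge.metaplan import MatePairLibrary

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SiteSpec:
    """One planted variant site.

    ``rel_pos`` locates the site as a fraction of the whole genome;
    ``carriers`` is the number of haplotypes (out of H) carrying the
    alternate allele; ``kind`` one of snv/ins/del; ``size`` the number
    of inserted or deleted bases (ignored for SNVs).
    """

    rel_pos: float
    carriers: int
    kind: str = "snv"
    size: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.rel_pos < 1.0:
            raise ValueError("rel_pos must lie strictly inside (0, 1)")
        if self.kind not in ("snv", "ins", "del"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.size < 1:
            raise ValueError("indel size must be >= 1")


@dataclass
class PopulationConfig:
    genome_length: int = 10_000
    n_chromosomes: int = 1
    H: int = 6
    site_spec: Sequence[SiteSpec] = field(default_factory=tuple)
    gc: float = 0.41  # human-like GC content
    seed: int = 0
    sampled: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.H < 1:
            raise ValueError("need at least one haplotype")
        for s in self.site_spec:
            if not 0 <= s.carriers <= self.H:
                raise ValueError(
                    f"carrier count {s.carriers} outside [0, H={self.H}]"
                )


@dataclass
class SynthBundle:
    backbone: list[GenomeSequence]
    haplotypes: list[list[GenomeSequence]]
    truth_callsets: list[HaplotypeCallset]
    truth_af: AFPanel
    truth_variants: list[tuple[Variant, int]]  # (normalized site, carriers)


def random_genome(
    length: int, n_chromosomes: int, gc: float, rng: np.random.Generator,
    name_prefix: str = "chr",
) -> list[GenomeSequence]:
    """Random genome with the requested GC fraction, split evenly."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per = length // n_chromosomes
    out = []
    for i in range(n_chromosomes):
        n = per if i < n_chromosomes - 1 else length - per * (n_chromosomes - 1)
        seq = "".join(rng.choice(_BASES, size=n, p=p))
        out.append(GenomeSequence(name=f"{name_prefix}{i + 1}", seq=seq))
    return out


def _site_variant(
    spec: SiteSpec, backbone: list[GenomeSequence], rng: np.random.Generator
) -> Variant:
    """Materialize a site spec as a normalized variant on the backbone."""
    total = sum(s.length for s in backbone)
    offset = int(spec.rel_pos * total)
    for rec in backbone:
        if offset < rec.length:
            break
        offset -= rec.length
    # keep indels clear of the sequence edges
    offset = min(max(offset, 1), rec.length - spec.size - 2)
    pos = offset + 1  # 1-based
    seq = rec.seq
    if spec.kind == "snv":
        ref = seq[offset]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    elif spec.kind == "ins":
        ref = seq[offset]
        alt = ref + "".join(rng.choice(_BASES, size=spec.size))
    else:  # del
        ref = seq[offset : offset + spec.size + 1]
        alt = ref[0]
    v = Variant(rec.name, pos, ref, alt)
    return normalize_variant(v, backbone)


def _apply_to_sequence(seq: str, variants: Sequence[Variant]) -> str:
    """Right-to-left edit application (independent of the consensus
    engine, so the two can cross-check each other)."""
    out = seq
    for v in sorted(variants, key=lambda v: -v.pos):
        assert out[v.start : v.end] == v.ref
        out = out[: v.start] + v.alt + out[v.end :]
    return out


def simulate_population(cfg: PopulationConfig) -> SynthBundle:
    """Backbone + H haplotypes with exact per-site carrier counts.

    Raises a configuration error listing collisions when two sites'
    normalized REF spans touch or overlap (such truth sets are
    ill-posed: voting could not distinguish the sites).
    """
    rng = np.random.default_rng(cfg.seed)
    backbone = random_genome(cfg.genome_length, cfg.n_chromosomes, cfg.gc, rng)

    truth: list[tuple[Variant, int]] = []
    for spec in cfg.site_spec:
        v = _site_variant(spec, backbone, rng)
        if cfg.sampled:
            carriers = int(rng.binomial(cfg.H, spec.carriers / cfg.H))
        else:
            carriers = spec.carriers
        truth.append((v, carriers))
    truth.sort(key=lambda t: (t[0].chrom, t[0].pos))

    collisions = []
    for (a, _), (b, _) in zip(truth, truth[1:]):
        # require a one-base buffer so normalization cannot entangle sites
        if a.chrom == b.chrom and b.start <= a.end:
            collisions.append(f"{a.chrom}:{a.pos} vs {b.chrom}:{b.pos}")
    if collisions:
        raise ValueError(
            "site specs collide after normalization: " + ", ".join(collisions)
        )

    backbone_by_name = {s.name: s for s in backbone}
    haplotypes: list[list[GenomeSequence]] = []
    callsets: list[HaplotypeCallset] = []
    for h in range(cfg.H):
        variants = [v for v, carriers in truth if h < carriers]
        callsets.append(
            HaplotypeCallset(haplotype_id=f"hap{h + 1}", variants=variants)
        )
        hap_seqs = []
        for rec in backbone:
            vs = [v for v in variants if v.chrom == rec.name]
            hap_seqs.append(
                GenomeSequence(name=rec.name, seq=_apply_to_sequence(rec.seq, vs))
            )
        haplotypes.append(hap_seqs)

    panel = AFPanel(
        af={(v.chrom, v.pos, v.ref, v.alt): carriers / cfg.H for v, carriers in truth}
    )
    assert all(v.chrom in backbone_by_name for v, _ in truth)
    return SynthBundle(
        backbone=backbone,
        haplotypes=haplotypes,
        truth_callsets=callsets,
        truth_af=panel,
        truth_variants=truth,
    )


def write_population_vcfs(bundle: SynthBundle, out_dir, params_line: str | None = None
                          ) -> list[str]:
    """One minimal VCF per haplotype; returns the written paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    contigs = {s.name: s.length for s in bundle.backbone}
    for cs in bundle.truth_callsets:
        path = out_dir / f"{cs.haplotype_id}.vcf"
        with open(path, "wt") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if params_line:
                fh.write(f"##{params_line}\n")
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in cs.variants:
                fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")
        paths.append(str(path))
    return paths


# ---------------------------------------------------------------------------
# STS markers


@dataclass
class PlantedMarkers:
    genome: list[GenomeSequence]
    markers: list[STSMarker]
    map_table: MapTable
    truth_loci: list[tuple[str, str, int, int]]  # (marker_id, chrom, start, end)


def plant_sts_markers(
    genome: Sequence[GenomeSequence],
    n_markers: int,
    primer_len: int = 20,
    product_size_range: tuple[int, int] = (200, 600),
    map_names: Sequence[str] = ("genetic_a", "rh_a"),
    seed: int = 0,
) -> PlantedMarkers:
    """Write marker amplicons into a genome and record their map positions.

    Each marker overwrites its forward primer at the amplicon start and
    the reverse complement of its reverse primer at the amplicon end;
    loci never overlap.  Map positions increase monotonically with the
    amplicon coordinate along each chromosome (genetic maps in cM, RH
    maps in cR — here simply two monotone scales), so every map agrees
    with the true layout.
    """
    rng = np.random.default_rng(seed)
    genome = [GenomeSequence(s.name, s.seq) for s in genome]
    total = sum(s.length for s in genome)
    if n_markers == 0:
        return PlantedMarkers(
            genome=list(genome), markers=[],
            map_table=MapTable(rows=pd.DataFrame(
                columns=["map_name", "marker_id", "group", "position"])),
            truth_loci=[],
        )

    # allocate markers to chromosomes proportionally to length
    per_chrom = [max(1, round(n_markers * s.length / total)) for s in genome]
    while sum(per_chrom) > n_markers:
        per_chrom[int(np.argmax(per_chrom))] -= 1
    while sum(per_chrom) < n_markers:
        per_chrom[int(np.argmax([s.length for s in genome]))] += 1

    markers: list[STSMarker] = []
    loci: list[tuple[str, str, int, int]] = []
    rows: list[dict] = []
    new_seqs: list[GenomeSequence] = []
    mi = 0
    for rec, count in zip(genome, per_chrom):
        max_size = product_size_range[1]
        slot = rec.length // max(count, 1)
        if slot < max_size + 2:
            raise ValueError(
                f"insufficient space on {rec.name} for {count} markers of up "
                f"to {max_size} bp"
            )
        seq = list(rec.seq)
        starts = []
        for j in range(count):
            size = int(rng.integers(product_size_range[0], product_size_range[1] + 1))
            start = j * slot + int(rng.integers(0, slot - size))
            starts.append((start, size))
        for start, size in starts:
            mi += 1
            marker_id = f"STS{mi:04d}"
            fwd = "".join(rng.choice(_BASES, size=primer_len))
            rev = "".join(rng.choice(_BASES, size=primer_len))
            seq[start : start + primer_len] = fwd
            seq[start + size - primer_len : start + size] = revcomp(rev)
            positions = []
            for k, map_name in enumerate(map_names):
                # distinct monotone scales per map (cM-like vs cR-like)
                scale = 1.0 if k % 2 == 0 else 30.0
                pos_map = (start + size / 2) / rec.length * 100.0 * scale
                positions.append((map_name, rec.name, pos_map))
                rows.append({"map_name": map_name, "marker_id": marker_id,
                             "group": rec.name, "position": pos_map})
            markers.append(
                STSMarker(marker_id=marker_id, fwd=fwd, rev=rev,
                          expected_size=size, size_margin=None,
                          map_positions=tuple(positions))
            )
            loci.append((marker_id, rec.name, start, start + size))
        new_seqs.append(GenomeSequence(name=rec.name, seq="".join(seq)))
    table = MapTable(rows=pd.DataFrame(rows))
    return PlantedMarkers(genome=new_seqs, markers=markers,
                          map_table=table, truth_loci=loci)


# ---------------------------------------------------------------------------
# mate pairs


def simulate_matepairs(
    genome_length: int,
    library: MatePairLibrary,
    n_pairs: int,
    structural_edit: tuple[int, int] | None = None,
    seed: int = 0,
    noise: bool = False,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Insert coordinates (chrom, left, right) from a mate-pair library.

    With ``noise`` off every insert is exactly ``mu`` bases; with it on
    sizes are normal(mu, sigma), rounded, floored at 1.
    ``structural_edit=(position, size)`` models an assembly that
    deleted ``size`` bases at ``position`` (negative size: inserted):
    inserts spanning the position appear longer by ``size`` (shorter
    for insertions), exactly the signal the CE statistic detects.
    """
    rng = np.random.default_rng(seed)
    mu = int(round(library.mu))
    span = max(genome_length - mu, 1)
    left = rng.integers(0, span, size=n_pairs)
    if noise:
        sizes = np.maximum(
            np.rint(rng.normal(library.mu, library.sigma, size=n_pairs)), 1
        ).astype(np.int64)
    else:
        sizes = np.full(n_pairs, mu, dtype=np.int64)
    right = left + sizes
    if structural_edit is not None:
        pos, size = structural_edit
        spanning = (left < pos) & (right > pos)
        right = right + np.where(spanning, size, 0)
    df = pd.DataFrame({"chrom": chrom, "left": left, "right": right})
    return df.sort_values(["left", "right"], ignore_index=True)


# ---------------------------------------------------------------------------
# depth matrices


def simulate_depth(
    n_windows: int,
    n_samples: int,
    mean_depth: int = 30,
    dropout: Mapping[int, float] | None = None,
    seed: int = 0,
    window_width: int = 100,
    chrom: str = "chr1",
) -> DepthMatrix:
    """Integer depths near ``mean_depth``, clipped into [10, 100).

    ``dropout`` maps window index → fraction of samples forced below
    depth 10 in that window, which makes it fail the callable-region
    rule when the fraction in range drops under the threshold.
    """
    rng = np.random.default_rng(seed)
    depths = np.clip(
        np.rint(rng.normal(mean_depth, 5, size=(n_windows, n_samples))),
        10, 99,
    ).astype(np.int64)
    for widx, frac in (dropout or {}).items():
        k = int(np.ceil(frac * n_samples))
        cols = rng.choice(n_samples, size=k, replace=False)
        depths[widx, cols] = rng.integers(0, 10, size=k)
    windows = [
        (chrom, i * window_width, (i + 1) * window_width) for i in range(n_windows)
    ]
    samples = [f"s{i + 1}" for i in range(n_samples)]
    return DepthMatrix(windows=windows, depths=depths, samples=samples)
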