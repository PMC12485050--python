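"""Map-based scaffold anchoring: chromosome assignment, ordering,
orientation and pseudomolecule construction.

Scaffolds carry STS-marker hits; markers carry positions on one or more
genetic (cM) or radiation-hybrid (cR) maps.  Because cM and cR scales
are not commensurable, each map's positions are min-max normalized to
[0, 1] per linkage group before maps are combined by weight.  A
scaffold is assigned to the linkage group holding the largest share of
its marker weight, ordered along the chromosome by the weighted mean of
its markers' normalized positions, and oriented by the sign of the
weighted Spearman correlation between marker coordinates on the
scaffold and their map positions.

This is a deterministic heuristic replacement for the
genetic-algorithm ordering of ALLMAPS-style anchoring tools: on
mutually consistent maps it restores the true order and orientation
exactly, and its output never depends on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from refforge.core_io import GenomeSequence
from refforge.epcr import MarkerHit, revcomp

DEFAULT_GAP_LENGTH = 100


@dataclass(frozen=True)
class ScaffoldPlacement:
    """Where one scaffold sits in a pseudomolecule.

    ``order_key`` is the weighted mean normalized map position in
    [0, 1]; ``support`` the total marker weight backing the chromosome
    call; ``conflict`` the weight fraction pointing at other groups.
    """

    seq_name: str
    chrom: str
    order_key: float
    orientation: str
    support: float
    conflict: float


@dataclass
class MapTable:
    """Marker positions on one or more maps, with per-map weights.

    ``rows`` columns: map_name, marker_id, group, position.  Weights
    default to 1 per map; a zero-weight map contributes nothing.
    """

    rows: pd.DataFrame
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"map_name", "marker_id", "group", "position"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"map table lacks columns {sorted(missing)}")
        dupes = self.rows.duplicated(subset=["map_name", "marker_id"])
        if dupes.any():
            bad = self.rows[dupes].iloc[0]
            raise ValueError(
                f"duplicate map entry ({bad.map_name}, {bad.marker_id})"
            )
        if len(self.rows):
            self.rows = self.rows.astype({"position": "float64"})
            if not np.isfinite(self.rows["position"]).all():
                raise ValueError("non-finite map position")

    def weight(self, map_name: str) -> float:
        return self.weights.get(map_name, 1.0)

    def normalized(self) -> pd.DataFrame:
        """Rows with a ``norm_pos`` column: per (map, group) min-max to [0,1].

        A group with a single marker (zero span) normalizes to 0.5.
        """
        df = self.rows.copy()

        def _norm(series: pd.Series) -> pd.Series:
            lo, hi = series.min(), series.max()
            if hi == lo:
                return pd.Series(0.5, index=series.index)
            return (series - lo) / (hi - lo)

        df["norm_pos"] = df.groupby(["map_name", "group"])["position"].transform(_norm)
        df["weight"] = df["map_name"].map(self.weight)
        return df

    @classmethod
    def from_tsv(cls, path: str | Path, weights: dict[str, float] | None = None
                 ) -> "MapTable":
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"map_name": str, "marker_id": str, "group": str})
        return cls(rows=df, weights=weights or {})


def assign_chromosome(
    hits: Sequence[MarkerHit], maps: MapTable
) -> tuple[str, float, float] | None:
    """Pick the linkage group for one scaffold's marker hits.

    Returns (group, support, conflict) where support is the winning
    group's summed map weight and conflict the weight fraction on other
    groups; ``None`` (unplaced) when no hit joins a map row or when two
    groups tie for the top weight.
    """
    df = maps.normalized()
    marker_ids = {h.marker_id for h in hits}
    joined = df[df["marker_id"].isin(marker_ids)]
    joined = joined[joined["weight"] > 0]
    if joined.empty:
        return None
    by_group = joined.groupby("group")["weight"].sum().sort_index()
    total = float(by_group.sum())
    top = by_group.max()
    leaders = by_group[by_group == top]
    if len(leaders) > 1:
        return None
    group = leaders.index[0]
    support = float(top)
    return group, support, 1.0 - support / total


def _weighted_spearman_sign(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> str:
    """Orientation from the weighted rank correlation of scaffold
    coordinate vs map position; undefined correlation → '+'."""
    if len(x) < 2:
        return "+"
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    wsum = w.sum()
    mx, my = (rx * w).sum() / wsum, (ry * w).sum() / wsum
    cov = (w * (rx - mx) * (ry - my)).sum()
    vx = (w * (rx - mx) ** 2).sum()
    vy = (w * (ry - my) ** 2).sum()
    if vx == 0 or vy == 0 or cov == 0:
        return "+"
    return "+" if cov > 0 else "-"


def order_and_orient(
    hits: Sequence[MarkerHit], maps: MapTable, min_conflict: float = 0.5
) -> list[ScaffoldPlacement]:
    """Place every scaffold with mapped markers: chromosome, order, strand.

    Scaffolds whose chromosome call is tied, or whose conflicting
    marker weight reaches ``min_conflict``, are left out (unplaced).
    Output is sorted by (chrom, order_key, name).
    """
    df = maps.normalized()
    by_scaffold: dict[str, list[MarkerHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.seq_name, []).append(h)

    placements: list[ScaffoldPlacement] = []
    for seq_name in sorted(by_scaffold):
        shits = by_scaffold[seq_name]
        call = assign_chromosome(shits, maps)
        if call is None:
            continue
        group, support, conflict = call
        if conflict >= min_conflict:
            continue
        rows = df[(df["group"] == group) & (df["weight"] > 0)]
        pos_by_marker = rows.set_index(["map_name", "marker_id"])
        coords, norms, weights = [], [], []
        for h in shits:
            for (map_name, marker_id), row in pos_by_marker.iterrows():
                if marker_id != h.marker_id:
                    continue
                coords.append((h.start + h.end) / 2.0)
                norms.append(float(row["norm_pos"]))
                weights.append(float(row["weight"]))
        if not coords:
            continue
        coords_a = np.asarray(coords)
        norms_a = np.asarray(norms)
        w_a = np.asarray(weights)
        order_key = float((norms_a * w_a).sum() / w_a.sum())
        orientation = _weighted_spearman_sign(coords_a, norms_a, w_a)
        placements.append(
            ScaffoldPlacement(
                seq_name=seq_name,
                chrom=group,
                order_key=order_key,
                orientation=orientation,
                support=support,
                conflict=conflict,
            )
        )
    placements.sort(key=lambda p: (p.chrom, p.order_key, p.seq_name))
    return placements


# ---------------------------------------------------------------------------
# pseudomolecules and AGP


def build_pseudomolecules(
    placements: Sequence[ScaffoldPlacement],
    sequences: Sequence[GenomeSequence] | Mapping[str, GenomeSequence],
    gap_length: int = DEFAULT_GAP_LENGTH,
) -> tuple[list[GenomeSequence], list[tuple]]:
    """Concatenate ordered, oriented scaffolds into chromosome sequences.

    Scaffolds on the ``-`` strand are reverse-complemented; consecutive
    scaffolds are separated by ``gap_length`` Ns.  Returns the
    pseudomolecules and AGP v2.1 rows (alternating W component and U gap
    lines) that reconstruct them exactly.
    """
    if not isinstance(sequences, Mapping):
        sequences = {s.name: s for s in sequences}
    by_chrom: dict[str, list[ScaffoldPlacement]] = {}
    for p in sorted(placements, key=lambda p: (p.chrom, p.order_key, p.seq_name)):
        if p.seq_name not in sequences:
            raise KeyError(f"placement references missing sequence {p.seq_name!r}")
        by_chrom.setdefault(p.chrom, []).append(p)

    molecules: list[GenomeSequence] = []
    agp_rows: list[tuple] = []
    for chrom in sorted(by_chrom):
        parts: list[str] = []
        cursor = 0  # 0-based length so far
        part_number = 0
        for i, p in enumerate(by_chrom[chrom]):
            if i > 0 and gap_length > 0:
                part_number += 1
                agp_rows.append(
                    (chrom, cursor + 1, cursor + gap_length, part_number,
                     "U", gap_length, "scaffold", "yes", "map")
                )
                parts.append("N" * gap_length)
                cursor += gap_length
            seq = sequences[p.seq_name].seq
            if p.orientation == "-":
                seq = revcomp(seq)
            part_number += 1
            agp_rows.append(
                (chrom, cursor + 1, cursor + len(seq), part_number,
                 "W", p.seq_name, 1, len(seq), p.orientation)
            )
            parts.append(seq)
            cursor += len(seq)
        molecules.append(GenomeSequence(name=chrom, seq="".join(parts)))
    return molecules, agp_rows


def write_agp(rows: Iterable[tuple], path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        fh.write("##agp-version 2.1\n")
        for line in header_lines:
            fh.write("# " + line.rstrip("\n") + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_agp(path: str | Path) -> list[tuple]:
    rows = []
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[4] == "W":
                rows.append((f[0], int(f[1]), int(f[2]), int(f[3]), "W",
                             f[5], int(f[6]), int(f[7]), f[8]))
            else:
                rows.append((f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                             int(f[5]), f[6], f[7], f[8]))
    return rows


def agp_to_sequences(
    rows: Sequence[tuple],
    components: Sequence[GenomeSequence] | Mapping[str, GenomeSequence],
) -> list[GenomeSequence]:
    """Rebuild object sequences from AGP rows plus component sequences."""
    if not isinstance(components, Mapping):
        components = {s.name: s for s in components}
    by_obj: dict[str, list[tuple]] = {}
    order: list[str] = []
    for row in rows:
        if row[0] not in by_obj:
            order.append(row[0])
        by_obj.setdefault(row[0], []).append(row)
    out = []
    for obj in order:
        parts = []
        for row in sorted(by_obj[obj], key=lambda r: r[3]):
            if row[4] == "W":
                _, _, _, _, _, comp, cbeg, cend, orient = row
                seq = components[comp].seq[cbeg - 1 : cend]
                parts.append(revcomp(seq) if orient == "-" else seq)
            else:
                parts.append("N" * int(row[5]))
        out.append(GenomeSequence(name=obj, seq="".join(parts)))
    return out


def write_placements(placements: Iterable[ScaffoldPlacement], path: str | Path,
                     header_lines: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("seq_name\tchrom\torder_key\torientation\tsupport\tconflict\n")
        for p in placements:
            fh.write(
                f"{p.seq_name}\t{p.chrom}\t{p.order_key:.6f}\t{p.orientation}\t"
                f"{p.support:.4f}\t{p.conflict:.4f}\n"
            )
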