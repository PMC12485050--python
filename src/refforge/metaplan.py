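"""Meta-assembly planning and the compression–expansion statistic.

Meta-assembly reconciles assemblies pairwise and progressively: each
merge takes a primary assembly and corrects it with a secondary, so
``x + y`` and ``y + x`` are different operations and a plan over n
assemblies is an *ordered* full binary merge tree.  The number of
distinct plans is Catalan(n-1) x n!: 2 plans for two assemblies, 12 for
three, 120 for four (24 when restricted to the balanced two-step shape
``((w+x)+(y+z))``).

The compression–expansion (CE) statistic evaluates an assembly locus
with mate-pair inserts: for the fragments spanning a position, CE is
the z-score of their mean observed insert size against the library mean
``(mean(obs) - mu) / (sigma / sqrt(n))``.  Positive CE (expansion)
flags sequence missing from the assembly — spanning inserts appear
stretched — and negative CE (compression) flags extra sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_CE_WINDOW = 100
DEFAULT_MIN_SPANNING = 5


@dataclass(frozen=True)
class MergePlan:
    """An ordered binary merge expression; left operand is the primary."""

    tree: tuple  # nested (left, right) tuples with str leaves

    def serialize(self) -> str:
        def _s(node) -> str:
            if isinstance(node, str):
                return node
            return f"({_s(node[0])}+{_s(node[1])})"

        return _s(self.tree)

    def leaves(self) -> list[str]:
        out: list[str] = []

        def _walk(node) -> None:
            if isinstance(node, str):
                out.append(node)
            else:
                _walk(node[0])
                _walk(node[1])

        _walk(self.tree)
        return out

    def __str__(self) -> str:
        return self.serialize()


def _tree_shapes(labels: Sequence[str]):
    """Every ordered full binary tree over labels in the given order."""
    if len(labels) == 1:
        yield labels[0]
        return
    for i in range(1, len(labels)):
        for left in _tree_shapes(labels[:i]):
            for right in _tree_shapes(labels[i:]):
                yield (left, right)


def enumerate_plans(labels: Sequence[str], shape: str = "all") -> list[MergePlan]:
    """All distinct ordered merge plans over the given assembly labels.

    ``shape="all"`` enumerates every ordered full binary merge tree over
    every leaf order; ``shape="balanced"`` (4 labels only) restricts to
    the two-step ``((w+x)+(y+z))`` shape.  Output is deduplicated by
    serialization and sorted lexicographically, so it is deterministic.
    """
    if not 2 <= len(labels) <= 6:
        raise ValueError("plan enumeration supports 2..6 assemblies")
    if len(set(labels)) != len(labels):
        raise ValueError("assembly labels must be unique")
    plans: dict[str, MergePlan] = {}
    if shape == "all":
        for perm in itertools.permutations(labels):
            for tree in _tree_shapes(perm):
                p = MergePlan(tree=tree)
                plans[p.serialize()] = p
    elif shape == "balanced":
        if len(labels) != 4:
            raise ValueError("balanced shape requires exactly 4 assemblies")
        for w, x, y, z in itertools.permutations(labels):
            p = MergePlan(tree=((w, x), (y, z)))
            plans[p.serialize()] = p
    else:
        raise ValueError(f"unknown shape {shape!r} (expected 'all' or 'balanced')")
    return [plans[k] for k in sorted(plans)]


def select_best(candidates: Sequence[tuple[str, int, int]]) -> str:
    """Pick the meta-assembly with the longest scaffold, then the fewest
    scaffolds, then the lexicographically smallest label.

    Candidates are (label, max scaffold length, scaffold count).
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    return min(candidates, key=lambda c: (-c[1], c[2], c[0]))[0]


@dataclass
class CEProfile:
    """Per-window CE z-scores along one assembly sequence.

    ``ce`` is NaN where fewer than ``min_spanning`` inserts span the
    window midpoint (undefined, not zero).
    """

    chrom: str
    positions: np.ndarray  # window midpoints
    ce: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "window_mid": self.positions,
             "n": self.n, "ce": self.ce}
        )


@dataclass(frozen=True)
class MatePairLibrary:
    """Insert-size model of a mate-pair library: mean and SD in bases."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("library mu and sigma must both be positive")


def ce_statistic(
    inserts: pd.DataFrame,
    library: MatePairLibrary,
    window: int = DEFAULT_CE_WINDOW,
    min_spanning: int = DEFAULT_MIN_SPANNING,
) -> list[CEProfile]:
    """Compute CE per window from spanning mate-pair inserts.

    ``inserts`` needs columns chrom, left, right (0-based fragment
    ends, right exclusive of nothing — simply the two outer mapping
    coordinates; size = right - left).  For each window midpoint p the
    spanning set is the inserts with left < p and right > p, and
    CE(p) = (mean(size) - mu) / (sigma / sqrt(n)).
    """
    required = {"chrom", "left", "right"}
    if not required <= set(inserts.columns):
        raise ValueError(f"insert table lacks columns {sorted(required - set(inserts.columns))}")
    if (inserts["right"] <= inserts["left"]).any():
        raise ValueError("every insert must satisfy right > left")

    profiles = []
    for chrom, grp in inserts.groupby("chrom", sort=True):
        left = grp["left"].to_numpy(dtype=np.int64)
        right = grp["right"].to_numpy(dtype=np.int64)
        sizes = (right - left).astype(np.float64)
        lo, hi = int(left.min()), int(right.max())
        mids = np.arange(lo + window // 2, hi, window, dtype=np.float64)

        # range-update via difference arrays: insert i covers midpoints
        # strictly inside (left_i, right_i)
        idx_first = np.searchsorted(mids, left, side="right")
        idx_last = np.searchsorted(mids, right, side="left")  # exclusive
        n_diff = np.zeros(len(mids) + 1)
        s_diff = np.zeros(len(mids) + 1)
        valid = idx_first < idx_last
        np.add.at(n_diff, idx_first[valid], 1.0)
        np.add.at(n_diff, idx_last[valid], -1.0)
        np.add.at(s_diff, idx_first[valid], sizes[valid])
        np.add.at(s_diff, idx_last[valid], -sizes[valid])
        n = np.cumsum(n_diff)[:-1]
        total = np.cumsum(s_diff)[:-1]

        with np.errstate(invalid="ignore", divide="ignore"):
            mean = total / n
            ce = (mean - library.mu) / (library.sigma / np.sqrt(n))
        ce[n < min_spanning] = np.nan
        profiles.append(
            CEProfile(chrom=str(chrom), positions=mids, ce=ce,
                      n=n.astype(np.int64))
        )
    return profiles


def ce_at(
    inserts: pd.DataFrame, chrom: str, pos: float, library: MatePairLibrary,
    min_spanning: int = DEFAULT_MIN_SPANNING,
) -> tuple[float, int]:
    """CE at a single position (brute evaluation of the spanning set)."""
    grp = inserts[inserts["chrom"] == chrom]
    span = grp[(grp["left"] < pos) & (grp["right"] > pos)]
    n = len(span)
    if n < min_spanning or n == 0:
        return float("nan"), n
    sizes = (span["right"] - span["left"]).to_numpy(dtype=float)
    return float((sizes.mean() - library.mu) / (library.sigma / sqrt(n))), n


def read_inserts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"chrom": str, "left": "int64", "right": "int64"})


def write_ce_profiles(profiles: Iterable[CEProfile], path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("chrom\twindow_mid\tn\tce\n")
        for p in profiles:
            for mid, n, ce in zip(p.positions, p.n, p.ce):
                ce_s = "NA" if np.isnan(ce) else f"{ce:.4f}"
                fh.write(f"{p.chrom}\t{int(mid)}\t{int(n)}\t{ce_s}\n")
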