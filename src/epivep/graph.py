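"""Partner graphs and alignment-region planning.

A partner graph links residue positions of one protein by unordered pairs of
two kinds: *structural* (spatially close C-alpha atoms) and *coevolutionary*
(highly coupled alignment columns).  The graph is the substrate of the
partners score: a position inherits evidence from the clinical labels of its
partners.

This module also plans the overlapping sequence windows used to build local
multiple-sequence alignments for coupling inference on long proteins, and
merges adjacent windows when the alignment is deep enough or the coupling
distribution is informative enough to support a larger region.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

KINDS = ("structural", "coevolutionary")


@dataclasses.dataclass
class PartnerGraph:
    """Unordered residue pairs of a single protein, tagged by kind.

    Pairs are stored as (min, max) tuples; for coevolutionary pairs seen in
    both orders the maximum coupling probability is retained.
    """

    protein: str = ""
    _pairs: dict = dataclasses.field(default_factory=dict)  # kind -> {(i,j): prob|None}

    def add(self, i: int, j: int, kind: str, probability: Optional[float] = None) -> None:
        if kind not in KINDS:
            raise ValueError(f"unknown pair kind {kind!r}")
        if i == j:
            raise ValueError(f"self-pair at position {i}")
        key = (min(i, j), max(i, j))
        bucket = self._pairs.setdefault(kind, {})
        prev = bucket.get(key)
        if prev is None or (probability is not None and probability > prev):
            bucket[key] = probability

    def pairs(self, kind: Optional[str] = None) -> list[tuple[int, int]]:
        if kind is not None:
            return sorted(self._pairs.get(kind, {}))
        merged = set()
        for bucket in self._pairs.values():
            merged.update(bucket)
        return sorted(merged)

    def probability(self, i: int, j: int) -> Optional[float]:
        key = (min(i, j), max(i, j))
        return self._pairs.get("coevolutionary", {}).get(key)

    def partners_of(self, position: int, kind: Optional[str] = None) -> list[int]:
        out = set()
        for i, j in self.pairs(kind):
            if i == position:
                out.add(j)
            elif j == position:
                out.add(i)
        return sorted(out)

    def positions(self, kind: Optional[str] = None) -> list[int]:
        out = set()
        for i, j in self.pairs(kind):
            out.update((i, j))
        return sorted(out)

    def n_pairs(self, kind: Optional[str] = None) -> int:
        return len(self.pairs(kind))

    def subgraph(self, kind: str) -> "PartnerGraph":
        return PartnerGraph(protein=self.protein,
                            _pairs={kind: dict(self._pairs.get(kind, {}))})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein": self.protein, "i": i, "j": j, "kind": kind}
            for kind in KINDS
            for (i, j) in sorted(self._pairs.get(kind, {}))
        ]
        return pd.DataFrame(rows, columns=["protein", "i", "j", "kind"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PartnerGraph":
        df = pd.read_csv(Path(path), sep="\t")
        graph = cls(protein=str(df["protein"].iloc[0]) if len(df) else "")
        for row in df.itertuples(index=False):
            graph.add(int(row.i), int(row.j), kind=str(row.kind))
        return graph


def coupling_partners(
    pairs: "pd.DataFrame | str | Path",
    probability_cutoff: float = 0.6,
    protein: str = "",
) -> PartnerGraph:
    """Select strongly coupled residue pairs from a coupling list.

    ``pairs`` is a CSV file (header columns ``i``, ``j``, ``probability``,
    coupling-inference style) or an equivalent DataFrame.  Pairs with
    probability >= cutoff are kept (default 0.6, the threshold at which
    downstream partner-score sensitivity and specificity balance);
    duplicates in either order collapse onto the larger probability.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.read_csv(Path(pairs))
    required = {"i", "j", "probability"}
    if not required <= set(pairs.columns):
        raise ValueError(f"coupling table needs columns {sorted(required)}")
    graph = PartnerGraph(protein=protein)
    for idx, row in enumerate(pairs.itertuples(index=False)):
        p = float(row.probability)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"row {idx}: probability {p} outside [0, 1]")
        if p >= probability_cutoff:
            graph.add(int(row.i), int(row.j), kind="coevolutionary", probability=p)
    return graph


@dataclasses.dataclass
class TileRegion:
    """A 1-based inclusive sequence window with optional alignment statistics."""

    start: int
    end: int
    n_sequences: Optional[int] = None
    ec_skewness: Optional[float] = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def plan_tiles(length: int, tile: int = 100, step: int = 50) -> list[TileRegion]:
    """Plan overlapping alignment windows over a sequence.

    Windows follow the boundary convention 1-100, 50-150, 100-200, …: the
    first window starts at 1, each later one at a multiple of ``step``, and
    every window ends ``tile`` residues after that multiple.  The last window
    is truncated (or extended) to end exactly at ``length``, so the windows
    always cover [1, length] with no gaps.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if step >= tile:
        raise ValueError(f"step ({step}) must be smaller than tile ({tile})")
    if length <= tile:
        return [TileRegion(1, length)]
    regions = [TileRegion(1, tile)]
    k = 1
    while True:
        start, end = k * step, k * step + tile
        if end >= length:
            regions.append(TileRegion(start, length))
            break
        regions.append(TileRegion(start, end))
        k += 1
    return regions


def _criterion(region: TileRegion) -> bool:
    if region.n_sequences is None or region.ec_skewness is None:
        raise ValueError(f"region {region.start}-{region.end} is missing statistics")
    return region.n_sequences > 5 * region.length or region.ec_skewness > 1.0


def _conservative_combine(a: TileRegion, b: TileRegion) -> TileRegion:
    # stand-in evaluator: without re-running an aligner, credit the merged
    # region with the weaker of its parts' statistics
    for r in (a, b):
        if r.n_sequences is None or r.ec_skewness is None:
            raise ValueError(f"region {r.start}-{r.end} is missing statistics")
    return TileRegion(
        start=a.start,
        end=b.end,
        n_sequences=min(a.n_sequences, b.n_sequences),
        ec_skewness=min(a.ec_skewness, b.ec_skewness),
    )


def merge_tiles(
    regions: Sequence[TileRegion],
    evaluate: Optional[Callable[[TileRegion, TileRegion], TileRegion]] = None,
) -> list[TileRegion]:
    """Merge adjacent windows while the merged region stays well supported.

    Two adjacent regions merge when the candidate merged region has either an
    alignment deeper than 5x its length or a coupling-score skewness above 1.
    Candidate statistics come from ``evaluate(left, right)`` — normally a
    closure over an alignment pipeline; by default the weaker parent
    statistics stand in.  The left-to-right sweep repeats to a fixpoint, so
    the result is deterministic.
    """
    if evaluate is None:
        evaluate = _conservative_combine
    current = list(regions)
    changed = True
    while changed:
        changed = False
        merged: list[TileRegion] = []
        i = 0
        while i < len(current):
            if i + 1 < len(current):
                candidate = evaluate(current[i], current[i + 1])
                if _criterion(candidate):
                    merged.append(candidate)
                    i += 2
                    changed = True
                    continue
            merged.append(current[i])
            i += 1
        current = merged
    return current
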