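"""UMI deduplication, prefix-tree binning, singleton rescue, bin filters.

Mate-pairs sharing an observed UMI form a bin; a prefix tree over the
deduplicated UMIs supports exact and one-mismatch lookups. Sequencer
errors inside the UMI spawn satellite bins, so a single-member bin is
rescued into its true bin when exactly one bin sits at Hamming distance 1
and that destination already holds more than 5 mate-pairs. Bins then pass
size (>= 6 mate-pairs), strand-presence, and 1:3-3:1 template:polymerized
ratio filters before consensus calling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .ingest import PairObservations


@dataclass
class UmiBin:
    """Mate-pairs sharing one (possibly corrected) canonical UMI."""

    bin_id: int
    umi: str
    members: list[int] = field(default_factory=list)  # pair indices
    n_template: int = 0
    n_polymerized: int = 0

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def ratio(self) -> float:
        """template:polymerized count ratio (inf when polymerized absent)."""
        if self.n_polymerized == 0:
            return float("inf")
        return self.n_template / self.n_polymerized


class UmiTrie:
    """Fixed-depth prefix tree over UMI strings with 1-mismatch search."""

    def __init__(self, umis=()):
        self.root: dict = {}
        self.length: int | None = None
        for u in umis:
            self.insert(u)

    def insert(self, umi: str) -> None:
        if self.length is None:
            self.length = len(umi)
        elif len(umi) != self.length:
            raise ValueError("mixed UMI lengths in one index")
        node = self.root
        for ch in umi:
            node = node.setdefault(ch, {})

    def contains(self, umi: str) -> bool:
        node = self.root
        for ch in umi:
            node = node.get(ch)
            if node is None:
                return False
        return True

    def within_one(self, umi: str) -> list[str]:
        """All stored UMIs at Hamming distance <= 1, sorted."""
        hits: list[str] = []
        stack = [(self.root, 0, 0, "")]
        while stack:
            node, depth, mism, prefix = stack.pop()
            if depth == len(umi):
                hits.append(prefix)
                continue
            for ch, child in node.items():
                m = mism + (ch != umi[depth])
                if m <= 1:
                    stack.append((child, depth + 1, m, prefix + ch))
        return sorted(hits)


def _recount(b: UmiBin, obs: PairObservations) -> None:
    poly = obs.strand_is_poly[b.members]
    b.n_polymerized = int(poly.sum())
    b.n_template = len(b.members) - b.n_polymerized


def build_bins(obs: PairObservations) -> list[UmiBin]:
    """One bin per distinct observed UMI, ids dense in first-seen order."""
    bins: list[UmiBin] = []
    index: dict[str, UmiBin] = {}
    for i, umi in enumerate(obs.umi_strings):
        b = index.get(umi)
        if b is None:
            b = UmiBin(bin_id=len(bins), umi=umi)
            bins.append(b)
            index[umi] = b
        b.members.append(i)
    for b in bins:
        _recount(b, obs)
    return bins


def rebin_singletons(
    obs: PairObservations,
    bins: list[UmiBin],
    destination_min: int = 5,
) -> tuple[list[UmiBin], Counter]:
    """Apply the singleton rescue rule in one pass over the initial state.

    A single-member bin moves its mate-pair into the unique bin at Hamming
    distance 1, provided that destination held more than ``destination_min``
    mate-pairs before any move; moves never cascade. Mate-pairs are
    conserved.
    """
    stats: Counter = Counter()
    pre_sizes = {b.umi: b.size for b in bins}
    by_umi = {b.umi: b for b in bins}
    trie = UmiTrie(by_umi)
    moved_from: set[str] = set()
    for b in sorted(bins, key=lambda x: x.bin_id):
        if b.size != 1:
            continue
        neighbours = [u for u in trie.within_one(b.umi) if u != b.umi]
        if len(neighbours) != 1:
            stats["singleton_ambiguous" if len(neighbours) > 1 else "singleton_no_neighbour"] += 1
            continue
        dest = by_umi[neighbours[0]]
        if pre_sizes[dest.umi] <= destination_min:
            stats["singleton_destination_too_small"] += 1
            continue
        dest.members.extend(b.members)
        moved_from.add(b.umi)
        stats["singleton_rebinned"] += 1
    out = [b for b in bins if b.umi not in moved_from]
    for b in out:
        _recount(b, obs)
    return out, stats


def filter_bins(
    bins: list[UmiBin],
    min_pairs: int = 6,
    ratio_bounds: tuple[float, float] = (1.0 / 3.0, 3.0),
) -> tuple[list[UmiBin], Counter]:
    """Retain bins usable for strand comparison.

    Requires >= ``min_pairs`` mate-pairs, at least one pair of each strand
    class, and a template:polymerized ratio within ``ratio_bounds``
    (inclusive; default 1:3 to 3:1).
    """
    stats: Counter = Counter()
    retained: list[UmiBin] = []
    for b in bins:
        if b.size < min_pairs:
            stats["too_few_pairs"] += 1
        elif b.n_template == 0 or b.n_polymerized == 0:
            stats["missing_strand"] += 1
        elif not (ratio_bounds[0] - 1e-12 <= b.ratio <= ratio_bounds[1] + 1e-12):
            stats["strand_ratio"] += 1
        else:
            retained.append(b)
            continue
    stats["retained"] = len(retained)
    return retained, stats


def bin_table(bins: list[UmiBin]) -> "np.ndarray":
    import pandas as pd

    return pd.DataFrame(
        {
            "bin_id": [b.bin_id for b in bins],
            "umi": [b.umi for b in bins],
            "n_template": [b.n_template for b in bins],
            "n_polymerized": [b.n_polymerized for b in bins],
            "size": [b.size for b in bins],
        }
    )
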