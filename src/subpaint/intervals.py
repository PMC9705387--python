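"""Interval algebra on single sequences: merging overlapping alignment
ranges to disjoint unions, coverage fractions, alignment-weighted identity,
and gap bridging for repeat-region statistics.

Merging overlapping alignments "down to a single range" is the primitive the
whole coverage analysis rests on, so it is implemented directly (sort +
sweep) rather than through a tree structure: inputs arrive in bulk and are
merged once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignio import AlignmentRecord, ContigSet

__all__ = [
    "IntervalSet",
    "merge_intervals",
    "intersect",
    "subtract",
    "covered_fraction",
    "weighted_identity",
    "plain_mean_identity",
    "bridge_and_count",
]


@dataclass
class IntervalSet:
    """Disjoint, sorted, non-adjacent 0-based half-open intervals."""

    seq_id: str = ""
    intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def validate(self) -> None:
        prev_end = None
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty interval ({s},{e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"intervals overlap or touch at {s}")
            prev_end = e


def merge_intervals(raw, seq_id: str = "") -> IntervalSet:
    """Union of raw (start, end) pairs as a disjoint sorted IntervalSet.

    Touching intervals (end == next start) are merged.  Empty or reversed
    inputs are errors.
    """
    pairs = sorted((int(s), int(e)) for s, e in raw)
    for s, e in pairs:
        if e <= s:
            raise ValueError(f"interval ({s},{e}) has end <= start")
    merged: list[tuple[int, int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return IntervalSet(seq_id=seq_id, intervals=merged)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Intersection of two merged interval sets (linear sweep)."""
    out: list[tuple[int, int]] = []
    i = j = 0
    ai, bi = a.intervals, b.intervals
    while i < len(ai) and j < len(bi):
        s = max(ai[i][0], bi[j][0])
        e = min(ai[i][1], bi[j][1])
        if s < e:
            out.append((s, e))
        if ai[i][1] <= bi[j][1]:
            i += 1
        else:
            j += 1
    return IntervalSet(seq_id=a.seq_id, intervals=out)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases in ``a`` not in ``b``."""
    out: list[tuple[int, int]] = []
    j = 0
    bi = b.intervals
    for s, e in a.intervals:
        cur = s
        while j < len(bi) and bi[j][1] <= cur:
            j += 1
        k = j
        while k < len(bi) and bi[k][0] < e:
            if bi[k][0] > cur:
                out.append((cur, bi[k][0]))
            cur = max(cur, bi[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return IntervalSet(seq_id=a.seq_id, intervals=out)


def covered_fraction(
    records: list[AlignmentRecord],
    side: str,
    lengths: ContigSet,
):
    """Fraction of each sequence covered by merged alignment ranges.

    ``side`` selects which coordinates to merge: ``"query"`` or
    ``"reference"``.  Returns ``(per_seq, aggregate)`` where ``per_seq`` maps
    sequence id -> covered fraction for every sequence in ``lengths``
    (sequences without alignments get 0.0) and ``aggregate`` is total covered
    bp over total bp — the genome-wide "percent that mapped".  Records naming
    sequences absent from ``lengths`` are an error.
    """
    if side not in ("query", "reference"):
        raise ValueError(f"side must be 'query' or 'reference', got {side!r}")
    by_seq: dict[str, list[tuple[int, int]]] = {}
    unknown = set()
    for r in records:
        if side == "query":
            name, span = r.query_id, (r.query_start, r.query_end)
        else:
            name, span = r.ref_id, (r.ref_start, r.ref_end)
        if name not in lengths:
            unknown.add(name)
            continue
        by_seq.setdefault(name, []).append(span)
    if unknown:
        raise ValueError(f"records reference unknown sequences: {sorted(unknown)}")
    per_seq: dict[str, float] = {}
    covered_total = 0
    for name, length in lengths.lengths.items():
        cov = merge_intervals(by_seq.get(name, []), seq_id=name).total_bp if name in by_seq else 0
        cov = min(cov, length)
        per_seq[name] = cov / length
        covered_total += cov
    aggregate = covered_total / lengths.total_bp if len(lengths) else 0.0
    return per_seq, aggregate


def weighted_identity(records: list[AlignmentRecord]) -> float:
    """Alignment-column-weighted mean identity, in percent.

    Weighting by aligned columns keeps short spurious hits from dominating
    the genome-wide figure; the unweighted mean is available via
    :func:`plain_mean_identity`.  Empty input is an error, not 0.
    """
    if not records:
        raise ValueError("weighted_identity of an empty record list is undefined")
    wsum = sum(r.aligned_columns for r in records)
    if wsum == 0:
        raise ValueError("all records have zero aligned columns")
    return sum(r.identity_pct * r.aligned_columns for r in records) / wsum


def plain_mean_identity(records: list[AlignmentRecord]) -> float:
    """Unweighted mean of per-alignment identity values, in percent."""
    if not records:
        raise ValueError("mean identity of an empty record list is undefined")
    return sum(r.identity_pct for r in records) / len(records)


def bridge_and_count(
    regions: IntervalSet,
    max_gap: int = 10,
    min_region: int = 20_000,
) -> tuple[IntervalSet, int]:
    """Close short gaps between intervals and count large resulting regions.

    Gaps strictly shorter than ``max_gap`` are bridged (a gap of exactly
    ``max_gap`` survives).  Returns the bridged set and the number of bridged
    regions strictly longer than ``min_region``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    regions.validate()
    bridged: list[tuple[int, int]] = []
    for s, e in regions.intervals:
        if bridged and s - bridged[-1][1] < max_gap:
            bridged[-1] = (bridged[-1][0], e)
        else:
            bridged.append((s, e))
    count = sum(1 for s, e in bridged if e - s > min_region)
    return IntervalSet(seq_id=regions.seq_id, intervals=bridged), count
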