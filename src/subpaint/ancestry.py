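"""Per-contig subgenome ancestry calling and chimera (recombinant-contig)
detection for assemblies of interspecific hybrids.

Each assembly contig is aligned separately to the two progenitor references
(A and B).  Because the progenitors are typically >90% identical, most
sequence aligns to *both* references; raw coverage alone cannot discriminate
ancestry.  Bases are therefore credited competitively: a base covered by
both references counts for the one aligned with the higher local identity,
and for both only when the identities are within a small margin (the
"mapped almost equally" case).  A contig whose credited bp alternates
between ancestors in long runs is flagged recombinant — on a hybrid of two
largely isolated subgenomes an excess of such contigs indicates assembly
chimerism rather than biology.

Also here: depth-based single/multi-copy partitioning (collapsed-repeat
detection), concordance of unplaced contigs with the painted chromosomes,
chromosome-number-normalized recombinant-rate comparison, and whole-genome
coverage/identity summaries.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

from .alignio import AlignmentRecord, ContigSet
from .intervals import (
    IntervalSet,
    covered_fraction,
    intersect,
    merge_intervals,
    plain_mean_identity,
    weighted_identity,
)

__all__ = [
    "AncestryParams",
    "AncestryCall",
    "DepthRecord",
    "CATEGORIES",
    "call_contig_ancestry",
    "call_assembly",
    "detect_recombinant",
    "disambiguate_equal",
    "ancestry_bp_totals",
    "normalized_recomb_ratio",
    "depth_partition",
    "unplaced_concordance",
    "compare_genomes",
]

CATEGORIES = ("A_dominant", "B_dominant", "equal", "recombinant", "unaligned")


@dataclass(frozen=True)
class AncestryParams:
    """Thresholds of the ancestry classifier.

    equal_tolerance
        Relative bp-imbalance below which a contig "maps almost equally" to
        both ancestors: |bp_A - bp_B| / (bp_A + bp_B) <= tau.
    recomb_min_segment_bp / recomb_min_segment_frac
        An alternating ancestry run only counts toward a recombinant call if
        it spans at least max(min_bp, frac * aligned length).
    min_aligned_frac
        Minimum fraction of the contig that must align to either reference
        for any call; below it the contig is "unaligned".
    depth_multi_threshold
        A contig is multi-copy (collapsed) when its depth exceeds this
        multiple of the length-weighted median depth.
    identity_margin_pct
        Bases covered by both references are credited to the higher-identity
        side unless the identities are within this margin (percentage
        points), in which case both sides are credited.
    window_bp
        Window size for the run-detection majority vote along the contig.
    """

    equal_tolerance: float = 0.10
    recomb_min_segment_frac: float = 0.05
    recomb_min_segment_bp: int = 10_000
    min_aligned_frac: float = 0.10
    depth_multi_threshold: float = 1.5
    identity_margin_pct: float = 1.0
    window_bp: int = 1_000

    def __post_init__(self) -> None:
        if not 0 <= self.equal_tolerance < 1:
            raise ValueError("equal_tolerance must be in [0,1)")
        for name in ("recomb_min_segment_frac", "min_aligned_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.recomb_min_segment_bp < 0 or self.window_bp <= 0:
            raise ValueError("segment/window sizes must be positive")
        if self.depth_multi_threshold <= 0:
            raise ValueError("depth_multi_threshold must be > 0")


@dataclass
class AncestryCall:
    """Ancestry assignment of one contig."""

    contig_id: str
    length: int
    bp_A: int
    bp_B: int
    category: str
    segments: list[tuple[int, int, str]] = field(default_factory=list)
    breakpoints: list[int] = field(default_factory=list)
    disambiguated: bool = False


@dataclass(frozen=True)
class DepthRecord:
    """Median mapped-read depth of one contig."""

    contig_id: str
    depth: float
    length: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")


# ---------------------------------------------------------------------------
# competitive base crediting
# ---------------------------------------------------------------------------

def _best_identity_profile(records: list[AlignmentRecord], bounds: list[int]):
    """Max identity per atomic piece (None where uncovered).

    ``bounds`` is the sorted list of atomic breakpoints; returns a list of
    per-piece best identities of length len(bounds)-1.
    """
    n = len(bounds) - 1
    best: list[float | None] = [None] * n
    for r in records:
        i = bisect.bisect_left(bounds, r.query_start)
        while i < n and bounds[i] < r.query_end:
            cur = best[i]
            if cur is None or r.identity_pct > cur:
                best[i] = r.identity_pct
            i += 1
    return best


def _credit(aln_A, aln_B, length: int, params: AncestryParams):
    """Piecewise competitive crediting of contig bases to ancestors.

    Returns (credit_A, credit_B, excl_A, excl_B) as IntervalSets on the
    contig.  credit_X = bases where X aligns and is not beaten by the other
    ancestor by more than the identity margin; excl_X = bases credited to X
    alone.
    """
    cuts = {0, length}
    for r in list(aln_A) + list(aln_B):
        cuts.add(min(r.query_start, length))
        cuts.add(min(r.query_end, length))
    bounds = sorted(cuts)
    best_a = _best_identity_profile(aln_A, bounds)
    best_b = _best_identity_profile(aln_B, bounds)
    margin = params.identity_margin_pct
    ca, cb, xa, xb = [], [], [], []
    for i in range(len(bounds) - 1):
        piece = (bounds[i], bounds[i + 1])
        a, b = best_a[i], best_b[i]
        a_credit = a is not None and (b is None or a >= b - margin)
        b_credit = b is not None and (a is None or b >= a - margin)
        if a_credit:
            ca.append(piece)
        if b_credit:
            cb.append(piece)
        if a_credit and not b_credit:
            xa.append(piece)
        if b_credit and not a_credit:
            xb.append(piece)
    return (
        merge_intervals(ca),
        merge_intervals(cb),
        merge_intervals(xa),
        merge_intervals(xb),
    )


def _window_bp(iset: IntervalSet, length: int, window: int) -> list[int]:
    """Covered bp of ``iset`` inside each window tiling [0, length)."""
    n = (length + window - 1) // window
    out = [0] * n
    for s, e in iset:
        w = s // window
        while w * window < e:
            lo = max(s, w * window)
            hi = min(e, (w + 1) * window)
            out[w] += hi - lo
            w += 1
    return out


# ---------------------------------------------------------------------------
# recombinant detection and per-contig calling
# ---------------------------------------------------------------------------

def detect_recombinant(
    aln_A: list[AlignmentRecord],
    aln_B: list[AlignmentRecord],
    length: int,
    params: AncestryParams = AncestryParams(),
):
    """Test one contig for alternating-ancestry structure.

    The contig is tiled into windows; each window is labelled by the majority
    of ancestor-exclusive credited bp (A vs B; ties and empty windows are
    unlabelled and do not break runs).  Maximal same-label runs spanning at
    least ``max(recomb_min_segment_bp, frac * aligned_length)`` qualify; the
    contig is recombinant iff qualifying runs include both ancestries.
    Breakpoints are placed at the midpoint between consecutive qualifying
    runs of different ancestry.

    Returns ``(is_recombinant, segments, breakpoints)`` where segments tile
    [0, length) split at the breakpoints and carry the run ancestry
    ("A"/"B"); segments are empty when not recombinant.
    """
    _check_one_contig(aln_A, aln_B)
    credit_a, credit_b, excl_a, excl_b = _credit(aln_A, aln_B, length, params)
    aligned = merge_intervals(list(credit_a) + list(credit_b)).total_bp
    return _detect_from_exclusive(excl_a, excl_b, aligned, length, params)


def _detect_from_exclusive(excl_a, excl_b, aligned_bp, length, params):
    window = params.window_bp
    wa = _window_bp(excl_a, length, window)
    wb = _window_bp(excl_b, length, window)
    runs: list[list] = []  # [label, first_window, last_window]
    for i, (a, b) in enumerate(zip(wa, wb)):
        if a == b:
            continue
        label = "A" if a > b else "B"
        if runs and runs[-1][0] == label:
            runs[-1][2] = i
        else:
            runs.append([label, i, i])
    min_span = max(params.recomb_min_segment_bp, params.recomb_min_segment_frac * aligned_bp)
    qual = []
    for label, w0, w1 in runs:
        span = min((w1 + 1) * window, length) - w0 * window
        if span >= min_span:
            qual.append((label, w0 * window, min((w1 + 1) * window, length)))
    labels = {q[0] for q in qual}
    if len(qual) < 2 or len(labels) < 2:
        return False, [], []
    breakpoints = []
    for (la, _sa, ea), (lb, sb, _eb) in zip(qual, qual[1:]):
        if la != lb:
            breakpoints.append((ea + sb) // 2)
    # tile the contig at the breakpoints; each tile carries the ancestry of
    # the qualifying run(s) lying inside it
    segments = []
    edges = [0] + breakpoints + [length]
    for s, e in zip(edges, edges[1:]):
        label = None
        for q in qual:
            if s <= q[1] and q[2] <= e:
                label = q[0]
                break
        if label is None:
            label = segments[-1][2] if segments else qual[0][0]
        segments.append((s, e, label))
    return True, segments, breakpoints


def call_contig_ancestry(
    aln_A: list[AlignmentRecord],
    aln_B: list[AlignmentRecord],
    length: int,
    params: AncestryParams = AncestryParams(),
    contig_id: str | None = None,
) -> AncestryCall:
    """Classify one contig from its alignments to the two progenitors.

    bp_A and bp_B are competitively credited base totals (see module
    docstring).  Categories, in order of precedence: unaligned (too little
    of the contig aligns at all), recombinant (alternating-ancestry runs),
    equal (|bp_A - bp_B|/(bp_A + bp_B) within tolerance), else the dominant
    ancestor.
    """
    cid = _check_one_contig(aln_A, aln_B, contig_id)
    credit_a, credit_b, excl_a, excl_b = _credit(aln_A, aln_B, length, params)
    bp_a = min(credit_a.total_bp, length)
    bp_b = min(credit_b.total_bp, length)
    aligned = merge_intervals(list(credit_a) + list(credit_b)).total_bp
    call = AncestryCall(contig_id=cid, length=length, bp_A=bp_a, bp_B=bp_b, category="unaligned")
    if length <= 0:
        raise ValueError("contig length must be positive")
    if max(bp_a, bp_b) / length < params.min_aligned_frac:
        return call
    is_rec, segments, breakpoints = _detect_from_exclusive(
        excl_a, excl_b, aligned, length, params
    )
    if is_rec:
        call.category = "recombinant"
        call.segments = segments
        call.breakpoints = breakpoints
        return call
    if bp_a + bp_b > 0 and abs(bp_a - bp_b) / (bp_a + bp_b) <= params.equal_tolerance:
        call.category = "equal"
    else:
        call.category = "A_dominant" if bp_a > bp_b else "B_dominant"
    return call


def call_assembly(
    aln_A: list[AlignmentRecord],
    aln_B: list[AlignmentRecord],
    lengths: ContigSet,
    params: AncestryParams = AncestryParams(),
) -> dict[str, AncestryCall]:
    """Classify every contig in ``lengths``; contigs without alignments are
    called unaligned."""
    by_a: dict[str, list] = {}
    by_b: dict[str, list] = {}
    for r in aln_A:
        by_a.setdefault(r.query_id, []).append(r)
    for r in aln_B:
        by_b.setdefault(r.query_id, []).append(r)
    calls = {}
    for cid, length in lengths.lengths.items():
        calls[cid] = call_contig_ancestry(
            by_a.get(cid, []), by_b.get(cid, []), length, params, contig_id=cid
        )
    return calls


def _check_one_contig(aln_A, aln_B, contig_id=None) -> str:
    ids = {r.query_id for r in aln_A} | {r.query_id for r in aln_B}
    if contig_id is not None:
        ids.add(contig_id)
    if len(ids) > 1:
        raise ValueError(f"records from multiple contigs: {sorted(ids)}")
    return next(iter(ids)) if ids else ""


# ---------------------------------------------------------------------------
# second-pass disambiguation of "equal" contigs
# ---------------------------------------------------------------------------

def disambiguate_equal(
    calls: dict[str, AncestryCall],
    aln_A_second: list[AlignmentRecord],
    aln_B_second: list[AlignmentRecord],
    params: AncestryParams = AncestryParams(),
) -> dict[str, AncestryCall]:
    """Re-examine "equal" contigs with a second, differently-parameterized
    mapping pass.

    For each equal contig, bp tallies are recomputed on the second-pass
    alignments; if the imbalance now exceeds the tolerance the contig is
    reassigned to the dominant ancestor and flagged ``disambiguated``.
    Contigs with no second-pass alignments stay equal with a warning.
    Returns a new call dict; the input is not mutated.
    """
    by_a: dict[str, list] = {}
    by_b: dict[str, list] = {}
    for r in aln_A_second:
        by_a.setdefault(r.query_id, []).append(r)
    for r in aln_B_second:
        by_b.setdefault(r.query_id, []).append(r)
    out: dict[str, AncestryCall] = {}
    for cid, call in calls.items():
        if call.category != "equal":
            out[cid] = call
            continue
        a2, b2 = by_a.get(cid, []), by_b.get(cid, [])
        if not a2 and not b2:
            warnings.warn(f"no second-pass alignments for equal contig {cid}", stacklevel=2)
            out[cid] = call
            continue
        credit_a, credit_b, _, _ = _credit(a2, b2, call.length, params)
        bp_a, bp_b = credit_a.total_bp, credit_b.total_bp
        if bp_a + bp_b > 0 and abs(bp_a - bp_b) / (bp_a + bp_b) > params.equal_tolerance:
            new = AncestryCall(
                contig_id=cid,
                length=call.length,
                bp_A=call.bp_A,
                bp_B=call.bp_B,
                category="A_dominant" if bp_a > bp_b else "B_dominant",
                disambiguated=True,
            )
            out[cid] = new
        else:
            out[cid] = call
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def ancestry_bp_totals(calls) -> dict[str, dict[str, int]]:
    """Per-category contig counts and summed contig bp.

    The categories partition the assembly: summed bp over categories equals
    the summed contig lengths.
    """
    vals = calls.values() if isinstance(calls, dict) else calls
    totals = {cat: {"n": 0, "bp": 0} for cat in CATEGORIES}
    for call in vals:
        totals[call.category]["n"] += 1
        totals[call.category]["bp"] += call.length
    return totals


def normalized_recomb_ratio(
    n_recomb_1: int, n_chrom_1: int, n_recomb_2: int, n_chrom_2: int
) -> float:
    """Ratio of per-chromosome recombinant-contig rates between two
    assemblies: (n1/c1) / (n2/c2)."""
    if n_chrom_1 <= 0 or n_chrom_2 <= 0:
        raise ValueError("chromosome counts must be positive")
    if n_recomb_2 == 0:
        raise ValueError("second assembly has zero recombinant contigs; ratio undefined")
    return (n_recomb_1 / n_chrom_1) / (n_recomb_2 / n_chrom_2)


def depth_partition(
    depths: list[DepthRecord],
    params: AncestryParams = AncestryParams(),
) -> tuple[float, int, int]:
    """Partition assembly bp into single- and multi-copy by read depth.

    The genome-wide reference point is the length-weighted median of
    per-contig depths (the depth at which half the assembly bp lies in
    contigs no deeper).  A contig is multi-copy (collapsed) iff its depth
    strictly exceeds ``depth_multi_threshold *`` that median; ties are
    single-copy.  Returns (median_depth, single_copy_bp, multi_copy_bp).
    """
    if not depths:
        raise ValueError("depth_partition of empty input")
    total = sum(d.length for d in depths)
    half = total / 2
    acc = 0
    median = None
    for d in sorted(depths, key=lambda d: d.depth):
        acc += d.length
        if acc >= half:
            median = d.depth
            break
    cutoff = params.depth_multi_threshold * median
    multi = sum(d.length for d in depths if d.depth > cutoff)
    return median, total - multi, multi


def unplaced_concordance(
    unplaced_calls,
    unplaced_to_scaffold_alns: list[AlignmentRecord],
    placed_ancestry_map: dict[str, list[tuple[int, int, str]]],
):
    """How much unplaced sequence aligns to the pseudochromosomes, and how
    often its ancestry agrees with the ancestry painted there.

    ``placed_ancestry_map`` maps chromosome -> painted (start, end, category)
    blocks.  Returns ``(aligned_fraction, same_ancestry_fraction)``.  The
    aligned fraction is merged aligned unplaced bp over total unplaced bp.
    The concordance term considers only A/B-dominant unplaced contigs over
    A/B-painted target bases (equal/recombinant/unaligned excluded on both
    sides); it is None when that denominator is empty.
    """
    calls = unplaced_calls if isinstance(unplaced_calls, dict) else {
        c.contig_id: c for c in unplaced_calls
    }
    total_unplaced = sum(c.length for c in calls.values())
    if total_unplaced == 0:
        raise ValueError("no unplaced contigs supplied")
    # merged query-side footprints per contig
    by_contig_q: dict[str, list[tuple[int, int]]] = {}
    by_contig_chrom_r: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in unplaced_to_scaffold_alns:
        if r.query_id not in calls:
            raise ValueError(f"alignment for unknown unplaced contig {r.query_id}")
        by_contig_q.setdefault(r.query_id, []).append((r.query_start, r.query_end))
        by_contig_chrom_r.setdefault((r.query_id, r.ref_id), []).append(
            (r.ref_start, r.ref_end)
        )
    aligned_bp = sum(
        min(merge_intervals(v).total_bp, calls[cid].length)
        for cid, v in by_contig_q.items()
    )
    aligned_fraction = aligned_bp / total_unplaced

    painted = {
        chrom: {
            side: merge_intervals(
                [(s, e) for s, e, cat in blocks if cat == side + "_dominant"]
            )
            for side in ("A", "B")
        }
        for chrom, blocks in placed_ancestry_map.items()
    }
    num = denom = 0
    for (cid, chrom), spans in by_contig_chrom_r.items():
        cat = calls[cid].category
        if cat not in ("A_dominant", "B_dominant") or chrom not in painted:
            continue
        own = cat[0]  # "A" or "B"
        footprint = merge_intervals(spans)
        for side in ("A", "B"):
            overlap = intersect(footprint, painted[chrom][side]).total_bp
            denom += overlap
            if side == own:
                num += overlap
    concordance = num / denom if denom else None
    return aligned_fraction, concordance


def compare_genomes(
    records: list[AlignmentRecord],
    query_lengths: ContigSet,
    ref_lengths: ContigSet,
) -> dict:
    """Whole-genome comparison summary from one genome aligned to another.

    Reports the fraction of each genome covered by merged alignment ranges
    and the average nucleotide identity, both alignment-length weighted and
    as a plain mean over alignments (the two can differ; both are given).
    """
    q_per, q_agg = _covered_or_zero(records, "query", query_lengths)
    r_per, r_agg = _covered_or_zero(records, "reference", ref_lengths)
    return {
        "query_covered_fraction": q_agg,
        "ref_covered_fraction": r_agg,
        "weighted_identity": weighted_identity(records) if records else None,
        "plain_mean_identity": plain_mean_identity(records) if records else None,
        "n_alignments": len(records),
        "query_covered_per_seq": q_per,
        "ref_covered_per_seq": r_per,
    }


def _covered_or_zero(records, side, lengths):
    if not records:
        return {name: 0.0 for name in lengths.lengths}, 0.0
    return covered_fraction(records, side, lengths)
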