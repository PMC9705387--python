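"""Report builders: chromosome ancestry paintings, repeat-landscape
summaries, and gene-family tallies.

Painting palette (fixed; documented here and in docs/methods.md):

======================  =================  ===========
category                color              itemRgb
======================  =================  ===========
A_dominant              teal               0,128,128
B_dominant              green              34,139,34
equal                   pink               255,105,180
recombinant             purple             128,0,128
unaligned               grey               160,160,160
======================  =================  ===========
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .alignio import AgpPlacement, AlignmentRecord, RepeatHit
from .ancestry import AncestryCall
from .intervals import bridge_and_count, merge_intervals

__all__ = [
    "PALETTE",
    "PaintingBlock",
    "PaintingTrack",
    "RepeatClassSummary",
    "build_painting",
    "build_two_track_painting",
    "painting_ancestry_map",
    "repeat_summary",
    "repeat_grand_total",
    "family_count_table",
    "plot_painting",
]

PALETTE = {
    "A_dominant": "0,128,128",
    "B_dominant": "34,139,34",
    "equal": "255,105,180",
    "recombinant": "128,0,128",
    "unaligned": "160,160,160",
}


@dataclass(frozen=True)
class PaintingBlock:
    chrom_start: int
    chrom_end: int
    name: str
    category: str
    rgb: str


@dataclass
class PaintingTrack:
    """Colored blocks along one chromosome (sorted, non-overlapping)."""

    chrom: str
    blocks: list[PaintingBlock] = field(default_factory=list)

    @property
    def total_bp(self) -> int:
        return sum(b.chrom_end - b.chrom_start for b in self.blocks)


@dataclass
class RepeatClassSummary:
    """Masked-bp accounting for one repeat class."""

    repeat_class: str
    element_count: int
    masked_bp: int
    pct_genome: float


def build_painting(
    agp: list[AgpPlacement],
    calls,
    min_display_bp: int = 100_000,
) -> list[PaintingTrack]:
    """Paint each chromosome by the ancestry category of its placed contigs.

    Components shorter than ``min_display_bp`` are omitted from the display
    (they remain in any bp totals computed from the calls themselves).
    Components without a call are painted "unaligned" with a warning.
    Track order follows first appearance in the AGP; blocks are sorted.
    """
    call_map = calls if isinstance(calls, dict) else {c.contig_id: c for c in calls}
    tracks: dict[str, PaintingTrack] = {}
    missing = []
    for p in agp:
        track = tracks.setdefault(p.chrom, PaintingTrack(chrom=p.chrom))
        if p.is_gap:
            continue
        if p.chrom_end - p.chrom_start < min_display_bp:
            continue
        call = call_map.get(p.component_id)
        if call is None:
            missing.append(p.component_id)
            category = "unaligned"
        else:
            category = call.category
        track.blocks.append(
            PaintingBlock(p.chrom_start, p.chrom_end, p.component_id, category, PALETTE[category])
        )
    if missing:
        warnings.warn(
            f"{len(missing)} placed contigs without ancestry calls painted as "
            f"unaligned (first: {missing[:3]})",
            stacklevel=2,
        )
    for t in tracks.values():
        t.blocks.sort(key=lambda b: b.chrom_start)
    return list(tracks.values())


def build_two_track_painting(
    agp: list[AgpPlacement],
    placed_calls,
    unplaced_alignments: list[AlignmentRecord],
    unplaced_calls,
    min_display_bp: int = 100_000,
) -> dict[str, tuple[PaintingTrack, PaintingTrack]]:
    """Per chromosome: (bottom, top) tracks.

    Bottom is the scaffolded-contig painting; top shows unplaced contigs at
    their merged alignment footprints on the chromosome, colored by the
    unplaced contig's own ancestry category.
    """
    bottom = {t.chrom: t for t in build_painting(agp, placed_calls, min_display_bp)}
    unplaced_map = (
        unplaced_calls
        if isinstance(unplaced_calls, dict)
        else {c.contig_id: c for c in unplaced_calls}
    )
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in unplaced_alignments:
        spans.setdefault((r.ref_id, r.query_id), []).append((r.ref_start, r.ref_end))
    top: dict[str, PaintingTrack] = {chrom: PaintingTrack(chrom=chrom) for chrom in bottom}
    for (chrom, cid), ranges in sorted(spans.items()):
        call = unplaced_map.get(cid)
        if call is None:
            continue
        track = top.setdefault(chrom, PaintingTrack(chrom=chrom))
        for s, e in merge_intervals(ranges):
            track.blocks.append(
                PaintingBlock(s, e, cid, call.category, PALETTE[call.category])
            )
    for t in top.values():
        t.blocks.sort(key=lambda b: (b.chrom_start, b.chrom_end, b.name))
    return {chrom: (bottom[chrom], top.get(chrom, PaintingTrack(chrom=chrom))) for chrom in bottom}


def painting_ancestry_map(tracks: list[PaintingTrack]) -> dict[str, list[tuple[int, int, str]]]:
    """Collapse painting tracks to chrom -> (start, end, category) blocks,
    the form consumed by ancestry.unplaced_concordance."""
    return {
        t.chrom: [(b.chrom_start, b.chrom_end, b.category) for b in t.blocks]
        for t in tracks
    }


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

def repeat_summary(
    hits: list[RepeatHit],
    genome_size: int,
    bridge_gap: int = 10,
    big_region_bp: int = 20_000,
):
    """Summarize a repeat annotation.

    Per class: element count and masked bp after merging that class's hits
    per target (a base hit twice by one class counts once).  The union view
    merges across classes, bridges gaps shorter than ``bridge_gap`` and
    counts bridged regions larger than ``big_region_bp`` — per-class totals
    can exceed the union because classes overlap, so both are reported.

    Returns ``(summaries, union_masked_bp, union_pct, regions_gt_big)`` with
    summaries in order of first appearance plus percentages of
    ``genome_size``.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    order: list[str] = []
    per_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    counts: dict[str, int] = {}
    all_by_target: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if h.repeat_class not in per_class:
            order.append(h.repeat_class)
            per_class[h.repeat_class] = {}
            counts[h.repeat_class] = 0
        counts[h.repeat_class] += 1
        per_class[h.repeat_class].setdefault(h.target_id, []).append((h.start, h.end))
        all_by_target.setdefault(h.target_id, []).append((h.start, h.end))
    summaries = []
    for cls in order:
        masked = sum(
            merge_intervals(v).total_bp for v in per_class[cls].values()
        )
        summaries.append(
            RepeatClassSummary(cls, counts[cls], masked, 100.0 * masked / genome_size)
        )
    union_masked = 0
    regions_gt = 0
    for target, spans in all_by_target.items():
        merged = merge_intervals(spans, seq_id=target)
        bridged, n_big = bridge_and_count(merged, max_gap=bridge_gap, min_region=big_region_bp)
        union_masked += bridged.total_bp
        regions_gt += n_big
    return summaries, union_masked, 100.0 * union_masked / genome_size, regions_gt


def repeat_grand_total(summaries: list[RepeatClassSummary]) -> tuple[int, int]:
    """Grand-total row of a repeat table: (total elements, total masked bp),
    computed as the sum of the per-class rows."""
    return (
        sum(s.element_count for s in summaries),
        sum(s.masked_bp for s in summaries),
    )


# ---------------------------------------------------------------------------
# gene-family tallies
# ---------------------------------------------------------------------------

def family_count_table(assignments) -> tuple[list[tuple[str, int]], int]:
    """Count gene-family assignments.

    ``assignments`` is an iterable of (gene_id, family).  Returns
    ``(rows, total)`` with rows ordered by first appearance of each family
    and total equal to the number of assignments.
    """
    order: list[str] = []
    counts: dict[str, int] = {}
    total = 0
    for _gene, fam in assignments:
        if fam not in counts:
            order.append(fam)
            counts[fam] = 0
        counts[fam] += 1
        total += 1
    return [(fam, counts[fam]) for fam in order], total


# ---------------------------------------------------------------------------
# optional static plot
# ---------------------------------------------------------------------------

def plot_painting(tracks, path, chrom_lengths=None):
    """Horizontal-bar painting figure, one row per chromosome (PNG/PDF/SVG
    by extension).  Needs matplotlib; import deferred so the plotting
    dependency stays optional."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tracks = list(tracks)
    fig_height = max(2.0, 0.45 * len(tracks) + 0.8)
    fig, ax = plt.subplots(figsize=(10, fig_height))
    for row, track in enumerate(tracks):
        for b in track.blocks:
            rgb = tuple(int(c) / 255 for c in b.rgb.split(","))
            ax.barh(row, b.chrom_end - b.chrom_start, left=b.chrom_start,
                    height=0.7, color=rgb, edgecolor="none")
        if chrom_lengths and track.chrom in chrom_lengths:
            ax.plot([0, chrom_lengths[track.chrom]], [row - 0.42, row - 0.42],
                    color="0.7", lw=0.5)
    ax.set_yticks(range(len(tracks)))
    ax.set_yticklabels([t.chrom for t in tracks])
    ax.set_xlabel("position (bp)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
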