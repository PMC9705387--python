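"""Synthetic hybrid-genome test bed.

Generates, from a single seed: a pair of progenitor genomes at a chosen
nucleotide divergence, a "hybrid assembly" of contigs copied from the
progenitors — some pure, some deliberately chimeric with known breakpoints —
truth alignments that stand in for aligner output, collapsed-contig depth
profiles, and an AGP placing a subset of contigs on pseudochromosomes.
Everything downstream (parsers, interval algebra, ancestry calling,
painting) can therefore be exercised end to end with exact ground truth and
no external data.

Also here: a deliberately minimal model of consensus long-read correction,
quantifying how often majority-vote correction by identity-recruited short
reads overwrites a read's true subgenome allele with the homoeologous one —
the mechanism by which correcting noisy long reads in a hybrid whose
subgenomes are less diverged than the read error rate produces chimeric
reads.  It is a probabilistic cartoon of that mechanism, not a
reimplementation of any assembler's correction stage.

Default divergence is 0.057, matching progenitor genomes that align at
~94.3% identity.  Genomes default to 1 Mb over 5 chromosomes: large enough
for binomial bounds on realized divergence to be tight, small enough for
seconds-scale tests.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignio import AgpPlacement, AlignmentRecord, ContigSet
from .ancestry import DepthRecord

__all__ = [
    "SimParams",
    "CorrectionModel",
    "TruthContig",
    "TruthTable",
    "simulate_progenitors",
    "simulate_hybrid_assembly",
    "export_truth_alignments",
    "export_progenitor_alignments",
    "export_unplaced_truth_alignments",
    "simulate_depth",
    "evaluate_recovery",
    "make_agp",
    "simulate_dataset",
    "SimDataset",
    "simulate_consensus_correction",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Conditions of one simulated hybrid-assembly experiment.

    divergence is the iid substitution rate separating the progenitors
    (0.057 ~ 94.3% identity); chimera_fraction the probability a contig is
    stitched across progenitors; contigs are uniform in length between
    ``contig_length`` bounds and must fit within one chromosome.  Chimeric
    segments are re-drawn until all exceed ``chimera_min_segment_bp``.
    ``prob_ancestor_a`` reflects the unequal subgenome dosage of a cross in
    which one parent contributes two chromosome sets and the other one.
    """

    genome_length: int = 1_000_000
    n_chromosome_segments: int = 5
    divergence: float = 0.057
    indel_rate: float = 0.0
    n_contigs: int = 200
    contig_length: tuple[int, int] = (120_000, 180_000)
    chimera_fraction: float = 0.20
    max_breakpoints: int = 3
    chimera_min_segment_bp: int = 5_000
    collapsed_fraction: float = 0.10
    prob_ancestor_a: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "indel_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0,1)")
        for name in ("chimera_fraction", "collapsed_fraction", "prob_ancestor_a"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.genome_length <= 0 or self.n_chromosome_segments <= 0:
            raise ValueError("genome_length and n_chromosome_segments must be positive")
        lo, hi = self.contig_length
        if not 0 < lo <= hi:
            raise ValueError("contig_length bounds must satisfy 0 < min <= max")
        if hi > self.genome_length // self.n_chromosome_segments:
            raise ValueError("contigs must fit within one chromosome segment")
        if not 1 <= self.max_breakpoints <= 3:
            raise ValueError("max_breakpoints must be in 1..3")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class CorrectionModel:
    """Parameters of the consensus-correction chimerization model.

    e: long-read error rate (short-read errors are e/10); c_a/c_b: short
    reads per subgenome covering a site; m: recruitment margin — a short
    read is recruited when its window identity to the long read is at least
    1 - e - m; w: window length in bp.
    """

    e: float = 0.12
    c_a: int = 6
    c_b: int = 6
    m: float = 0.05
    w: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.e < 0.5:
            raise ValueError("e must be in [0, 0.5)")
        if self.c_a < 0 or self.c_b < 0:
            raise ValueError("coverages must be >= 0")
        if self.m < 0 or self.w <= 0:
            raise ValueError("m must be >= 0 and w > 0")


@dataclass
class TruthContig:
    """Planted truth for one contig: source window, ancestry segments on the
    contig (tiling [0, length)), breakpoints, copy number."""

    contig_id: str
    length: int
    chrom: str
    source_start: int
    segments: list[tuple[int, int, str]]
    breakpoints: list[int] = field(default_factory=list)
    copy_number: int = 1

    @property
    def is_chimeric(self) -> bool:
        return len({anc for _s, _e, anc in self.segments}) > 1

    @property
    def dominant_ancestry(self) -> str:
        bp = {"A": 0, "B": 0}
        for s, e, anc in self.segments:
            bp[anc] += e - s
        return "A" if bp["A"] >= bp["B"] else "B"


class TruthTable:
    """Per-contig planted truth; iterable, indexable by contig id."""

    def __init__(self, contigs: list[TruthContig]):
        self.contigs = {c.contig_id: c for c in contigs}
        if len(self.contigs) != len(contigs):
            raise ValueError("duplicate contig ids in truth")
        for c in contigs:
            edges = [c.segments[0][0]] + [e for _s, e, _a in c.segments]
            if c.segments[0][0] != 0 or c.segments[-1][1] != c.length:
                raise ValueError(f"{c.contig_id}: segments do not tile the contig")
            for (s1, e1, _), (s2, e2, _) in zip(c.segments, c.segments[1:]):
                if s2 != e1:
                    raise ValueError(f"{c.contig_id}: segments not contiguous")

    def __iter__(self):
        return iter(self.contigs.values())

    def __len__(self):
        return len(self.contigs)

    def __getitem__(self, cid: str) -> TruthContig:
        return self.contigs[cid]

    def chimeric_ids(self) -> set[str]:
        return {c.contig_id for c in self if c.is_chimeric}

    def to_rows(self) -> list[dict]:
        return [
            {
                "contig_id": c.contig_id,
                "length": c.length,
                "chrom": c.chrom,
                "source_start": c.source_start,
                "copy_number": c.copy_number,
                "segments": ";".join(f"{s}:{e}:{a}" for s, e, a in c.segments),
                "breakpoints": ",".join(str(b) for b in c.breakpoints),
            }
            for c in self
        ]


# ---------------------------------------------------------------------------
# progenitor genomes
# ---------------------------------------------------------------------------

def simulate_progenitors(params: SimParams):
    """Generate progenitor genomes A and B and the variant truth list.

    B is derived from A by iid substitutions at the divergence rate (the
    substituted base drawn uniformly from the three alternatives) and, when
    ``indel_rate`` > 0, short (1-3 bp) insertions/deletions.  Returns
    ``(genome_A, genome_B, variants)`` as ContigSets carrying sequences and
    a list of variant dicts (chrom, pos on A, kind, detail).
    """
    rng = np.random.default_rng(params.seed)
    n_chrom = params.n_chromosome_segments
    chrom_len = params.genome_length // n_chrom
    a_seqs: dict[str, str] = {}
    b_seqs: dict[str, str] = {}
    variants: list[dict] = []
    for i in range(n_chrom):
        chrom = f"chr{i + 1}"
        a_codes = rng.integers(0, 4, size=chrom_len, dtype=np.uint8)
        b_codes = a_codes.copy()
        sub_mask = rng.random(chrom_len) < params.divergence
        idx = np.flatnonzero(sub_mask)
        # shift by 1-3 places in base space => uniform over the 3 alternatives
        b_codes[idx] = (a_codes[idx] + rng.integers(1, 4, size=idx.size)) % 4
        for pos in idx:
            variants.append(
                {"chrom": chrom, "pos": int(pos), "kind": "sub",
                 "ref": int(a_codes[pos]), "alt": int(b_codes[pos])}
            )
        if params.indel_rate > 0:
            b_codes, indel_vars = _apply_indels(chrom, b_codes, params.indel_rate, rng)
            variants.extend(indel_vars)
        a_seqs[chrom] = _BASES[a_codes].tobytes().decode()
        b_seqs[chrom] = _BASES[b_codes].tobytes().decode()
    genome_a = ContigSet({c: len(s) for c, s in a_seqs.items()}, a_seqs)
    genome_b = ContigSet({c: len(s) for c, s in b_seqs.items()}, b_seqs)
    return genome_a, genome_b, variants


def _apply_indels(chrom, codes, rate, rng):
    mask = rng.random(codes.size) < rate
    positions = np.flatnonzero(mask)
    out = []
    variants = []
    prev = 0
    for pos in positions:
        out.append(codes[prev:pos])
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # insertion into B
            ins = rng.integers(0, 4, size=length, dtype=np.uint8)
            out.append(codes[pos:pos + 1])
            out.append(ins)
            variants.append({"chrom": chrom, "pos": int(pos), "kind": "ins", "len": length})
            prev = pos + 1
        else:  # deletion from B
            variants.append({"chrom": chrom, "pos": int(pos), "kind": "del", "len": length})
            prev = pos + length
    out.append(codes[prev:])
    return np.concatenate(out), variants


def _b_offset_fn(variants, chrom):
    """Map A coordinates to B coordinates on one chromosome (piecewise shift
    from the planted indels; identity when indel-free)."""
    events = sorted(
        (v["pos"], v["len"] if v["kind"] == "ins" else -v["len"])
        for v in variants
        if v["chrom"] == chrom and v["kind"] in ("ins", "del")
    )
    if not events:
        return lambda x: x
    positions = [p for p, _ in events]
    shifts = np.cumsum([s for _, s in events])

    def fn(x: int) -> int:
        import bisect

        i = bisect.bisect_right(positions, x)
        return x + (int(shifts[i - 1]) if i else 0)

    return fn


# ---------------------------------------------------------------------------
# hybrid assembly
# ---------------------------------------------------------------------------

def simulate_hybrid_assembly(genomes, params: SimParams, variants=None):
    """Copy contigs out of the progenitors, planting chimeras and collapsed
    copies; returns ``(contigs, truth)``.

    Each contig takes a uniform window on a random chromosome.  With
    probability ``chimera_fraction`` it is stitched across the progenitors
    at 1..max_breakpoints uniform positions (re-drawn until every segment
    exceeds the minimum), alternating ancestry from a random starting side;
    otherwise it is a pure copy of one progenitor (ancestor A with
    probability ``prob_ancestor_a``).  Collapsed contigs (planted copy
    number 2-3) model depth-inflated repeats.
    """
    genome_a, genome_b = genomes
    rng = np.random.default_rng(_derive_seed(params.seed, 1))
    offset_fns = {
        chrom: (_b_offset_fn(variants, chrom) if variants else (lambda x: x))
        for chrom in genome_a.lengths
    }
    chroms = sorted(genome_a.lengths)
    lo, hi = params.contig_length
    contigs_seq: dict[str, str] = {}
    rows: list[TruthContig] = []
    for i in range(params.n_contigs):
        cid = f"ctg{i + 1:05d}"
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        chrom_len = genome_a.lengths[chrom]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, chrom_len - length + 1))
        if rng.random() < params.chimera_fraction:
            k = int(rng.integers(1, params.max_breakpoints + 1))
            breakpoints = _draw_breakpoints(rng, length, k, params.chimera_min_segment_bp)
            first = "A" if rng.random() < 0.5 else "B"
            edges = [0] + breakpoints + [length]
            segments = [
                (s, e, first if j % 2 == 0 else ("B" if first == "A" else "A"))
                for j, (s, e) in enumerate(zip(edges, edges[1:]))
            ]
        else:
            anc = "A" if rng.random() < params.prob_ancestor_a else "B"
            breakpoints = []
            segments = [(0, length, anc)]
        copy_number = 1
        if rng.random() < params.collapsed_fraction:
            copy_number = int(rng.integers(2, 4))
        parts = []
        for s, e, anc in segments:
            if anc == "A":
                parts.append(genome_a.sequences[chrom][start + s:start + e])
            else:
                fn = offset_fns[chrom]
                parts.append(genome_b.sequences[chrom][fn(start + s):fn(start + e)])
        contigs_seq[cid] = "".join(parts)
        rows.append(
            TruthContig(cid, len(contigs_seq[cid]), chrom, start,
                        segments, breakpoints, copy_number)
        )
    contigs = ContigSet({c: len(s) for c, s in contigs_seq.items()}, contigs_seq)
    return contigs, TruthTable(rows)


def _draw_breakpoints(rng, length, k, min_seg, max_tries=1000):
    for _ in range(max_tries):
        pts = sorted(int(p) for p in rng.integers(1, length, size=k))
        edges = [0] + pts + [length]
        if len(set(pts)) == k and all(b - a >= min_seg for a, b in zip(edges, edges[1:])):
            return pts
    raise RuntimeError(
        f"could not place {k} breakpoints with {min_seg} bp segments in {length} bp"
    )


# ---------------------------------------------------------------------------
# truth alignments
# ---------------------------------------------------------------------------

def export_truth_alignments(truth: TruthTable, genome_a: ContigSet,
                            genome_b: ContigSet, variants=None):
    """Idealized aligner output: one record per (segment x progenitor).

    Each planted segment yields a 100%-identity record to its source
    progenitor and a record to the other progenitor at the identity implied
    by the planted divergence, computed exactly by comparing the two
    subsequences.  Record coordinates partition exactly at the planted
    breakpoints, so parsers and the ancestry caller can be validated against
    this list.  Returns ``(aln_to_A, aln_to_B)``.
    """
    offset_fns = {
        chrom: (_b_offset_fn(variants, chrom) if variants else (lambda x: x))
        for chrom in genome_a.lengths
    }
    aln_a: list[AlignmentRecord] = []
    aln_b: list[AlignmentRecord] = []
    for c in truth:
        fn = offset_fns[c.chrom]
        for s, e, anc in c.segments:
            a_lo, a_hi = c.source_start + s, c.source_start + e
            b_lo, b_hi = fn(a_lo), fn(a_hi)
            sub_a = genome_a.sequences[c.chrom][a_lo:a_hi]
            sub_b = genome_b.sequences[c.chrom][b_lo:b_hi]
            cross_idy, cross_cols = _pair_identity(sub_a, sub_b)
            if anc == "A":
                aln_a.append(_rec(c.contig_id, s, e, c.chrom, a_lo, a_hi, e - s, 100.0))
                aln_b.append(_rec(c.contig_id, s, e, c.chrom, b_lo, b_hi, cross_cols, cross_idy))
            else:
                aln_b.append(_rec(c.contig_id, s, e, c.chrom, b_lo, b_hi, e - s, 100.0))
                aln_a.append(_rec(c.contig_id, s, e, c.chrom, a_lo, a_hi, cross_cols, cross_idy))
    return aln_a, aln_b


def _rec(qid, qs, qe, rid, rs, re_, cols, idy):
    return AlignmentRecord(
        query_id=qid, query_start=qs, query_end=qe,
        ref_id=rid, ref_start=rs, ref_end=re_,
        strand="+", aligned_columns=cols, identity_pct=idy, source="truth",
    )


def _pair_identity(seq1: str, seq2: str) -> tuple[float, int]:
    """Identity (%) and alignment columns between two sequences; a direct
    mismatch count when lengths agree, edit distance otherwise."""
    if len(seq1) == len(seq2):
        a = np.frombuffer(seq1.encode(), dtype=np.uint8)
        b = np.frombuffer(seq2.encode(), dtype=np.uint8)
        mism = int((a != b).sum())
        cols = len(seq1)
    else:
        import edlib

        mism = edlib.align(seq1, seq2, task="distance")["editDistance"]
        cols = max(len(seq1), len(seq2))
    return 100.0 * (cols - mism) / cols, cols


def export_progenitor_alignments(genome_a: ContigSet, genome_b: ContigSet):
    """Whole-genome truth alignment of B onto A: one full-length record per
    chromosome at the realized identity (B as query, A as reference)."""
    records = []
    for chrom, a_seq in genome_a.sequences.items():
        b_seq = genome_b.sequences[chrom]
        idy, cols = _pair_identity(a_seq, b_seq)
        records.append(
            AlignmentRecord(
                query_id=chrom, query_start=0, query_end=len(b_seq),
                ref_id=chrom, ref_start=0, ref_end=len(a_seq),
                strand="+", aligned_columns=cols, identity_pct=idy, source="truth",
            )
        )
    return records


# ---------------------------------------------------------------------------
# depth, AGP, dataset bundle
# ---------------------------------------------------------------------------

def simulate_depth(truth: TruthTable, base_depth: int = 13, noise: int = 0,
                   seed: int = 0) -> list[DepthRecord]:
    """Per-contig depth = base_depth * planted copy number + integer noise
    drawn uniformly from [-noise, noise]."""
    rng = np.random.default_rng(_derive_seed(seed, 2))
    out = []
    for c in truth:
        depth = base_depth * c.copy_number
        if noise:
            depth = max(0, depth + int(rng.integers(-noise, noise + 1)))
        out.append(DepthRecord(contig_id=c.contig_id, depth=float(depth), length=c.length))
    return out


def make_agp(truth: TruthTable, placed_fraction: float = 0.7, gap: int = 100,
             seed: int = 0):
    """Place a random subset of contigs on pseudochromosomes.

    Contigs are grouped by source chromosome and laid out in source order
    with fixed-size U gaps; the rest are the "unplaced" set.  Returns
    ``(placements, unplaced_ids)``.
    """
    rng = np.random.default_rng(_derive_seed(seed, 3))
    ids = sorted(c.contig_id for c in truth)
    placed = {cid for cid in ids if rng.random() < placed_fraction}
    by_chrom: dict[str, list[TruthContig]] = {}
    for c in truth:
        if c.contig_id in placed:
            by_chrom.setdefault(c.chrom, []).append(c)
    placements: list[AgpPlacement] = []
    for chrom in sorted(by_chrom):
        scaf = f"scaf_{chrom}"
        pos = 0
        members = sorted(by_chrom[chrom], key=lambda c: (c.source_start, c.contig_id))
        for j, c in enumerate(members):
            if j:
                placements.append(
                    AgpPlacement(scaf, pos, pos + gap, None, "+", True, gap)
                )
                pos += gap
            placements.append(
                AgpPlacement(scaf, pos, pos + c.length, c.contig_id, "+", False, 0)
            )
            pos += c.length
    unplaced = [cid for cid in ids if cid not in placed]
    return placements, unplaced


def export_unplaced_truth_alignments(truth: TruthTable, placements, unplaced_ids):
    """Truth alignments of unplaced contigs onto the pseudochromosome
    scaffolds: wherever an unplaced contig's source window overlaps a placed
    contig's source window, a record maps the overlap into scaffold
    coordinates."""
    placed_index: dict[str, list[tuple[int, int, str, int]]] = {}
    for p in placements:
        if p.is_gap:
            continue
        c = truth[p.component_id]
        placed_index.setdefault(c.chrom, []).append(
            (c.source_start, c.source_start + c.length, p.chrom, p.chrom_start)
        )
    records = []
    for uid in unplaced_ids:
        u = truth[uid]
        u_lo, u_hi = u.source_start, u.source_start + u.length
        for p_lo, p_hi, scaf, scaf_start in placed_index.get(u.chrom, []):
            lo, hi = max(u_lo, p_lo), min(u_hi, p_hi)
            if lo >= hi:
                continue
            records.append(
                AlignmentRecord(
                    query_id=uid,
                    query_start=lo - u_lo, query_end=hi - u_lo,
                    ref_id=scaf,
                    ref_start=scaf_start + (lo - p_lo),
                    ref_end=scaf_start + (hi - p_lo),
                    strand="+", aligned_columns=hi - lo,
                    identity_pct=100.0, source="truth",
                )
            )
    return records


@dataclass
class SimDataset:
    """Everything one seeded simulation produces, in memory."""

    params: SimParams
    genome_a: ContigSet
    genome_b: ContigSet
    variants: list
    contigs: ContigSet
    truth: TruthTable
    aln_a: list
    aln_b: list
    depths: list
    placements: list
    unplaced_ids: list


def simulate_dataset(params: SimParams) -> SimDataset:
    """Run the full generator: progenitors, hybrid contigs, truth
    alignments, depths and AGP, all derived from ``params.seed``."""
    genome_a, genome_b, variants = simulate_progenitors(params)
    contigs, truth = simulate_hybrid_assembly((genome_a, genome_b), params, variants)
    aln_a, aln_b = export_truth_alignments(truth, genome_a, genome_b, variants)
    depths = simulate_depth(truth, seed=params.seed)
    placements, unplaced = make_agp(truth, seed=params.seed)
    return SimDataset(params, genome_a, genome_b, variants, contigs, truth,
                      aln_a, aln_b, depths, placements, unplaced)


def evaluate_recovery(calls, truth: TruthTable) -> dict:
    """Score ancestry calls against the planted truth.

    pure_accuracy: fraction of pure contigs assigned to their true ancestor.
    chimera_sensitivity / chimera_fpr: recombinant-call rates on planted
    chimeras and pure contigs.  breakpoint_mae: mean distance from each
    reported breakpoint (on a true chimera) to the nearest planted
    breakpoint — a localization error; planted breakpoints whose flanking
    segment is below the detector's minimum run span are invisible by
    design and are accounted by sensitivity, not by this term.
    """
    call_map = calls if isinstance(calls, dict) else {c.contig_id: c for c in calls}
    pure = [c for c in truth if not c.is_chimeric]
    chim = [c for c in truth if c.is_chimeric]
    n_acc = sum(
        1 for c in pure
        if call_map[c.contig_id].category == c.dominant_ancestry + "_dominant"
    )
    n_hit = sum(1 for c in chim if call_map[c.contig_id].category == "recombinant")
    n_fp = sum(1 for c in pure if call_map[c.contig_id].category == "recombinant")
    errors = []
    for c in chim:
        call = call_map[c.contig_id]
        if call.category != "recombinant" or not c.breakpoints:
            continue
        for cb in call.breakpoints:
            errors.append(min(abs(cb - tb) for tb in c.breakpoints))
    return {
        "n_pure": len(pure),
        "n_chimeric": len(chim),
        "pure_accuracy": n_acc / len(pure) if pure else None,
        "chimera_sensitivity": n_hit / len(chim) if chim else None,
        "chimera_fpr": n_fp / len(pure) if pure else None,
        "breakpoint_mae": sum(errors) / len(errors) if errors else None,
    }


def write_fasta(contigs: ContigSet, stream, width: int = 70) -> None:
    """Write a ContigSet's sequences as FASTA (ids in insertion order)."""
    for name, seq in contigs.sequences.items():
        stream.write(f">{name}\n")
        for i in range(0, len(seq), width):
            stream.write(seq[i:i + width] + "\n")


def _derive_seed(seed: int, stream_id: int) -> int:
    return (int(seed) * 1_000_003 + stream_id) % (2**31 - 1)


# ---------------------------------------------------------------------------
# consensus-correction chimerization model
# ---------------------------------------------------------------------------

_SITE_ALPHABET = 4  # 0 = subgenome-A allele, 1 = subgenome-B allele, 2/3 = other


def simulate_consensus_correction(model: CorrectionModel, d: float,
                                  n_sites: int, mode: str = "mc") -> float:
    """Fraction of diagnostic sites where consensus correction overwrites a
    long read's A allele with the homoeologous B allele.

    At each diagnostic site (a position where the subgenomes differ) a long
    read from subgenome A carries the A allele unless a read error (prob e)
    flipped it.  Short reads from both subgenomes (c_a and c_b per site,
    error rate e/10) are recruited when their identity to the long read over
    a w-bp window centred on the site is at least 1 - e - m; the corrected
    base is the modal base among recruited reads (ties, or no recruits, keep
    the long read's own base).  The returned rate is the probability the
    corrected base is the B allele.

    ``mode="mc"`` runs a seeded Monte-Carlo over ``n_sites`` windows;
    ``mode="exact"`` enumerates the window-mismatch distributions (intended
    for small w and coverage; independent of n_sites).  d = 0 means no
    diagnostic sites exist and the rate is reported as 0 by convention.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if not 0 <= d < 1:
        raise ValueError("d must be in [0,1)")
    if d == 0:
        return 0.0
    if mode == "mc":
        return _correction_mc(model, d, n_sites)
    if mode == "exact":
        return _correction_exact(model, d)
    raise ValueError(f"unknown mode {mode!r}")


def _correction_mc(model: CorrectionModel, d: float, n_sites: int) -> float:
    rng = np.random.default_rng(_derive_seed(model.seed, 7))
    w, e = model.w, model.e
    es = e / 10.0
    n_reads = model.c_a + model.c_b
    max_mm = math.floor(w * (e + model.m))
    site = w // 2

    # genome templates per window: A is all-0; B differs at Bernoulli(d)
    # positions, always including the diagnostic site, with allele code 1
    b_template = np.zeros((n_sites, w), dtype=np.uint8)
    b_template[rng.random((n_sites, w)) < d] = 1
    b_template[:, site] = 1

    long_read = _with_errors(np.zeros((n_sites, w), dtype=np.uint8), e, rng)
    reads = np.empty((n_reads, n_sites, w), dtype=np.uint8)
    for i in range(model.c_a):
        reads[i] = _with_errors(np.zeros((n_sites, w), dtype=np.uint8), es, rng)
    for i in range(model.c_b):
        reads[model.c_a + i] = _with_errors(b_template.copy(), es, rng)

    mism = (reads != long_read[None, :, :]).sum(axis=2)
    recruited = mism <= max_mm  # (n_reads, n_sites)
    votes = reads[:, :, site]  # (n_reads, n_sites)
    counts = np.zeros((_SITE_ALPHABET, n_sites), dtype=np.int64)
    for base in range(_SITE_ALPHABET):
        counts[base] = ((votes == base) & recruited).sum(axis=0)
    top = counts.max(axis=0)
    # modal base; ties or zero recruits fall back to the long read's base
    corrected = np.where(
        (counts == top).sum(axis=0) == 1,
        counts.argmax(axis=0),
        long_read[:, site],
    )
    corrected = np.where(top == 0, long_read[:, site], corrected)
    return float((corrected == 1).mean())


def _with_errors(template: np.ndarray, rate: float, rng) -> np.ndarray:
    err = rng.random(template.shape) < rate
    idx = np.nonzero(err)
    template[idx] = (template[idx] + rng.integers(1, 4, size=idx[0].size).astype(np.uint8)) % 4
    return template


def _correction_exact(model: CorrectionModel, d: float) -> float:
    """Exact rate by enumerating long-read errors (j), divergent positions
    (k), their overlap (h) and the site bases, then convolving per-class
    mismatch binomials and a vote-count DP over reads.  O(w^3) contexts;
    intended for w <= ~20 and small coverage."""
    w, e, m = model.w, model.e, model.m
    es = e / 10.0
    n = w - 1  # non-site positions
    max_mm = math.floor(w * (e + m))
    pj = stats.binom.pmf(np.arange(n + 1), n, e)
    pk = stats.binom.pmf(np.arange(n + 1), n, d)

    # site-base distributions over {A=0, B=1, o1=2, o2=3}
    long_site = np.array([1 - e, e / 3, e / 3, e / 3])
    a_site = np.array([1 - es, es / 3, es / 3, es / 3])
    b_site = np.array([es / 3, 1 - es, es / 3, es / 3])

    total = 0.0
    for j in range(n + 1):
        if pj[j] < 1e-12:
            continue
        # A-short non-site mismatch pmf depends only on j
        pmf_a = _conv_binom([(j, 1 - es / 3), (n - j, es)])
        for k in range(n + 1):
            if pk[k] < 1e-12:
                continue
            ph = stats.hypergeom.pmf(np.arange(0, min(j, k) + 1), n, k, j)
            for h in range(min(j, k) + 1):
                ctx_p = pj[j] * pk[k] * ph[h]
                if ctx_p < 1e-10:
                    continue
                pmf_b = _conv_binom([
                    (h, 1 - ((1 - es) / 3 + 2 * es / 9)),
                    (k - h, 1 - es / 3),
                    (j - h, 1 - es / 3),
                    (n - j - k + h, es),
                ])
                for s_long in range(4):
                    p_ctx = ctx_p * long_site[s_long]
                    if p_ctx < 1e-12:
                        continue
                    a_read = _read_vote_dist(pmf_a, a_site, s_long, max_mm)
                    b_read = _read_vote_dist(pmf_b, b_site, s_long, max_mm)
                    total += p_ctx * _p_corrected_b(
                        a_read, b_read, model.c_a, model.c_b, s_long
                    )
    return total


def _conv_binom(parts):
    pmf = np.array([1.0])
    for n, p in parts:
        if n <= 0:
            continue
        pmf = np.convolve(pmf, stats.binom.pmf(np.arange(n + 1), n, p))
    return pmf


def _read_vote_dist(pmf_nonsite, site_dist, s_long, max_mm):
    """Per-read outcome distribution: P(recruited & vote = base) for each of
    the 4 site bases, plus P(not recruited)."""
    cdf = np.cumsum(pmf_nonsite)

    def p_le(t):
        if t < 0:
            return 0.0
        return float(cdf[min(t, len(cdf) - 1)])

    probs = np.zeros(5)
    for base in range(4):
        extra = 0 if base == s_long else 1
        probs[base] = site_dist[base] * p_le(max_mm - extra)
    probs[4] = 1.0 - probs[:4].sum()
    return probs


def _p_corrected_b(a_read, b_read, c_a, c_b, s_long) -> float:
    """Probability the modal recruited vote is the B allele (ties and empty
    recruitment fall back to the long read's site base)."""
    states = {(0, 0, 0, 0): 1.0}
    for probs, count in ((a_read, c_a), (b_read, c_b)):
        for _ in range(count):
            new: dict[tuple, float] = {}
            for counts, p in states.items():
                for base in range(4):
                    key = tuple(
                        c + (1 if i == base else 0) for i, c in enumerate(counts)
                    )
                    new[key] = new.get(key, 0.0) + p * probs[base]
                key = counts
                new[key] = new.get(key, 0.0) + p * probs[4]
            states = new
    total = 0.0
    for counts, p in states.items():
        top = max(counts)
        if top == 0:
            corrected_b = s_long == 1
        else:
            winners = [i for i, c in enumerate(counts) if c == top]
            if len(winners) == 1:
                corrected_b = winners[0] == 1
            else:
                corrected_b = s_long == 1
        if corrected_b:
            total += p
    return total
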