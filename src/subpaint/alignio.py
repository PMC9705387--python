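"""Readers and writers for the alignment, placement and annotation formats
the pipeline consumes.

All coordinates are normalized to a single internal convention: 0-based,
half-open, ``start < end`` on both query and reference.  Formats that use
1-based inclusive coordinates (MUMmer ``show-coords`` tables, RepeatMasker
``.out``, AGP) are converted at this boundary; PAF already matches the
internal convention and is passed through.

Alignments from every source are represented by a single
:class:`AlignmentRecord` so that downstream interval and ancestry code never
needs to know which aligner produced them.
"""

from __future__ import annotations

import io
import os
import tempfile
import warnings
from dataclasses import dataclass, field, replace

import pysam
from Bio import SeqIO

__all__ = [
    "AlignmentRecord",
    "ContigSet",
    "AgpPlacement",
    "RepeatHit",
    "ParseError",
    "read_coords",
    "write_coords",
    "read_paf",
    "write_paf",
    "read_sam_alignments",
    "read_repeatmasker_out",
    "read_agp",
    "read_fasta_lengths",
    "write_bed9",
    "write_tsv",
]


class ParseError(ValueError):
    """Malformed input; the message names the offending line."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One query-vs-reference alignment.

    Coordinates are 0-based half-open on both sides with ``start < end``
    regardless of strand; ``strand`` records the relative orientation.
    ``aligned_columns`` counts alignment columns (matches, mismatches and
    indel columns) and is the weight used for identity averaging.
    """

    query_id: str
    query_start: int
    query_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    aligned_columns: int
    identity_pct: float
    score: float | None = None
    source: str = "truth"
    is_secondary: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start:
            raise ValueError(
                f"query interval empty or reversed: {self.query_id} "
                f"[{self.query_start},{self.query_end})"
            )
        if self.ref_end <= self.ref_start:
            raise ValueError(
                f"reference interval empty or reversed: {self.ref_id} "
                f"[{self.ref_start},{self.ref_end})"
            )
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity out of range: {self.identity_pct}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class ContigSet:
    """Named sequences with lengths and (optionally) the sequences themselves."""

    lengths: dict[str, int]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.lengths.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive lengths for: {bad[:5]}")

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())


@dataclass(frozen=True)
class AgpPlacement:
    """One AGP component line: a contig (or gap) tiling part of an object."""

    chrom: str
    chrom_start: int  # 0-based half-open on the object
    chrom_end: int
    component_id: str | None
    component_orientation: str = "+"
    is_gap: bool = False
    gap_length: int = 0


@dataclass(frozen=True)
class RepeatHit:
    """One RepeatMasker annotation: a repeat class hitting a target interval."""

    repeat_class: str
    target_id: str
    start: int  # 0-based half-open on the target
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty repeat hit on {self.target_id}")

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# MUMmer show-coords tables
# ---------------------------------------------------------------------------

def _coords_fields(line: str) -> list[str]:
    # default show-coords output separates column groups with '|'
    return line.replace("|", " ").split()


def read_coords(stream) -> list[AlignmentRecord]:
    """Parse a ``show-coords`` table into alignment records.

    Expects the tabular layout ``S1 E1 S2 E2 LEN1 LEN2 %IDY [extra...] REF QUERY``
    with sequence 1 the reference and sequence 2 the query, 1-based inclusive.
    Works for plain, ``-T`` and ``-l`` output: the first seven whitespace
    fields must be the numeric columns and the last two the sequence tags
    (``|`` group separators are ignored).  Header/ruler lines are skipped.
    A reversed query range (S2 > E2) becomes strand ``-`` with start < end;
    a reversed reference range is rejected as an unsupported dialect.
    """
    records: list[AlignmentRecord] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = _coords_fields(line)
        if not fields or not _is_int(fields[0]):
            continue  # header, ruler or path line
        if len(fields) < 9:
            raise ParseError(f"coords line {lineno}: expected >= 9 fields, got {len(fields)}")
        try:
            s1, e1, s2, e2, len1, len2 = (int(x) for x in fields[:6])
            idy = float(fields[6])
        except ValueError as exc:
            raise ParseError(f"coords line {lineno}: {exc}") from None
        ref_id, query_id = fields[-2], fields[-1]
        if e1 < s1:
            raise ParseError(
                f"coords line {lineno}: reversed reference range {s1}..{e1} "
                "(unsupported dialect; reference coordinates must ascend)"
            )
        strand = "+"
        if e2 < s2:
            strand = "-"
            s2, e2 = e2, s2
        records.append(
            AlignmentRecord(
                query_id=query_id,
                query_start=s2 - 1,
                query_end=e2,
                ref_id=ref_id,
                ref_start=s1 - 1,
                ref_end=e1,
                strand=strand,
                aligned_columns=max(len1, len2),
                identity_pct=idy,
                source="coords",
            )
        )
    return records


def write_coords(records, stream) -> None:
    """Serialize records in the tab-separated ``show-coords -T`` layout.

    Round-trips through :func:`read_coords` up to the ``source`` tag.
    """
    stream.write("[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[TAGS]\n")
    for r in records:
        s2, e2 = r.query_start + 1, r.query_end
        if r.strand == "-":
            s2, e2 = e2, s2
        stream.write(
            f"{r.ref_start + 1}\t{r.ref_end}\t{s2}\t{e2}\t"
            f"{r.ref_span}\t{r.query_span}\t{r.identity_pct:.2f}\t"
            f"{r.ref_id}\t{r.query_id}\n"
        )


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(stream, min_score: float | None = None) -> list[AlignmentRecord]:
    """Parse minimap2-style PAF.  Identity is residue matches over block length.

    ``min_score`` filters on the ``AS:i`` tag when given; records lacking the
    tag under an active filter raise, rather than silently passing.
    """
    records: list[AlignmentRecord] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"PAF line {lineno}: expected >= 12 columns, got {len(fields)}")
        qname, _qlen, qstart, qend, strand, tname, _tlen, tstart, tend, nmatch, blocklen = (
            fields[0], fields[1], int(fields[2]), int(fields[3]), fields[4],
            fields[5], fields[6], int(fields[7]), int(fields[8]),
            int(fields[9]), int(fields[10]),
        )
        score = _paf_tag(fields[12:], "AS")
        if min_score is not None:
            if score is None:
                raise ParseError(f"PAF line {lineno}: min_score set but no AS tag")
            if score < min_score:
                continue
        records.append(
            AlignmentRecord(
                query_id=qname,
                query_start=qstart,
                query_end=qend,
                ref_id=tname,
                ref_start=tstart,
                ref_end=tend,
                strand=strand,
                aligned_columns=blocklen,
                identity_pct=100.0 * nmatch / blocklen if blocklen else 0.0,
                score=score,
                source="paf",
            )
        )
    return records


def write_paf(records, stream, query_lengths=None, ref_lengths=None) -> None:
    """Serialize records as 12-column PAF (+ AS tag when a score is present)."""
    qlen = query_lengths.lengths if query_lengths is not None else {}
    rlen = ref_lengths.lengths if ref_lengths is not None else {}
    for r in records:
        nmatch = round(r.aligned_columns * r.identity_pct / 100.0)
        cols = [
            r.query_id, qlen.get(r.query_id, r.query_end), r.query_start, r.query_end,
            r.strand,
            r.ref_id, rlen.get(r.ref_id, r.ref_end), r.ref_start, r.ref_end,
            nmatch, r.aligned_columns, 60,
        ]
        line = "\t".join(str(c) for c in cols)
        if r.score is not None:
            line += f"\tAS:i:{int(r.score)}"
        stream.write(line + "\n")


def _paf_tag(tags: list[str], name: str) -> float | None:
    for t in tags:
        if t.startswith(name + ":"):
            return float(t.split(":", 2)[2])
    return None


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")


def read_sam_alignments(stream, min_score: int | None = None) -> list[AlignmentRecord]:
    """Extract aligned ranges from a SAM stream by walking each CIGAR.

    The query range is the CIGAR's query-consuming span with soft/hard clips
    excluded, expressed on the original (forward) contig; for reverse-strand
    records the clip-delimited span is flipped using the full read length
    including hard clips.  The reference range is POS plus all
    reference-consuming operations.  ``aligned_columns`` counts M/=/X + I + D.

    Identity is ``100*(aligned_columns - NM)/aligned_columns`` when the NM tag
    is present, else ``100*=/(=+X+I+D)`` when the CIGAR uses =/X operators;
    records with neither raise.  ``min_score`` filters on the AS tag (the
    analogue of bwa-mem's ``-T``); a filtered record without AS raises.
    Secondary and supplementary alignments are retained and flagged; unmapped
    records are skipped, as are records with CIGAR ``*`` (with a warning).
    """
    records: list[AlignmentRecord] = []
    with _sam_file(stream) as sam:
        for seg in sam.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            if not seg.cigartuples:
                warnings.warn(f"record {seg.query_name}: no CIGAR, skipped", stacklevel=2)
                continue
            if min_score is not None:
                if not seg.has_tag("AS"):
                    raise ParseError(
                        f"record {seg.query_name}: min_score set but no AS tag"
                    )
                if seg.get_tag("AS") < min_score:
                    continue
            cigar = seg.cigarstring
            qstart, qend, total_read_len, ref_consumed, cols, eq, mismatchy = _walk_cigar(cigar)
            if seg.is_reverse:
                qstart, qend = total_read_len - qend, total_read_len - qstart
            if seg.has_tag("NM"):
                nm = seg.get_tag("NM")
                identity = 100.0 * (cols - nm) / cols
            elif eq or mismatchy:
                identity = 100.0 * eq / (eq + mismatchy)
            else:
                raise ParseError(
                    f"record {seg.query_name}: neither NM tag nor =/X operators; "
                    "cannot derive identity"
                )
            records.append(
                AlignmentRecord(
                    query_id=seg.query_name,
                    query_start=qstart,
                    query_end=qend,
                    ref_id=seg.reference_name,
                    ref_start=seg.reference_start,
                    ref_end=seg.reference_start + ref_consumed,
                    strand="-" if seg.is_reverse else "+",
                    aligned_columns=cols,
                    identity_pct=identity,
                    score=float(seg.get_tag("AS")) if seg.has_tag("AS") else None,
                    source="sam",
                    is_secondary=seg.is_secondary,
                    is_supplementary=seg.is_supplementary,
                )
            )
    return records


def _walk_cigar(cigar: str):
    """Single pass over a CIGAR string.

    Returns (query_start, query_end, total_read_len_incl_hard_clips,
    ref_consumed, aligned_columns, n_eq, n_mismatchy) where query coordinates
    are on the stored read orientation and n_mismatchy = X + I + D.
    """
    qpos = 0
    qstart = None
    qend = 0
    ref = 0
    cols = 0
    n_eq = 0
    n_mm = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
            continue
        n, num = num, 0
        if ch in "SH":
            qpos += n
            continue
        if ch in _QUERY_OPS:
            if qstart is None:
                qstart = qpos
            qpos += n
            qend = qpos
        if ch in "M=XID":
            cols += n
        if ch == "=":
            n_eq += n
        elif ch in "XID":
            n_mm += n
        if ch in _REF_OPS:
            ref += n
    if qstart is None:
        raise ParseError(f"CIGAR {cigar!r} consumes no query bases")
    return qstart, qend, qpos, ref, cols, n_eq, n_mm


class _sam_file:
    """Open a pysam AlignmentFile from a path or a text stream."""

    def __init__(self, stream):
        self._tmp = None
        if isinstance(stream, (str, os.PathLike)):
            self._path = os.fspath(stream)
        else:
            text = stream.read()
            tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
            tmp.write(text)
            tmp.close()
            self._tmp = tmp.name
            self._path = tmp.name

    def __enter__(self):
        self._fh = pysam.AlignmentFile(self._path, "r", check_sq=False)
        return self._fh

    def __exit__(self, *exc):
        self._fh.close()
        if self._tmp:
            os.unlink(self._tmp)
        return False


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(stream) -> list[RepeatHit]:
    """Parse RepeatMasker ``.out`` annotation lines into repeat hits.

    The standard file carries 2 header lines plus a blank line; anything whose
    first field is not an integer score is skipped as header.  Columns used:
    5 (target), 6-7 (1-based inclusive span) and 11 (class/family, kept
    verbatim).
    """
    hits: list[RepeatHit] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        fields = raw.split()
        if not fields or not _is_int(fields[0]):
            continue
        if len(fields) < 11:
            raise ParseError(f"RepeatMasker line {lineno}: too few columns")
        try:
            start = int(fields[5]) - 1
            end = int(fields[6])
        except ValueError:
            raise ParseError(f"RepeatMasker line {lineno}: bad coordinates") from None
        if end <= start:
            raise ParseError(f"RepeatMasker line {lineno}: empty span")
        hits.append(RepeatHit(repeat_class=fields[10], target_id=fields[4], start=start, end=end))
    return hits


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------

_GAP_TYPES = {"N", "U"}


def read_agp(stream) -> list[AgpPlacement]:
    """Parse AGP v2.1; recognizes component types W (contig) and N/U (gap).

    Object coordinates are converted to 0-based half-open.  Overlapping object
    coordinates on a chromosome and unknown component types are errors.
    """
    placements: list[AgpPlacement] = []
    last_end: dict[str, int] = {}
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 8:
            raise ParseError(f"AGP line {lineno}: expected >= 8 columns")
        chrom, beg, end, _part, ctype = fields[0], int(fields[1]), int(fields[2]), fields[3], fields[4]
        start0, end0 = beg - 1, end
        if end0 <= start0:
            raise ParseError(f"AGP line {lineno}: empty object span")
        if start0 < last_end.get(chrom, 0):
            raise ParseError(f"AGP line {lineno}: overlapping object coordinates on {chrom}")
        last_end[chrom] = end0
        if ctype == "W":
            comp_id, cbeg, cend = fields[5], int(fields[6]), int(fields[7])
            orient = fields[8] if len(fields) > 8 else "?"
            if orient not in "+-?":
                orient = "?"
            if (cend - cbeg + 1) != (end0 - start0):
                raise ParseError(
                    f"AGP line {lineno}: component span != object span for {comp_id}"
                )
            placements.append(AgpPlacement(chrom, start0, end0, comp_id, orient, False, 0))
        elif ctype in _GAP_TYPES:
            placements.append(
                AgpPlacement(chrom, start0, end0, None, "+", True, int(fields[5]))
            )
        else:
            raise ParseError(f"AGP line {lineno}: unknown component type {ctype!r}")
    return placements


# ---------------------------------------------------------------------------
# FASTA, BED9, TSV
# ---------------------------------------------------------------------------

def read_fasta_lengths(stream, keep_sequence: bool = False) -> ContigSet:
    """Read a FASTA stream into a ContigSet (ids must be unique)."""
    lengths: dict[str, int] = {}
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(_as_text_handle(stream), "fasta"):
        if rec.id in lengths:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        lengths[rec.id] = len(rec.seq)
        if keep_sequence:
            seqs[rec.id] = str(rec.seq)
    return ContigSet(lengths=lengths, sequences=seqs)


def write_bed9(tracks, stream) -> None:
    """Write painting tracks as BED9 (0-based half-open, itemRgb per block).

    ``tracks`` is an iterable of objects with ``chrom`` and ``blocks``; each
    block provides (chrom_start, chrom_end, name, category, rgb).  Output is
    byte-stable for a given input order.
    """
    for track in tracks:
        for blk in track.blocks:
            stream.write(
                f"{track.chrom}\t{blk.chrom_start}\t{blk.chrom_end}\t{blk.name}\t0\t+\t"
                f"{blk.chrom_start}\t{blk.chrom_end}\t{blk.rgb}\n"
            )


def write_tsv(report, stream, columns=None) -> None:
    """Write a list of dicts (or dataclass-likes) as a TSV with a header row."""
    rows = [r if isinstance(r, dict) else vars(r) for r in report]
    if not rows:
        return
    cols = list(columns) if columns else list(rows[0])
    stream.write("\t".join(cols) + "\n")
    for row in rows:
        stream.write("\t".join(str(row[c]) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _is_int(tok: str) -> bool:
    return tok.lstrip("-").isdigit()


def _as_lines(stream):
    if isinstance(stream, (str, os.PathLike)):
        with open(stream) as fh:
            yield from fh
    else:
        yield from stream


def _as_text_handle(stream):
    if isinstance(stream, (str, os.PathLike)):
        return open(stream)
    return stream
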