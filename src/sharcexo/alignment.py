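"""Gapped-alignment parsing, classification and gap filtering.

Proximity-ligation libraries yield chimeric ("gapped") reads whose aligned
segments ("arms") derive from two RNA fragments that were crosslinked and
ligated.  A spliced aligner reports these as CIGAR ``N``/``D`` gaps or as
supplementary (chimeric) alignment records.  This module parses such SAM
output into :class:`GappedAlignment` objects, classifies each read into one
of six geometric classes, and removes gaps that are explained by splicing
or by short indels rather than by ligation.

Coordinate conventions
----------------------
Internal coordinates are 0-based half-open.  SAM input/output is 1-based per
the SAM standard (pysam performs the conversion).  Splice-junction tables
are 0-based: ``donor_pos`` is the first skipped (intronic) base and
``acceptor_pos`` the position one past the last skipped base, so a gap
``[donor_pos, acceptor_pos)`` exactly matches the junction.
"""

from __future__ import annotations

import io
import logging
import os
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

#: The six alignment classes, mirroring the per-class SAM file suffixes.
ALIGNMENT_CLASSES = ("cont", "gap1", "gapm", "trans", "homo", "bad")


@dataclass(frozen=True, order=True)
class Segment:
    """One aligned arm on a reference: 0-based half-open ``[start, end)``."""

    ref_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty segment [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Segment") -> bool:
        return (
            self.ref_id == other.ref_id
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def three_prime_end(self) -> int:
        """0-based position of the arm's 3'-terminal nucleotide."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GappedAlignment:
    """One read's aligned segments, in reference order, plus its class."""

    read_id: str
    segments: tuple[Segment, ...]
    alignment_class: str | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("alignment needs at least one segment")
        self.segments = tuple(sorted(self.segments, key=lambda s: (s.ref_id, s.start, s.end)))

    @property
    def left_arm(self) -> Segment:
        return self.segments[0]

    @property
    def right_arm(self) -> Segment:
        return self.segments[-1]

    def gaps(self) -> list[tuple[int, int]]:
        """0-based half-open gap intervals between consecutive same-reference segments."""
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            if a.ref_id == b.ref_id and a.end <= b.start:
                out.append((a.end, b.start))
        return out


@dataclass
class SpliceAnnotation:
    """Set of splice junctions as ``(ref_id, donor_pos, acceptor_pos)``, 0-based."""

    junctions: frozenset[tuple[str, int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.junctions = frozenset(self.junctions)
        for ref, d, a in self.junctions:
            if not d < a:
                raise ValueError(f"junction {ref}:{d}-{a} has donor >= acceptor")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SpliceAnnotation":
        juncs = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                ref, d, a = line.split("\t")[:3]
                juncs.add((ref, int(d), int(a)))
        return cls(frozenset(juncs))

    def matches(self, ref_id: str, gap: tuple[int, int], tol: int = 2) -> bool:
        return any(
            ref == ref_id and abs(d - gap[0]) <= tol and abs(a - gap[1]) <= tol
            for ref, d, a in self.junctions
        )


def _segments_from_record(rec: pysam.AlignedSegment, merge_del: int = 2) -> list[Segment]:
    """Split one SAM record into reference segments at N gaps and deletions > merge_del."""
    strand = "-" if rec.is_reverse else "+"
    ref = rec.reference_name
    pos = rec.reference_start
    segs: list[Segment] = []
    cur_start: int | None = None
    for op, length in rec.cigartuples:
        if op in (0, 7, 8):  # M, =, X consume both
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op == 2:  # D consumes reference
            if length <= merge_del and cur_start is not None:
                pos += length  # short deletion absorbed into the segment
            else:
                if cur_start is not None:
                    segs.append(Segment(ref, cur_start, pos, strand))
                    cur_start = None
                pos += length
        elif op == 3:  # N: ligation/splice gap
            if cur_start is not None:
                segs.append(Segment(ref, cur_start, pos, strand))
                cur_start = None
            pos += length
        elif op in (1, 4, 5, 6):  # I, S, H, P consume no reference
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if cur_start is not None:
        segs.append(Segment(ref, cur_start, pos, strand))
    return segs


def classify(aln: GappedAlignment) -> str:
    """Assign one of the six classes from segment geometry alone.

    * ``cont`` — a single segment.
    * ``gap1`` — two non-overlapping segments on one reference/strand.
    * ``gapm`` — more than two pairwise non-overlapping segments on one
      reference/strand.
    * ``trans`` — segments on different references or strands, none of the
      same-reference/strand segments overlapping.
    * ``homo`` — exactly two segments on one reference/strand overlapping
      each other.
    * ``bad`` — any remaining indel/gap combination.
    """
    segs = aln.segments
    if len(segs) == 1:
        return "cont"
    keys = {(s.ref_id, s.strand) for s in segs}
    by_key: dict[tuple[str, str], list[Segment]] = defaultdict(list)
    for s in segs:
        by_key[(s.ref_id, s.strand)].append(s)
    any_overlap = any(
        a.start < b.end and b.start < a.end
        for group in by_key.values()
        for i, a in enumerate(group)
        for b in group[i + 1 :]
    )
    if len(keys) == 1:
        if len(segs) == 2:
            return "homo" if any_overlap else "gap1"
        return "bad" if any_overlap else "gapm"
    return "bad" if any_overlap else "trans"


def parse_sam(source, merge_del: int = 2) -> list[GappedAlignment]:
    """Parse a SAM file (path or text stream) into classified alignments.

    Primary and supplementary lines sharing a read id are merged into one
    :class:`GappedAlignment`; secondary alignments and unmapped records are
    ignored.  Records with malformed CIGAR strings are skipped and counted.
    """
    path, tmp = _as_path(source)
    try:
        by_read: dict[str, list[Segment]] = {}
        order: list[str] = []
        skipped = 0
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary:
                    continue
                try:
                    segs = _segments_from_record(rec, merge_del=merge_del)
                except (ValueError, TypeError):
                    skipped += 1
                    continue
                if not segs:
                    skipped += 1
                    continue
                if rec.query_name not in by_read:
                    by_read[rec.query_name] = []
                    order.append(rec.query_name)
                by_read[rec.query_name].extend(segs)
        if skipped:
            logger.warning("skipped %d records with unusable CIGAR", skipped)
        out = []
        for name in order:
            aln = GappedAlignment(name, tuple(by_read[name]))
            aln.alignment_class = classify(aln)
            out.append(aln)
        return out
    finally:
        if tmp:
            os.unlink(path)


def _as_path(source) -> tuple[str, bool]:
    """Accept a filesystem path or a text stream; return (path, is_temporary)."""
    if isinstance(source, (str, os.PathLike)) and not (
        isinstance(source, str) and source.lstrip().startswith("@")
    ):
        return str(source), False
    text = source if isinstance(source, str) else source.read()
    fd, name = tempfile.mkstemp(suffix=".sam")
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    return name, True


def filter_gaps(
    alns: Iterable[GappedAlignment],
    splice: SpliceAnnotation | None = None,
    min_gap: int = 3,
    junction_tol: int = 2,
) -> tuple[list[GappedAlignment], list[GappedAlignment]]:
    """Drop gapped alignments whose every gap is short or splice-explained.

    A gap is *uninformative* when it is shorter than ``min_gap`` nucleotides
    (short 1-2 nt gaps are indel artifacts) or coincides, within
    ``junction_tol`` nt at both edges, with an annotated splice junction.
    Alignments retaining at least one informative gap are kept.
    """
    splice = splice or SpliceAnnotation()
    kept, dropped = [], []
    for aln in alns:
        gaps = aln.gaps()
        good = [
            g
            for g in gaps
            if (g[1] - g[0]) >= min_gap
            and not splice.matches(aln.segments[0].ref_id, g, tol=junction_tol)
        ]
        (kept if good else dropped).append(aln)
    return kept, dropped


def write_sam(
    alns: Iterable[GappedAlignment],
    path: str | os.PathLike,
    ref_lengths: dict[str, int],
) -> None:
    """Write alignments back to SAM (one line per reference/strand run).

    Query sequences are not retained by :func:`parse_sam`, so ``SEQ`` is
    emitted as ``*``.  Segments on one reference/strand become an
    ``M``/``N`` CIGAR; additional reference/strand groups are written as
    supplementary lines, which round-trips through :func:`parse_sam`.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alns:
            groups: dict[tuple[str, str], list[Segment]] = defaultdict(list)
            for seg in aln.segments:
                groups[(seg.ref_id, seg.strand)].append(seg)
            for idx, ((ref, strand), segs) in enumerate(sorted(groups.items())):
                segs = sorted(segs, key=lambda s: s.start)
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = aln.read_id
                rec.reference_name = ref
                rec.reference_start = segs[0].start
                rec.mapping_quality = 255
                flag = 0
                if strand == "-":
                    flag |= 0x10
                if idx > 0:
                    flag |= 0x800
                rec.flag = flag
                cig = []
                for a, b in zip(segs, segs[1:]):
                    cig.append((0, a.length))
                    cig.append((3, b.start - a.end))
                cig.append((0, segs[-1].length))
                rec.cigartuples = cig
                if aln.alignment_class:
                    rec.set_tag("XC", aln.alignment_class)
                out.write(rec)


def split_by_class(
    alns: Iterable[GappedAlignment],
) -> dict[str, list[GappedAlignment]]:
    """Partition alignments by class; every class key is present."""
    out: dict[str, list[GappedAlignment]] = {c: [] for c in ALIGNMENT_CLASSES}
    for aln in alns:
        cls = aln.alignment_class or classify(aln)
        out[cls].append(aln)
    return out


def write_class_sams(
    alns: Iterable[GappedAlignment],
    out_prefix: str | os.PathLike,
    ref_lengths: dict[str, int],
) -> dict[str, str]:
    """Write one SAM per class with the conventional suffixes; return the paths."""
    paths = {}
    for cls, group in split_by_class(alns).items():
        path = f"{out_prefix}_{cls}.sam"
        write_sam(group, path, ref_lengths)
        paths[cls] = path
    return paths
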