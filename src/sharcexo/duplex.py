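"""Duplex-group (DG) assembly and non-overlap verification.

A duplex group is a cluster of gapped reads whose two arms co-localize; one
DG nominates one crosslinked nucleotide pair.  Reads are clustered by
single-linkage over reciprocal arm overlap: two reads join the same DG when
both their left arms and their right arms overlap by at least
``min_overlap_frac`` of the shorter arm.  Assembled DGs are then checked
with the non-overlap rule: a DG fails if any read's left-arm start is at or
beyond another member's right-arm end, in which case the worst offenders
are removed until the group passes.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .alignment import GappedAlignment, Segment


@dataclass
class DuplexGroup:
    dg_id: str
    left_arm: Segment  # envelope over member left arms
    right_arm: Segment  # envelope over member right arms
    reads: list[GappedAlignment] = field(default_factory=list)

    @property
    def coverage(self) -> int:
        return len(self.reads)

    def recompute_envelope(self) -> None:
        ls = [r.left_arm for r in self.reads]
        rs = [r.right_arm for r in self.reads]
        self.left_arm = Segment(
            ls[0].ref_id, min(s.start for s in ls), max(s.end for s in ls), ls[0].strand
        )
        self.right_arm = Segment(
            rs[0].ref_id, min(s.start for s in rs), max(s.end for s in rs), rs[0].strand
        )


def _arm_overlap_adjacency(
    starts: np.ndarray, ends: np.ndarray, frac: float
) -> np.ndarray:
    """Boolean matrix: reciprocal overlap >= frac * shorter arm length."""
    ov = np.minimum(ends[:, None], ends[None, :]) - np.maximum(
        starts[:, None], starts[None, :]
    )
    lengths = ends - starts
    shorter = np.minimum(lengths[:, None], lengths[None, :])
    return ov >= frac * shorter


def assemble(
    alns: list[GappedAlignment],
    min_overlap_frac: float = 0.5,
    dg_prefix: str = "DG",
) -> list[DuplexGroup]:
    """Cluster gap1 alignments into duplex groups.

    Alignments are first grouped by (reference, strand) of both arms, then
    single-linkage-clustered on the conjunction of left-arm and right-arm
    reciprocal overlap.  The result is independent of input order: members
    and groups are sorted by coordinates before ids are assigned.
    """
    by_pair: dict[tuple, list[GappedAlignment]] = defaultdict(list)
    for aln in alns:
        if (aln.alignment_class or "gap1") != "gap1":
            raise ValueError(f"assemble expects gap1 alignments, got {aln.alignment_class}")
        l, r = aln.left_arm, aln.right_arm
        by_pair[(l.ref_id, l.strand, r.ref_id, r.strand)].append(aln)

    groups: list[list[GappedAlignment]] = []
    for key in sorted(by_pair):
        members = sorted(
            by_pair[key],
            key=lambda a: (a.left_arm.start, a.left_arm.end, a.right_arm.start, a.right_arm.end, a.read_id),
        )
        ls = np.array([a.left_arm.start for a in members])
        le = np.array([a.left_arm.end for a in members])
        rs = np.array([a.right_arm.start for a in members])
        re_ = np.array([a.right_arm.end for a in members])
        adj = _arm_overlap_adjacency(ls, le, min_overlap_frac) & _arm_overlap_adjacency(
            rs, re_, min_overlap_frac
        )
        n = len(members)
        ii, jj = np.nonzero(adj)
        graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
        comp: dict[int, list[GappedAlignment]] = defaultdict(list)
        for lab, aln in zip(labels, members):
            comp[lab].append(aln)
        groups.extend(comp[lab] for lab in sorted(comp))

    groups.sort(
        key=lambda g: (
            g[0].left_arm.ref_id,
            min(a.left_arm.start for a in g),
            min(a.right_arm.start for a in g),
        )
    )
    dgs = []
    for i, members in enumerate(groups):
        dg = DuplexGroup(f"{dg_prefix}{i:04d}", members[0].left_arm, members[0].right_arm, members)
        dg.recompute_envelope()
        dgs.append(dg)
    return dgs


def verify(dg: DuplexGroup) -> tuple[bool, list[tuple[str, str]]]:
    """Check the DG non-overlap rule.

    Fails iff some read's left-arm start is >= another read's right-arm
    end.  Returns (passed, offending read-id pairs).
    """
    ls = np.array([r.left_arm.start for r in dg.reads])
    re_ = np.array([r.right_arm.end for r in dg.reads])
    bad = ls[:, None] >= re_[None, :]
    np.fill_diagonal(bad, False)
    ii, jj = np.nonzero(bad)
    pairs = [(dg.reads[i].read_id, dg.reads[j].read_id) for i, j in zip(ii, jj)]
    return len(pairs) == 0, pairs


def enforce_non_overlap(dg: DuplexGroup) -> list[GappedAlignment]:
    """Repair a failing DG by removing minimal offenders; returns removed reads.

    The read participating in the most violating pairs is removed first,
    ties broken by lexicographic read id.  Deterministic and idempotent:
    a passing DG is returned untouched.
    """
    removed: list[GappedAlignment] = []
    while True:
        ok, pairs = verify(dg)
        if ok:
            return removed
        counts: dict[str, int] = defaultdict(int)
        for a, b in pairs:
            counts[a] += 1
            counts[b] += 1
        victim_id = min(counts, key=lambda rid: (-counts[rid], rid))
        victim = next(r for r in dg.reads if r.read_id == victim_id)
        dg.reads.remove(victim)
        removed.append(victim)
        if dg.reads:
            dg.recompute_envelope()
        else:
            return removed


def assemble_and_verify(
    alns: list[GappedAlignment], min_overlap_frac: float = 0.5
) -> tuple[list[DuplexGroup], list[GappedAlignment]]:
    """Full DG assembly: cluster, then repair every failing group.

    Returns the passing DGs (empty groups discarded) and the reads removed
    by the non-overlap repair.
    """
    dgs = assemble(alns, min_overlap_frac=min_overlap_frac)
    removed: list[GappedAlignment] = []
    for dg in dgs:
        removed.extend(enforce_non_overlap(dg))
    return [dg for dg in dgs if dg.reads], removed


BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]


def write_bedpe(dgs: list[DuplexGroup], path: str | os.PathLike) -> None:
    """Write DGs as 10-column BEDPE (0-based half-open), score = coverage."""
    rows = [
        (
            dg.left_arm.ref_id, dg.left_arm.start, dg.left_arm.end,
            dg.right_arm.ref_id, dg.right_arm.start, dg.right_arm.end,
            dg.dg_id, dg.coverage, dg.left_arm.strand, dg.right_arm.strand,
        )
        for dg in dgs
    ]
    df = pd.DataFrame(rows, columns=BEDPE_COLUMNS)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_bedpe(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", names=BEDPE_COLUMNS)


def write_arcs_bed(dgs: list[DuplexGroup], path: str | os.PathLike) -> None:
    """Genome-browser arc track: one BED12-style line spanning each DG's arms."""
    with open(path, "w") as fh:
        fh.write('track graphType=arc name="duplex groups"\n')
        for dg in dgs:
            if dg.left_arm.ref_id != dg.right_arm.ref_id:
                continue
            start = dg.left_arm.start
            end = dg.right_arm.end
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        dg.left_arm.ref_id, start, end, dg.dg_id, dg.coverage,
                        dg.left_arm.strand, start, end, "0,0,0", 2,
                        f"{dg.left_arm.length},{dg.right_arm.length}",
                        f"0,{dg.right_arm.start - start}",
                    )
                )
                + "\n"
            )


def dg_tags(dgs: list[DuplexGroup]) -> dict[str, str]:
    """Map read id -> DG id, for tagging assigned reads in SAM output."""
    return {read.read_id: dg.dg_id for dg in dgs for read in dg.reads}
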