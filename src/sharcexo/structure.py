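"""3D-structure loading and spatial distance metrics for gapped reads.

Crosslinkers bridge the ribose 2'-OH groups of two *flexible* nucleotides —
nucleotides that are single-stranded in the secondary structure or
chemically reactive (SHAPE-activated).  Given a coordinate model and a
chain-to-transcript mapping, this module measures, per gapped read, the
minimum O2'-O2' distance between flexible nucleotides on the two arms,
either over whole arms or restricted to the empirically trimmed offset
window (3-7 from each 3' end).  It also provides the shuffled-read null,
structural categorisation (helix-constrained vs tertiary core vs expansion
segment), cumulative distance summaries, binned contact maps and the
minimum-position offset heatmap.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .alignment import GappedAlignment, Segment

O2_PRIME = "O2'"
STANDARD_ATOMS = ("O2'", "P", "C4'")
CATEGORIES = ("dsRNA", "core_tertiary", "es_tertiary")


class StructureModel:
    """Named-atom coordinates indexed by (transcript, 0-based position).

    ``coords[transcript][atom]`` is an ``(L, 3)`` float array with NaN rows
    for unresolved residues or missing atoms.
    """

    def __init__(self, coords: Mapping[str, Mapping[str, np.ndarray]]):
        self.coords = {
            t: {a: np.asarray(xyz, dtype=float) for a, xyz in atoms.items()}
            for t, atoms in coords.items()
        }
        for t, atoms in self.coords.items():
            lengths = {a: len(xyz) for a, xyz in atoms.items()}
            if len(set(lengths.values())) > 1:
                raise ValueError(f"{t}: inconsistent atom array lengths {lengths}")

    def length(self, transcript: str) -> int:
        atoms = self.coords[transcript]
        return len(next(iter(atoms.values())))

    def atom_coords(self, transcript: str, atom: str = O2_PRIME) -> np.ndarray:
        return self.coords[transcript][atom]

    def resolved(self, transcript: str, atom: str = O2_PRIME) -> np.ndarray:
        """Boolean mask of positions with finite coordinates for ``atom``."""
        return np.isfinite(self.atom_coords(transcript, atom)).all(axis=1)

    def qc_report(self) -> pd.DataFrame:
        rows = [
            (t, self.length(t), int(self.resolved(t).sum()))
            for t in sorted(self.coords)
        ]
        return pd.DataFrame(rows, columns=["transcript", "length", "resolved_o2"])

    @classmethod
    def from_pdb(
        cls,
        pdb_path: str | os.PathLike,
        chain_map: "pd.DataFrame | str | os.PathLike",
        atoms: Sequence[str] = STANDARD_ATOMS,
    ) -> "StructureModel":
        """Load a PDB/mmCIF model through a chain->transcript mapping table.

        ``chain_map`` columns: pdb_chain, pdb_resnum, transcript, position
        (transcript positions 0-based).  Residues mapped but absent from
        the model, or lacking an atom, stay NaN and are excluded from
        distance calculations downstream.
        """
        if not isinstance(chain_map, pd.DataFrame):
            chain_map = pd.read_csv(chain_map, sep="\t", comment="#")
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        model = st[0]
        chain_names = {ch.name for ch in model}
        missing = set(chain_map["pdb_chain"].astype(str)) - chain_names
        if missing:
            raise ValueError(f"chains {sorted(missing)} not present in {pdb_path}")

        atom_xyz: dict[tuple[str, int, str], np.ndarray] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    key = (chain.name, res.seqid.num, atom.name)
                    atom_xyz.setdefault(
                        key, np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    )

        coords: dict[str, dict[str, np.ndarray]] = {}
        for transcript, sub in chain_map.groupby("transcript"):
            L = int(sub["position"].max()) + 1
            coords[str(transcript)] = {
                a: np.full((L, 3), np.nan) for a in atoms
            }
            for row in sub.itertuples():
                for a in atoms:
                    xyz = atom_xyz.get((str(row.pdb_chain), int(row.pdb_resnum), a))
                    if xyz is not None:
                        coords[str(transcript)][a][int(row.position)] = xyz
        return cls(coords)


@dataclass
class BasePairAnnotation:
    """Unordered base-pair set with WC / non-WC tags (0-based positions)."""

    pairs: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for (i, j), kind in self.pairs.items():
            if i == j:
                raise ValueError(f"position {i} paired with itself")
            norm[(min(i, j), max(i, j))] = kind
        self.pairs = norm

    def __len__(self) -> int:
        return len(self.pairs)

    def partners(self) -> set[int]:
        return {p for ij in self.pairs for p in ij}

    @classmethod
    def from_dotbracket(cls, db: str) -> "BasePairAnnotation":
        """Parse dot-bracket; supports nested () and pseudoknot [] {} <> tiers."""
        openers = {"(": ")", "[": "]", "{": "}", "<": ">"}
        closers = {v: k for k, v in openers.items()}
        stacks: dict[str, list[int]] = {k: [] for k in openers}
        pairs = {}
        for i, ch in enumerate(db):
            if ch in openers:
                stacks[ch].append(i)
            elif ch in closers:
                opener = closers[ch]
                if not stacks[opener]:
                    raise ValueError(f"unbalanced {ch!r} at {i}")
                pairs[(stacks[opener].pop(), i)] = "WC"
            elif ch not in ".-":
                raise ValueError(f"unexpected character {ch!r} at {i}")
        leftovers = [s for st in stacks.values() for s in st]
        if leftovers:
            raise ValueError(f"unclosed brackets at {sorted(leftovers)}")
        return cls(pairs)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "BasePairAnnotation":
        """Pair-list TSV: columns i, j, type (0-based positions)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls({(int(r.i), int(r.j)): str(r.type) for r in df.itertuples()})

    def to_tsv(self, path: str | os.PathLike) -> None:
        rows = sorted((i, j, k) for (i, j), k in self.pairs.items())
        pd.DataFrame(rows, columns=["i", "j", "type"]).to_csv(path, sep="\t", index=False)

    def pairs_between(self, left: Segment, right: Segment) -> int:
        """Number of annotated pairs connecting the two arm intervals."""
        n = 0
        for i, j in self.pairs:
            fwd = left.start <= i < left.end and right.start <= j < right.end
            rev = left.start <= j < left.end and right.start <= i < right.end
            if fwd or rev:
                n += 1
        return n


def flexible_mask(
    length: int,
    pairs: BasePairAnnotation | None = None,
    reactivity: np.ndarray | None = None,
    reactivity_threshold: float | None = None,
) -> np.ndarray:
    """Flexible = single-stranded (unpaired) OR reactivity >= threshold."""
    mask = np.ones(length, dtype=bool)
    if pairs is not None:
        for p in pairs.partners():
            if p < length:
                mask[p] = False
    if reactivity is not None and reactivity_threshold is not None:
        react = np.asarray(reactivity, dtype=float)
        with np.errstate(invalid="ignore"):
            mask |= np.nan_to_num(react, nan=-np.inf) >= reactivity_threshold
    return mask


@dataclass(frozen=True)
class DistanceRecord:
    """Per-read spatial measurement against the structure model."""

    read_id: str
    dg_id: str | None
    d_min: float
    minpos: tuple[int, int]  # (offset_left, offset_right) from the 3' ends
    d_window: float | None = None
    category: str | None = None


def _arm_offset_positions(seg: Segment) -> tuple[np.ndarray, np.ndarray]:
    """(offsets from 3' end starting at 1, reference positions), full arm."""
    offs = np.arange(1, seg.length + 1)
    if seg.strand == "+":
        pos = seg.end - offs
    else:
        pos = seg.start + offs - 1
    return offs, pos


def _flexible_arm(
    seg: Segment, model: StructureModel, mask: Mapping[str, np.ndarray], atom: str
) -> tuple[np.ndarray, np.ndarray]:
    offs, pos = _arm_offset_positions(seg)
    m = np.asarray(mask[seg.ref_id], dtype=bool)
    resolved = model.resolved(seg.ref_id, atom)
    L = model.length(seg.ref_id)
    ok = (pos >= 0) & (pos < min(len(m), L))
    ok[ok] &= m[pos[ok]] & resolved[pos[ok]]
    return offs[ok], pos[ok]


def min_arm_distance(
    read: GappedAlignment,
    model: StructureModel,
    mask: Mapping[str, np.ndarray],
    atom: str = O2_PRIME,
) -> tuple[float, tuple[int, int]] | None:
    """Minimum atom distance between flexible nucleotides on the two arms.

    Returns ``(d_min, (offset_left, offset_right))`` with offsets counted
    from each arm's 3' end (terminal nt = 1); ties resolved toward the
    smallest (left, right) offsets.  ``None`` when either arm has no
    flexible resolved nucleotide.
    """
    loff, lpos = _flexible_arm(read.left_arm, model, mask, atom)
    roff, rpos = _flexible_arm(read.right_arm, model, mask, atom)
    if len(loff) == 0 or len(roff) == 0:
        return None
    lxyz = model.atom_coords(read.left_arm.ref_id, atom)[lpos]
    rxyz = model.atom_coords(read.right_arm.ref_id, atom)[rpos]
    d = np.linalg.norm(lxyz[:, None, :] - rxyz[None, :, :], axis=2)
    dmin = d.min()
    ii, jj = np.nonzero(d == dmin)
    candidates = sorted(zip(loff[ii], roff[jj]))
    best = candidates[0]
    return float(dmin), (int(best[0]), int(best[1]))


def window_distance(
    read: GappedAlignment,
    model: StructureModel,
    mask: Mapping[str, np.ndarray],
    window: tuple[int, int] = (3, 7),
    atom: str = O2_PRIME,
) -> float | None:
    """Minimum distance with both offsets restricted to ``window`` (inclusive)."""
    lo, hi = window
    loff, lpos = _flexible_arm(read.left_arm, model, mask, atom)
    roff, rpos = _flexible_arm(read.right_arm, model, mask, atom)
    lsel = (loff >= lo) & (loff <= hi)
    rsel = (roff >= lo) & (roff <= hi)
    if not lsel.any() or not rsel.any():
        return None
    lxyz = model.atom_coords(read.left_arm.ref_id, atom)[lpos[lsel]]
    rxyz = model.atom_coords(read.right_arm.ref_id, atom)[rpos[rsel]]
    d = np.linalg.norm(lxyz[:, None, :] - rxyz[None, :, :], axis=2)
    return float(d.min())


def shuffle_reads(
    reads: Sequence[GappedAlignment],
    ref_lengths: Mapping[str, int],
    seed: int,
) -> list[GappedAlignment]:
    """Positional null model: arm lengths kept, positions uniform, arms re-sorted.

    Each arm is independently placed uniformly on its own reference;
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for read in reads:
        new_segs = []
        for seg in read.segments:
            L = ref_lengths[seg.ref_id]
            if seg.length > L:
                raise ValueError(f"arm longer than reference {seg.ref_id}")
            start = int(rng.integers(0, L - seg.length + 1))
            new_segs.append(Segment(seg.ref_id, start, start + seg.length, seg.strand))
        shuf = GappedAlignment(read.read_id, tuple(new_segs))
        shuf.alignment_class = read.alignment_class
        out.append(shuf)
    return out


def categorize(
    read: GappedAlignment,
    pairs: BasePairAnnotation,
    es_regions: Sequence[tuple[str, int, int]] = (),
    min_bp: int = 2,
) -> str:
    """Structural category of a gapped read.

    ``dsRNA`` when >= min_bp annotated base pairs connect the two arms
    (helix-constrained proximity); otherwise ``es_tertiary`` when either
    arm overlaps an expansion-segment region; otherwise ``core_tertiary``.
    Symmetric in arm order.
    """
    if pairs.pairs_between(read.left_arm, read.right_arm) >= min_bp:
        return "dsRNA"
    for arm in (read.left_arm, read.right_arm):
        for ref, start, end in es_regions:
            if ref == arm.ref_id and arm.start < end and start < arm.end:
                return "es_tertiary"
    return "core_tertiary"


def read_regions_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """BED intervals (chrom, start, end), 0-based half-open."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append((chrom, int(start), int(end)))
    return regions


def distance_summary(
    records: Iterable[DistanceRecord],
    thresholds: Sequence[float] = (20.0, 40.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category fractions below each threshold plus a pooled CDF table.

    Categories with no records report NaN fractions.  The CDF table lists
    each category's sorted distances with cumulative fractions.
    """
    recs = list(records)
    rows = []
    cdf_rows = []
    for cat in ("all",) + CATEGORIES:
        ds = np.array(
            [r.d_min for r in recs if cat == "all" or r.category == cat], dtype=float
        )
        row: dict[str, object] = {"category": cat, "n": len(ds)}
        for t in thresholds:
            row[f"frac_le_{t:g}A"] = float((ds <= t).mean()) if len(ds) else float("nan")
        rows.append(row)
        if len(ds):
            ds.sort()
            cdf_rows.extend(
                {"category": cat, "distance_A": float(d), "cum_frac": (k + 1) / len(ds)}
                for k, d in enumerate(ds)
            )
    return pd.DataFrame(rows), pd.DataFrame(cdf_rows, columns=["category", "distance_A", "cum_frac"])


def sqrt_scale(matrix: np.ndarray) -> np.ndarray:
    return np.sqrt(np.asarray(matrix, dtype=float))


def contact_map(
    reads: Iterable[GappedAlignment],
    ref_length: int,
    bin_size: int = 25,
    reference_pairs: Iterable[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned intra-transcript contact matrix.

    Read counts go to the upper triangle (row = left-arm midpoint bin,
    col = right-arm midpoint bin, row <= col); reference pair counts, when
    given, to the lower triangle.  Returns ``(raw_counts, display)`` where
    ``display`` has the read counts square-root scaled.
    """
    n_bins = math.ceil(ref_length / bin_size)
    raw = np.zeros((n_bins, n_bins))
    for read in reads:
        li = ((read.left_arm.start + read.left_arm.end - 1) // 2) // bin_size
        ri = ((read.right_arm.start + read.right_arm.end - 1) // 2) // bin_size
        i, j = min(li, ri), max(li, ri)
        raw[i, j] += 1
    display = sqrt_scale(raw)
    if reference_pairs is not None:
        for i, j in reference_pairs:
            bi, bj = i // bin_size, j // bin_size
            lo, hi = min(bi, bj), max(bi, bj)
            if lo != hi:
                display[hi, lo] += 1
    return raw, display


def minpos_heatmap(
    records: Iterable[DistanceRecord], max_offset: int = 15
) -> np.ndarray:
    """Frequency matrix of minimum-distance offsets; entry [k-1, l-1] counts
    records whose closest pair sits at offsets (k from left 3' end, l from
    right).  Display with :func:`sqrt_scale`; raw frequencies sum to the
    record count (offsets beyond ``max_offset`` are clipped to the edge)."""
    m = np.zeros((max_offset, max_offset))
    for rec in records:
        i = min(rec.minpos[0], max_offset) - 1
        j = min(rec.minpos[1], max_offset) - 1
        m[i, j] += 1
    return m


def measure_reads(
    reads: Iterable[GappedAlignment],
    model: StructureModel,
    mask: Mapping[str, np.ndarray],
    pairs: BasePairAnnotation | None = None,
    es_regions: Sequence[tuple[str, int, int]] = (),
    window: tuple[int, int] = (3, 7),
    min_bp: int = 2,
    dg_of_read: Mapping[str, str] | None = None,
) -> tuple[list[DistanceRecord], list[tuple[str, str]]]:
    """Per-read distance records; returns (records, skipped (read_id, reason))."""
    records, skipped = [], []
    for read in reads:
        res = min_arm_distance(read, model, mask)
        if res is None:
            skipped.append((read.read_id, "no flexible resolved nt on an arm"))
            continue
        d_min, minpos = res
        d_window = window_distance(read, model, mask, window=window)
        category = categorize(read, pairs, es_regions, min_bp) if pairs is not None else None
        records.append(
            DistanceRecord(
                read_id=read.read_id,
                dg_id=(dg_of_read or {}).get(read.read_id),
                d_min=d_min,
                minpos=minpos,
                d_window=d_window,
                category=category,
            )
        )
    return records, skipped


def write_records_tsv(records: Iterable[DistanceRecord], path: str | os.PathLike) -> None:
    rows = [
        (r.read_id, r.dg_id or "", r.d_min, r.minpos[0], r.minpos[1],
         "" if r.d_window is None else r.d_window, r.category or "")
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["read_id", "dg_id", "d_min_A", "minpos_left", "minpos_right", "d_window_A", "category"],
    ).to_csv(path, sep="\t", index=False)
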