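"""Crosslink-site calling from exonuclease trim stops.

Exonuclease trimming stops a fixed small distance downstream (3') of a
crosslinked nucleotide, so within one duplex group the arm 3' ends pile up
``offset - 1`` nt past the crosslink.  The caller takes the median 3' end
per arm (robust against incompletely trimmed outliers) and steps back
``offset - 1`` nt, with the 3'-terminal nucleotide counted as offset 1.
The empirical trim-stop window is offsets 3-7 with a peak at 5.

Also provided are per-offset diagnostic profiles along the arms: the
fraction of single-stranded nucleotides, the mean chemical reactivity, and
base composition near the called sites — the enrichment of flexible
nucleotides at offset ~5 is the signature of successful trimming.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import GappedAlignment, Segment
from .duplex import DuplexGroup

DEFAULT_OFFSET = 5
DEFAULT_WINDOW = (3, 7)


@dataclass(frozen=True)
class CrosslinkCall:
    """A putative crosslinked nucleotide pair (0-based transcript coords)."""

    dg_id: str
    ref_left: str
    site_left: int
    ref_right: str
    site_right: int
    offset: int = DEFAULT_OFFSET
    window: tuple[int, int] = DEFAULT_WINDOW
    support: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo <= self.offset <= hi:
            raise ValueError(f"offset {self.offset} outside window {self.window}")


def lower_median(values: Sequence[int]) -> int:
    """Median taking the lower of the two middles for even n (stays on-grid)."""
    ordered = sorted(values)
    if not ordered:
        raise ValueError("median of empty collection")
    return ordered[(len(ordered) - 1) // 2]


def _site_from_end(end3: int, strand: str, offset: int) -> int:
    # stepping offset-1 nt in the 5' direction from the 3'-terminal nt
    return end3 - (offset - 1) if strand == "+" else end3 + (offset - 1)


def call_sites(
    dg: DuplexGroup,
    offset: int = DEFAULT_OFFSET,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> CrosslinkCall:
    """Call the crosslinked pair of one duplex group from its arm 3' ends."""
    if dg.coverage < 1:
        raise ValueError(f"{dg.dg_id}: empty duplex group")
    left_ends = [r.left_arm.three_prime_end for r in dg.reads]
    right_ends = [r.right_arm.three_prime_end for r in dg.reads]
    return CrosslinkCall(
        dg_id=dg.dg_id,
        ref_left=dg.left_arm.ref_id,
        site_left=_site_from_end(lower_median(left_ends), dg.left_arm.strand, offset),
        ref_right=dg.right_arm.ref_id,
        site_right=_site_from_end(lower_median(right_ends), dg.right_arm.strand, offset),
        offset=offset,
        window=window,
        support=dg.coverage,
    )


@dataclass
class OffsetProfile:
    """Per-offset values along the arms, offset 1 = 3'-terminal nucleotide."""

    values: np.ndarray  # shape (max_offset,)
    n: np.ndarray  # arms contributing at each offset

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values, "n": self.n})


def _arm_positions(seg: Segment, max_offset: int) -> np.ndarray:
    """Reference positions of offsets 1..min(len, max_offset) from the 3' end."""
    k = min(seg.length, max_offset)
    if seg.strand == "+":
        return seg.end - 1 - np.arange(k)
    return seg.start + np.arange(k)


def _iter_arms(reads: Iterable[GappedAlignment]):
    for read in reads:
        yield read.left_arm
        yield read.right_arm


def profile_ss_fraction(
    reads: Iterable[GappedAlignment],
    ss_mask: Mapping[str, np.ndarray],
    max_offset: int = 15,
) -> OffsetProfile:
    """Fraction of arms whose k-th nt from the 3' end is single-stranded."""
    hits = np.zeros(max_offset)
    n = np.zeros(max_offset)
    for arm in _iter_arms(reads):
        mask = ss_mask[arm.ref_id]
        pos = _arm_positions(arm, max_offset)
        valid = (pos >= 0) & (pos < len(mask))
        k = np.arange(len(pos))[valid]
        n[k] += 1
        hits[k] += mask[pos[valid]].astype(float)
    if not n.any():
        raise ValueError("no arms to profile")
    with np.errstate(invalid="ignore"):
        vals = np.where(n > 0, hits / np.maximum(n, 1), np.nan)
    return OffsetProfile(vals, n.astype(int))


def profile_reactivity(
    reads: Iterable[GappedAlignment],
    reactivity: Mapping[str, np.ndarray],
    max_offset: int = 15,
) -> OffsetProfile:
    """Mean per-nucleotide reactivity at each offset; NaN values excluded."""
    total = np.zeros(max_offset)
    n = np.zeros(max_offset)
    any_arm = False
    for arm in _iter_arms(reads):
        any_arm = True
        vals = reactivity[arm.ref_id]
        pos = _arm_positions(arm, max_offset)
        valid = (pos >= 0) & (pos < len(vals))
        k = np.arange(len(pos))[valid]
        v = vals[pos[valid]].astype(float)
        finite = np.isfinite(v)
        n[k[finite]] += 1
        total[k[finite]] += v[finite]
    if not any_arm:
        raise ValueError("no arms to profile")
    with np.errstate(invalid="ignore"):
        vals = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return OffsetProfile(vals, n.astype(int))


def nt_composition(
    calls: Iterable[CrosslinkCall],
    sequences: Mapping[str, str],
    halfwidth: int = 2,
) -> dict[str, float]:
    """Base composition in ±halfwidth nt windows around called sites.

    Windows extending beyond the reference are clipped.  Returns fractions
    over A/C/G/U (T read as U), ignoring other characters.
    """
    counts: dict[str, int] = {b: 0 for b in "ACGU"}
    for call in calls:
        for ref, site in ((call.ref_left, call.site_left), (call.ref_right, call.site_right)):
            seq = sequences[ref]
            lo = max(0, site - halfwidth)
            hi = min(len(seq), site + halfwidth + 1)
            for base in seq[lo:hi].upper().replace("T", "U"):
                if base in counts:
                    counts[base] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no bases in any call window")
    return {b: c / total for b, c in counts.items()}


CALL_COLUMNS = [
    "dg_id", "ref_left", "site_left", "ref_right", "site_right",
    "offset", "window_lo", "window_hi", "support",
]


def write_calls_tsv(calls: Iterable[CrosslinkCall], path: str | os.PathLike) -> None:
    """Calls table, positions 0-based."""
    rows = [
        (
            c.dg_id, c.ref_left, c.site_left, c.ref_right, c.site_right,
            c.offset, c.window[0], c.window[1], c.support,
        )
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | os.PathLike) -> list[CrosslinkCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        CrosslinkCall(
            dg_id=str(r.dg_id),
            ref_left=str(r.ref_left),
            site_left=int(r.site_left),
            ref_right=str(r.ref_right),
            site_right=int(r.site_right),
            offset=int(r.offset),
            window=(int(r.window_lo), int(r.window_hi)),
            support=int(r.support),
        )
        for r in df.itertuples()
    ]
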