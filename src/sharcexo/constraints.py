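"""Rosetta-dialect distance constraints and model clash checking.

Crosslink calls become ``AtomPair ... LINEAR_PENALTY`` restraints between
ribose O2' atoms: zero energy within a trough around an ideal distance and
a linear ramp beyond.  With the default parameters (ideal 10.0 Å, well
depth 0, trough 10 Å, slope 1.0 per Å) distances of 0-20 Å carry no
penalty and each extra ångström costs one energy unit — matching how
flexible-linker crosslinks bound, rather than pin, a distance.

The clash check screens candidate models against their surroundings:
every modeled nucleotide phosphate is compared to environment RNA
phosphates and protein C-alpha atoms, and any pair strictly closer than
5 Å counts as a clash.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .calling import CrosslinkCall

logger = logging.getLogger(__name__)

PRIME = "′"
ATOM_O2_PRIME = f"O2{PRIME}"
ATOM_O2_ASCII = "O2'"
DEFAULT_PARAMS = (10.0, 0, 10, 1.0)  # ideal Å, well depth, trough Å, slope per Å


def _fmt(x) -> str:
    """Preserve int/float spelling: 0 -> '0', 10 -> '10', 10.0 -> '10.0'."""
    return str(x)


@dataclass(frozen=True)
class ConstraintRecord:
    pos_i: int
    pos_j: int
    ideal: float = DEFAULT_PARAMS[0]
    penalty0: float = DEFAULT_PARAMS[1]
    trough: float = DEFAULT_PARAMS[2]
    slope: float = DEFAULT_PARAMS[3]
    atom: str = ATOM_O2_PRIME

    def __post_init__(self) -> None:
        if self.trough < 0:
            raise ValueError("trough must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")

    def line(self, ascii_atoms: bool = False) -> str:
        atom = ATOM_O2_ASCII if ascii_atoms else self.atom
        return (
            f"AtomPair {atom} {self.pos_i} {atom} {self.pos_j} LINEAR_PENALTY "
            f"{_fmt(self.ideal)} {_fmt(self.penalty0)} {_fmt(self.trough)} {_fmt(self.slope)}"
        )

    def penalty(self, d: float) -> float:
        return penalty(d, (self.ideal, self.penalty0, self.trough, self.slope))


def penalty(d: float, params: Sequence[float] = DEFAULT_PARAMS) -> float:
    """LINEAR_PENALTY energy at distance ``d``.

    ``penalty0 + slope * max(0, |d - ideal| - trough)``: flat (at the well
    depth) on ``[ideal - trough, ideal + trough]`` and piecewise linear
    outside, hence continuous and non-negative for non-negative well depth.
    """
    ideal, penalty0, trough, slope = params
    return penalty0 + slope * max(0.0, abs(d - ideal) - trough)


def load_renumber_map(path: str | os.PathLike) -> dict[tuple[str, int], int]:
    """TSV (transcript, position, model_resnum): transcript coords (0-based)
    to model-local Rosetta residue numbers (1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        (str(r.transcript), int(r.position)): int(r.model_resnum)
        for r in df.itertuples()
    }


def constraints_from_calls(
    calls: Iterable[CrosslinkCall],
    renumber_map: Mapping[tuple[str, int], int] | None = None,
    params: Sequence[float] = DEFAULT_PARAMS,
) -> tuple[list[ConstraintRecord], list[CrosslinkCall]]:
    """Map calls into the modeled segment; unmappable calls are skipped.

    With no renumber map, transcript positions are converted to 1-based
    residue numbers directly.
    """
    ideal, penalty0, trough, slope = params
    records, skipped = [], []
    for call in calls:
        if renumber_map is None:
            i, j = call.site_left + 1, call.site_right + 1
        else:
            ki = (call.ref_left, call.site_left)
            kj = (call.ref_right, call.site_right)
            if ki not in renumber_map or kj not in renumber_map:
                logger.warning("call %s maps outside the modeled segment; skipped", call.dg_id)
                skipped.append(call)
                continue
            i, j = renumber_map[ki], renumber_map[kj]
        records.append(
            ConstraintRecord(i, j, ideal=ideal, penalty0=penalty0, trough=trough, slope=slope)
        )
    return records, skipped


def write_constraints(
    records: Iterable[ConstraintRecord],
    path: str | os.PathLike | None = None,
    ascii_atoms: bool = False,
) -> str:
    """Render (and optionally write) the constraint file text."""
    text = "".join(rec.line(ascii_atoms=ascii_atoms) + "\n" for rec in records)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def parse_constraints(text: str) -> list[ConstraintRecord]:
    """Inverse of :func:`write_constraints`; accepts prime or ASCII atom names."""

    def num(tok: str):
        return int(tok) if tok.lstrip("+-").isdigit() else float(tok)

    records = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != 10 or toks[0] != "AtomPair" or toks[5] != "LINEAR_PENALTY":
            raise ValueError(f"line {ln}: not an AtomPair LINEAR_PENALTY constraint")
        atom = toks[1]
        if atom == ATOM_O2_ASCII:
            atom = ATOM_O2_PRIME
        records.append(
            ConstraintRecord(
                pos_i=int(toks[2]),
                pos_j=int(toks[4]),
                ideal=num(toks[6]),
                penalty0=num(toks[7]),
                trough=num(toks[8]),
                slope=num(toks[9]),
                atom=atom,
            )
        )
    return records


def clash_count(
    model_coords: np.ndarray,
    env_coords: np.ndarray,
    threshold: float = 5.0,
) -> tuple[int, list[tuple[int, int]]]:
    """Count (model atom, environment atom) pairs strictly closer than ``threshold``.

    Intended usage: model nucleotide P atoms against environment RNA P and
    protein CA atoms.  Uses a KD-tree; returns the count and the index
    pairs, sorted.
    """
    model_coords = np.asarray(model_coords, dtype=float)
    env_coords = np.asarray(env_coords, dtype=float)
    pairs: list[tuple[int, int]] = []
    if len(model_coords) == 0 or len(env_coords) == 0:
        return 0, pairs
    tree = cKDTree(env_coords)
    for i, neighbors in enumerate(tree.query_ball_point(model_coords, r=threshold)):
        for j in neighbors:
            if np.linalg.norm(model_coords[i] - env_coords[j]) < threshold:
                pairs.append((i, int(j)))
    pairs.sort()
    return len(pairs), pairs
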