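"""Synthetic crosslink-and-trim experiment generator with ground truth.

The generator inverts the measurement chain: it picks crosslinked
nucleotide pairs among *flexible* nucleotides whose O2'-O2' distance is
within the crosslinker reach, then emits gapped reads whose two arms end
(3') a stochastic trim offset downstream of the crosslinked nucleotides.
The trim-stop offset is drawn from the empirical 3-7 window with the mode
at 5; an ``untrimmed_fraction`` of reads instead carries uninformative,
broadly distributed 3' ends, reproducing the no-trimming control in which
the offset-5 enrichment disappears.

Toy structures use synthetic ideal-helix geometry: residues on an A-form
like cylinder (rise 2.81 Å, twist 32.7°), hairpin loops as semicircular
arcs, and fixed pseudo-atom offsets for P and C4' relative to O2'.  They
are geometric stand-ins adequate for distance logic, not physical models.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from .structure import BasePairAnnotation, StructureModel, flexible_mask

RISE = 2.81  # Å per stacked residue along the helix axis
TWIST = np.deg2rad(32.7)
RADIUS = 9.0  # Å, backbone cylinder radius
STRAND_PHASE = np.deg2rad(150.0)  # angular offset of the paired strand
TIP_GAP = 6.0  # Å between the two hairpin loop apexes (two_helix_loop)
BULGE_SPACING = 6  # stem rungs between internal loops (two_helix_loop)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults are the characterised operating point: crosslinker reach
    ~7 Å, trim stops on offsets 3-7 peaking at 5, ~10 reads per crosslink
    and arms of 13-18 nt.  ``min_separation`` excludes nucleotide pairs
    too close along the sequence to yield two non-overlapping arms.
    """

    linker_max: float = 7.0
    n_crosslinks: int = 200
    reads_per_crosslink: int = 10
    trim_offsets: tuple[int, ...] = (3, 4, 5, 6, 7)
    trim_weights: tuple[float, ...] = (0.15, 0.2, 0.3, 0.2, 0.15)
    untrimmed_fraction: float = 0.0
    untrimmed_max_offset: int = 15
    arm_length_range: tuple[int, int] = (13, 18)
    min_separation: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linker_max <= 0:
            raise ValueError("linker_max must be positive")
        if len(self.trim_offsets) != len(self.trim_weights):
            raise ValueError("trim offset/weight lengths differ")
        if max(self.trim_offsets) > self.arm_length_range[0]:
            raise ValueError("trim offsets must fit inside the shortest arm")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("trim_offsets", "trim_weights", "arm_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = asdict(self)
        for key in ("trim_offsets", "trim_weights", "arm_length_range"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class ToyStructure:
    """A generated structure: coordinates, secondary structure, identity map."""

    name: str
    coords: dict[str, np.ndarray]  # atom -> (L, 3)
    dotbracket: str

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    @property
    def pairs(self) -> BasePairAnnotation:
        return BasePairAnnotation.from_dotbracket(self.dotbracket)

    def to_structure_model(self) -> StructureModel:
        return StructureModel({self.name: self.coords})

    def ss_mask(self) -> np.ndarray:
        return flexible_mask(self.length, self.pairs)

    def chain_map(self, chain: str = "A") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pdb_chain": chain,
                "pdb_resnum": np.arange(1, self.length + 1),
                "transcript": self.name,
                "position": np.arange(self.length),
            }
        )

    def write_chain_map(self, path: str | os.PathLike, chain: str = "A") -> None:
        self.chain_map(chain).to_csv(path, sep="\t", index=False)

    def write_dotbracket(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n{self.dotbracket}\n")

    def to_pdb(self, path: str | os.PathLike, chain_name: str = "A") -> None:
        st = gemmi.Structure()
        st.name = self.name
        model = gemmi.Model("1")
        chain = gemmi.Chain(chain_name)
        for i in range(self.length):
            res = gemmi.Residue()
            res.name = "A"
            res.seqid = gemmi.SeqId(i + 1, " ")
            for atom_name, xyz in self.coords.items():
                if not np.isfinite(xyz[i]).all():
                    continue
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[0])
                atom.occ = 1.0
                atom.pos = gemmi.Position(*xyz[i])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


def _pseudo_atoms(points: np.ndarray) -> dict[str, np.ndarray]:
    """Place O2' on the backbone trace, P and C4' at fixed small offsets."""
    radial = points.copy()
    radial[:, 2] = 0.0
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    radial = np.divide(radial, norms, out=np.zeros_like(radial), where=norms > 1e-9)
    return {
        "O2'": points,
        "P": points + 1.5 * radial + np.array([0.0, 0.0, 1.0]),
        "C4'": points - 1.0 * radial + np.array([0.0, 0.0, 0.5]),
    }


def _duplex_points(n_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Two antiparallel strands on the helix cylinder, paired per rung."""
    k = np.arange(n_bp)
    a = np.stack(
        [RADIUS * np.cos(k * TWIST), RADIUS * np.sin(k * TWIST), k * RISE], axis=1
    )
    b = np.stack(
        [
            RADIUS * np.cos(k * TWIST + STRAND_PHASE),
            RADIUS * np.sin(k * TWIST + STRAND_PHASE),
            k * RISE,
        ],
        axis=1,
    )
    return a, b


def _hairpin_points(n_bp: int, n_loop: int) -> np.ndarray:
    """Hairpin residue positions in sequence order (5' strand, loop, 3' strand)."""
    a, b = _duplex_points(n_bp)
    pa, pb = a[-1], b[-1]
    center = (pa + pb) / 2
    r_loop = np.linalg.norm(pa - pb) / 2
    phi = np.pi * np.arange(1, n_loop + 1) / (n_loop + 1)
    loop = (
        center
        + np.cos(phi)[:, None] * (pa - center)
        + np.sin(phi)[:, None] * r_loop * np.array([0.0, 0.0, 1.0])
    )
    return np.vstack([a, loop, b[::-1]])


def make_toy_structure(
    kind: str = "two_helix_loop",
    length: int | None = None,
    seed: int = 0,
    name: str = "toyRNA",
) -> ToyStructure:
    """Generate a toy structure of the requested kind.

    ``helix``: a fully paired duplex (``length`` even; position k pairs
    with length-1-k).  ``two_helix_loop``: two hairpins joined by a
    single-stranded linker and stacked coaxially loop-tip to loop-tip
    ~6 Å apart, so only the apical loop nucleotides of the two hairpins
    are within crosslinker reach of each other; periodic internal-loop
    rungs along the stems provide flexible nucleotides spread over the
    whole structure (they matter for the shuffled null).  ``random_coil``:
    an unpaired persistent random walk.  Deterministic for
    (kind, length, seed).
    """
    if length is None:
        length = {"helix": 40, "two_helix_loop": 143, "random_coil": 80}[kind]
    if kind == "helix":
        if length % 2:
            raise ValueError("helix length must be even")
        n = length // 2
        a, b = _duplex_points(n)
        points = np.vstack([a, b[::-1]])
        db = "(" * n + ")" * n
    elif kind == "two_helix_loop":
        n_loop, n_link = 5, 5
        n_bp = (length - 2 * n_loop - n_link) // 4
        if n_bp < 8:
            raise ValueError("length too short for two hairpins (need >= 47)")
        used = 4 * n_bp + 2 * n_loop + n_link
        n_link += length - used  # absorb rounding into the linker
        bulges = set(range(4, n_bp - 4, BULGE_SPACING))
        h1 = _hairpin_points(n_bp, n_loop)
        h2 = _hairpin_points(n_bp, n_loop)
        # flip hairpin 2 upside-down and park its loop apex TIP_GAP from hairpin 1's
        h2 = h2 * np.array([1.0, -1.0, -1.0])
        a1 = h1[n_bp + n_loop // 2]
        a2_now = h2[n_bp + n_loop // 2]
        h2 = h2 + (a1 + np.array([TIP_GAP, 0.0, 0.0]) - a2_now)
        # linker arcs away laterally so it stays clear of the loop contact
        p_end1, p_start2 = h1[-1], h2[0]
        mid = (p_end1 + p_start2) / 2 + np.array([-18.0, 0.0, 0.0])
        t = (np.arange(1, n_link + 1) / (n_link + 1))[:, None]
        linker = (1 - t) ** 2 * p_end1 + 2 * (1 - t) * t * mid + t**2 * p_start2
        points = np.vstack([h1, linker, h2])
        strand5 = "".join("." if k in bulges else "(" for k in range(n_bp))
        strand3 = "".join("." if (n_bp - 1 - m) in bulges else ")" for m in range(n_bp))
        hp_db = strand5 + "." * n_loop + strand3
        db = hp_db + "." * n_link + hp_db
    elif kind == "random_coil":
        rng = np.random.default_rng(seed)
        step = 5.9
        direction = np.array([1.0, 0.0, 0.0])
        pts = [np.zeros(3)]
        for _ in range(length - 1):
            # persistent walk: jitter the direction, keep moving forward
            direction = direction + 0.6 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pts.append(pts[-1] + step * direction)
        points = np.array(pts)
        db = "." * length
    else:
        raise ValueError(f"unknown toy structure kind {kind!r}")
    return ToyStructure(name=name, coords=_pseudo_atoms(points), dotbracket=db)


@dataclass
class GroundTruth:
    """Truth for one simulated crosslink (one would-be duplex group)."""

    crosslink_id: str
    site_left: int
    site_right: int
    distance: float
    read_ids: list[str] = field(default_factory=list)


def sample_crosslinks(
    model: StructureModel,
    mask: Mapping[str, np.ndarray] | np.ndarray,
    config: SimulationConfig,
    transcript: str | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Draw crosslinked pairs uniformly from the eligible set.

    Eligible pairs: both nucleotides flexible and resolved, O2'-O2'
    distance <= ``linker_max``, sequence separation >= ``min_separation``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if transcript is None:
        transcript = next(iter(model.coords))
    m = np.asarray(mask[transcript] if isinstance(mask, Mapping) else mask, dtype=bool)
    resolved = model.resolved(transcript)
    flex = np.nonzero(m & resolved)[0]
    xyz = model.atom_coords(transcript)[flex]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    sep = np.abs(flex[:, None] - flex[None, :])
    ii, jj = np.nonzero((d <= config.linker_max) & (sep >= config.min_separation))
    eligible = sorted({(int(flex[i]), int(flex[j])) for i, j in zip(ii, jj) if flex[i] < flex[j]})
    if not eligible:
        raise ValueError("no eligible crosslink pair within linker reach")
    picks = rng.integers(0, len(eligible), size=config.n_crosslinks)
    return [eligible[p] for p in picks]


def _sample_offset(config: SimulationConfig, rng: np.random.Generator) -> int:
    weights = np.asarray(config.trim_weights, dtype=float)
    weights = weights / weights.sum()
    return int(rng.choice(np.asarray(config.trim_offsets), p=weights))


def emit_reads(
    crosslinks: Sequence[tuple[int, int]],
    config: SimulationConfig,
    ref_name: str,
    ref_length: int,
    model: StructureModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[GroundTruth]]:
    """Emit gapped reads as SAM text plus the per-crosslink ground truth.

    Each arm's 3' end sits ``offset - 1`` nt downstream of its crosslinked
    nucleotide (offset drawn from the trim distribution, or from a broad
    uniform law for untrimmed reads); the arm extends a sampled length
    upstream.  Reads whose arms would overlap are discarded (such pairs
    are excluded by ``min_separation`` under default geometry).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{ref_name}\tLN:{ref_length}",
    ]
    truths: list[GroundTruth] = []
    lo_len, hi_len = config.arm_length_range
    for cid, (i, j) in enumerate(crosslinks):
        dist = float("nan")
        if model is not None:
            xyz = model.atom_coords(ref_name)
            dist = float(np.linalg.norm(xyz[i] - xyz[j]))
        truth = GroundTruth(f"X{cid:04d}", i, j, dist)
        for r in range(config.reads_per_crosslink):
            untrimmed = rng.random() < config.untrimmed_fraction
            arms = []
            for site in (i, j):
                if untrimmed:
                    off = int(rng.integers(1, config.untrimmed_max_offset + 1))
                else:
                    off = _sample_offset(config, rng)
                alen = int(rng.integers(lo_len, hi_len + 1))
                end3 = min(site + off - 1, ref_length - 1)
                start = max(0, end3 - alen + 1)
                arms.append((start, end3 + 1))
            (ls, le), (rs, re_) = sorted(arms)
            if le > rs:
                continue  # arms collided; unobservable as a gapped read
            qname = f"{truth.crosslink_id}R{r}"
            cigar = f"{le - ls}M{rs - le}N{re_ - rs}M"
            lines.append(
                f"{qname}\t0\t{ref_name}\t{ls + 1}\t255\t{cigar}\t*\t0\t0\t*\t*"
            )
            truth.read_ids.append(qname)
        truths.append(truth)
    return "\n".join(lines) + "\n", truths


def write_truth_tsv(truths: Sequence[GroundTruth], path: str | os.PathLike) -> None:
    rows = [
        (t.crosslink_id, t.site_left, t.site_right, t.distance, ",".join(t.read_ids))
        for t in truths
    ]
    pd.DataFrame(
        rows, columns=["crosslink_id", "site_left", "site_right", "distance_A", "read_ids"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | os.PathLike) -> list[GroundTruth]:
    df = pd.read_csv(path, sep="\t")
    return [
        GroundTruth(
            str(r.crosslink_id), int(r.site_left), int(r.site_right),
            float(r.distance_A),
            [] if pd.isna(r.read_ids) else str(r.read_ids).split(","),
        )
        for r in df.itertuples()
    ]


@dataclass
class SimulationResult:
    structure: ToyStructure
    config: SimulationConfig
    sam_text: str
    truths: list[GroundTruth]


def simulate_experiment(
    config: SimulationConfig | None = None,
    structure: ToyStructure | None = None,
    outdir: str | os.PathLike | None = None,
) -> SimulationResult:
    """Run the full generator; optionally write all artifacts to ``outdir``.

    Artifacts: ``sim.sam``, ``truth.tsv``, ``toy.pdb``, ``toy.dotbracket``,
    ``chain_map.tsv``, ``config.yaml``.
    """
    config = config or SimulationConfig()
    structure = structure or make_toy_structure("two_helix_loop", seed=config.seed)
    rng = np.random.default_rng(config.seed)
    model = structure.to_structure_model()
    crosslinks = sample_crosslinks(model, structure.ss_mask(), config,
                                   transcript=structure.name, rng=rng)
    sam_text, truths = emit_reads(
        crosslinks, config, structure.name, structure.length, model=model, rng=rng
    )
    result = SimulationResult(structure, config, sam_text, truths)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "sim.sam").write_text(sam_text)
        write_truth_tsv(truths, outdir / "truth.tsv")
        structure.to_pdb(outdir / "toy.pdb")
        structure.write_dotbracket(outdir / "toy.dotbracket")
        structure.write_chain_map(outdir / "chain_map.tsv")
        config.to_yaml(outdir / "config.yaml")
    return result
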