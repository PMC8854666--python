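"""Pipeline orchestration: classify -> filter -> cluster -> call -> measure.

The pipeline is pure composition of the stage functions; each stage is
individually invokable from the CLI.  All randomness (the shuffle null)
derives from the configured seed, so a rerun with identical config and
inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, calling, constraints, duplex, structure

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run.  Parameter defaults are the
    characterised operating point: point offset 5, window 3-7, distance
    thresholds 20/40 Å, clash threshold 5 Å, constraint parameters
    (10.0, 0, 10, 1.0)."""

    sam: str = ""
    outdir: str = "sharcexo_out"
    junctions: str | None = None
    pdb: str | None = None
    chain_map: str | None = None
    pairs_tsv: str | None = None
    dotbracket: str | None = None
    regions_bed: str | None = None
    reactivity_tsv: str | None = None
    renumber_map: str | None = None

    min_gap: int = 3
    junction_tol: int = 2
    min_overlap_frac: float = 0.5
    offset: int = 5
    window: tuple[int, int] = (3, 7)
    thresholds: tuple[float, float] = (20.0, 40.0)
    min_bp: int = 2
    reactivity_threshold: float | None = None
    constraint_params: tuple[float, float, float, float] = (10.0, 0, 10, 1.0)
    clash_threshold: float = 5.0
    contact_bin: int = 25
    n_shuffle: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("window", "thresholds", "constraint_params"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not self.sam or not os.path.exists(self.sam):
            raise FileNotFoundError(f"SAM input not found: {self.sam!r}")
        for label in ("junctions", "pdb", "chain_map", "pairs_tsv", "dotbracket",
                      "regions_bed", "renumber_map"):
            path = getattr(self, label)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{label} not found: {path!r}")
        if self.pdb is not None and self.chain_map is None:
            raise ValueError("a PDB model requires a chain_map")


def _load_dotbracket(path: str) -> str:
    lines = [l.strip() for l in open(path) if l.strip() and not l.startswith(">")]
    return "".join(lines)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all applicable stages; returns the machine-readable report.

    Distance stages run only when a structure model is configured.
    Outputs are written under ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # --- classify ---------------------------------------------------------
    alns = alignment.parse_sam(config.sam)
    ref_lengths = _ref_lengths(config.sam)
    by_class = alignment.split_by_class(alns)
    alignment.write_class_sams(alns, outdir / "alignments", ref_lengths)
    report["stages"]["classify"] = {c: len(v) for c, v in by_class.items()}
    report["stages"]["classify"]["total"] = len(alns)

    # --- filter -----------------------------------------------------------
    splice = (
        alignment.SpliceAnnotation.from_tsv(config.junctions)
        if config.junctions
        else None
    )
    gapped = by_class["gap1"] + by_class["gapm"]
    kept, dropped = alignment.filter_gaps(
        gapped, splice, min_gap=config.min_gap, junction_tol=config.junction_tol
    )
    gap1 = [a for a in kept if a.alignment_class == "gap1"]
    report["stages"]["filter"] = {
        "kept": len(kept), "dropped": len(dropped), "gap1_kept": len(gap1)
    }

    # --- cluster ----------------------------------------------------------
    dgs, removed = duplex.assemble_and_verify(gap1, min_overlap_frac=config.min_overlap_frac)
    duplex.write_bedpe(dgs, outdir / "dg.bedpe")
    duplex.write_arcs_bed(dgs, outdir / "dg_arcs.bed")
    tags = duplex.dg_tags(dgs)
    report["stages"]["cluster"] = {
        "duplex_groups": len(dgs),
        "assigned_reads": sum(dg.coverage for dg in dgs),
        "removed_non_overlap": len(removed),
    }

    # --- call sites -------------------------------------------------------
    calls = [calling.call_sites(dg, offset=config.offset, window=config.window) for dg in dgs]
    calling.write_calls_tsv(calls, outdir / "calls.tsv")
    report["stages"]["callsites"] = {"calls": len(calls)}

    # --- structure-dependent stages ---------------------------------------
    if config.pdb is not None:
        model = structure.StructureModel.from_pdb(config.pdb, config.chain_map)
        pairs = _load_pairs(config)
        regions = (
            structure.read_regions_bed(config.regions_bed) if config.regions_bed else ()
        )
        masks = _build_masks(config, model, pairs)
        assigned = [r for dg in dgs for r in dg.reads]
        records, skipped = structure.measure_reads(
            assigned, model, masks, pairs=pairs, es_regions=regions,
            window=config.window, min_bp=config.min_bp, dg_of_read=tags,
        )
        structure.write_records_tsv(records, outdir / "distance_records.tsv")
        summary, cdf = structure.distance_summary(records, thresholds=config.thresholds)
        summary.to_csv(outdir / "distance_summary.tsv", sep="\t", index=False)
        cdf.to_csv(outdir / "distance_cdf.tsv", sep="\t", index=False)

        heat = structure.minpos_heatmap(records)
        np.savetxt(outdir / "minpos_heatmap.tsv", structure.sqrt_scale(heat),
                   delimiter="\t", fmt="%.4f")

        transcript = next(iter(model.coords))
        intra = [r for r in assigned
                 if r.left_arm.ref_id == r.right_arm.ref_id == transcript]
        raw, display = structure.contact_map(
            intra, model.length(transcript), bin_size=config.contact_bin,
            reference_pairs=(pairs.pairs if pairs else None),
        )
        np.savetxt(outdir / "contact_map.tsv", display, delimiter="\t", fmt="%.4f")

        shuffled = structure.shuffle_reads(
            _subsample(assigned, config.n_shuffle, config.seed),
            {t: model.length(t) for t in model.coords},
            seed=config.seed,
        )
        null_records, _ = structure.measure_reads(shuffled, model, masks, window=config.window)
        from scipy.stats import mannwhitneyu

        obs = np.array([r.d_min for r in records])
        null = np.array([r.d_min for r in null_records])
        shuffle_p = float("nan")
        if len(obs) and len(null):
            shuffle_p = float(mannwhitneyu(null, obs, alternative="greater").pvalue)
        report["stages"]["distances"] = {
            "records": len(records),
            "skipped": len(skipped),
            "null_records": len(null_records),
            "median_dmin_A": float(np.median(obs)) if len(obs) else None,
            "null_median_dmin_A": float(np.median(null)) if len(null) else None,
            "shuffle_greater_p": shuffle_p,
        }

        # --- constraints ---------------------------------------------------
        renum = (
            constraints.load_renumber_map(config.renumber_map)
            if config.renumber_map
            else None
        )
        recs, skipped_calls = constraints.constraints_from_calls(
            calls, renum, params=config.constraint_params
        )
        constraints.write_constraints(recs, outdir / "constraints.cst")
        report["stages"]["constraints"] = {
            "written": len(recs), "skipped": len(skipped_calls)
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _subsample(reads, n, seed):
    if len(reads) <= n:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in sorted(idx)]


def _ref_lengths(sam_path: str) -> dict[str, int]:
    import pysam

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        return dict(zip(sam.references, sam.lengths))


def _load_pairs(config: PipelineConfig):
    if config.pairs_tsv:
        return structure.BasePairAnnotation.from_tsv(config.pairs_tsv)
    if config.dotbracket:
        return structure.BasePairAnnotation.from_dotbracket(
            _load_dotbracket(config.dotbracket)
        )
    return None


def _build_masks(config, model, pairs) -> dict[str, np.ndarray]:
    reactivity = None
    if config.reactivity_tsv:
        df = pd.read_csv(config.reactivity_tsv, sep="\t")
        reactivity = {}
        for t, sub in df.groupby("transcript"):
            arr = np.full(model.length(str(t)), np.nan)
            arr[sub["position"].to_numpy()] = sub["value"].to_numpy()
            reactivity[str(t)] = arr
    masks = {}
    for t in model.coords:
        masks[t] = structure.flexible_mask(
            model.length(t),
            pairs,
            None if reactivity is None else reactivity.get(t),
            config.reactivity_threshold,
        )
    return masks
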