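# Methods

## Measurement model

A bifunctional 2′-OH acylation crosslinker of reach *L* (~7 Å for the
dipicolinic reagent) joins two *flexible* nucleotides — nucleotides that are
single-stranded in the secondary structure or chemically reactive by
SHAPE-type probing — whose ribose O2′ atoms are within reach. After
fragmentation, a 3′→5′ exonuclease digests each crosslinked fragment until it
stalls near the adduct, leaving the fragment's 3′ end at a small offset
downstream of the crosslinked nucleotide. Proximity ligation joins the two
fragments; sequencing and spliced alignment yield a gapped read whose two
arms mark the two fragments. Counting the 3′-terminal nucleotide as offset 1,
the trim stop is empirically at offsets 3–7 with a mode at 5.

The caller inverts this: within a duplex group (DG — a cluster of reads
sharing both arm locations, one DG ≈ one crosslinked pair), the per-arm
**median** 3′ end is taken (the lower middle for even coverage, so calls stay
on the nucleotide grid and a single untrimmed outlier cannot move the call at
coverage ≥ 3) and the site is `median − (offset − 1)` on the plus strand
(mirrored on the minus strand), default offset 5, reported with the 3–7
window.

## Stage conventions and parameters

| parameter | default | meaning |
|---|---|---|
| `min_gap` | 3 nt | gaps of 1–2 nt are indel artifacts, not ligation gaps |
| `junction_tol` | ±2 nt | slack when matching a gap to an annotated splice junction |
| `min_overlap_frac` | 0.5 | reciprocal arm overlap (fraction of the shorter arm) for DG clustering |
| `offset` / `window` | 5 / (3, 7) | trim-stop point call and window |
| `min_bp` | 2 | annotated base pairs bridging the arms needed to call a contact helix-constrained (`dsRNA`) |
| distance thresholds | 20 / 40 Å | reporting bins for the distance CDFs |
| constraint params | (10.0, 0, 10, 1.0) | LINEAR_PENALTY ideal, well depth, trough, slope |
| `clash_threshold` | 5 Å | strict upper bound for model-P vs environment-P/Cα clashes |

Coordinates are 0-based half-open internally; SAM I/O is 1-based per the
standard; BEDPE output is 0-based; constraint files use 1-based model-local
residue numbers via an explicit renumbering table. Splice junction tables
give the first and one-past-last skipped base, 0-based.

Classification is a total function of segment geometry: one segment →
`cont`; two non-overlapping segments on one reference/strand → `gap1`; more
than two, pairwise non-overlapping → `gapm`; two overlapping → `homo`;
segments on several references/strands without same-reference overlap →
`trans`; everything else → `bad`. Deletions of ≤ 2 nt are absorbed into the
segment; `N` operations and longer deletions split arms.

DG clustering is reciprocal-overlap single-linkage. The published pipeline
delegates clustering to an external tool whose exact algorithm is not
restated here, so the overlap fraction is a documented, configurable
stand-in chosen because it reproduces arm-coherent groups and is checkable
against a brute-force overlap-graph oracle. After clustering, groups are
checked with the non-overlap rule (fail iff some member's left-arm start ≥
another member's right-arm end); failing groups are repaired by iteratively
removing the read involved in the most violations (ties by read id), the
repair being idempotent and deterministic.

The LINEAR_PENALTY energy is `penalty0 + slope·max(0, |d − ideal| − trough)`
— flat at the well depth on `[ideal − trough, ideal + trough]`, linear
outside, continuous, non-negative. With the default parameters the free
range is 0–20 Å and the cost is 1 energy unit per ångström beyond, which
encodes that a flexible-linker crosslink bounds a distance rather than
pinning it. The atom token is emitted with the typographic prime (`O2′`) as
the dialect prints it, with an ASCII `O2'` fallback flag because Rosetta
builds differ.

Distance measurement uses O2′ atoms (the crosslinked moiety is the
2′ oxygen), restricted to flexible, coordinate-resolved nucleotides; arms
without any such nucleotide are skipped and counted. Ties in the minimum
are resolved toward the smallest (left, right) offsets so the
minimum-position heatmap is deterministic. The shuffled null preserves each
arm's length and re-places it uniformly on its reference (arm order restored
by sorting); only arm lengths are preserved, not gap lengths, since the
published control states only random shuffling.

## The simulator

`simulate` inverts the measurement chain. Crosslinks are drawn uniformly
from the eligible set — flexible, resolved pairs with O2′–O2′ ≤ `linker_max`
(default 7 Å) and sequence separation ≥ `min_separation` (default 32 nt).
The separation floor exists because two fragments closer than roughly one
fragment length cannot yield two non-overlapping arms after ligation: such
events surface as `cont`/`homo` reads that the classifier removes, so
sampling them would simulate unobservable data. Per crosslink (default 200),
10 reads are emitted; each arm's 3′ end sits `offset − 1` nt downstream of
its site with offsets drawn from the 3–7 window (weights 0.15/0.2/0.3/0.2/
0.15, mode at 5), arm lengths uniform on 13–18 nt. An `untrimmed_fraction`
of reads instead draws offsets uniformly on 1–15, reproducing the
no-trimming control in which the offset-5 enrichment disappears.

The default toy structure (`two_helix_loop`, 143 nt) is two 32-bp hairpins
stacked coaxially loop-tip to loop-tip 6 Å apart, joined by a 5-nt
single-stranded linker that arcs laterally away from the contact. Only the
apical loop nucleotides of the two hairpins (plus one linker–stem internal
loop touch) are within crosslinker reach, giving eligible distances of
5.2–7.0 Å and a site spread of ±1 nt — so the ±2 nt recovery question is
well-posed. Internal-loop rungs every 6 bp along the stems contribute
flexible nucleotides spread over the ~200 Å extent of the molecule; these
are what give the shuffled null its broad distance distribution. Geometry is
a synthetic ideal-helix parameterisation (2.81 Å rise, 32.7° twist, 9 Å
backbone radius, semicircular loops, fixed pseudo-atom offsets for P and
C4′ relative to O2′), adequate for distance logic but not a physical
sugar-phosphate model.

What the simulator does *not* emulate: sequence content and sequencing
error, PCR duplication, alignment ambiguity and soft-clipping, partial
trimming correlated with adduct chemistry, inter-molecular ligation, and
the conformational heterogeneity of real RNA. Passing the synthetic
recovery and null-separation checks therefore demonstrates the estimator's
correctness under the stated generative model, not its performance on real
libraries.

## Problem sizes and numerical choices

The standard study conditions used by the test suite and the acceptance
script are 200 crosslinks × 10 reads (2 000 gapped reads) on the 143-nt toy
structure, with 1 000 shuffled reads for the null; the whole analysis runs
in seconds. Pairwise operations (clustering adjacency, verification,
distance minima) are vectorised dense scans — appropriate at these scales
and checked against quadratic brute-force oracles; the clash check uses a
KD-tree with exact re-measurement so the strict `< threshold` inequality is
honoured at boundaries. Mode statistics use 1-Å histogram bins. The
rank-sum comparison of shuffled vs observed distances is one-sided
(null greater).

## Pipeline config (YAML keys)

`sam`, `outdir`, plus optional `junctions`, `pdb`, `chain_map`,
`pairs_tsv` or `dotbracket`, `regions_bed`, `reactivity_tsv`,
`renumber_map`, and the parameters in the table above (`min_gap`,
`min_overlap_frac`, `offset`, `window`, `thresholds`, `min_bp`,
`reactivity_threshold`, `constraint_params`, `clash_threshold`,
`contact_bin`, `n_shuffle`, `seed`). Reruns with identical config and
inputs are byte-identical.

## Known limitations

- Base-pair annotations and flexibility masks are keyed by position only,
  so multi-transcript runs share one annotation namespace; the intended use
  is one transcript (or one concatenated curated reference) per run.
- Reads mapping ambiguously between identical molecules (homodimers) are
  treated as intramolecular, following the method's stated assumption.
- Gap filtering is exposed through the `classify` subcommand
  (`--junctions`) and the pipeline rather than as a separate executable;
  contact maps are written by the `distances`/`run` stages.
- Non-overlapping-group (NG) super-clustering and trans-reference DG
  assembly beyond pairing by reference are out of scope.
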