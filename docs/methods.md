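# Methods

## Scope and model

`aqpkit` codifies the sequence-level characterization of a plant aquaporin
(MIP) family. The underlying structural model is the canonical MIP fold:
six transmembrane (TM) helices, five connecting loops, and two NPA
tripeptides — one in loop B (between TM2 and TM3) and one in loop E
(between TM5 and TM6) — that form the central pore constriction together
with the four-residue ar/R filter (H2 from TM2, H5 from TM5, LE1 and LE2
from loop E). Selectivity prediction is purely pattern-based: no energetics,
no structural modelling.

## TM segmentation

Hydropathy segmentation replaces dedicated topology predictors. Each residue
is scored by the mean Kyte–Doolittle index of the window centered on it;
maximal runs of qualifying residues are merged when separated by fewer than
3 residues and discarded when shorter than 12.

* `window = 19` residues (odd; roughly one membrane-spanning helix).
* `threshold = 1.6` mean hydropathy. Window and threshold were fixed once so
  that the six planted helices of the canonical synthetic templates are
  recovered; both are exposed as arguments.

On sequences diverged away from the templates the segment count drifts below
six for a growing fraction of records; the pipeline does not depend on an
exact six-helix segmentation (see anchoring below), and the completeness
screen only requires ≥ 5 segments.

## NPA anchoring

Candidates are N-P-x tripeptides with x in `{A, T, L, V, S, C, G, I, M}` —
alanine, every third-residue variant observed in plant MIPs (threonine and
leucine in SIPs, valine in XIPs and NIP5/6 groups, serine) plus conservative
neighbours. With exactly six TM segments, the loop-B motif is sought between
TM2 and TM3 and the loop-E motif between TM5 and TM6. Otherwise the fallback
selects the candidate pair separated by 80–160 residues (typical loop-B to
loop-E spacing across the TM3–TM5 core) whose third residues score highest
under the preference A > T, V, L, S > others; ties resolve to the earliest
pair. Fewer than two candidates, or no admissible pair, is an anchoring
failure, which feeds the screen as a verdict rather than an error.

## Completeness screen

A record is `complete` when all of: length within 200–400 residues
(full-length MIPs cluster near 250–330), at least 5 TM segments, and both
NPA anchors resolved. Anything else is `pseudogene_like`, with each failed
rule listed. The published screens of this kind were manual; these rules are
a reconstruction and the thresholds are configurable arguments.

## Subfamily classification

Nearest-annotated-reference assignment replaces maximum-likelihood
phylogenetics: each record is aligned to every reference template
(Needleman–Wunsch, BLOSUM62, affine gap open 10 / extend 1, via Biopython's
PairwiseAligner) and takes the subfamily and group of the best reference by
normalized identity (matches over aligned non-gap columns). A call requires
identity ≥ 0.35 over ≥ 150 aligned columns — a conservative family-level
recognition floor well below within-subfamily identity and well above the
identity of unrelated sequences. Published family surveys use trees only to
assign subfamily membership, which nearest-reference reproduces; an optional
neighbor-joining tree (p-distances from the same pairwise alignments,
negative branch lengths clamped to zero) is emitted for inspection, without
bootstrap support.

## Signature extraction

Two complementary coordinate systems:

* **NPA-relative offsets** (authoritative where applicable). The loop-B
  region is the 10-mer `[NPA1−5, NPA1+5)` and the loop-E region the 11-mer
  `[NPA2−4, NPA2+7)`; these offsets place the canonical PIP exemplars
  `SGGHINPAVT` and `GTGINPARSLG` on their published frames, from which also
  LE1 = NPA2−3 and LE2 = NPA2+3 (the T and R of the PIP exemplar).
* **Template transfer** for positions with no sequence-local rule (H2, H5,
  P1–P5): the record is aligned globally to its subfamily-group template and
  each annotated template index maps across the alignment; a position
  aligned to a gap becomes an `position_unresolved:<name>` flag.

When both routes resolve LE1/LE2 and disagree, the NPA-relative value wins
(the published region definitions are NPA-anchored) and the conflict is
logged at WARN. Flagged signatures are carried through but treated as
non-matching by substrate prediction.

## Substrate prediction

Each substrate row holds four position-wise residue-class patterns (ar/R: 4,
loop-B: 10, loop-E: 11, Froger: 5) compiled from a PROSITE-like syntax
(`[AGI]` = class, bare letter = singleton). A raw match requires all four
components to match positionwise. Because several substrate rows share
residue classes, raw matching deliberately over-calls (a silicon-consistent
NIP signature also satisfies the arsenic, antimony and urea classes). The
`restricted` mode applies per-substrate subfamily gates shipped as a data
file (`data/substrate_gates.json`, user-overridable): CO₂ → PIP; Si → NIP
with ar/R exactly GSGR; As, Sb → NIP; NH₃ → TIP; B → NIP group 5 or XIP;
urea → TIP or XIP; H₂O₂ ungated. The gates reconstruct the published
transporter rosters, which embed subfamily priors from experimental
literature; they are a reconstruction, not a stated algorithm, and remain
imperfect (e.g. they do not separate NIP groups for arsenic). The antimony
row has patterns but an empty published roster; it is still evaluated in raw
mode.

Roster strings use inclusive range notation (`NtPIP1;4–8`); both the
en-dash and the hyphen are accepted.

## Gene structure

Introns are the gaps between consecutive exons in 0-based half-open
coordinates (GFF3 1-based closed intervals convert at the I/O boundary, so
interval arithmetic never needs ±1 corrections). Introns ≥ 10 kb (the
scale of the longest introns highlighted in family surveys) are flagged;
the threshold is an argument. With several mRNAs per gene, the mRNA with the
most exons represents the gene.

## Expression calling

Replicates aggregate by arithmetic mean of FPKM before the log transform
(median is available via an argument; the published procedure does not state
the aggregation). A gene is expressed in a condition iff
log₁₀(mean FPKM) > 0, strictly — mean FPKM exactly 1 is not expressed. A
zero mean has no logarithm: it is reported with a sentinel (−inf internally,
`NA` in heatmap exports) and called not expressed. When all replicates are
equal the aggregate is returned exactly, bypassing floating-point summation
drift. The ubiquitous set is the intersection of the per-condition expressed
sets.

## Synthetic worlds

The generators are pure functions of (spec, seed) and are regenerated
byte-identically.

* **Templates** (~274 residues): six 21-residue blocks drawn from {I, L, V}
  separated by mildly polar loops (G/S/T/P/N mix), with strongly polar
  flanks immediately around the planted loop-B 10-mer and loop-E 11-mer.
  The block/loop compositions were chosen once so the hydropathy scanner
  recovers the planted helices on the undiverged templates. Each
  subfamily-group plants a fixed representative of the published pattern
  classes (canonical PIPs the CO₂ exemplar strings, NIP2 the silicon
  exemplars, NIP5 a boron-class signature with the loop-E NPV variant, SIPs
  the loop-B NPT/NPL variants, XIPs the loop-B NPV variant), and groups
  within a subfamily differ by ~12% drift confined to unprotected loop
  residues.
* **Families**: i.i.d. substitutions at unprotected positions at the spec's
  divergence. Protected positions are the 11 annotated indices plus the two
  NPA-region windows. A substitution that would create a new Asn-Pro
  dipeptide anywhere is re-drawn, so the planted motifs remain the only
  anchor candidates at any divergence.
* **Gene models**: exon lengths uniform in 50–300 bp, introns in 80–2000 bp,
  with an optional planted intron of 10–15 kb.
* **FPKM matrices**: expressed cells draw log₁₀ mean from N(1.0, 0.5)
  (mean FPKM ≈ 10) floored at FPKM 1.25; non-expressed cells draw uniform
  [0, 0.8]; replicate noise is multiplicative log-normal (sd 0.1 in log₁₀)
  renormalized to preserve the replicate mean exactly. The floor/cap and the
  mean-preserving noise keep every label on its side of the FPKM = 1
  decision boundary, so count-recovery tests are exact rather than
  probabilistic.

What the synthetic worlds do **not** emulate: insertions/deletions, rate
heterogeneity, compositional bias of real membrane proteins, homoeologous
subgenomes, splice variants, count overdispersion or library-size effects.
Passing recovery tests therefore demonstrates the internal consistency of
the pipeline's rules, not its accuracy on real proteomes; on real data the
reference templates should be replaced with annotated sequences of the
target clade (`refs.json` in the CLI).

## Numerical choices

* Molecular weight: average residue masses plus one water, in kDa;
  undetermined residues (X) score the mean residue mass and flag the value
  approximate.
* Isoelectric point: bisection of the Bjellqvist-model net-charge curve
  (Biopython's charge function) on pH ∈ [0, 14] to a default tolerance of
  0.01 pH. Note the Bjellqvist table makes terminal pKa values depend on the
  terminal residue, so adding a *terminal* charged residue can move pI
  against naive intuition; monotonicity holds for internal insertions.
* Alignment tie-breaks follow Biopython's deterministic traceback order.
* Bundled-table loaders validate structure (row counts, pattern lengths) at
  load time so transcription errors fail fast.

## Known limitations

Subcellular localization is carried as annotation only (no predictor).
Substrate prediction is signature-based and should be treated as hypothesis
generation; single substitutions outside the scored positions can change
channel behaviour. Genome-scale identification (the BLAST screen that
produces candidate FASTA input) is out of scope, as is recomputing FPKM from
raw reads. Published organ-level expressed counts from real RNA-seq are not
reproducible at desk scale and are represented here only by the planted
synthetic worlds.
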