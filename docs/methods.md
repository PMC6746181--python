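# Methods

## Scope and model

`ctdnakit` implements an in-silico reference pipeline for patient-specific
ctDNA resequencing: UMI-based single-molecule mutant counting with error
suppression, spike-in calibration of molecule numbers, depth-downsampling
re-analysis, ultra-low-pass whole-genome copy-number profiling with tumor
content (PTC) and genome-altered (PGA) summaries, and clonality-driven
selection of assay targets from multiregion tumor data. Every stage runs
against a synthetic-data generator with known ground truth, so all claims
below are statements about simulated data; how far they carry to real plasma
is discussed under *Limitations*.

## Read simulator

Each library is modelled at the molecule level:

- **Capture.** Each input template molecule becomes a sequenced family with
  probability `capture_efficiency` (default 0.5 — libraries lose a
  substantial fraction of input during preparation; the exact value is assay
  dependent and freely configurable).
- **Tagging.** Captured molecules draw a UMI uniformly from `4**umi_length`
  (default 7 bases, capacity 16,384) and a fragment length from
  N(165, 10) bp truncated at the amplicon length, matching the ~165 bp mode
  of plasma cfDNA. The UMI occupies the first bases of each read and is also
  recorded after the last colon of the read name.
- **Library-prep errors.** Applied once per molecule at rate
  `prep_error_rate` per base (default 1e-4) and copied into every read of
  the family — a first-cycle error model, the simplest mechanism that
  produces consensus-surviving false mutations, which is exactly the error
  mode the caller's two-independent-families rule must reject.
- **Sequencing errors.** Independent per read base at `seq_error_rate`
  (default 1e-3), UMI bases included, so UMI satellites arise naturally.
- **Depth.** Reads per molecule are geometric with mean
  `mean_reads_per_molecule` (default 50), a cheap stand-in for PCR jackpot
  overdispersion. When `reads_per_library` is set (default 100,000, the
  assumed per-library sequencing budget), family read counts are allocated
  multinomially over the geometric weights so that the library totals the
  budget; molecules can then receive zero reads, which is the depth
  competition that caps the observed spike-in saturation far below the
  theoretical UMI capacity.
- **Background.** Every locus of every benchmark library (negative controls
  included) carries `background_wt_per_locus` wild-type templates
  (default 500), standing in for the abundant normal cfDNA of donor plasma.

Reads are single-end; indels, structural variants, real genome content,
mappability and germline variation are not simulated. Identical
(design, config, seed) triples give byte-identical FASTQ output;
per-library RNG streams are spawned from the master seed.

The default benchmark design is two genotype sources × six log-spaced spike
levels (10¹–10⁶ molecules) × duplicates, plus four negative controls, with
two library preparations per sample: 24 spike-in samples and 56 libraries.
In the default `level_scope="library"` the level's molecules are split
multinomially across loci (truth totals per library equal the level);
`level_scope="locus"` gives each locus the full amount and is used for
per-locus sensitivity experiments.

## Caller

Thresholds (all in `CallerConfig`): reads shorter than UMI + 20 bases are
discarded with a QC tally; locus assignment by unique anchor 15-mer match
with ≤1 mismatch (ambiguous prefixes unassigned; identical anchors are a
configuration error); UMI merge distance 1 using the directional rule —
counts *a* and *b* connect when Hamming ≤ 1 and max ≥ 2·min − 1 — with
families taken as connected components of that graph (equivalently, a
union-find over the stated rule; the test suite checks this equivalence
against an independent graph-library oracle); consensus by majority vote at
the target base, ties ambiguous and never mutant; mutant family = consensus
equals the alternate allele, ≥2 reads, ≥0.9 agreement; detection = ≥2
independent mutant families. The two-family rule is the core specificity
device: a prep error creates one internally-consistent mutant family, never
two independent UMIs, while ≥10 genuine templates at 50% capture almost
always leave ≥2 families.

## Calibration

The spike-in curve stores, per usable level, the mean of log10(observed
mutant families ≥1) over replicates; levels with all-zero observations are
excluded (with a warning) and fewer than three usable levels is an error.
Monotonicity is enforced by isotonic regression; the inverse is
piecewise-linear in log–log space, clamping observations at or above the
plateau to the largest calibrated input with a saturation flag, mapping zero
observations to zero molecules, and extrapolating proportionally toward the
origin below the lowest support. A monotone interpolant was chosen over a
parametric saturating fit because it honors the six-point design exactly
with no functional-form assumption. Curves are pooled across loci by
default. The theoretical ceiling is `4**umi_length` with birthday-collision
expectation U·(1−(1−1/U)ⁿ); the observed plateau is far lower because
wild-type molecules consume capture and depth.

## Downsampling

Whole-library or per-target uniform sampling without replacement, applied
to raw reads before UMI grouping. Composition of subsamples matches a
single subsample of the composed size in distribution, and detection is
monotone non-increasing in expectation as depth falls; the package reports
the per-depth retention curve of deduplicated counts rather than any fixed
reduction factor, since the latter depends on the family-size spectrum.

## Copy-number stage

1 Mb bins over a 2,875 Mb autosome model (GRCh37 lengths rounded to 1 Mb;
sex chromosomes excluded). GC correction divides counts by their GC-decile
median before log2 transformation against the genome-wide median; it
removes realistic monotone GC trends to |residual correlation| < 0.05 but,
being piecewise-constant, leaves residual trend under extreme bias.
Segmentation is deterministic recursive binary splitting: the candidate
split maximises the two-sample t statistic and is accepted while the
between-side mean difference reaches `segment_penalty`, with at least
`min_segment_bins` bins per side; segments never cross chromosomes. States
are thresholded at `gain_cut`/`loss_cut`.

Two configurations are provided. The default (±0.1 cuts, penalty 0.1)
only responds to events visible at tumor fractions above roughly 25% under
the single-copy model (|log2((2−f)/2)| ≥ 0.1 ⟺ f ≳ 0.26).
`sensitive_config()` (penalty 0.04, cuts ±0.04, min 10 bins) targets the
regime of detectable plasma tumor burden: a single-copy loss at f = 0.07
gives r = log2(0.965) = −0.051, comfortably above the ±0.04 cut yet ~5
standard errors above the Poisson noise floor of a 3,000-read/bin,
10-bin segment (per-bin σ(log2) ≈ 0.026), which keeps zero-tumor samples
indeterminate in ≥19/20 simulations while recovering f ∈ {0.07, 0.14, 0.30}
within ±0.05. 3,000 reads per 1 Mb bin corresponds to ≈0.3× coverage with
100 bp reads, the depth regime of ultra-low-pass plasma sequencing.

Artifact flagging is cohort-level: a non-neutral segment is flagged when
non-neutral segments with ≥50% reciprocal overlap occur in ≥80% of the
samples of its collection batch (batches of ≥2), emulating tube-type
batch artifacts; flagged segments are excluded from PTC and PGA, so a
batch-wide artifact cohort correctly yields indeterminate PTC while a
tumor profile private to one sample is untouched. PTC assumes single-copy
events; multi-copy amplifications inflate f̂ (clipped to [0, 1]) and
subclonal events deflate it. Ploidy is reported uncorrected as the
length-weighted mean of 2·2ʳ.

## Multiregion stage

Mutation classes are defined by focus sharing: all foci = trunk, exactly
one = leaf, otherwise branch. Trees are built from point mutations only
(the plasma assay sequences point mutations); a conflict-free matrix yields
the unique perfect phylogeny, and conflicting column patterns are dropped
greedily (most pairwise conflicts first, deterministic tie-breaks) and
reported. Target selection ranks trunk first, then branches by descending
focus count — prevalence as a proxy for clone size, since no quantitative
definition of a "major" branch exists — with coordinate tie-breaks.
Amplicon windows are ≤139 bp with ≥20 bp flanks where the reference
permits, anchors unique and free of ≥8-base homopolymers (windows shift
otherwise); primer thermodynamics are not modelled. The simulator draws a
laminar clade family (linear, balanced or random shape), always assigns
the first mutation to the trunk, and emits a perfect-phylogeny matrix, so
generator → classifier/tree round-trips are exact by construction — these
round-trips validate the algorithms, not the realism of mutation calling
from tissue.

## Problem sizes and determinism

The shipped detection benchmark uses 10 seeds × (4 spike libraries at
10/100/1,000/10,000 molecules per locus + 2 negative libraries) × 10 loci
at 100,000 reads per library — 400 mutant and 200 wild-type locus
decisions, a scale chosen to give ~1% standard error on the sensitivity
estimate at single-CPU minutes of runtime. All randomness flows from
explicit integer seeds through `numpy` generators; `scripts/acceptance.py`
derives its ten simulation seeds from `--seed`.

## Limitations

- Synthetic references are i.i.d. random sequence; locus assignment and
  amplicon-anchor uniqueness are easier than on a real genome with repeats.
- The error model is substitution-only with uniform rates; no
  context-dependent errors, indels, strand bias or quality-score
  information (no duplex consensus either).
- PTC uses a transparent single-copy inversion, not a probabilistic
  mixture model; no ploidy/purity joint correction, no subclonal SCNA
  deconvolution.
- Mutation presence in multiregion data is binary; cancer-cell-fraction
  modelling and SCNA-aware phylogenies are out of scope.
- Passing simulations demonstrate internal consistency of the algorithms
  under the stated error model, not clinical performance on real plasma.
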