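# ctdnakit

Tools for patient-specific detection of circulating tumor DNA (ctDNA) in
plasma, built around four stages:

1. **Single-molecule mutant counting** (`ctdnakit.umi`). Amplicon reads carry
   a 7-base inline unique molecular identifier (UMI). Reads are assigned to
   target loci alignment-free (anchor 15-mer, ≤1 mismatch), grouped into UMI
   families (exact grouping plus a directional merge that absorbs
   sequencing-error satellite UMIs), and collapsed to a per-family consensus
   at the target base. A family counts as one mutant template molecule only
   if it has ≥2 reads agreeing at ≥90% on the alternate allele; a locus is
   *detected* only with ≥2 independent mutant families, which rejects
   library-prep errors that survive consensus. Wild-type families are
   tallied but ignored.
2. **Spike-in calibration** (`ctdnakit.calibration`). Known input amounts of
   mutant template (10¹–10⁶ molecules) map to observed unique mutant
   families; the monotone piecewise-linear log–log curve is inverted to
   back-calculate molecule numbers from observed counts. The UMI capacity is
   4⁷ = 16,384 molecules with collision correction
   E[distinct] = U·(1−(1−1/U)ⁿ).
3. **Ultra-low-pass WGS copy number** (`ctdnakit.cna`). 1 Mb bin counts are
   GC-normalised by decile medians, segmented by recursive binary splitting,
   and thresholded into loss/neutral/gain. Recurrent batch-shared segments
   are flagged as collection artifacts. Percent tumor content inverts the
   single-copy mixture relation — depth ratio (2(1−f)+c·f)/2, so
   f̂ = 2(1−2ʳ) for losses and f̂ = 2(2ʳ−1) for gains — averaged over
   altered segments; percent genome altered is the altered-bin fraction.
4. **Clonality-driven target selection** (`ctdnakit.phylo`). Multiregion
   focus-by-mutation matrices classify mutations as trunk (all foci), branch
   (several) or leaf (one), reconstruct the perfect phylogeny when the
   three-gamete condition holds, and pick trunk/major-branch mutations for
   amplicon windows of ≤139 bp.

A synthetic-data generator (`ctdnakit.synthetic`) produces every input with
known ground truth: FASTQ spike-in libraries under an explicit molecular
error model (family-wide library-prep errors, per-base sequencing errors,
geometric PCR jackpotting, ~165 bp fragments), ULP-WGS bin tables at set
tumor fractions with prostate-like copy-number profiles, and multiregion
matrices drawn from known clone trees. `ctdnakit.downsample` re-evaluates
detection under reduced depth.

Intended users: developers and analysts of UMI-based liquid-biopsy assays
who need a transparent, fully testable reference pipeline.

## Worked example

```python
import numpy as np
from ctdnakit import (SimConfig, make_reference, design_amplicons,
                      simulate_library, call_reads)

reference, alleles = make_reference(8, 400, seed=1)
amplicons, _ = design_amplicons(reference, alleles)
cfg = SimConfig(seed=1, reads_per_library=20_000)
reads = simulate_library(50, cfg, amplicon=amplicons[0], allele=alleles[0],
                         wt_molecules=500)
report = call_reads(reads, alleles, amplicons).reports[alleles[0].locus_id]
print(report.dedup_mutant_count, report.detected)
```

prints `17 True`: of 50 spiked mutant templates, 17 survive capture
(50% efficiency), read allocation and the ≥2-read/≥90%-agreement family
filters as independent mutant UMI families — comfortably above the
2-family detection threshold — while the 500 wild-type templates produce no
mutant call on their own. The same objects drive the CLI
(`ctdnakit simulate-benchmark / call / calibrate / quantify / downsample /
cna / targets / design`).

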