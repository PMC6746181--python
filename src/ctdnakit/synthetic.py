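"""Synthetic-data generator for every stage of the pipeline.

Generates (i) random reference loci with defined target alleles, (ii)
spike-in benchmark FASTQ libraries with inline UMIs under an explicit
molecular error model, (iii) ultra-low-pass WGS bin-count tables at set
tumor fractions with GC bias and collection-batch artifacts, and (iv)
multiregion focus-by-mutation matrices drawn from a known clone tree.

Error model of the read simulator
---------------------------------
Each input template molecule is captured with probability
``capture_efficiency``; a captured molecule receives a UMI drawn uniformly
from ``4**umi_length`` possibilities and a fragment length drawn from a
truncated normal.  Library-prep errors are applied once per molecule (first
amplification cycle) and are therefore shared by the molecule's entire read
family -- the one error mode a consensus caller cannot vote away.
Sequencing errors are applied independently per read base, UMI bases
included.  Reads per molecule follow a geometric ("jackpot") distribution;
when a per-library depth budget is set, family read counts are allocated
multinomially over the geometric weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as ckio
from ._genome import autosome_lengths_bp
from .config import BenchmarkDesign, SimConfig
from .phylo import CloneTree, FocusMutationMatrix, design_amplicons, tree_from_clades
from .types import AmpliconDesign, TargetAllele, TruthRecord

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
_DECODE = np.frombuffer(b"ACGT\x00", dtype=np.uint8)  # index 4 = past-end sentinel
_SENTINEL = 4


def _encode(seq: str) -> np.ndarray:
    arr = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _umi_to_str(umi_int: int, length: int) -> str:
    return "".join("ACGT"[(umi_int >> (2 * k)) & 3] for k in range(length))


# ---------------------------------------------------------------------------
# Reference construction


def make_reference(
    n_loci: int, locus_length_bp: int = 400, seed: int = 0
) -> tuple[dict[str, str], list[TargetAllele]]:
    """Generate random reference loci, one target SNV per locus.

    Each locus is an independent random sequence carrying a single defined
    somatic SNV placed so that at least 70 bp of flank remains on both sides
    (room for an amplicon window).  Deterministic in ``seed``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if locus_length_bp < 200:
        raise ValueError("locus_length_bp must be >= 200 to host an amplicon")
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    alleles: list[TargetAllele] = []
    for i in range(n_loci):
        locus_id = f"locus{i:02d}"
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, locus_length_bp)])
        pos0 = int(rng.integers(70, locus_length_bp - 70))
        ref = seq[pos0]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        reference[locus_id] = seq
        alleles.append(
            TargetAllele(locus_id=locus_id, chrom=locus_id, pos=pos0 + 1, ref=ref, alt=str(alt))
        )
    return reference, alleles


# ---------------------------------------------------------------------------
# Read simulation

class _MoleculePool:
    """Captured template molecules of one library, across loci."""

    def __init__(self, cfg: SimConfig, width: int):
        self.cfg = cfg
        self.width = cfg.umi_length + width  # columns: UMI then fragment
        self.blocks: list[np.ndarray] = []
        self.frag_lens: list[np.ndarray] = []
        self.umis: list[np.ndarray] = []
        self.locus_ids: list[str] = []
        self.locus_of: list[np.ndarray] = []

    def add_locus(
        self,
        amplicon: AmpliconDesign,
        allele: Optional[TargetAllele],
        n_mut: int,
        n_wt: int,
        rng: np.random.Generator,
    ) -> int:
        """Capture, tag and prep-copy molecules for one locus.

        Returns the number of captured mutant molecules.
        """
        cfg = self.cfg
        cap = cfg.capture_efficiency
        cm = int(rng.binomial(n_mut, cap)) if n_mut else 0
        cw = int(rng.binomial(n_wt, cap)) if n_wt else 0
        m = cm + cw
        if m == 0:
            return 0
        amp = _encode(amplicon.sequence)
        amp_len = len(amp)
        ulen = cfg.umi_length

        block = np.full((m, self.width), _SENTINEL, dtype=np.uint8)
        umis = rng.integers(0, 4**ulen, size=m, dtype=np.int64) if ulen else np.zeros(m, np.int64)
        for k in range(ulen):
            block[:, k] = (umis >> (2 * k)) & 3
        block[:, ulen : ulen + amp_len] = amp
        if cm:
            if allele is None:
                raise ValueError("mutant molecules require a target allele")
            block[:cm, ulen + amplicon.target_offset] = _encode(allele.alt)[0]

        frag = np.clip(
            np.rint(rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd, m)),
            min(30, amp_len),
            amp_len,
        ).astype(np.int64)
        cols = np.arange(amp_len)
        block[:, ulen : ulen + amp_len][cols[None, :] >= frag[:, None]] = _SENTINEL

        # first-cycle library-prep errors: once per molecule, family-wide
        if cfg.prep_error_rate > 0:
            valid_flat = np.flatnonzero(block.ravel() != _SENTINEL)
            n_err = rng.binomial(valid_flat.size, cfg.prep_error_rate)
            if n_err:
                picks = rng.choice(valid_flat, size=n_err, replace=False)
                flat = block.ravel()
                flat[picks] = (flat[picks] + rng.integers(1, 4, n_err)) % 4

        self.blocks.append(block)
        self.frag_lens.append(frag)
        self.umis.append(umis)
        idx = len(self.locus_ids)
        self.locus_ids.append(amplicon.locus_id)
        self.locus_of.append(np.full(m, idx, dtype=np.int32))
        return cm

    def emit_reads(self, library_id: str, rng: np.random.Generator) -> list[ckio.SimRead]:
        cfg = self.cfg
        if not self.blocks:
            return []
        mols = np.vstack(self.blocks)
        frag = np.concatenate(self.frag_lens)
        umis = np.concatenate(self.umis)
        m = mols.shape[0]

        weights = rng.geometric(1.0 / cfg.mean_reads_per_molecule, size=m)
        if cfg.reads_per_library is not None:
            counts = rng.multinomial(cfg.reads_per_library, weights / weights.sum())
        else:
            counts = weights

        reads = np.repeat(mols, counts, axis=0)
        read_len = np.repeat(frag + cfg.umi_length, counts)
        mol_idx = np.repeat(np.arange(m), counts)
        n_reads = reads.shape[0]
        if n_reads == 0:
            return []

        if cfg.seq_error_rate > 0:
            valid_flat = np.flatnonzero(reads.ravel() != _SENTINEL)
            n_err = rng.binomial(valid_flat.size, cfg.seq_error_rate)
            if n_err:
                picks = rng.choice(valid_flat, size=n_err, replace=False)
                flat = reads.ravel()
                flat[picks] = (flat[picks] + rng.integers(1, 4, n_err)) % 4

        perm = rng.permutation(n_reads)
        chars = _DECODE[reads[perm]]
        read_len = read_len[perm]
        mol_idx = mol_idx[perm]
        ulen = cfg.umi_length
        out: list[ckio.SimRead] = []
        for i in range(n_reads):
            seq = chars[i, : read_len[i]].tobytes().decode()
            umi = _umi_to_str(int(umis[mol_idx[i]]), ulen)
            out.append((f"{library_id}:{i}:{umi}", seq))
        return out


def simulate_library(
    molecules: int,
    cfg: SimConfig,
    amplicon: Optional[AmpliconDesign] = None,
    allele: Optional[TargetAllele] = None,
    wt_molecules: int = 0,
    library_id: str = "lib",
    rng: Optional[np.random.Generator] = None,
) -> list[ckio.SimRead]:
    """Simulate reads for ``molecules`` mutant templates at a single locus.

    ``wt_molecules`` adds wild-type background templates at the same locus.
    With zero error rates and full capture every read exactly matches its
    template and the number of distinct UMIs never exceeds the molecule count.
    """
    if molecules < 0 or wt_molecules < 0:
        raise ValueError("molecule counts must be >= 0")
    if molecules + wt_molecules == 0:
        return []
    if amplicon is None:
        raise ValueError("an amplicon design is required to simulate reads")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pool = _MoleculePool(cfg, len(amplicon.sequence))
    pool.add_locus(amplicon, allele, molecules, wt_molecules, rng)
    return pool.emit_reads(library_id, rng)


# ---------------------------------------------------------------------------
# Benchmark experiment


@dataclass
class SimulatedLibrary:
    library_id: str
    sample_id: str
    source: Optional[str]
    spike_level: int  # 0 for negative controls
    replicate: int
    prep: int
    is_negative: bool
    reads: list = field(default_factory=list, repr=False)
    fastq_path: Optional[Path] = None


@dataclass
class BenchmarkResult:
    design: BenchmarkDesign
    cfg: SimConfig
    reference: dict[str, str]
    alleles: list[TargetAllele]
    amplicons: list[AmpliconDesign]
    libraries: list[SimulatedLibrary]
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_id": [t.library_id for t in self.truth],
                "locus_id": [t.locus_id for t in self.truth],
                "molecules": [t.true_template_molecules for t in self.truth],
                "mutant": [t.true_mutant for t in self.truth],
            }
        )


def simulate_benchmark(
    design: BenchmarkDesign,
    cfg: SimConfig,
    reference: Optional[dict[str, str]] = None,
    alleles: Optional[Sequence[TargetAllele]] = None,
    out_dir: Optional[str | Path] = None,
    keep_reads: bool = True,
) -> BenchmarkResult:
    """Simulate the full spike-in benchmark experiment.

    Emits ``(|sources| * |levels| * replicates + negatives) * preps``
    libraries.  In ``level_scope="library"`` mode the spike level's template
    molecules are split multinomially across target loci, so per-library
    truth totals equal the designed level; negative controls carry zero
    mutant templates everywhere.  Wild-type background templates are added
    at every locus of every library.
    """
    if alleles is None:
        alleles = design.alleles
    if reference is None or alleles is None:
        reference, alleles = make_reference(8, 400, seed=cfg.seed)
    alleles = list(alleles)
    amplicons, failures = design_amplicons(reference, alleles)
    if failures:
        raise ValueError(f"amplicon design failed for {failures}")
    amp_by_locus = {a.locus_id: a for a in amplicons}
    allele_by_locus = {a.locus_id: a for a in alleles}
    n_loci = len(alleles)

    # enumerate samples then libraries, deterministically
    samples: list[tuple[str, Optional[str], int, int, bool]] = []
    for src in design.sources:
        for level in design.spike_levels:
            for rep in range(1, design.replicates_per_condition + 1):
                samples.append((f"{src}_L{level}_R{rep}", src, level, rep, False))
    for i in range(1, design.negative_controls + 1):
        samples.append((f"NEG_{i}", None, 0, i, True))

    lib_seeds = np.random.SeedSequence(cfg.seed).spawn(len(samples) * design.preps_per_sample)
    libraries: list[SimulatedLibrary] = []
    truth: list[TruthRecord] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    max_amp = max(len(a.sequence) for a in amplicons)
    lib_index = 0
    for sample_id, src, level, rep, is_neg in samples:
        for prep in range(1, design.preps_per_sample + 1):
            library_id = f"{sample_id}_P{prep}"
            rng = np.random.default_rng(lib_seeds[lib_index])
            lib_index += 1
            if is_neg:
                alloc = np.zeros(n_loci, dtype=np.int64)
            elif design.level_scope == "library":
                alloc = rng.multinomial(level, np.full(n_loci, 1.0 / n_loci))
            else:
                alloc = np.full(n_loci, level, dtype=np.int64)
            pool = _MoleculePool(cfg, max_amp)
            for j, allele in enumerate(alleles):
                pool.add_locus(
                    amp_by_locus[allele.locus_id],
                    allele,
                    int(alloc[j]),
                    design.background_wt_per_locus,
                    rng,
                )
                truth.append(
                    TruthRecord(library_id, allele.locus_id, int(alloc[j]), bool(alloc[j] > 0))
                )
            reads = pool.emit_reads(library_id, rng)
            lib = SimulatedLibrary(
                library_id, sample_id, src, level, rep, prep, is_neg,
                reads=reads if keep_reads else [],
            )
            if out_dir is not None:
                lib.fastq_path = out_dir / f"{library_id}.fastq.gz"
                ckio.write_fastq(reads, lib.fastq_path)
            libraries.append(lib)

    result = BenchmarkResult(
        design, cfg, dict(reference), alleles, amplicons, libraries, truth
    )
    if out_dir is not None:
        ckio.write_fasta(result.reference, out_dir / "reference.fa")
        ckio.write_targets_vcf(alleles, out_dir / "targets.vcf")
        ckio.write_amplicons_bed(amplicons, out_dir / "amplicons.bed")
        ckio.write_truth_tsv(truth, out_dir / "truth.tsv")
        design.to_json(out_dir / "design.json")
        cfg.to_json(out_dir / "config.json")
        pd.DataFrame(
            {
                "library_id": [l.library_id for l in libraries],
                "sample_id": [l.sample_id for l in libraries],
                "source": [l.source or "" for l in libraries],
                "spike_level": [l.spike_level for l in libraries],
                "replicate": [l.replicate for l in libraries],
                "prep": [l.prep for l in libraries],
                "is_negative": [int(l.is_negative) for l in libraries],
                "fastq": [str(l.fastq_path) for l in libraries],
            }
        ).to_csv(out_dir / "libraries.tsv", sep="\t", index=False)
    return result


# ---------------------------------------------------------------------------
# Ultra-low-pass WGS bin counts

_GC_TRACK_SEED = 20_170_408  # fixed: GC content is a property of the genome


def _genome_bins(genome: dict[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    rng = np.random.default_rng(_GC_TRACK_SEED)
    wave = 0.06 * np.sin(2 * np.pi * np.arange(len(bins)) / 47.0)
    bins["gc"] = np.clip(0.41 + wave + rng.normal(0, 0.02, len(bins)), 0.30, 0.60)
    return bins


def simulate_ulp_bins(
    tumor_fraction: float,
    scna_profile: Optional[Sequence[tuple[str, int, int, int]]] = None,
    mean_reads_per_bin: float = 3000.0,
    gc_bias_params: Optional[tuple[float, float]] = None,
    batch_artifacts: Optional[Sequence[tuple[str, int, int, float]]] = None,
    seed: int = 0,
    bin_size: int = 1_000_000,
    genome: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Simulate a per-bin read-count table for one ULP-WGS plasma sample.

    Expected bin counts are ``mean_reads_per_bin * (2(1-f) + c*f)/2`` times a
    GC-bias factor, where ``f`` is the tumor fraction and ``c`` the tumor
    copy number of the bin (diploid outside ``scna_profile`` intervals).
    ``batch_artifacts`` multiplies affected bins by ``2**shift``, emulating
    collection-batch-specific recurrent artifacts.  Counts are Poisson.
    At 1 Mb bins, ``mean_reads_per_bin=3000`` corresponds to roughly 0.3x
    genome coverage with 100 bp reads.
    """
    if not (0.0 <= tumor_fraction <= 1.0):
        raise ValueError("tumor_fraction must lie in [0, 1]")
    genome = dict(genome) if genome is not None else autosome_lengths_bp()
    bins = _genome_bins(genome, bin_size)
    cn = np.full(len(bins), 2.0)
    for chrom, start, end, copies in scna_profile or []:
        if chrom not in genome:
            raise ValueError(f"profile interval on unknown chromosome {chrom}")
        if not (0 <= start < end <= genome[chrom]):
            raise ValueError(f"profile interval outside {chrom}: {start}-{end}")
        sel = (bins["chrom"] == chrom) & (bins["start"] < end) & (bins["end"] > start)
        cn[sel.to_numpy()] = copies
    ratio = (2.0 * (1.0 - tumor_fraction) + cn * tumor_fraction) / 2.0

    gc = bins["gc"].to_numpy()
    if gc_bias_params is not None:
        a, b = gc_bias_params
        factor = 1.0 + a * (gc - 0.41) + b * (gc - 0.41) ** 2
        factor = np.clip(factor, 0.05, None)
        factor /= factor.mean()
    else:
        factor = np.ones_like(gc)

    shift = np.zeros(len(bins))
    for chrom, start, end, s in batch_artifacts or []:
        if chrom not in genome:
            raise ValueError(f"artifact interval on unknown chromosome {chrom}")
        sel = (bins["chrom"] == chrom) & (bins["start"] < end) & (bins["end"] > start)
        shift[sel.to_numpy()] += s

    rng = np.random.default_rng(seed)
    mean = mean_reads_per_bin * ratio * factor * np.power(2.0, shift)
    bins["count"] = rng.poisson(mean)
    return bins


# ---------------------------------------------------------------------------
# Multiregion tumors


def _split_foci(
    foci: list[str], tree_shape: str, rng: np.random.Generator
) -> list[frozenset]:
    """Recursive partition of the focus set into a laminar clade family."""
    clades = [frozenset(foci)]
    if len(foci) == 1:
        return clades
    if tree_shape == "linear":
        left, right = foci[:1], foci[1:]
    elif tree_shape == "balanced":
        mid = len(foci) // 2
        left, right = foci[:mid], foci[mid:]
    elif tree_shape == "random":
        cut = int(rng.integers(1, len(foci)))
        order = list(rng.permutation(foci))
        left, right = sorted(order[:cut]), sorted(order[cut:])
    else:
        raise ValueError("tree_shape must be linear/balanced/random")
    clades += _split_foci(left, tree_shape, rng)
    clades += _split_foci(right, tree_shape, rng)
    return clades


def simulate_multiregion(
    n_foci: int,
    n_mutations: int = 20,
    tree_shape: str = "random",
    seed: int = 0,
) -> tuple[FocusMutationMatrix, CloneTree, dict[str, str]]:
    """Simulate a focus-by-mutation matrix from a known clone tree.

    The matrix is consistent with a perfect phylogeny on the returned truth
    tree; the first mutation is always truncal (present in every focus).
    Returns ``(matrix, truth_tree, truth_classes)``.
    """
    if n_foci < 2:
        raise ValueError("n_foci must be >= 2")
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    rng = np.random.default_rng(seed)
    foci = [f"F{i+1}" for i in range(n_foci)]
    clades = sorted(set(_split_foci(foci, tree_shape, rng)), key=lambda c: (-len(c), sorted(c)))

    mut_ids = [f"m{j:03d}" for j in range(n_mutations)]
    full = frozenset(foci)
    assignment: dict[str, frozenset] = {mut_ids[0]: full}
    idx = rng.integers(0, len(clades), size=n_mutations - 1)
    for mut, k in zip(mut_ids[1:], idx):
        assignment[mut] = clades[int(k)]

    presence = np.zeros((n_foci, n_mutations), dtype=bool)
    for j, mut in enumerate(mut_ids):
        for i, f in enumerate(foci):
            presence[i, j] = f in assignment[mut]
    matrix = FocusMutationMatrix(foci, mut_ids, presence)

    clade_mutations: dict[frozenset, list[str]] = {}
    for mut, clade in assignment.items():
        clade_mutations.setdefault(clade, []).append(mut)
    truth_tree = tree_from_clades(clade_mutations, foci)

    classes = {
        mut: ("trunk" if clade == full else "leaf" if len(clade) == 1 else "branch")
        for mut, clade in assignment.items()
    }
    return matrix, truth_tree, classes
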