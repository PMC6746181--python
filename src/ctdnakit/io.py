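"""Readers and writers for the plain-text formats used by the pipeline.

FASTA is read through :mod:`pyfaidx`, FASTQ through :class:`pysam.FastxFile`.
Writers emit uncompressed or gzip text depending on the file suffix.
Coordinates follow the usual conventions: BED is 0-based half-open, VCF is
1-based.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

from .types import AmpliconDesign, LocusCallReport, Segment, TargetAllele, TruthRecord

SimRead = tuple[str, str]  # (read name, sequence); qualities are synthetic


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fastq(reads: Iterable[SimRead], path: str | Path, quality_char: str = "I") -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | Path) -> Iterator[SimRead]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence


# ---------------------------------------------------------------------------
# Targets (VCF) and amplicons (BED)


def write_targets_vcf(alleles: Sequence[TargetAllele], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=LOCUS,Number=1,Type=String,Description="Target locus id">\n')
        fh.write(
            '##INFO=<ID=CLONALITY,Number=1,Type=String,'
            'Description="trunk/branch/leaf/unknown">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for a in alleles:
            info = f"LOCUS={a.locus_id};CLONALITY={a.clonality}"
            fh.write(f"{a.chrom}\t{a.pos}\t{a.locus_id}\t{a.ref}\t{a.alt}\t.\t.\t{info}\n")


def read_targets_vcf(path: str | Path) -> list[TargetAllele]:
    alleles = []
    with _open_text(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, vid, ref, alt, _qual, _filt, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            alleles.append(
                TargetAllele(
                    locus_id=fields.get("LOCUS", vid),
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    clonality=fields.get("CLONALITY", "unknown"),
                )
            )
    return alleles


def write_amplicons_bed(designs: Sequence[AmpliconDesign], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for d in designs:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.locus_id}\n")


def read_amplicons_bed(path: str | Path, reference: dict[str, str],
                       targets: Sequence[TargetAllele], anchor_length: int = 15
                       ) -> list[AmpliconDesign]:
    """Rehydrate amplicon designs from a BED file plus the reference."""
    by_locus = {a.locus_id: a for a in targets}
    designs = []
    with _open_text(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, locus_id = line.rstrip("\n").split("\t")[:4]
            start, end = int(start), int(end)
            seq = reference[chrom][start:end]
            allele = by_locus[locus_id]
            designs.append(
                AmpliconDesign(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    sequence=seq,
                    target_offset=allele.pos - 1 - start,
                    anchor=seq[:anchor_length],
                )
            )
    return designs


# ---------------------------------------------------------------------------
# Tables


def write_truth_tsv(records: Sequence[TruthRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "library_id": [r.library_id for r in records],
            "locus_id": [r.locus_id for r in records],
            "molecules": [r.true_template_molecules for r in records],
            "mutant": [int(r.true_mutant) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(r.library_id, r.locus_id, int(r.molecules), bool(r.mutant))
        for r in df.itertuples()
    ]


def reports_to_frame(reports: dict[str, LocusCallReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports.values()])


def write_reports_tsv(reports: dict[str, LocusCallReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False)


def write_reports_json(reports: dict[str, LocusCallReport], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2) + "\n"
    )


def write_seg(segments: Sequence[Segment], sample_id: str, path: str | Path) -> None:
    """Write segments in the tab-separated SEG convention."""
    with _open_text(path, "wt") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\tstate\tartifact\n")
        for s in segments:
            fh.write(
                f"{sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.n_bins}\t"
                f"{s.mean_log2:.4f}\t{s.state}\t{int(s.artifact)}\n"
            )


def read_bins_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gc", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bin table is missing columns: {sorted(missing)}")
    return df


def write_bins_tsv(bins: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "gc", "count", "norm_log2") if c in bins.columns]
    bins[cols].to_csv(path, sep="\t", index=False)
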