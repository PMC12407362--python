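"""Standard-format readers and writers.

All intervals are 0-based half-open in memory (BED convention); positions are
converted to and from the 1-based VCF convention only at the VCF boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .matrix import MISSING, GenotypeMatrix
from .simulate import Genome, PairedReads, TruthSet

log = logging.getLogger("invscan")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> Genome:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pair(reads: PairedReads, prefix: str | Path) -> tuple[Path, Path]:
    """Write mates to <prefix>_1.fastq and <prefix>_2.fastq (Q40 qualities)."""
    paths = (Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq"))
    for mate, (path, seqs) in enumerate(zip(paths, (reads.r1, reads.r2)), start=1):
        records = []
        for name, seq in zip(reads.names, seqs):
            rec = SeqRecord(Seq(seq), id=f"{name}/{mate}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")
    return paths


def read_fastq_pair(prefix: str | Path) -> PairedReads:
    r1_recs = list(SeqIO.parse(f"{prefix}_1.fastq", "fastq"))
    r2_recs = list(SeqIO.parse(f"{prefix}_2.fastq", "fastq"))
    if len(r1_recs) != len(r2_recs):
        raise ValueError("mate files differ in read count")
    return PairedReads(
        r1=[str(r.seq) for r in r1_recs],
        r2=[str(r.seq) for r in r2_recs],
        names=[r.id.rsplit("/", 1)[0] for r in r1_recs],
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    gm: GenotypeMatrix, path: str | Path, contig_lengths: dict[str, int] | None = None
) -> None:
    """Write the dosage matrix as a VCF v4.2 with GT calls (0-based positions
    converted to the 1-based VCF convention by pysam)."""
    header = pysam.VariantHeader()
    contigs = dict.fromkeys(gm.chroms)
    for chrom in contigs:
        length = (contig_lengths or {}).get(chrom)
        if length is None:
            length = int(gm.positions[gm.chroms == chrom].max()) + 2
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in gm.samples:
        header.add_sample(sample)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for s in range(gm.n_sites):
            ref = gm.ref[s] if gm.ref is not None else "A"
            alt = gm.alt[s] if gm.alt is not None else "T"
            rec = vf.new_record(
                contig=str(gm.chroms[s]),
                start=int(gm.positions[s]),
                alleles=(ref, alt),
                id=f"site{s}",
            )
            for i, sample in enumerate(gm.samples):
                rec.samples[sample]["GT"] = gt_of[int(gm.dosages[i, s])]
            vf.write(rec)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic records into a GenotypeMatrix; multiallelic and
    non-SNP-coded records are skipped with a logged count."""
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, positions, refs, alts, rows = [], [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        chroms.append(var.CHROM)
        positions.append(var.POS - 1)  # to 0-based
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = var.gt_types.astype(np.int8)  # 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic records", skipped)
    dosages = (
        np.column_stack(rows) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        dosages=dosages,
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        samples=samples,
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


def read_genotypes(
    vcf_path: str | Path, groups_path: str | Path
) -> tuple[GenotypeMatrix, list[str]]:
    """VCF + two-column sample/group TSV -> (matrix, per-sample labels)."""
    gm = read_vcf(vcf_path)
    groups = read_groups(groups_path)
    missing = [s for s in groups if s not in gm.samples]
    if missing:
        raise ValueError(f"groups file names samples absent from VCF: {missing}")
    absent = [s for s in gm.samples if s not in groups]
    if absent:
        raise ValueError(f"VCF samples missing from groups file: {absent}")
    return gm, [groups[s] for s in gm.samples]


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV
# ---------------------------------------------------------------------------

def write_bed(intervals, path: str | Path) -> None:
    """Intervals as (chrom, start, end[, name/score...]) tuples, 0-based half-open."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return out


def write_bedgraph(
    chrom: str, window: int, values, path: str | Path, length: int | None = None
) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            start = i * window
            end = start + window
            if length is not None:
                end = min(end, length)
            fh.write(f"{chrom}\t{start}\t{end}\t{v}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], comment="#"
    )


def write_groups(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_groups(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# truth sets
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, outdir: str | Path) -> None:
    """Lossless on-disk truth: inversion BED, planted-SNP sites VCF, and a
    TSV/JSON pair for per-sample classes and metadata."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(truth.inversions, outdir / "inversions.bed")

    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(c for c, *_ in truth.snps) or {"chrUnknown": None}:
        length = 1 + max(p for c, p, *_ in truth.snps if c == chrom) + 1 if truth.snps else 2
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(str(outdir / "snps.vcf"), "w", header=header) as vf:
        for chrom, pos, ref, alt in truth.snps:
            vf.write(vf.new_record(contig=chrom, start=pos, alleles=(ref, alt)))

    rows = sorted(set(truth.arrangement) | set(truth.haplotype_group))
    pd.DataFrame(
        {
            "sample": rows,
            "arrangement": [truth.arrangement.get(s, "") for s in rows],
            "haplotype_group": [truth.haplotype_group.get(s, "") for s in rows],
        }
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    meta = {"seed": truth.seed, "block": list(truth.block) if truth.block else None}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))


def read_truth(outdir: str | Path) -> TruthSet:
    import json

    outdir = Path(outdir)
    truth = TruthSet()
    truth.inversions = [
        (c, s, e) for c, s, e, *_ in read_bed(outdir / "inversions.bed")
    ]
    for var in VCF(str(outdir / "snps.vcf")):
        truth.snps.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
    df = pd.read_csv(outdir / "samples.tsv", sep="\t").fillna("")
    for _, row in df.iterrows():
        if row["arrangement"]:
            truth.arrangement[row["sample"]] = row["arrangement"]
        if row["haplotype_group"]:
            truth.haplotype_group[row["sample"]] = row["haplotype_group"]
    meta = json.loads((outdir / "meta.json").read_text())
    truth.seed = meta["seed"]
    truth.block = tuple(meta["block"]) if meta["block"] else None
    return truth
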