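"""Breakpoint-read-ratio genotyping of large inversions.

Each known inversion has two breakpoints. For each breakpoint and each of the
two reference arrangements we build a junction sequence of length 2L centered
on the breakpoint. A read supports a junction when it matches the junction
across the breakpoint with at least ``min_overlap`` exactly matched bases on
each side. The per-sample statistic is the percent ratio

    r = 100 * N_A / (N_A + N_B)

of reads supporting the A-arrangement junctions over all junction-supporting
reads; r in [80, 100] is called same-as-A, r in [0, 20] same-as-B, anything
between heterozygous, and no junction-spanning reads at all gives no-call.

Counting is mapping-free: junction matching on raw reads replaces short-read
alignment while preserving the same support statistic. Pre-computed counts
from an external aligner can be fed directly into :func:`support_ratio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq import reverse_complement, seq_to_array
from .simulate import Genome, PairedReads

SAME_AS_A = "same-as-A"
SAME_AS_B = "same-as-B"
HETEROZYGOUS = "heterozygous"
NO_CALL = "no-call"

JUNCTION_KEYS = (("A", "left"), ("A", "right"), ("B", "left"), ("B", "right"))

# matching tolerance outside the exact cores: <= 1 mismatch per this many
# overlap bases, so low-rate sequencing errors do not discard true support
MISMATCH_SPAN = 50


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("inversion end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class JunctionSet:
    """Four 2L-bp junction sequences, breakpoint at offset L in each."""

    flank: int
    junctions: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        if set(self.junctions) != set(JUNCTION_KEYS):
            raise ValueError("junction set must contain exactly the four A/B x left/right keys")
        for key, seq in self.junctions.items():
            if len(seq) != 2 * self.flank:
                raise ValueError(f"junction {key} length != 2*flank")


@dataclass
class InversionCall:
    counts: dict[tuple[str, str], int]
    ratio_left: float | None
    ratio_right: float | None
    ratio_pooled: float | None
    arrangement: str


def extract_junctions(
    genome_a: Genome, genome_b: Genome, inv: Inversion, flank: int = 150
) -> JunctionSet:
    """Cut the 2L-bp sequence centered on each breakpoint from each genome."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    junctions: dict[tuple[str, str], str] = {}
    for ref, genome in (("A", genome_a), ("B", genome_b)):
        if inv.chrom not in genome:
            raise ValueError(f"chromosome {inv.chrom} missing from genome {ref}")
        seq = genome[inv.chrom]
        for side, bp in (("left", inv.start), ("right", inv.end)):
            if bp - flank < 0 or bp + flank > len(seq):
                raise ValueError("flank exceeds chromosome bounds at breakpoint")
            junctions[(ref, side)] = seq[bp - flank:bp + flank]
    return JunctionSet(flank=flank, junctions=junctions)


def _match_at(read_arr, junc_arr, offset: int, flank: int, min_overlap: int) -> bool:
    """Match the read aligned with its position 0 at junction coordinate
    ``offset``; the overlap must cross the breakpoint with min_overlap bases
    on each side. Candidate offsets come from exact occurrences of the
    breakpoint core in the read, so the cores are exact by construction and
    the mismatch budget applies to the flanking overlap only."""
    j_lo = max(0, offset)
    j_hi = min(len(junc_arr), offset + len(read_arr))
    overlap = j_hi - j_lo
    if j_lo > flank - min_overlap or j_hi < flank + min_overlap:
        return False
    seg_read = read_arr[j_lo - offset:j_hi - offset]
    seg_junc = junc_arr[j_lo:j_hi]
    mism = int((seg_read != seg_junc).sum())
    return mism <= overlap // MISMATCH_SPAN


def count_junction_support(
    reads: PairedReads | list[str],
    junctions: JunctionSet,
    min_overlap: int = 20,
) -> dict[tuple[str, str], int]:
    """Count reads supporting each junction.

    A read supports a junction iff the read or its reverse complement matches
    the junction over a span crossing the breakpoint with >= min_overlap
    exactly matched bases on each side (the cores); outside the cores up to
    one mismatch per 50 bp of overlap is tolerated. Each read counts at most
    once per junction.
    """
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    if isinstance(reads, PairedReads):
        read_list = reads.all_reads()
    else:
        read_list = list(reads)
    if read_list and len(read_list[0]) < 2 * min_overlap:
        raise ValueError("read length must be >= 2*min_overlap")
    flank = junctions.flank
    prepared = []
    for key in JUNCTION_KEYS:
        jseq = junctions.junctions[key]
        core = jseq[flank - min_overlap:flank + min_overlap]
        prepared.append((key, core, seq_to_array(jseq)))
    counts = {key: 0 for key in JUNCTION_KEYS}
    core_at = flank - min_overlap  # junction coordinate where each core starts
    for read in read_list:
        rc = reverse_complement(read)
        for key, core, junc_arr in prepared:
            hit = False
            for oriented in (read, rc):
                # fast exact-core prefilter: a supporting read must contain
                # the 2*min_overlap-bp breakpoint core verbatim
                i = oriented.find(core)
                if i < 0:
                    continue
                read_arr = seq_to_array(oriented)
                while i >= 0 and not hit:
                    hit = _match_at(read_arr, junc_arr, core_at - i, flank, min_overlap)
                    i = oriented.find(core, i + 1)
                if hit:
                    break
            if hit:
                counts[key] += 1
    return counts


def _ratio(n_a: int, n_b: int) -> float | None:
    total = n_a + n_b
    if total == 0:
        return None
    return 100.0 * n_a / total


def support_ratio(counts: dict[tuple[str, str], int]):
    """Percent A-support ratio per breakpoint side and pooled across sides."""
    for v in counts.values():
        if v < 0:
            raise ValueError("counts must be non-negative")
    left = _ratio(counts[("A", "left")], counts[("B", "left")])
    right = _ratio(counts[("A", "right")], counts[("B", "right")])
    pooled = _ratio(
        counts[("A", "left")] + counts[("A", "right")],
        counts[("B", "left")] + counts[("B", "right")],
    )
    return left, right, pooled


def classify_arrangement(r: float | None) -> str:
    """Closed-interval classification of the pooled percent ratio."""
    if r is None:
        return NO_CALL
    if not 0.0 <= r <= 100.0:
        raise ValueError("ratio must be in [0,100]")
    if r >= 80.0:
        return SAME_AS_A
    if r <= 20.0:
        return SAME_AS_B
    return HETEROZYGOUS


def genotype_inversion(
    genome_a: Genome,
    genome_b: Genome,
    inv: Inversion,
    reads: PairedReads | list[str],
    flank: int = 150,
    min_overlap: int = 20,
) -> InversionCall:
    """End-to-end call: junctions -> support counts -> pooled ratio -> class."""
    junctions = extract_junctions(genome_a, genome_b, inv, flank)
    counts = count_junction_support(reads, junctions, min_overlap)
    left, right, pooled = support_ratio(counts)
    return InversionCall(
        counts=counts,
        ratio_left=left,
        ratio_right=right,
        ratio_pooled=pooled,
        arrangement=classify_arrangement(pooled),
    )
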