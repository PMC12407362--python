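"""Synthetic data generation.

Everything the downstream analyses consume can be generated here with a known
truth set: a pair of reference genomes differing by large inversions and
background SNPs, short paired-end reads, a structured two-deme genotype panel
(Balding-Nichols model), phenotypes tied to a causal haplotype, and windowed
ChIP/input coverage tracks with a planted centromeric enrichment.

The defaults mirror a resequencing study of a halophyte legume panel: 51
diploid accessions (31 inland, 20 coastal) at ~20x 150-bp paired-end coverage,
two ~1 Gb reference genomes differing by peri/centromeric inversions (scaled
down here to desk-size chromosomes), a 139-bp centromeric satellite, and a
salt-survival phenotype with tolerant/sensitive group means of 91.83% and
1.11%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix
from .seq import mutate_bases, random_sequence, reverse_complement

# default study-design constants
DEFAULT_READ_LEN = 150
DEFAULT_DEPTH = 20.6
DEFAULT_DEME_SIZES = (31, 20)      # inland (AI), coastal (AC)
TOLERANT_SURVIVAL = 91.83          # % — tolerant-haplotype group mean
SENSITIVE_SURVIVAL = 1.11          # % — sensitive-haplotype group mean
TOLERANT_SURVIVAL_SD = 2.25
SENSITIVE_SURVIVAL_SD = 1.57
SATELLITE_PERIOD = 139             # bp — dominant centromeric satellite unit

Genome = dict[str, str]


# ---------------------------------------------------------------------------
# specs and truth
# ---------------------------------------------------------------------------

@dataclass
class GenomePairSpec:
    """Parameters for a pair of genomes differing by inversions and SNPs.

    chromosomes: name -> length (bp).
    inversions: (chrom, start, end) 0-based half-open, non-overlapping.
    snp_rate: per-bp divergence applied outside inversions only, so the
        junction sequences of the two genomes stay exact.
    """

    chromosomes: dict[str, int]
    inversions: list[tuple[str, int, int]] = field(default_factory=list)
    snp_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.snp_rate <= 1.0:
            raise ValueError("snp_rate must be in [0,1]")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.inversions:
            if chrom not in self.chromosomes:
                raise ValueError(f"inversion on unknown chromosome {chrom}")
            if end - start < 2:
                raise ValueError("inversion length must be >= 2")
            if start < 0 or end > self.chromosomes[chrom]:
                raise ValueError("inversion outside chromosome bounds")
            by_chrom.setdefault(chrom, []).append((start, end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError("inversions overlap")


@dataclass
class PopulationSpec:
    """Two-deme Balding-Nichols panel with a planted divergence block.

    Deme allele frequencies are drawn around an ancestral frequency p with a
    differentiation parameter F: p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F), which has
    mean p and variance F p(1-p). F applies per region: ``f_background``
    genome-wide and ``f_block`` inside ``block`` (the divergence region).
    ``marker_positions`` are inversion-diagnostic sites perfectly correlated
    with each deme's arrangement; ``causal_positions`` define the tolerant/
    sensitive haplotype (all inland samples carry the sensitive haplotype;
    coastal samples carry the tolerant one with probability
    ``tolerant_freq_coastal``, matching the observed 55/45 coastal split).
    """

    n_inland: int = DEFAULT_DEME_SIZES[0]
    n_coastal: int = DEFAULT_DEME_SIZES[1]
    n_sites: int = 20_000
    chrom: str = "chr5"
    chrom_length: int = 2_000_000
    freq_range: tuple[float, float] = (0.05, 0.95)
    f_background: float = 0.05
    f_block: float = 0.6
    block: tuple[int, int] | None = (600_000, 1_400_000)
    marker_positions: tuple[int, ...] = ()
    causal_positions: tuple[int, ...] = ()
    tolerant_freq_coastal: float = 0.55
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.f_background, self.f_block):
            if not 0.0 <= f < 1.0:
                raise ValueError("differentiation F must be in [0,1)")
        if self.n_inland < 2 or self.n_coastal < 2:
            raise ValueError("deme sizes must be >= 2")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0,1]")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_range must satisfy 0 < lo <= hi < 1")
        if self.block is not None:
            s, e = self.block
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError("divergence block outside simulated chromosome")


@dataclass
class TruthSet:
    """Machine-readable record of everything the generators planted."""

    inversions: list[tuple[str, int, int]] = field(default_factory=list)
    snps: list[tuple[str, int, str, str]] = field(default_factory=list)  # chrom, pos0, ref, alt
    arrangement: dict[str, str] = field(default_factory=dict)            # sample -> class
    haplotype_group: dict[str, str] = field(default_factory=dict)        # sample -> tolerant/sensitive
    block: tuple[str, int, int] | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------

def generate_genome_pair(spec: GenomePairSpec) -> tuple[Genome, Genome, TruthSet]:
    """Genome B equals genome A with each inversion reverse-complemented and
    SNP divergence applied outside the inversions."""
    rng = np.random.default_rng(spec.seed)
    truth = TruthSet(seed=spec.seed)
    genome_a: Genome = {}
    genome_b: Genome = {}
    inv_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in spec.inversions:
        inv_by_chrom.setdefault(chrom, []).append((start, end))
        truth.inversions.append((chrom, start, end))

    for chrom, length in spec.chromosomes.items():
        seq_a = random_sequence(rng, length)
        arr = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8).copy()
        inversions = sorted(inv_by_chrom.get(chrom, []))
        if spec.snp_rate > 0:
            mask = np.ones(length, dtype=bool)
            for s, e in inversions:
                mask[s:e] = False
            candidates = np.flatnonzero(mask)
            hits = candidates[rng.random(candidates.size) < spec.snp_rate]
            if hits.size:
                bases = np.frombuffer(b"ACGT", dtype=np.uint8)
                cur = np.searchsorted(bases, arr[hits])
                shift = rng.integers(1, 4, size=hits.size)
                arr[hits] = bases[(cur + shift) % 4]
                for pos in hits:
                    truth.snps.append((chrom, int(pos), seq_a[pos], chr(arr[pos])))
        seq_b = arr.tobytes().decode("ascii")
        for s, e in inversions:
            seq_b = seq_b[:s] + reverse_complement(seq_a[s:e]) + seq_b[e:]
        genome_a[chrom] = seq_a
        genome_b[chrom] = seq_b
    truth.snps.sort()
    return genome_a, genome_b, truth


def plant_satellite_array(
    genome: Genome,
    region: tuple[str, int, int],
    monomer: str,
    copies: int,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> Genome:
    """Replace the start of ``region`` with a tandem array of ``monomer``.

    The array (period x copies bp) must fit inside the region; any remainder of
    the region keeps its original sequence so chromosome length is unchanged.
    Substitutions are applied i.i.d. at ``mutation_rate``.
    """
    chrom, start, end = region
    if chrom not in genome:
        raise ValueError(f"unknown chromosome {chrom}")
    monomer = monomer.upper()
    if set(monomer) - set("ACGT"):
        raise ValueError("monomer contains invalid bases")
    array_len = len(monomer) * copies
    if end - start < array_len:
        raise ValueError("region too small for the requested array")
    rng = np.random.default_rng(seed)
    array = mutate_bases(rng, monomer * copies, mutation_rate)
    seq = genome[chrom]
    out = dict(genome)
    out[chrom] = seq[:start] + array + seq[start + array_len:]
    return out


# ---------------------------------------------------------------------------
# paired-end reads
# ---------------------------------------------------------------------------

@dataclass
class PairedReads:
    r1: list[str]
    r2: list[str]
    names: list[str]

    def __len__(self) -> int:
        return len(self.r1)

    def all_reads(self) -> list[str]:
        return self.r1 + self.r2


def simulate_paired_reads(
    genome: Genome,
    depth: float,
    read_len: int = DEFAULT_READ_LEN,
    insert_mean: int = 350,
    insert_sd: int = 50,
    error_rate: float = 0.0,
    seed: int = 0,
    name_prefix: str = "read",
) -> PairedReads:
    """Uniform-coverage paired-end reads.

    Pair count = round(depth * genome_length / (2 * read_len)). Fragment start
    positions are uniform, fragment strand is random, the second mate is the
    reverse complement of the fragment end, and substitution errors are i.i.d.
    at ``error_rate``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_len < 20:
        raise ValueError("read_len must be >= 20")
    if read_len > insert_mean:
        raise ValueError("read_len must not exceed insert_mean")
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    total = lengths.sum()
    n_pairs = int(round(depth * total / (2 * read_len)))
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lengths / total)
    inserts = np.maximum(
        read_len, np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int)
    )
    strands = rng.integers(0, 2, size=n_pairs)
    starts_u = rng.random(n_pairs)

    r1: list[str] = []
    r2: list[str] = []
    names: list[str] = []
    for i in range(n_pairs):
        seq = genome[chroms[chrom_idx[i]]]
        ins = min(int(inserts[i]), len(seq))
        start = int(starts_u[i] * (len(seq) - ins + 1))
        frag = seq[start:start + ins]
        if strands[i]:
            frag = reverse_complement(frag)
        r1.append(frag[:read_len])
        r2.append(reverse_complement(frag[-read_len:]))
        names.append(f"{name_prefix}_{i}")
    if error_rate > 0:
        r1 = [mutate_bases(rng, s, error_rate) for s in r1]
        r2 = [mutate_bases(rng, s, error_rate) for s in r2]
    return PairedReads(r1=r1, r2=r2, names=names)


# ---------------------------------------------------------------------------
# population panel
# ---------------------------------------------------------------------------

def _deme_frequencies(
    rng: np.random.Generator, p: np.ndarray, f: np.ndarray
) -> np.ndarray:
    """Balding-Nichols deme frequency draw; F=0 sites keep the ancestral p."""
    out = p.copy()
    hot = f > 0
    if hot.any():
        a = p[hot] * (1 - f[hot]) / f[hot]
        b = (1 - p[hot]) * (1 - f[hot]) / f[hot]
        out[hot] = rng.beta(a, b)
    return out


def simulate_population(
    spec: PopulationSpec,
) -> tuple[GenotypeMatrix, list[str], TruthSet]:
    """Two-deme diploid genotype panel with a planted high-F divergence block,
    inversion-diagnostic markers and an optional causal haplotype."""
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_inland, spec.n_coastal
    samples = [f"AI{i + 1:03d}" for i in range(n1)] + [
        f"AC{i + 1:03d}" for i in range(n2)
    ]
    labels = ["AI"] * n1 + ["AC"] * n2

    special = sorted(set(spec.marker_positions) | set(spec.causal_positions))
    n_random = spec.n_sites - len(special)
    if n_random < 0:
        raise ValueError("more special positions than n_sites")
    positions = np.sort(
        rng.choice(spec.chrom_length, size=n_random, replace=False)
    ).astype(np.int64)
    lo, hi = spec.freq_range
    p_anc = rng.uniform(lo, hi, size=n_random)
    f = np.full(n_random, spec.f_background)
    if spec.block is not None:
        s, e = spec.block
        f[(positions >= s) & (positions < e)] = spec.f_block

    p1 = _deme_frequencies(rng, p_anc, f)
    p2 = _deme_frequencies(rng, p_anc, f)
    dos1 = rng.binomial(2, p1[None, :], size=(n1, n_random))
    dos2 = rng.binomial(2, p2[None, :], size=(n2, n_random))
    dosages = np.vstack([dos1, dos2]).astype(np.int8)

    truth = TruthSet(seed=spec.seed)
    if spec.block is not None:
        truth.block = (spec.chrom, spec.block[0], spec.block[1])

    # arrangement: inland carries the inverted (B) arrangement, coastal the
    # reference (A) arrangement — markers are perfectly correlated with it
    for i, s in enumerate(samples):
        truth.arrangement[s] = "same-as-B" if labels[i] == "AI" else "same-as-A"
    arrangement_dos = np.array(
        [2 if truth.arrangement[s] == "same-as-B" else 0 for s in samples],
        dtype=np.int8,
    )

    # causal haplotype: inland all sensitive; coastal tolerant w.p. tolerant_freq_coastal
    hap_tolerant = np.zeros(len(samples), dtype=bool)
    coastal = np.array([lab == "AC" for lab in labels])
    hap_tolerant[coastal] = rng.random(coastal.sum()) < spec.tolerant_freq_coastal
    for i, s in enumerate(samples):
        truth.haplotype_group[s] = "tolerant" if hap_tolerant[i] else "sensitive"
    causal_dos = np.where(hap_tolerant, 2, 0).astype(np.int8)

    extra_pos: list[int] = []
    extra_cols: list[np.ndarray] = []
    for pos in special:
        col = np.zeros(len(samples), dtype=np.int8)
        if pos in spec.marker_positions:
            col = arrangement_dos.copy()
        if pos in spec.causal_positions:
            col = causal_dos.copy()
        extra_pos.append(pos)
        extra_cols.append(col)
    if extra_pos:
        positions = np.concatenate([positions, np.array(extra_pos, dtype=np.int64)])
        dosages = np.hstack([dosages, np.column_stack(extra_cols)])
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        dosages = dosages[:, order]

    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages = dosages.copy()
        dosages[mask] = MISSING

    ref = np.full(len(positions), "A", dtype=object)
    alt = np.full(len(positions), "T", dtype=object)
    gm = GenotypeMatrix(
        dosages=dosages,
        chroms=np.full(len(positions), spec.chrom, dtype=object),
        positions=positions,
        samples=samples,
        ref=ref,
        alt=alt,
    )
    return gm, labels, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    groups: dict[str, str],
    group_means: dict[str, float] | None = None,
    noise_sd: float | dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Survival-percentage phenotypes: group mean + Gaussian noise, truncated
    to [0, 100].

    ``groups`` maps sample -> haplotype group. Defaults use the tolerant /
    sensitive survival means (91.83% / 1.11%) with their observed s.d.
    """
    if group_means is None:
        group_means = {"tolerant": TOLERANT_SURVIVAL, "sensitive": SENSITIVE_SURVIVAL}
    if noise_sd is None:
        noise_sd = {"tolerant": TOLERANT_SURVIVAL_SD, "sensitive": SENSITIVE_SURVIVAL_SD}
    for m in group_means.values():
        if not 0.0 <= m <= 100.0:
            raise ValueError("group means must be in [0,100]")
    if isinstance(noise_sd, dict):
        sd_of = noise_sd.get
        if any(v < 0 for v in noise_sd.values()):
            raise ValueError("noise_sd must be non-negative")
    else:
        if noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        sd_of = lambda g, default=None: noise_sd  # noqa: E731
    rng = np.random.default_rng(seed)
    rows = []
    for sample, group in groups.items():
        mean = group_means[group]
        sd = sd_of(group, 0.0) or 0.0
        value = mean if sd == 0 else float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
        rows.append({"sample": sample, "group": group, "survival": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ChIP coverage tracks
# ---------------------------------------------------------------------------

def simulate_chip_tracks(
    genome_length: int,
    centromere: tuple[int, int],
    fold: float,
    depth: float,
    window: int = 10_000,
    read_len: int = DEFAULT_READ_LEN,
    seed: int = 0,
):
    """Poisson window counts for an IP and an input track.

    Expected reads per window = depth * window / read_len; the IP rate is
    multiplied by ``fold`` inside the centromere interval.
    """
    from .centromere import CoverageTrack

    if depth <= 0:
        raise ValueError("depth must be positive")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    s, e = centromere
    if not (0 <= s < e <= genome_length):
        raise ValueError("centromere outside genome")
    rng = np.random.default_rng(seed)
    n_windows = int(np.ceil(genome_length / window))
    lam = depth * window / read_len
    starts = np.arange(n_windows) * window
    in_cen = (starts + window > s) & (starts < e)
    ip_rate = np.where(in_cen, lam * fold, lam)
    ip = rng.poisson(ip_rate).astype(np.int64)
    inp = rng.poisson(np.full(n_windows, lam)).astype(np.int64)
    return (
        CoverageTrack(window=window, counts=ip),
        CoverageTrack(window=window, counts=inp),
    )
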