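"""Centromere profiling: CENH3 fold-enrichment windows and domain calling,
satellite period detection, monomer consensus with per-position variant
frequencies, and a windowed sequence-identity matrix.

Fold enrichment follows the standard ChIP/input convention: window counts are
normalised by each track's total read count and ratioed, with a pseudocount
guarding empty windows. The satellite tools assume substitution-only
divergence between monomers (no indels), which is what the tandem arrays the
synthetic generator plants look like; period detection uses the spacing of
recurring k-mers rather than full tandem-repeat annotation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .seq import reverse_complement, seq_to_array

DEFAULT_ENRICH_WINDOW = 10_000
DEFAULT_IDENTITY_WINDOW = 2_000
DEFAULT_PERIOD_K = 12
DEFAULT_IDENTITY_K = 15
PERIOD_SUPPORT_MIN = 0.3
MIN_PERIOD_OBSERVATIONS = 10


@dataclass
class CoverageTrack:
    """Non-overlapping fixed-width window read counts for one chromosome."""

    window: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("window counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_windows(self) -> int:
        return len(self.counts)


@dataclass
class MonomerModel:
    period: int
    phase: int
    consensus: str
    variant_freq: np.ndarray  # length == period, each in [0,1]
    n_monomers: int


def fold_enrichment(
    ip: CoverageTrack, input_: CoverageTrack, pseudocount: float = 1.0
) -> np.ndarray:
    """Per-window fold = ((ip_w+pc)/IP_total) / ((input_w+pc)/INPUT_total)."""
    if ip.window != input_.window or ip.n_windows != input_.n_windows:
        raise ValueError("IP and input tracks must share the same window grid")
    if ip.total == 0 or input_.total == 0:
        raise ValueError("track totals must be positive")
    ip_norm = (ip.counts + pseudocount) / ip.total
    in_norm = (input_.counts + pseudocount) / input_.total
    return ip_norm / in_norm


def call_centromere_domain(
    fold: np.ndarray,
    window: int,
    fold_threshold: float = 2.0,
    min_length: int = 100_000,
    max_gap: int = 1,
) -> list[tuple[int, int]]:
    """Maximal runs of windows with fold >= threshold, bridging up to
    ``max_gap`` consecutive sub-threshold windows, kept if span >= min_length.

    Returns 0-based half-open bp intervals on the track's window grid.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    above = np.asarray(fold) >= fold_threshold
    domains: list[tuple[int, int]] = []
    start = None
    last_above = None
    for i, flag in enumerate(above):
        if flag:
            if start is None:
                start = i
            elif i - last_above - 1 > max_gap:
                if (last_above + 1 - start) * window >= min_length:
                    domains.append((start * window, (last_above + 1) * window))
                start = i
            last_above = i
    if start is not None and (last_above + 1 - start) * window >= min_length:
        domains.append((start * window, (last_above + 1) * window))
    return domains


# ---------------------------------------------------------------------------
# satellite monomers
# ---------------------------------------------------------------------------

def detect_period(
    seq: str,
    k: int = DEFAULT_PERIOD_K,
    max_period: int = 2_000,
) -> tuple[int, float] | None:
    """Dominant tandem-repeat period from recurring k-mer spacing.

    For every k-mer occurring more than once, collect the distances between
    consecutive occurrences; the most frequent distance <= max_period is the
    period candidate, reported with its support fraction. Returns None when
    there are too few recurrences or the top distance falls below the support
    threshold — e.g. on random sequence.
    """
    if len(seq) < 3 * k:
        raise ValueError("sequence shorter than 3k")
    last_seen: dict[str, int] = {}
    spacings: Counter[int] = Counter()
    total = 0
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        prev = last_seen.get(kmer)
        if prev is not None:
            d = i - prev
            if 0 < d <= max_period:
                spacings[d] += 1
                total += 1
        last_seen[kmer] = i
    if total < MIN_PERIOD_OBSERVATIONS:
        return None
    period, count = spacings.most_common(1)[0]
    support = count / total
    if support < PERIOD_SUPPORT_MIN:
        return None
    return period, support


def extract_monomers(seq: str, period: int) -> tuple[list[str], int]:
    """Cut a substitution-mutated tandem array into monomers.

    The phase offset in [0, period) is chosen to minimise the total Hamming
    distance of all monomers to the first monomer at that phase; returns
    floor((len(seq) - phase) / period) monomers.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if len(seq) < 2 * period:
        raise ValueError("sequence must contain at least two periods")
    arr = seq_to_array(seq)
    best_phase, best_cost = 0, None
    for phase in range(period):
        m = (len(arr) - phase) // period
        if m < 2:
            continue
        view = arr[phase:phase + m * period].reshape(m, period)
        # per-comparison cost, else phases yielding fewer monomers win; ties
        # (clean arrays, where every rotation is consistent) keep the
        # smallest phase
        cost = float((view != view[0]).sum()) / (m - 1)
        if best_cost is None or cost < best_cost:
            best_phase, best_cost = phase, cost
    m = (len(arr) - best_phase) // period
    view = arr[best_phase:best_phase + m * period].reshape(m, period)
    monomers = [row.tobytes().decode("ascii") for row in view]
    return monomers, best_phase


def build_consensus_profile(monomers: list[str]) -> MonomerModel:
    """Column-majority consensus and per-position variant frequency.

    consensus[i] is the most common base in column i (ties broken
    alphabetically); variant_freq[i] = 1 - majority count / column depth.
    """
    if len(monomers) < 2:
        raise ValueError("need at least two monomers")
    period = len(monomers[0])
    if any(len(m) != period for m in monomers):
        raise ValueError("monomers must have equal length")
    mat = np.vstack([seq_to_array(m) for m in monomers])
    depth = mat.shape[0]
    consensus_chars = []
    variant = np.empty(period)
    for i in range(period):
        col = mat[:, i]
        bases, counts = np.unique(col, return_counts=True)
        best = counts.max()
        # alphabetical tie-break: np.unique returns ascending byte order
        maj = bases[np.argmax(counts)]
        consensus_chars.append(chr(maj))
        variant[i] = 1.0 - best / depth
    return MonomerModel(
        period=period,
        phase=0,
        consensus="".join(consensus_chars),
        variant_freq=variant,
        n_monomers=depth,
    )


def profile_satellite(seq: str, period: int | None = None) -> MonomerModel:
    """Convenience: detect period (unless given), phase, and build profile."""
    if period is None:
        hit = detect_period(seq)
        if hit is None:
            raise ValueError("no tandem period detected")
        period = hit[0]
    monomers, phase = extract_monomers(seq, period)
    model = build_consensus_profile(monomers)
    model.phase = phase
    return model


# ---------------------------------------------------------------------------
# windowed identity matrix
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _jaccard_to_identity(j: float, k: int) -> float:
    """Mash-style mapping from k-mer Jaccard to an average base identity."""
    if j <= 0.0:
        return 0.0
    if j >= 1.0:
        return 1.0
    dist = -np.log(2.0 * j / (1.0 + j)) / k
    return float(max(0.0, 1.0 - dist))


def window_identity_matrix(
    seq: str,
    window: int = DEFAULT_IDENTITY_WINDOW,
    k: int = DEFAULT_IDENTITY_K,
) -> np.ndarray:
    """Symmetric all-vs-all identity estimate between non-overlapping windows,
    taking the better of the forward and reverse-complement comparison."""
    if window < 2 * k:
        raise ValueError("window must be >= 2k")
    if len(seq) < 2 * window:
        raise ValueError("sequence must contain at least two windows")
    n = len(seq) // window
    fwd = [_kmer_set(seq[i * window:(i + 1) * window], k) for i in range(n)]
    rev = [_kmer_set(reverse_complement(seq[i * window:(i + 1) * window]), k) for i in range(n)]
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter_f = len(fwd[i] & fwd[j])
            inter_r = len(fwd[i] & rev[j])
            union_f = len(fwd[i] | fwd[j])
            union_r = len(fwd[i] | rev[j])
            jac = max(
                inter_f / union_f if union_f else 0.0,
                inter_r / union_r if union_r else 0.0,
            )
            mat[i, j] = mat[j, i] = _jaccard_to_identity(jac, k)
    return mat
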