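"""Two-group divergence scan: per-site Weir-Cockerham F_ST and nucleotide
diversity, sliding-window summaries, and genetic divergence region (GDR)
calling as merged top-quantile windows.

The F_ST estimator is the Weir & Cockerham (1984) two-population theta in its
allele-count form: with deme allele-sample sizes n_i (2 x genotyped samples)
and alternate counts j_i,

    n_bar = (n_1+n_2)/2,   n_c = (n - (n_1^2+n_2^2)/n),   n = n_1+n_2
    p_bar = (j_1+j_2)/n,   s^2 = sum_i n_i (p_i - p_bar)^2 / n_bar
    a = (n_bar/n_c) * [ s^2 - (p_bar(1-p_bar) - s^2/2) / (n_bar-1) ]
    b = (n_bar/(n_bar-1)) * [ p_bar(1-p_bar) - s^2/2 ]
    theta = a / (a + b)

Negative per-site values are kept; windowed and genome-wide summaries use the
ratio-of-sums ("weighted") form sum(a)/sum(a+b), with the mean of per-site
ratios reported alongside. Sites monomorphic across both groups are undefined
and excluded from the sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 10_000
DEFAULT_GDR_QUANTILE = 0.95
MIN_WINDOWS_FOR_GDR = 20


@dataclass
class ScanConfig:
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    gdr_quantile: float = DEFAULT_GDR_QUANTILE

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must not exceed window")
        if not 0.0 < self.gdr_quantile < 1.0:
            raise ValueError("gdr_quantile must be in (0,1)")


# ---------------------------------------------------------------------------
# site filtering and counts
# ---------------------------------------------------------------------------

def filter_variants(
    gm: GenotypeMatrix, maf_min: float = 0.03, missing_max: float = 0.1
) -> GenotypeMatrix:
    """Keep sites with MAF >= maf_min (over non-missing calls) and missing
    fraction <= missing_max."""
    if gm.n_sites == 0:
        return gm
    missing = gm.missing_mask()
    miss_frac = missing.mean(axis=0)
    af = gm.allele_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(af, 1.0 - af)
    keep = (~np.isnan(maf)) & (maf >= maf_min) & (miss_frac <= missing_max)
    return gm.take_sites(np.flatnonzero(keep))


def allele_counts_by_group(
    gm: GenotypeMatrix, labels: list[str]
) -> pd.DataFrame:
    """Per-site allele-sample size n (2 x genotyped) and alternate count j for
    each of the two groups. Sites where a group has no genotyped sample are
    flagged undefined."""
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    lab = np.asarray(labels)
    out: dict[str, np.ndarray] = {}
    for gi, g in enumerate(uniq, start=1):
        d = gm.dosages[lab == g]
        called = d != MISSING
        out[f"n{gi}"] = 2 * called.sum(axis=0)
        out[f"j{gi}"] = np.where(called, d, 0).sum(axis=0)
    df = pd.DataFrame(out)
    df.insert(0, "chrom", gm.chroms)
    df.insert(1, "pos", gm.positions)
    df["defined"] = (df["n1"] > 0) & (df["n2"] > 0)
    df.attrs["groups"] = uniq
    return df


# ---------------------------------------------------------------------------
# per-site estimators
# ---------------------------------------------------------------------------

def wc_fst_components(
    n1: np.ndarray, j1: np.ndarray, n2: np.ndarray, j2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components per site.

    Returns (a, d) with d = a + b; theta = a/d. Undefined sites (a group with
    n=0, or monomorphic across both groups) get NaN in both.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    j1 = np.asarray(j1, dtype=float)
    j2 = np.asarray(j2, dtype=float)
    n = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = j1 / n1
        p2 = j2 / n2
        pbar = (j1 + j2) / n
        nbar = n / 2.0
        nc = n - (n1**2 + n2**2) / n
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        inner = pbar * (1.0 - pbar) - s2 / 2.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * inner
        d = a + b
    undef = (n1 == 0) | (n2 == 0) | (pbar <= 0.0) | (pbar >= 1.0) | (nc <= 0)
    a = np.where(undef, np.nan, a)
    d = np.where(undef, np.nan, d)
    return a, d


def fst_site(n1: int, j1: int, n2: int, j2: int) -> tuple[float, float, float]:
    """Single-site convenience wrapper: returns (a, d, theta)."""
    a, d = wc_fst_components(
        np.array([n1]), np.array([j1]), np.array([n2]), np.array([j2])
    )
    a_, d_ = float(a[0]), float(d[0])
    theta = np.nan if (np.isnan(d_) or d_ == 0.0) else a_ / d_
    return a_, d_, theta


def pi_site(n: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity pi = 2 j (n-j) / (n (n-1))."""
    n = np.asarray(n, dtype=float)
    j = np.asarray(j, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    return np.where(n < 2, np.nan, pi)


def genome_wide_fst(a: np.ndarray, d: np.ndarray) -> float:
    """Weighted (ratio-of-sums) theta over all defined sites."""
    ok = ~np.isnan(d)
    denom = d[ok].sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def site_stats(gm: GenotypeMatrix, labels: list[str]) -> pd.DataFrame:
    """Per-site table: WC components, theta, and per-group pi."""
    counts = allele_counts_by_group(gm, labels)
    a, d = wc_fst_components(counts.n1, counts.j1, counts.n2, counts.j2)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / d
    counts["a"] = a
    counts["d"] = d
    counts["theta"] = theta
    counts["pi1"] = pi_site(counts.n1, counts.j1)
    counts["pi2"] = pi_site(counts.n2, counts.j2)
    return counts


# ---------------------------------------------------------------------------
# windows and GDRs
# ---------------------------------------------------------------------------

def _window_starts(chrom_length: int, window: int, step: int) -> np.ndarray:
    if chrom_length <= window:
        return np.array([0], dtype=np.int64)
    n = (chrom_length - window) // step + 1
    return np.arange(n, dtype=np.int64) * step

def windowed_scan(
    stats: pd.DataFrame,
    chrom_lengths: dict[str, int],
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Sliding-window F_ST and pi.

    Windows start at 0 and advance by ``step``; the last start is at most
    chrom_length - window. Windowed F_ST is the ratio of sums over defined
    sites; windowed pi divides the per-site pi sum by the window span in bp.
    """
    config = config or ScanConfig()
    w, s = config.window, config.step
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = stats[stats.chrom == chrom]
        pos = sub.pos.to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        a = sub.a.to_numpy()[order]
        d = sub.d.to_numpy()[order]
        theta = sub.theta.to_numpy()[order]
        pi1 = np.nan_to_num(sub.pi1.to_numpy()[order])
        pi2 = np.nan_to_num(sub.pi2.to_numpy()[order])
        ok = ~np.isnan(d)
        # prefix sums over sorted sites for O(1) window aggregation
        ca = np.concatenate([[0.0], np.cumsum(np.where(ok, a, 0.0))])
        cd = np.concatenate([[0.0], np.cumsum(np.where(ok, d, 0.0))])
        cth = np.concatenate([[0.0], np.cumsum(np.where(ok, theta, 0.0))])
        cnt = np.concatenate([[0], np.cumsum(ok.astype(int))])
        cp1 = np.concatenate([[0.0], np.cumsum(pi1)])
        cp2 = np.concatenate([[0.0], np.cumsum(pi2)])
        nall = np.concatenate([[0], np.cumsum(np.ones(len(pos), dtype=int))])
        for start in _window_starts(length, w, s):
            end = min(start + w, length)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            n_def = int(cnt[hi] - cnt[lo])
            sum_d = cd[hi] - cd[lo]
            fst_w = (ca[hi] - ca[lo]) / sum_d if (n_def > 0 and sum_d != 0) else np.nan
            fst_m = (cth[hi] - cth[lo]) / n_def if n_def > 0 else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_sites": int(nall[hi] - nall[lo]),
                    "n_defined": n_def,
                    "fst_weighted": fst_w,
                    "fst_mean": fst_m,
                    "pi1": (cp1[hi] - cp1[lo]) / (end - start),
                    "pi2": (cp2[hi] - cp2[lo]) / (end - start),
                }
            )
    return pd.DataFrame(rows)


def call_gdrs(
    windows: pd.DataFrame, config: ScanConfig | None = None
) -> pd.DataFrame:
    """Merge windows strictly above the top-quantile F_ST threshold into
    genetic divergence regions.

    The threshold is the linear-interpolation empirical quantile over defined
    windows only; ties at the threshold are not called (a constant track
    yields no GDRs). Selected windows that overlap or abut are merged; each
    region reports the mean windowed F_ST of its member windows.
    """
    config = config or ScanConfig()
    vals = windows.fst_weighted.to_numpy()
    defined = windows[~np.isnan(vals)]
    if len(defined) < MIN_WINDOWS_FOR_GDR:
        raise ValueError(
            f"need >= {MIN_WINDOWS_FOR_GDR} defined windows, got {len(defined)}"
        )
    threshold = float(np.quantile(defined.fst_weighted.to_numpy(), config.gdr_quantile))
    sel = defined[defined.fst_weighted > threshold].sort_values(["chrom", "start"])
    regions: list[dict] = []
    for _, row in sel.iterrows():
        if (
            regions
            and regions[-1]["chrom"] == row.chrom
            and row.start <= regions[-1]["end"]
        ):
            regions[-1]["end"] = max(regions[-1]["end"], int(row.end))
            regions[-1]["_vals"].append(row.fst_weighted)
        else:
            regions.append(
                {
                    "chrom": row.chrom,
                    "start": int(row.start),
                    "end": int(row.end),
                    "_vals": [row.fst_weighted],
                }
            )
    out = pd.DataFrame(
        [
            {
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "mean_fst": float(np.mean(r["_vals"])),
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "mean_fst"],
    )
    out.attrs["threshold"] = threshold
    return out
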