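"""Gene-centric aggregation and statistical comparisons.

Covers expression-based gene classification, promoter/gene-body region
construction, overlap-weighted per-region summaries, strand-aware metagene
profiles with SEM, the rank-based group/profile comparisons, rank correlation
with expression, and the genome fraction of significantly changed bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import RankTestResult, mann_whitney, wilcoxon_signed_rank
from .tracks import BinnedTrack, PerBpTrack

__all__ = [
    "GeneModel",
    "ProfileMatrix",
    "classify_upregulated_genes",
    "gene_body_region",
    "promoter_region",
    "per_region_mean",
    "metagene_profile",
    "compare_group_timepoints",
    "compare_profiles_signed_rank",
    "correlate_with_expression",
    "fraction_significant_changes",
    "sample_random_sites",
]

log = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """TSS is the transcription start regardless of orientation, so a minus
    strand gene has TSS > TTS."""

    gene_id: str
    chrom: str
    tss: int
    tts: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: + strand requires TSS < TTS")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: - strand requires TSS > TTS")


@dataclass
class ProfileMatrix:
    offsets: np.ndarray          # strand-oriented, 5' -> 3'
    matrix: np.ndarray           # rows = anchors
    mean: np.ndarray
    sem: np.ndarray
    anchors: pd.DataFrame


def classify_upregulated_genes(expr: pd.DataFrame, variant: str = "results",
                               epsilon: float = 0.5) -> Set[str]:
    """Select up-regulated genes from an expression table.

    variant='results': fold(0->1 h) >= 2 and the gene is either further
    up-regulated from 1 to 4 h or does not change more than ``epsilon`` in
    log2 units after 1 h.
    variant='methods': fold >= 2 at both 0-1 h and 0-4 h with significance
    flags set on both intervals.
    """
    needed = {"gene_id", "log2fc_0_1", "log2fc_1_4", "log2fc_0_4"}
    missing = needed - set(expr.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if variant == "results":
        sel = (expr["log2fc_0_1"] >= 1.0) & (expr["log2fc_1_4"] >= -epsilon)
    elif variant == "methods":
        for col in ("significant_0_1", "significant_0_4"):
            if col not in expr.columns:
                raise ValueError(f"methods variant needs column {col}")
        sel = ((expr["log2fc_0_1"] >= 1.0) & (expr["log2fc_0_4"] >= 1.0)
               & expr["significant_0_1"] & expr["significant_0_4"])
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return set(expr.loc[sel, "gene_id"])


def _clip_interval(start: int, end: int, chrom_len: Optional[int],
                   label: str) -> Tuple[int, int]:
    if start < 0:
        warnings.warn(f"{label}: interval clipped at chromosome start")
        start = 0
    if chrom_len is not None and end > chrom_len:
        warnings.warn(f"{label}: interval clipped at chromosome end")
        end = chrom_len
    return start, end


def gene_body_region(g: GeneModel, upstream: int = 500,
                     chrom_len: Optional[int] = None) -> Tuple[int, int]:
    """[TSS - upstream, TTS) in transcription orientation."""
    if g.strand == "+":
        start, end = g.tss - upstream, g.tts
    else:
        start, end = g.tts, g.tss + upstream
    return _clip_interval(start, end, chrom_len, g.gene_id)


def promoter_region(g: GeneModel, flank: int = 1000,
                    chrom_len: Optional[int] = None) -> Tuple[int, int]:
    """TSS +/- flank, a strand-independent span."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    return _clip_interval(g.tss - flank, g.tss + flank, chrom_len, g.gene_id)


def per_region_mean(track: BinnedTrack,
                    regions: Sequence[Tuple[str, int, int]]) -> np.ndarray:
    """Overlap-weighted mean of bin values over each region.

    Each overlapping bin contributes with weight equal to the overlap length.
    Regions covering no bins (or only NaN bins) yield NaN.
    """
    bs = track.bin_size
    out = np.full(len(regions), np.nan)
    for i, (chrom, start, end) in enumerate(regions):
        if chrom not in track.data or end <= start:
            continue
        vals = track.data[chrom]
        b0 = max(start // bs, 0)
        b1 = min(-(-end // bs), len(vals))
        if b1 <= b0:
            continue
        idx = np.arange(b0, b1)
        lo = np.maximum(idx * bs, start)
        hi = np.minimum((idx + 1) * bs, end)
        w = (hi - lo).astype(float)
        v = vals[idx]
        ok = np.isfinite(v) & (w > 0)
        if ok.any():
            out[i] = np.average(v[ok], weights=w[ok])
    return out


def _values_at(track, chrom: str, positions: np.ndarray) -> np.ndarray:
    if isinstance(track, PerBpTrack):
        return track.values_at(chrom, positions)
    return track.values_at(chrom, positions)


def metagene_profile(track, anchors: pd.DataFrame, flank: int = 1000,
                     step: Optional[int] = None) -> ProfileMatrix:
    """Strand-oriented average profile around anchor positions.

    ``anchors`` needs columns chrom, pos, strand. Offsets run 5'->3'; minus
    strand rows are read in decreasing coordinates so profiles align in
    transcription orientation. SEM = sd/sqrt(n) (0 for a single anchor).
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    if step is None:
        step = getattr(track, "bin_size", 1)
    offsets = np.arange(-flank, flank + 1, step)
    chrom_lengths = track.chrom_lengths
    rows = []
    kept = []
    for _, a in anchors.iterrows():
        strand = a.get("strand", "+") if hasattr(a, "get") else "+"
        sign = 1 if strand == "+" else -1
        positions = int(a.pos) + sign * offsets
        L = chrom_lengths[a.chrom]
        if positions.min() < 0 or positions.max() >= L:
            continue
        rows.append(_values_at(track, a.chrom, positions))
        kept.append(a)
    if not rows:
        raise ValueError("no anchor fits within the genome at this flank")
    matrix = np.vstack(rows)
    mean = np.nanmean(matrix, axis=0)
    n = matrix.shape[0]
    sd = np.nanstd(matrix, axis=0, ddof=1) if n > 1 else np.zeros(matrix.shape[1])
    sem = sd / np.sqrt(n)
    return ProfileMatrix(offsets=offsets, matrix=matrix, mean=mean, sem=sem,
                         anchors=pd.DataFrame(kept))


def compare_group_timepoints(values_a, values_b) -> RankTestResult:
    """Two-sided Mann-Whitney comparison of two groups of per-gene values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 finite values per group")
    return mann_whitney(a, b, alternative="two-sided")


def compare_profiles_signed_rank(values_a, values_b,
                                 alternative: str = "increase") -> RankTestResult:
    """One-sided paired signed-rank test of b against a over a region.

    alternative='increase' tests whether b exceeds a (used for accessibility);
    'decrease' tests whether b falls below a (used for occupancy). Zero
    differences are dropped.
    """
    if alternative not in ("increase", "decrease"):
        raise ValueError("alternative must be 'increase' or 'decrease'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    side = "greater" if alternative == "increase" else "less"
    return wilcoxon_signed_rank(b[ok], a[ok], alternative=side)


def correlate_with_expression(metric, expression) -> Tuple[float, float]:
    """Spearman rank correlation (rho, p); NaN for degenerate input."""
    m = np.asarray(metric, dtype=float)
    e = np.asarray(expression, dtype=float)
    ok = np.isfinite(m) & np.isfinite(e)
    m, e = m[ok], e[ok]
    if len(m) < 3 or np.ptp(m) == 0 or np.ptp(e) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(m, e)
    return float(rho), float(p)


def fraction_significant_changes(reps_t0: Sequence[np.ndarray],
                                 reps_t1: Sequence[np.ndarray],
                                 change_thresholds: Sequence[float],
                                 alpha: float = 0.05,
                                 equal_var: bool = True) -> Dict[float, float]:
    """Percentage of bins with a significant between-time change per threshold.

    Per bin, a two-sample t-test across replicate values and the mean change;
    a bin is significant when p < alpha AND |mean change| >= threshold. The
    pooled-variance test is the default because it holds its nominal size
    exactly at the 2-4 replicates typical here (Welch is available via
    ``equal_var=False`` but is conservative at such replicate counts).
    Raw p-values, no multiplicity correction. Monotone non-increasing in the
    threshold.
    """
    a = np.vstack([np.asarray(r, dtype=float).ravel() for r in reps_t0])
    b = np.vstack([np.asarray(r, dtype=float).ravel() for r in reps_t1])
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 replicates per time point")
    if a.shape[1] != b.shape[1]:
        raise ValueError("replicate tracks must share the bin grid")
    ok = np.all(np.isfinite(a), axis=0) & np.all(np.isfinite(b), axis=0)
    a, b = a[:, ok], b[:, ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(b, a, axis=0, equal_var=equal_var)
    change = b.mean(axis=0) - a.mean(axis=0)
    sig = np.asarray(p) < alpha
    n = a.shape[1]
    return {float(th): 100.0 * np.mean(sig & (np.abs(change) >= th)) if n else 0.0
            for th in change_thresholds}


def sample_random_sites(n: int, chrom_lengths: Dict[str, int], seed: int = 0,
                        exclude_flank: int = 0) -> pd.DataFrame:
    """Uniform random anchor positions, excluding ``exclude_flank`` bp at ends."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    avail = np.array([max(chrom_lengths[c] - 2 * exclude_flank, 0) for c in chroms])
    total = avail.sum()
    if n > total:
        raise ValueError(f"requested {n} sites but only {total} positions available")
    if n == 0:
        return pd.DataFrame(columns=["chrom", "pos", "strand"])
    which = rng.choice(len(chroms), size=n, p=avail / total)
    pos = np.array([rng.integers(exclude_flank,
                                 chrom_lengths[chroms[w]] - exclude_flank)
                    for w in which])
    return (pd.DataFrame({"chrom": [chroms[w] for w in which],
                          "pos": pos, "strand": "+"})
            .sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True))
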