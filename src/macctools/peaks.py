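"""Stable nucleosome-position calling and positional-stability comparison.

Positions are local maxima of Gaussian-smoothed per-bp occupancy coverage,
pruned by a minimum height quantile and a minimum spacing; stability between
two peak sets is judged by comparing nearest-peak distance distributions
(replicate-vs-replicate against time-point-vs-time-point) with a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import ks_2samp

from .tracks import PerBpTrack

__all__ = [
    "PeakSet",
    "call_stable_positions",
    "nearest_peak_distances",
    "compare_stability",
    "StabilityResult",
]


@dataclass
class PeakSet:
    positions: Dict[str, np.ndarray]  # sorted dyad positions per chromosome
    heights: Dict[str, np.ndarray]
    params: Dict[str, float] = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def to_bed(self, path, half_width: int = 73) -> None:
        rows = []
        for chrom in sorted(self.positions):
            for pos, h in zip(self.positions[chrom], self.heights[chrom]):
                rows.append((chrom, max(pos - half_width, 0), pos + half_width,
                             f"nuc_{chrom}_{pos}", f"{h:.4g}", "."))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def call_stable_positions(coverage: PerBpTrack, sigma: float = 20.0,
                          min_spacing: int = 120,
                          min_height_quantile: float = 0.25) -> PeakSet:
    """Local maxima of Gaussian-smoothed coverage.

    A maximum is kept when its smoothed height reaches the
    ``min_height_quantile`` of positive smoothed values (genome-wide) and no
    higher maximum lies within ``min_spacing`` bp.
    """
    for v in coverage.data.values():
        if np.any(np.asarray(v) < 0):
            raise ValueError("coverage must be non-negative")
    smoothed = {c: gaussian_filter1d(np.asarray(v, dtype=float), sigma)
                for c, v in coverage.data.items()}
    allpos = np.concatenate([s[s > 0] for s in smoothed.values()] or [np.array([])])
    if allpos.size == 0:
        return PeakSet(positions={c: np.array([], dtype=int) for c in smoothed},
                       heights={c: np.array([]) for c in smoothed},
                       params=dict(sigma=sigma, min_spacing=min_spacing,
                                   min_height_quantile=min_height_quantile))
    min_height = float(np.quantile(allpos, min_height_quantile))
    positions, heights = {}, {}
    for chrom, s in smoothed.items():
        idx, props = find_peaks(s, height=min_height, distance=min_spacing)
        positions[chrom] = idx.astype(int)
        heights[chrom] = props["peak_heights"]
    return PeakSet(positions=positions, heights=heights,
                   params=dict(sigma=sigma, min_spacing=min_spacing,
                               min_height_quantile=min_height_quantile))


def nearest_peak_distances(peaks_a: PeakSet, peaks_b: PeakSet,
                           symmetric: bool = False) -> np.ndarray:
    """Distance from each peak in a to its nearest peak in b (bp).

    ``symmetric=True`` pools both directions. Chromosomes present in only one
    set are skipped; an entirely empty set is an error.
    """
    if peaks_a.n_peaks == 0 or peaks_b.n_peaks == 0:
        raise ValueError("both peak sets must be non-empty")
    out = []
    for chrom in peaks_a.positions:
        a = peaks_a.positions[chrom]
        b = peaks_b.positions.get(chrom, np.array([], dtype=int))
        if len(a) == 0 or len(b) == 0:
            continue
        j = np.searchsorted(b, a)
        left = b[np.clip(j - 1, 0, len(b) - 1)]
        right = b[np.clip(j, 0, len(b) - 1)]
        out.append(np.minimum(np.abs(a - left), np.abs(a - right)))
    dists = np.concatenate(out) if out else np.array([])
    if symmetric:
        dists = np.concatenate([dists, nearest_peak_distances(peaks_b, peaks_a)])
    return dists


@dataclass
class StabilityResult:
    statistic: float
    pvalue: float
    stable: bool
    n_control: int
    n_test: int


def compare_stability(dist_rep_vs_rep: np.ndarray, dist_t0_vs_t1: np.ndarray,
                      alpha: float = 0.05) -> StabilityResult:
    """KS comparison of nearest-peak distance distributions.

    The control sample is replicate-vs-replicate at one time point; the test
    sample compares time points. 'stable' when the distributions are not
    distinguishable at level ``alpha``.
    """
    a = np.asarray(dist_rep_vs_rep, dtype=float)
    b = np.asarray(dist_t0_vs_t1, dtype=float)
    if len(a) < 50 or len(b) < 50:
        raise ValueError("need at least 50 distances per sample")
    res = ks_2samp(a, b)
    return StabilityResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                           stable=bool(res.pvalue > alpha),
                           n_control=len(a), n_test=len(b))
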