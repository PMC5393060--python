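"""Accessibility (MACC) and occupancy scoring from titration fragment sets.

The accessibility score of a bin is minus the GC-detrended ordinary
least-squares slope of its library-normalized fragment frequency across the
four digestion levels: material that shifts toward low digestion levels
(negative raw slope) marks accessible chromatin and scores positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .io_filtering import normalize_to_library
from .tracks import BinnedTrack, FragmentSet, PerBpTrack, _check_grid

__all__ = [
    "TitrationSeries",
    "MaccTrack",
    "OccupancyTrack",
    "bin_frequencies",
    "fit_titration_slope",
    "gc_correct",
    "compute_occupancy",
    "pooled_occupancy",
    "coverage_track",
    "summarize_atac",
    "scale_metric",
    "scale_track",
]

log = logging.getLogger(__name__)

OCCUPANCY_MODES = ("raw", "chip_over_input", "input_subtracted", "pooled")


@dataclass
class TitrationSeries:
    """Four library-normalized binned frequency tracks at increasing MNase levels."""

    tracks: List[BinnedTrack]
    levels: Sequence[float] = (1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if len(self.tracks) != len(self.levels):
            raise ValueError("one track per titration level required")
        if len(self.tracks) < 2:
            raise ValueError("need at least two titration levels")
        for t in self.tracks[1:]:
            _check_grid(self.tracks[0], t)

    @property
    def bin_size(self) -> int:
        return self.tracks[0].bin_size

    def stacked(self, chrom: str) -> np.ndarray:
        """(n_levels, n_bins) frequency matrix for one chromosome."""
        return np.vstack([t.data[chrom] for t in self.tracks])


@dataclass
class MaccTrack:
    """Per-bin accessibility score plus the GC fractions used for correction."""

    scores: BinnedTrack
    gc: BinnedTrack
    sign_flipped: bool = True

    def flatten(self, full_bins_only: bool = False) -> np.ndarray:
        return self.scores.flatten(full_bins_only=full_bins_only)


@dataclass
class OccupancyTrack:
    values: object  # BinnedTrack or PerBpTrack
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in OCCUPANCY_MODES:
            raise ValueError(f"mode must be one of {OCCUPANCY_MODES}")

    def flatten(self, **kw) -> np.ndarray:
        return self.values.flatten(**kw)


def bin_frequencies(fs: FragmentSet, bin_size: int = 200,
                    chrom_lengths: Optional[Dict[str, int]] = None,
                    normalize: bool = True,
                    library_size: Optional[int] = None) -> BinnedTrack:
    """Fragment frequency per non-overlapping bin, in CPM.

    Each fragment is assigned to exactly one bin by its midpoint (half-open
    grid, midpoint on a boundary goes to the right bin).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chrom_lengths = chrom_lengths or fs.chrom_lengths
    if chrom_lengths is None:
        raise ValueError("chromosome lengths required (on FragmentSet or as argument)")
    track = BinnedTrack.zeros(bin_size, chrom_lengths)
    for chrom, sub in fs.by_chrom():
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        idx = mids // bin_size
        np.add.at(track.data[chrom], idx, 1.0)
    if normalize:
        lib = library_size if library_size is not None else fs.library_size
        for chrom in track.data:
            track.data[chrom] = normalize_to_library(track.data[chrom], lib)
    return track


def fit_titration_slope(series: TitrationSeries) -> BinnedTrack:
    """Per-bin OLS slope of frequency against titration level.

    With the default equally spaced level indices (1, 2, 3, 4) this equals
    (-3 f1 - f2 + f3 + 3 f4) / 10. Bins with a missing (NaN) frequency at any
    level are NaN in the output.
    """
    x = np.asarray(series.levels, dtype=float)
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    out = {}
    for chrom in series.tracks[0].data:
        f = series.stacked(chrom)
        out[chrom] = (xc[:, None] * (f - f.mean(axis=0))).sum(axis=0) / denom
    return BinnedTrack(bin_size=series.bin_size, data=out,
                       chrom_lengths=dict(series.tracks[0].chrom_lengths))


def _lowess_trend(slopes: np.ndarray, gc: np.ndarray, span: float) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    delta = 0.01 * (gc.max() - gc.min())
    return lowess(slopes, gc, frac=span, it=1, delta=delta, return_sorted=False)


def gc_correct(slopes: BinnedTrack, gc: BinnedTrack, span: float = 0.3,
               sign_flip: bool = True) -> MaccTrack:
    """Remove the GC-dependent trend from raw titration slopes.

    A locally weighted linear smoother estimates the conditional mean of the
    slope given bin GC fraction over all valid bins; the corrected value is
    the residual, negated (by default) so that accessible bins score positive.
    Falls back to a global linear trend when fewer than 100 bins are available.
    """
    _check_grid(slopes, gc)
    flat_s = slopes.flatten()
    flat_g = gc.flatten()
    valid = np.isfinite(flat_s) & np.isfinite(flat_g)
    if not np.any(valid):
        raise ValueError("no valid bins to correct")
    if np.any((flat_g[valid] < 0) | (flat_g[valid] > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")
    s, g = flat_s[valid], flat_g[valid]
    if valid.sum() < 100:
        warnings.warn("fewer than 100 bins; using a linear GC trend")
        if np.ptp(g) == 0:
            trend = np.full_like(s, s.mean())
        else:
            coef = np.polyfit(g, s, 1)
            trend = np.polyval(coef, g)
    elif np.ptp(g) == 0:
        trend = np.full_like(s, s.mean())
    else:
        trend = _lowess_trend(s, g, span)
    corrected = np.full_like(flat_s, np.nan)
    corrected[valid] = s - trend
    if sign_flip:
        corrected = -corrected

    out = BinnedTrack.zeros(slopes.bin_size, slopes.chrom_lengths)
    pos = 0
    for chrom in sorted(slopes.data):
        n = len(slopes.data[chrom])
        out.data[chrom] = corrected[pos:pos + n]
        pos += n
    return MaccTrack(scores=out, gc=gc, sign_flipped=sign_flip)


def compute_occupancy(series: TitrationSeries, mode: str = "raw",
                      input_series: Optional[TitrationSeries] = None) -> OccupancyTrack:
    """Titration-averaged frequency, optionally input-corrected.

    raw: mean(f1..f4); chip_over_input: mean(f)/mean(input); input_subtracted:
    mean(f) - mean(input). Bins with zero input under chip_over_input are NaN.
    """
    if mode not in ("raw", "chip_over_input", "input_subtracted"):
        raise ValueError(f"unknown occupancy mode {mode!r}")
    if mode != "raw" and input_series is None:
        raise ValueError(f"mode {mode!r} requires an input series")
    mean = {c: series.stacked(c).mean(axis=0) for c in series.tracks[0].data}
    if mode == "raw":
        data = mean
    else:
        _check_grid(series.tracks[0], input_series.tracks[0])
        imean = {c: input_series.stacked(c).mean(axis=0)
                 for c in input_series.tracks[0].data}
        data = {}
        n_undefined = 0
        for c in mean:
            if mode == "chip_over_input":
                with np.errstate(divide="ignore", invalid="ignore"):
                    v = np.where(imean[c] > 0, mean[c] / np.where(imean[c] > 0,
                                                                  imean[c], 1.0), np.nan)
                n_undefined += int((imean[c] <= 0).sum())
                data[c] = v
            else:
                data[c] = mean[c] - imean[c]
        if mode == "chip_over_input" and n_undefined:
            log.warning("chip_over_input undefined in %d zero-input bins", n_undefined)
    track = BinnedTrack(bin_size=series.bin_size, data=data,
                        chrom_lengths=dict(series.tracks[0].chrom_lengths))
    return OccupancyTrack(values=track, mode=mode)


def coverage_track(fs: FragmentSet,
                   chrom_lengths: Optional[Dict[str, int]] = None,
                   normalize: bool = True) -> PerBpTrack:
    """Library-normalized number of fragments spanning each genomic location."""
    chrom_lengths = chrom_lengths or fs.chrom_lengths
    if chrom_lengths is None:
        raise ValueError("chromosome lengths required")
    scale = 1e6 / fs.library_size if (normalize and fs.library_size > 0) else 1.0
    data = {c: np.zeros(l) for c, l in chrom_lengths.items()}
    for chrom, sub in fs.by_chrom():
        # integer count accumulation avoids negative float round-off
        diff = np.zeros(chrom_lengths[chrom] + 1, dtype=np.int64)
        np.add.at(diff, sub["start"].to_numpy(), 1)
        np.add.at(diff, sub["end"].to_numpy(), -1)
        data[chrom] = np.cumsum(diff[:-1]).astype(float) * scale
    return PerBpTrack(data=data, chrom_lengths=dict(chrom_lengths))


def pooled_occupancy(pooled_fs: FragmentSet,
                     chrom_lengths: Optional[Dict[str, int]] = None) -> OccupancyTrack:
    """Traditional occupancy from a pooled-digest library (per-bp coverage)."""
    return OccupancyTrack(values=coverage_track(pooled_fs, chrom_lengths),
                          mode="pooled")


def summarize_atac(fs: FragmentSet, bin_size: int = 200,
                   chrom_lengths: Optional[Dict[str, int]] = None) -> BinnedTrack:
    """ATAC signal summarized on the same bin grid as the titration data."""
    return bin_frequencies(fs, bin_size=bin_size, chrom_lengths=chrom_lengths)


def scale_metric(values, n_groups: int = 20) -> np.ndarray:
    """Scale so the medians of the lowest and highest quantile groups map to 0 and 1.

    Values are split by rank into ``n_groups`` equal-count groups; with
    m_lo/m_hi the medians of the extreme groups, v -> (v - m_lo)/(m_hi - m_lo).
    Values beyond the extreme-group medians are NOT clipped. NaNs pass through.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    vals = v[finite]
    if len(vals) < n_groups:
        raise ValueError(f"need at least {n_groups} finite values")
    order = np.argsort(vals, kind="stable")
    group = (np.arange(len(vals)) * n_groups) // len(vals)
    sorted_vals = vals[order]
    m_lo = float(np.median(sorted_vals[group == 0]))
    m_hi = float(np.median(sorted_vals[group == n_groups - 1]))
    if m_hi == m_lo:
        raise ValueError("degenerate distribution: extreme group medians equal")
    out = np.full_like(v, np.nan)
    out[finite] = (vals - m_lo) / (m_hi - m_lo)
    return out


def scale_track(track: BinnedTrack, n_groups: int = 20) -> BinnedTrack:
    """scale_metric applied to a BinnedTrack with genome-wide quantile groups.

    Partial terminal bins are excluded from the quantile-group computation but
    are transformed with the same affine map.
    """
    ref = track.flatten(full_bins_only=True)
    finite = ref[np.isfinite(ref)]
    if len(finite) < n_groups:
        raise ValueError(f"need at least {n_groups} finite values")
    order = np.argsort(finite, kind="stable")
    group = (np.arange(len(finite)) * n_groups) // len(finite)
    sv = finite[order]
    m_lo = float(np.median(sv[group == 0]))
    m_hi = float(np.median(sv[group == n_groups - 1]))
    if m_hi == m_lo:
        raise ValueError("degenerate distribution: extreme group medians equal")
    return track.map(lambda v: (v - m_lo) / (m_hi - m_lo))
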