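"""TSS-distal H3K27ac enhancer identification and time-course classification.

Enrichment uses a Poisson window Z-score of ChIP counts against the
library-scaled input expectation in fixed 200-bp windows (a documented
stand-in for a full cross-correlation peak model). Windows with Z above
threshold are merged when closer than a join gap, intersected across
replicates, purged of promoter-proximal calls, and classified from their
per-time-point ChIP/input folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .macc import bin_frequencies
from .tracks import FragmentSet

__all__ = [
    "EnhancerSet",
    "window_enrichment",
    "call_enriched_regions",
    "replicate_consistent",
    "exclude_promoter_proximal",
    "classify_enhancers",
    "region_fold",
]

ENHANCER_CLASSES = ("up_regulated", "constitutive_high", "other")


@dataclass
class EnhancerSet:
    regions: pd.DataFrame  # chrom, start, end, class, fold_0h/1h/4h
    params: Dict[str, object] = field(default_factory=dict)

    def to_bed(self, path) -> None:
        out = self.regions.copy()
        out["score"] = 0
        out["strand"] = "."
        out[["chrom", "start", "end", "class", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False)


def window_enrichment(chip_fs: FragmentSet, input_fs: FragmentSet,
                      window: int = 200,
                      chrom_lengths: Optional[Dict[str, int]] = None) -> pd.DataFrame:
    """Per-window ChIP enrichment against library-scaled input.

    Columns: chrom, start, end, chip, input, expected, z, fold, input_floored.
    z = (chip - e)/sqrt(e) with e = input * chip_lib/input_lib; zero-input
    windows get e floored at the genome-mean input count and are flagged.
    """
    if chip_fs.library_size == 0 or input_fs.library_size == 0:
        raise ValueError("both ChIP and input fragment sets must be non-empty")
    chrom_lengths = chrom_lengths or chip_fs.chrom_lengths or input_fs.chrom_lengths
    chip = bin_frequencies(chip_fs, bin_size=window, chrom_lengths=chrom_lengths,
                           normalize=False)
    inp = bin_frequencies(input_fs, bin_size=window, chrom_lengths=chrom_lengths,
                          normalize=False)
    ratio = chip_fs.library_size / input_fs.library_size
    inp_flat = inp.flatten()
    mean_input = inp_flat[inp_flat >= 0].mean()

    rows = []
    for chrom in sorted(chip.data):
        c = chip.data[chrom]
        i = inp.data[chrom]
        floored = i <= 0
        e = np.where(floored, max(mean_input, 1e-9), i) * ratio
        z = (c - e) / np.sqrt(e)
        cpm_c = c * 1e6 / chip_fs.library_size
        cpm_i = np.where(floored, max(mean_input, 1e-9), i) * 1e6 / input_fs.library_size
        fold = cpm_c / cpm_i
        starts = np.arange(len(c)) * window
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + window, chrom_lengths[chrom]),
            "chip": c, "input": i, "expected": e, "z": z, "fold": fold,
            "input_floored": floored,
        }))
    return pd.concat(rows, ignore_index=True)


def call_enriched_regions(windows: pd.DataFrame, z_thresh: float = 10.0,
                          join_gap: int = 150) -> pd.DataFrame:
    """Merge above-threshold windows separated by less than ``join_gap`` bp."""
    sel = windows[windows["z"] > z_thresh].sort_values(["chrom", "start"])
    out: List[Tuple[str, int, int]] = []
    for chrom, sub in sel.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s - cur_e < join_gap:  # strictly closer than the gap are joined
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def replicate_consistent(regions_rep1: pd.DataFrame,
                         regions_rep2: pd.DataFrame) -> pd.DataFrame:
    """Keep regions supported by both replicates; coordinates = intersection."""
    out = []
    for chrom, sub1 in regions_rep1.groupby("chrom", sort=True):
        sub2 = regions_rep2[regions_rep2["chrom"] == chrom]
        if sub2.empty:
            continue
        s2 = sub2.sort_values("start")
        for _, r in sub1.sort_values("start").iterrows():
            ov = s2[(s2["end"] > r.start) & (s2["start"] < r.end)]
            for _, q in ov.iterrows():
                out.append((chrom, max(r.start, q.start), min(r.end, q.end)))
    df = pd.DataFrame(out, columns=["chrom", "start", "end"])
    return df.drop_duplicates().sort_values(["chrom", "start"]).reset_index(drop=True)


def exclude_promoter_proximal(regions: pd.DataFrame, genes: pd.DataFrame,
                              upstream: int = 1000,
                              downstream: int = 500) -> pd.DataFrame:
    """Drop regions overlapping [TSS - upstream, TSS + downstream] in
    transcription orientation of any gene."""
    zones: Dict[str, List[Tuple[int, int]]] = {}
    for _, g in genes.iterrows():
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        else:
            lo, hi = g.tss - downstream, g.tss + upstream
        zones.setdefault(g.chrom, []).append((lo, hi))
    keep = []
    for _, r in regions.iterrows():
        bad = any(r.start <= hi and r.end > lo
                  for lo, hi in zones.get(r.chrom, []))
        keep.append(not bad)
    return regions[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def region_fold(regions: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """ChIP/input fold per region from summed window counts (CPM ratio).

    Summing counts before taking the ratio is less noisy than averaging
    per-window folds; zero input sums fall back to the genome-mean input.
    """
    folds = np.full(len(regions), np.nan)
    mean_input = max(float(windows["input"].mean()), 1e-9)
    lib_ratio = windows["input"].sum() / max(windows["chip"].sum(), 1e-9)
    for i, (_, r) in enumerate(regions.iterrows()):
        sub = windows[(windows["chrom"] == r.chrom)
                      & (windows["end"] > r.start) & (windows["start"] < r.end)]
        if len(sub):
            chip = sub["chip"].sum()
            inp = sub["input"].sum()
            if inp <= 0:
                inp = mean_input * len(sub)
            folds[i] = (chip / inp) * lib_ratio
    return folds


def classify_enhancers(regions: pd.DataFrame,
                       folds_by_time: Dict[int, np.ndarray],
                       significant: Optional[Dict[str, np.ndarray]] = None,
                       variant: str = "methods") -> EnhancerSet:
    """Classify enhancers from their H3K27ac enrichment time course.

    up_regulated: at least twofold significant increase over 0-1 h and 0-4 h
    (variant='methods'; variant='results' tests 0-1 h and 1-4 h instead).
    constitutive_high: no significant twofold change in either direction, but
    enrichment above fourfold at all three time points. Everything else: other.
    ``significant`` optionally carries boolean per-region flags for the two
    tested intervals (keys 'first', 'second'); absent flags default to True
    (fold change alone decides).
    """
    for t in (0, 1, 4):
        if t not in folds_by_time:
            raise ValueError(f"missing fold values for time point {t}")
    f0 = np.asarray(folds_by_time[0], dtype=float)
    f1 = np.asarray(folds_by_time[1], dtype=float)
    f4 = np.asarray(folds_by_time[4], dtype=float)
    if variant == "methods":
        r_first, r_second = f1 / f0, f4 / f0
    elif variant == "results":
        r_first, r_second = f1 / f0, f4 / f1
    else:
        raise ValueError(f"unknown variant {variant!r}")
    n = len(f0)
    sig_first = np.ones(n, bool) if significant is None else np.asarray(significant["first"])
    sig_second = np.ones(n, bool) if significant is None else np.asarray(significant["second"])

    up = (r_first >= 2.0) & (r_second >= 2.0) & sig_first & sig_second
    down = (r_first <= 0.5) & (r_second <= 0.5) & sig_first & sig_second
    twofold_change = up | down
    constitutive = (~twofold_change) & (f0 > 4.0) & (f1 > 4.0) & (f4 > 4.0)

    labels = np.where(up, "up_regulated",
                      np.where(constitutive, "constitutive_high", "other"))
    out = regions.copy().reset_index(drop=True)
    out["class"] = labels
    out["fold_0h"], out["fold_1h"], out["fold_4h"] = f0, f1, f4
    return EnhancerSet(regions=out, params=dict(variant=variant))
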