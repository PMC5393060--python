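"""Fragment-file parsing, read-level filters and library normalization.

Filters applied, in pipeline order:

1. insert-size filter — fragments with length < ``min_len`` or > ``max_len``
   are removed (bounds themselves are retained);
2. anomalous-position mask — genome-wide per-position tag counts at fragment
   5' starts are converted to Z-scores over positions with at least one tag,
   and fragments starting at positions with Z above the threshold (default 7)
   are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .tracks import FragmentSet

__all__ = [
    "read_fragments",
    "filter_by_insert",
    "mask_anomalous_positions",
    "normalize_to_library",
    "apply_standard_filters",
    "FilterReport",
]

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    input_fragments: int = 0
    removed_by_insert: int = 0
    removed_by_anomaly: int = 0
    anomalous_positions: int = 0
    retained: int = 0
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("input_fragments", self.input_fragments),
                ("removed_by_insert", self.removed_by_insert),
                ("removed_by_anomaly", self.removed_by_anomaly),
                ("anomalous_positions", self.anomalous_positions),
                ("retained", self.retained),
            ],
            columns=["rule", "count"],
        )


class FragmentParseError(ValueError):
    pass


def _read_bed(path, chrom_lengths: Optional[Dict[str, int]]) -> pd.DataFrame:
    rows = {"chrom": [], "start": [], "end": []}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FragmentParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FragmentParseError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise FragmentParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})")
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise FragmentParseError(
                        f"{path}:{lineno}: chromosome {chrom!r} absent from genome")
                if end > chrom_lengths[chrom]:
                    raise FragmentParseError(
                        f"{path}:{lineno}: interval end {end} beyond "
                        f"{chrom} length {chrom_lengths[chrom]}")
            rows["chrom"].append(chrom)
            rows["start"].append(start)
            rows["end"].append(end)
    return pd.DataFrame({"chrom": rows["chrom"],
                         "start": np.asarray(rows["start"], dtype=np.int64),
                         "end": np.asarray(rows["end"], dtype=np.int64)})


def _read_bam(path, chrom_lengths: Optional[Dict[str, int]]) -> pd.DataFrame:
    import pysam

    rows = {"chrom": [], "start": [], "end": []}
    with pysam.AlignmentFile(str(path)) as bam:  # auto-detects SAM/BAM
        for rec in bam:
            if (rec.is_unmapped or rec.mate_is_unmapped or not rec.is_proper_pair
                    or rec.is_secondary or rec.is_supplementary or not rec.is_read1):
                continue
            tlen = rec.template_length
            if tlen == 0:
                continue
            start = rec.reference_start if tlen > 0 else rec.next_reference_start
            end = start + abs(tlen)
            chrom = rec.reference_name
            if chrom_lengths is not None and chrom not in chrom_lengths:
                raise FragmentParseError(
                    f"{path}: chromosome {chrom!r} absent from genome")
            rows["chrom"].append(chrom)
            rows["start"].append(start)
            rows["end"].append(end)
    return pd.DataFrame({"chrom": rows["chrom"],
                         "start": np.asarray(rows["start"], dtype=np.int64),
                         "end": np.asarray(rows["end"], dtype=np.int64)})


def read_fragments(path, format: str = "bed",
                   chrom_lengths: Optional[Dict[str, int]] = None,
                   metadata: Optional[dict] = None) -> FragmentSet:
    """Read paired-end fragments from a BED3+ file or a paired BAM.

    One fragment per template, coordinates 0-based half-open.
    """
    fmt = format.lower()
    if fmt == "bed":
        df = _read_bed(path, chrom_lengths)
    elif fmt == "bam":
        df = _read_bam(path, chrom_lengths)
    else:
        raise ValueError(f"unknown fragment format {format!r}")
    return FragmentSet(fragments=df, metadata=dict(metadata or {}),
                       chrom_lengths=chrom_lengths)


def filter_by_insert(fs: FragmentSet, min_len: int = 50, max_len: int = 500,
                     report: Optional[FilterReport] = None) -> FragmentSet:
    """Keep fragments with min_len <= insert length <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    lengths = fs.lengths
    keep = (lengths >= min_len) & (lengths <= max_len)
    if report is not None:
        report.removed_by_insert += int((~keep).sum())
    return fs.replace(fs.fragments[keep])


def mask_anomalous_positions(fs: FragmentSet, z_thresh: float = 7.0,
                             report: Optional[FilterReport] = None) -> FragmentSet:
    """Drop fragments starting at positions with anomalously high tag counts.

    The Z statistic is computed genome-wide over positions carrying at least
    one tag (zero-count positions excluded; including them would make Z scale
    with genome size rather than with pileup pathology).
    """
    if len(fs.fragments) == 0 or math.isinf(z_thresh):
        return fs
    key = fs.fragments["chrom"].astype(str) + ":" + fs.fragments["start"].astype(str)
    counts = key.value_counts()
    mean = counts.mean()
    sd = counts.std(ddof=0)
    if sd == 0:
        log.info("all per-position counts equal (sd=0); no anomalous positions")
        if report is not None:
            report.notes.append("anomaly filter skipped: sd of position counts is 0")
        return fs
    z = (counts - mean) / sd
    bad = set(z.index[z > z_thresh])
    if not bad:
        return fs
    keep = ~key.isin(bad)
    if report is not None:
        report.removed_by_anomaly += int((~keep).sum())
        report.anomalous_positions += len(bad)
    return fs.replace(fs.fragments[keep.to_numpy()])


def normalize_to_library(counts, library_size: int) -> np.ndarray:
    """Counts per million retained fragments."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.asarray(counts, dtype=float) * (1e6 / library_size)


def apply_standard_filters(fs: FragmentSet, min_len: int = 50, max_len: int = 500,
                           z_thresh: float = 7.0) -> tuple:
    """Insert filter then anomalous-position mask; returns (FragmentSet, report)."""
    report = FilterReport(input_fragments=len(fs.fragments))
    out = filter_by_insert(fs, min_len=min_len, max_len=max_len, report=report)
    out = mask_anomalous_positions(out, z_thresh=z_thresh, report=report)
    report.retained = len(out.fragments)
    return out, report
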