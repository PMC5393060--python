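"""Plain-text track and table readers shared by the CLI."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .tracks import BinnedTrack

__all__ = ["read_bedgraph", "read_gene_table", "read_regions_bed"]


def read_bedgraph(path, bin_size: Optional[int] = None,
                  chrom_lengths: Optional[Dict[str, int]] = None) -> BinnedTrack:
    """Read a fixed-grid bedGraph written by this package back into a track."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     comment="#", dtype={"chrom": str})
    if df.empty:
        raise ValueError(f"{path}: empty bedGraph")
    if bin_size is None:
        bin_size = int((df["end"] - df["start"]).mode().iloc[0])
    if chrom_lengths is None:
        chrom_lengths = df.groupby("chrom")["end"].max().to_dict()
    data = {}
    for chrom, sub in df.groupby("chrom"):
        n_bins = -(-chrom_lengths[chrom] // bin_size)
        v = np.full(n_bins, np.nan)
        idx = sub["start"].to_numpy() // bin_size
        v[idx] = sub["value"].to_numpy(dtype=float)
        data[chrom] = v
    for chrom, length in chrom_lengths.items():
        data.setdefault(chrom, np.full(-(-length // bin_size), np.nan))
    return BinnedTrack(bin_size=bin_size, data=data, chrom_lengths=dict(chrom_lengths))


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "chrom", "tss", "tts", "strand"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    return df


def read_regions_bed(path) -> List[Tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(str(r[0]), int(r[1]), int(r[2])) for r in df.itertuples(index=False)]
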