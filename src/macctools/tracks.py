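"""Genomic containers: genomes, fragment sets and fixed-grid binned tracks."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["Genome", "FragmentSet", "BinnedTrack", "PerBpTrack"]

_GC_BYTES = frozenset(b"GCgc")


@dataclass
class Genome:
    """A small in-memory genome: chromosome name -> sequence string."""

    sequences: Dict[str, str]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def gc_fraction(self, chrom: str, start: int, end: int) -> float:
        seq = self.sequences[chrom][max(start, 0):end]
        if not seq:
            return float("nan")
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        gc = np.isin(arr, np.frombuffer(b"GCgc", dtype=np.uint8)).sum()
        return float(gc) / len(seq)

    def gc_track(self, bin_size: int) -> "BinnedTrack":
        """Per-bin GC fraction on the fixed analysis grid."""
        data = {}
        for chrom, seq in self.sequences.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_gc = np.isin(arr, np.frombuffer(b"GCgc", dtype=np.uint8)).astype(np.float64)
            n_bins = -(-len(arr) // bin_size)
            gc = np.empty(n_bins)
            for i in range(n_bins):
                chunk = is_gc[i * bin_size:(i + 1) * bin_size]
                gc[i] = chunk.mean()
            data[chrom] = gc
        return BinnedTrack(bin_size=bin_size, data=data, chrom_lengths=self.chrom_lengths)

    def write_fasta(self, path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i:i + line_width] + "\n")

    @classmethod
    def read_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls(sequences={name: str(fa[name][:]) for name in fa.keys()})


@dataclass
class FragmentSet:
    """Paired-end fragments with sample metadata.

    ``fragments`` holds 0-based half-open coordinates in columns
    (chrom, start, end); ``library_size`` is the retained fragment count
    used as the normalization denominator.
    """

    fragments: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)
    chrom_lengths: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.fragments.columns):
            raise ValueError(f"fragment table needs columns {sorted(required)}")

    @property
    def library_size(self) -> int:
        return len(self.fragments)

    @property
    def lengths(self) -> np.ndarray:
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        f = self.fragments
        return ((f["start"].to_numpy() + f["end"].to_numpy()) // 2)

    def replace(self, fragments: pd.DataFrame) -> "FragmentSet":
        return dataclasses.replace(self, fragments=fragments.reset_index(drop=True))

    def by_chrom(self) -> Iterator[tuple]:
        for chrom, sub in self.fragments.groupby("chrom", sort=True):
            yield chrom, sub

    def write_bed(self, path) -> None:
        """6-column BED: chrom, start, end, name, score(level), strand('.')."""
        f = self.fragments
        level = self.metadata.get("titration_level", 0)
        out = pd.DataFrame(
            {
                "chrom": f["chrom"],
                "start": f["start"],
                "end": f["end"],
                "name": [f"frag{i}" for i in range(len(f))],
                "score": level,
                "strand": ".",
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def _check_grid(a: "BinnedTrack", b: "BinnedTrack") -> None:
    if a.bin_size != b.bin_size or set(a.data) != set(b.data):
        raise ValueError("tracks are on different grids")
    for c in a.data:
        if a.data[c].shape != b.data[c].shape:
            raise ValueError(f"tracks differ in bin count on {c}")


@dataclass
class BinnedTrack:
    """Per-chromosome values on a fixed grid of ``bin_size`` bp starting at 0.

    The last bin of a chromosome may be partial; it is retained in ``data``
    and flagged via :meth:`partial_last_bin` so genome-wide summaries can
    exclude it.
    """

    bin_size: int
    data: Dict[str, np.ndarray]
    chrom_lengths: Dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.chrom_lengths.items():
            n_bins = -(-length // self.bin_size)
            if chrom in self.data and len(self.data[chrom]) != n_bins:
                raise ValueError(f"{chrom}: expected {n_bins} bins, got {len(self.data[chrom])}")

    @classmethod
    def zeros(cls, bin_size: int, chrom_lengths: Mapping[str, int]) -> "BinnedTrack":
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        data = {c: np.zeros(-(-l // bin_size)) for c, l in chrom_lengths.items()}
        return cls(bin_size=bin_size, data=data, chrom_lengths=dict(chrom_lengths))

    def partial_last_bin(self, chrom: str) -> bool:
        return self.chrom_lengths[chrom] % self.bin_size != 0

    def full_bin_mask(self, chrom: str) -> np.ndarray:
        """Boolean mask of complete (non-partial) bins."""
        mask = np.ones(len(self.data[chrom]), dtype=bool)
        if self.partial_last_bin(chrom):
            mask[-1] = False
        return mask

    def flatten(self, full_bins_only: bool = False) -> np.ndarray:
        parts = []
        for chrom in sorted(self.data):
            v = self.data[chrom]
            parts.append(v[self.full_bin_mask(chrom)] if full_bins_only else v)
        return np.concatenate(parts) if parts else np.array([])

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.data[chrom][pos // self.bin_size])

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        idx = np.asarray(positions) // self.bin_size
        return self.data[chrom][idx]

    def map(self, func) -> "BinnedTrack":
        return BinnedTrack(
            bin_size=self.bin_size,
            data={c: func(v) for c, v in self.data.items()},
            chrom_lengths=dict(self.chrom_lengths),
        )

    def binop(self, other: "BinnedTrack", func) -> "BinnedTrack":
        _check_grid(self, other)
        return BinnedTrack(
            bin_size=self.bin_size,
            data={c: func(self.data[c], other.data[c]) for c in self.data},
            chrom_lengths=dict(self.chrom_lengths),
        )

    def write_bedgraph(self, path, precision: int = 6) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                vals = self.data[chrom]
                length = self.chrom_lengths[chrom]
                for i, v in enumerate(vals):
                    start = i * self.bin_size
                    end = min(start + self.bin_size, length)
                    fh.write(f"{chrom}\t{start}\t{end}\t{v:.{precision}g}\n")


@dataclass
class PerBpTrack:
    """Per-base-pair track (used for coverage / pooled occupancy)."""

    data: Dict[str, np.ndarray]
    chrom_lengths: Dict[str, int]

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in sorted(self.data)])

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.data[chrom][pos])

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        return self.data[chrom][np.asarray(positions)]
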