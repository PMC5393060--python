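"""Synthetic MNase-titration data with planted ground truth.

Generates a small genome with a smoothly varying GC landscape, a nucleosome
lattice with known per-nucleosome occupancy and accessibility, genes and
TSS-distal enhancers with time-course effects, and samples fragment sets for
the titration, ChIP, and ATAC assays the pipeline consumes.

The release model is the core of the forward simulation: a nucleosome with
accessibility ``a`` distributes its released material over the four digestion
levels according to a unimodal kernel centred at ``mu(a) = 2.5 - 1.5 a``,
normalized so that the TOTAL release across levels is independent of ``a``
(accessibility redistributes signal across the titration; it does not create
or destroy it). Highly accessible nucleosomes (a = +1) therefore give
monotonically decreasing counts over levels 1..4 and inaccessible ones
(a = -1) monotonically increasing counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .tracks import BinnedTrack, FragmentSet, Genome

__all__ = [
    "SyntheticGenomeSpec",
    "NucleosomeTruth",
    "TimeCourseEffect",
    "SyntheticTruth",
    "PlacementError",
    "build_genome",
    "release_profile",
    "simulate_titration_fragments",
    "simulate_chip_pair",
    "simulate_atac",
    "simulate_expression_table",
    "write_truth",
]

TIME_POINTS = (0, 1, 4)
GENE_CLASSES = ("up_access_only", "up_access_and_occ_loss", "down", "unchanged")
ENHANCER_CLASSES = ("enhancer_up", "enhancer_constitutive")

#: labelled MNase amounts (units) for run metadata; the regression itself
#: uses level indices 1..4, so only the first and last labels matter outside
#: bookkeeping.
MNASE_UNIT_LABELS = (1.5, 6.25, 25.0, 100.0)


class PlacementError(ValueError):
    """Raised when genes/enhancers cannot be placed with required spacing."""


@dataclass
class SyntheticGenomeSpec:
    chrom_lengths: Dict[str, int]
    gc_mean: float = 0.5
    gc_amplitude: float = 0.15
    gc_wavelength: float = 50_000.0
    n_genes: int = 0
    n_enhancers: int = 0
    nucleosome_spacing: int = 180
    seed: int = 0
    # latent-state distribution (defaults give a flat, fully neutral genome)
    accessibility_mean: float = 0.0
    accessibility_sd: float = 0.0
    occupancy_alpha: float = 6.0
    occupancy_beta: float = 2.0
    gene_class_fractions: Dict[str, float] = field(
        default_factory=lambda: {"up_access_only": 0.25, "down": 0.25, "unchanged": 0.5}
    )

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be positive")
        lo = self.gc_mean - self.gc_amplitude
        hi = self.gc_mean + self.gc_amplitude
        if lo < 0.2 or hi > 0.8:
            raise ValueError("GC profile must stay within [0.2, 0.8]")
        unknown = set(self.gene_class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")


@dataclass
class NucleosomeTruth:
    chrom: str
    dyad: int
    occupancy: float
    accessibility: float


@dataclass
class TimeCourseEffect:
    """A planted regional change over the time course."""

    chrom: str
    start: int
    end: int
    class_label: str
    d_accessibility: Dict[int, float] = field(default_factory=dict)
    d_occupancy: Dict[int, float] = field(default_factory=dict)
    expression_log2fc: Tuple[float, float] = (0.0, 0.0)  # (0->1 h, 1->4 h)
    h3k27ac_fold: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_label == "up_access_only" and any(
            v != 0 for v in self.d_occupancy.values()
        ):
            raise ValueError("up_access_only effects must not change occupancy")


@dataclass
class SyntheticTruth:
    """Planted ground truth plus the generating genome."""

    spec: SyntheticGenomeSpec
    genome: Genome
    nucleosomes: pd.DataFrame  # chrom, dyad, occupancy, accessibility, gc
    genes: pd.DataFrame
    enhancers: pd.DataFrame
    effects: List[TimeCourseEffect]
    bin_size: int = 200

    def nucleosome_state(self, time_point: int) -> Tuple[np.ndarray, np.ndarray]:
        """(occupancy, accessibility) per nucleosome at a time point."""
        if time_point not in TIME_POINTS:
            raise ValueError(f"time_point must be one of {TIME_POINTS}")
        occ = self.nucleosomes["occupancy"].to_numpy().copy()
        acc = self.nucleosomes["accessibility"].to_numpy().copy()
        chroms = self.nucleosomes["chrom"].to_numpy()
        dyads = self.nucleosomes["dyad"].to_numpy()
        for eff in self.effects:
            da = eff.d_accessibility.get(time_point, 0.0)
            do = eff.d_occupancy.get(time_point, 0.0)
            if da == 0.0 and do == 0.0:
                continue
            mask = (chroms == eff.chrom) & (dyads >= eff.start) & (dyads < eff.end)
            acc[mask] += da
            occ[mask] += do
        return np.clip(occ, 0.0, 1.0), np.clip(acc, -1.0, 1.0)

    def _bin_index(self) -> Tuple[np.ndarray, Dict[str, slice]]:
        """Flattened bin index of each nucleosome dyad + per-chrom bin slices."""
        offsets = {}
        total = 0
        for chrom in sorted(self.genome.sequences):
            n_bins = -(-self.genome.chrom_lengths[chrom] // self.bin_size)
            offsets[chrom] = slice(total, total + n_bins)
            total += n_bins
        chroms = self.nucleosomes["chrom"].to_numpy()
        dyads = self.nucleosomes["dyad"].to_numpy()
        idx = np.empty(len(dyads), dtype=np.int64)
        for chrom, sl in offsets.items():
            m = chroms == chrom
            idx[m] = sl.start + dyads[m] // self.bin_size
        return idx, offsets

    def _track_from_flat(self, flat: np.ndarray, offsets: Dict[str, slice]) -> BinnedTrack:
        data = {c: flat[sl].copy() for c, sl in offsets.items()}
        return BinnedTrack(bin_size=self.bin_size, data=data,
                           chrom_lengths=self.genome.chrom_lengths)

    def occupancy_track(self, time_point: int = 0) -> BinnedTrack:
        """True per-bin occupancy: summed nucleosome occupancy of dyads in bin."""
        occ, _ = self.nucleosome_state(time_point)
        idx, offsets = self._bin_index()
        n_total = max(sl.stop for sl in offsets.values())
        flat = np.zeros(n_total)
        np.add.at(flat, idx, occ)
        return self._track_from_flat(flat, offsets)

    def accessibility_track(self, time_point: int = 0) -> BinnedTrack:
        """True per-bin accessibility: occupancy-weighted mean over dyads in bin.

        Bins without a dyad are NaN.
        """
        occ, acc = self.nucleosome_state(time_point)
        idx, offsets = self._bin_index()
        n_total = max(sl.stop for sl in offsets.values())
        wsum = np.zeros(n_total)
        vsum = np.zeros(n_total)
        np.add.at(wsum, idx, occ)
        np.add.at(vsum, idx, occ * acc)
        with np.errstate(invalid="ignore", divide="ignore"):
            flat = np.where(wsum > 0, vsum / np.maximum(wsum, 1e-300), np.nan)
        return self._track_from_flat(flat, offsets)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _gc_profile(spec: SyntheticGenomeSpec, length: int) -> np.ndarray:
    x = np.arange(length, dtype=np.float64)
    gc = spec.gc_mean + spec.gc_amplitude * np.sin(2 * np.pi * x / spec.gc_wavelength)
    return np.clip(gc, 0.2, 0.8)

_CHUNK = 100  # GC content is matched exactly per 100-bp chunk


def _make_sequence(spec: SyntheticGenomeSpec, length: int, rng: np.random.Generator) -> str:
    gc = _gc_profile(spec, length)
    is_gc = np.zeros(length, dtype=bool)
    n_full = length // _CHUNK
    if n_full:
        chunk_gc = gc[: n_full * _CHUNK].reshape(n_full, _CHUNK).mean(axis=1)
        k = np.rint(chunk_gc * _CHUNK).astype(int)
        keys = rng.random((n_full, _CHUNK))
        order = np.argsort(keys, axis=1)
        ranks = np.argsort(order, axis=1)
        is_gc[: n_full * _CHUNK] = (ranks < k[:, None]).ravel()
    rem = length - n_full * _CHUNK
    if rem:
        tail_gc = gc[n_full * _CHUNK:].mean()
        k_tail = int(round(tail_gc * rem))
        pick = rng.permutation(rem)[:k_tail]
        tail = np.zeros(rem, dtype=bool)
        tail[pick] = True
        is_gc[n_full * _CHUNK:] = tail
    bases = np.where(
        is_gc,
        rng.choice(np.frombuffer(b"GC", dtype=np.uint8), size=length),
        rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=length),
    )
    return bases.tobytes().decode("ascii")


def _place_nucleosomes(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    jitter_max = max(1, spec.nucleosome_spacing // 8)
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        grid = np.arange(100, length - 100, spec.nucleosome_spacing)
        if len(grid) == 0:
            continue
        jitter = rng.integers(-jitter_max, jitter_max + 1, size=len(grid))
        dyads = np.clip(grid + jitter, 73, length - 74)
        # enforce the minimum inter-dyad distance after jitter
        for i in range(1, len(dyads)):
            if dyads[i] - dyads[i - 1] < 120:
                dyads[i] = dyads[i - 1] + 120
        dyads = dyads[dyads <= length - 74]
        occ = rng.beta(spec.occupancy_alpha, spec.occupancy_beta, size=len(dyads))
        if spec.accessibility_sd > 0:
            acc = rng.normal(spec.accessibility_mean, spec.accessibility_sd, size=len(dyads))
        else:
            acc = np.full(len(dyads), float(spec.accessibility_mean))
        acc = np.clip(acc, -1.0, 1.0)
        rows.append(pd.DataFrame({"chrom": chrom, "dyad": dyads,
                                  "occupancy": occ, "accessibility": acc}))
    if not rows:
        raise PlacementError("no chromosome can hold a nucleosome")
    return pd.concat(rows, ignore_index=True)


def _assign_gene_classes(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> List[str]:
    fracs = spec.gene_class_fractions
    labels: List[str] = []
    for cls in GENE_CLASSES:
        labels.extend([cls] * int(round(fracs.get(cls, 0.0) * spec.n_genes)))
    while len(labels) < spec.n_genes:
        labels.append("unchanged")
    labels = labels[: spec.n_genes]
    rng.shuffle(labels)
    return labels


_GENE_EFFECTS = {
    # (d_acc@1h, d_acc@4h, d_occ@1h, d_occ@4h, lfc range 0->1, lfc range 1->4)
    "up_access_only": (0.45, 0.65, 0.0, 0.0, (1.1, 2.2), (0.0, 0.45)),
    "up_access_and_occ_loss": (0.45, 0.65, -0.25, -0.35, (1.1, 2.2), (0.0, 0.45)),
    "down": (-0.30, -0.45, 0.0, 0.0, (-2.2, -1.1), (-0.45, 0.0)),
    "unchanged": (0.0, 0.0, 0.0, 0.0, (-0.12, 0.12), (-0.12, 0.12)),
}

_ENHANCER_FOLDS = {
    "enhancer_up": {0: 1.0, 1: 2.5, 4: 6.0},
    "enhancer_constitutive": {0: 5.0, 1: 5.5, 4: 5.2},
}


def _place_genes(spec: SyntheticGenomeSpec, rng: np.random.Generator
                 ) -> Tuple[pd.DataFrame, List[TimeCourseEffect]]:
    labels = _assign_gene_classes(spec, rng)
    chroms = sorted(spec.chrom_lengths)
    rows, effects = [], []
    ci = 0
    cursor = 2500
    for gi in range(spec.n_genes):
        length = int(rng.integers(2000, 5001))
        gap = int(rng.integers(1800, 3200))
        while ci < len(chroms) and cursor + length + 2500 > spec.chrom_lengths[chroms[ci]]:
            ci += 1
            cursor = 2500
        if ci >= len(chroms):
            raise PlacementError(
                f"cannot place gene {gi + 1}/{spec.n_genes}: genome too small"
            )
        chrom = chroms[ci]
        start, end = cursor, cursor + length
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tts = (start, end) if strand == "+" else (end, start)
        cls = labels[gi]
        da1, da4, do1, do4, lfc01_rng, lfc14_rng = _GENE_EFFECTS[cls]
        lfc01 = float(rng.uniform(*lfc01_rng))
        lfc14 = float(rng.uniform(*lfc14_rng))
        rows.append(dict(gene_id=f"gene{gi:04d}", chrom=chrom, tss=tss, tts=tts,
                         strand=strand, class_label=cls,
                         log2fc_0_1=lfc01, log2fc_1_4=lfc14))
        if cls != "unchanged":
            effects.append(TimeCourseEffect(
                chrom=chrom, start=start - 1000, end=end + 1000, class_label=cls,
                d_accessibility={1: da1, 4: da4},
                d_occupancy={1: do1, 4: do4},
                expression_log2fc=(lfc01, lfc14),
            ))
        cursor = end + gap
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "tts", "strand", "class_label",
                       "log2fc_0_1", "log2fc_1_4"])
    return genes, effects


def _place_enhancers(spec: SyntheticGenomeSpec, genes: pd.DataFrame,
                     rng: np.random.Generator
                     ) -> Tuple[pd.DataFrame, List[TimeCourseEffect]]:
    width = 400  # bin-grid aligned so an enhancer spans whole 200-bp windows
    # zones to avoid: gene bodies plus 2 kb on each side
    forbidden: Dict[str, List[Tuple[int, int]]] = {c: [] for c in spec.chrom_lengths}
    for _, g in genes.iterrows():
        lo, hi = min(g.tss, g.tts), max(g.tss, g.tts)
        forbidden[g.chrom].append((lo - 2000, hi + 2000))
    candidates = []
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        zones = sorted(forbidden[chrom])
        pos = 1000
        for lo, hi in zones + [(length - 1000, length)]:
            while pos + width + 400 < lo:
                candidates.append((chrom, pos))
                pos += width + 400
            pos = max(pos, -(-(hi + 400) // 200) * 200)
    if len(candidates) < spec.n_enhancers:
        raise PlacementError(
            f"only {len(candidates)} enhancer slots for {spec.n_enhancers} requested")
    pick = rng.choice(len(candidates), size=spec.n_enhancers, replace=False)
    pick.sort()
    rows, effects = [], []
    for ei, idx in enumerate(pick):
        chrom, start = candidates[idx]
        cls = ENHANCER_CLASSES[ei % 2]
        folds = dict(_ENHANCER_FOLDS[cls])
        rows.append(dict(enh_id=f"enh{ei:03d}", chrom=chrom, start=start,
                         end=start + width, class_label=cls,
                         fold_0h=folds[0], fold_1h=folds[1], fold_4h=folds[4]))
        effects.append(TimeCourseEffect(
            chrom=chrom, start=start, end=start + width, class_label=cls,
            d_accessibility={1: 0.5, 4: 0.7} if cls == "enhancer_up" else {},
            h3k27ac_fold=folds,
        ))
    enh = pd.DataFrame(
        rows, columns=["enh_id", "chrom", "start", "end", "class_label",
                       "fold_0h", "fold_1h", "fold_4h"])
    return enh, effects


def build_genome(spec: SyntheticGenomeSpec) -> SyntheticTruth:
    """Build sequences, nucleosome lattice, genes, enhancers, and truth tracks."""
    rng = np.random.default_rng(spec.seed)
    sequences = {c: _make_sequence(spec, l, rng)
                 for c, l in sorted(spec.chrom_lengths.items())}
    genome = Genome(sequences=sequences)
    nucs = _place_nucleosomes(spec, rng)
    genes, gene_effects = _place_genes(spec, rng) if spec.n_genes else (
        pd.DataFrame(columns=["gene_id", "chrom", "tss", "tts", "strand",
                              "class_label", "log2fc_0_1", "log2fc_1_4"]), [])
    enhancers, enh_effects = _place_enhancers(spec, genes, rng) if spec.n_enhancers else (
        pd.DataFrame(columns=["enh_id", "chrom", "start", "end", "class_label",
                              "fold_0h", "fold_1h", "fold_4h"]), [])

    # promoter nucleosome-depleted dip: occupancy cut by 60% over TSS +/- 100 bp
    occ = nucs["occupancy"].to_numpy()
    for _, g in genes.iterrows():
        mask = ((nucs["chrom"] == g.chrom)
                & (nucs["dyad"] >= g.tss - 100) & (nucs["dyad"] <= g.tss + 100))
        occ[mask.to_numpy()] *= 0.4
    nucs["occupancy"] = occ

    # cache per-nucleosome GC of the wrapped 147 bp
    gc = np.empty(len(nucs))
    for chrom, sub in nucs.groupby("chrom"):
        arr = np.frombuffer(sequences[chrom].encode("ascii"), dtype=np.uint8)
        is_gc = np.isin(arr, np.frombuffer(b"GCgc", dtype=np.uint8)).astype(np.float64)
        cum = np.concatenate([[0.0], np.cumsum(is_gc)])
        d = sub["dyad"].to_numpy()
        lo = np.maximum(d - 73, 0)
        hi = np.minimum(d + 74, len(arr))
        gc[sub.index.to_numpy()] = (cum[hi] - cum[lo]) / (hi - lo)
    nucs["gc"] = gc

    return SyntheticTruth(spec=spec, genome=genome, nucleosomes=nucs,
                          genes=genes, enhancers=enhancers,
                          effects=gene_effects + enh_effects)


# ---------------------------------------------------------------------------
# fragment simulators
# ---------------------------------------------------------------------------

def release_profile(level: int, accessibility: np.ndarray,
                    mu0: float = 2.5, mu_slope: float = 1.5,
                    sigma: float = 1.2) -> np.ndarray:
    """Fraction of a nucleosome's material released at a titration level.

    Unimodal kernel over levels 1..4 centred at ``mu0 - mu_slope * a``,
    normalized so the four levels sum to 1 for every nucleosome.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError("titration level must be in 1..4")
    a = np.asarray(accessibility, dtype=float)
    mu = mu0 - mu_slope * a
    levels = np.arange(1, 5, dtype=float)
    k = np.exp(-((levels[None, :] - mu[..., None]) ** 2) / (2 * sigma ** 2))
    return k[..., level - 1] / k.sum(axis=-1)


def _sample_lengths(n: int, rng: np.random.Generator, mean: float, sd: float,
                    contaminant_fraction: float) -> np.ndarray:
    from scipy.stats import truncnorm

    lo, hi = (50 - mean) / sd, (500 - mean) / sd
    lengths = truncnorm.rvs(lo, hi, loc=mean, scale=sd, size=n,
                            random_state=rng).round().astype(np.int64)
    if contaminant_fraction > 0:
        bad = rng.random(n) < contaminant_fraction
        n_bad = int(bad.sum())
        short = rng.random(n_bad) < 0.5
        contam = np.where(short,
                          rng.integers(20, 50, size=n_bad),
                          rng.integers(501, 650, size=n_bad))
        lengths[bad] = contam
    return lengths


def _fragments_from_centers(chroms: np.ndarray, centers: np.ndarray,
                            lengths: np.ndarray,
                            chrom_lengths: Dict[str, int]) -> pd.DataFrame:
    start = centers - lengths // 2
    end = start + lengths
    # shift fragments overhanging chromosome ends back inside
    for chrom in np.unique(chroms):
        m = chroms == chrom
        L = chrom_lengths[str(chrom)]
        shift = np.where(start[m] < 0, -start[m], 0) + np.where(
            end[m] > L, L - end[m], 0)
        start[m] = start[m] + shift
        end[m] = end[m] + shift
        start[m] = np.clip(start[m], 0, L - 1)
        end[m] = np.clip(end[m], start[m] + 1, L)
    df = pd.DataFrame({"chrom": chroms, "start": start, "end": end})
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def simulate_titration_fragments(
    truth: SyntheticTruth,
    time_point: int,
    titration_level: int,
    depth: int,
    gc_bias_strength: float = 0.0,
    seed: int = 0,
    replicate: int = 1,
    frag_len_mean: float = 147.0,
    frag_len_sd: float = 15.0,
    contaminant_fraction: float = 0.02,
    position_jitter_sd: float = 12.0,
) -> FragmentSet:
    """Sample one titration library.

    Expected fragment count at a nucleosome is proportional to
    ``occupancy * release(level, accessibility) * exp(beta_level * (gc - 0.5))``
    where the GC-bias exponent grows with digestion depth
    (``beta_level = gc_bias_strength * (level - 2.5) / 1.5``), mimicking the
    digestion-dependent sequence bias that the downstream GC correction must
    remove.
    """
    if titration_level not in (1, 2, 3, 4):
        raise ValueError(f"unknown titration level {titration_level!r}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    meta = dict(assay="mnase_titration", time_point=time_point,
                titration_level=titration_level, replicate=replicate,
                mnase_units=MNASE_UNIT_LABELS[titration_level - 1])
    chrom_lengths = truth.genome.chrom_lengths
    if depth == 0 or len(truth.nucleosomes) == 0:
        empty = pd.DataFrame({"chrom": pd.Series(dtype=object),
                              "start": pd.Series(dtype=np.int64),
                              "end": pd.Series(dtype=np.int64)})
        return FragmentSet(fragments=empty, metadata=meta, chrom_lengths=chrom_lengths)

    occ, acc = truth.nucleosome_state(time_point)
    rel = release_profile(titration_level, acc)
    beta = gc_bias_strength * (titration_level - 2.5) / 1.5
    gc = truth.nucleosomes["gc"].to_numpy()
    w = occ * rel * np.exp(beta * (gc - 0.5))
    total = w.sum()
    if total <= 0:
        raise ValueError("all nucleosome weights are zero")
    counts = rng.multinomial(depth, w / total)

    nuc_idx = np.repeat(np.arange(len(w)), counts)
    dyads = truth.nucleosomes["dyad"].to_numpy()[nuc_idx]
    chroms = truth.nucleosomes["chrom"].to_numpy()[nuc_idx]
    centers = dyads + np.rint(rng.normal(0, position_jitter_sd, size=depth)).astype(np.int64)
    lengths = _sample_lengths(depth, rng, frag_len_mean, frag_len_sd,
                              contaminant_fraction)
    frags = _fragments_from_centers(chroms, centers, lengths, chrom_lengths)
    return FragmentSet(fragments=frags, metadata=meta, chrom_lengths=chrom_lengths)


def _bin_weight_sampler(truth: SyntheticTruth, weights_flat: np.ndarray,
                        offsets: Dict[str, slice], depth: int,
                        rng: np.random.Generator, frag_len_mean: float,
                        frag_len_sd: float) -> pd.DataFrame:
    counts = rng.multinomial(depth, weights_flat / weights_flat.sum())
    bin_idx = np.repeat(np.arange(len(weights_flat)), counts)
    chrom_of = np.empty(len(weights_flat), dtype=object)
    local = np.empty(len(weights_flat), dtype=np.int64)
    for chrom, sl in offsets.items():
        chrom_of[sl] = chrom
        local[sl] = np.arange(sl.stop - sl.start)
    chroms = chrom_of[bin_idx]
    centers = (local[bin_idx] * truth.bin_size
               + rng.integers(0, truth.bin_size, size=depth))
    lengths = np.clip(
        np.rint(rng.normal(frag_len_mean, frag_len_sd, size=depth)).astype(np.int64),
        50, 500)
    return _fragments_from_centers(chroms, centers, lengths,
                                   truth.genome.chrom_lengths)


def simulate_chip_pair(
    truth: SyntheticTruth,
    mark: str,
    time_point: int,
    depth: int,
    seed: int = 0,
    replicate: int = 1,
    enrichment_model: Optional[Dict[str, Dict[int, float]]] = None,
    gc_bias_strength: float = 0.0,
    frag_len_mean: float = 200.0,
    frag_len_sd: float = 25.0,
) -> Tuple[FragmentSet, FragmentSet]:
    """Sample a (ChIP, input) library pair.

    Input coverage is uniform per bin up to GC bias; ChIP multiplies the
    input expectation by the planted fold at enhancer (H3K27ac) or gene-body
    (PolII) intervals and 1 elsewhere. ``enrichment_model`` optionally
    overrides the per-class time-course folds.
    """
    if mark not in ("H3K27ac", "PolII"):
        raise ValueError(f"unknown mark {mark!r}")
    if time_point not in TIME_POINTS:
        raise ValueError(f"time_point must be one of {TIME_POINTS}")
    rng = np.random.default_rng(seed)
    idx, offsets = truth._bin_index()
    n_total = max(sl.stop for sl in offsets.values())

    gc_flat = truth.genome.gc_track(truth.bin_size).flatten()
    input_w = np.exp(gc_bias_strength * (gc_flat - 0.5))

    fold = np.ones(n_total)
    fold_col = {0: "fold_0h", 1: "fold_1h", 4: "fold_4h"}[time_point]
    if mark == "H3K27ac":
        for _, e in truth.enhancers.iterrows():
            sl = offsets[e.chrom]
            b0 = sl.start + int(e.start) // truth.bin_size
            b1 = sl.start + (int(e.end) - 1) // truth.bin_size + 1
            if enrichment_model is not None and e.class_label in enrichment_model:
                fold[b0:b1] = enrichment_model[e.class_label][time_point]
            else:
                fold[b0:b1] = e[fold_col]
    else:  # PolII tracks expression over gene bodies
        for _, g in truth.genes.iterrows():
            sl = offsets[g.chrom]
            lo, hi = min(g.tss, g.tts), max(g.tss, g.tts)
            b0 = sl.start + lo // truth.bin_size
            b1 = sl.start + (hi - 1) // truth.bin_size + 1
            lfc = g.log2fc_0_1 * (time_point >= 1) + g.log2fc_1_4 * (time_point >= 4)
            fold[b0:b1] = max(2.0 ** lfc, 0.25)

    chip = _bin_weight_sampler(truth, input_w * fold, offsets, depth, rng,
                               frag_len_mean, frag_len_sd)
    inp = _bin_weight_sampler(truth, input_w, offsets, depth, rng,
                              frag_len_mean, frag_len_sd)
    meta = dict(time_point=time_point, replicate=replicate, mark=mark)
    return (
        FragmentSet(chip, metadata=dict(assay=f"{mark}_chip", **meta),
                    chrom_lengths=truth.genome.chrom_lengths),
        FragmentSet(inp, metadata=dict(assay=f"{mark}_input", **meta),
                    chrom_lengths=truth.genome.chrom_lengths),
    )


def simulate_atac(truth: SyntheticTruth, time_point: int, depth: int,
                  seed: int = 0, replicate: int = 1, floor: float = 0.05,
                  frag_len_mean: float = 90.0, frag_len_sd: float = 15.0) -> FragmentSet:
    """ATAC-like fragments: per-bin expectation = max(accessibility, 0) + floor."""
    if time_point not in TIME_POINTS:
        raise ValueError(f"time_point must be one of {TIME_POINTS}")
    rng = np.random.default_rng(seed)
    acc_track = truth.accessibility_track(time_point)
    _, offsets = truth._bin_index()
    acc_flat = np.concatenate([acc_track.data[c] for c in sorted(acc_track.data)])
    w = np.where(np.isfinite(acc_flat), np.maximum(acc_flat, 0.0), 0.0) + floor
    frags = _bin_weight_sampler(truth, w, offsets, depth, rng,
                                frag_len_mean, frag_len_sd)
    return FragmentSet(frags, metadata=dict(assay="atac", time_point=time_point,
                                            replicate=replicate),
                       chrom_lengths=truth.genome.chrom_lengths)


def simulate_expression_table(truth: SyntheticTruth, seed: int = 0,
                              noise_sd: float = 0.15) -> pd.DataFrame:
    """Per-gene expression at 0/1/4 h with planted (class-faithful) fold changes.

    Fold changes are fixed by the truth; noise only perturbs the absolute
    baseline, so class labels are seed-invariant.
    """
    rng = np.random.default_rng(seed)
    g = truth.genes
    base = 2.0 ** rng.normal(6.0, 1.0 + noise_sd, size=len(g))
    lfc01 = g["log2fc_0_1"].to_numpy(dtype=float)
    lfc14 = g["log2fc_1_4"].to_numpy(dtype=float)
    expr0 = base
    expr1 = base * 2.0 ** lfc01
    expr4 = expr1 * 2.0 ** lfc14
    lfc04 = lfc01 + lfc14
    changed = g["class_label"].isin(["up_access_only", "up_access_and_occ_loss", "down"])
    return pd.DataFrame({
        "gene_id": g["gene_id"],
        "expr_0h": expr0, "expr_1h": expr1, "expr_4h": expr4,
        "log2fc_0_1": lfc01, "log2fc_1_4": lfc14, "log2fc_0_4": lfc04,
        "significant_0_1": changed & (np.abs(lfc01) >= 1.0),
        "significant_0_4": changed & (np.abs(lfc04) >= 1.0),
        "class_label": g["class_label"],
    })


def write_truth(truth: SyntheticTruth, outdir) -> None:
    """Write genome FASTA and all truth tables as plain text."""
    import os

    os.makedirs(outdir, exist_ok=True)
    truth.genome.write_fasta(os.path.join(outdir, "genome.fa"))
    truth.nucleosomes.to_csv(os.path.join(outdir, "nucleosomes.tsv"),
                             sep="\t", index=False)
    truth.genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    truth.enhancers.to_csv(os.path.join(outdir, "enhancers.tsv"), sep="\t", index=False)
    for t in TIME_POINTS:
        truth.occupancy_track(t).write_bedgraph(
            os.path.join(outdir, f"true_occupancy_t{t}.bedgraph"))
        truth.accessibility_track(t).write_bedgraph(
            os.path.join(outdir, f"true_accessibility_t{t}.bedgraph"))
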