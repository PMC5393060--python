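import numpy as np
import pandas as pd
import pytest

from macctools import io_filtering as iof
from macctools import macc as mc
from macctools import synthetic as syn
from macctools.tracks import BinnedTrack, FragmentSet


def make_fragment_set(rows, chrom_lengths=None, **metadata) -> FragmentSet:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return FragmentSet(fragments=df, metadata=metadata, chrom_lengths=chrom_lengths)


def titration_series(truth, time_point, depth, seed_base, gc_bias_strength=0.0,
                     replicates=(1,), bin_size=200, filter_anomalies=True):
    """Simulate, filter and bin one titration series (replicates pooled)."""
    tracks = []
    for level in (1, 2, 3, 4):
        dfs = []
        for rep in replicates:
            fs = syn.simulate_titration_fragments(
                truth, time_point, level, depth,
                gc_bias_strength=gc_bias_strength,
                seed=seed_base + 10 * level + rep, replicate=rep)
            dfs.append(fs.fragments)
        pooled = fs.replace(pd.concat(dfs, ignore_index=True))
        z = 7.0 if filter_anomalies else np.inf
        pooled, _ = iof.apply_standard_filters(pooled, z_thresh=z)
        tracks.append(mc.bin_frequencies(pooled, bin_size=bin_size,
                                         chrom_lengths=truth.genome.chrom_lengths))
    return mc.TitrationSeries(tracks=tracks)


def pooled_coverage(truth, time_point, seed_base, depth=500_000):
    """Pooled-digest per-bp coverage (equal parts of the four levels)."""
    dfs = [syn.simulate_titration_fragments(truth, time_point, lev, depth // 4,
                                            seed=seed_base + lev).fragments
           for lev in (1, 2, 3, 4)]
    fs = syn.simulate_titration_fragments(truth, time_point, 1, 0)
    fs = fs.replace(pd.concat(dfs, ignore_index=True))
    fs, _ = iof.apply_standard_filters(fs)
    return mc.coverage_track(fs, truth.genome.chrom_lengths)


@pytest.fixture(scope="session")
def flat_truth():
    """300-kb neutral genome: lattice only, varied latent state, no annotation."""
    spec = syn.SyntheticGenomeSpec(chrom_lengths={"chr1": 300_000},
                                   accessibility_sd=0.3, seed=42)
    return syn.build_genome(spec)


@pytest.fixture(scope="session")
def gene_truth():
    """500-kb genome with genes and enhancers and a planted time course."""
    spec = syn.SyntheticGenomeSpec(chrom_lengths={"chr1": 500_000},
                                   n_genes=40, n_enhancers=8,
                                   accessibility_sd=0.2, seed=7)
    return syn.build_genome(spec)


@pytest.fixture
def flat_track():
    data = {"chr1": np.arange(10, dtype=float)}
    return BinnedTrack(bin_size=200, data=data, chrom_lengths={"chr1": 2000})
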