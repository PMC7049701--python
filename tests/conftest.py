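import numpy as np
import pytest

from netseqtools import (
    AnnotationSet,
    GeneModel,
    SimulationConfig,
    StrandedTrack,
    TagSet,
    make_annotation,
    simulate_tags,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=10, seed=7)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return make_annotation(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, small_annotation):
    tags, truth = simulate_tags(small_annotation, small_config)
    return tags, truth


@pytest.fixture
def toy_annotation():
    """Two hand-built genes (one per strand) with known exon structure.

    plus gene:  [1000, 2000), exons [1000,1400) + [1600,2000), intron
    [1400,1600): donor 1399, acceptor 1600.
    minus gene: [3000, 4000), exons [3000,3400) + [3600,4000), intron
    [3400,3600): donor 3600, acceptor 3399 (transcription right-to-left).
    """
    genes = [
        GeneModel("gplus", "chr1", "+", 1000, 2000, [(1000, 1400), (1600, 2000)]),
        GeneModel("gminus", "chr1", "-", 3000, 4000, [(3000, 3400), (3600, 4000)]),
    ]
    return AnnotationSet(genes, {"chr1": 6000})


def make_track(chrom_sizes, entries):
    """Build a StrandedTrack from (chrom, position, strand, value) tuples."""
    track = StrandedTrack(chrom_sizes)
    for chrom, pos, strand, value in entries:
        track.get(chrom, strand)[pos] += value
    return track


def make_tagset(rows, chrom_sizes):
    """TagSet from (chrom, position, strand[, mapq[, is_split]]) tuples."""
    import pandas as pd

    full = []
    for row in rows:
        chrom, pos, strand = row[:3]
        mapq = row[3] if len(row) > 3 else 255
        split = row[4] if len(row) > 4 else False
        full.append((chrom, pos, strand, mapq, split))
    if full:
        df = pd.DataFrame(
            full, columns=["chrom", "position", "strand", "mapq", "is_split"]
        )
    else:
        df = TagSet.empty_frame()
    return TagSet(df, chrom_sizes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
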