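import numpy as np
import pytest

from parclip import (
    GenomeLayout,
    CoverageTrack,
    SimConfig,
    Transcript,
    simulate_annotation,
)


@pytest.fixture(scope="session")
def sim():
    """One shared small synthetic genome for the expensive tests."""
    cfg = SimConfig(seed=7)
    layout, transcripts = simulate_annotation(cfg)
    return cfg, layout, transcripts


@pytest.fixture
def tiny_layout():
    return GenomeLayout({"chrI": 10_000})


def make_track(layout, fill=0.0):
    return {
        (chrom, strand): np.full(length, float(fill))
        for chrom, length in layout.chrom_lengths.items()
        for strand in ("+", "-")
    }


@pytest.fixture
def tiny_track(tiny_layout):
    return make_track(tiny_layout)


def plus_transcript(tss=1000, pa=2000, klass="mRNA", tid="t+", introns=()):
    return Transcript(id=tid, chrom="chrI", strand="+", tss=tss, pa=pa,
                      klass=klass, introns=introns)


def minus_transcript(tss=2000, pa=1000, klass="mRNA", tid="t-", introns=()):
    return Transcript(id=tid, chrom="chrI", strand="-", tss=tss, pa=pa,
                      klass=klass, introns=introns)
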