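"""Shared fixtures.

Light fixtures build tiny genomes/site tables in milliseconds.  The three
session-scoped "study" fixtures run the full simulate/train/evaluate
pipeline at desk scale and are shared by every test that needs a trained
model; each is computed once per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methynet import workflows as wf
from methynet.io import GenomeSequence
from methynet.simulate import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_genome():
    #            123456789012345678901234567890
    return GenomeSequence("toy", "ACGTACGGCCAATTCGCGNNACGTACGTAC")


@pytest.fixture
def random_genome(rng):
    """1 kb random genome for property tests."""
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
    return GenomeSequence("rand", seq)


@pytest.fixture
def tiny_sim():
    """Small full simulation (2 x 6 kb) for fast end-to-end plumbing tests."""
    cfg = SimConfig(n_chroms=2, chrom_length=6000, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_study():
    """Both-signals regime: all three models trained and scored."""
    return wf.run_study(wf.default_study_config(seed=11),
                        wf.StudySizes(12000, 1500, 3000), seed=0)


@pytest.fixture(scope="session")
def spatial_study():
    """Neighbor-signal-only regime: DNA and methylation models."""
    return wf.run_study(wf.spatial_study_config(seed=12),
                        wf.StudySizes(4000, 800, 2000),
                        which=("dna", "meth"), seed=0)


@pytest.fixture(scope="session")
def motif_study():
    """Sequence-signal-only regime: DNA and methylation models."""
    return wf.run_study(wf.motif_study_config(seed=13),
                        wf.StudySizes(8000, 1200, 2000),
                        which=("dna", "meth"), seed=0)


@pytest.fixture
def labeled_sites():
    """Hand-built site table on one chromosome with a few NA sites."""
    return pd.DataFrame({
        "chrom": "toy",
        "pos": [2, 7, 9, 10, 11, 22, 26],
        "strand": ["+", "+", "-", "+", "-", "+", "+"],
        "context": ["CpG", "CHG", "CpG", "CHH", "CHH", "CpG", "CHH"],
        "n_meth": [5, 0, 2, 6, 1, 4, 0],
        "n_unmeth": [0, 6, 1, 1, 0, 1, 5],
        "depth": [5, 6, 3, 7, 1, 5, 5],
        "rate": [1.0, 0.0, 2 / 3, 6 / 7, 1.0, 0.8, 0.0],
        "label": [1.0, 0.0, np.nan, 1.0, np.nan, 1.0, 0.0],
    })
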