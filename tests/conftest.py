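"""Shared fixtures: toy gene sets, references, and simulated samples."""

from __future__ import annotations

import numpy as np
import pytest

from trfkit.refdb import build_reference
from trfkit.simulate import SimConfig, make_toy_gene_set, simulate_reads


@pytest.fixture(scope="session")
def toy_annotations():
    return make_toy_gene_set(seed=1, n_genes=4)


@pytest.fixture(scope="session")
def toy_ref(toy_annotations):
    annotations, genome = toy_annotations
    return build_reference(annotations, genome)


@pytest.fixture(scope="session")
def clean_sim(toy_ref):
    """Error-free simulation: no mods, no additions, no truncation."""
    config = SimConfig(seed=7, depth=2000, n_samples=2)
    samples, truth = simulate_reads(config, toy_ref)
    return config, samples, truth


@pytest.fixture(scope="session")
def clean_hits(toy_ref, clean_sim):
    from trfkit.align import ReadAligner
    from trfkit.additions import detect_additions

    _config, samples, _truth = clean_sim
    aligner = ReadAligner(toy_ref)
    hits_by_sample = {}
    for sample, reads in samples.items():
        hits, _stats = aligner.map_reads((r[0], r[1]) for r in reads)
        hits_by_sample[sample] = hits
    detect_additions(hits_by_sample, toy_ref)
    return hits_by_sample


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
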