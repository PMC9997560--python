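"""Shared fixtures: small synthetic genomes and experiments.

Everything is generated programmatically at test time; nothing is read
from disk except files the tests themselves write.
"""

from __future__ import annotations

import numpy as np
import pytest

import halomut as hm
from halomut.simulate import SpectrumMatrix


@pytest.fixture(scope="session")
def small_genome() -> hm.GenomeModel:
    """A 3-replicon genome (~10 kb) mirroring the main/mini-chromosome design."""
    return hm.generate_genome(
        [("chr", 6000, 0.68), ("pA", 2000, 0.58), ("pB", 1500, 0.59)], seed=101
    )


@pytest.fixture(scope="session")
def inflated_spectrum() -> SpectrumMatrix:
    """Paper-shaped spectrum with rates x2000 so small genomes get hits."""
    base = SpectrumMatrix()
    return SpectrumMatrix(
        class_rates={k: v * 2000 for k, v in base.class_rates.items()},
        insertion_rate=base.insertion_rate * 2000,
        deletion_rate=base.deletion_rate * 2000,
    )


@pytest.fixture(scope="session")
def clean_experiment(small_genome, inflated_spectrum):
    """Noise-free simulated experiment: genome, truth, per-line site blocks."""
    line_ids = [f"L{i:03d}" for i in range(1, 9)]
    truth = hm.simulate_ma_lines(
        small_genome, inflated_spectrum, n_lines=8, generations=1267,
        seed=7, line_ids=line_ids,
    )
    blocks = dict(
        hm.simulate_read_summaries(
            small_genome, truth, line_ids,
            error_rate=0.0, contamination=0.0, callability=1.0,
            seed=8, as_frames=False,
        )
    )
    return small_genome, truth, blocks, line_ids


def rate_keys(calls) -> set:
    return {(c.line_id, c.replicon, c.pos, c.ref, c.alt) for c in calls}


@pytest.fixture
def call_keys():
    return rate_keys
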