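"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from coevodock.alignment import Alignment, frequencies
from coevodock.synthetic import (
    FixtureSpec,
    generate_decoys,
    make_coupled_model,
    make_toy_complex,
    sample_potts_msa,
)


@pytest.fixture(scope="session")
def toy_spec() -> FixtureSpec:
    return FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def toy_native(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_decoys(toy_spec, toy_native):
    return generate_decoys(toy_native, toy_spec)


@pytest.fixture(scope="session")
def coupled_msa():
    """A small MSA sampled from a model with one strong planted coupling."""
    spec = FixtureSpec(
        seed=5, n1=4, n2=4, q=4, m=600, planted_pairs=((1, 5, 2.0),)
    )
    model = make_coupled_model(spec)
    return spec, model, sample_potts_msa(model, spec.m, seed=spec.seed)


@pytest.fixture(scope="session")
def small_fixture_table():
    """Out-of-fold-scored component table of a small 3-complex dataset."""
    from coevodock.ranking import cross_validate
    from coevodock.synthetic import make_benchmark_fixture

    spec = FixtureSpec(seed=0, m=120, n_decoys=24)
    table, _ = make_benchmark_fixture(3, seed=9, base_spec=spec, cd_updates=150)
    oof, _ = cross_validate(table, ("S_N", "S_ent"), k=3, seed=2)
    return oof


@pytest.fixture()
def tiny_alignment() -> Alignment:
    seqs = ["ACDA", "ACDV", "AVDA", "AVDV"]
    return Alignment.from_sequences(seqs, boundary=2)


@pytest.fixture()
def tiny_frequencies(tiny_alignment):
    return frequencies(tiny_alignment, pseudocount=0.0)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
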