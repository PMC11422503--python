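"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from pancore.matrix_io import PresenceAbsenceMatrix, CompletenessTable


def brute_force_poisbin_pmf(probs) -> np.ndarray:
    """Poisson-binomial pmf by enumeration over all 2^N outcomes.

    Deliberately naive — the oracle against which the dynamic-programming
    convolution is checked. Only usable for small N.
    """
    probs = np.asarray(probs, dtype=float)
    n = probs.size
    pmf = np.zeros(n + 1)
    for outcome in product((0, 1), repeat=n):
        p = 1.0
        for success, pi in zip(outcome, probs):
            p *= pi if success else 1.0 - pi
        pmf[sum(outcome)] += p
    return pmf


def random_matrix(rng: np.random.Generator, n_genes: int, n_genomes: int) -> PresenceAbsenceMatrix:
    return PresenceAbsenceMatrix(
        gene_ids=[f"gene_{g}" for g in range(n_genes)],
        genome_ids=[f"genome_{i}" for i in range(n_genomes)],
        values=(rng.random((n_genes, n_genomes)) < 0.5).astype(np.uint8),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix() -> PresenceAbsenceMatrix:
    values = np.array(
        [
            [1, 1, 1, 1],
            [1, 0, 1, 0],
            [0, 0, 0, 0],
        ],
        dtype=np.uint8,
    )
    return PresenceAbsenceMatrix(
        gene_ids=["gA", "gB", "gC"],
        genome_ids=["s1", "s2", "s3", "s4"],
        values=values,
    )


@pytest.fixture
def small_table() -> CompletenessTable:
    return CompletenessTable(
        genome_ids=["s1", "s2", "s3", "s4"],
        completeness=np.array([0.95, 0.8, 0.9, 1.0]),
    )


@pytest.fixture
def toy_fasta_dir(tmp_path):
    """Three small single/multi-contig assemblies."""
    rng = np.random.default_rng(7)
    alphabet = np.array(list("ACGT"))
    fdir = tmp_path / "assemblies"
    fdir.mkdir()
    specs = {
        "asm1.fasta": [("c1", 4000)],
        "asm2.fasta": [("c1", 2500), ("c2", 1500)],
        "asm3.fasta": [("c1", 1200), ("c2", 1800), ("c3", 1000)],
    }
    for fname, contigs in specs.items():
        with (fdir / fname).open("w") as fh:
            for cid, length in contigs:
                seq = "".join(rng.choice(alphabet, size=length))
                fh.write(f">{cid}\n{seq}\n")
    return fdir
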