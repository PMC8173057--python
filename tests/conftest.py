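"""Shared fixtures: programmatically generated barcode sets, sheets, mocks."""

import numpy as np
import pytest

from amplimux import (
    Barcode,
    BarcodeSet,
    Scheme,
    assign_samples,
    default_mock_reference,
    hamming,
)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def greedy_distant_set(
    rng: np.random.Generator, n: int, length: int, d_min: int
) -> BarcodeSet:
    """Generate n random barcodes with pairwise Hamming distance >= d_min."""
    chosen: list[str] = []
    while len(chosen) < n:
        cand = random_dna(rng, length)
        if all(hamming(cand, c) >= d_min for c in chosen):
            chosen.append(cand)
    return BarcodeSet([Barcode(f"bc{i:03d}", s) for i, s in enumerate(chosen)])


@pytest.fixture(scope="session")
def bc12():
    """Twenty 12-nt barcodes, min pairwise distance >= 5."""
    return greedy_distant_set(np.random.default_rng(11), 20, 12, 5)


@pytest.fixture(scope="session")
def bc8():
    """Twelve 8-nt barcodes, min pairwise distance >= 3."""
    return greedy_distant_set(np.random.default_rng(13), 12, 8, 3)


@pytest.fixture(scope="session")
def mock_ref():
    return default_mock_reference()


@pytest.fixture(scope="session")
def sheets(bc12, bc8):
    """One small valid sample sheet per scheme."""
    return {
        Scheme.SB: assign_samples(Scheme.SB, [f"s{i}" for i in range(6)],
                                  bc8, seed=1),
        Scheme.UDB_H11: assign_samples(Scheme.UDB_H11,
                                       [f"s{i}" for i in range(6)], bc12, seed=1),
        Scheme.UDB_H12: assign_samples(Scheme.UDB_H12,
                                       [f"s{i}" for i in range(6)], bc12, seed=1),
        Scheme.CDB_H12: assign_samples(Scheme.CDB_H12,
                                       [f"s{i}" for i in range(6)], bc12, seed=1),
    }
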