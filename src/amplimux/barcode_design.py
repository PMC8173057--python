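"""Barcode sets for amplicon multiplexing: representation, validation, selection.

Sample barcodes are short fixed-length DNA tags (8 or 12 nt) prepended to
amplicons in a second-step (barcoding) PCR. A usable barcode set must keep
every pair of tags far apart in Hamming distance — so that sequencing errors
cannot convert one barcode into another — and should have a near-uniform base
composition at every tag position, which protects Illumina base calling from
low-complexity cycles.

This module provides the :class:`Barcode` / :class:`BarcodeSet` containers,
pairwise-distance and per-position composition profiling, a report-style
validator, and a seeded greedy selector that picks a subset of a candidate
pool subject to a minimum-distance constraint while minimising the
composition-uniformity deviation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DNA_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}

#: Default minimum pairwise Hamming distance for accepted barcode sets.
DEFAULT_MIN_DISTANCE = 4


class BarcodeError(ValueError):
    """Invalid barcode or barcode-set construction."""


class InsufficientSetError(BarcodeError):
    """Operation requires more barcodes than the set contains."""


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ.

    Raises
    ------
    ValueError
        If the strings have different lengths.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Barcode:
    """A single fixed-length DNA barcode.

    ``seq`` must be over {A,C,G,T}; lowercase input is normalised to
    uppercase. No degenerate bases or gaps are allowed in barcodes.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - set(DNA_ALPHABET)
        if bad or not self.seq:
            raise BarcodeError(
                f"barcode {self.id!r}: sequence must be non-empty A/C/G/T, "
                f"got {self.seq!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length DNA strings as an (n, L) uint8 matrix."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


@dataclass
class DistanceProfile:
    """Summary of all pairwise Hamming distances in a barcode set."""

    min: int
    median: float
    #: histogram[d] = number of unordered pairs at distance d, length L+1.
    histogram: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.histogram.sum())


@dataclass
class CompositionProfile:
    """Per-position base frequencies of a barcode set.

    ``freqs`` has shape (L, 4) with columns ordered A, C, G, T; each row
    sums to 1. ``uniformity_score`` is the maximum absolute deviation from
    0.25 over all entries — 0 for a perfectly balanced set, at most 0.75.
    """

    freqs: np.ndarray
    uniformity_score: float

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


class BarcodeSet:
    """An ordered collection of distinct, equal-length barcodes."""

    def __init__(self, barcodes: Iterable[Barcode]):
        self.barcodes: list[Barcode] = list(barcodes)
        if not self.barcodes:
            raise InsufficientSetError("barcode set cannot be empty")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise BarcodeError(f"mixed barcode lengths: {sorted(lengths)}")
        seqs = [b.seq for b in self.barcodes]
        if len(set(seqs)) != len(seqs):
            dups = sorted({s for s in seqs if seqs.count(s) > 1})
            raise BarcodeError(f"duplicate barcode sequences: {dups}")
        self.length: int = lengths.pop()

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    def __getitem__(self, i: int) -> Barcode:
        return self.barcodes[i]

    @property
    def seqs(self) -> list[str]:
        return [b.seq for b in self.barcodes]

    @property
    def min_distance(self) -> int:
        return distance_profile(self).min

    @property
    def distance_median(self) -> float:
        return distance_profile(self).median

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeSet":
        """Read a two-column (id, sequence) TSV barcode list.

        A header line is detected (second column not pure DNA) and skipped;
        '#'-prefixed lines are ignored; sequences are case-normalised.
        """
        barcodes = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise BarcodeError(f"{path}: expected 2 columns, got {row!r}")
                bc_id, seq = row[0].strip(), row[1].strip()
                if not set(seq.upper()) <= set(DNA_ALPHABET):
                    continue  # header line
                barcodes.append(Barcode(bc_id, seq))
        return cls(barcodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["id", "sequence"])
            for b in self.barcodes:
                w.writerow([b.id, b.seq])


def distance_matrix(bset: BarcodeSet) -> np.ndarray:
    """Full (n, n) pairwise Hamming distance matrix."""
    enc = _encode(bset.seqs)
    return (enc[:, None, :] != enc[None, :, :]).sum(axis=2)


def distance_profile(bset: BarcodeSet) -> DistanceProfile:
    """Min, median and histogram of all unordered pairwise Hamming distances."""
    if len(bset) < 2:
        raise InsufficientSetError("distance profile needs >= 2 barcodes")
    dm = distance_matrix(bset)
    iu = np.triu_indices(len(bset), k=1)
    dists = dm[iu]
    hist = np.bincount(dists, minlength=bset.length + 1)
    return DistanceProfile(
        min=int(dists.min()), median=float(np.median(dists)), histogram=hist
    )


def composition_profile(bset: BarcodeSet) -> CompositionProfile:
    """Per-position base frequencies and their worst deviation from 0.25."""
    enc = _encode(bset.seqs)
    freqs = np.empty((bset.length, 4))
    for i, base in enumerate(DNA_ALPHABET):
        freqs[:, i] = (enc == ord(base)).mean(axis=0)
    score = float(np.abs(freqs - 0.25).max())
    return CompositionProfile(freqs=freqs, uniformity_score=score)


# ---------------------------------------------------------------- validation


@dataclass
class ValidationReport:
    """Outcome of checking a barcode list against a distance threshold."""

    passed: bool
    d_min: int
    offending_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)
    mixed_lengths: bool = False

    def summary(self) -> str:
        if self.passed:
            return f"PASS (min pairwise distance >= {self.d_min})"
        parts = []
        if self.mixed_lengths:
            parts.append("mixed lengths")
        if self.duplicates:
            parts.append(f"{len(self.duplicates)} duplicate sequence(s)")
        if self.offending_pairs:
            parts.append(
                f"{len(self.offending_pairs)} pair(s) below distance {self.d_min}"
            )
        return "FAIL: " + "; ".join(parts)


def validate_set(
    barcodes: BarcodeSet | Sequence[Barcode], d_min: int
) -> ValidationReport:
    """Check distinctness, uniform length and the pairwise-distance floor.

    Unlike :class:`BarcodeSet` construction this never raises: it returns a
    report listing every offending pair so a failing list can be repaired.
    """
    bcs = list(barcodes)
    report = ValidationReport(passed=True, d_min=d_min)
    lengths = {len(b) for b in bcs}
    if len(lengths) > 1:
        report.mixed_lengths = True
        report.passed = False
        return report
    seen: dict[str, str] = {}
    for b in bcs:
        if b.seq in seen:
            report.duplicates.append(b.seq)
        seen[b.seq] = b.id
    for i in range(len(bcs)):
        for j in range(i + 1, len(bcs)):
            d = hamming(bcs[i].seq, bcs[j].seq)
            if d < d_min:
                report.offending_pairs.append((bcs[i].id, bcs[j].id, d))
    if report.duplicates or report.offending_pairs:
        report.passed = False
    return report


# ----------------------------------------------------------------- selection


@dataclass
class SelectionResult:
    """Result of :func:`select_barcodes`.

    ``reached_target`` is False when no subset of the requested size exists
    under the distance constraint along the explored greedy path; the largest
    subset found is returned in that case.
    """

    barcode_set: BarcodeSet
    reached_target: bool
    uniformity_score: float


def select_barcodes(
    candidates: BarcodeSet,
    k: int,
    d_min: int = DEFAULT_MIN_DISTANCE,
    seed: int = 0,
    uniformity_weight: float = 1.0,
    refine_passes: int = 2,
) -> SelectionResult:
    """Select up to ``k`` barcodes with pairwise Hamming distance >= ``d_min``.

    The procedure is a seeded greedy max–min build followed by local swap
    refinement: starting from a shuffled candidate order, the next barcode
    chosen is always a feasible candidate (distance >= ``d_min`` to every
    selected barcode) maximising its minimum distance to the current
    selection, ties broken by shuffled input order. Refinement then attempts
    single in/out swaps that keep the distance constraint and lower the
    composition ``uniformity_score``; ``uniformity_weight`` = 0 disables
    refinement entirely (distance-only selection).

    Deterministic given ``seed``.
    """
    if d_min < 1:
        raise ValueError("d_min must be >= 1")
    if d_min > candidates.length:
        raise BarcodeError(
            f"impossible constraint: d_min {d_min} exceeds barcode length "
            f"{candidates.length}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds candidate pool size {len(candidates)}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    pool = [candidates[int(i)] for i in order]
    dm_full = distance_matrix(candidates)
    dm = dm_full[np.ix_(order, order)]

    n = len(pool)
    selected: list[int] = [0]
    # min distance from each pool index to the current selection
    min_to_sel = dm[0].copy()
    while len(selected) < k:
        feasible = np.flatnonzero(min_to_sel >= d_min)
        feasible = feasible[~np.isin(feasible, selected)]
        if feasible.size == 0:
            break
        # max-min greedy; argmax takes the first (= shuffled-order) tie winner
        best = int(feasible[np.argmax(min_to_sel[feasible])])
        selected.append(best)
        min_to_sel = np.minimum(min_to_sel, dm[best])

    def _score(idx: list[int]) -> float:
        sub = BarcodeSet([pool[i] for i in idx])
        return composition_profile(sub).uniformity_score

    if uniformity_weight > 0 and len(selected) >= 2:
        current = _score(selected)
        for _ in range(refine_passes):
            improved = False
            outside = [i for i in range(n) if i not in selected]
            for pos in range(len(selected)):
                kept = selected[:pos] + selected[pos + 1 :]
                for cand in outside:
                    if min(dm[cand, j] for j in kept) < d_min:
                        continue
                    trial = kept[:pos] + [cand] + kept[pos:]
                    s = _score(trial)
                    if s < current - 1e-12:
                        selected = trial
                        current = s
                        improved = True
                        outside = [i for i in range(n) if i not in selected]
                        break
            if not improved:
                break

    chosen = BarcodeSet([pool[i] for i in sorted(selected)])
    return SelectionResult(
        barcode_set=chosen,
        reached_target=len(chosen) == k,
        uniformity_score=composition_profile(chosen).uniformity_score,
    )
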