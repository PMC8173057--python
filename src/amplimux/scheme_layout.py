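"""Barcoding schemes for two-step-PCR amplicon multiplexing.

In a two-step PCR workflow, target-gene primers carry a constant 16-nt head
(linker) sequence at their 5' ends; a second, barcoding PCR then extends the
amplicons with barcode–head fusion primers. Four layouts are supported:

``SB``
    Single barcoding — one barcode–H1 fusion primer tags both amplicon ends
    (classically with 8-nt barcodes). Capacity = k barcodes.
``UDB_H11``
    Unique dual barcoding, one head — both primers carry H1 and each sample
    consumes an exclusive *pair* of barcodes. Capacity = floor(k/2).
``UDB_H12``
    Unique dual barcoding, two heads — the forward primer carries H1 and the
    reverse carries H2; every barcode is used at most once per side.
    Capacity = k.
``CDB_H12``
    Combinatorial dual barcoding — samples are identified by unique *ordered*
    pairs of individually reused barcodes. Capacity = k·(k−1), i.e. 299,756
    for the 548-barcode set, at the cost of crosstalk detectability: a single
    hopped barcode can produce another sample's valid combination.

The module also builds and validates sample sheets (barcode-to-sample
assignments) and the decoder lookup used by the demultiplexer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .barcode_design import Barcode, BarcodeSet

IUPAC_ALPHABET = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class HeadSequence:
    """A constant 16-nt head (linker) between barcode and target primer."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != 16:
            raise ValueError(f"head {self.id} must be 16 nt, got {len(self.seq)}")


H1 = HeadSequence("H1", "GCTATGCGCGAGCTGC")
H2 = HeadSequence("H2", "TAGCGCACACCTGGTA")
HEAD_LENGTH = 16


@dataclass(frozen=True)
class PrimerPair:
    """A target-gene primer pair (IUPAC degeneracy allowed).

    ``cycling`` holds the thermal protocol as free-text metadata only.
    """

    name: str
    fwd: str
    rev: str
    region: str
    cycling: str = ""

    def __post_init__(self) -> None:
        for seq in (self.fwd, self.rev):
            bad = set(seq) - IUPAC_ALPHABET
            if bad:
                raise ValueError(f"primer {self.name}: non-IUPAC chars {bad}")


#: Built-in 16S rRNA gene primer pairs used with these schemes.
PRIMER_PAIRS: dict[str, PrimerPair] = {
    "515F-806R": PrimerPair(
        "515F-806R",
        fwd="GTGYCAGCMGCCGCGGTAA",
        rev="GGACTACNVGGGTWTCTAAT",
        region="V4",
        cycling="94C 3min; 30x(94C 45s, 52C 60s, 72C 90s); 72C 10min",
    ),
    "341F-785R": PrimerPair(
        "341F-785R",
        fwd="CCTACGGGNGGCWGCAG",
        rev="GACTACHVGGGTATCTAATCC",
        region="V3-V4",
        cycling="94C 3min; 30x(95C 30s, 55C 30s, 72C 60s); 72C 10min",
    ),
}


class Scheme(Enum):
    """The four barcoding layouts."""

    SB = "sb"
    UDB_H11 = "udb-h11"
    UDB_H12 = "udb-h12"
    CDB_H12 = "cdb-h12"

    @classmethod
    def parse(cls, text: str) -> "Scheme":
        key = text.strip().lower().replace("_", "-")
        for s in cls:
            if s.value == key:
                return s
        raise ValueError(f"unknown scheme {text!r}; choose from "
                         f"{[s.value for s in cls]}")

    @property
    def fwd_head(self) -> HeadSequence:
        return H1

    @property
    def rev_head(self) -> HeadSequence:
        return H2 if self in (Scheme.UDB_H12, Scheme.CDB_H12) else H1

    @property
    def dual_barcode(self) -> bool:
        """Whether samples carry two (possibly different) barcodes."""
        return self is not Scheme.SB


def capacity(scheme: Scheme, k: int) -> int:
    """Maximum number of samples multiplexable with one primer pair.

    ``k`` is the barcode-set size. SB uses one barcode per sample (k);
    UDB-H11 consumes an exclusive unordered pair per sample (floor(k/2));
    UDB-H12 uses each barcode once per side (k); CDB-H12 enumerates ordered
    pairs of two distinct barcodes (k·(k−1)).
    """
    if k < 0:
        raise ValueError("barcode-set size k must be >= 0")
    if scheme is Scheme.SB:
        return k
    if scheme is Scheme.UDB_H11:
        return k // 2
    if scheme is Scheme.UDB_H12:
        return k
    return k * (k - 1) if k >= 1 else 0


def total_capacity(scheme: Scheme, k: int, n_primer_pairs: int, m_pools: int) -> int:
    """capacity × n primer pairs × m pooled amplicon libraries per run."""
    if n_primer_pairs < 1 or m_pools < 1:
        raise ValueError("n_primer_pairs and m_pools must be >= 1")
    return capacity(scheme, k) * n_primer_pairs * m_pools


# -------------------------------------------------------------- sample sheet


class SampleSheetError(ValueError):
    """Sample sheet violates a scheme invariant."""


class CapacityExceededError(SampleSheetError):
    """More samples requested than the scheme/barcode set supports."""


@dataclass(frozen=True)
class SampleRecord:
    """One sample's barcode assignment.

    ``bc1`` sits on the forward (H1) side; ``bc2`` on the reverse side
    (H1 for UDB-H11, H2 for the H12 schemes), or ``None`` for SB.
    """

    sample_id: str
    primer_pair: str
    bc1: Barcode
    bc2: Optional[Barcode] = None


@dataclass
class SampleSheet:
    """Scheme-specific mapping from samples to barcode assignments."""

    scheme: Scheme
    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.records)

    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def validate(self) -> None:
        ids = self.sample_ids()
        if len(set(ids)) != len(ids):
            raise SampleSheetError("duplicate sample_ids in sheet")
        sch = self.scheme
        if sch is Scheme.SB:
            seqs = [r.bc1.seq for r in self.records]
            if any(r.bc2 is not None for r in self.records):
                raise SampleSheetError("SB records must not carry a second barcode")
            if len(set(seqs)) != len(seqs):
                raise SampleSheetError("SB: barcode reused across samples")
            return
        for r in self.records:
            if r.bc2 is None:
                raise SampleSheetError(f"{sch.value}: sample {r.sample_id} "
                                       "needs two barcodes")
            if r.bc1.seq == r.bc2.seq:
                raise SampleSheetError(
                    f"sample {r.sample_id}: identical barcode on both sides")
        if sch is Scheme.UDB_H11:
            used: set[str] = set()
            for r in self.records:
                for s in (r.bc1.seq, r.bc2.seq):
                    if s in used:
                        raise SampleSheetError(
                            f"UDB-H11: barcode {s} shared between samples")
                    used.add(s)
        elif sch is Scheme.UDB_H12:
            for side in ("bc1", "bc2"):
                seqs = [getattr(r, side).seq for r in self.records]
                if len(set(seqs)) != len(seqs):
                    raise SampleSheetError(
                        f"UDB-H12: barcode reused on the {side} side")
        else:  # CDB_H12
            pairs = [(r.bc1.seq, r.bc2.seq) for r in self.records]
            if len(set(pairs)) != len(pairs):
                raise SampleSheetError("CDB-H12: ordered barcode pair reused")

    # ------------------------------------------------------------------ I/O

    _COLUMNS = ["sample_id", "scheme", "primer_pair",
                "bc1_id", "bc1_seq", "bc2_id", "bc2_seq"]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(self._COLUMNS)
            for r in self.records:
                w.writerow([
                    r.sample_id, self.scheme.value, r.primer_pair,
                    r.bc1.id, r.bc1.seq,
                    r.bc2.id if r.bc2 else "", r.bc2.seq if r.bc2 else "",
                ])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        records: list[SampleRecord] = []
        scheme: Optional[Scheme] = None
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh, delimiter="\t")
                    if r and not r[0].startswith("#")]
        if not rows:
            raise SampleSheetError(f"{path}: empty sample sheet")
        header = rows[0]
        if header[: len(cls._COLUMNS)] != cls._COLUMNS:
            raise SampleSheetError(
                f"{path}: unexpected header {header!r}")
        for row in rows[1:]:
            sid, sch, primer, b1i, b1s, b2i, b2s = row[:7]
            row_scheme = Scheme.parse(sch)
            if scheme is None:
                scheme = row_scheme
            elif row_scheme is not scheme:
                raise SampleSheetError(f"{path}: mixed schemes in one sheet")
            bc2 = Barcode(b2i, b2s) if b2s else None
            records.append(SampleRecord(sid, primer, Barcode(b1i, b1s), bc2))
        assert scheme is not None
        return cls(scheme=scheme, records=records)


def assign_samples(
    scheme: Scheme,
    sample_ids: Sequence[str],
    barcode_set: BarcodeSet,
    seed: int = 0,
    primer_pair: str = "515F-806R",
    barcode_set2: Optional[BarcodeSet] = None,
) -> SampleSheet:
    """Assign barcodes to samples under a scheme's pairing rules.

    Barcode order is shuffled deterministically from ``seed`` before
    assignment. ``barcode_set2`` optionally supplies a distinct reverse-side
    pool for the H12 schemes (defaults to the same pool).

    Pairing rules: SB takes one barcode per sample; UDB-H11 consumes disjoint
    consecutive pairs; UDB-H12 pairs barcode i (forward) with barcode
    i+1 mod k (reverse) — a circular offset, so the two barcodes of a sample
    always differ even with a single shared pool; CDB-H12 enumerates ordered
    distinct pairs (i, j) in index order.
    """
    import numpy as np

    ids = list(sample_ids)
    if len(set(ids)) != len(ids):
        raise SampleSheetError("duplicate sample_ids")
    fwd_pool = list(barcode_set)
    rev_pool = list(barcode_set2) if barcode_set2 is not None else None
    if rev_pool is not None and scheme in (Scheme.SB, Scheme.UDB_H11):
        raise SampleSheetError(f"{scheme.value} uses a single barcode pool")

    rng = np.random.default_rng(seed)
    fwd_pool = [fwd_pool[int(i)] for i in rng.permutation(len(fwd_pool))]
    if rev_pool is not None:
        rev_pool = [rev_pool[int(i)] for i in rng.permutation(len(rev_pool))]

    k = len(fwd_pool) if rev_pool is None else min(len(fwd_pool), len(rev_pool))
    cap = capacity(scheme, k)
    if len(ids) > cap:
        raise CapacityExceededError(
            f"{len(ids)} samples exceed {scheme.value} capacity {cap} "
            f"for a {k}-barcode set")

    records: list[SampleRecord] = []
    if scheme is Scheme.SB:
        for i, sid in enumerate(ids):
            records.append(SampleRecord(sid, primer_pair, fwd_pool[i]))
    elif scheme is Scheme.UDB_H11:
        for i, sid in enumerate(ids):
            records.append(
                SampleRecord(sid, primer_pair, fwd_pool[2 * i], fwd_pool[2 * i + 1]))
    elif scheme is Scheme.UDB_H12:
        rp = rev_pool if rev_pool is not None else fwd_pool
        for i, sid in enumerate(ids):
            bc2 = rp[(i + 1) % k] if rev_pool is None else rp[i]
            if bc2.seq == fwd_pool[i].seq:  # distinct pools may still collide
                bc2 = rp[(i + 1) % k]
            records.append(SampleRecord(sid, primer_pair, fwd_pool[i], bc2))
    else:  # CDB_H12
        rp = rev_pool if rev_pool is not None else fwd_pool
        n = 0
        for i in range(k):
            for j in range(k):
                if n >= len(ids):
                    break
                if rp[j].seq == fwd_pool[i].seq:
                    continue
                records.append(SampleRecord(ids[n], primer_pair, fwd_pool[i], rp[j]))
                n += 1
    return SampleSheet(scheme=scheme, records=records)


# ------------------------------------------------------------------ decoder


@dataclass
class Decoder:
    """Lookup from observed (forward-side, reverse-side) barcodes to samples.

    ``fwd_set`` / ``rev_set`` are the barcodes actually in use on each side,
    used by the demultiplexer for mismatch-tolerant matching; ``mapping``
    resolves an ordered pair of matched barcode sequences to a sample id, or
    to ``None`` (invalid combination) when both barcodes are known but the
    pair is unused.
    """

    scheme: Scheme
    fwd_set: BarcodeSet
    rev_set: BarcodeSet
    mapping: dict[tuple[str, str], str]
    primer_pairs: dict[str, PrimerPair]

    def lookup(self, fwd_seq: str, rev_seq: str) -> Optional[str]:
        return self.mapping.get((fwd_seq, rev_seq))


def build_decoder(
    sheet: SampleSheet,
    primer_pairs: Optional[dict[str, PrimerPair]] = None,
) -> Decoder:
    """Build the barcode-evidence → sample lookup for a valid sheet.

    SB: the same barcode is expected on both ends, so only the diagonal
    (bc, bc) maps to a sample. UDB-H11: the barcoding PCR runs two H1 fusion
    primers in one reaction, so all four ordered end combinations of a
    sample's pair — (a,b), (b,a), (a,a), (b,b) — identify that sample.
    H12 schemes: the observed (H1-side, H2-side) ordered pair must equal the
    sample's assigned pair.
    """
    sheet.validate()
    pp = dict(primer_pairs or PRIMER_PAIRS)
    missing = {r.primer_pair for r in sheet.records} - pp.keys()
    if missing:
        raise SampleSheetError(f"unknown primer pair(s) in sheet: {missing}")

    mapping: dict[tuple[str, str], str] = {}
    fwd: dict[str, Barcode] = {}
    rev: dict[str, Barcode] = {}
    for r in sheet.records:
        if sheet.scheme is Scheme.SB:
            mapping[(r.bc1.seq, r.bc1.seq)] = r.sample_id
            fwd[r.bc1.seq] = r.bc1
            rev[r.bc1.seq] = r.bc1
        elif sheet.scheme is Scheme.UDB_H11:
            a, b = r.bc1, r.bc2
            assert b is not None
            for x, y in ((a, b), (b, a), (a, a), (b, b)):
                mapping[(x.seq, y.seq)] = r.sample_id
            fwd[a.seq] = a
            fwd[b.seq] = b
            rev[a.seq] = a
            rev[b.seq] = b
        else:
            assert r.bc2 is not None
            mapping[(r.bc1.seq, r.bc2.seq)] = r.sample_id
            fwd[r.bc1.seq] = r.bc1
            rev[r.bc2.seq] = r.bc2
    return Decoder(
        scheme=sheet.scheme,
        fwd_set=BarcodeSet(fwd.values()),
        rev_set=BarcodeSet(rev.values()),
        mapping=mapping,
        primer_pairs=pp,
    )
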