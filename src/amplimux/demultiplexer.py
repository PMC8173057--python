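"""Mismatch-tolerant paired-end demultiplexing of barcoded amplicon reads.

Each read starts with a fixed-layout technical prefix::

    [barcode (8 or 12 nt)] [head (16 nt)] [target primer] [insert ...]

Demultiplexing anchors this layout at position 0 (no indel tolerance — the
construct is fixed-position and substitutions dominate Illumina errors),
matches the barcode against the sample sheet's set allowing
``max_mm_barcode`` substitutions (default 1), the head and primer allowing
``max_mm_head`` / ``max_mm_primer`` substitutions (default 2, IUPAC-aware
for degenerate primer bases), resolves the ordered barcode pair through the
scheme decoder, and trims the technical prefix off the insert.

Because library preparation randomises which physical end becomes R1, dual
schemes are tried in both orientations (R1 = forward/H1 side, then R1 =
reverse side); a pair that resolves to two different samples in the two
orientations is rejected as ambiguous rather than guessed.
"""

from __future__ import annotations

import gzip
import json
import io
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, TextIO, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcode_design import Barcode, BarcodeSet, hamming
from .scheme_layout import (
    Decoder,
    HEAD_LENGTH,
    SampleSheet,
    Scheme,
    build_decoder,
)

# --------------------------------------------------------- IUPAC utilities

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string."""
    return seq.translate(_COMPLEMENT)[::-1]


def match_iupac(pattern: str, observed: str, max_mm: int) -> Optional[int]:
    """Count mismatches of ``observed`` against an IUPAC ``pattern``.

    A position matches when the observed base is in the IUPAC expansion of
    the pattern base (N matches everything). Returns the mismatch count if
    it is <= ``max_mm``, else ``None``.

    Raises
    ------
    ValueError
        On unequal lengths or a non-IUPAC pattern character.
    """
    if len(pattern) != len(observed):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs observed {len(observed)}")
    mm = 0
    for p, o in zip(pattern, observed):
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC character {p!r} in pattern") from None
        if o not in allowed:
            mm += 1
            if mm > max_mm:
                return None
    return mm


#: Sentinel returned by :func:`match_barcode` when >= 2 barcodes tie.
AMBIGUOUS = object()


def match_barcode(
    observed: str, bset: BarcodeSet, max_mm: int
) -> Union[Barcode, None, object]:
    """Match an observed barcode-length substring against a barcode set.

    Returns the unique :class:`Barcode` within ``max_mm`` substitutions,
    ``None`` if no barcode qualifies, or the :data:`AMBIGUOUS` sentinel if
    two or more qualify (ties are rejected, never guessed).
    """
    if len(observed) != bset.length:
        return None
    hit: Optional[Barcode] = None
    for bc in bset:
        if hamming(observed, bc.seq) <= max_mm:
            if hit is not None:
                return AMBIGUOUS
            hit = bc
    return hit


# ----------------------------------------------------------- outcome types


class Category(str, Enum):
    """Classification of one read pair."""

    ASSIGNED = "assigned"
    UNKNOWN_BARCODE = "unknown_barcode"
    INVALID_COMBINATION = "invalid_combination"
    HEAD_MISMATCH = "head_mismatch"
    PRIMER_MISMATCH = "primer_mismatch"
    AMBIGUOUS = "ambiguous"
    STRUCTURAL = "structural"  # read shorter than barcode+head+primer


# how far a parse got; higher rank = more informative outcome
_RANK = {
    Category.STRUCTURAL: 0,
    Category.HEAD_MISMATCH: 1,
    Category.PRIMER_MISMATCH: 2,
    Category.UNKNOWN_BARCODE: 3,
    Category.AMBIGUOUS: 4,
    Category.INVALID_COMBINATION: 5,
    Category.ASSIGNED: 6,
}


@dataclass
class DemuxParams:
    """Mismatch tolerances and matching options.

    Defaults mirror standard practice for this read layout: one substitution
    allowed in the barcode, two in the 16-nt head and in the primer.
    """

    max_mm_barcode: int = 1
    max_mm_head: int = 2
    max_mm_primer: int = 2
    try_both_orientations: bool = True
    write_unassigned: bool = False

    def __post_init__(self) -> None:
        if min(self.max_mm_barcode, self.max_mm_head, self.max_mm_primer) < 0:
            raise ValueError("mismatch tolerances must be >= 0")

    def check_against(self, bset: BarcodeSet) -> Optional[str]:
        """Warn-text if the barcode tolerance can make decoding ambiguous."""
        import math
        if len(bset) < 2:
            return None
        d = bset.min_distance
        if self.max_mm_barcode >= math.ceil(d / 2):
            return (f"max_mm_barcode={self.max_mm_barcode} >= ceil({d}/2): "
                    "distinct barcodes may become indistinguishable")
        return None


@dataclass(frozen=True)
class Read:
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence and quality lengths differ")


@dataclass(frozen=True)
class ReadPair:
    """One paired-end FASTQ record."""

    id: str
    r1: Read
    r2: Read


@dataclass
class ParsedStart:
    """Successful anchored parse of one read's technical prefix."""

    barcode_obs: str
    head_mm: int
    primer_mm: int
    insert_offset: int


def parse_read_start(
    seq: str,
    barcode_len: int,
    head: str,
    primer: str,
    params: DemuxParams,
) -> Union[ParsedStart, Category]:
    """Parse barcode/head/primer at the start of a read (anchored, indel-free).

    Returns a :class:`ParsedStart` on success, otherwise the failure
    :class:`Category` (``STRUCTURAL`` for a too-short read, then
    ``HEAD_MISMATCH`` / ``PRIMER_MISMATCH`` in layout order).
    """
    offset = barcode_len + HEAD_LENGTH + len(primer)
    if len(seq) < offset:
        return Category.STRUCTURAL
    obs_head = seq[barcode_len : barcode_len + HEAD_LENGTH]
    hmm = match_iupac(head, obs_head, params.max_mm_head)
    if hmm is None:
        return Category.HEAD_MISMATCH
    obs_primer = seq[barcode_len + HEAD_LENGTH : offset]
    pmm = match_iupac(primer, obs_primer, params.max_mm_primer)
    if pmm is None:
        return Category.PRIMER_MISMATCH
    return ParsedStart(
        barcode_obs=seq[:barcode_len],
        head_mm=hmm,
        primer_mm=pmm,
        insert_offset=offset,
    )


@dataclass
class DemuxOutcome:
    """Classification of one read pair.

    For assigned pairs, ``insert_fwd`` is the trimmed insert of whichever
    read matched the forward (H1) side — i.e. it is orientation-normalised
    and reads in template orientation — and ``insert_rev`` the other side's.
    """

    category: Category
    sample_id: Optional[str] = None
    bc_fwd: Optional[str] = None
    bc_rev: Optional[str] = None
    orientation: Optional[str] = None  # "A": r1 = forward side; "B": swapped
    insert_fwd: Optional[Read] = None
    insert_rev: Optional[Read] = None


def _try_orientation(
    fwd: Read, rev: Read, decoder: Decoder, primer_name: str, params: DemuxParams
) -> DemuxOutcome:
    pp = decoder.primer_pairs[primer_name]
    p_fwd = parse_read_start(
        fwd.seq, decoder.fwd_set.length, decoder.scheme.fwd_head.seq,
        pp.fwd, params)
    if isinstance(p_fwd, Category):
        return DemuxOutcome(category=p_fwd)
    p_rev = parse_read_start(
        rev.seq, decoder.rev_set.length, decoder.scheme.rev_head.seq,
        pp.rev, params)
    if isinstance(p_rev, Category):
        return DemuxOutcome(category=p_rev)

    m_fwd = match_barcode(p_fwd.barcode_obs, decoder.fwd_set, params.max_mm_barcode)
    m_rev = match_barcode(p_rev.barcode_obs, decoder.rev_set, params.max_mm_barcode)
    if m_fwd is None or m_rev is None:
        return DemuxOutcome(category=Category.UNKNOWN_BARCODE)
    if m_fwd is AMBIGUOUS or m_rev is AMBIGUOUS:
        return DemuxOutcome(category=Category.AMBIGUOUS)
    assert isinstance(m_fwd, Barcode) and isinstance(m_rev, Barcode)

    sample = decoder.lookup(m_fwd.seq, m_rev.seq)
    if sample is None:
        return DemuxOutcome(
            category=Category.INVALID_COMBINATION,
            bc_fwd=m_fwd.seq, bc_rev=m_rev.seq)
    return DemuxOutcome(
        category=Category.ASSIGNED,
        sample_id=sample,
        bc_fwd=m_fwd.seq,
        bc_rev=m_rev.seq,
        insert_fwd=Read(fwd.seq[p_fwd.insert_offset:], fwd.qual[p_fwd.insert_offset:]),
        insert_rev=Read(rev.seq[p_rev.insert_offset:], rev.qual[p_rev.insert_offset:]),
    )


def demultiplex_pair(
    rp: ReadPair,
    decoder: Decoder,
    params: Optional[DemuxParams] = None,
    primer_pair: Optional[str] = None,
) -> DemuxOutcome:
    """Classify one read pair against a sample-sheet decoder.

    Orientation A (r1 = forward/H1 side) is tried first, then orientation B
    with the reads swapped (when ``try_both_orientations`` is on). The more
    informative outcome wins; if both orientations assign the pair to
    *different* samples the pair is rejected as ambiguous.
    """
    params = params or DemuxParams()
    if primer_pair is None:
        primer_pair = next(iter(decoder.primer_pairs))
    out_a = _try_orientation(rp.r1, rp.r2, decoder, primer_pair, params)
    out_a.orientation = "A"
    if not params.try_both_orientations:
        return out_a
    out_b = _try_orientation(rp.r2, rp.r1, decoder, primer_pair, params)
    out_b.orientation = "B"
    if (out_a.category is Category.ASSIGNED
            and out_b.category is Category.ASSIGNED):
        if out_a.sample_id == out_b.sample_id:
            return out_a
        return DemuxOutcome(category=Category.AMBIGUOUS)
    return out_a if _RANK[out_a.category] >= _RANK[out_b.category] else out_b


# --------------------------------------------------------------- file-level


class PairedFastqError(IOError):
    """Desynchronised or truncated paired FASTQ input."""


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _strip_mate(read_id: str) -> str:
    head = read_id.split()[0]
    return head[:-2] if head.endswith(("/1", "/2")) else head


def iter_read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream synchronised read pairs from two (optionally gzipped) FASTQs."""
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        idx = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise PairedFastqError(
                    f"paired FASTQs desynchronised: one file ended at record {idx}")
            (id1, seq1, q1), (id2, seq2, q2) = rec1, rec2
            if _strip_mate(id1) != _strip_mate(id2):
                raise PairedFastqError(
                    f"read id mismatch at record {idx}: {id1!r} vs {id2!r}")
            yield ReadPair(_strip_mate(id1), Read(seq1, q1), Read(seq2, q2))
            idx += 1


@dataclass
class DemuxStats:
    """Aggregate demultiplexing statistics.

    ``yield_fraction`` follows the pool-level yield definition: assigned
    read pairs over total read pairs, before any quality filtering.
    """

    total: int = 0
    category_counts: Counter = field(default_factory=Counter)
    per_sample: Counter = field(default_factory=Counter)
    insert_counts: dict[str, Counter] = field(default_factory=dict)

    @property
    def yield_fraction(self) -> float:
        if self.total == 0:
            return 0.0
        return self.category_counts.get(Category.ASSIGNED.value, 0) / self.total

    def add(self, outcome: DemuxOutcome, collect_counts: bool) -> None:
        self.total += 1
        self.category_counts[outcome.category.value] += 1
        if outcome.category is Category.ASSIGNED:
            assert outcome.sample_id is not None
            self.per_sample[outcome.sample_id] += 1
            if collect_counts:
                assert outcome.insert_fwd is not None
                self.insert_counts.setdefault(outcome.sample_id, Counter())[
                    outcome.insert_fwd.seq] += 1

    def to_json(self) -> str:
        return json.dumps({
            "total": self.total,
            "yield": self.yield_fraction,
            "categories": dict(self.category_counts),
            "per_sample": dict(self.per_sample),
        }, indent=2, sort_keys=True)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"total\t{self.total}\n")
            fh.write(f"yield\t{self.yield_fraction:.6f}\n")
            for cat in Category:
                fh.write(f"category:{cat.value}\t"
                         f"{self.category_counts.get(cat.value, 0)}\n")
            for sid in sorted(self.per_sample):
                fh.write(f"sample:{sid}\t{self.per_sample[sid]}\n")


def _fastq_record(read_id: str, read: Read) -> str:
    return f"@{read_id}\n{read.seq}\n+\n{read.qual}\n"


def run_demux(
    r1_path: str | Path,
    r2_path: str | Path,
    sheet: SampleSheet,
    params: Optional[DemuxParams] = None,
    outdir: str | Path | None = None,
    collect_counts: bool = True,
) -> DemuxStats:
    """Demultiplex a paired FASTQ into per-sample trimmed FASTQ pairs.

    For each assigned sample, ``<sample>_R1.fastq.gz`` holds the trimmed
    insert of the forward-(H1-)side read (orientation-normalised) and
    ``_R2`` the reverse side. With ``params.write_unassigned``, rejected
    pairs go untrimmed to ``unassigned_<category>_R{1,2}.fastq.gz``.
    Category counts always partition the total pair count.
    """
    params = params or DemuxParams()
    decoder = build_decoder(sheet)
    stats = DemuxStats()
    handles: dict[str, tuple] = {}

    def _get_handles(name: str):
        if name not in handles and outdir is not None:
            base = Path(outdir)
            base.mkdir(parents=True, exist_ok=True)
            handles[name] = (
                gzip.open(base / f"{name}_R1.fastq.gz", "wt"),
                gzip.open(base / f"{name}_R2.fastq.gz", "wt"),
            )
        return handles.get(name)

    try:
        for rp in iter_read_pairs(r1_path, r2_path):
            primer = sheet.records[0].primer_pair if sheet.records else None
            out = demultiplex_pair(rp, decoder, params, primer_pair=primer)
            stats.add(out, collect_counts)
            if out.category is Category.ASSIGNED and outdir is not None:
                assert out.sample_id and out.insert_fwd and out.insert_rev
                h = _get_handles(out.sample_id)
                if h:
                    h[0].write(_fastq_record(rp.id, out.insert_fwd))
                    h[1].write(_fastq_record(rp.id, out.insert_rev))
            elif (out.category is not Category.ASSIGNED
                  and params.write_unassigned and outdir is not None):
                h = _get_handles(f"unassigned_{out.category.value}")
                if h:
                    h[0].write(_fastq_record(rp.id, rp.r1))
                    h[1].write(_fastq_record(rp.id, rp.r2))
    finally:
        for h1, h2 in handles.values():
            h1.close()
            h2.close()
    return stats
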