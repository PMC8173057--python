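"""Ground-truthed simulation of multiplexed barcoded amplicon reads.

Generates paired-end FASTQ data with the two-step-PCR read layout
(barcode + 16-nt head + target primer + insert) for any barcoding scheme
and sample sheet, so the demultiplexer and evaluation metrics can be tested
end-to-end without sequencing data. The simulator covers:

* mock-community composition sampling — multinomial draws over the
  reference's per-16S-gene relative abundances (default draw size 2,438
  read pairs, 100 replicates for count-only simulation);
* read construction per scheme, with degenerate primer positions resolved
  uniformly at random per read and reverse-side inserts reverse-complemented;
* independent per-base substitution errors at rate ``error_rate``;
* barcode-swap (index-hopping) events at rate ``swap_rate``: one randomly
  chosen side's barcode is replaced by a barcode in use by a *different*
  sample on that side.

Every emitted read pair is recorded in a manifest (true sample, true
template, injected edits, swap events), which is the ground truth for
round-trip and misassignment measurements.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .demultiplexer import IUPAC_SETS, Read, ReadPair, revcomp
from .scheme_layout import (
    PRIMER_PAIRS,
    PrimerPair,
    SampleRecord,
    SampleSheet,
    Scheme,
)

# ------------------------------------------------------------ mock reference


@dataclass(frozen=True)
class MockVariant:
    """One 16S gene variant of a mock-community member.

    Non-identical intragenomic 16S copies are separate variants (they
    dereplicate into separate ASVs); ``weight`` is the variant's relative
    abundance at the 16S-gene level, across the whole community.
    """

    variant_id: str
    species: str
    seq: str
    weight: float


class MockReference:
    """A defined community: 16S variants with per-gene relative abundances."""

    def __init__(self, variants: Sequence[MockVariant]):
        self.variants = list(variants)
        if not self.variants:
            raise ValueError("mock reference needs >= 1 variant")
        for v in self.variants:
            if not v.seq or set(v.seq) - set("ACGT"):
                raise ValueError(f"variant {v.variant_id}: non-ACGT sequence")
            if v.weight < 0:
                raise ValueError(f"variant {v.variant_id}: negative weight")
        total = sum(v.weight for v in self.variants)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant weights sum to {total}, expected 1")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def probs(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants])

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def species_abundance(self) -> dict[str, float]:
        """Theoretical relative abundance aggregated to species."""
        out: dict[str, float] = {}
        for v in self.variants:
            out[v.species] = out.get(v.species, 0.0) + v.weight
        return out

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_files(cls, fasta: str | Path, abundance_tsv: str | Path
                   ) -> "MockReference":
        """Load variants from FASTA plus a (variant, species, abundance) TSV."""
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(fasta), "fasta")}
        tab = pd.read_csv(abundance_tsv, sep="\t", comment="#")
        required = {"variant", "species", "abundance"}
        if not required <= set(tab.columns):
            raise ValueError(f"abundance TSV needs columns {sorted(required)}")
        variants = []
        for _, row in tab.iterrows():
            vid = str(row["variant"])
            if vid not in seqs:
                raise ValueError(f"variant {vid} missing from FASTA")
            variants.append(MockVariant(vid, str(row["species"]),
                                        seqs[vid], float(row["abundance"])))
        return cls(variants)

    def to_files(self, fasta: str | Path, abundance_tsv: str | Path) -> None:
        records = [SeqRecord(Seq(v.seq), id=v.variant_id, description=v.species)
                   for v in self.variants]
        SeqIO.write(records, str(fasta), "fasta")
        pd.DataFrame(
            {"variant": [v.variant_id for v in self.variants],
             "species": [v.species for v in self.variants],
             "abundance": [v.weight for v in self.variants]}
        ).to_csv(abundance_tsv, sep="\t", index=False)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def default_mock_reference(
    n_species: int = 8,
    insert_len: int = 150,
    seed: int = 7,
) -> MockReference:
    """A synthetic staggered (log-distributed) mock community.

    Species abundances are spaced by factors of 10 (normalised), mirroring
    the design of commercial log-distribution DNA standards; the two most
    abundant members carry two non-identical intragenomic 16S variants
    (5 substitutions apart, split 60/40 within the species). Sequences are
    random DNA — this is a synthetic stand-in, not real 16S data.
    """
    rng = np.random.default_rng(seed)
    raw = np.array([10.0 ** (-i) for i in range(n_species)])
    raw /= raw.sum()
    variants: list[MockVariant] = []
    for i in range(n_species):
        species = f"species_{i + 1:02d}"
        base = _random_dna(rng, insert_len)
        if i < 2:
            # second intragenomic 16S copy, 5 substitutions away
            alt = list(base)
            for pos in rng.choice(insert_len, size=5, replace=False):
                alt[pos] = rng.permuted([b for b in "ACGT" if b != alt[pos]])[0]
            variants.append(MockVariant(f"{species}_16S_1", species, base,
                                        raw[i] * 0.6))
            variants.append(MockVariant(f"{species}_16S_2", species, "".join(alt),
                                        raw[i] * 0.4))
        else:
            variants.append(MockVariant(f"{species}_16S_1", species, base, raw[i]))
    return MockReference(variants)


# --------------------------------------------------------- count simulation


def simulate_mock_counts(
    ref: MockReference,
    size: int = 2438,
    reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Multinomial count vectors over mock variants.

    Per-gene relative abundances serve as multinomial probabilities; each of
    ``reps`` replicates is one draw of ``size`` simulated read pairs.
    Returns an (reps, n_variants) integer array; deterministic given seed.
    """
    if size < 0:
        raise ValueError("size must be >= 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    probs = ref.probs  # MockReference already validated the sum
    rng = np.random.default_rng(seed)
    return rng.multinomial(size, probs, size=reps)


# ----------------------------------------------------------- read building


def expand_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Resolve degenerate positions uniformly at random (seeded)."""
    out = []
    for ch in pattern:
        opts = sorted(IUPAC_SETS[ch])
        out.append(opts[0] if len(opts) == 1 else
                   opts[int(rng.integers(len(opts)))])
    return "".join(out)


def build_read_pair(
    insert: str,
    record: SampleRecord,
    scheme: Scheme,
    primer_pair: PrimerPair,
    orientation: str = "A",
    rng: Optional[np.random.Generator] = None,
    qual_char: str = "I",
    read_id: str = "read",
) -> ReadPair:
    """Construct one error-free read pair for a sample.

    The forward-side read is ``bc1 + H1 + fwd-primer + insert``; the
    reverse-side read is ``bc2 + rev-head + rev-primer + revcomp(insert)``
    (SB uses bc1 on both sides). Orientation "A" puts the forward side on
    R1, "B" swaps the reads.
    """
    if not insert:
        raise ValueError("insert must be >= 1 nt")
    if orientation not in ("A", "B"):
        raise ValueError("orientation must be 'A' or 'B'")
    rng = rng if rng is not None else np.random.default_rng(0)
    bc_rev = record.bc2 if record.bc2 is not None else record.bc1
    fwd_seq = (record.bc1.seq + scheme.fwd_head.seq
               + expand_iupac(primer_pair.fwd, rng) + insert)
    rev_seq = (bc_rev.seq + scheme.rev_head.seq
               + expand_iupac(primer_pair.rev, rng) + revcomp(insert))
    fwd = Read(fwd_seq, qual_char * len(fwd_seq))
    rev = Read(rev_seq, qual_char * len(rev_seq))
    if orientation == "A":
        return ReadPair(read_id, fwd, rev)
    return ReadPair(read_id, rev, fwd)


# ---------------------------------------------------------- error injection


def inject_errors(
    rp: ReadPair,
    error_rate: float,
    rng: Union[int, np.random.Generator] = 0,
) -> tuple[ReadPair, list[tuple[str, int, str, str]]]:
    """Apply independent per-base substitutions at the given rate.

    Each base is substituted, with probability ``error_rate``, to a
    uniformly chosen *different* base. Returns the mutated pair and the
    edit list as (read, position, old, new) tuples.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    edits: list[tuple[str, int, str, str]] = []
    new_reads = {}
    for label, read in (("r1", rp.r1), ("r2", rp.r2)):
        if error_rate == 0.0:
            new_reads[label] = read
            continue
        seq = list(read.seq)
        hits = np.flatnonzero(gen.random(len(seq)) < error_rate)
        for pos in hits:
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            new = choices[int(gen.integers(3))]
            seq[pos] = new
            edits.append((label, int(pos), old, new))
        new_reads[label] = Read("".join(seq), read.qual)
    return ReadPair(rp.id, new_reads["r1"], new_reads["r2"]), edits


def inject_barcode_substitutions(
    rp: ReadPair,
    n_subs: int,
    barcode_len: int,
    rng: Union[int, np.random.Generator] = 0,
    sides: Sequence[str] = ("r1", "r2"),
) -> ReadPair:
    """Place exactly ``n_subs`` substitutions inside each chosen read's
    barcode region (positions [0, barcode_len)). Used to probe the
    demultiplexer's mismatch tolerance at a controlled error weight."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    reads = {"r1": rp.r1, "r2": rp.r2}
    for side in sides:
        read = reads[side]
        seq = list(read.seq)
        for pos in gen.choice(barcode_len, size=n_subs, replace=False):
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            seq[pos] = choices[int(gen.integers(3))]
        reads[side] = Read("".join(seq), read.qual)
    return ReadPair(rp.id, reads["r1"], reads["r2"])


# ------------------------------------------------------- crosstalk injection


def _side_usage(sheet: SampleSheet) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Map barcode seq -> sample ids using it, per side (fwd, rev)."""
    fwd: dict[str, set[str]] = {}
    rev: dict[str, set[str]] = {}
    for r in sheet.records:
        if sheet.scheme is Scheme.SB:
            fwd.setdefault(r.bc1.seq, set()).add(r.sample_id)
            rev.setdefault(r.bc1.seq, set()).add(r.sample_id)
        elif sheet.scheme is Scheme.UDB_H11:
            assert r.bc2 is not None
            for s in (r.bc1.seq, r.bc2.seq):  # H11 sides are interchangeable
                fwd.setdefault(s, set()).add(r.sample_id)
                rev.setdefault(s, set()).add(r.sample_id)
        else:
            assert r.bc2 is not None
            fwd.setdefault(r.bc1.seq, set()).add(r.sample_id)
            rev.setdefault(r.bc2.seq, set()).add(r.sample_id)
    return fwd, rev


def inject_crosstalk(
    pairs: Sequence[ReadPair],
    meta: Sequence[dict],
    swap_rate: float,
    sheet: SampleSheet,
    rng: Union[int, np.random.Generator] = 0,
) -> tuple[list[ReadPair], list[dict]]:
    """Inject barcode-swap (index-hopping) events into a read stream.

    With probability ``swap_rate`` per pair, one uniformly chosen side's
    barcode is replaced by a barcode in use on that side by a different
    sample, excluding the barcode on the un-swapped side (a hop between a
    pair's own two tags is not between-sample crosstalk). ``meta`` rows must
    carry ``sample_id`` and ``orientation``; swap events are recorded
    in-place on copies (``swapped``, ``swap_side``, ``swap_to``).
    """
    if not 0.0 <= swap_rate <= 1.0:
        raise ValueError("swap_rate must be in [0, 1]")
    if swap_rate > 0 and len(sheet) < 2:
        raise ValueError("crosstalk injection needs >= 2 samples")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    fwd_use, rev_use = _side_usage(sheet)
    bc_len = len(sheet.records[0].bc1.seq)
    out_pairs: list[ReadPair] = []
    out_meta: list[dict] = []
    for rp, row in zip(pairs, meta):
        row = dict(row)
        row.setdefault("swapped", False)
        row.setdefault("swap_side", "")
        row.setdefault("swap_to", "")
        if swap_rate > 0 and gen.random() < swap_rate:
            first = ("fwd", "rev")[int(gen.integers(2))]
            # fall back to the other side if the chosen one has no legal
            # replacement (tiny sheets), so the effective rate stays `swap_rate`
            for side in (first, "rev" if first == "fwd" else "fwd"):
                usage = fwd_use if side == "fwd" else rev_use
                # which physical read carries this side depends on orientation
                read_label = ("r1" if row["orientation"] == "A" else "r2")
                if side == "rev":
                    read_label = "r2" if read_label == "r1" else "r1"
                reads = {"r1": rp.r1, "r2": rp.r2}
                cur = reads[read_label].seq[:bc_len]
                other_label = "r2" if read_label == "r1" else "r1"
                other = reads[other_label].seq[:bc_len]
                sid = row["sample_id"]
                candidates = sorted(
                    s for s, owners in usage.items()
                    if owners - {sid} and s != cur and s != other)
                if candidates:
                    new_bc = candidates[int(gen.integers(len(candidates)))]
                    read = reads[read_label]
                    reads[read_label] = Read(new_bc + read.seq[bc_len:],
                                             read.qual)
                    rp = ReadPair(rp.id, reads["r1"], reads["r2"])
                    row.update(swapped=True, swap_side=side, swap_to=new_bc)
                    break
        out_pairs.append(rp)
        out_meta.append(row)
    return out_pairs, out_meta


# ------------------------------------------------------------- full pipeline

#: Per-sample template source markers for :class:`SimConfig`.
MOCK = "mock"
BLANK = "blank"


@dataclass
class SimConfig:
    """Configuration of one simulated multiplexed sequencing run.

    ``sample_sources`` maps sample ids to :data:`MOCK` (draw templates from
    ``reference``), :data:`BLANK` (negative control, emits no reads), or an
    explicit composition — a list of (sequence, weight) pairs. Samples not
    listed default to :data:`MOCK`. ``reads_per_sample`` defaults to 2,438,
    the standard mock draw size used throughout.
    """

    sheet: SampleSheet
    reference: Optional[MockReference] = None
    sample_sources: Optional[dict[str, object]] = None
    reads_per_sample: int = 2438
    error_rate: float = 0.0
    swap_rate: float = 0.0
    orientation: str = "A"  # "A", "B" or "random"
    qual_char: str = "I"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")
        for name in ("error_rate", "swap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.orientation not in ("A", "B", "random"):
            raise ValueError("orientation must be 'A', 'B' or 'random'")
        srcs = self.sample_sources or {}
        unknown = set(srcs) - set(self.sheet.sample_ids())
        if unknown:
            raise ValueError(f"sources for samples not in sheet: {sorted(unknown)}")
        needs_mock = (self.sample_sources is None
                      or any(s == MOCK for s in srcs.values())
                      or len(srcs) < len(self.sheet))
        if needs_mock and self.reference is None:
            raise ValueError("a MockReference is required for mock-source samples")


@dataclass
class SimResult:
    """Outputs of :func:`simulate_run` / :func:`simulate_pairs`."""

    pairs: list[ReadPair]
    manifest: pd.DataFrame
    variant_seqs: dict[str, str]
    r1_path: Optional[Path] = None
    r2_path: Optional[Path] = None

    def truth_table(self) -> pd.DataFrame:
        """Per-sample true template counts (variants × samples)."""
        if self.manifest.empty:
            return pd.DataFrame()
        return (self.manifest.groupby(["variant_id", "sample_id"])
                .size().unstack(fill_value=0))


def simulate_pairs(config: SimConfig) -> SimResult:
    """Simulate the read stream in memory (see :func:`simulate_run`)."""
    ss = np.random.SeedSequence(config.seed)
    comp_rng, build_rng, swap_rng, err_rng, shuf_rng = (
        np.random.default_rng(c) for c in ss.spawn(5))
    sheet = config.sheet
    srcs = config.sample_sources or {}
    pp = PRIMER_PAIRS  # sheet primer names resolved against the registry

    pairs: list[ReadPair] = []
    meta: list[dict] = []
    variant_seqs: dict[str, str] = {}

    for record in sheet.records:
        source = srcs.get(record.sample_id, MOCK)
        if source == BLANK:
            continue
        if source == MOCK:
            assert config.reference is not None
            vids = config.reference.variant_ids
            vseqs = {v.variant_id: v.seq for v in config.reference.variants}
            probs = config.reference.probs
        else:
            comp = list(source)  # type: ignore[arg-type]
            vids = [f"{record.sample_id}:v{i}" for i in range(len(comp))]
            vseqs = {vid: seq for vid, (seq, _) in zip(vids, comp)}
            w = np.array([float(wt) for _, wt in comp])
            if w.sum() <= 0:
                raise ValueError(
                    f"sample {record.sample_id}: non-positive weights")
            probs = w / w.sum()
        variant_seqs.update(vseqs)
        counts = comp_rng.multinomial(config.reads_per_sample, probs)
        primer = pp[record.primer_pair]
        i = 0
        for vid, n in zip(vids, counts):
            for _ in range(int(n)):
                orient = (config.orientation if config.orientation != "random"
                          else ("A", "B")[int(build_rng.integers(2))])
                rp = build_read_pair(
                    vseqs[vid], record, sheet.scheme, primer,
                    orientation=orient, rng=build_rng,
                    qual_char=config.qual_char,
                    read_id=f"sim_{record.sample_id}_{i}")
                pairs.append(rp)
                meta.append({"read_id": rp.id, "sample_id": record.sample_id,
                             "variant_id": vid, "orientation": orient})
                i += 1

    if config.swap_rate > 0:
        pairs, meta = inject_crosstalk(pairs, meta, config.swap_rate,
                                       sheet, swap_rng)
    else:
        meta = [dict(row, swapped=False, swap_side="", swap_to="")
                for row in meta]

    if config.error_rate > 0:
        mutated = []
        for rp, row in zip(pairs, meta):
            rp, edits = inject_errors(rp, config.error_rate, err_rng)
            row["n_subs_r1"] = sum(1 for e in edits if e[0] == "r1")
            row["n_subs_r2"] = sum(1 for e in edits if e[0] == "r2")
            mutated.append(rp)
        pairs = mutated
    else:
        for row in meta:
            row["n_subs_r1"] = 0
            row["n_subs_r2"] = 0

    order = shuf_rng.permutation(len(pairs))
    pairs = [pairs[int(i)] for i in order]
    meta = [meta[int(i)] for i in order]
    manifest = pd.DataFrame(
        meta, columns=["read_id", "sample_id", "variant_id", "orientation",
                       "swapped", "swap_side", "swap_to",
                       "n_subs_r1", "n_subs_r2"])
    return SimResult(pairs=pairs, manifest=manifest, variant_seqs=variant_seqs)


def simulate_run(config: SimConfig, outdir: str | Path) -> SimResult:
    """Simulate a multiplexed run and write its artefacts.

    Writes ``reads_R1.fastq.gz`` / ``reads_R2.fastq.gz`` (sample-shuffled),
    ``manifest.tsv`` (per-read ground truth) and ``truth_counts.tsv``
    (variants × samples) under ``outdir``. Byte-identical given the same
    config and seed.
    """
    res = simulate_pairs(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r1_path = outdir / "reads_R1.fastq.gz"
    r2_path = outdir / "reads_R2.fastq.gz"
    # mtime=0 keeps gzip output byte-identical across runs
    with gzip.GzipFile(r1_path, "wb", mtime=0) as g1, \
            gzip.GzipFile(r2_path, "wb", mtime=0) as g2:
        for rp in res.pairs:
            g1.write(f"@{rp.id}\n{rp.r1.seq}\n+\n{rp.r1.qual}\n".encode())
            g2.write(f"@{rp.id}\n{rp.r2.seq}\n+\n{rp.r2.qual}\n".encode())
    res.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    truth = res.truth_table()
    truth.to_csv(outdir / "truth_counts.tsv", sep="\t")
    res.r1_path = r1_path
    res.r2_path = r2_path
    return res
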