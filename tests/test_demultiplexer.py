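"""Anchored mismatch-tolerant matching, pair classification and file demux."""

import gzip

import numpy as np
import pytest

from amplimux import (
    AMBIGUOUS,
    Barcode,
    BarcodeSet,
    Category,
    DemuxParams,
    PRIMER_PAIRS,
    Read,
    ReadPair,
    Scheme,
    assign_samples,
    build_decoder,
    build_read_pair,
    demultiplex_pair,
    hamming,
    match_barcode,
    match_iupac,
    parse_read_start,
    run_demux,
    simulate_run,
    SimConfig,
)
from amplimux.demultiplexer import PairedFastqError, iter_read_pairs
from amplimux.synthetic_amplicons import expand_iupac


def _bset(seqs):
    return BarcodeSet([Barcode(f"b{i}", s) for i, s in enumerate(seqs)])


class TestMatchBarcode:
    def test_exact_member(self, bc12):
        assert match_barcode(bc12[3].seq, bc12, max_mm=1) is bc12[3]

    def test_single_mismatch_resolves_uniquely(self, bc12):
        mutated = "T" + bc12[0].seq[1:] if bc12[0].seq[0] != "T" \
            else "A" + bc12[0].seq[1:]
        assert match_barcode(mutated, bc12, max_mm=1) is bc12[0]

    def test_tie_is_ambiguous(self):
        assert match_barcode("AATT", _bset(["AAAA", "TTTT"]), 2) is AMBIGUOUS

    def test_no_match_returns_none(self, bc12):
        # two substitutions exceed tolerance 1; min distance 5 keeps all
        # other barcodes at distance >= 3
        seq = list(bc12[0].seq)
        seq[0] = "A" if seq[0] != "A" else "C"
        seq[1] = "A" if seq[1] != "A" else "C"
        assert match_barcode("".join(seq), bc12, max_mm=1) is None

    def test_wrong_length_is_none(self, bc12):
        assert match_barcode("ACGT", bc12, max_mm=1) is None

    def test_single_mutants_never_cross_barcodes(self, bc12):
        """With min distance >= 3 and tolerance 1, no single substitution of
        any barcode can be claimed by a different barcode (exhaustive)."""
        assert bc12.min_distance >= 3
        for bc in bc12:
            for pos in range(len(bc.seq)):
                for base in "ACGT":
                    if base == bc.seq[pos]:
                        continue
                    mut = bc.seq[:pos] + base + bc.seq[pos + 1:]
                    hit = match_barcode(mut, bc12, max_mm=1)
                    assert hit is bc


class TestMatchIupac:
    def test_degenerate_positions_match_their_expansion(self):
        pattern = PRIMER_PAIRS["515F-806R"].fwd  # GTGYCAGCMGCCGCGGTAA
        observed = pattern.replace("Y", "C").replace("M", "A")
        assert match_iupac(pattern, observed, 2) == 0

    def test_exact_match_no_degeneracy(self):
        assert match_iupac("ACGT", "ACGT", 0) == 0

    def test_exceeding_tolerance_fails(self):
        assert match_iupac("AC", "TG", 1) is None

    def test_n_matches_everything(self):
        assert match_iupac("NNNN", "ACGT", 0) == 0

    def test_invalid_pattern_char(self):
        with pytest.raises(ValueError, match="IUPAC"):
            match_iupac("ACGX", "ACGT", 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            match_iupac("ACG", "ACGT", 1)


class TestParseReadStart:
    PARAMS = DemuxParams()

    def _read(self, bc12):
        rng = np.random.default_rng(0)
        primer = expand_iupac(PRIMER_PAIRS["515F-806R"].fwd, rng)
        return bc12[0].seq + Scheme.UDB_H12.fwd_head.seq + primer + "ACGT" * 30

    def test_insert_offset_is_47_for_v4_forward(self, bc12):
        parsed = parse_read_start(
            self._read(bc12), 12, Scheme.UDB_H12.fwd_head.seq,
            PRIMER_PAIRS["515F-806R"].fwd, self.PARAMS)
        assert parsed.insert_offset == 12 + 16 + 19 == 47
        assert parsed.barcode_obs == bc12[0].seq
        assert parsed.head_mm == 0 and parsed.primer_mm == 0

    def test_three_head_substitutions_fail(self, bc12):
        read = self._read(bc12)
        head = list(read[12:28])
        for i in range(3):
            head[i] = "A" if head[i] != "A" else "C"
        read = read[:12] + "".join(head) + read[28:]
        assert parse_read_start(
            read, 12, Scheme.UDB_H12.fwd_head.seq,
            PRIMER_PAIRS["515F-806R"].fwd, self.PARAMS) is Category.HEAD_MISMATCH

    def test_too_short_read_is_structural(self, bc12):
        assert parse_read_start(
            "ACGT" * 10, 12, Scheme.UDB_H12.fwd_head.seq,
            PRIMER_PAIRS["515F-806R"].fwd, self.PARAMS) is Category.STRUCTURAL


def _mutate(seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        out[p] = "A" if out[p] != "A" else "C"
    return "".join(out)


class TestDemultiplexPair:
    @pytest.mark.parametrize("scheme", list(Scheme))
    @pytest.mark.parametrize("orientation", ["A", "B"])
    def test_error_free_roundtrip(self, scheme, orientation, sheets):
        sheet = sheets[scheme]
        dec = build_decoder(sheet)
        record = sheet.records[2]
        insert = "ACGTTGCA" * 20
        rp = build_read_pair(insert, record, scheme,
                             PRIMER_PAIRS[record.primer_pair],
                             orientation=orientation,
                             rng=np.random.default_rng(1))
        out = demultiplex_pair(rp, dec)
        assert out.category is Category.ASSIGNED
        assert out.sample_id == record.sample_id
        assert out.orientation == orientation
        assert out.insert_fwd.seq == insert  # trimming recovers the template

    def test_udb_h12_swap_is_invalid_combination(self, sheets):
        """Swapping the reverse barcode to another sample's reverse barcode
        must be flagged, not assigned (enumerated over samples)."""
        sheet = sheets[Scheme.UDB_H12]
        dec = build_decoder(sheet)
        for record in sheet.records:
            foreign = next(r.bc2 for r in sheet.records
                           if r.sample_id != record.sample_id)
            rp = build_read_pair("ACGT" * 40, record, Scheme.UDB_H12,
                                 PRIMER_PAIRS[record.primer_pair],
                                 rng=np.random.default_rng(0))
            r2 = Read(foreign.seq + rp.r2.seq[12:], rp.r2.qual)
            out = demultiplex_pair(ReadPair(rp.id, rp.r1, r2), dec)
            assert out.category in (Category.INVALID_COMBINATION,
                                    Category.ASSIGNED)
            if out.category is Category.ASSIGNED:
                # only legal when the swap recreated the sample's own pair
                assert out.sample_id == record.sample_id
            else:
                assert out.sample_id is None

    def test_cdb_swap_can_misassign(self, bc12):
        """On a fully-used CDB sheet the swapped pair IS another sample's —
        the crosstalk risk inherent to combinatorial barcoding."""
        sub = BarcodeSet(list(bc12)[:3])
        ids = [f"s{i}" for i in range(6)]  # 3*(3-1) pairs, fully used
        sheet = assign_samples(Scheme.CDB_H12, ids, sub, seed=0)
        dec = build_decoder(sheet)
        record = sheet.records[0]
        other_rev = next(r.bc2 for r in sheet.records
                         if r.bc2.seq not in (record.bc2.seq, record.bc1.seq))
        rp = build_read_pair("ACGT" * 40, record, Scheme.CDB_H12,
                             PRIMER_PAIRS[record.primer_pair],
                             rng=np.random.default_rng(0))
        r2 = Read(other_rev.seq + rp.r2.seq[12:], rp.r2.qual)
        out = demultiplex_pair(ReadPair(rp.id, rp.r1, r2), dec)
        assert out.category is Category.ASSIGNED
        assert out.sample_id != record.sample_id

    def test_barcode_tie_rejected_as_ambiguous(self):
        bcs = _bset(["AAAAAAAATTTTTTTT", "TTTTTTTTAAAAAAAA"])
        sheet = assign_samples(Scheme.UDB_H12, ["s0", "s1"], bcs, seed=0)
        dec = build_decoder(sheet)
        record = sheet.records[0]
        rp = build_read_pair("ACGT" * 40, record, Scheme.UDB_H12,
                             PRIMER_PAIRS[record.primer_pair],
                             rng=np.random.default_rng(0))
        # equidistant observed barcode: 8 mismatches to both set members
        tie = "AAAAAAAAAAAAAAAA"
        out = demultiplex_pair(
            ReadPair(rp.id, Read(tie + rp.r1.seq[16:], rp.r1.qual), rp.r2),
            dec, DemuxParams(max_mm_barcode=8))
        assert out.category is Category.AMBIGUOUS

    def test_unknown_barcode_after_two_substitutions(self, sheets):
        sheet = sheets[Scheme.UDB_H12]
        dec = build_decoder(sheet)
        record = sheet.records[0]
        rp = build_read_pair("ACGT" * 40, record, Scheme.UDB_H12,
                             PRIMER_PAIRS[record.primer_pair],
                             rng=np.random.default_rng(0))
        r1 = Read(_mutate(rp.r1.seq, [0, 1]), rp.r1.qual)
        out = demultiplex_pair(ReadPair(rp.id, r1, rp.r2), dec)
        assert out.category is Category.UNKNOWN_BARCODE


class TestRunDemux:
    def _simulate(self, sheets, mock_ref, tmp_path, **kw):
        sheet = sheets[Scheme.UDB_H12]
        config = SimConfig(sheet=sheet, reference=mock_ref,
                           reads_per_sample=100, seed=21, **kw)
        res = simulate_run(config, tmp_path / "sim")
        return sheet, res

    def test_clean_run_full_yield_and_conservation(self, sheets, mock_ref,
                                                   tmp_path):
        sheet, res = self._simulate(sheets, mock_ref, tmp_path,
                                    orientation="random")
        stats = run_demux(res.r1_path, res.r2_path, sheet,
                          outdir=tmp_path / "demux")
        assert stats.total == len(res.pairs)
        assert stats.yield_fraction == 1.0
        assert sum(stats.category_counts.values()) == stats.total
        expected = res.manifest.groupby("sample_id").size().to_dict()
        assert dict(stats.per_sample) == expected

    def test_trimmed_outputs_match_templates(self, sheets, mock_ref, tmp_path):
        sheet, res = self._simulate(sheets, mock_ref, tmp_path)
        outdir = tmp_path / "demux"
        run_demux(res.r1_path, res.r2_path, sheet, outdir=outdir)
        sid = sheet.records[0].sample_id
        with gzip.open(outdir / f"{sid}_R1.fastq.gz", "rt") as fh:
            lines = fh.read().splitlines()
        seqs = set(lines[1::4])
        assert seqs <= set(res.variant_seqs.values())

    def test_desynchronised_inputs_rejected(self, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@a\nACGT\n+\nIIII\n@b\nACGT\n+\nIIII\n")
        r2.write_text("@a\nACGT\n+\nIIII\n")
        with pytest.raises(PairedFastqError, match="record 1"):
            list(iter_read_pairs(r1, r2))

    def test_mismatched_ids_rejected(self, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@a/1\nACGT\n+\nIIII\n")
        r2.write_text("@zzz/2\nACGT\n+\nIIII\n")
        with pytest.raises(PairedFastqError, match="mismatch"):
            list(iter_read_pairs(r1, r2))

    def test_mate_suffixes_pair_up(self, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@a/1\nACGT\n+\nIIII\n")
        r2.write_text("@a/2\nTTTT\n+\nIIII\n")
        pairs = list(iter_read_pairs(r1, r2))
        assert len(pairs) == 1 and pairs[0].id == "a"


class TestParams:
    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            DemuxParams(max_mm_barcode=-1)

    def test_tolerance_warning_against_tight_set(self):
        bcs = _bset(["AAAA", "AATT"])  # min distance 2
        assert DemuxParams(max_mm_barcode=1).check_against(bcs) is not None
        assert DemuxParams(max_mm_barcode=0).check_against(bcs) is None
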