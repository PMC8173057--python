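"""Crosstalk and diversity metrics on demultiplexed amplicon count data.

Works on a count table — a pandas DataFrame with unique insert sequences
(or variant ids) as the row index and samples as columns — built e.g. by
exact dereplication of demultiplexed reads. Provides:

* reference matching: a sequence is attributed to a mock-community member
  when it is within one substitution of a reference variant of equal
  length; everything else is spurious (a contaminant);
* spurious/contamination reporting per library and for PCR negative
  controls (where *every* detected sequence is spurious by definition);
* alpha diversity: observed richness and the bias-corrected Chao1
  estimator S_obs + f1·(f1−1)/(2·(f2+1));
* Bray–Curtis dissimilarity, rarefaction (subsampling without
  replacement), and a strict relative-abundance filter (drop rows never
  exceeding the threshold in any sample; default 0.25%);
* expected-vs-measured agreement: per-pool Pearson r of log-transformed
  species relative abundances against the reference, then averaged.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.stats import pearsonr
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .barcode_design import hamming
from .demultiplexer import DemuxStats
from .synthetic_amplicons import MockReference

# ---------------------------------------------------------------- containers


def count_table_from_demux(stats: DemuxStats) -> pd.DataFrame:
    """Exact-dereplication count table from in-memory demux statistics.

    Rows are unique forward-side insert sequences, columns samples. This is
    the denoising-free analogue of an ASV table for synthetic reads.
    """
    if not stats.insert_counts:
        return pd.DataFrame()
    df = pd.DataFrame(stats.insert_counts).fillna(0).astype(int)
    return df.sort_index()


def count_table_from_fastq_dir(
    outdir: str | Path, sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Dereplicate per-sample trimmed ``<sample>_R1.fastq.gz`` files."""
    from .demultiplexer import _open_text
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    cols: dict[str, Counter] = {}
    for sid in sample_ids:
        path = Path(outdir) / f"{sid}_R1.fastq.gz"
        counts: Counter = Counter()
        if path.exists():
            with _open_text(path) as fh:
                for _, seq, _ in FastqGeneralIterator(fh):
                    counts[seq] += 1
        cols[sid] = counts
    df = pd.DataFrame(cols).fillna(0).astype(int)
    return df.sort_index()


def _validate_counts(x: np.ndarray) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


# --------------------------------------------------------- reference matching


def match_to_reference(
    seq: str, ref: MockReference, max_mm: int = 1
) -> Optional[str]:
    """Attribute a sequence to a mock variant within ``max_mm`` substitutions.

    Returns the variant id of the closest qualifying reference variant of
    equal length (ties broken by reference order), or ``None`` — spurious.
    Length-mismatched sequences are spurious by construction (matching is
    Hamming-based on the fixed-length synthetic inserts).
    """
    best_id, best_d = None, max_mm + 1
    for v in ref.variants:
        if len(v.seq) != len(seq):
            continue
        d = hamming(seq, v.seq)
        if d < best_d:
            best_id, best_d = v.variant_id, d
    return best_id


@dataclass
class SpuriousReport:
    """Contamination summary per library and per negative control.

    ``per_library`` columns: n_matched, n_spurious (unique sequences),
    spurious_read_fraction. ``negative_controls`` columns: n_detected
    (every sequence in a PCR negative control counts as spurious).
    """

    per_library: pd.DataFrame
    negative_controls: pd.DataFrame


def spurious_report(
    table: pd.DataFrame,
    ref: MockReference,
    negative_control_ids: Sequence[str] = (),
    mock_ids: Optional[Sequence[str]] = None,
    max_mm: int = 1,
) -> SpuriousReport:
    """Count spurious sequences against a mock reference.

    ``mock_ids`` defaults to every column that is not a negative control.
    """
    unknown = set(negative_control_ids) - set(table.columns)
    if unknown:
        raise ValueError(f"negative-control ids not in table: {sorted(unknown)}")
    if mock_ids is None:
        mock_ids = [c for c in table.columns if c not in set(negative_control_ids)]
    unknown = set(mock_ids) - set(table.columns)
    if unknown:
        raise ValueError(f"library ids not in table: {sorted(unknown)}")

    matched_cache = {s: match_to_reference(s, ref, max_mm) for s in table.index}
    lib_rows = []
    for sid in mock_ids:
        col = table[sid]
        present = col[col > 0]
        n_matched = sum(1 for s in present.index if matched_cache[s] is not None)
        n_spurious = len(present) - n_matched
        spurious_reads = int(sum(c for s, c in present.items()
                                 if matched_cache[s] is None))
        total = int(present.sum())
        lib_rows.append({
            "library": sid,
            "n_matched": n_matched,
            "n_spurious": n_spurious,
            "spurious_read_fraction": spurious_reads / total if total else 0.0,
        })
    neg_rows = [{"library": sid,
                 "n_detected": int((table[sid] > 0).sum())}
                for sid in negative_control_ids]
    return SpuriousReport(
        per_library=pd.DataFrame(
            lib_rows, columns=["library", "n_matched", "n_spurious",
                               "spurious_read_fraction"]).set_index("library"),
        negative_controls=pd.DataFrame(
            neg_rows, columns=["library", "n_detected"]).set_index("library")
        if neg_rows else pd.DataFrame(columns=["n_detected"]),
    )


def mock_sequence_prevalence(
    table: pd.DataFrame,
    ref: MockReference,
    mock_ids: Sequence[str],
    max_mm: int = 1,
) -> tuple[pd.Series, float]:
    """Prevalence of mock-community sequences outside the mock libraries.

    Interpretation note: this operationalises "the fraction of amplicon
    samples in which sequences known to be specific to the mock community
    are detected" as the fraction of *non-mock* samples containing at least
    one sequence within ``max_mm`` of a mock reference variant — reads that
    can only have arrived there through crosstalk or contamination.

    Returns a boolean per-sample Series (mock-sequence detected) over the
    non-mock columns, and its mean (the prevalence fraction).
    """
    unknown = set(mock_ids) - set(table.columns)
    if unknown:
        raise ValueError(f"mock ids not in table: {sorted(unknown)}")
    others = [c for c in table.columns if c not in set(mock_ids)]
    if not others:
        raise ValueError("no non-mock samples in table")
    matched = {s for s in table.index
               if match_to_reference(str(s), ref, max_mm) is not None}
    flags = pd.Series(
        {c: bool((table.loc[list(matched), c] > 0).any()) if matched else False
         for c in others})
    return flags, float(flags.mean())


# ------------------------------------------------------------ alpha diversity


def observed_richness(counts: Iterable[float]) -> int:
    """Number of sequences with non-zero count."""
    arr = _validate_counts(np.asarray(list(counts)))
    return int((arr > 0).sum())


def chao1(counts: Iterable[float]) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1·(f1−1)/(2·(f2+1)).

    f1/f2 are singleton/doubleton counts; always >= observed richness,
    with equality when f1 <= 1.
    """
    arr = _validate_counts(np.asarray(list(counts)))
    if arr.sum() == 0:
        return 0.0
    return float(_skbio_chao1(arr.astype(int), bias_corrected=True))


# ----------------------------------------------------------------- beta etc.


def bray_curtis(x: Iterable[float], y: Iterable[float]) -> float:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y), in [0, 1]."""
    xa = _validate_counts(np.asarray(list(x), dtype=float))
    ya = _validate_counts(np.asarray(list(y), dtype=float))
    if len(xa) != len(ya):
        raise ValueError("vectors must have equal length")
    if xa.sum() == 0 and ya.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(xa, ya))


def rarefy(counts: Iterable[float], depth: int, seed: int = 0) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    Multivariate-hypergeometric draw; the result sums to ``depth`` and is
    deterministic given ``seed``.
    """
    arr = _validate_counts(np.asarray(list(counts))).astype(np.int64)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, depth)


def rarefy_table(table: pd.DataFrame, depth: Optional[int] = None,
                 seed: int = 0) -> pd.DataFrame:
    """Rarefy every column to a common depth (default: the smallest)."""
    if depth is None:
        depth = int(table.sum(axis=0).min())
    out = {}
    for i, col in enumerate(table.columns):
        out[col] = rarefy(table[col].to_numpy(), depth, seed=seed + i)
    return pd.DataFrame(out, index=table.index)


def abundance_filter(table: pd.DataFrame, threshold: float = 0.0025
                     ) -> pd.DataFrame:
    """Drop rows never *strictly* exceeding the relative-abundance threshold.

    Relative abundance is per sample (column). The default 0.25% is the
    standard spurious-sequence cutoff for crosstalk mitigation; surviving
    rows keep their raw counts.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    totals = table.sum(axis=0).replace(0, np.nan)
    rel = table.div(totals, axis=1).fillna(0.0)
    keep = (rel > threshold).any(axis=1)
    return table.loc[keep]


# ----------------------------------------------------- expected vs. measured


def expected_vs_measured(
    table: pd.DataFrame,
    ref: MockReference,
    pools: dict[str, Sequence[str]],
    exclude_species: Sequence[str] = (),
    max_mm: int = 1,
) -> tuple[dict[str, float], float]:
    """Pearson r of log species abundances, per amplicon pool, then averaged.

    For each pool, reads of its member libraries are summed, every sequence
    within ``max_mm`` of a reference variant is attributed to that variant's
    species ("added up into the same species"), and measured relative
    abundances are correlated with the theoretical ones on the log scale.
    Species undetected in a pool are excluded from that pool's correlation
    (no pseudocount); pools with fewer than two detected species are
    skipped with a warning. ``exclude_species`` supports manual curation of
    presumed external contaminants.

    Returns (per-pool r, mean r); the mean is NaN if every pool was skipped.
    """
    expected = {sp: ab for sp, ab in ref.species_abundance().items()
                if sp not in set(exclude_species)}
    species_of = {v.variant_id: v.species for v in ref.variants}
    results: dict[str, float] = {}
    for pool, samples in pools.items():
        missing = set(samples) - set(table.columns)
        if missing:
            raise ValueError(f"pool {pool}: unknown samples {sorted(missing)}")
        pooled = table[list(samples)].sum(axis=1)
        sp_counts: dict[str, float] = {}
        for seq, n in pooled[pooled > 0].items():
            vid = match_to_reference(str(seq), ref, max_mm)
            if vid is None:
                continue
            sp = species_of[vid]
            if sp in expected:
                sp_counts[sp] = sp_counts.get(sp, 0.0) + float(n)
        shared = sorted(sp for sp in sp_counts if expected.get(sp, 0) > 0)
        if len(shared) < 2:
            warnings.warn(f"pool {pool}: fewer than 2 shared detected "
                          "species; skipped")
            continue
        total = sum(sp_counts[sp] for sp in shared)
        meas = np.log([sp_counts[sp] / total for sp in shared])
        exp_total = sum(expected[sp] for sp in shared)
        exp = np.log([expected[sp] / exp_total for sp in shared])
        results[pool] = float(pearsonr(exp, meas).statistic)
    mean_r = float(np.mean(list(results.values()))) if results else float("nan")
    return results, mean_r
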