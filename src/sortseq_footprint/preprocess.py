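"""Read preprocessing: filtering, deduplication and per-position base counts.

The chain mirrors standard sort-seq amplicon handling of merged reads:

    raw reads -> drop ambiguous bases -> length filter (exact amplicon
    length) -> collapse redundant reads -> Hamming-distance filter against
    the wild type (hypermutated reads out) -> per-position A/C/G/T count
    matrix -> primer trim.

Alignment to the reference is positional identity: substitution-only
mutagenesis on a fixed amplicon means every retained read has exactly the
reference length, so column i of the read stack is position P(i+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import ALPHABET, ReferenceAmplicon, encode_reads

logger = logging.getLogger(__name__)

BIN_LABELS = ("unsorted", "low", "high")

__all__ = [
    "UniqueReadSet",
    "CountMatrix",
    "SubstitutionSpectrum",
    "filter_ambiguous",
    "filter_by_length",
    "collapse_unique",
    "hamming_distance",
    "filter_hypermutated",
    "count_bases",
    "trim_counts",
    "mutation_frequency",
    "substitution_spectrum",
]


@dataclass(frozen=True)
class UniqueReadSet:
    """Deduplicated reads with multiplicities and their bin of origin."""

    records: tuple[tuple[str, int], ...]
    bin_label: str
    n_raw: int

    def __post_init__(self) -> None:
        if self.bin_label not in BIN_LABELS:
            raise ValueError(f"bin_label must be one of {BIN_LABELS}")
        seqs = [s for s, _ in self.records]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate sequences in a UniqueReadSet")
        if any(m < 1 for _, m in self.records):
            raise ValueError("multiplicities must be positive")

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.records]

    @property
    def multiplicities(self) -> np.ndarray:
        return np.array([m for _, m in self.records], dtype=np.int64)

    @property
    def n_unique(self) -> int:
        return len(self.records)

    @property
    def n_reads(self) -> int:
        return int(self.multiplicities.sum()) if self.records else 0


@dataclass(frozen=True)
class CountMatrix:
    """Per-position occurrence counts of A, C, G, T for one library.

    ``counts`` is a DataFrame indexed by 1-based P-coordinates with columns
    A, C, G, T; every row sums to ``library_total``, the number of
    contributing sequences (unique sequences or multiplicity-weighted
    reads, depending on how it was built).
    """

    counts: pd.DataFrame
    library_total: int

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(ALPHABET):
            raise ValueError(f"count columns must be {list(ALPHABET)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        row_sums = self.counts.sum(axis=1)
        if len(row_sums) and not (row_sums == self.library_total).all():
            raise ValueError("every position row must sum to library_total")

    @property
    def position_labels(self) -> list[int]:
        return list(self.counts.index)

    @property
    def n_positions(self) -> int:
        return len(self.counts)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index = [f"P{p}" for p in out.index]
        out.index.name = "position"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = [int(str(p).lstrip("P")) for p in df.index]
        totals = df.sum(axis=1).unique()
        if len(totals) != 1:
            raise ValueError("row sums differ: not a valid count matrix")
        return cls(df[list(ALPHABET)].astype(np.int64), int(totals[0]))


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Counts and frequencies of the 12 ordered ref->mutant substitutions."""

    counts: pd.Series  # index like "A>G"
    total_mismatches: int = field(init=False)

    def __post_init__(self) -> None:
        expected = [f"{r}>{m}" for r in ALPHABET for m in ALPHABET if r != m]
        if list(self.counts.index) != expected:
            raise ValueError("spectrum must cover the 12 ordered substitutions")
        object.__setattr__(self, "total_mismatches", int(self.counts.sum()))

    @property
    def frequencies(self) -> pd.Series:
        """Normalized spectrum; all-NaN when no mismatch was observed."""
        if self.total_mismatches == 0:
            return pd.Series(np.nan, index=self.counts.index)
        return self.counts / self.total_mismatches

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts, "frequency": self.frequencies})


def filter_ambiguous(reads: list[str]) -> list[str]:
    """Drop reads containing any character outside {A,C,G,T}."""
    kept = [r for r in reads if set(r) <= set(ALPHABET)]
    dropped = len(reads) - len(kept)
    if dropped:
        logger.info("filter_ambiguous: dropped %d read(s) with ambiguity codes", dropped)
    return kept


def filter_by_length(
    reads: list[str], min_length: int = 247, strict: bool = True
) -> list[str]:
    """Remove reads shorter than ``min_length``.

    In the default strict mode reads longer than ``min_length`` are also
    removed, so the survivors have exactly the amplicon length and admit
    positional-identity alignment.
    """
    if strict:
        kept = [r for r in reads if len(r) == min_length]
    else:
        kept = [r for r in reads if len(r) >= min_length]
    logger.info(
        "filter_by_length(min=%d, strict=%s): kept %d / %d",
        min_length, strict, len(kept), len(reads),
    )
    return kept


def collapse_unique(reads: list[str], bin_label: str) -> UniqueReadSet:
    """Collapse redundant reads into unique records with multiplicities."""
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    return UniqueReadSet(
        records=tuple(counts.items()), bin_label=bin_label, n_raw=len(reads)
    )


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def filter_hypermutated(
    readset: UniqueReadSet,
    reference: ReferenceAmplicon,
    max_distance: int = 20,
) -> tuple[UniqueReadSet, int]:
    """Drop records farther than ``max_distance`` substitutions from wild type.

    The boundary is inclusive: a read at exactly ``max_distance`` is kept.
    Records whose length differs from the reference are rejected with a
    warning (they cannot be compared positionally).  Returns the filtered
    set and the number of unique records removed.
    """
    L = len(reference)
    wrong_length = [rec for rec in readset.records if len(rec[0]) != L]
    for seq, _ in wrong_length:
        logger.warning(
            "filter_hypermutated: rejecting read of length %d (reference %d)",
            len(seq), L,
        )
    comparable = [rec for rec in readset.records if len(rec[0]) == L]
    if comparable:
        stack = encode_reads([s for s, _ in comparable])
        dist = (stack != reference.encoded).sum(axis=1)
        kept = tuple(rec for rec, d in zip(comparable, dist) if d <= max_distance)
    else:
        kept = ()
    removed = len(readset.records) - len(kept)
    logger.info(
        "filter_hypermutated(max=%d): kept %d / %d unique records",
        max_distance, len(kept), len(readset.records),
    )
    return (
        UniqueReadSet(records=kept, bin_label=readset.bin_label, n_raw=readset.n_raw),
        removed,
    )


def count_bases(
    readset: UniqueReadSet,
    reference: ReferenceAmplicon,
    weighting: str = "unique",
) -> CountMatrix:
    """Tally A/C/G/T occurrences per position over the retained reads.

    ``weighting='unique'`` counts each distinct sequence once (deduplicated
    counting); ``'multiplicity'`` weights each by its read multiplicity.
    """
    if weighting not in ("unique", "multiplicity"):
        raise ValueError("weighting must be 'unique' or 'multiplicity'")
    L = len(reference)
    positions = reference.position_labels
    if not readset.records:
        df = pd.DataFrame(0, index=positions, columns=list(ALPHABET), dtype=np.int64)
        return CountMatrix(df, 0)
    stack = encode_reads(readset.sequences)
    if stack.shape[1] != L:
        raise ValueError("read length does not match the reference")
    weights = (
        np.ones(len(stack), dtype=np.int64)
        if weighting == "unique"
        else readset.multiplicities
    )
    counts = np.zeros((L, 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = weights @ (stack == b)
    df = pd.DataFrame(counts, index=positions, columns=list(ALPHABET))
    return CountMatrix(df, int(weights.sum()))


def trim_counts(matrix: CountMatrix, trim_width: int = 20) -> CountMatrix:
    """Drop ``trim_width`` primer-proximal positions from each end.

    Original P-labels are preserved: trimming a P1..P247 matrix by 20
    leaves P21..P227 (207 positions).
    """
    if trim_width < 0:
        raise ValueError("trim_width must be non-negative")
    if 2 * trim_width >= matrix.n_positions:
        raise ValueError(
            f"trim_width {trim_width} would remove all {matrix.n_positions} positions"
        )
    if trim_width == 0:
        return matrix
    trimmed = matrix.counts.iloc[trim_width:-trim_width]
    return CountMatrix(trimmed, matrix.library_total)


def mutation_frequency(
    matrix: CountMatrix, reference: ReferenceAmplicon
) -> pd.Series:
    """Fraction of non-reference bases per position.

    ``freq[p] = 1 - counts[p, ref_base(p)] / row_sum(p)``; positions with a
    zero row sum are reported as NaN rather than silently zero.
    """
    freqs = {}
    for pos in matrix.position_labels:
        row = matrix.counts.loc[pos]
        total = row.sum()
        if total == 0:
            freqs[pos] = np.nan
        else:
            freqs[pos] = 1.0 - row[reference.base_at(pos)] / total
    return pd.Series(freqs, name="mutation_frequency")


def substitution_spectrum(
    readset: UniqueReadSet, reference: ReferenceAmplicon
) -> SubstitutionSpectrum:
    """Tally every ref->mutant mismatch type over the retained sequences.

    Each unique sequence contributes once per mismatched position (unique
    weighting, consistent with deduplicated counting).
    """
    index = [f"{r}>{m}" for r in ALPHABET for m in ALPHABET if r != m]
    tallies = pd.Series(0, index=index, dtype=np.int64)
    if readset.records:
        stack = encode_reads(readset.sequences)
        if stack.shape[1] != len(reference):
            raise ValueError("read length does not match the reference")
        ref = reference.encoded
        for r in range(4):
            ref_cols = ref == r
            for m in range(4):
                if m == r:
                    continue
                tallies[f"{ALPHABET[r]}>{ALPHABET[m]}"] = int(
                    (stack[:, ref_cols] == m).sum()
                )
    return SubstitutionSpectrum(tallies)
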