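"""Mutual-information footprints and bin-vs-unsorted enrichment maps.

For each position i the base identity :math:`b_i` and the sorting bin
:math:`\\mu \\in \\{low, high\\}` define a joint frequency table
:math:`f(b_i, \\mu)`; the per-position mutual information

.. math::

    I(b_i; \\mu) = \\sum_{b_i, \\mu} f(b_i,\\mu)
        \\log_2 \\frac{f(b_i,\\mu)}{f(b_i)\\, f(\\mu)}

measures, in bits, how much the base at that position tells about which
expression bin a read was sorted into.  Positions whose identity drives
expression peak in this "information footprint".  Enrichment maps report
the per-base log2 ratio of a sorted bin's base frequency to the unsorted
library's, showing which identities are enriched or depleted by sorting.

Mutual information uses only the two sorted bins; the unsorted library
enters only the enrichment maps.  Bin weighting f(mu) defaults to equal
(1/2, 1/2), with read-proportional weighting as an option.  The MI
pseudocount defaults to 0 (0*log 0 := 0 handles empty cells); enrichment
defaults to pseudocount 1 so depleted bases keep finite log-ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CountMatrix, UniqueReadSet
from .reference import ALPHABET, ReferenceAmplicon, encode_reads

__all__ = [
    "FootprintOptions",
    "JointFrequencyTable",
    "FootprintResult",
    "EnrichmentMap",
    "joint_frequencies",
    "mutual_information",
    "information_footprint",
    "enrichment_map",
    "rank_positions",
    "recovery_score",
    "permutation_null",
]

BIN_ORDER = ("low", "high")


@dataclass(frozen=True)
class FootprintOptions:
    """Knobs of the footprint computation, recorded in every result."""

    bin_weighting: str = "equal"  # or "read_proportional"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_weighting not in ("equal", "read_proportional"):
            raise ValueError("bin_weighting must be 'equal' or 'read_proportional'")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


@dataclass(frozen=True)
class JointFrequencyTable:
    """Joint base-by-bin frequencies at one position, with marginals."""

    f_joint: pd.DataFrame  # index A,C,G,T; columns low, high
    position: int

    def __post_init__(self) -> None:
        if list(self.f_joint.index) != list(ALPHABET) or list(
            self.f_joint.columns
        ) != list(BIN_ORDER):
            raise ValueError("f_joint must be indexed by A,C,G,T x (low, high)")
        total = float(self.f_joint.to_numpy().sum())
        if not np.isclose(total, 1.0):
            raise ValueError(f"joint frequencies must sum to 1, got {total}")
        if ((self.f_joint.to_numpy() < 0) | (self.f_joint.to_numpy() > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def f_base(self) -> pd.Series:
        return self.f_joint.sum(axis=1)

    @property
    def f_bin(self) -> pd.Series:
        return self.f_joint.sum(axis=0)


@dataclass(frozen=True)
class FootprintResult:
    """Per-position mutual information (bits) over the retained positions."""

    mi_bits: pd.Series  # index: P-coordinates
    options: FootprintOptions
    no_variation: pd.Series = field(default=None)  # bool flags, same index

    def __post_init__(self) -> None:
        if self.no_variation is None:
            object.__setattr__(
                self, "no_variation", pd.Series(False, index=self.mi_bits.index)
            )
        if (self.mi_bits < -1e-12).any():
            raise ValueError("mutual information cannot be negative")

    @property
    def positions(self) -> list[int]:
        return list(self.mi_bits.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mi_bits": self.mi_bits, "no_variation": self.no_variation}
        ).rename_axis("position")


@dataclass(frozen=True)
class EnrichmentMap:
    """log2 bin-vs-unsorted frequency ratios per position and base."""

    log2_ratio: pd.DataFrame  # index positions, columns A,C,G,T
    bin_label: str
    pseudocount: float
    absent_in_bin: pd.DataFrame = None  # bool: zero raw count in the bin

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_ratio.to_numpy()).all():
            raise ValueError("log2 ratios must be finite (use pseudocount > 0)")

    def to_long(self) -> pd.DataFrame:
        long = self.log2_ratio.rename_axis("position").reset_index().melt(
            id_vars="position", var_name="base", value_name="log2_ratio"
        )
        long["bin"] = self.bin_label
        flags = self.absent_in_bin.rename_axis("position").reset_index().melt(
            id_vars="position", var_name="base", value_name="absent_in_bin"
        )
        return long.merge(flags, on=["position", "base"]).sort_values(
            ["position", "base"], ignore_index=True
        )


def _bin_weights(total_low: float, total_high: float, bin_weighting: str) -> np.ndarray:
    if bin_weighting == "equal":
        return np.array([0.5, 0.5])
    total = total_low + total_high
    return np.array([total_low / total, total_high / total])


def _conditional_frequencies(
    counts: np.ndarray, total: float, pseudocount: float
) -> np.ndarray:
    return (counts + pseudocount) / (total + 4.0 * pseudocount)


def joint_frequencies(
    counts_low: CountMatrix,
    counts_high: CountMatrix,
    position: int,
    bin_weighting: str = "equal",
    pseudocount: float = 0.0,
) -> JointFrequencyTable:
    """Build the base-by-bin joint frequency table at one position.

    Within-bin base frequencies are ``(count + psi) / (total + 4 psi)``;
    the joint is ``f(b, mu) = f(mu) * f(b | mu)`` with bin weights either
    equal or proportional to library totals.
    """
    FootprintOptions(bin_weighting, pseudocount)  # validate
    for cm, label in ((counts_low, "low"), (counts_high, "high")):
        if position not in cm.counts.index:
            raise ValueError(f"position P{position} missing from the {label} matrix")
        if cm.library_total <= 0:
            raise ValueError(f"{label} matrix has zero library total")
    f_low = _conditional_frequencies(
        counts_low.counts.loc[position].to_numpy(float),
        counts_low.library_total,
        pseudocount,
    )
    f_high = _conditional_frequencies(
        counts_high.counts.loc[position].to_numpy(float),
        counts_high.library_total,
        pseudocount,
    )
    w = _bin_weights(counts_low.library_total, counts_high.library_total, bin_weighting)
    joint = pd.DataFrame(
        {"low": w[0] * f_low, "high": w[1] * f_high}, index=list(ALPHABET)
    )
    return JointFrequencyTable(f_joint=joint, position=position)


def mutual_information(table: JointFrequencyTable) -> float:
    """Mutual information of one joint table, in bits (0*log 0 := 0)."""
    joint = table.f_joint.to_numpy(float)
    f_b = joint.sum(axis=1, keepdims=True)
    f_mu = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (f_b * f_mu))
    return float(np.where(joint > 0, terms, 0.0).sum())


def _mi_from_count_arrays(
    counts_low: np.ndarray,
    counts_high: np.ndarray,
    totals: tuple[float, float],
    options: FootprintOptions,
) -> np.ndarray:
    """Vectorized per-position MI for (P, 4) count arrays of the two bins."""
    psi = options.pseudocount
    f_low = _conditional_frequencies(counts_low.astype(float), totals[0], psi)
    f_high = _conditional_frequencies(counts_high.astype(float), totals[1], psi)
    w = _bin_weights(totals[0], totals[1], options.bin_weighting)
    joint = np.stack([w[0] * f_low, w[1] * f_high], axis=2)  # (P, 4, 2)
    f_b = joint.sum(axis=2, keepdims=True)
    f_mu = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (f_b * f_mu))
    return np.where(joint > 0, terms, 0.0).sum(axis=(1, 2))


def information_footprint(
    counts_low: CountMatrix,
    counts_high: CountMatrix,
    options: FootprintOptions = FootprintOptions(),
) -> FootprintResult:
    """Apply the joint-frequency + MI computation at every shared position.

    Positions where both bins observed a single identical base carry no
    variation; they are flagged (their MI is exactly 0 at pseudocount 0).
    """
    if counts_low.position_labels != counts_high.position_labels:
        raise ValueError("count matrices must share identical position labels")
    if counts_low.library_total <= 0 or counts_high.library_total <= 0:
        raise ValueError("both bins need a positive library total")
    cl = counts_low.counts.to_numpy()
    ch = counts_high.counts.to_numpy()
    mi = _mi_from_count_arrays(
        cl, ch, (counts_low.library_total, counts_high.library_total), options
    )
    pooled = cl + ch
    no_var = (pooled > 0).sum(axis=1) <= 1
    index = counts_low.counts.index
    return FootprintResult(
        mi_bits=pd.Series(np.maximum(mi, 0.0), index=index, name="mi_bits"),
        options=options,
        no_variation=pd.Series(no_var, index=index),
    )


def enrichment_map(
    counts_bin: CountMatrix,
    counts_unsorted: CountMatrix,
    pseudocount: float = 1.0,
    bin_label: str = "high",
) -> EnrichmentMap:
    """Per-position, per-base log2 ratio of bin vs unsorted frequencies.

    ``log2(((c_bin + psi)/(T_bin + 4 psi)) / ((c_uns + psi)/(T_uns + 4 psi)))``.
    Positive entries mark identities enriched by sorting into the bin,
    negative entries depleted ones.
    """
    if counts_bin.position_labels != counts_unsorted.position_labels:
        raise ValueError("count matrices must share identical position labels")
    cb = counts_bin.counts.to_numpy(float)
    cu = counts_unsorted.counts.to_numpy(float)
    if pseudocount <= 0 and ((cb == 0).any() or (cu == 0).any()):
        raise ValueError("zero counts present: a positive pseudocount is required")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    fb = _conditional_frequencies(cb, counts_bin.library_total, pseudocount)
    fu = _conditional_frequencies(cu, counts_unsorted.library_total, pseudocount)
    ratio = pd.DataFrame(
        np.log2(fb / fu), index=counts_bin.counts.index, columns=list(ALPHABET)
    )
    absent = pd.DataFrame(
        cb == 0, index=counts_bin.counts.index, columns=list(ALPHABET)
    )
    return EnrichmentMap(
        log2_ratio=ratio,
        bin_label=bin_label,
        pseudocount=pseudocount,
        absent_in_bin=absent,
    )


def rank_positions(footprint: FootprintResult, k: int | None = None) -> list[int]:
    """Top-k positions by MI, descending; ties broken by ascending P-label."""
    if k is None:
        k = len(footprint.mi_bits)
    if k > len(footprint.mi_bits):
        raise ValueError("k exceeds the number of positions")
    order = sorted(
        footprint.mi_bits.items(), key=lambda item: (-item[1], item[0])
    )
    return [pos for pos, _ in order[:k]]


def recovery_score(
    footprint: FootprintResult, planted: set[int], k: int
) -> float:
    """Fraction of planted positions recovered in the top-k MI ranks."""
    if not planted:
        raise ValueError("planted position set must be non-empty")
    top = set(rank_positions(footprint, k))
    return len(top & set(planted)) / len(planted)


def permutation_null(
    low: UniqueReadSet,
    high: UniqueReadSet,
    reference: ReferenceAmplicon,
    n_permutations: int = 100,
    seed: int = 0,
    options: FootprintOptions = FootprintOptions(),
    weighting: str = "unique",
    trim_width: int | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Null distribution of per-position MI under random bin labels.

    Pools the two bins' records, randomly reassigns them to bins of the
    original sizes ``n_permutations`` times, and recomputes the footprint
    each time.  Returns an (n_permutations, n_positions) array of MI values
    and the retained position labels; column-wise quantiles calibrate how
    much MI pure sampling noise produces at each position.
    """
    if weighting not in ("unique", "multiplicity"):
        raise ValueError("weighting must be 'unique' or 'multiplicity'")
    tw = reference.trim_width if trim_width is None else trim_width
    sequences = low.sequences + high.sequences
    if not sequences:
        raise ValueError("no reads to permute")
    stack = encode_reads(sequences)
    if stack.shape[1] != len(reference):
        raise ValueError("read length does not match the reference")
    keep = slice(tw, len(reference) - tw if tw else None)
    positions = reference.position_labels[keep]
    stack = stack[:, keep]
    if weighting == "unique":
        weights = np.ones(len(sequences))
    else:
        weights = np.concatenate(
            [low.multiplicities, high.multiplicities]
        ).astype(float)
    base_ind = [(stack == b).astype(float) for b in range(4)]
    n_low = low.n_unique
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(positions)))
    n_total = len(sequences)
    for p in range(n_permutations):
        perm = rng.permutation(n_total)
        is_low = np.zeros(n_total, dtype=bool)
        is_low[perm[:n_low]] = True
        w_low = np.where(is_low, weights, 0.0)
        w_high = weights - w_low
        counts_low = np.stack([w_low @ B for B in base_ind], axis=1)
        counts_high = np.stack([w_high @ B for B in base_ind], axis=1)
        null[p] = _mi_from_count_arrays(
            counts_low,
            counts_high,
            (w_low.sum(), w_high.sum()),
            options,
        )
    return null, positions
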