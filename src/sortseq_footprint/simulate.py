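"""Synthetic sort-seq generator: epPCR libraries, expression, FACS sorting, reads.

The generator emulates the experiment end to end so the analysis chain can be
exercised and calibrated without external data:

1. Error-prone PCR is collapsed to a single effective per-position
   substitution process (default rate 0.05, matching the ~5 % per-position
   mutation frequency of a round-5 epPCR library) with a configurable
   substitution-bias matrix.
2. A planted sequence-to-expression model maps each variant to a noise-free
   fluorescence in arbitrary units (AU): an essential core where any
   substitution drops expression to basal leak, graded deleterious effects
   around it, one beneficial single mutant, and one strictly epistatic
   beneficial double mutant.
3. Cells are sampled from the library, log-normal expression noise is added,
   and FACS gates take the top 5 % (high-GFP bin) and bottom 10 % (low-GFP
   bin) of cells.
4. Amplicon sequencing emits one read per cell with independent uniform
   substitution errors.

All randomness flows through explicit integer seeds; identical seeds give
byte-identical libraries, pools and read files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reference import (
    ALPHABET,
    BASE_INDEX,
    ReferenceAmplicon,
    decode_sequence,
    encode_reads,
    encode_sequence,
)

__all__ = [
    "EpPCRModel",
    "ExpressionModel",
    "VariantLibrary",
    "SortGates",
    "SortedPools",
    "mutagenize_library",
    "score_expression",
    "default_expression_model",
    "sort_cells",
    "emit_reads",
]


def uniform_bias() -> np.ndarray:
    """4x4 substitution matrix with each mutant base equally likely (1/3)."""
    bias = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(bias, 0.0)
    return bias


@dataclass(frozen=True)
class EpPCRModel:
    """Effective per-position substitution model for an epPCR library.

    ``bias[i, j]`` is the conditional probability that reference base ``i``
    mutates to base ``j`` given that a substitution occurs; rows are
    stochastic over the three non-reference bases and the diagonal is zero.
    """

    per_position_rate: float = 0.05
    bias: np.ndarray = field(default_factory=uniform_bias)

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_position_rate <= 1.0:
            raise ValueError("per_position_rate must be in [0, 1]")
        bias = np.asarray(self.bias, dtype=float)
        if bias.shape != (4, 4):
            raise ValueError("bias must be a 4x4 matrix")
        if (bias < 0).any():
            raise ValueError("bias probabilities must be non-negative")
        if not np.allclose(np.diag(bias), 0.0):
            raise ValueError("self-substitution (diagonal) must be zero")
        if not np.allclose(bias.sum(axis=1), 1.0):
            raise ValueError("each bias row must sum to 1 over mutant bases")
        object.__setattr__(self, "bias", bias)


@dataclass(frozen=True)
class VariantLibrary:
    """A pool of variant sequences with abundances (cell or molecule counts)."""

    sequences: tuple[str, ...]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=np.int64)
        if len(ab) != len(self.sequences):
            raise ValueError("abundances and sequences differ in length")
        if len(ab) and (ab <= 0).any():
            raise ValueError("abundances must be positive")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("all sequences must share one length")
        object.__setattr__(self, "sequences", tuple(self.sequences))
        object.__setattr__(self, "abundances", ab)

    @property
    def entries(self) -> list[tuple[str, int]]:
        return list(zip(self.sequences, self.abundances.tolist()))

    @property
    def total_variants(self) -> int:
        """Total number of molecules/cells (sum of abundances)."""
        return int(self.abundances.sum())

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_sequences(cls, sequences: list[str]) -> "VariantLibrary":
        """Collapse a flat sequence list into (sequence, abundance) entries."""
        counts: dict[str, int] = {}
        for s in sequences:
            counts[s] = counts.get(s, 0) + 1
        return cls(tuple(counts), np.array(list(counts.values()), dtype=np.int64))

    def expand_encoded(self) -> np.ndarray:
        """Per-cell encoded matrix with each sequence repeated by abundance."""
        if not self.sequences:
            return np.empty((0, 0), dtype=np.uint8)
        uniq = encode_reads(list(self.sequences))
        return np.repeat(uniq, self.abundances, axis=0)


@dataclass(frozen=True)
class ExpressionModel:
    """Planted sequence-to-expression map on the log scale.

    Expression of a variant is ``basal_leak`` if any lethal position carries
    a non-reference base, and otherwise::

        baseline * exp(sum of additive effects + sum of satisfied epistasis)

    ``additive_effects`` maps ``(position, base)`` to a natural-log effect;
    ``epistasis_terms`` maps a pair of (position, base) identities to an
    effect applied only when both are present.  Effects at reference bases
    are zero by construction.  Cell-level noise is Gaussian on log
    expression with standard deviation ``noise_sd`` (log-normal AU).
    """

    reference: ReferenceAmplicon
    baseline: float = 1000.0
    additive_effects: dict[tuple[int, str], float] = field(default_factory=dict)
    epistasis_terms: dict[tuple[tuple[int, str], tuple[int, str]], float] = field(
        default_factory=dict
    )
    lethal_positions: frozenset[int] = frozenset()
    basal_leak: float = 10.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not self.baseline > self.basal_leak > 0:
            raise ValueError("require baseline > basal_leak > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        L = len(self.reference)
        for (pos, base), eff in self.additive_effects.items():
            if not 1 <= pos <= L:
                raise ValueError(f"additive effect at P{pos} outside amplicon")
            if base == self.reference.base_at(pos) and eff != 0.0:
                raise ValueError(f"non-zero effect at reference base P{pos}={base}")
        for (a, b) in self.epistasis_terms:
            for pos, base in (a, b):
                if not 1 <= pos <= L:
                    raise ValueError(f"epistasis term at P{pos} outside amplicon")
                if base == self.reference.base_at(pos):
                    raise ValueError(
                        f"epistasis term keyed on reference base P{pos}={base}"
                    )
        object.__setattr__(self, "lethal_positions", frozenset(self.lethal_positions))

    def effect_matrix(self) -> np.ndarray:
        """(L, 4) additive log effects; zero at reference bases."""
        eff = np.zeros((len(self.reference), 4))
        for (pos, base), val in self.additive_effects.items():
            eff[pos - 1, BASE_INDEX[base]] = val
        return eff

    def log_scores(self, encoded: np.ndarray) -> np.ndarray:
        """Noise-free log expression for an (n, L) encoded variant matrix."""
        if encoded.shape[1] != len(self.reference):
            raise ValueError("variant length does not match the reference")
        eff = self.effect_matrix()
        log_expr = math.log(self.baseline) + eff[np.arange(encoded.shape[1]), encoded].sum(
            axis=1
        )
        for ((p1, b1), (p2, b2)), val in self.epistasis_terms.items():
            hit = (encoded[:, p1 - 1] == BASE_INDEX[b1]) & (
                encoded[:, p2 - 1] == BASE_INDEX[b2]
            )
            log_expr += val * hit
        if self.lethal_positions:
            idx = np.array(sorted(self.lethal_positions)) - 1
            ref = self.reference.encoded[idx]
            dead = (encoded[:, idx] != ref).any(axis=1)
            log_expr[dead] = math.log(self.basal_leak)
        return log_expr


def default_expression_model(
    reference: ReferenceAmplicon | None = None, noise_sd: float = 0.3
) -> ExpressionModel:
    """The default planted model calibrated to the validated phenotypes.

    * lethality at P199-P201: any substitution drops expression to leak
      (the essential TGT core; G200A alone abolishes function),
    * graded deleterious additive effects across P196-P207 except P203,
      strongest next to the essential core,
    * a +ln(4) strictly epistatic term for the (P129=T, P130=C) hairpin
      double mutant with zero single-mutant effects (4-fold gain),
    * a +ln(1.64) additive effect for P205=A (1.64-fold gain).
    """
    from .reference import bmo_reference

    ref = reference if reference is not None else bmo_reference()
    additive: dict[tuple[int, str], float] = {}
    # graded deleterious band flanking the essential core; |effect| decays
    # with distance from P200 at 0.25 nats per position (min 0.25)
    for pos in range(196, 208):
        if pos in (199, 200, 201, 203):
            continue
        effect = -max(2.0 - 0.25 * abs(pos - 200), 0.25)
        ref_base = ref.base_at(pos)
        for base in ALPHABET:
            if base != ref_base:
                additive[(pos, base)] = effect
    additive[(205, "A")] = math.log(1.64)  # the one beneficial single mutant
    epistasis = {((129, "T"), (130, "C")): math.log(4.0)}
    return ExpressionModel(
        reference=ref,
        additive_effects=additive,
        epistasis_terms=epistasis,
        lethal_positions=frozenset({199, 200, 201}),
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class SortGates:
    """FACS gate fractions: top ``high_fraction`` and bottom ``low_fraction``."""

    high_fraction: float = 0.05
    low_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.high_fraction < 1 and 0 < self.low_fraction < 1):
            raise ValueError("gate fractions must lie in (0, 1)")
        if self.high_fraction + self.low_fraction > 1:
            raise ValueError("gates overlap: fractions sum above 1")


@dataclass(frozen=True)
class SortedPools:
    """Outcome of one sort: the sampled library and its two gated bins."""

    unsorted: VariantLibrary
    high: VariantLibrary
    low: VariantLibrary
    expression_trace: "np.ndarray | None" = None  # columns: variant idx, AU


def mutagenize_library(
    reference: ReferenceAmplicon,
    model: EpPCRModel,
    n_variants: int,
    seed: int,
) -> VariantLibrary:
    """Draw an epPCR library of ``n_variants`` independent variants.

    Each position mutates independently with probability
    ``model.per_position_rate``; the mutant base is drawn from the bias row
    of the reference base.  Deterministic for a fixed seed.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be non-negative")
    rng = np.random.default_rng(seed)
    L = len(reference)
    ref = reference.encoded
    if n_variants == 0:
        return VariantLibrary((), np.array([], dtype=np.int64))
    variants = np.tile(ref, (n_variants, 1))
    hit = rng.random((n_variants, L)) < model.per_position_rate
    if hit.any():
        rows, cols = np.nonzero(hit)
        cum = np.cumsum(model.bias[ref[cols]], axis=1)
        u = rng.random(len(rows))
        variants[rows, cols] = (u[:, None] < cum).argmax(axis=1)
    seqs = ["".join(s) for s in np.asarray(list(ALPHABET))[variants]]
    return VariantLibrary.from_sequences(seqs)


def score_expression(sequence: str, model: ExpressionModel) -> float:
    """Noise-free expression (AU) of one variant under the planted model."""
    if len(sequence) != len(model.reference):
        raise ValueError(
            f"sequence length {len(sequence)} does not match reference "
            f"length {len(model.reference)}"
        )
    encoded = encode_sequence(sequence)[None, :]
    return float(np.exp(model.log_scores(encoded)[0]))


def sort_cells(
    library: VariantLibrary,
    model: ExpressionModel,
    gates: SortGates,
    n_cells: int,
    seed: int,
    keep_trace: bool = False,
) -> SortedPools:
    """Sample cells, add log-normal expression noise, and gate into bins.

    ``n_cells`` cells are drawn with replacement proportional to library
    abundance; the top ``round(n_cells * high_fraction)`` cells by noisy
    expression form the high pool and the bottom
    ``round(n_cells * low_fraction)`` the low pool.  The unsorted pool is
    the full cell sample.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if len(library) == 0:
        raise ValueError("library is empty")
    rng = np.random.default_rng(seed)
    probs = library.abundances / library.total_variants
    cell_variant = rng.choice(len(library), size=n_cells, p=probs)
    uniq_encoded = encode_reads(list(library.sequences))
    log_mu = model.log_scores(uniq_encoded)
    log_expr = log_mu[cell_variant]
    if model.noise_sd > 0:
        log_expr = log_expr + rng.normal(0.0, model.noise_sd, size=n_cells)
    order = np.argsort(log_expr, kind="stable")
    n_high = round(n_cells * gates.high_fraction)
    n_low = round(n_cells * gates.low_fraction)
    low_cells = order[:n_low]
    high_cells = order[n_cells - n_high :] if n_high else order[:0]

    def _pool(cells: np.ndarray) -> VariantLibrary:
        idx, counts = np.unique(cell_variant[cells], return_counts=True)
        return VariantLibrary(
            tuple(library.sequences[i] for i in idx), counts.astype(np.int64)
        )

    trace = None
    if keep_trace:
        trace = np.column_stack([cell_variant.astype(float), np.exp(log_expr)])
    return SortedPools(
        unsorted=_pool(np.arange(n_cells)),
        high=_pool(high_cells),
        low=_pool(low_cells),
        expression_trace=trace,
    )


def emit_reads(
    pool: VariantLibrary,
    seq_error_rate: float,
    seed: int,
    n_reads: int | None = None,
) -> list[str]:
    """Sequence a pool: one read per cell with uniform substitution errors.

    By default every cell in the pool yields one read; pass ``n_reads`` to
    resample the pool with replacement to a target depth (amplicon
    sequencing reads many PCR copies per cell).  Errors substitute an
    independent uniformly chosen different base at rate ``seq_error_rate``.
    """
    if not 0.0 <= seq_error_rate < 1.0:
        raise ValueError("seq_error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cells = pool.expand_encoded()
    if n_reads is not None:
        if n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if len(cells) == 0 and n_reads > 0:
            raise ValueError("cannot sample reads from an empty pool")
        cells = cells[rng.integers(0, len(cells), size=n_reads)] if n_reads else cells[:0]
    if cells.size and seq_error_rate > 0:
        err = rng.random(cells.shape) < seq_error_rate
        if err.any():
            cells = cells.copy()
            # uniform among the 3 non-current bases via a 1..3 offset mod 4
            offsets = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            rows, cols = np.nonzero(err)
            cells[rows, cols] = (cells[rows, cols] + offsets) % 4
    return [decode_sequence(row) for row in cells]
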