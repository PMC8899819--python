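"""Reference amplicon: the fixed mutagenized promoter region and its coordinates.

Positions are reported with 1-based labels P1..PL matching the coordinate
convention used for promoter mutagenesis maps; the first and last
``trim_width`` positions (primer-proximal) are excluded from downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Default length of the mutagenized amplicon (nt).
AMPLICON_LENGTH = 247

#: Default number of primer-proximal positions dropped at each end.
DEFAULT_TRIM_WIDTH = 20

# Synthetic stand-in for the wild-type 247-nt mutagenized region.  The true
# promoter sequence is not bundled; this sequence is random except at the
# positions the planted expression model references, which carry the
# wild-type identities implied by the validated variants:
# P129=C, P130=A (the hairpin mismatch pair), P199-P201=TGT (essential core),
# P205=G, and P191-P196=GCCGCG.
SYNTHETIC_BMO_AMPLICON = (
    "TATTTCGATGCAATCTCCGACCCTCTGACTACCCTACGGCGCAAGACTTTTGTTCGCTAC"
    "AACTCAAAAATAAGCTTACTTCGTCCGTCAGCGGCATATGTTATGCTAACACCCCCTACA"
    "TTTTTTCTCAGCCGGCATGGTTCGCGCGTTACGCAACCAGCGTGCTGGCGATATCGAGCG"
    "GTGGCGGAGAGCCGCGATTGTATCGCAACCAGACCCCGTCCTCCTAGCTGCTATATCTTG"
    "GATTGAC"
)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array of base indices (A=0..T=3)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    out = lut[arr]
    if (out == 255).any():
        bad = sorted({sequence[i] for i in np.flatnonzero(out == 255)})
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return out


def encode_reads(reads: list[str]) -> np.ndarray:
    """Encode equal-length reads as an (n_reads, length) uint8 matrix."""
    if not reads:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(reads[0])
    if any(len(r) != length for r in reads):
        raise ValueError("reads must all have the same length")
    return encode_sequence("".join(reads)).reshape(len(reads), length)


def decode_sequence(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in indices)


@dataclass(frozen=True)
class ReferenceAmplicon:
    """The wild-type mutagenized region with its P-coordinate convention.

    Parameters
    ----------
    sequence:
        Wild-type nucleotide string over {A,C,G,T}.
    trim_width:
        Number of primer-proximal positions excluded from analysis at each
        end (default 20, leaving P21..P227 of a 247-nt amplicon).
    """

    sequence: str
    trim_width: int = DEFAULT_TRIM_WIDTH
    encoded: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        object.__setattr__(self, "encoded", encode_sequence(self.sequence))
        if self.trim_width < 0:
            raise ValueError("trim_width must be non-negative")
        if 2 * self.trim_width >= len(self.sequence):
            raise ValueError(
                f"trim_width {self.trim_width} removes the whole "
                f"{len(self.sequence)}-nt amplicon"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def position_labels(self) -> list[int]:
        """1-based P-coordinates P1..PL."""
        return list(range(1, len(self.sequence) + 1))

    @property
    def analysis_positions(self) -> list[int]:
        """P-coordinates retained after trimming both primer-proximal ends."""
        return list(range(self.trim_width + 1, len(self.sequence) - self.trim_width + 1))

    def base_at(self, position: int) -> str:
        """Wild-type base at a 1-based P-coordinate."""
        if not 1 <= position <= len(self.sequence):
            raise ValueError(f"position P{position} outside P1..P{len(self.sequence)}")
        return self.sequence[position - 1]


def bmo_reference(trim_width: int = DEFAULT_TRIM_WIDTH) -> ReferenceAmplicon:
    """The packaged synthetic 247-nt amplicon with default trimming."""
    return ReferenceAmplicon(SYNTHETIC_BMO_AMPLICON, trim_width=trim_width)
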