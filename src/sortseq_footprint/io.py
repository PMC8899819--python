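"""FASTA/FASTQ and table I/O helpers (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Constant Phred quality written for simulated reads (Phred+33 'I' = Q40).
SIMULATED_PHRED = 40


def read_sequences(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (format inferred from suffix)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def read_reference_fasta(path: str | Path) -> str:
    """Read a single-record reference FASTA."""
    records = list(SeqIO.parse(str(Path(path)), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one reference record, found {len(records)}")
    return str(records[0].seq).upper()


def write_fasta(sequences: list[str], path: str | Path, prefix: str = "read") -> None:
    records = (
        SeqRecord(Seq(s), id=f"{prefix}_{i}", description="") for i, s in enumerate(sequences)
    )
    SeqIO.write(records, str(Path(path)), "fasta")


def write_fastq(sequences: list[str], path: str | Path, prefix: str = "read") -> None:
    """Write reads as FASTQ with constant quality (simulated reads carry no
    per-base quality information)."""

    def _records():
        for i, s in enumerate(sequences):
            rec = SeqRecord(Seq(s), id=f"{prefix}_{i}", description="")
            rec.letter_annotations["phred_quality"] = [SIMULATED_PHRED] * len(s)
            yield rec

    SeqIO.write(_records(), str(Path(path)), "fastq")


def write_reads(sequences: list[str], path: str | Path, prefix: str = "read") -> None:
    """Dispatch on suffix: .fastq/.fq write FASTQ, anything else FASTA."""
    if Path(path).suffix.lower() in {".fastq", ".fq"}:
        write_fastq(sequences, path, prefix)
    else:
        write_fasta(sequences, path, prefix)
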