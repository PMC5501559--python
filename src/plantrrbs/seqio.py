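"""Small sequence/file helpers shared across the toolkit.

FASTA and FASTQ round-tripping is delegated to Biopython; the helpers here
exist so the rest of the package can work with plain ``dict``/``list``
structures (contig name -> uppercase sequence string, and ``FastqRead``
records) without carrying SeqRecord objects around.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def ct_convert(seq: str) -> str:
    """Fully bisulfite-convert the top strand in silico: every C becomes T."""
    return seq.replace("C", "T")


def ga_convert(seq: str) -> str:
    """Bottom-strand conversion viewed in reference orientation: G becomes A."""
    return seq.replace("G", "A")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-)FASTA into a contig -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class FastqRead:
    """One FASTQ record with per-base Phred qualities."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


def read_fastq(path: str | Path) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(FastqRead(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
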