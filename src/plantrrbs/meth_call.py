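"""Per-cytosine methylation calling from clipped alignments.

The methylation level at a cytosine position i is Ci / (Ci + Ti), where
Ci counts aligned read bases showing an unconverted C (methylated) and
Ti counts converted T observations; C and T together are the
"informative nucleotides" at the position.  Positions are strand
specific throughout: a "+" call sits on a reference C and collects
evidence from top-strand molecules, a "-" call sits on a reference G
and collects G (=Ci) / A (=Ti) evidence from bottom-strand molecules.
Calls are retained when they reach ``min_informative`` (default 10)
informative nucleotides.

Bisulfite conversion efficiency is estimated on a control contig whose
cytosines are known to be unmethylated (the chloroplast genome in real
libraries): efficiency = 1 - sum(Ci) / sum(Ci + Ti) over its positions.

Call files are CGmap-like TSVs with 1-based positions on disk; all
in-memory coordinates are 0-based, converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .bs_align import AlignmentRecord
from .read_simulator import Key

_CGMAP_HEADER = "contig\tbase\tposition\tcontext\tdinucleotide\tlevel\tc_count\ttotal_count\n"


@dataclass(frozen=True)
class MethylationCall:
    """One strand-specific cytosine with its informative counts."""

    contig: str
    position: int  # 0-based
    strand: str    # "+" reference C, "-" reference G
    context: str
    c_count: int
    t_count: int
    dinucleotide: str = "NN"

    def __post_init__(self) -> None:
        if self.c_count < 0 or self.t_count < 0:
            raise ValueError("negative informative counts")

    @property
    def total(self) -> int:
        return self.c_count + self.t_count

    @property
    def level(self) -> float:
        if self.total == 0:
            raise ValueError("level undefined with zero informative nucleotides")
        return self.c_count / self.total

    @property
    def key(self) -> Key:
        return (self.contig, self.position, self.strand)


@dataclass
class CallFilter:
    """Minimum informative nucleotides for a position to be called."""

    min_informative: int = 10

    def __post_init__(self) -> None:
        if self.min_informative < 1:
            raise ValueError("min_informative must be >= 1")


def pileup(
    records: Iterable[AlignmentRecord],
    genome: Mapping[str, str],
    contexts: Mapping[Key, str],
) -> dict[Key, tuple[int, int]]:
    """Count informative nucleotides per classified cytosine position.

    Records must already be overlap-clipped (each pair's mate 2 only
    contributes its non-overlapping sub-intervals), so a pair never
    counts a position twice.  Observed bases other than C/T on "+"
    positions or G/A on "-" positions are non-informative and ignored.
    """
    counts: dict[Key, list[int]] = {}
    for rec in records:
        seq = genome.get(rec.contig)
        if seq is None:
            raise ValueError(f"alignment on unknown contig {rec.contig!r}")
        strand_key = "+" if rec.strand == "top" else "-"
        if rec.mate1.start < 0 or rec.mate1.end > len(seq) or rec.mate2.end > len(seq):
            raise ValueError(f"alignment outside contig bounds on {rec.contig}")
        for mate_positions in (rec.mate1.iter_kept(), rec.mate2.iter_kept()):
            for pos, base in mate_positions:
                key = (rec.contig, pos, strand_key)
                if key not in contexts:
                    continue
                if strand_key == "+":
                    ci, ti = base == "C", base == "T"
                else:
                    ci, ti = base == "G", base == "A"
                if ci or ti:
                    entry = counts.setdefault(key, [0, 0])
                    entry[0] += ci
                    entry[1] += ti
    return {k: (v[0], v[1]) for k, v in counts.items()}


def _dinucleotide(genome: Mapping[str, str], key: Key) -> str:
    contig, pos, strand = key
    seq = genome[contig]
    if strand == "+":
        return seq[pos: pos + 2].ljust(2, "N")
    prev = seq[pos - 1] if pos > 0 else "N"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(prev, "N")
    return "C" + comp


def call_levels(
    counts: Mapping[Key, tuple[int, int]],
    contexts: Mapping[Key, str],
    call_filter: CallFilter | None = None,
    genome: Mapping[str, str] | None = None,
) -> list[MethylationCall]:
    """Apply the informative-nucleotide floor and emit sorted calls."""
    call_filter = call_filter or CallFilter()
    calls = []
    for key in sorted(counts):
        ci, ti = counts[key]
        if ci + ti < call_filter.min_informative:
            continue
        dinuc = _dinucleotide(genome, key) if genome is not None else "NN"
        calls.append(
            MethylationCall(key[0], key[1], key[2], contexts[key], ci, ti, dinuc)
        )
    return calls


def estimate_conversion_efficiency(
    calls: Sequence[MethylationCall], control_contig: str
) -> float:
    """1 - pooled methylation level over the unmethylated control contig."""
    ci = ti = 0
    for call in calls:
        if call.contig == control_contig:
            ci += call.c_count
            ti += call.t_count
    if ci + ti == 0:
        raise ValueError(
            f"control contig {control_contig!r} absent or without informative positions"
        )
    return 1.0 - ci / (ci + ti)


def write_cgmap(calls: Iterable[MethylationCall], path: str | Path) -> None:
    """CGmap-like TSV; positions 1-based on disk, deterministic order."""
    ordered = sorted(calls, key=lambda c: c.key)
    with open(path, "w") as fh:
        fh.write(_CGMAP_HEADER)
        for c in ordered:
            base = "C" if c.strand == "+" else "G"
            fh.write(
                f"{c.contig}\t{base}\t{c.position + 1}\t{c.context}\t{c.dinucleotide}\t"
                f"{c.level:.6f}\t{c.c_count}\t{c.total}\n"
            )


def read_cgmap(path: str | Path) -> list[MethylationCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline()
        if header != _CGMAP_HEADER:
            raise ValueError(f"{path}:1: unexpected call-file header")
        for line_no, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 8:
                raise ValueError(f"{path}:{line_no}: expected 8 columns, got {len(parts)}")
            contig, base, pos, context, dinuc, _level, ci, total = parts
            try:
                pos_i, ci_i, total_i = int(pos), int(ci), int(total)
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: non-integer field ({exc})") from exc
            if base not in ("C", "G") or total_i < ci_i:
                raise ValueError(f"{path}:{line_no}: malformed call line")
            calls.append(
                MethylationCall(
                    contig, pos_i - 1, "+" if base == "C" else "-",
                    context, ci_i, total_i - ci_i, dinuc,
                )
            )
    return calls
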