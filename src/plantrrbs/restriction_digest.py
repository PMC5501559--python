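"""In silico restriction digestion and reduced-representation design.

Double digestion with methylation-insensitive endonucleases followed by
size selection restricts sequencing to a reproducible genome fraction.
This module parses cut-site specifications written as the recognition
sequence with a dash at the cut position (``"C-CGG"`` for MspI,
``"-GATC"`` for DpnII, ``"G-CWGC"`` for ApeKI), performs exhaustive
single/double digestion of a genome, size-selects the resulting
fragments, and reports the per-base genome coverage of the reduced
representation relative to the full reference length.

Coordinates are 0-based half-open throughout; fragment BED output uses
the same convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: IUPAC degenerate nucleotide codes mapped to the set of concrete bases
#: they stand for.  An N in the *genome* matches no pattern letter: the
#: regex character classes below only ever contain A/C/G/T.
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def iupac_revcomp(pattern: str) -> str:
    """Reverse complement of an IUPAC degenerate pattern."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


class CutSpecError(ValueError):
    """Raised for malformed cut-site specification strings."""


@dataclass(frozen=True)
class CutSpec:
    """A restriction enzyme recognition pattern with its cut position.

    ``recognition`` is the IUPAC pattern without the dash; ``cut_offset``
    is the index of the dash in the spec string, i.e. the number of
    pattern bases 5' of the cut on the strand being scanned.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise CutSpecError("empty recognition sequence")
        for c in self.recognition:
            if c not in IUPAC_SETS:
                raise CutSpecError(f"non-IUPAC character {c!r} in recognition {self.recognition!r}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise CutSpecError(
                f"cut offset {self.cut_offset} outside [0, {len(self.recognition)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        """True when the degenerate pattern equals its own reverse complement."""
        return self.recognition == iupac_revcomp(self.recognition)

    def format(self) -> str:
        """Render back to the dash notation, e.g. ``"C-CGG"``."""
        return self.recognition[: self.cut_offset] + "-" + self.recognition[self.cut_offset:]


def parse_cut_spec(spec: str, name: str | None = None) -> CutSpec:
    """Parse a single dash-notation cut-site string into a :class:`CutSpec`.

    >>> parse_cut_spec("C-CGG")
    CutSpec(name='C-CGG', recognition='CCGG', cut_offset=1)
    """
    spec = spec.strip().upper()
    n_dash = spec.count("-")
    if n_dash == 0:
        raise CutSpecError(f"{spec!r}: no '-' cut position")
    if n_dash > 1:
        raise CutSpecError(f"{spec!r}: multiple '-' characters")
    offset = spec.index("-")
    recognition = spec.replace("-", "")
    return CutSpec(name=name or spec, recognition=recognition, cut_offset=offset)


def parse_cut_specs(specs: str | Iterable[str]) -> list[CutSpec]:
    """Parse a comma-separated string (or iterable) of cut-site specs."""
    if isinstance(specs, str):
        specs = [s for s in specs.split(",") if s.strip()]
    return [parse_cut_spec(s) for s in specs]


@dataclass(frozen=True, order=True)
class Fragment:
    """A genomic interval of the reduced representation (0-based half-open)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid fragment [{self.start}, {self.end}) on {self.contig}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DigestConfig:
    """Size-selection window and terminal-segment handling for a digest.

    The defaults select fragments between 150 and 420 bp (inclusive on
    both ends), the predicted library insert range; segments before the
    first and after the last cut of a contig carry only one ligatable
    end and are excluded unless ``include_terminal`` is set.
    """

    min_len: int = 150
    max_len: int = 420
    include_terminal: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError(f"need 0 < min_len <= max_len, got [{self.min_len}, {self.max_len}]")


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found
    body = "".join(f"[{IUPAC_SETS[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def find_cut_positions(sequence: str, spec: CutSpec) -> list[int]:
    """All cut coordinates of one enzyme on a sequence (forward scan).

    Palindromic recognition patterns (all three enzymes used here:
    CCGG, GATC, GCWGC) need only the forward-strand scan; for a
    non-palindromic pattern the reverse-complement pattern is scanned
    too, with the mirrored cut offset.
    """
    sequence = sequence.upper()
    cuts = {m.start() + spec.cut_offset for m in _pattern_regex(spec.recognition).finditer(sequence)}
    if not spec.is_palindromic:
        rc = iupac_revcomp(spec.recognition)
        mirrored = len(spec.recognition) - spec.cut_offset
        cuts.update(
            m.start() + mirrored for m in _pattern_regex(rc).finditer(sequence)
        )
    return sorted(cuts)


def double_digest(
    genome: Mapping[str, str],
    specs: Sequence[CutSpec],
    config: DigestConfig | None = None,
) -> list[Fragment]:
    """Exhaustive (complete) digestion of a genome with one or more enzymes.

    Cut positions of all enzymes are pooled per contig; fragments are the
    intervals between consecutive cuts, then size-filtered to
    ``[min_len, max_len]``.  Any adjacent pair of cuts forms a fragment
    regardless of which enzyme produced each end.
    """
    if not specs:
        raise ValueError("at least one cut spec is required")
    config = config or DigestConfig()
    fragments: list[Fragment] = []
    for contig in genome:
        seq = genome[contig]
        cuts: set[int] = set()
        for spec in specs:
            cuts.update(find_cut_positions(seq, spec))
        bounds = sorted(cuts)
        segments = list(zip(bounds[:-1], bounds[1:]))
        if config.include_terminal:
            if bounds:
                if bounds[0] > 0:
                    segments.insert(0, (0, bounds[0]))
                if bounds[-1] < len(seq):
                    segments.append((bounds[-1], len(seq)))
            elif len(seq) > 0:
                segments = [(0, len(seq))]
        for start, end in segments:
            if config.min_len <= end - start <= config.max_len:
                fragments.append(Fragment(contig, start, end))
    return fragments


def in_silico_coverage(fragments: Iterable[Fragment], genome: Mapping[str, str]) -> float:
    """Percent of the genome covered by digestion fragments.

    The denominator is the full reference length including N bases.
    """
    total = sum(len(s) for s in genome.values())
    if total == 0:
        return 0.0
    covered = sum(f.length for f in fragments)
    return 100.0 * covered / total


@dataclass
class DigestReport:
    """Per-spec cut counts, fragment-length histogram and coverage summary."""

    cut_counts: dict[str, int] = field(default_factory=dict)
    n_fragments: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)
    coverage_percent: float = 0.0


def digest_report(
    genome: Mapping[str, str],
    specs: Sequence[CutSpec],
    fragments: Sequence[Fragment],
    bin_width: int = 50,
) -> DigestReport:
    report = DigestReport()
    for spec in specs:
        report.cut_counts[spec.format()] = sum(
            len(find_cut_positions(seq, spec)) for seq in genome.values()
        )
    report.n_fragments = len(fragments)
    for f in fragments:
        b = (f.length // bin_width) * bin_width
        report.length_histogram[b] = report.length_histogram.get(b, 0) + 1
    report.coverage_percent = in_silico_coverage(fragments, genome)
    return report


def write_bed(fragments: Iterable[Fragment], path: str | Path, name_prefix: str = "frag") -> None:
    """Write fragments as 4-column BED (contig, start, end, name)."""
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{name_prefix}{i}\n")


def read_bed(path: str | Path) -> list[Fragment]:
    fragments = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: expected >=3 BED columns")
            fragments.append(Fragment(parts[0], int(parts[1]), int(parts[2])))
    return fragments
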