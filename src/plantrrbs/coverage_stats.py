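"""Coverage and reproducibility statistics for RRBS replicate sets.

Implements the summary metrics used to evaluate a reduced-representation
run: per-base genome coverage (positions touched by at least one clipped
read), cytosine coverage (fraction of the genome's both-strand cytosines
with a called methylation level), the efficiency ratio between the two,
per-context union/intersection/Jaccard overlap across biological
replicates, coverage-threshold curves, recovery of predicted digestion
fragments by full read coverage, and intra-line methylation-level
homogeneity under a maximum-minus-minimum threshold.

Position identity everywhere is the strand-specific key
(contig, 0-based position, strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .bs_align import AlignmentRecord
from .meth_call import MethylationCall
from .read_simulator import Key
from .restriction_digest import Fragment


@dataclass
class CoverageSummary:
    """Per-library coverage figures in the units used for reporting."""

    genome_coverage: float  # percent
    cytosine_coverage: float  # percent
    efficiency: float  # ratio cytosine/genome coverage
    context_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ReplicateSet:
    """Per-line collection of filtered call tables."""

    line: str
    replicates: list[list[MethylationCall]]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("a replicate set needs at least one replicate")

    def position_sets(self, context: str | None = None) -> list[set[Key]]:
        return [
            {c.key for c in rep if context is None or c.context == context}
            for rep in self.replicates
        ]

    def level_tables(self) -> list[dict[Key, float]]:
        return [{c.key: c.level for c in rep} for rep in self.replicates]


def covered_positions(records: Iterable[AlignmentRecord]) -> set[tuple[str, int]]:
    """Reference positions covered by at least one clipped read base."""
    covered: set[tuple[str, int]] = set()
    for rec in records:
        for s, e in [(rec.mate1.start, rec.mate1.end), *rec.mate2.kept]:
            covered.update((rec.contig, p) for p in range(s, e))
    return covered


def genome_coverage(records: Iterable[AlignmentRecord], genome_length: int) -> float:
    """Percent of genome positions covered by >= 1 clipped read."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    return 100.0 * len(covered_positions(records)) / genome_length


def total_genome_cytosines(genome: Mapping[str, str]) -> int:
    """Both-strand cytosine count: C plus G bases in the reference."""
    return sum(seq.count("C") + seq.count("G") for seq in genome.values())


def cytosine_coverage(
    calls: Sequence[MethylationCall] | Iterable[int] | int,
    total_cytosines: int,
) -> float:
    """Percent of genome cytosines (both strands) with a called level.

    Accepts a list of calls, an iterable of per-context counts, or a
    single total count, so printed table counts can be re-checked
    directly.
    """
    if total_cytosines <= 0:
        raise ValueError("total cytosine count must be positive")
    if isinstance(calls, int):
        n = calls
    else:
        calls = list(calls)
        n = len(calls) if calls and isinstance(calls[0], MethylationCall) else sum(calls)
    return 100.0 * n / total_cytosines


def efficiency_ratio(cytosine_coverage_pct: float, genome_coverage_pct: float) -> float:
    """Ratio of cytosine coverage to genome coverage (both in percent)."""
    if genome_coverage_pct == 0:
        raise ValueError("efficiency undefined at zero genome coverage")
    return cytosine_coverage_pct / genome_coverage_pct


def union_intersection(position_sets: Sequence[set[Key]]) -> tuple[int, int, float]:
    """(|union|, |intersection|, Jaccard %) over replicate position sets."""
    if not position_sets:
        raise ValueError("need at least one replicate position set")
    union = set().union(*position_sets)
    inter = set(position_sets[0]).intersection(*position_sets[1:])
    jaccard = 100.0 * len(inter) / len(union) if union else 0.0
    return len(union), len(inter), jaccard


def jaccard_percent(intersection_count: int, union_count: int) -> float:
    """Jaccard similarity in percent from printed/pre-computed set sizes."""
    if union_count < intersection_count or intersection_count < 0:
        raise ValueError("need 0 <= intersection <= union")
    return 100.0 * intersection_count / union_count if union_count else 0.0


def union_cytosine_percent(context_counts: Iterable[int], total_cytosines: int) -> float:
    """Percent of genome cytosines in the summed per-context position counts."""
    if total_cytosines <= 0:
        raise ValueError("total cytosine count must be positive")
    return 100.0 * sum(context_counts) / total_cytosines


def coverage_threshold_curve(
    counts: Mapping[Key, tuple[int, int]], max_k: int = 30
) -> list[tuple[int, int]]:
    """(k, number of positions with >= k informative nucleotides) table."""
    depths = sorted((ci + ti for ci, ti in counts.values()), reverse=True)
    curve = []
    for k in range(1, max_k + 1):
        # depths sorted descending: count entries >= k
        lo, hi = 0, len(depths)
        while lo < hi:
            mid = (lo + hi) // 2
            if depths[mid] >= k:
                lo = mid + 1
            else:
                hi = mid
        curve.append((k, lo))
    return curve


def fragment_recovery(
    fragments: Sequence[Fragment], records: Iterable[AlignmentRecord]
) -> float:
    """Percent of predicted fragments whose every base is read-covered."""
    if not fragments:
        return 0.0
    covered = covered_positions(records)
    n_full = sum(
        all((f.contig, p) in covered for p in range(f.start, f.end)) for f in fragments
    )
    return 100.0 * n_full / len(fragments)


def intra_line_homogeneity(
    level_tables: Sequence[Mapping[Key, float]], threshold: float = 25.0
) -> float:
    """Percent of intersection positions with consistent levels.

    A position is consistent when the spread between the highest and the
    lowest replicate methylation level is strictly below ``threshold``
    percentage points.
    """
    if not level_tables:
        raise ValueError("need at least one replicate level table")
    common = set(level_tables[0]).intersection(*map(set, level_tables[1:]))
    if not common:
        raise ValueError("no common positions across replicates")
    consistent = 0
    for key in common:
        levels = [t[key] for t in level_tables]
        if (max(levels) - min(levels)) * 100.0 < threshold:
            consistent += 1
    return 100.0 * consistent / len(common)


def summarize_library(
    records: Iterable[AlignmentRecord],
    calls: Sequence[MethylationCall],
    genome: Mapping[str, str],
) -> CoverageSummary:
    """Genome coverage, cytosine coverage and efficiency for one library."""
    glen = sum(len(s) for s in genome.values())
    total_c = total_genome_cytosines(genome)
    gcov = genome_coverage(records, glen)
    ccov = cytosine_coverage(calls, total_c)
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.context] = counts.get(c.context, 0) + 1
    return CoverageSummary(gcov, ccov, efficiency_ratio(ccov, gcov), counts)
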