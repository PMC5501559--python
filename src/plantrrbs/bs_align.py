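"""Read preprocessing and alignment against a cut-site-restricted index.

Reduced-representation bisulfite reads start at restriction cut sites,
so instead of indexing the whole genome the aligner indexes only the
digestion fragments, in both bisulfite-converted spaces: a C->T version
of each fragment (matching reads from original top-strand molecules) and
a G->A version (original bottom strand).  Because library inserts are
fragment-sized, every properly paired read anchors at a fragment end;
the seed table therefore maps the converted 20-mers at fragment ends to
their (fragment, strand, mate role) of origin, and extension simply
counts mismatches in converted space over the full read.

A pair is accepted only when both mates hit the same fragment in proper
orientation, the insert (= fragment length) is at most ``max_insert``,
each mate has at most ``max_mismatches`` converted-space mismatches and
the best-scoring location is unique; ambiguous best hits are dropped.
Overlapping mates are clipped after alignment so no reference position
is counted twice in the pileup.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .restriction_digest import CutSpec, DigestConfig, Fragment, double_digest
from .seqio import FastqRead, ct_convert, ga_convert, revcomp

SEED_K = 20


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    reads1: Sequence[FastqRead],
    reads2: Sequence[FastqRead],
    target_len: int = 50,
    min_qual: int = 20,
    min_len: int = 20,
) -> tuple[list[FastqRead], list[FastqRead]]:
    """3'-trim to a uniform length, quality-trim, drop short pairs.

    Each read is first truncated at the 3' end to ``target_len`` (so
    libraries of different read lengths become comparable), then 3'
    bases with quality below ``min_qual`` are removed; pairs in which
    either mate falls below ``min_len`` are discarded together.
    """
    if len(reads1) != len(reads2):
        raise ValueError(f"mismatched pair counts: {len(reads1)} vs {len(reads2)}")

    def trim(read: FastqRead) -> FastqRead:
        seq, quals = read.seq[:target_len], read.quals[:target_len]
        end = len(seq)
        while end > 0 and quals[end - 1] < min_qual:
            end -= 1
        return FastqRead(read.id, seq[:end], quals[:end])

    out1, out2 = [], []
    for r1, r2 in zip(reads1, reads2):
        t1, t2 = trim(r1), trim(r2)
        if len(t1.seq) >= min_len and len(t2.seq) >= min_len:
            out1.append(t1)
            out2.append(t2)
    return out1, out2


# ---------------------------------------------------------------------------
# reduced index
# ---------------------------------------------------------------------------

@dataclass
class ReducedIndex:
    """Converted fragment sequences plus an end-anchored seed table.

    For each fragment ``ct`` is the C->T converted sequence and ``ga``
    the G->A converted sequence (both in reference orientation).  Seeds
    map a converted k-mer to the fragment ends it can start a mate at:
    ``(fragment index, molecule strand, mate role)``.
    """

    fragments: list[Fragment]
    ct: list[str]
    ga: list[str]
    seeds: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def build_reduced_index(
    genome: Mapping[str, str],
    specs: Sequence[CutSpec],
    config: DigestConfig | None = None,
) -> ReducedIndex:
    """Digest the genome and index the fragments for bisulfite mapping.

    By default fragments are *not* size-filtered here (size selection is
    a library-preparation step that happened upstream; mapping should
    accept inserts of any length), which corresponds to a very wide
    :class:`DigestConfig` window.
    """
    if config is None:
        config = DigestConfig(min_len=1, max_len=10**9)
    fragments = double_digest(genome, specs, config)
    index = ReducedIndex(fragments=fragments, ct=[], ga=[])
    for i, frag in enumerate(fragments):
        seq = genome[frag.contig][frag.start:frag.end]
        ct, ga = ct_convert(seq), ga_convert(seq)
        index.ct.append(ct)
        index.ga.append(ga)
        if frag.length < SEED_K:
            continue
        # read 1 of a top-strand molecule starts at the fragment 5' end
        # in C->T space; read 2 anchors the opposite end, and the bottom
        # strand mirrors both (see simulate_reads for the geometry).
        for key, entry in (
            (ct[:SEED_K], (i, "top", "r1")),
            (revcomp(ct)[:SEED_K], (i, "top", "r2")),
            (revcomp(ga)[:SEED_K], (i, "bottom", "r1")),
            (ga[:SEED_K], (i, "bottom", "r2")),
        ):
            index.seeds.setdefault(key, []).append(entry)
    return index


# ---------------------------------------------------------------------------
# alignment records
# ---------------------------------------------------------------------------

@dataclass
class AlignedMate:
    """One aligned mate with its bases laid out in reference orientation.

    ``kept`` lists the reference sub-intervals that survive overlap
    clipping (initially the whole span).  ``base_at(pos)`` returns the
    read base observed over a reference position inside the span.
    """

    start: int
    end: int
    bases: str  # reference-oriented read bases, bases[j] covers start + j
    mismatches: int
    kept: list[tuple[int, int]] | None = None  # None means "not yet clipped"

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = [(self.start, self.end)]

    def base_at(self, pos: int) -> str:
        return self.bases[pos - self.start]

    def iter_kept(self) -> Iterable[tuple[int, str]]:
        for s, e in self.kept:
            for p in range(s, e):
                yield p, self.bases[p - self.start]

    @property
    def kept_length(self) -> int:
        return sum(e - s for s, e in self.kept)


@dataclass
class AlignmentRecord:
    """A properly paired alignment of one read pair to one fragment."""

    read_id: str
    contig: str
    strand: str  # "top" or "bottom": strand of the original molecule
    mate1: AlignedMate
    mate2: AlignedMate
    fragment_index: int = -1


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def align_pair(
    read1: FastqRead,
    read2: FastqRead,
    index: ReducedIndex,
    max_mismatches: int = 2,
    max_insert: int = 500,
) -> AlignmentRecord | None:
    """Seed-and-extend both mates against the reduced index.

    Returns ``None`` for unmappable pairs: no consistent seed, any mate
    over the mismatch ceiling, insert above ``max_insert``, or a tie
    between equally good locations.
    """
    if len(read1.seq) < SEED_K or len(read2.seq) < SEED_K:
        return None
    c1 = ct_convert(read1.seq)
    g2 = ga_convert(read2.seq)
    hits1 = {
        (i, strand)
        for i, strand, role in index.seeds.get(c1[:SEED_K], ())
        if role == "r1"
    }
    hits2 = {
        (i, strand)
        for i, strand, role in index.seeds.get(g2[:SEED_K], ())
        if role == "r2"
    }
    best: list[tuple[int, str, int, int]] = []  # (frag, strand, mm1, mm2)
    best_score: int | None = None
    for i, strand in hits1 & hits2:
        frag = index.fragments[i]
        if frag.length > max_insert or frag.length < max(len(c1), len(g2)):
            continue
        if strand == "top":
            ref1 = index.ct[i][: len(c1)]
            ref2 = revcomp(index.ct[i])[: len(g2)]
        else:
            ref1 = revcomp(index.ga[i])[: len(c1)]
            ref2 = index.ga[i][: len(g2)]
        mm1, mm2 = _mismatches(c1, ref1), _mismatches(g2, ref2)
        if mm1 > max_mismatches or mm2 > max_mismatches:
            continue
        score = mm1 + mm2
        if best_score is None or score < best_score:
            best, best_score = [(i, strand, mm1, mm2)], score
        elif score == best_score:
            best.append((i, strand, mm1, mm2))
    if len(best) != 1:
        return None
    i, strand, mm1, mm2 = best[0]
    frag = index.fragments[i]
    l1, l2 = len(read1.seq), len(read2.seq)
    if strand == "top":
        mate1 = AlignedMate(frag.start, frag.start + l1, read1.seq, mm1)
        mate2 = AlignedMate(frag.end - l2, frag.end, revcomp(read2.seq), mm2)
    else:
        mate1 = AlignedMate(frag.end - l1, frag.end, revcomp(read1.seq), mm1)
        mate2 = AlignedMate(frag.start, frag.start + l2, read2.seq, mm2)
    rid = read1.id.rsplit("/", 1)[0]
    return AlignmentRecord(rid, frag.contig, strand, mate1, mate2, fragment_index=i)


def clip_overlap(record: AlignmentRecord) -> AlignmentRecord:
    """Remove mate 2's portion overlapping mate 1 so coverage is single.

    The clipped mate keeps the (0, 1 or 2) sub-intervals of its span
    that fall outside mate 1; total covered positions equal the union of
    the two spans.
    """
    a_s, a_e = record.mate1.start, record.mate1.end
    kept: list[tuple[int, int]] = []
    for s, e in record.mate2.kept:
        if e <= a_s or s >= a_e:  # disjoint
            kept.append((s, e))
            continue
        if s < a_s:
            kept.append((s, a_s))
        if e > a_e:
            kept.append((a_e, e))
    mate2 = replace(record.mate2, kept=kept)
    return replace(record, mate2=mate2)


def align_all(
    reads1: Sequence[FastqRead],
    reads2: Sequence[FastqRead],
    index: ReducedIndex,
    max_mismatches: int = 2,
    max_insert: int = 500,
    clip: bool = True,
) -> tuple[list[AlignmentRecord], int]:
    """Align every pair; returns (records, number of unmapped pairs)."""
    if len(reads1) != len(reads2):
        raise ValueError("mismatched pair counts")
    records: list[AlignmentRecord] = []
    unmapped = 0
    for r1, r2 in zip(reads1, reads2):
        rec = align_pair(r1, r2, index, max_mismatches, max_insert)
        if rec is None:
            unmapped += 1
        else:
            records.append(clip_overlap(rec) if clip else rec)
    return records, unmapped


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

_TSV_HEADER = "read_id\tcontig\tstrand\tm1_start\tm1_end\tm1_bases\tm1_mm\tm2_start\tm2_end\tm2_bases\tm2_mm\tm2_kept\n"


def write_alignments_tsv(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Minimal SAM-like TSV with reference-oriented bases and clip info."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for r in records:
            kept = ",".join(f"{s}-{e}" for s, e in r.mate2.kept)
            fh.write(
                f"{r.read_id}\t{r.contig}\t{r.strand}\t"
                f"{r.mate1.start}\t{r.mate1.end}\t{r.mate1.bases}\t{r.mate1.mismatches}\t"
                f"{r.mate2.start}\t{r.mate2.end}\t{r.mate2.bases}\t{r.mate2.mismatches}\t{kept}\n"
            )


def read_alignments_tsv(path: str | Path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if header != _TSV_HEADER:
            raise ValueError(f"{path}: unexpected alignment TSV header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            kept = [
                (int(s), int(e))
                for s, e in (part.split("-") for part in f[11].split(",") if part)
            ]
            records.append(
                AlignmentRecord(
                    f[0], f[1], f[2],
                    AlignedMate(int(f[3]), int(f[4]), f[5], int(f[6])),
                    AlignedMate(int(f[7]), int(f[8]), f[9], int(f[10]), kept=kept),
                )
            )
    return records


def write_sam(
    records: Iterable[AlignmentRecord],
    genome: Mapping[str, str],
    path: str | Path,
) -> None:
    """Standard SAM output (pre-clipping spans; converted-space mismatch
    count in the ``XM`` tag, original-molecule strand in ``XS``)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig, seq in genome.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{len(seq)}\n")
        for r in records:
            bottom = r.strand == "bottom"
            for mate, other, mate_no in ((r.mate1, r.mate2, 1), (r.mate2, r.mate1, 2)):
                # mate orientation on the reference: mate1 of a bottom
                # molecule and mate2 of a top molecule were sequenced
                # from the minus strand of the reference.
                rev = bottom if mate_no == 1 else not bottom
                flag = 0x1 | 0x2 | (0x40 if mate_no == 1 else 0x80)
                if rev:
                    flag |= 0x10
                else:
                    flag |= 0x20
                tlen = other.end - mate.start if mate.start <= other.start else -(mate.end - other.start)
                # SEQ is stored as aligned, i.e. already reference-oriented
                fh.write(
                    f"{r.read_id}\t{flag}\t{r.contig}\t{mate.start + 1}\t255\t"
                    f"{len(mate.bases)}M\t=\t{other.start + 1}\t{tlen}\t"
                    f"{mate.bases}\t{'I' * len(mate.bases)}\t"
                    f"XM:i:{mate.mismatches}\tXS:A:{'-' if bottom else '+'}\n"
                )
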