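"""Genomic-feature annotation of called and differential cytosines.

Parses GFF3 gene models, derives introns (gaps between consecutive
exons of a transcript) and strand-aware promoter windows (2000
nucleotides upstream of the transcription start site by default), and
maps cytosine positions to every feature they overlap.  A position may
carry multiple labels; when it lies in both a non-coding and a
protein-coding gene, the shared child labels (transcript, exon, CDS)
are discarded so the protein-coding interpretation is not skewed —
except "intron", which is always retained.  Positions overlapping no
gene feature are "not-annotated"; promoters are, by the reporting
convention used here, a subset of the not-annotated space.

Methylation levels per feature are summarized in ten 10%-wide bins,
the top bin closed so a level of exactly 1 is representable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

from .meth_call import MethylationCall
from .read_simulator import Key

GENE_LABELS = ("protein_coding_gene", "non_coding_gene")
CHILD_LABELS = ("transcript", "exon", "CDS")
ALL_LABELS = (*GENE_LABELS, *CHILD_LABELS, "intron", "promoter")
#: labels that make a position count as "annotated" (gene-associated);
#: promoter deliberately excluded — it belongs to the not-annotated space.
GENE_BODY_LABELS = frozenset((*GENE_LABELS, *CHILD_LABELS, "intron"))

_TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "ncRNA", "lnc_RNA", "tRNA", "rRNA", "snoRNA", "snRNA", "miRNA",
}


@dataclass
class AnnotationConfig:
    """Promoter window length and methylation-level binning."""

    promoter_len: int = 2000
    bin_count: int = 10
    bin_width: float = 10.0

    def __post_init__(self) -> None:
        if self.promoter_len <= 0:
            raise ValueError("promoter_len must be positive")
        if abs(self.bin_count * self.bin_width - 100.0) > 1e-9:
            raise ValueError("bins must tile [0, 100]")


@dataclass
class FeatureModel:
    """Per-contig interval trees of feature labels (0-based half-open)."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def add(self, contig: str, start: int, end: int, label: str) -> None:
        if end <= start:
            return
        self.trees.setdefault(contig, IntervalTree()).addi(start, end, label)

    def labels_at(self, contig: str, position: int) -> set[str]:
        tree = self.trees.get(contig)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(position)}


def infer_introns(
    exons: Sequence[tuple[int, int]], span: tuple[int, int] | None = None
) -> list[tuple[int, int]]:
    """Gaps between consecutive exons, clipped to the transcript span."""
    ordered = sorted(exons)
    introns = []
    for (s1, e1), (s2, e2) in zip(ordered[:-1], ordered[1:]):
        gap = (e1, s2)
        if span is not None:
            gap = (max(gap[0], span[0]), min(gap[1], span[1]))
        if gap[1] > gap[0]:
            introns.append(gap)
    return introns


def promoter_window(
    gene_start: int,
    gene_end: int,
    strand: str,
    contig_length: int,
    promoter_len: int = 2000,
) -> tuple[int, int]:
    """Strand-aware upstream window, clipped at contig bounds.

    For a plus-strand gene the TSS is ``gene_start``; for a minus-strand
    gene it is ``gene_end`` (exclusive end of the 0-based span).
    """
    if strand == "+":
        return (max(0, gene_start - promoter_len), gene_start)
    return (gene_end, min(contig_length, gene_end + promoter_len))


def load_gff3(
    path: str | Path,
    contig_lengths: Mapping[str, int],
    config: AnnotationConfig | None = None,
) -> FeatureModel:
    """Build a :class:`FeatureModel` from a GFF3 file.

    Genes are classified protein-coding vs non-coding by their
    ``biotype`` attribute when present, otherwise by whether any CDS
    descends from them.  GFF3 coordinates (1-based inclusive) are
    converted to 0-based half-open here.
    """
    config = config or AnnotationConfig()
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    model = FeatureModel(contig_lengths=dict(contig_lengths))
    for gene in db.features_of_type("gene"):
        contig = gene.seqid
        g_start, g_end = gene.start - 1, gene.end
        biotype = (gene.attributes.get("biotype") or [None])[0]
        if biotype is not None:
            coding = biotype == "protein_coding"
        else:
            coding = any(True for _ in db.children(gene, featuretype="CDS"))
        model.add(contig, g_start, g_end, "protein_coding_gene" if coding else "non_coding_gene")
        length = contig_lengths.get(contig)
        if length is None:
            raise ValueError(f"GFF3 contig {contig!r} absent from the genome")
        ps, pe = promoter_window(g_start, g_end, gene.strand, length, config.promoter_len)
        model.add(contig, ps, pe, "promoter")
        for child in db.children(gene, level=1):
            if child.featuretype not in _TRANSCRIPT_TYPES:
                continue
            t_span = (child.start - 1, child.end)
            model.add(contig, *t_span, "transcript")
            exons = [
                (e.start - 1, e.end) for e in db.children(child, featuretype="exon")
            ]
            for es, ee in exons:
                model.add(contig, es, ee, "exon")
            for c in db.children(child, featuretype="CDS"):
                model.add(contig, c.start - 1, c.end, "CDS")
            for is_, ie in infer_introns(exons, t_span):
                model.add(contig, is_, ie, "intron")
    return model


def annotate_positions(
    positions: Iterable[Key], model: FeatureModel
) -> dict[Key, set[str]]:
    """Feature label set per position, after the child-feature de-dup rule."""
    out: dict[Key, set[str]] = {}
    for key in positions:
        labels = model.labels_at(key[0], key[1])
        if "protein_coding_gene" in labels and "non_coding_gene" in labels:
            labels = labels - set(CHILD_LABELS)
        out[key] = labels
    return out


def summarize_categories(annotations: Mapping[Key, set[str]]) -> Counter:
    """Counts for the reporting categories, with multiple counting.

    ``annotated`` counts positions carrying any gene-body label;
    ``not_annotated`` the rest (including promoter-only positions, since
    promoters belong to the not-annotated space by convention);
    ``gene`` counts positions inside a gene span of either biotype, and
    ``promoter`` positions inside any promoter window.  Counts per
    gene-body label are included as well; one position can contribute to
    several categories.
    """
    counts: Counter = Counter()
    for labels in annotations.values():
        if labels & GENE_BODY_LABELS:
            counts["annotated"] += 1
        else:
            counts["not_annotated"] += 1
        if labels & set(GENE_LABELS):
            counts["gene"] += 1
        if "promoter" in labels:
            counts["promoter"] += 1
        for label in labels & GENE_BODY_LABELS:
            counts[label] += 1
    return counts


def bin_levels(
    levels_by_feature: Mapping[str, Sequence[float]],
    config: AnnotationConfig | None = None,
) -> dict[str, list[float]]:
    """Proportion of calls per 10%-methylation-level bin, per feature.

    Bins are [0,10), [10,20), ..., [90,100] on level x 100; proportions
    sum to 1 for every feature with at least one call.
    """
    config = config or AnnotationConfig()
    out: dict[str, list[float]] = {}
    for feature, levels in levels_by_feature.items():
        counts = [0] * config.bin_count
        for level in levels:
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"level {level} outside [0, 1]")
            idx = min(int(level * 100.0 // config.bin_width), config.bin_count - 1)
            counts[idx] += 1
        total = sum(counts)
        out[feature] = [c / total for c in counts] if total else [0.0] * config.bin_count
    return out


def annotate_calls(
    calls: Sequence[MethylationCall], model: FeatureModel
) -> tuple[dict[Key, set[str]], dict[str, list[float]]]:
    """Label calls and collect per-feature level lists (for binning)."""
    annotations = annotate_positions([c.key for c in calls], model)
    by_feature: dict[str, list[float]] = {}
    for call in calls:
        labels = annotations[call.key]
        targets = labels if labels else {"not_annotated"}
        for label in targets:
            by_feature.setdefault(label, []).append(call.level)
    return annotations, by_feature


def write_annotations_tsv(
    annotations: Mapping[Key, set[str]], path: str | Path
) -> None:
    """One row per position-label pair (label 'not_annotated' if none)."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tstrand\tfeature\n")
        for key in sorted(annotations):
            labels = sorted(annotations[key]) or ["not_annotated"]
            for label in labels:
                fh.write(f"{key[0]}\t{key[1]}\t{key[2]}\t{label}\n")


def write_bin_matrix(
    bins: Mapping[str, Sequence[float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        n = len(next(iter(bins.values()))) if bins else 10
        header = "\t".join(f"bin_{int(i * 100 / n)}_{int((i + 1) * 100 / n)}" for i in range(n))
        fh.write(f"feature\t{header}\n")
        for feature in sorted(bins):
            fh.write(feature + "\t" + "\t".join(f"{p:.6f}" for p in bins[feature]) + "\n")
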