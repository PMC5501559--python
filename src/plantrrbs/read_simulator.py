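"""Synthetic genomes, methylation truth and directional bisulfite reads.

This module is the package's synthetic-data generator.  It builds random
test genomes (with a dedicated always-unmethylated control contig that
emulates the chloroplast conversion control), assigns each cytosine its
sequence context (CG, CHG or CHH, with H = A, T or C, on both strands),
draws a per-position methylation truth from per-context probabilities,
and emits directional paired-end bisulfite FASTQ reads from
size-selected restriction fragments.

The directional protocol is modelled as in methylated-adapter library
construction: each sequenced fragment copy derives from the original top
or bottom genomic strand with equal probability; read 1 is the first
``read_len`` nucleotides of the bisulfite-converted strand 5'->3' and
read 2 is the reverse complement of its last ``read_len`` nucleotides.
An unmethylated cytosine reads as T with probability
``conversion_efficiency``; a methylated cytosine reads as T with
probability ``inappropriate_conversion`` (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .restriction_digest import Fragment
from .seqio import FastqRead, revcomp

#: context truth keys are (contig, 0-based position, strand); strand "+"
#: marks a reference C, "-" a reference G (a cytosine on the bottom strand).
Key = tuple[str, int, str]

CONTEXTS = ("CG", "CHG", "CHH")
_H = frozenset("ACT")          # H on the strand carrying the cytosine
_H_REF_MINUS = frozenset("TGA")  # reference bases whose complement is in H


@dataclass
class MethylationProfile:
    """Per-context methylation probabilities plus per-position overrides.

    Defaults emulate a CG-rich plant methylome (high symmetric CG, moderate
    CHG, sparse CHH).  ``control_contig`` names a contig whose cytosines are
    always unmethylated, standing in for the chloroplast genome used to
    measure bisulfite conversion efficiency.
    """

    context_prob: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.7, "CHG": 0.4, "CHH": 0.05}
    )
    overrides: dict[Key, float] = field(default_factory=dict)
    control_contig: str | None = None

    def __post_init__(self) -> None:
        for ctx, p in self.context_prob.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} for {ctx} outside [0, 1]")
        for key, p in self.overrides.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"override probability {p} at {key} outside [0, 1]")


@dataclass
class SimConfig:
    """Read-simulation parameters.

    ``mean_depth`` is the Poisson mean number of sequenced copies per
    fragment; ``conversion_efficiency`` is the probability that an
    unmethylated C reads as T (libraries in this protocol family convert
    at ~99% or better); ``error_rate`` is a per-base substitution
    probability applied after conversion.
    """

    read_len: int = 50
    mean_depth: float = 30.0
    conversion_efficiency: float = 0.99
    inappropriate_conversion: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_efficiency", "inappropriate_conversion", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.read_len < 20:
            raise ValueError("read_len must be >= 20")


# ---------------------------------------------------------------------------
# genome and annotation generation
# ---------------------------------------------------------------------------

def random_genome(
    contig_lengths: Mapping[str, int], gc: float = 0.43, seed: int = 0
) -> dict[str, str]:
    """I.i.d. random genome with the given GC content (rice-like default)."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    return {
        name: "".join(rng.choice(bases, size=length, p=probs))
        for name, length in contig_lengths.items()
    }


@dataclass(frozen=True)
class GeneModel:
    """One synthetic gene: span, strand, coding flag and exon intervals."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    coding: bool
    exons: tuple[tuple[int, int], ...]


def synthetic_annotation(
    genome: Mapping[str, str],
    seed: int = 0,
    skip_contigs: Sequence[str] = (),
    noncoding_every: int = 5,
) -> list[GeneModel]:
    """Scatter gene models along each contig for annotation testing.

    Genes alternate strand at random, have 1-3 exons separated by
    introns, and every ``noncoding_every``-th gene is non-coding (no CDS).
    Intergenic gaps are left so that promoter windows and not-annotated
    space both exist.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    counter = 0
    for contig, seq in genome.items():
        if contig in skip_contigs:
            continue
        pos = int(rng.integers(300, 1200))
        while pos + 600 < len(seq):
            glen = int(rng.integers(600, 2001))
            end = min(pos + glen, len(seq))
            if end - pos < 300:
                break
            n_exons = int(rng.integers(1, 4))
            bounds = sorted(rng.choice(np.arange(pos + 50, end - 50), size=2 * (n_exons - 1), replace=False)) if n_exons > 1 else []
            edges = [pos, *map(int, bounds), end]
            exons = tuple((edges[2 * i], edges[2 * i + 1]) for i in range(n_exons))
            counter += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{counter}",
                    contig=contig,
                    start=pos,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    coding=(counter % noncoding_every != 0),
                    exons=exons,
                )
            )
            pos = end + int(rng.integers(300, 2500))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            biotype = "protein_coding" if g.coding else "ncRNA"
            fh.write(
                f"{g.contig}\tplantrrbs_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype={biotype}\n"
            )
            tid = f"{g.gene_id}.t1"
            ttype = "mRNA" if g.coding else "ncRNA"
            fh.write(
                f"{g.contig}\tplantrrbs_sim\t{ttype}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig}\tplantrrbs_sim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
                if g.coding:
                    fh.write(
                        f"{g.contig}\tplantrrbs_sim\tCDS\t{es + 1}\t{ee}\t.\t{g.strand}\t0\t"
                        f"ID={tid}.cds{i};Parent={tid}\n"
                    )


# ---------------------------------------------------------------------------
# cytosine contexts and methylation truth
# ---------------------------------------------------------------------------

def assign_contexts(genome: Mapping[str, str]) -> dict[Key, str]:
    """Classify every cytosine on both strands into CG / CHG / CHH.

    Plus strand: a C at i is CG when base i+1 is G, else CHG when base
    i+2 is G, else CHH.  Minus strand mirrors this on reference G
    positions reading along the bottom strand (reference positions i-1,
    i-2).  Positions whose required downstream bases run off the contig
    or are N (and that are not already CG) are excluded.
    """
    contexts: dict[Key, str] = {}
    for contig, seq in genome.items():
        n = len(seq)
        for i, base in enumerate(seq):
            if base == "C":
                if i + 1 < n and seq[i + 1] == "G":
                    contexts[(contig, i, "+")] = "CG"
                elif i + 2 < n and seq[i + 1] in _H:
                    if seq[i + 2] == "G":
                        contexts[(contig, i, "+")] = "CHG"
                    elif seq[i + 2] in _H:
                        contexts[(contig, i, "+")] = "CHH"
            elif base == "G":
                if i - 1 >= 0 and seq[i - 1] == "C":
                    contexts[(contig, i, "-")] = "CG"
                elif i - 2 >= 0 and seq[i - 1] in _H_REF_MINUS:
                    if seq[i - 2] == "C":
                        contexts[(contig, i, "-")] = "CHG"
                    elif seq[i - 2] in _H_REF_MINUS:
                        contexts[(contig, i, "-")] = "CHH"
    return contexts


def simulate_truth(
    contexts: Mapping[Key, str], profile: MethylationProfile, seed: int = 0
) -> dict[Key, bool]:
    """Independent Bernoulli methylation state per classified cytosine."""
    for key in profile.overrides:
        if key not in contexts:
            raise ValueError(f"override position {key} is not a classified cytosine")
    rng = np.random.default_rng(seed)
    truth: dict[Key, bool] = {}
    for key in sorted(contexts):
        if profile.control_contig is not None and key[0] == profile.control_contig:
            truth[key] = False
            continue
        p = profile.overrides.get(key, profile.context_prob.get(contexts[key], 0.0))
        truth[key] = bool(rng.random() < p)
    return truth


def make_epiline_truth(
    truth: Mapping[Key, bool],
    regions: Sequence[tuple[str, int, int]],
    new_prob: float,
    seed: int = 0,
) -> tuple[dict[Key, bool], set[Key]]:
    """Redraw methylation inside genomic regions at a new probability.

    Emulates an epiline: outside ``regions`` (contig, start, end) the
    truth is copied; inside, states are redrawn i.i.d. at ``new_prob``.
    Returns the new truth and the set of redrawn position keys.
    """
    rng = np.random.default_rng(seed)
    out = dict(truth)
    changed: set[Key] = set()
    for key in sorted(truth):
        contig, pos, _ = key
        if any(contig == c and s <= pos < e for c, s, e in regions):
            out[key] = bool(rng.random() < new_prob)
            changed.add(key)
    return out, changed


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadOrigin:
    """Ground-truth provenance of one simulated read pair."""

    read_id: str
    contig: str
    frag_start: int
    frag_end: int
    strand: str  # "top" or "bottom" original molecule
    r1_start: int
    r1_end: int
    r2_start: int
    r2_end: int


def _convert_strand(
    bases: list[str],
    ref_positions: Sequence[int],
    contig: str,
    strand_key: str,
    truth: Mapping[Key, bool],
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Bisulfite-convert the C positions of one molecule strand in place.

    ``bases`` is the molecule 5'->3'; ``ref_positions[j]`` is the
    reference coordinate of base j.  Cytosines not present in the truth
    table (unclassifiable near contig ends or Ns) convert as
    unmethylated.
    """
    for j, b in enumerate(bases):
        if b != "C":
            continue
        key = (contig, ref_positions[j], strand_key)
        methylated = truth.get(key, False)
        if methylated:
            if rng.random() < config.inappropriate_conversion:
                bases[j] = "T"
        else:
            if rng.random() < config.conversion_efficiency:
                bases[j] = "T"


def _apply_errors(bases: list[str], rate: float, rng: np.random.Generator) -> None:
    if rate <= 0.0:
        return
    alphabet = "ACGT"
    for j in range(len(bases)):
        if rng.random() < rate:
            others = alphabet.replace(bases[j], "") if bases[j] in alphabet else alphabet
            bases[j] = others[int(rng.integers(len(others)))]


def simulate_reads(
    fragments: Sequence[Fragment],
    genome: Mapping[str, str],
    truth: Mapping[Key, bool],
    config: SimConfig,
    id_prefix: str = "sim",
) -> tuple[list[FastqRead], list[FastqRead], list[ReadOrigin]]:
    """Directional paired-end bisulfite reads from fragment copies.

    Per fragment the copy number is Poisson(``mean_depth``); each copy
    derives from the original top or bottom strand with probability 0.5.
    Reads are truncated to the fragment length when the fragment is
    shorter than ``read_len``.  Base qualities are constant Q40.
    """
    rng = np.random.default_rng(config.seed)
    r1_out: list[FastqRead] = []
    r2_out: list[FastqRead] = []
    origins: list[ReadOrigin] = []
    serial = 0
    for frag in fragments:
        seq = genome[frag.contig][frag.start:frag.end]
        n_copies = int(rng.poisson(config.mean_depth))
        for _ in range(n_copies):
            serial += 1
            rid = f"{id_prefix}:{serial}"
            rlen = min(config.read_len, frag.length)
            top = rng.random() < 0.5
            if top:
                molecule = list(seq)
                ref_pos = list(range(frag.start, frag.end))
                strand_key = "+"
            else:
                molecule = list(revcomp(seq))
                ref_pos = list(range(frag.end - 1, frag.start - 1, -1))
                strand_key = "-"
            _convert_strand(molecule, ref_pos, frag.contig, strand_key, truth, config, rng)
            read1 = molecule[:rlen]
            read2 = [ _COMP[b] for b in reversed(molecule[-rlen:]) ]
            _apply_errors(read1, config.error_rate, rng)
            _apply_errors(read2, config.error_rate, rng)
            q = [40] * rlen
            r1_out.append(FastqRead(f"{rid}/1", "".join(read1), list(q)))
            r2_out.append(FastqRead(f"{rid}/2", "".join(read2), list(q)))
            if top:
                spans = (frag.start, frag.start + rlen, frag.end - rlen, frag.end)
            else:
                spans = (frag.end - rlen, frag.end, frag.start, frag.start + rlen)
            origins.append(
                ReadOrigin(
                    rid, frag.contig, frag.start, frag.end,
                    "top" if top else "bottom", *spans,
                )
            )
    return r1_out, r2_out, origins


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def simulate_counts_from_truth(
    contexts: Mapping[Key, str],
    truth: Mapping[Key, bool],
    mean_depth: float = 30.0,
    conversion_efficiency: float = 0.99,
    inappropriate_conversion: float = 0.0,
    seed: int = 0,
) -> dict[Key, tuple[int, int]]:
    """Draw per-position (Ci, Ti) counts directly from the truth table.

    A call-level shortcut generator for exercising the replicate
    statistics and differential-methylation stages in isolation: depth is
    Poisson per position, each read of an unmethylated cytosine converts
    with ``conversion_efficiency`` and each read of a methylated cytosine
    mis-converts with ``inappropriate_conversion``.
    """
    rng = np.random.default_rng(seed)
    counts: dict[Key, tuple[int, int]] = {}
    for key in sorted(contexts):
        depth = int(rng.poisson(mean_depth))
        if depth == 0:
            counts[key] = (0, 0)
            continue
        p_c = (1.0 - inappropriate_conversion) if truth[key] else (1.0 - conversion_efficiency)
        ci = int(rng.binomial(depth, p_c))
        counts[key] = (ci, depth - ci)
    return counts


# ---------------------------------------------------------------------------
# plain-text writers for truth and origin tables
# ---------------------------------------------------------------------------

def write_truth(
    truth: Mapping[Key, bool], contexts: Mapping[Key, str], path: str | Path
) -> None:
    """TSV: contig, 0-based position, strand, context, methylated flag."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tstrand\tcontext\tmethylated\n")
        for key in sorted(truth):
            contig, pos, strand = key
            fh.write(f"{contig}\t{pos}\t{strand}\t{contexts[key]}\t{int(truth[key])}\n")


def read_truth(path: str | Path) -> tuple[dict[Key, bool], dict[Key, str]]:
    truth: dict[Key, bool] = {}
    contexts: dict[Key, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig\t"):
            raise ValueError(f"{path}: missing truth-table header")
        for line in fh:
            contig, pos, strand, context, flag = line.rstrip("\n").split("\t")
            key = (contig, int(pos), strand)
            truth[key] = bool(int(flag))
            contexts[key] = context
    return truth, contexts


def write_origins(origins: Iterable[ReadOrigin], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tcontig\tfrag_start\tfrag_end\tstrand\t"
            "r1_start\tr1_end\tr2_start\tr2_end\n"
        )
        for o in origins:
            fh.write(
                f"{o.read_id}\t{o.contig}\t{o.frag_start}\t{o.frag_end}\t{o.strand}\t"
                f"{o.r1_start}\t{o.r1_end}\t{o.r2_start}\t{o.r2_end}\n"
            )


def read_origins(path: str | Path) -> list[ReadOrigin]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                ReadOrigin(f[0], f[1], int(f[2]), int(f[3]), f[4],
                           int(f[5]), int(f[6]), int(f[7]), int(f[8]))
            )
    return out
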