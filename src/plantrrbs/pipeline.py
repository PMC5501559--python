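"""End-to-end orchestration of the RRBS workflow.

Runs digest -> simulate -> preprocess -> align -> call -> stats -> diff
-> annotate from one structured YAML configuration, writing every
stage's standard-format outputs plus a machine-readable run manifest.
A single global seed fans out to fixed per-stage, per-replicate seeds so
any stage can be reproduced in isolation; a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import annotate_features as af
from . import bs_align, coverage_stats, diff_meth, meth_call, read_simulator, restriction_digest
from .meth_call import CallFilter
from .seqio import read_fasta, write_fasta, write_fastq

log = logging.getLogger("plantrrbs")

_DEFAULTS: dict[str, Any] = {
    "genome": None,
    "cut_sites": "C-CGG,-GATC",
    "size_selection": {"min_len": 150, "max_len": 420},
    "simulation": {
        "contig_lengths": {"chr1": 30000, "chr2": 15000},
        "control_contig": "chloro_ctrl",
        "control_length": 8000,
        "gc": 0.43,
        "profile": {"CG": 0.7, "CHG": 0.4, "CHH": 0.05},
        "depth": 30.0,
        "conversion_efficiency": 0.99,
        "inappropriate_conversion": 0.0,
        "error_rate": 0.0,
        "read_len": 50,
        "replicates": {"control": 3, "epiline": 3},
        "epiline_regions": 4,
        "epiline_region_len": 800,
        "epiline_new_prob": 0.1,
        "seed": 1,
    },
    "alignment": {"mismatches": 2, "max_insert": 500},
    "calling": {"min_informative": 10},
    "diff": {"q_threshold": 0.01, "delta_threshold": 25.0, "normalization": "median"},
    "annotation": {"gff3": None, "promoter_len": 2000},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict[str, Any]:
    """Read and validate a pipeline YAML configuration."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)


def validate_config(user: Mapping[str, Any]) -> dict[str, Any]:
    cfg = _merge(_DEFAULTS, user)
    if cfg["genome"] is not None and not Path(cfg["genome"]).exists():
        raise PipelineError(f"config: genome FASTA {cfg['genome']!r} does not exist")
    gff = cfg["annotation"]["gff3"]
    if gff is not None and not Path(gff).exists():
        raise PipelineError(f"config: GFF3 {gff!r} does not exist")
    restriction_digest.parse_cut_specs(cfg["cut_sites"])
    size = cfg["size_selection"]
    restriction_digest.DigestConfig(size["min_len"], size["max_len"])
    for ctx, p in cfg["simulation"]["profile"].items():
        if ctx not in read_simulator.CONTEXTS or not 0 <= p <= 1:
            raise PipelineError(f"config: bad profile entry {ctx}={p}")
    return cfg


def stage_seed(base: int, stage: int, replicate: int = 0) -> int:
    """Deterministic per-stage / per-replicate seed below 2**31."""
    return (base * 10007 + stage * 101 + replicate) % (2**31 - 1)


@dataclass
class RunManifest:
    seed: int = 0
    parameters: dict[str, Any] = field(default_factory=dict)
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, **counts: Any) -> None:
        self.stages[stage] = counts
        log.info("stage %-10s %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> Path:
    """Execute the whole workflow; returns the artifact directory."""
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg["simulation"]
    base_seed = int(sim["seed"])
    manifest = RunManifest(seed=base_seed, parameters=json.loads(json.dumps(cfg)))

    def guard(stage: str):
        class _Guard:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
                return False

        return _Guard()

    # ---- genome -----------------------------------------------------------
    with guard("genome"):
        if cfg["genome"] is not None:
            genome = read_fasta(cfg["genome"])
            control_contig = sim["control_contig"] if sim["control_contig"] in genome else None
        else:
            lengths = dict(sim["contig_lengths"])
            control_contig = sim["control_contig"]
            lengths[control_contig] = sim["control_length"]
            genome = read_simulator.random_genome(
                lengths, gc=sim["gc"], seed=stage_seed(base_seed, 0)
            )
            write_fasta(genome, out / "genome.fa")
        manifest.record("genome", contigs=len(genome), length=sum(map(len, genome.values())))

    # ---- digest -----------------------------------------------------------
    with guard("digest"):
        specs = restriction_digest.parse_cut_specs(cfg["cut_sites"])
        size = cfg["size_selection"]
        digest_cfg = restriction_digest.DigestConfig(size["min_len"], size["max_len"])
        fragments = restriction_digest.double_digest(genome, specs, digest_cfg)
        restriction_digest.write_bed(fragments, out / "fragments.bed")
        coverage = restriction_digest.in_silico_coverage(fragments, genome)
        manifest.record("digest", fragments=len(fragments), coverage_pct=round(coverage, 2))

    # ---- annotation (synthetic unless provided) ---------------------------
    with guard("annotation_input"):
        if cfg["annotation"]["gff3"] is None:
            skip = [control_contig] if control_contig else []
            genes = read_simulator.synthetic_annotation(
                genome, seed=stage_seed(base_seed, 1), skip_contigs=skip
            )
            gff_path = out / "annotation.gff3"
            read_simulator.write_gff3(genes, gff_path)
        else:
            gff_path = Path(cfg["annotation"]["gff3"])
        manifest.record("annotation_input", gff3=str(gff_path))

    # ---- methylation truth ------------------------------------------------
    with guard("truth"):
        contexts = read_simulator.assign_contexts(genome)
        profile = read_simulator.MethylationProfile(
            context_prob=dict(sim["profile"]), control_contig=control_contig
        )
        truth_control = read_simulator.simulate_truth(
            contexts, profile, seed=stage_seed(base_seed, 2)
        )
        rng = np.random.default_rng(stage_seed(base_seed, 3))
        regions = []
        data_contigs = [c for c in genome if c != control_contig]
        for _ in range(int(sim["epiline_regions"])):
            contig = data_contigs[int(rng.integers(len(data_contigs)))]
            start = int(rng.integers(0, max(1, len(genome[contig]) - sim["epiline_region_len"])))
            regions.append((contig, start, start + int(sim["epiline_region_len"])))
        truth_epiline, changed = read_simulator.make_epiline_truth(
            truth_control, regions, sim["epiline_new_prob"], seed=stage_seed(base_seed, 4)
        )
        read_simulator.write_truth(truth_control, contexts, out / "truth_control.tsv")
        read_simulator.write_truth(truth_epiline, contexts, out / "truth_epiline.tsv")
        with open(out / "epiline_regions.bed", "w") as fh:
            for contig, s, e in regions:
                fh.write(f"{contig}\t{s}\t{e}\tshifted\n")
        manifest.record("truth", cytosines=len(contexts), shifted=len(changed))

    # ---- per-replicate simulate / preprocess / align / call ---------------
    index = bs_align.build_reduced_index(genome, specs)
    aln_cfg = cfg["alignment"]
    call_filter = CallFilter(cfg["calling"]["min_informative"])
    call_tables: dict[str, list[list[meth_call.MethylationCall]]] = {"control": [], "epiline": []}
    records_per_rep: dict[str, list] = {}
    for line, truth in (("control", truth_control), ("epiline", truth_epiline)):
        n_reps = int(sim["replicates"][line])
        for rep in range(1, n_reps + 1):
            name = f"{line}_{rep}"
            with guard(f"simulate:{name}"):
                sconf = read_simulator.SimConfig(
                    read_len=int(sim["read_len"]),
                    mean_depth=float(sim["depth"]),
                    conversion_efficiency=float(sim["conversion_efficiency"]),
                    inappropriate_conversion=float(sim["inappropriate_conversion"]),
                    error_rate=float(sim["error_rate"]),
                    seed=stage_seed(base_seed, 5 + (line == "epiline") * 100, rep),
                )
                r1, r2, origins = read_simulator.simulate_reads(
                    fragments, genome, truth, sconf, id_prefix=name
                )
                write_fastq(r1, out / f"{name}_1.fastq")
                write_fastq(r2, out / f"{name}_2.fastq")
                read_simulator.write_origins(origins, out / f"{name}_origins.tsv")
            with guard(f"align:{name}"):
                p1, p2 = bs_align.preprocess(r1, r2, target_len=int(sim["read_len"]))
                records, unmapped = bs_align.align_all(
                    p1, p2, index,
                    max_mismatches=int(aln_cfg["mismatches"]),
                    max_insert=int(aln_cfg["max_insert"]),
                )
                bs_align.write_alignments_tsv(records, out / f"{name}.aln.tsv")
                records_per_rep[name] = records
            with guard(f"call:{name}"):
                counts = meth_call.pileup(records, genome, contexts)
                calls = meth_call.call_levels(counts, contexts, call_filter, genome)
                meth_call.write_cgmap(calls, out / f"{name}.cgmap.tsv")
                call_tables[line].append(calls)
            manifest.record(
                f"library:{name}", pairs=len(r1), mapped=len(records),
                unmapped=unmapped, calls=len(calls),
            )

    # ---- stats ------------------------------------------------------------
    with guard("stats"):
        total_c = coverage_stats.total_genome_cytosines(genome)
        summary: dict[str, Any] = {"total_genome_cytosines": total_c}
        for line in ("control", "epiline"):
            reps = call_tables[line]
            rep_set = coverage_stats.ReplicateSet(line, reps)
            line_summary: dict[str, Any] = {}
            for context in read_simulator.CONTEXTS:
                u, i, j = coverage_stats.union_intersection(rep_set.position_sets(context))
                line_summary[context] = {"union": u, "intersection": i, "jaccard_pct": round(j, 1)}
            line_summary["homogeneity_pct"] = round(
                coverage_stats.intra_line_homogeneity(rep_set.level_tables()), 1
            )
            per_rep = []
            for rep_idx, calls in enumerate(reps, 1):
                recs = records_per_rep[f"{line}_{rep_idx}"]
                cs = coverage_stats.summarize_library(recs, calls, genome)
                per_rep.append(
                    {
                        "genome_coverage_pct": round(cs.genome_coverage, 1),
                        "cytosine_coverage_pct": round(cs.cytosine_coverage, 1),
                        "efficiency": round(cs.efficiency, 1),
                    }
                )
            line_summary["replicates"] = per_rep
            summary[line] = line_summary
        if control_contig is not None:
            effs = [
                meth_call.estimate_conversion_efficiency(calls, control_contig)
                for calls in call_tables["control"] + call_tables["epiline"]
            ]
            summary["conversion_efficiency"] = [round(e, 4) for e in effs]
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest.record("stats", lines=2)

    # ---- differential methylation ----------------------------------------
    with guard("diff"):
        dconf = diff_meth.DiffConfig(
            min_informative=int(cfg["calling"]["min_informative"]),
            q_threshold=float(cfg["diff"]["q_threshold"]),
            delta_threshold=float(cfg["diff"]["delta_threshold"]),
            normalization=cfg["diff"]["normalization"],
        )
        matrix = diff_meth.unite(call_tables["control"], call_tables["epiline"], dconf)
        matrix = diff_meth.normalize_coverage(matrix, dconf.normalization)
        diff_meth.write_unite_tsv(matrix, out / "unite.tsv")
        dmcs = diff_meth.call_dmcs(matrix, dconf)
        diff_meth.write_dmc_tsv(dmcs, out / "dmc.tsv")
        manifest.record("diff", tested=len(matrix.keys), dmcs=len(dmcs))

    # ---- annotation -------------------------------------------------------
    with guard("annotate"):
        ann_cfg = af.AnnotationConfig(promoter_len=int(cfg["annotation"]["promoter_len"]))
        lengths = {c: len(s) for c, s in genome.items()}
        model = af.load_gff3(gff_path, lengths, ann_cfg)
        dmc_keys = [(d.contig, d.position, d.strand) for d in dmcs]
        annotations = af.annotate_positions(dmc_keys, model)
        af.write_annotations_tsv(annotations, out / "dmc_annotation.tsv")
        categories = af.summarize_categories(annotations)
        union_calls = [c for reps in call_tables.values() for rep in reps for c in rep]
        _, by_feature = af.annotate_calls(union_calls, model)
        af.write_bin_matrix(af.bin_levels(by_feature, ann_cfg), out / "level_bins.tsv")
        with open(out / "dmc_categories.json", "w") as fh:
            json.dump(dict(categories), fh, indent=2, sort_keys=True)
        manifest.record("annotate", dmcs=len(dmc_keys), categories=len(categories))

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {"seed": manifest.seed, "parameters": manifest.parameters, "stages": manifest.stages},
            fh, indent=2, sort_keys=True,
        )
    return out
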