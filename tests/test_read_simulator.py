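"""Synthetic data: context assignment, methylation truth, read simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plantrrbs as p
from plantrrbs.read_simulator import (
    read_origins,
    read_truth,
    simulate_counts_from_truth,
    write_origins,
    write_truth,
)
from plantrrbs.seqio import revcomp


class TestAssignContexts:
    def test_plus_strand_classification(self):
        ctx = p.assign_contexts({"c": "ACGTCAGCCT"})
        assert ctx[("c", 1, "+")] == "CG"
        assert ctx[("c", 4, "+")] == "CHG"
        assert ctx[("c", 7, "+")] == "CHH"

    def test_minus_strand_classification(self):
        ctx = p.assign_contexts({"c": "ACGTCAGCCT"})
        assert ctx[("c", 2, "-")] == "CG"
        assert ctx[("c", 6, "-")] == "CHG"

    def test_ambiguous_positions_excluded(self):
        assert p.assign_contexts({"c": "ACN"}) == {}
        # C at the last position has no downstream base at all
        assert ("c", 4, "+") not in p.assign_contexts({"c": "AAAAC"})

    def test_cg_positions_are_strand_paired(self):
        genome = p.random_genome({"c": 3000}, seed=1)
        ctx = p.assign_contexts(genome)
        plus_cg = {k[1] for k, v in ctx.items() if v == "CG" and k[2] == "+"}
        minus_cg = {k[1] for k, v in ctx.items() if v == "CG" and k[2] == "-"}
        assert {i + 1 for i in plus_cg} == minus_cg

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
    def test_partition_matches_eligible_cytosines(self, seq):
        """Every classified +strand position is a C with unambiguous
        downstream bases, and classification mirrors on the revcomp."""
        ctx = p.assign_contexts({"c": seq})
        for (contig, i, strand), context in ctx.items():
            base = seq[i]
            assert base == ("C" if strand == "+" else "G")
        # strand mirror: minus-strand contexts equal plus-strand contexts
        # of the reverse complement at the mirrored coordinate
        rc_ctx = p.assign_contexts({"c": revcomp(seq)})
        n = len(seq)
        minus = {(n - 1 - i): v for (_, i, s), v in ctx.items() if s == "-"}
        rc_plus = {i: v for (_, i, s), v in rc_ctx.items() if s == "+"}
        assert minus == rc_plus


class TestSimulateTruth:
    def test_all_zero_and_all_one_profiles(self):
        genome = p.random_genome({"c": 1000, "ctrl": 500}, seed=2)
        ctx = p.assign_contexts(genome)
        zero = p.MethylationProfile(context_prob={c: 0.0 for c in ("CG", "CHG", "CHH")})
        assert not any(p.simulate_truth(ctx, zero, seed=1).values())
        one = p.MethylationProfile(
            context_prob={c: 1.0 for c in ("CG", "CHG", "CHH")}, control_contig="ctrl"
        )
        truth = p.simulate_truth(ctx, one, seed=1)
        assert all(v for k, v in truth.items() if k[0] != "ctrl")
        assert not any(v for k, v in truth.items() if k[0] == "ctrl")

    def test_cg_fraction_within_binomial_bound(self):
        # 'CG' repeats: every cytosine on both strands is CG context
        genome = {"c": "CG" * 10_000}
        ctx = p.assign_contexts(genome)
        assert len(ctx) >= 10_000
        profile = p.MethylationProfile(context_prob={"CG": 0.7, "CHG": 0.0, "CHH": 0.0})
        truth = p.simulate_truth(ctx, profile, seed=3)
        frac = sum(truth.values()) / len(truth)
        sigma = np.sqrt(0.7 * 0.3 / len(truth))
        assert abs(frac - 0.7) <= 3 * sigma

    def test_override_on_unclassified_position_errors(self):
        genome = {"c": "ACGTACGT"}
        ctx = p.assign_contexts(genome)
        bad = p.MethylationProfile(overrides={("c", 0, "+"): 0.5})
        with pytest.raises(ValueError, match="not a classified cytosine"):
            p.simulate_truth(ctx, bad, seed=0)

    def test_deterministic_under_fixed_seed(self):
        genome = p.random_genome({"c": 2000}, seed=4)
        ctx = p.assign_contexts(genome)
        profile = p.MethylationProfile()
        assert p.simulate_truth(ctx, profile, seed=9) == p.simulate_truth(ctx, profile, seed=9)


class TestEpilineTruth:
    def test_empty_regions_identity(self):
        genome = p.random_genome({"c": 1000}, seed=5)
        ctx = p.assign_contexts(genome)
        truth = p.simulate_truth(ctx, p.MethylationProfile(), seed=5)
        out, changed = p.make_epiline_truth(truth, [], 0.1, seed=6)
        assert out == truth and changed == set()

    def test_region_redraw_shifts_pooled_level(self):
        genome = {"c": "CG" * 5000}
        ctx = p.assign_contexts(genome)
        high = p.MethylationProfile(context_prob={"CG": 0.9, "CHG": 0.0, "CHH": 0.0})
        truth = p.simulate_truth(ctx, high, seed=7)
        out, changed = p.make_epiline_truth(truth, [("c", 0, 10_000)], 0.1, seed=8)
        assert changed == set(truth)
        before = sum(truth.values()) / len(truth)
        after = sum(out.values()) / len(out)
        assert before - after == pytest.approx(0.8, abs=0.03)

    def test_outside_regions_copied(self):
        genome = p.random_genome({"c": 2000}, seed=9)
        ctx = p.assign_contexts(genome)
        truth = p.simulate_truth(ctx, p.MethylationProfile(), seed=10)
        out, changed = p.make_epiline_truth(truth, [("c", 0, 500)], 0.5, seed=11)
        assert all(k[1] < 500 for k in changed)
        for k in truth:
            if k not in changed:
                assert out[k] == truth[k]


@pytest.fixture(scope="module")
def tiny_library(mspi_dpnii):
    genome = p.random_genome({"c": 8000}, seed=20)
    frags = p.double_digest(genome, mspi_dpnii, p.DigestConfig(40, 420))
    ctx = p.assign_contexts(genome)
    return genome, frags, ctx


class TestSimulateReads:
    def test_full_conversion_removes_all_cytosine_signal(self, tiny_library):
        genome, frags, ctx = tiny_library
        truth = {k: False for k in ctx}
        cfg = p.SimConfig(conversion_efficiency=1.0, seed=21)
        r1, r2, _ = p.simulate_reads(frags, genome, truth, cfg)
        assert r1, "simulation produced no reads"
        # converted strand has no C left; read 2 is its reverse complement
        assert all("C" not in r.seq for r in r1)
        assert all("G" not in r.seq for r in r2)

    def test_all_methylated_preserves_reference(self, tiny_library):
        genome, frags, ctx = tiny_library
        truth = {k: True for k in ctx}
        cfg = p.SimConfig(inappropriate_conversion=0.0, seed=22)
        r1, r2, origins = p.simulate_reads(frags, genome, truth, cfg)
        by_id = {o.read_id: o for o in origins}
        mism = 0
        for read in r1:
            o = by_id[read.id.rsplit("/", 1)[0]]
            ref = genome[o.contig][o.r1_start:o.r1_end]
            expected = ref if o.strand == "top" else revcomp(ref)
            # cytosines outside the classified set (contig ends) still
            # convert as unmethylated; ignore those rare positions
            mism += sum(a != b for a, b in zip(read.seq, expected))
        assert mism <= len(r1) * 0.001

    def test_conversion_touches_only_cytosines(self, tiny_library):
        genome, frags, ctx = tiny_library
        truth = {k: False for k in ctx}
        cfg = p.SimConfig(conversion_efficiency=0.5, error_rate=0.0, seed=23)
        r1, _, origins = p.simulate_reads(frags, genome, truth, cfg)
        by_id = {o.read_id: o for o in origins}
        for read in r1[:500]:
            o = by_id[read.id.rsplit("/", 1)[0]]
            ref = genome[o.contig][o.r1_start:o.r1_end]
            source = ref if o.strand == "top" else revcomp(ref)
            for got, exp in zip(read.seq, source):
                if got != exp:
                    assert (exp, got) == ("C", "T")

    def test_fixed_seed_is_reproducible(self, tiny_library):
        genome, frags, ctx = tiny_library
        truth = {k: False for k in ctx}
        cfg = p.SimConfig(seed=24)
        first = p.simulate_reads(frags, genome, truth, cfg)
        second = p.simulate_reads(frags, genome, truth, cfg)
        assert first == second

    def test_empty_fragment_list(self, tiny_library):
        genome, _, ctx = tiny_library
        truth = {k: False for k in ctx}
        r1, r2, origins = p.simulate_reads([], genome, truth, p.SimConfig(seed=1))
        assert (r1, r2, origins) == ([], [], [])

    def test_reads_truncated_to_short_fragments(self, tiny_library):
        genome, _, ctx = tiny_library
        truth = {k: False for k in ctx}
        frag = p.Fragment("c", 100, 130)
        r1, r2, _ = p.simulate_reads([frag], genome, truth, p.SimConfig(seed=2))
        assert all(len(r.seq) == 30 for r in r1 + r2)


def test_counts_generator_tracks_truth():
    genome = {"c": "CG" * 3000}
    ctx = p.assign_contexts(genome)
    truth = {k: (k[1] % 4 == 0) for k in ctx}
    counts = simulate_counts_from_truth(ctx, truth, mean_depth=40, seed=5)
    for key, (ci, ti) in counts.items():
        if ci + ti < 10:
            continue
        level = ci / (ci + ti)
        assert level > 0.5 if truth[key] else level < 0.5


def test_truth_and_origin_tables_roundtrip(tmp_path, tiny_library):
    genome, frags, ctx = tiny_library
    truth = p.simulate_truth(ctx, p.MethylationProfile(), seed=30)
    path = tmp_path / "truth.tsv"
    write_truth(truth, ctx, path)
    truth2, ctx2 = read_truth(path)
    assert truth2 == truth and ctx2 == ctx
    _, _, origins = p.simulate_reads(frags[:3], genome, truth, p.SimConfig(seed=31))
    opath = tmp_path / "origins.tsv"
    write_origins(origins, opath)
    assert read_origins(opath) == origins


def test_synthetic_annotation_structure(tmp_path):
    genome = p.random_genome({"chr1": 20_000, "ctrl": 4_000}, seed=40)
    genes = p.synthetic_annotation(genome, seed=41, skip_contigs=["ctrl"])
    assert genes, "no genes placed"
    assert all(g.contig == "chr1" for g in genes)
    assert any(not g.coding for g in genes)
    for g in genes:
        assert g.start < g.end <= 20_000
        assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            assert s1 < e1 <= s2 < e2
    # genes do not overlap
    spans = sorted((g.start, g.end) for g in genes)
    assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
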