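"""Shared fixtures: a toy digestion genome and one simulated RRBS library.

The session-scoped ``sim_dataset`` fixture runs the whole computational
chain once (random genome with a control contig, MspI-DpnII digestion
with a widened size window so short fragments survive, directional read
simulation at mean depth 30 with 99% conversion, preprocessing,
alignment and calling) and is shared by the alignment, calling,
statistics and acceptance tests.
"""

from types import SimpleNamespace

import pytest

import plantrrbs as p
from plantrrbs import meth_call

TOY_SEQ = "TTCCGGAAGATCTTCCGGTT"


@pytest.fixture(scope="session")
def mspi_dpnii():
    return p.parse_cut_specs("C-CGG,-GATC")


@pytest.fixture(scope="session")
def sim_dataset(mspi_dpnii):
    genome = p.random_genome({"chr1": 50_000, "chloro_ctrl": 8_000}, seed=11)
    fragments = p.double_digest(genome, mspi_dpnii, p.DigestConfig(40, 420))
    contexts = p.assign_contexts(genome)
    profile = p.MethylationProfile(control_contig="chloro_ctrl")
    truth = p.simulate_truth(contexts, profile, seed=12)
    config = p.SimConfig(mean_depth=30.0, conversion_efficiency=0.99, seed=13)
    r1, r2, origins = p.simulate_reads(fragments, genome, truth, config)
    index = p.build_reduced_index(genome, mspi_dpnii)
    p1, p2 = p.preprocess(r1, r2)
    records, unmapped = p.align_all(p1, p2, index)
    counts = meth_call.pileup(records, genome, contexts)
    calls = meth_call.call_levels(counts, contexts, meth_call.CallFilter(10), genome)
    return SimpleNamespace(
        genome=genome,
        specs=mspi_dpnii,
        fragments=fragments,
        contexts=contexts,
        profile=profile,
        truth=truth,
        config=config,
        reads1=r1,
        reads2=r2,
        origins=origins,
        index=index,
        records=records,
        unmapped=unmapped,
        counts=counts,
        calls=calls,
    )
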