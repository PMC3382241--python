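import numpy as np
import pytest

from igloci.genome_io import Scaffold
from igloci.rss_scanner import RssModel, scan_rss
from igloci.synthetic_locus import (
    SyntheticLocusSpec,
    _build_v_cassette,
    _make_leader,
    _make_v_exon_ancestor,
    _rand_seq,
    generate_locus,
)


@pytest.fixture(scope="session")
def seed7_locus():
    """One synthetic heavy-chain locus shared by pipeline-level tests."""
    return generate_locus(SyntheticLocusSpec(seed=7))


def make_v_scaffold(seed: int, mutate=None):
    """A single V cassette embedded in random background, plus its RSS hit.

    ``mutate`` optionally transforms the cassette string before embedding
    (metamorphic defect tests).  Returns (scaffold, hit, cassette_offset,
    cassette) where the hit is the discovery-budget RSS abutting the exon.
    """
    rng = np.random.default_rng(seed)
    leader = _make_leader(rng)
    exon = _make_v_exon_ancestor(rng)
    cas = _build_v_cassette(leader, exon, rng)
    seq = cas.seq
    if mutate is not None:
        seq = mutate(seq, cas)
    left = _rand_seq(rng, 600)
    right = _rand_seq(rng, 300)
    scaffold = Scaffold.from_seq(f"v_test_{seed}", left + seq + right)
    model = RssModel(max_mismatch_total=5, max_mismatch_heptamer=5)
    exon_end_genomic = len(left) + cas.exon[1] + (len(seq) - len(cas.seq))
    hits = [
        h for h in scan_rss(scaffold, model)
        if h.strand == "+" and abs(h.heptamer_interval.start - exon_end_genomic) <= 2
    ]
    assert hits, "planted RSS not discovered"
    hit = min(hits, key=lambda h: (h.mismatches_total, abs(h.heptamer_interval.start - exon_end_genomic)))
    return scaffold, hit, len(left), cas
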