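import numpy as np
import pytest

import _oracles
from igloci.genome_io import Interval, Scaffold, revcomp
from igloci.rss_scanner import DEFAULT_HEPTAMER, DEFAULT_NONAMER, RssModel, RssHit, scan_rss
from igloci.segment_annotator import (
    AnnotatorConfig,
    Evidence,
    GeneSegment,
    call_d_segment,
    call_j_segment,
    call_v_segment,
    classify_functionality,
    find_c_exons,
    find_orfs,
    find_v_anchors,
    translate,
)
from igloci.synthetic_locus import (
    CYS1_AA,
    CYS2_AA,
    DONOR,
    TRP_AA,
    corrupt_segment,
    _make_d_core,
    _make_j_core,
    _rand_seq,
    _rss,
    _rss_upstream,
)
from conftest import make_v_scaffold


def rand_seq(seed, n):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# ORFs and anchors

def test_find_orfs_examples():
    got = find_orfs("ATGAAATAA", min_aa=2)
    assert (0, Interval(0, 6)) in got
    # a run of stop codons yields no ORF in the reading frame of the stops
    assert not any(f == 0 for f, _ in find_orfs("TAATAGTGA", min_aa=1))


def test_find_orfs_matches_naive_oracle():
    seq = rand_seq(123, 300)
    got = {(f, iv.start, iv.end) for f, iv in find_orfs(seq, min_aa=5)}
    assert got == _oracles.naive_orfs(seq, 5)


def test_find_v_anchors_on_template():
    _, _, _, cas = make_v_scaffold(1)
    exon = cas.seq[cas.exon[0] : cas.exon[1]]
    anchors = find_v_anchors(translate(exon))
    assert anchors is not None
    assert (anchors.cys1_pos, anchors.trp_pos, anchors.cys2_pos) == (CYS1_AA, TRP_AA, CYS2_AA)
    # boundaries partition the translated exon in order
    bounds = anchors.fr_cdr_boundaries
    assert bounds[0][0] == 0
    for (a, b), (c, d) in zip(bounds, bounds[1:]):
        assert a < b == c < d


def test_find_v_anchors_broken_cys_and_short():
    _, _, _, cas = make_v_scaffold(2)
    aa = translate(cas.seq[cas.exon[0] : cas.exon[1]])
    mutated = aa[:CYS2_AA] + "S" + aa[CYS2_AA + 1 :]
    assert find_v_anchors(mutated) is None
    assert find_v_anchors(aa[:80]) is None


# ---------------------------------------------------------------------------
# V calling (metamorphic over the pseudogene defect classes)

def test_call_v_functional():
    scaffold, hit, off, cas = make_v_scaffold(10)
    seg = call_v_segment(scaffold, hit)
    assert seg is not None
    assert seg.segment_type == "V" and seg.strand == "+"
    assert seg.functionality == "functional" and seg.defect_reasons == []
    assert seg.coding_interval == Interval(off + cas.exon[0], off + cas.exon[1], "+")
    # a plausible ATG-initiated leader is reported (chance upstream ATGs can
    # offer an equally valid start, so the exact interval is not unique)
    assert seg.leader_interval is not None
    lead = scaffold.seq[seg.leader_interval.start : seg.leader_interval.end]
    assert lead.startswith("ATG") and 45 <= len(lead) <= 75


@pytest.mark.parametrize("defect", ["internal_stop", "frameshift", "truncation",
                                    "rss_defect", "leader_missing"])
def test_call_v_metamorphic_defects(defect):
    """Each planted defect flips the call to pseudogene with its own tag."""
    def mutate(seq, cas):
        return corrupt_segment(
            seq, defect, seed=99,
            exon_start=cas.exon[0], exon_end=cas.exon[1],
            leader_start=cas.leader[0],
            rss_heptamer_start=cas.rss_heptamer_start,
        )

    scaffold, hit, off, cas = make_v_scaffold(20, mutate=mutate)
    seg = call_v_segment(scaffold, hit)
    assert seg is not None, defect
    assert seg.functionality == "pseudogene"
    assert defect in seg.defect_reasons


def test_call_v_minus_strand():
    scaffold, hit, off, cas = make_v_scaffold(30)
    flipped = Scaffold.from_seq("rc", revcomp(scaffold.seq))
    model = RssModel(max_mismatch_total=5, max_mismatch_heptamer=5)
    n = len(flipped)
    hits = [h for h in scan_rss(flipped, model)
            if h.strand == "-" and h.heptamer_interval.end == n - (off + cas.exon[1])]
    assert hits
    seg = call_v_segment(flipped, min(hits, key=lambda h: h.mismatches_total))
    assert seg is not None and seg.strand == "-"
    assert seg.functionality == "functional"
    # the heptamer-side boundary is exact; the acceptor-side boundary may
    # shift by a few codons when an equally supported AG exists nearby
    assert seg.coding_interval.start == n - (off + cas.exon[1])
    assert abs(seg.coding_interval.end - (n - (off + cas.exon[0]))) <= 12


def test_call_v_none_when_no_room():
    # heptamer too close to the scaffold start: no open window
    seq = _rand_seq(np.random.default_rng(0), 20) + DEFAULT_HEPTAMER + \
        _rand_seq(np.random.default_rng(1), 23) + DEFAULT_NONAMER
    sc = Scaffold.from_seq("s", seq)
    hits = [h for h in scan_rss(sc, RssModel()) if h.strand == "+"]
    for h in hits:
        assert call_v_segment(sc, h) is None


# ---------------------------------------------------------------------------
# D calling

def _make_d_scaffold(core, seed=0):
    rng = np.random.default_rng(seed)
    cassette = _rss_upstream(rng, 12) + core + _rss(rng, 12)
    seq = _rand_seq(rng, 100) + cassette + _rand_seq(rng, 100)
    sc = Scaffold.from_seq("d", seq)
    hits = scan_rss(sc, RssModel(spacer_class="12-type"))
    left = [h for h in hits if h.strand == "-" and h.heptamer_interval.end == 100 + 28]
    right = [h for h in hits if h.strand == "+" and h.heptamer_interval.start == 100 + 28 + len(core)]
    assert left and right
    pick = lambda hs: min(hs, key=lambda h: h.mismatches_total)
    return sc, pick(left), pick(right)


def test_call_d_planted_core_frames_match_bruteforce():
    core = "GGTATAGTGGGAGCTA"
    sc, left, right = _make_d_scaffold(core)
    seg = call_d_segment(sc, left, right)
    assert seg is not None
    assert seg.segment_type == "D"
    assert sc.seq[seg.coding_interval.start : seg.coding_interval.end] == core
    stops = {"TAA", "TAG", "TGA"}
    expected = frozenset(
        f for f in range(3)
        if not any(core[i : i + 3] in stops for i in range(f, len(core) - 2, 3))
    )
    assert seg.evidence.frames_open == expected
    assert seg.functionality == "functional"


def test_call_d_all_frames_closed_is_pseudogene():
    core = "TAATTAATTAATTAAT"  # stops in all three frames
    stops = {"TAA", "TAG", "TGA"}
    for f in range(3):
        assert any(core[i:i + 3] in stops for i in range(f, len(core) - 2, 3))
    sc, left, right = _make_d_scaffold(core, seed=4)
    seg = call_d_segment(sc, left, right)
    assert seg is not None
    assert seg.functionality == "pseudogene"
    assert "no_open_frame" in seg.defect_reasons


def test_call_d_rejects_wrong_spacer_class():
    core = _make_d_core(np.random.default_rng(8))
    sc, left, right = _make_d_scaffold(core, seed=8)
    wrong = RssHit(
        scaffold_id=left.scaffold_id,
        heptamer_interval=left.heptamer_interval,
        nonamer_interval=left.nonamer_interval,
        spacer_len=23,
        strand=left.strand,
        spacer_class="23-type",
        mismatches_heptamer=0,
        mismatches_nonamer=0,
        orientation=left.orientation,
    )
    assert call_d_segment(sc, wrong, right) is None


# ---------------------------------------------------------------------------
# J calling

def _make_j_scaffold(mutate_core=None, seed=0):
    rng = np.random.default_rng(seed)
    core = _make_j_core(rng)
    if mutate_core is not None:
        core = mutate_core(core)
    cassette = _rss_upstream(rng, 23) + core + DONOR
    seq = _rand_seq(rng, 100) + cassette + _rand_seq(rng, 100)
    sc = Scaffold.from_seq("j", seq)
    hits = [h for h in scan_rss(sc, RssModel())
            if h.strand == "-" and h.heptamer_interval.end == 100 + 39]
    assert hits
    return sc, min(hits, key=lambda h: h.mismatches_total), 100 + 39, core


def test_call_j_functional_with_donor_at_planted_offset():
    sc, hit, core_start, core = _make_j_scaffold()
    seg = call_j_segment(sc, hit)
    assert seg is not None
    assert seg.functionality == "functional" and seg.strand == "+"
    assert seg.donor_pos == core_start + len(core)
    assert sc.seq[seg.donor_pos : seg.donor_pos + 2] == "GT"


def test_call_j_donor_mutation_flips_to_pseudogene():
    sc, hit, core_start, core = _make_j_scaffold(seed=1)
    # destroy the donor GT; the replacement tail carries no GT dinucleotide
    # so no cryptic donor can stand in within the search range
    tail = "CTAAGT" + "ACC" * 11
    broken = sc.seq[: core_start + len(core)] + tail + sc.seq[core_start + len(core) + len(tail) :]
    sc2 = Scaffold.from_seq("j2", broken)
    seg = call_j_segment(sc2, hit)
    assert seg is not None
    assert seg.functionality == "pseudogene"
    assert "no_splice_donor" in seg.defect_reasons


def test_call_j_internal_stop():
    def add_stop(core):
        # replace a codon before the WGxG motif (motif occupies codons 8-11)
        return core[:9] + "TAA" + core[12:]

    sc, hit, _, _ = _make_j_scaffold(mutate_core=add_stop, seed=2)
    seg = call_j_segment(sc, hit)
    assert seg is not None
    assert seg.functionality == "pseudogene"
    assert "internal_stop" in seg.defect_reasons


def test_call_j_minus_strand():
    sc, hit, core_start, core = _make_j_scaffold(seed=3)
    flipped = Scaffold.from_seq("rc", revcomp(sc.seq))
    n = len(flipped)
    hits = [h for h in scan_rss(flipped, RssModel())
            if h.strand == "+" and h.heptamer_interval.start == n - (core_start - 0)]
    assert hits
    seg = call_j_segment(flipped, hits[0])
    assert seg is not None and seg.strand == "-"
    assert seg.functionality == "functional"


# ---------------------------------------------------------------------------
# constant-region homology

REF_C = (
    "GSASAPTLFPLVSCENSPSDTSSVAVGCLAQDFLPDSITFSWKYKNNSDISSTRGFPSVLRGGKYAATSQ"
    "VLLPSKDVMQGTDEHVVCKVQHPNGNKEKNVPLPV"
)


def _codons_for(protein, rng):
    from Bio.Data.CodonTable import standard_dna_table

    by_aa = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    return "".join(sorted(by_aa[aa])[0] for aa in protein)


def test_find_c_exons_plus_and_minus():
    rng = np.random.default_rng(0)
    coding = _codons_for(REF_C, rng)
    seq = _rand_seq(rng, 500) + coding + _rand_seq(rng, 400) + revcomp(coding) + _rand_seq(rng, 300)
    sc = Scaffold.from_seq("c", seq)
    hits = find_c_exons(sc, [REF_C])
    assert len(hits) == 2
    plus, minus = hits
    assert plus.strand == "+" and plus.coding_interval == Interval(500, 500 + len(coding), "+")
    assert minus.strand == "-"
    assert minus.coding_interval.start == 500 + len(coding) + 400
    # score equals the reference's self-alignment score
    from igloci.segment_annotator import _make_protein_aligner

    self_score = _make_protein_aligner().align(REF_C, REF_C).score
    assert plus.score == pytest.approx(self_score)


def test_find_c_exons_random_scaffold_empty():
    sc = Scaffold.from_seq("r", _rand_seq(np.random.default_rng(77), 20_000))
    assert find_c_exons(sc, [REF_C]) == []


def test_find_c_exons_requires_reference():
    sc = Scaffold.from_seq("r", "ACGT" * 100)
    with pytest.raises(ValueError):
        find_c_exons(sc, [])


# ---------------------------------------------------------------------------
# classification

def _v_segment(**flags):
    ev = Evidence(
        has_leader=True, intron_ok=True, orf_intact=True, has_rss=True,
        has_v_domain_anchors=True, partial_anchors=True, full_length=True,
    )
    for k, v in flags.items():
        setattr(ev, k, v)
    return GeneSegment(
        scaffold_id="s", segment_type="V",
        coding_interval=Interval(0, 296), strand="+", evidence=ev,
    )


def test_classify_all_flags_true_is_functional():
    seg = classify_functionality(_v_segment())
    assert seg.functionality == "functional" and seg.defect_reasons == []


def test_classify_enumerates_every_failed_criterion():
    seg = classify_functionality(_v_segment(orf_intact=False, has_rss=False))
    assert seg.functionality == "pseudogene"
    assert "internal_stop" in seg.defect_reasons
    assert "rss_defect" in seg.defect_reasons


def test_classify_idempotent_and_monotone():
    seg = classify_functionality(_v_segment(has_leader=False))
    once = (seg.functionality, list(seg.defect_reasons))
    again = classify_functionality(seg)
    assert (again.functionality, again.defect_reasons) == once
    # adding a defect never converts pseudogene -> functional
    seg.evidence.orf_intact = False
    worse = classify_functionality(seg)
    assert worse.functionality == "pseudogene"
    assert set(once[1]) <= set(worse.defect_reasons)


def test_classify_unknown_type_rejected():
    seg = _v_segment()
    seg.segment_type = "Z"
    with pytest.raises(ValueError):
        classify_functionality(seg)
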