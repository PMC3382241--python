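"""Synthetic immunoglobulin-locus generator with a planted-truth ledger.

Generates multi-tens-of-kb scaffolds that contain the structures the
annotation pipeline looks for — V cassettes (leader exon, GT..AG intron,
V exon with Cys/Trp/Cys anchors, 23-spacer RSS), D cassettes (12-RSS on
both flanks), J cassettes (upstream 23-RSS, [WF]GxG motif, GT splice
donor), pseudogenized copies carrying a single planted defect, optional
inverted cassettes, N-run assembly gaps and pentameric switch arrays —
embedded in i.i.d. uniform intergenic background.  Everything is
deterministic under the spec's seed, and every planted element is recorded
in a :class:`TruthLedger` against which pipeline output can be scored.

Geometry of the canonical V cassette (all lengths in nt):

    [pad 150][leader 57, ATG-initiated][intron 90, GT..AG]
    [V exon 296, 1st-CYS at aa 22, TRP at aa 37, 2nd-CYS at aa 97]
    [RSS: heptamer + 23-spacer + nonamer]

Family structure follows a star model: one ancestor exon per family,
members derived by point substitution at the stated within-family
divergence (anchors protected, no stops introduced), ancestors separated
by the between-family divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import Interval, Scaffold, revcomp

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"
DONOR = "GTAAGT"

V_PAD = 150
V_LEADER_LEN = 57
V_INTRON_LEN = 90
V_EXON_LEN = 296
# 0-based amino-acid anchor positions within the V exon
CYS1_AA, TRP_AA, CYS2_AA = 21, 36, 96
_ANCHOR_NT = frozenset(
    range(3 * CYS1_AA, 3 * CYS1_AA + 3)
) | frozenset(range(3 * TRP_AA, 3 * TRP_AA + 3)) | frozenset(range(3 * CYS2_AA, 3 * CYS2_AA + 3))

J_CORE_LEN = 48
D_CORE_LEN = 16

# canonical 12/23 rule per locus: (V spacer, J spacer); D is always 12/12
LOCUS_SPACERS = {"IGH": (23, 23), "IGK": (12, 23), "IGL": (23, 12)}

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [a + b + c for a in _BASES for b in _BASES for c in _BASES
          if a + b + c not in _STOPS]
_SENSE_NO_MET = [c for c in _SENSE if c != "ATG"]

DEFECTS = ("internal_stop", "frameshift", "truncation", "rss_defect", "leader_missing")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _translate_frame0(nt: str) -> str:
    aa = []
    for i in range(0, len(nt) - 2, 3):
        aa.append("*" if nt[i : i + 3] in _STOPS else "A")
    return "".join(aa)


def _has_inframe_stop(nt: str) -> bool:
    return "*" in _translate_frame0(nt)


# ---------------------------------------------------------------------------
# spec

@dataclass(frozen=True)
class FamilyPlan:
    members: int
    within_divergence: float = 0.10
    between_divergence: float = 0.45


@dataclass
class SyntheticLocusSpec:
    """Study conditions for one synthetic locus."""

    seed: int = 0
    locus: str = "IGH"
    n_functional_v: int = 20
    n_pseudo_v: int = 10
    n_d: int = 5
    n_j: int = 3
    family_plan: tuple[FamilyPlan, ...] = (
        FamilyPlan(8), FamilyPlan(7), FamilyPlan(5),
    )
    pseudogene_defect_mix: dict = field(
        default_factory=lambda: {d: 1 / len(DEFECTS) for d in DEFECTS}
    )
    invert_fraction: float = 0.0
    gap_plan: tuple[int, ...] = (600, 800)
    switch_arrays: tuple[tuple[int, float], ...] = ((2500, 0.60),)
    intergenic_range: tuple[int, int] = (800, 1500)

    def __post_init__(self) -> None:
        if min(self.n_functional_v, self.n_pseudo_v, self.n_d, self.n_j) < 0:
            raise ValueError("segment counts must be >= 0")
        total = sum(self.pseudogene_defect_mix.values())
        if self.pseudogene_defect_mix and abs(total - 1.0) > 1e-9:
            raise ValueError("pseudogene_defect_mix probabilities must sum to 1")
        unknown = set(self.pseudogene_defect_mix) - set(DEFECTS)
        if unknown:
            raise ValueError(f"unknown defect tags {sorted(unknown)}")
        if sum(p.members for p in self.family_plan) != self.n_functional_v:
            raise ValueError("family plan member counts must sum to n_functional_v")
        if not (0.0 <= self.invert_fraction <= 1.0):
            raise ValueError("invert_fraction must be in [0, 1]")


@dataclass
class TruthRecord:
    id: str
    kind: str               # V / D / J / switch / gap
    interval: Interval      # coding interval (V exon, D/J core) or feature span
    strand: str
    functionality: Optional[str] = None
    defect: Optional[str] = None
    family_id: Optional[int] = None
    leader_interval: Optional[Interval] = None
    donor_pos: Optional[int] = None
    sequence: str = ""      # element sequence in gene orientation


@dataclass
class TruthLedger:
    scaffold_id: str
    records: list[TruthRecord] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    def segments(self) -> list[TruthRecord]:
        return [r for r in self.records if r.kind in ("V", "D", "J")]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "id": r.id, "kind": r.kind,
                "start": r.interval.start, "end": r.interval.end,
                "strand": r.strand, "functionality": r.functionality or "",
                "defect": r.defect or "", "family_id": r.family_id if r.family_id is not None else "",
                "leader_start": r.leader_interval.start if r.leader_interval else "",
                "leader_end": r.leader_interval.end if r.leader_interval else "",
                "donor_pos": r.donor_pos if r.donor_pos is not None else "",
                "sequence": r.sequence,
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cassette construction

def _make_leader(rng: np.random.Generator) -> str:
    """ATG-initiated, stop-free, no internal ATG in any frame."""
    while True:
        lead = "ATG" + "".join(rng.choice(_SENSE_NO_MET, size=(V_LEADER_LEN - 3) // 3))
        if "ATG" not in lead[1:]:
            return lead


def _make_v_exon_ancestor(rng: np.random.Generator) -> str:
    codons = list(rng.choice(_SENSE, size=V_EXON_LEN // 3))
    codons[CYS1_AA] = "TGC"
    codons[TRP_AA] = "TGG"
    codons[CYS2_AA] = "TGT"
    return "".join(codons) + _rand_seq(rng, V_EXON_LEN % 3)


def _mutate_exon(exon: str, divergence: float, rng: np.random.Generator) -> str:
    """Point substitutions at the given rate, protecting anchors and never
    introducing an in-frame stop."""
    n_mut = int(round(divergence * len(exon)))
    free = [i for i in range(len(exon)) if i not in _ANCHOR_NT]
    sites = rng.choice(free, size=min(n_mut, len(free)), replace=False)
    seq = list(exon)
    for i in sites:
        choices = [b for b in _BASES if b != seq[i]]
        choices = [choices[k] for k in rng.permutation(3)]
        old = seq[i]
        for b in choices:
            seq[i] = b
            cs = 3 * (i // 3)
            if "".join(seq[cs : cs + 3]) not in _STOPS:
                break
            seq[i] = old
    return "".join(seq)


def _rss(rng: np.random.Generator, spacer: int) -> str:
    return HEPTAMER + _rand_seq(rng, spacer) + NONAMER


def _rss_upstream(rng: np.random.Generator, spacer: int) -> str:
    """Upstream-of-gene RSS as it appears on the gene's own strand:
    revcomp of heptamer+spacer+nonamer, i.e. nonamer-first on the top strand."""
    return revcomp(_rss(rng, spacer))


@dataclass
class _VCassette:
    seq: str
    leader: tuple[int, int]
    exon: tuple[int, int]
    rss_heptamer_start: int


def _build_v_cassette(leader: str, exon: str, rng: np.random.Generator,
                      spacer: int = 23) -> _VCassette:
    pad = _rand_seq(rng, V_PAD)
    intron = "GT" + _rand_seq(rng, V_INTRON_LEN - 4) + "AG"
    rss = _rss(rng, spacer)
    seq = pad + leader + intron + exon + rss
    l0 = V_PAD
    e0 = V_PAD + len(leader) + V_INTRON_LEN
    return _VCassette(
        seq=seq,
        leader=(l0, l0 + len(leader)),
        exon=(e0, e0 + len(exon)),
        rss_heptamer_start=e0 + len(exon),
    )


def _make_j_core(rng: np.random.Generator) -> str:
    codons = list(rng.choice(_SENSE, size=J_CORE_LEN // 3))
    codons[8], codons[9], codons[10], codons[11] = "TGG", "GGC", "CAG", "GGA"  # W G Q G
    return "".join(codons)


def _make_d_core(rng: np.random.Generator) -> str:
    while True:
        core = _rand_seq(rng, D_CORE_LEN)
        if any("*" not in _translate_frame0(core[f:]) for f in range(3)):
            return core


def _make_switch_array(rng: np.random.Generator, length: int, occupancy: float) -> str:
    parts: list[str] = []
    total = 0
    while total < length:
        if rng.random() < occupancy:
            parts.append("GAGCT" if rng.random() < 0.5 else "GGGCT")
        else:
            parts.append(_rand_seq(rng, 5))
        total += 5
    return "".join(parts)[:length]


# ---------------------------------------------------------------------------
# corruption

def _scrub_atg(seq: str) -> str:
    while "ATG" in seq:
        seq = seq.replace("ATG", "ATC")
    return seq


def corrupt_segment(
    seq: str,
    defect: str,
    seed: int,
    *,
    exon_start: int = 0,
    exon_end: Optional[int] = None,
    leader_start: Optional[int] = None,
    rss_heptamer_start: Optional[int] = None,
) -> str:
    """Introduce exactly one pseudogenizing defect into a segment cassette.

    With only ``seq`` given, the whole string is treated as a frame-0 exon.
    Deterministic under ``seed``.

    * ``internal_stop`` — one in-frame codon (in FR3, between the TRP and
      2nd-CYS anchors when the canonical layout applies) becomes a stop.
    * ``frameshift`` — 1-2 nt deleted in the 3' half of the exon, at a site
      verified to disrupt the downstream reading frame.
    * ``truncation`` — the 3' half of the exon is removed.
    * ``rss_defect`` — three heptamer positions mutated, exceeding the
      scanner's strict heptamer budget.
    * ``leader_missing`` — the initiator ATG is destroyed (and every other
      upstream ATG scrubbed, so no cryptic start can stand in).
    """
    if defect not in DEFECTS:
        raise ValueError(f"unsupported defect {defect!r}")
    rng = np.random.default_rng(seed)
    if exon_end is None:
        exon_end = len(seq)
    exon_len = exon_end - exon_start
    canonical = exon_len == V_EXON_LEN

    if defect == "internal_stop":
        if canonical:
            lo, hi = TRP_AA + 3, CYS2_AA - 3
        else:
            lo, hi = 1, max(2, exon_len // 3 - 2)
        codon_idx = int(rng.integers(lo, hi))
        pos = exon_start + 3 * codon_idx
        stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
        return seq[:pos] + stop + seq[pos + 3 :]

    if defect == "frameshift":
        lo = exon_start + (3 * (TRP_AA + 2) if canonical else exon_len // 2)
        hi = exon_start + (3 * (CYS2_AA - 4) if canonical else exon_len - 6)
        ndel = int(rng.integers(1, 3))
        positions = list(rng.permutation(np.arange(lo, hi)))
        for pos in positions:
            cand = seq[:pos] + seq[pos + ndel :]
            new_exon = cand[exon_start : exon_end - ndel]
            if _has_inframe_stop(new_exon):
                return cand
        return seq[: positions[0]] + seq[positions[0] + ndel :]

    if defect == "truncation":
        keep = exon_len // 2
        return seq[: exon_start + keep] + seq[exon_end:]

    if defect == "rss_defect":
        if rss_heptamer_start is None:
            raise ValueError("rss_defect requires rss_heptamer_start")
        sites = rng.choice(7, size=3, replace=False)
        s = list(seq)
        for k in sites:
            pos = rss_heptamer_start + int(k)
            choices = [b for b in _BASES if b != s[pos]]
            s[pos] = choices[int(rng.integers(0, 3))]
        return "".join(s)

    # leader_missing
    if leader_start is None:
        raise ValueError("leader_missing requires leader_start")
    upstream = _scrub_atg(seq[:exon_start])
    return upstream + seq[exon_start:]


def _rss_truly_broken(cassette: str, exon_end: int, spacer: int) -> bool:
    """True when no strict-budget RSS match survives near the exon end —
    i.e. the planted defect cannot be rescued by a fortuitously shifted
    heptamer window."""
    from .rss_scanner import RssModel, scan_rss
    model = RssModel(spacer_class="23-type" if spacer >= 18 else "12-type")
    probe = Scaffold.from_seq("probe", cassette)
    for h in scan_rss(probe, model):
        if h.strand == "+" and -6 <= h.heptamer_interval.start - exon_end <= 40:
            return False
    return True


# ---------------------------------------------------------------------------
# locus assembly

def generate_locus(spec: SyntheticLocusSpec) -> tuple[Scaffold, TruthLedger]:
    """Build one synthetic locus scaffold plus its complete truth ledger.

    Deterministic under ``spec.seed``: re-running with the same spec yields
    byte-identical sequence and ledger.
    """
    rng = np.random.default_rng(spec.seed)
    leader_template = _make_leader(rng)
    v_spacer, j_spacer = LOCUS_SPACERS.get(spec.locus, (23, 23))

    # family ancestors: first drawn fresh, others mutated away from it
    ancestors: list[str] = []
    for i, plan in enumerate(spec.family_plan):
        if i == 0:
            ancestors.append(_make_v_exon_ancestor(rng))
        else:
            ancestors.append(_mutate_exon(ancestors[0], plan.between_divergence, rng))

    # plan V segments: functional members per family, pseudogenes cycling
    # through families; order shuffled so defects are not positionally biased
    v_plans: list[tuple[int, Optional[str]]] = []
    for fam_idx, plan in enumerate(spec.family_plan):
        v_plans.extend((fam_idx, None) for _ in range(plan.members))
    defect_tags = list(spec.pseudogene_defect_mix)
    defect_p = np.array([spec.pseudogene_defect_mix[t] for t in defect_tags])
    nfam = max(1, len(spec.family_plan))
    for k in range(spec.n_pseudo_v):
        tag = defect_tags[int(rng.choice(len(defect_tags), p=defect_p))]
        v_plans.append((k % nfam, tag))
    v_plans = [v_plans[i] for i in rng.permutation(len(v_plans))]

    chunks: list[str] = []
    records: list[TruthRecord] = []
    pos = 0
    gap_queue = list(spec.gap_plan)
    n_slots = len(v_plans) + spec.n_d + spec.n_j + len(spec.switch_arrays)
    gap_slots = set(
        int(x) for x in np.linspace(1, max(1, n_slots - 1), num=len(gap_queue), dtype=int)
    ) if gap_queue else set()

    carry = ""  # pre-drawn flank committed by an rss-defect QC lookahead

    def emit_intergenic(slot: int) -> None:
        nonlocal pos, carry
        seg = carry + _rand_seq(rng, int(rng.integers(*spec.intergenic_range)))
        carry = ""
        chunks.append(seg)
        pos += len(seg)
        if slot in gap_slots and gap_queue:
            glen = gap_queue.pop(0)
            records.append(TruthRecord(
                id=f"gap{len([r for r in records if r.kind == 'gap']) + 1}",
                kind="gap", interval=Interval(pos, pos + glen), strand="+",
            ))
            chunks.append("N" * glen)
            pos += glen

    slot = 0
    counters = {"V": 0, "D": 0, "J": 0, "S": 0}

    def place(cassette: str, invertible: bool = True,
              strand: Optional[str] = None) -> tuple[int, str]:
        """Append a cassette, possibly inverted; returns (offset, strand)."""
        nonlocal pos
        if strand is None:
            strand = "-" if invertible and rng.random() < spec.invert_fraction else "+"
        if strand == "-":
            cassette = revcomp(cassette)
        off = pos
        chunks.append(cassette)
        pos += len(cassette)
        return off, strand

    def to_genomic(local: tuple[int, int], off: int, clen: int, strand: str) -> Interval:
        if strand == "+":
            return Interval(off + local[0], off + local[1], "+")
        return Interval(off + clen - local[1], off + clen - local[0], "-")

    for fam_idx, defect in v_plans:
        emit_intergenic(slot); slot += 1
        counters["V"] += 1
        plan = spec.family_plan[fam_idx] if spec.family_plan else FamilyPlan(1)
        exon = _mutate_exon(ancestors[fam_idx], plan.within_divergence, rng)
        cas = _build_v_cassette(leader_template, exon, rng, spacer=v_spacer)
        seq = cas.seq
        exon_iv_local = cas.exon
        strand = "-" if rng.random() < spec.invert_fraction else "+"
        if defect is not None:
            if defect == "rss_defect":
                # the QC scan needs the true downstream flank: for a '+'
                # cassette pre-draw it (and commit it to the next
                # intergenic), for a '-' cassette it is the tail already laid
                if strand == "+":
                    carry = _rand_seq(rng, 80)
                    flank = carry
                else:
                    flank = revcomp(chunks[-1][-80:]) if chunks else ""
            else:
                flank = ""
            for _attempt in range(40):
                seed_k = int(rng.integers(0, 2**31 - 1))
                seq = corrupt_segment(
                    cas.seq, defect, seed_k,
                    exon_start=cas.exon[0], exon_end=cas.exon[1],
                    leader_start=cas.leader[0],
                    rss_heptamer_start=cas.rss_heptamer_start,
                )
                if defect != "rss_defect" or _rss_truly_broken(seq + flank, cas.exon[1], v_spacer):
                    break
                # an adversarial spacer can keep rescuing a shifted heptamer
                # window no matter how the heptamer is mutated: redraw it
                sp0 = cas.rss_heptamer_start + 7
                cas.seq = cas.seq[:sp0] + _rand_seq(rng, v_spacer) + cas.seq[sp0 + v_spacer:]
            if defect == "truncation":
                exon_iv_local = (cas.exon[0], cas.exon[0] + V_EXON_LEN // 2)
            elif defect == "frameshift":
                exon_iv_local = (cas.exon[0], cas.exon[0] + (len(seq) - len(cas.seq)) + V_EXON_LEN)
        off, strand = place(seq, strand=strand)
        iv = to_genomic(exon_iv_local, off, len(seq), strand)
        records.append(TruthRecord(
            id=f"V{counters['V']}", kind="V", interval=iv, strand=strand,
            functionality="functional" if defect is None else "pseudogene",
            defect=defect, family_id=fam_idx + 1,
            leader_interval=to_genomic(cas.leader, off, len(seq), strand),
            sequence=seq[exon_iv_local[0] : exon_iv_local[1]],
        ))

    for _ in range(spec.n_d):
        emit_intergenic(slot); slot += 1
        counters["D"] += 1
        core = _make_d_core(rng)
        cas = _rss_upstream(rng, 12) + core + _rss(rng, 12)
        off, strand = place(cas, invertible=False)  # 12/12 flanks are strand-symmetric
        records.append(TruthRecord(
            id=f"D{counters['D']}", kind="D",
            interval=Interval(off + 28, off + 28 + len(core), "+"),
            strand="+", functionality="functional", sequence=core,
        ))

    for _ in range(spec.n_j):
        emit_intergenic(slot); slot += 1
        counters["J"] += 1
        core = _make_j_core(rng)
        cas = _rss_upstream(rng, j_spacer) + core + DONOR
        off, strand = place(cas)
        rss_len = 16 + j_spacer
        local = (rss_len, rss_len + len(core))
        iv = to_genomic(local, off, len(cas), strand)
        donor_local = rss_len + len(core)
        donor = off + donor_local if strand == "+" else off + len(cas) - donor_local
        records.append(TruthRecord(
            id=f"J{counters['J']}", kind="J", interval=iv, strand=strand,
            functionality="functional", donor_pos=donor, sequence=core,
        ))

    for length, occupancy in spec.switch_arrays:
        emit_intergenic(slot); slot += 1
        counters["S"] += 1
        arr = _make_switch_array(rng, length, occupancy)
        off, _ = place(arr, invertible=False)
        records.append(TruthRecord(
            id=f"S{counters['S']}", kind="switch",
            interval=Interval(off, off + len(arr)), strand="+",
            sequence=arr,
        ))

    emit_intergenic(slot)
    scaffold = Scaffold.from_seq(f"synthetic_{spec.locus}_seed{spec.seed}", "".join(chunks))
    ledger = TruthLedger(scaffold_id=scaffold.id, records=records)
    return scaffold, ledger
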