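# Methods

This note records the models, parameter choices and numerical conventions
behind `igloci`, and what the synthetic-locus tests do and do not
demonstrate about real genome assemblies.

## Coordinates and alphabet

All internal coordinates are 0-based half-open on the top strand;
conversion to 1-based inclusive happens only in the GFF3 writer.  The
sequence alphabet is strictly `{A, C, G, T, N}`: lower-case and non-N
ambiguity codes are rejected on input rather than coerced, because the
mismatch semantics of every motif comparison are defined only over that
alphabet.  N mismatches everything, including N — a deliberate
conservative rule that prevents assembly gaps from satisfying motifs, and
implies that no called segment's coding region can overlap an N run.

## RSS model

An RSS is heptamer + spacer + nonamer, with the heptamer always
gene-proximal.  Defaults: heptamer consensus `CACAGTG`, nonamer consensus
`ACAAAAACC`, spacer ranges 11–13 bp (12-type) and 21–24 bp (23-type),
total mismatch budget 5, heptamer sub-budget 2.  The 23-type spacer range
absorbs the 22–23 bp spacers observed upstream of heavy-chain J segments
with ±1 bp of indel drift.  Notes on the budgets:

* The total budget of 5 is a ceiling (a motif search that *required* five
  mismatches would be meaningless).
* The heptamer sub-budget exists because the heptamer's CAC core is
  functionally critical and because an unpartitioned budget of 5 floods a
  scaffold with spurious nonamer-driven matches.  How the original
  FUZZNUC-style searches partitioned their budget is not documented;
  both budgets are configurable.
* The *pipeline's discovery scan* relaxes the heptamer sub-budget to the
  total budget.  This is what lets a V segment whose heptamer has decayed
  beyond the strict budget still be discovered and reported as an
  `rss_defect` pseudogene; the strict budgets then define the `has_rss`
  evidence flag that functional status requires.
* D-segment flanks use tighter budgets (total ≤ 3, heptamer ≤ 2 per
  flank).  The doubly-flanked 12/12 pattern carries far less information
  than a V exon or J motif — with the default budgets, a ~100-kb scaffold
  of random sequence yields of order one spurious facing 12/12 pair, and
  a short random core is very likely to have an open frame, so D calling
  must lean on RSS conservation.  Flanking RSSs of real D segments are
  described as conserved, which this encodes.

The scanner itself is exact: every qualifying window pair on either
strand is reported, verified set-identical to a naive enumeration oracle.
Near-duplicate hits (same heptamer window, different spacer) are
collapsed deterministically: lowest total mismatch, then shortest spacer,
then leftmost nonamer.

## V segment calling

Calling is RSS-first: each discovery-budget hit of the locus's V spacer
class anchors a search of the upstream (gene 5′) window — 450 bp for the
exon plus 400 bp of leader search space.  Candidate exon starts are AG
intron-acceptor dinucleotides; for each candidate the caller assesses

* **leader**: an ATG-initiated, stop-free exon of 45–75 nt, in frame with
  the V exon across an intron;
* **intron**: GT..AG boundaries, length 60–200 nt;
* **ORF**: no stop in leader + exon (complete codons);
* **anchors**: 1st-CYS at aa 21–25, TRP 14–20 aa later, 2nd-CYS 60–75 aa
  after the TRP (configurable windows; FR/CDR boundaries are derived from
  the anchors);
* **frameshift signature**: upstream anchors present, frame 0 broken, and
  a cysteine at the expected 2nd-CYS distance in a shifted frame — the
  footprint of a small deletion.

Candidates are ranked by evidence score, with two deliberate asymmetries:
a frameshift signature substitutes for an intact ORF in the score but can
never outscore one, and plausible exon length (270–330 nt, the span of a
typical V-REGION) outranks chance anchors in tie-breaks.  Both exist
because in random sequence an accidentally open short window is common
while genuine upstream structure is not; ranking ORF-intactness above
anchors systematically mis-segments frame-shifted pseudogenes.

A call is made on either of two gates: full coding structure
(leader + intron + ORF + anchors), or partial structure backed by a
near-perfect RSS (total mismatches ≤ 2).  The dual-evidence rule is the
package's answer to an unavoidable ambiguity: a truncated or
frame-shifted pseudogene is structurally close to background, so weaker
coding evidence demands stronger RSS evidence.  Functionality is then a
pure function of the evidence flags, and `defect_reasons` enumerates
every failed criterion.  "Partial sequence" is operationalized as an exon
shorter than 270 nt (tag `truncation`), anchors absent
(`v_domain_broken`), or a window clipped by a gap or scaffold end.
In-frame stops and frameshift signatures are reported independently —
both can hold, and a reviewer sees each line of evidence.

## D and J calling

D: a facing pair of 12-type hits (left reading on −, right on +) with a
core of 8–60 gap-free nt; `frames_open` is the set of stop-free reading
frames, and functionality requires at least one plus both flanks within
the D budgets.  The 12/12 flank pattern is strand-symmetric, so D strand
is reported as '+' unless only the reverse reading is open — a genuine
ambiguity of the motif model, documented rather than hidden.

J: the region 30–80 nt downstream of an upstream-orientation hit is
scanned for a GT donor (consensus tail `RAG`, one mismatch allowed after
the invariant GT); the exon ends at the 5′-most donor compatible with an
open frame containing the `[WF]G.G` J motif.  The motif is the calling
gate — without it, almost any open window with a chance GT would be
called — and a donor-less call additionally requires a near-perfect RSS.

C exons are local alignments (BLOSUM62, gap open −11 / extend −1) of
user-supplied constant-domain proteins against all six frames, with
iterative masking so multiple loci per frame are found; minus-strand hits
flag possible inverted remnants.  No references are bundled.

## Families, clans, trees

Identity is global Needleman–Wunsch (match +1, mismatch −1, gap open −5,
extend −1), counted over aligned columns after trimming terminal
overhangs.  Families are single-linkage components at identity > 0.70 —
single linkage because the family concept is transitive ("shares > 70%
with a member" chains) — with the 0.70–0.75 band reported as borderline
pairs, and subfamilies re-clustered at 0.80.  Family numbering is by
descending size, then leftmost genomic position.

No multiple aligner is bundled: every distance the package needs comes
from pairwise global alignments, and the bootstrap operates on an
already-aligned block supplied by the caller.  This keeps the alignment
step exchangeable (any external MSA tool can feed `bootstrap_support`)
and avoids a bespoke progressive aligner whose quality would be
untestable here.

Trees are Saitou–Nei NJ (via scikit-bio), consistent on additive
matrices — the test oracle generates random trees, derives their path
metric, and requires exact (1e-9) recovery.  Negative branch-length
estimates are clamped to zero and counted.  Bootstrap resamples columns
with replacement, rebuilds NJ per replicate, and maps bipartition
frequencies onto the full-data tree; labels are sorted internally so the
result is invariant to input order.  Clan assignment midpoint-roots the
joint segment+reference tree (an arbitrary NJ rooting can nest a segment
in the wrong clade), walks to the smallest reference-containing clade,
and takes the majority clan; ties are `unassigned`.

## Dot matrix and switch regions

The dot matrix is exact — point (i, j) iff the two 30-bp windows differ
at ≤ 9 positions — computed per diagonal with windowed cumulative sums;
no hashing heuristics, since inputs are at most a few hundred kb.

Switch regions replace visual dot-plot inspection with an explicit
segmentation: occurrences of the pentamers (GAGCT, GGGCT and their
reverse complements) are counted in a sliding 500-bp window; stretches
above 15 occurrences/kb are merged across ≤ 200 bp gaps and kept if
≥ 1 kb.  Because the window span overhangs the true array by up to one
window, each edge is trimmed to the outermost occurrence still backed by
at least half the core density within 150 bp inward; a gap-based trim is
not sufficient, since chance background pentamers (~4/kb) can chain.
These detection thresholds are calibrated only on the synthetic
generator; the 2.2–3 kb spans reported for mammalian switch regions are
the only external constraint on the defaults.

## The synthetic locus generator

The generator is the stand-in for a real assembly and defines the study
conditions: default 20 functional V in three families (8/7/5), 10 V
pseudogenes with a uniform defect mix, 5 D, 3 J, one 2.5-kb switch array
at 60% repeat occupancy, two intergenic N-gaps, i.i.d. uniform intergenic
background of 0.8–1.5 kb between cassettes (~70 kb total — desk-scale so
a 50-replicate closure test runs in seconds).  The canonical V cassette
is 150 nt pad, 57 nt leader, 90 nt GT..AG intron, 296 nt exon with
anchors at aa 22/37/97 (1-based), then the RSS.  Families follow a star
model: per-family ancestor exons at 45% mutual divergence, members at 10%
substitution divergence with anchors protected and stops excluded —
which places within-family identities above 0.75 and between-family
identities below 0.70 by construction.

Pseudogenes get exactly one defect: an in-frame stop planted in FR3
between the TRP and 2nd-CYS; a 1–2 nt deletion in the exon's 3′ half,
re-drawn until it actually breaks the frame; removal of the exon's 3′
half; three heptamer substitutions; or destruction of the initiator ATG
with every other upstream ATG scrubbed (so no cryptic start can silently
stand in).  The heptamer corruption is additionally verified against the
strict scanner on the cassette plus its real downstream flank, re-drawing
the mutation (and if necessary the RSS spacer) until no shifted window
rescues the motif — otherwise the planted truth label, not the caller,
would be wrong.  `invert_fraction` places whole cassettes on the minus
strand (default 0; V/J inversion is exercised in dedicated tests, D
strand being symmetric as noted above).

What the generator does **not** emulate: repeat/GC composition,
transposable elements, split leaders, allelic variation, indel divergence
within families, or gene conversion.  Passing the closure tests therefore
shows the pipeline implements its stated predicates correctly, not that
those predicates suffice on real genomes — on a real assembly the
mismatch budgets and the leader/intron geometry are the knobs most likely
to need loosening, and all are exposed in `AnnotatorConfig` / YAML.

## Measured behaviour

On 50 generator replicates at defaults, the pipeline recovers 99.9% of
planted segments with correct type, strand and verdict, and every
recovered pseudogene lists its planted defect; the residual failures
(≈ 1 in 2000) are chance full V structures arising inside or beside a
planted segment in random background — an irreducible feature of the
uniform-background world at these thresholds, not a calling bug.  The
same quantities are recomputed from scratch by `scripts/acceptance.py`.

## Known limitations

* Promoter/octamer elements and leader-internal splice structure are not
  modelled; the leader check is presence + intron boundaries.
* The D reading-frame criterion is "≥ 1 stop-free frame"; real D usage
  also depends on junctional processing beyond this package's scope.
* Clan assignment requires user-supplied reference V sequences spanning
  at least two clans; without references no clans are reported.
* Family thresholds operate on nucleotide identity only; amino-acid-level
  family definitions would need a different distance.
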