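# Methods

## The annotation problem

KolobokP-like DNA transposons are composite elements: an internal region
(INT) carrying the transposase machinery is flanked by two long terminal
*direct* repeats (LTDRs) of roughly 450 bp or roughly 660 bp, and each
LTDR carries its own short (11–18 bp, perfect or imperfect) terminal
inverted repeat plus the Kolobok-superfamily terminal hallmark of two
purines at the 5' end and two pyrimidines at the 3' end (5'-RR..YY-3').
Integration duplicates a 3–5-bp target site (TSD).  Genomic copies come
in a small structural vocabulary: solo LTDRs, monomers (LTDR-INT-LTDR),
shared-LTDR multimers ((LTDR-INT)<sub>n</sub>-LTDR), tandem-INT arrays
(LTDR-(INT)<sub>m</sub>-LTDR) whose INT–INT junctions show 3–4-bp
micro-deletions of the doubled edge motif, and partial forms (LTDR-INT,
INT-LTDR, solo INT) left behind when an LTDR excises together with 1–5
flanking bases on exactly one side.

The package annotates this vocabulary in genomic sequence and validates
every stage against a synthetic-genome simulator that plants each
structure with exact ground truth.

## Pipeline stages and the choices behind them

### Structural detectors (`core`)

* **TIR**: the longest arm length L in a configurable range (default
  8–30 bp) such that the first L bases match the reverse complement of
  the last L bases within a mismatch budget.  The default budget,
  `max(1, floor(0.15 L))`, encodes "perfect or imperfect"; N never
  matches anything.  One longest arm is reported, not all qualifying
  arms, because one TIR length characterizes a family.
* **Terminal signature**: a three-valued test (true / false /
  indeterminate) — an N at any of the four terminal positions makes the
  call indeterminate rather than false, so degraded copies are not
  silently counted as signature failures.
* **TSD**: longest k in [3, 6] with the k-suffix of the left flank equal
  to the k-prefix of the right flank.  Matching is exact by default with
  a one-mismatch switch; the gate that counts an insertion as having a
  "recognizable" TSD is therefore one defensible operationalization of a
  criterion the source analyses applied by expert eye.
* **Pairwise alignment** wraps Biopython's `PairwiseAligner` (affine
  gaps; a gap of length L costs `gap_open + L·gap_extend`; default
  match 2 / mismatch −3 / open −5 / extend −2).  Three modes: global,
  local, and glocal (query fully aligned, target local), the shape used
  to place a short part consensus inside a genomic window.  The first
  optimal traceback of the C implementation is taken, which is
  deterministic for fixed inputs; scores — the quantity all thresholds
  depend on — are tie-independent and are cross-checked against a
  pure-Python Smith–Waterman/Gotoh oracle.

### Scanner

Seed-and-extend, replacing a general repeat-search engine with a
focused one: exact 12-mer seeding on both strands via a numpy rolling
hash, windows grown around seed clusters, then edlib infix alignment to
locate the copy and a scoring alignment to refine it.  If the local
alignment covers ≥ 90 % of the query the hit is re-aligned glocally so
terminal mismatches cannot shave the element boundary (boundaries feed
the TSD gate, where a 1-bp error destroys an exact duplication);
truncated copies keep their local alignment and surface as hits with low
`query_coverage` rather than going missing.  Windows are re-searched
recursively left and right of each accepted hit so abutted copies
(shared LTDRs, tandem INTs) each produce their own hit.  The 75 %
identity floor is shared with the consensus-building cluster step.
Fragment merging joins same-part hits separated by ≤ 30 bp only when
their query coverages sum to ≤ 1.1 — two pieces that together exceed one
full consensus are genuinely distinct abutted copies, not fragments.

### Classifier

Hits within 200 bp of each other (same family, same contig) form one
locus; minus-strand loci are reverse-complement-normalized so tokens
read in element orientation.  The architecture grammar is deliberately
closed: anything outside the seven prototypes is COMPLEX and is reported
with a greedy longest-chunk segmentation instead of being forced into
the nearest prototype or dropped.  Census tables count accepted
(TSD-gated) loci only; solo-LTDR loci must additionally show the RR..YY
signature, since a lone LTDR-sized match has no second part to
corroborate it.

INT–INT junction micro-deletions are measured by aligning the *combined*
tandem region against a doubled INT consensus and reading off the length
deficit of the aligned spans.  The obvious per-copy method (align each
copy separately, add the tail gap and head gap) is unstable because the
split point between two abutted copies is ambiguous wherever the shared
edge motif could belong to either copy; the doubled-consensus form is
invariant to that split.

Percentages (the dimer fraction) round half-up so printed integers match
the convention of the tables they mirror.  Family diversity is the mean
percent divergence of copies from their consensus (not mean pairwise
divergence): families are defined by consensus throughout the pipeline,
so distance-to-consensus is the consistent statistic.

### Consensus builder

Greedy 75 %/75 % single-linkage clustering (seed = longest unassigned
sequence) guards the copy set; a star alignment onto the best copy gives
the column space (insertions at the same seed position are stacked, not
mutually aligned — the standard star-alignment simplification); and a
50 %-majority consensus is taken per column, with gap-majority columns
deleted and ties broken by whole-matrix base frequency then
alphabetically, flagged.

Flank extension exploits the fact that unrelated insertion loci share
sequence only inside the element: copies are re-extracted with 5,000-bp
flanks, flanks are stacked position-wise (substitution-divergence keeps
them columnwise comparable), and the element boundary is declared where
the mean per-column support over the next 20 columns drops below 0.7.
The 0.7 value separates the regimes even in the worst supported case of
two members (background mean support ≈ 0.64 for two random rows vs
≥ 0.9 inside the element at ≤ 5 % divergence); 20 columns is short
enough not to eat true termini and long enough that chance flank
agreement cannot sustain it.  Up to 10 copies (selected by descending
scanner identity) enter each round; rounds iterate until member
placements converge (max 10).  A single copy cannot terminate — there is
no flank disagreement to detect — and is returned un-extended, flagged
low-confidence.  If support never drops before the extraction window
ends (e.g. copies inserted into near-identical host repeats) the result
is flagged over-extended; the flag is sticky across rounds because later
rounds stop only after earlier ones have already swallowed shared
context.

Terminus calling scores candidate cut pairs within ±10 columns of the
support boundaries by three independent tests — RR..YY signature of the
candidate consensus, a TIR across it, and TSDs in the member flanks at
the candidate cut — and keeps the candidate passing the most tests
(member TSD count, then smallest shift, break ties).  All three flags
are reported so a consensus recovered without, say, an intact signature
is visibly weaker.

### Footprint analyzer

For partial insertions inside another repeat family, both locus flanks
are locally aligned to the host consensus (both orientations are tried,
because locus flanks are stored in element orientation); a collinear
mapping yields the reconstructed empty site.  The footprint is then read
from two breakpoints: how far the observed locus matches the empty site
from the left (t<sub>L</sub>) and from the right (t<sub>R</sub>).  An
intact insertion has overlap t<sub>L</sub> − t<sub>R</sub> equal to the
TSD length k; a one-sided deletion of d bases reduces it to k − d.
Which junction carries the deletion follows from the architecture
(LTDR-INT lost its right LTDR, INT-LTDR its left; solo INT is genuinely
two-sided-ambiguous).  Every (side, d, k) reading consistent with the
junctions is enumerated — when deleted bases equal their neighbours the
overlap inflates and several readings tie — and ranked by match to the
family's dominant TSD length, then by parsimony (fewest deleted bases).
Deletions no reading can keep within 0–5 bp mark the footprint COMPLEX;
two-sided deletions are structurally unrepresentable.  The measured
overlap is reported so callers can distinguish unambiguous junctions
(overlap = k − d exactly) from chance-extended ones.

## The simulator: what it emulates and what it does not

Planted study conditions follow the reported biology: two family models
per dataset mirroring the two LTDR length classes (473-bp LTDR with a
2,637-bp monomer; 664-bp LTDR with a 2,453-bp monomer — the
nonautonomous scale at which per-family structural censuses were
practical), 14/12-bp perfect TIRs, TATA INT edge motifs, 4/5-bp TSDs,
multimer n ≤ 4, tandem junction micro-deletions of 3 or 4 bp at either
tip, per-copy substitution divergence (indels available by flag at one
tenth the substitution rate, off by default), insertions on both
strands, and one-sided LTDR excisions deleting 0–5 flanking bases.  TSD
creation duplicates the k bases 3' of the cut (standard cut-and-paste
convention); no integration mechanism is modelled beyond its sequence
product.

The default study plants 100 insertions spanning all seven architectures
on a 2-Mb i.i.d. background at GC 0.36 (a mollusc-scale genome
composition) with ≥ 2-kb spacing.  Background sequence has no genes,
isochores, nested insertions or pre-existing repeats, so passing tests
demonstrate correctness of the structural logic, not robustness to
repeat-dense real genomes; overlapping plants are rejected rather than
nested.  The excision study plants monomers inside copies of a host
repeat (one 3-kb contig per event) and excises one LTDR with 1–5
outer-side flanking bases — the configuration in which empty-site
reconstruction is possible at all.

## Problem sizes and numerical conventions

Validation runs use a 2-Mb genome with 100 insertions for end-to-end
label/TSD recovery (about 40 s per annotate pass), 30 monomer copies on
400 kb for the consensus round trip, 100 single-excision contigs for the
footprint sweep, and 200 random pairs of ≤ 80-mers for the alignment
oracle; together they complete in a few minutes on one CPU.  All
coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive; TSVs carry a header comment naming the convention.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical outputs.

## Known limitations

* Divergence in the default conditions is substitution-only; star-MSA
  flank stacking and the ±k terminus search assume near-columnwise
  comparability and will degrade with indel-rich families.
* The scanner's split of two abutted identical copies is ambiguous at
  the shared edge motif; interval boundaries at such junctions can shift
  by up to the motif length (labels, TSDs and junction calls are
  unaffected — the junction statistic is computed split-invariantly).
* The TSD gate is exact-match by default; at ≥ 2 % divergence a mutated
  duplication or a 1–2-bp boundary error drops a genuine insertion from
  the census, mirroring the conservatism of counting only recognizable
  TSDs.
* `parse_architecture`'s COMPLEX segmentation is greedy and
  non-overlapping; chunks that would share an LTDR are split at the
  first boundary.
* Host-repeat discovery is out of scope: footprint reconstruction needs
  a user-supplied host consensus (or a second simulator family).
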