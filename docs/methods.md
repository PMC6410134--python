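# Methods

## The detection problem

A non-reference ERV insertion leaves no trace in a reference-mapped
alignment except through discordant mate pairs: one read of a pair falls
inside the inserted element (and therefore maps to an ERV sequence
library rather than to the reference point of insertion) while its mate
falls in unique flanking host DNA. With 50 nt reads and a ~3,500 nt
insert, the anchoring mate can sit anywhere up to one insert length away
from the junction, on one side of it. Each insertion therefore produces
two anchor clusters — one in the left (upstream) flank from pairs whose
ERV read entered the element across the 5′ junction, one in the right
(downstream) flank — and the pair of clusters is the locus call.

Coordinates are 0-based half-open throughout; BED is written natively and
GFF3 converted on parse. The three pools are always ordered (H, L, W).

## Junction geometry and the strand convention

With inward-pointing mate pairs the anchor's strand determines its flank:
a + anchor lies left of the junction (upstream), a − anchor right
(downstream). The ERV-side read's orientation against the consensus then
fixes the insertion orientation; the four combinations are tabulated in
`junctions.SIDE_ORIENTATION` and shared by the simulator, so the
convention is definitional rather than inferred.

Clustering is single linkage per (chromosome, side, orientation): anchors
link while the gap between their read intervals is below the insert bound
(3,500 nt), the transitive closure is then split left-to-right so no
cluster interval exceeds that bound, and clusters whose union read
footprint is under 2% of the bound (70 bases — i.e. at least two
overlapping 50 nt reads) are dropped. The footprint is the union of member
read intervals, not a per-read or summed quantity: a per-read rule is
unsatisfiable at 50 nt.

Pairing upstream with downstream clusters requires shared chromosome and
orientation, a non-empty intersection of target ERV identities, evidence
that the two clusters hit opposite ends of the element (a member read in
the 5′- respectively 3′-terminal third of the consensus, or in an LTR —
solo-LTR-derived reads map inside an LTR and either LTR counts, the two
being identical at integration; the check is skipped when consensus
lengths are unavailable), a span below 20 kb (accommodating 7–11 kb
elements plus secondary insertions), and the geometric constraint that
the upstream cluster lie entirely left of the downstream one — the two
flanks sandwich the junction, and without this constraint a greedy
matcher can cross-pair the facing clusters of two neighbouring
same-family insertions, whose separation is deceptively small. Matching
is greedy nearest-first with deterministic tie-breaks (leftmost span,
then smallest shared ERV id); unpaired clusters are reported as
half-supported but not tested. Relaxed-score reads (scores in [400, 425))
are appended to established cluster intervals only; they never create
loci.

The strict threshold of 425 can instead be tuned: `tune_to_target` sweeps
the threshold and picks the locus count closest to a target derived from
the library (about 20 solo-LTRs per full-length provirus, so ~10,000 loci
for a library of ~500 proviruses), preferring the more conservative
threshold on ties, or the most permissive one when every threshold
undershoots.

## Differential testing

Each locus yields the 2×3 table

|            | H        | L        | W        |
|------------|----------|----------|----------|
| locus      | k_H      | k_L      | k_W      |
| remainder  | T_H−k_H  | T_L−k_L  | T_W−k_W  |

where T are the line-wide ERV–host pair totals. Normalizing against
totals absorbs the pools' coverage imbalance. When min(k) < 15 the
Freeman–Halton exact test is used: enumeration over all tables with the
observed margins, multivariate-hypergeometric weights computed in log
space, p = the summed probability of tables no more probable than the
observed one (two-sided by construction; verified against R's
`fisher.test` and against an independent scipy enumeration to 1e-9).
Otherwise Pearson's chi-square with df = 2. An all-zero locus carries no
evidence and gets p = 1. Family-wise error over the m tested loci is
controlled by Bonferroni (α/m; 0.05 over 12,709 loci gives 3.9 × 10⁻⁶,
reported as 4 × 10⁻⁶ at one significant figure).

A line is called absent at a locus when its count is at or below
max(1, ⌊0.02 · expected⌋), the expectation being the locus total shared
out proportionally to the line totals; this quantifies "near-absence"
with a threshold exposed in configuration. The seven non-empty
presence patterns map onto the reporting rows; `HLW` loci (present
everywhere) are excluded from differential claims even when the
contingency test is formally significant — a fixed shared locus can beat
the corrected threshold simply because another line's totals are inflated
by loci it does not share.

Patterns are polarized on the fixed tree (((H,L),W), reference): a locus
present in the reference assembly is ancestrally present and absences are
losses; a non-reference locus is ancestrally absent and presences are
gains. When the pattern's carrier set equals one branch's clade a single
event suffices; otherwise the minimal two-event resolutions are
enumerated and the call is reported as ambiguous rather than forced.

## Landscape and phylogeny association

Gene relations are emitted for every (locus, gene) pair with a
nearest-edge gap of at most 150 kb (a TSS-anchored distance mode is
available behind a flag); overlap with the transcript is intragenic.
Distances bin at 10 kb; orientation is the locus strand against the gene
strand, with the intragenic antisense fraction tested two-sided against
0.5 (binomial). Sweep overlap uses the locus midpoint against merged
sweep intervals and an exact binomial test with p₀ = sweep bases / genome
bases. Per-pattern gene lists are exported as plain text for external
annotation services; ontology enrichment itself is out of scope.

Loci are associated to reference ERVs by summed member-read alignment
score (argmax, lexicographic tie-break, ambiguity flagged below a
configurable margin). Tree annotation is textual: comment blocks are
inserted after tip labels so topology and branch lengths are preserved
byte-for-byte (a tree writer would reformat them); dendropy validates the
newick and resolves tip labels. The clade-dispersion summary — per-clade
annotated-tip counts with a chi-square goodness-of-fit against clade
sizes — is this package's quantification of "spread across the
phylogeny"; a concentrated signal would instead indicate a
lineage-specific retroviral expansion.

## The simulator as study conditions

Defaults are the conditions of the motivating three-pool chicken design:
n = 11 diploid individuals per pool, coverage (5.53, 5.19, 3.37)×, 50 nt
reads, insert N(3500, 300²) truncated to [2L, 2·3500] (the libraries were
"3–4 kb"), full elements 7–11 kb with 300 nt LTRs, solo-LTRs 20/21 of
insertions, 1% noise pairs (mis-scored/mis-anchored; the true rate is
unknown, this is an exposed default), 25% of insertions present in the
reference assembly, alignment scores uniform on the integer range
400–493. Allele-frequency models: a shared Beta(0.5, 0.5) per insertion
(standing variation with no systematic line differences — the null),
independent per-line Beta draws, fixed triples, or a deterministic cycle
over triples for designed experiments. Pool dosage is Binomial(2n, f) per
line; reads are drawn per haplotype, treating the pool as a single DNA
mixture.

Junction-pair counts per flank are Poisson with intensity
λ = d · c/(2n) / (2L) · w, where w = min(insert − 2L, element − L): pair
starts occur at rate c/(2n)/(2L) per base per carrier haplotype and w is
the window of start positions putting one read inside the element and its
mate in the flank. Two consequences worth noting. First, element length
caps the window: a 300 nt solo-LTR gives w = 250 versus 3,400 for a full
element, so solo-LTRs at 3.4× pool coverage expect only ~8 junction pairs
per flank (~6 above the strict score threshold) — below the ≥10 pairs per
side that the recovery guarantee assumes, which is why solo-LTR recall
fluctuates a few percent below full-element recall and why the recovery
acceptance experiment plants full/truncated proviruses. Second, anchors
concentrate a full insert away from the junction for short elements, so
the junction-facing (inner) cluster edges, not the outer span bounds, are
the locus position estimates used when matching calls to truth
(tolerance: one insert length).

What the simulator does not emulate: sequencing error and colorspace
artifacts (scores are drawn, not computed from reads), reference mapping
ambiguity in repetitive flanks, chimeric library artifacts beyond the
uniform noise model, cross-mapping between related ERV families, and
linkage between nearby insertions. Passing tests therefore demonstrate
the pipeline's statistical behaviour under the assumed read-generation
model, not robustness to mapper-specific failure modes.

## Numerical and procedural choices

- Exact-test tie tolerance: tables with log-probability within 1e-9 of
  the observed one count as "as extreme" (guards against float ties).
- Chi-square is `scipy.stats.chi2_contingency` without continuity
  correction, matching the df = 2 three-group comparison.
- All randomness flows from `numpy.random.default_rng` seeded from the
  configuration; identical seeds give byte-identical fixture files.
- Greedy pairing, clustering splits and ERV assignment all carry
  deterministic tie-breaks so outputs are independent of input order.
- Problem sizes in tests and the acceptance script (200-insertion
  recovery runs, 3 × 10,000-locus null families, 600-locus orientation
  panels) were chosen to give the acceptance margins comfortable
  statistical resolution on a single CPU.
- Family-wise error calibration is asserted as at most one false
  rejection across three 10,000-locus replicate families: under
  FWER = 0.05 the probability of two or more is about 1%, making that the
  correct acceptance region at this replication level.

## Known limitations

- Solo-LTR sensitivity degrades at low pool coverage (see above); the
  survey-scale ~10,000-locus survey is represented in testing by its
  reporting arithmetic, not by a full-scale read simulation.
- Breakpoints are resolved only to cluster edges (± one insert); there is
  no split-read refinement, by design.
- The 2% footprint rule is applied per junction cluster (not per locus)
  and separation is measured between outer cluster bounds; both readings
  of the underspecified originals are flagged in code.
- Whether counts should additionally be coverage-normalized before
  testing is left as a mode; the default tests raw counts against
  line-total margins.
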