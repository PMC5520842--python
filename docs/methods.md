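# Methods

`optfam` reimplements, as a tested pipeline, the comparative-genomics
workflow used to reconstruct the evolutionary expansion of the rice
oligopeptide transporter (OsOPT) gene family: 16 members in two subfamilies
(PT and YSL) whose growth from 9 ancestral genes is explained by tandem and
segmental duplication across three stages of grass-genome history.  This
note records the models, the parameters that matter, the synthetic-data
design, and the choices made where the design was genuinely open.

## Family identification

Candidates are screened for the conserved OPT signature
`SPYxEVRxxVxxxDDP` (`x` = any residue, all other positions exact — the
standard reading of the printed motif).  Matching is a plain sliding
window; overlapping hits are all reported.

Protein parameters accompany each member:

* **Molecular weight** — sum of average residue masses plus one water
  (18.0153 Da), reported in kDa.  Masses come from Biopython's IUPAC
  average-mass table; the table is injectable so an exact cross-check
  against any other mass set is one argument away.  `X` residues get the
  mean residue mass and a logged warning.
* **Isoelectric point** — bisection over pH 0–14 for the zero of the
  Henderson–Hasselbalch net charge with a Bjellqvist/ExPASy-style pKa set
  (N-term 7.5, C-term 3.55, K 10.0, R 12.0, H 5.98, D 4.05, E 4.45,
  C 9.0, Y 10.0; injectable).  The charge is strictly decreasing in pH, so
  bisection is exact to the stated tolerance (1e-6 pH).  Different pKa
  sets shift pI by a few tenths of a unit, which is why published pI
  values are treated as ranges, not exact targets.
* **Transmembrane segments** — Kyte–Doolittle hydropathy, window 19,
  window-mean threshold 1.6, overlapping qualifying windows merged into
  segments.  This is a deterministic hydropathy flag, not an HMM topology
  predictor: it reliably separates polytopic transporters (12–16 helices,
  50–90 kDa in this family) from soluble proteins, but merged windows can
  undercount tightly packed helices.  Window and threshold are the
  classical values for membrane-span detection and are configurable.

## Phylogeny

Distances between aligned protein sequences use the Poisson correction
`d = −ln(1 − p)` on the proportion `p` of differing comparable sites.
Gap handling defaults to complete deletion (columns with any gap removed),
the distance-analysis default of the MEGA lineage of tools; pairwise
deletion is a flag.  `p = 1` has no finite Poisson distance and raises an
error naming the pair.

Trees are built by the Saitou–Nei neighbor-joining agglomeration.  Two
numerical choices are pinned for reproducibility: Q-matrix ties break at
the lowest (row, column) index pair, and negative branch estimates are
clamped to zero with the deficit moved to the sibling branch so the joined
pair's path length is preserved.  On additive matrices the tree reproduces
the input distances to ~1e-9 (verified against brute-force topology
enumeration for ≤6 taxa and against scikit-bio's NJ as an independent
implementation).

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree per replicate, and labels each internal bipartition of the
full-data tree with its replicate percentage (default 1000 replicates,
deterministic under a fixed seed).  A replicate whose resampled columns
saturate some pair is skipped and removed from the denominator.

Subfamily/section labels are not derivable from the tree alone — the
published sections are clades read off a figure — so labeling takes
user-supplied reference exemplars: the tree is rooted at the outgroup and
each taxon receives the group of the smallest rooted clade containing it
and references of exactly one group; mixed clades yield `ambiguous`
rather than a guess.

## Ka/Ks and selection

The estimator is Nei–Gojobori (1986) pathway counting with Jukes–Cantor
correction — the classical default of DNA-polymorphism software, which is
the reconstruction choice here since only the program name, not the
method, is recorded in the source analysis.  Site counts per codon
position are the fraction of viable single-base mutants (stop-creating
mutations excluded from the viable set) that preserve the amino acid; S is
averaged between the two sequences and N = 3·codons − S.  Codons with
multiple differences average synonymous/nonsynonymous step counts over all
minimal pathways, excluding pathways through stop codons (if every pathway
is blocked, all are used so differences are still counted).  Proportions
are corrected by `d = −(3/4)·ln(1 − (4/3)p)`; `p ≥ 3/4` raises a
saturation error.  Ka/Ks < 1 is purifying, > 1 positive, = 1 neutral
(with an optional ±ε band); Ks = 0 leaves the ratio undefined
(`undetermined`), never 0 or ∞.

A caveat the simulation study makes visible: at ω = 0 every fixed
difference is synonymous, but a codon hit twice synonymously can still
average over a mutation order whose intermediate is nonsynonymous, so the
NG86 Ka estimate is a small positive number (≪ Ks) rather than exactly
zero once multiple hits per codon appear (Ks ≳ 0.1 at realistic lengths).
NG86 also mildly underestimates large ω (the ω = 2 median recovers ~1.76–
1.78); both behaviors are properties of the estimator, not bugs, and the
recovery tests budget for them.

## Duplication mechanism

From a gene position table (1-based inclusive coordinates, per-chromosome
gene rank), a pair is **tandem** when both genes share a chromosome with
at most 20 intervening gene models — the rank-based reading of the
"separated by a maximum of twenty genes" convention, not a bp distance.
**Segmental** pairs sit in collinear blocks: chains of homologous anchor
pairs, order-consistent on both chromosomes (forward or inverted), with
at most 100 kb between consecutive anchors on each and at least 5 anchors.
The original analysis consumed precomputed duplicated segments; this
package substitutes a transparent greedy chaining with the same 100 kb gap
parameter and also accepts externally supplied blocks.  When both rules
hold, tandem takes precedence (proximal duplicates inside a duplicated
segment read as tandem).  Strand is ignored.

Because no coordinate table was published, the packaged gene map and
anchor set (`optfam.fixtures`) are a synthetic reconstruction: real locus
identifiers and chromosomes, fabricated coordinates/ranks/filler anchors,
built so the documented 4 tandem / 3 segmental classification emerges from
the rules above.

## Dating and stages

Duplication age is `T = Ks / 2λ` with λ = 6.5×10⁻⁹ substitutions per
silent site per year (the rice rate).  Reported dates and Ka/Ks ratios are
**truncated**, not rounded, at 2 and 4 decimals respectively — inferred
from the published values (76.169→76.16, 48.238→48.23, 1.80586→1.8058)
and applied only at the reporting layer; full precision is kept alongside.

Stages bin dates into 70–50, 50–20 and 20–9 My (half-open on the younger
bound).  Dates outside every bin take the nearest bin with an
out-of-range flag (the published narrative itself assigns a 76.16 My pair
to the 70–50 My stage).  A per-pair override map reproduces narrative
assignments that contradict strict binning — the packaged override places
the 22.58 My pair in the youngest stage, as the narrative does.

The ancestral-gene count treats duplication events as edges over the
family members; each connected component descends from one ancestor, so
the count is members − (nodes − components).  It is invariant under event
order and duplicate listings.

## Digital expression

Tag counts are normalized to tags per million per library.  A gene
responds to a treatment when `(treatment + c)/(control + c)` is ≥ 2 or
≤ 1/2 — boundary inclusive ("at least two-fold") — with a pseudo-count
c = 1 tpm to stabilize zero-control folds (configurable to 0 for the
exact rule); genes below 1 tpm in both members of a contrast are
`not_assessable`.  Presence is tpm ≥ 1 (the source analysis reports
presence qualitatively; 1 tpm is a conventional detection floor, and both
thresholds are parameters).  Pair diversification scores '+' per condition
class — Tissues, Salt, Drought, Cold, X. oryzae, M. grisea by default —
when the members' presence vectors (Tissues) or response calls (other
classes) differ in at least one contrast of the class.

## Synthetic data

* **Codon pairs** — an ancestral stop-free codon sequence evolves along
  two lineages by uniformly proposed single-base changes; stop-creating
  proposals are rejected, synonymous changes accepted with relative
  probability 1 and nonsynonymous with ω, until accepted synonymous
  events reach `target_Ks × S₀`.  Mutation-driven simulation was chosen
  over matrix exponentials for transparency; the realized event counts,
  not the target, are the scoring truth.  Targets above Ks = 2.5 are
  refused as saturated.
* **Gene maps** — ranked non-overlapping genes (2–6 kb, 5–40 kb apart) per
  chromosome, with planted tandem pairs at specified intervening counts
  and planted collinear blocks as runs of consecutive anchor genes.
* **Expression** — log-normal per-gene baselines (median 30 tpm, σ = 1;
  heavy-tailed and positive), one control/treatment library pair per
  stress class plus five tissue libraries, Poisson tag counts at a 10⁶
  depth, and a background row absorbing the remaining depth so simulated
  tpm sits at its planted scale.  The default planted effect is
  **four-fold**: an exactly-two-fold planting sits on the inclusive call
  boundary, where Poisson noise alone decides the call, so it is not a
  usable recovery target.  Poisson (not negative-binomial) noise matches
  the sampling character of signature counting; real MPSS data add
  signature-mapping ambiguity and biological replication variance that the
  generator does not emulate, so recovery rates here bound what the
  two-fold rule can do under sampling noise only.

All generators are deterministic under a seed, and each truth record is
sufficient to score every downstream call without re-derivation.

## Problem sizes in the test and acceptance runs

NJ correctness uses 200 random additive matrices of 5–8 taxa (topology
brute force for ≤6 taxa); NG86 oracle equivalence uses 1000 random codon
pairs with ≤2 differences; ω recovery uses 50 pairs of 1000 codons at
Ks ≈ 0.3 per ω ∈ {0.2, 1, 2}; duplication recovery uses 10 maps × 17
planted events; expression recovery uses 20 matrices × 4 planted
responses.  These sizes give stable medians and percentages while keeping
the whole suite in seconds.

## Known limitations

* The hydropathy TM counter and the injected pKa set approximate, but do
  not reproduce, the HMM/ProtParam numbers of the original survey; the
  published per-gene MW/pI/TM values also depend on sequence versions not
  packaged here, so they are validated as ranges and invariants.
* Sections (A1–A4, B1, B2) require reference exemplars; there is no
  unsupervised split criterion.
* Block chaining is greedy and orientation-consistent; it does not score
  collinearity statistically and will fragment blocks interrupted by
  large insertions.
* Dates inherit the fixed-λ molecular clock's assumptions; no rate
  variation or confidence intervals.
* The published per-stage "new gene" counts are internally inconsistent
  with the describable events (9 originals + 8 claimed new genes ≠ 16);
  the package reproduces the 9-ancestor count by the connected-components
  rule and leaves per-stage gene counts out of the validated surface.
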