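# Methods

`cetataste` implements the computational chain used to argue that a gene
family has been pseudogenized and released from purifying selection on a
species phylogeny: scan coding sequences for ORF-disrupting mutations, place
the shared mutations on the tree, test codon models for relaxation and
divergence of selection, and examine the protein-level consequences.  This
note records the models, the conventions, and the design choices made where
the design was genuinely open.

## ORF-disruption scanning

A query sequence is compared with a functional reference CDS by global
affine-gap alignment (Biopython's `PairwiseAligner`; default match +2,
mismatch −3, gap open −8, gap extend −2).  Gap placement is canonicalized by
left-shifting every gap run while the flanking residue on the gapless row is
unchanged — score-preserving moves only — so indel coordinates are
deterministic and reported in a single documented dialect (leftmost
placement, 1-based in the reference reading frame, closed intervals).

Classification rules:

* a gap run in the query row is a **deletion**, in the reference row an
  **insertion**; an indel is **frameshifting** iff its length is not a
  multiple of 3;
* **premature stops** are found by translating the query in its *local*
  frame (the query's own consecutive codons), so stops created downstream
  of a frameshift are still reported; such stops carry the cause
  `post-frameshift`.  A stop is premature when the reference codon it maps
  to precedes the reference terminal stop;
* terminal gap runs are treated as missing data (incomplete amplification),
  never as indels.  This means disruptions in the first or last aligned
  codon are not callable — a deliberate trade against false calls at ragged
  ends;
* truncation is summarized as `1 − (first_stop − 1)/L` with `L` the
  reference protein length;
* a deletion covering ≥ 95% of a user-supplied exon interval is annotated
  as a whole-exon loss.

Disruptions with identical kind, length, stop codon and coordinates across
taxa are grouped into shared events (exact identity by default; a ±k-codon
tolerance is available because alignment placement of a shared indel can be
ambiguous in repetitive context).

## Dollo mapping

An event's carriers are assumed to descend from a single origin that never
reverts (Dollo): if the carriers form a clade the event maps to the clade's
stem branch; otherwise the minimal no-reversal explanation places origins
on the stems of the maximal carrier-only clades.  When exactly one
non-carrier leaf nests inside the carriers' MRCA, the alternative "single
origin plus one reversal" is recorded as a note but never as the primary
call — indels essentially never revert, point stop codons occasionally can.
Note that the number of strict-Dollo origins for a carrier set missing one
leaf depends on where that leaf attaches: on the packaged 13-taxon topology
excluding the dwarf sperm whale yields 2 origins, excluding the baiji
yields 4.  Non-sampled taxa are treated as missing, never as carriers.

## Codon models

The substitution process is the Goldman–Yang codon model: for sense codons
i ≠ j differing at one nucleotide,

    q_ij ∝ pi_j                        synonymous transversion
    q_ij ∝ kappa · pi_j                synonymous transition
    q_ij ∝ omega · pi_j                nonsynonymous transversion
    q_ij ∝ omega · kappa · pi_j        nonsynonymous transition

with zero rate for multi-nucleotide changes, diagonal set so rows sum to
zero, and the generator scaled so the expected rate at stationarity is 1
(branch lengths are expected substitutions per codon).  Each distinct omega
gets its own normalized generator; this per-class normalization is a
convention (mixture models could instead be normalized by the class-average
rate) and is consistent across nested model pairs, which is what the LRTs
require.  Sense-codon indices are lexicographic over (A, C, G, T) —
packaged as data, fixed forever, because they define every matrix index.

Codon frequencies default to F3x4: products of position-specific nucleotide
frequencies counted from the data, stop codons removed, renormalized.
Frequencies are counted, not optimized, and are not included in the free
parameter count (np), matching the convention of the standard
implementations.  np = (#branches) + 1 (kappa) + the family's free
omega/proportion/shape parameters.

P(t) = exp(Qt) is computed by the pi-symmetrized eigendecomposition,
clipped at 0 and row-renormalized (clipping errors are at rounding level).
Likelihoods use Felsenstein pruning over the 61 sense-codon states with
per-node rescaling; MISSING and GAP codon states contribute all-ones
partials.  Site patterns are collapsed with weights before fitting.

Model families: branch models A (one omega), B (omega = 1), C (two-ratio
foreground/background), D (two-ratio, foreground omega = 1), E (free
ratio); site models M1a/M2a and M8/M8a (10 equal-probability beta
categories represented by their exact conditional means, computed from
regularized incomplete beta functions; the count is configurable); clade
model C and its null M2a_rel (three site classes; the third class has a
partition-specific omega, forced equal under the null).

### Pseudogene "repair"

Codon models are defined over sense codons only, so pseudogenized sequences
are repaired before entering a likelihood: (1) drop alignment columns where
the functional reference has a gap, (2) regroup into reference-frame
codons, (3) drop codon columns in which any row has a gap (removes all
frameshift columns and restores a common frame), (4) recode stop-containing
and ambiguous codons as MISSING.  The recipe is logged with counts in every
run manifest.  Published analyses of this kind do not state their recipe;
this one is deterministic and conservative (information is discarded, never
invented).

### Fitting

Maximum likelihood by L-BFGS-B over log branch lengths, log kappa, and
transformed family parameters (log for omegas and beta shapes, plain
bounded variables for proportions via stick-breaking).  Bounds:
t ∈ [1e-6, 50], kappa ∈ [1e-3, 100], omega ∈ [1e-4, 20], beta shapes
∈ [0.005, 99]; all configurable.  Multi-start is seeded (default 3 starts,
seed 1234); heavy simulation studies use a single start plus warm starts.
Alternative models are warm-started from the fitted null embedded in the
alternative's parameter space, which both speeds convergence and guarantees
the optimizer starts at a point no worse than the null; if an alternative
still ends below its null (optimizer failure), it is refit once from the
embedded null MLE.  The convergence flag reports the optimizer outcome
honestly and LRT results carry a warning when either fit did not converge.

## Likelihood-ratio tests

2Δ(lnL), clipped at zero, referred to a chi-square with df = np(alt) −
np(null).  The chi-square upper tail is the regularized upper incomplete
gamma Q(df/2, x/2).  The M8a-vs-M8 comparison uses the plain chi-square
with df 1 by default — the convention the published taste-receptor analyses
follow — with the 50:50 boundary-mixture correction available behind a
flag.  Ladder verdicts: relaxation requires A-vs-C significant with
omega_fg > omega_bg; D-vs-C significance means constraint is not fully
removed (`partially_relaxed` vs `fully_relaxed`); otherwise a significant
C-vs-E yields `heterogeneous`, else `purifying`.  Raw p-values are
reported; no correction across genes is applied (a report column says so).
The foreground for models C/D defaults to each mapped origin branch plus
all of its descendant branches, overridable with explicit tags — whether a
transitional origin branch belongs in the foreground is genuinely
ambiguous, so the choice is explicit and logged.

## Protein-level analyses

Conservation is profiled over a chosen reference taxon set, with positions
reported in the coordinates of a numbering reference (gap columns in that
reference carry no coordinate and are skipped).  Columns are `complete`
(level 1.0) or `partial80` (level ≥ 0.8), the two classes used in the salt
taste receptor analysis; variant calls at those columns are rendered
`<gene><consensus><position><observed>`.  Motif checks default to the
epithelial sodium channel signatures PPPXYXXL (C-terminal PY motif), HG
(N-terminal gating pair) and FPXXTXC (post-M1), with X a single-residue
wildcard and overlapping matches reported.

Property-change tests bin nonsynonymous changes into 8 equal-width
magnitude categories per physicochemical property (31 packaged scales;
categories 1–3 conservative, 6–8 radical).  Ancestral amino acids come from
Fitch parsimony on the fixed tree with lexicographic tie-breaking —
deterministic and swappable; ML reconstruction is deliberately not
re-implemented here.  The expected category distribution weights every
single-nucleotide nonsynonymous codon exchange by the observed frequency of
the source codon; category bins span the range attainable by single-
nucleotide exchanges, and rarer multi-step changes clamp into category 8.
z = (obs − Np)/sqrt(Np(1−p)); a category is flagged only when z is positive,
the category is 6–8, and the two-sided normal p-value is below 0.001
(configurable).  A sliding window of 15 codons repeats the test regionally;
edge windows shorter than 15 are skipped, not padded.  The property table
is a curated approximate re-tabulation of standard amino-acid index
compilations (see the header of `data/aa_properties.tsv`); magnitudes are
adequate for ranking changes but are not a certified copy of any single
published index.

## Synthetic data

The generator emulates the study conditions of a taste-receptor-style
analysis: codon alignments evolved on a 13-taxon cetacean-like tree (three
delphinids, finless porpoise, baiji, beaked whale, sperm and dwarf sperm
whale, two baleen whales, hippo, cow and pig outgroups; round plausible
branch lengths) under branch-specific omega with kappa and chosen codon
frequencies, and pseudogenizing events — frameshifting indels of 1, 2, 4, 5
or 17 nt and premature TGA/TAA/TAG stops — injected on chosen branches and
propagated to all descendant taxa.  Injection happens *after* sequence
simulation by editing the final alignment, so the injected truth is exactly
recoverable; simulating indels as an evolutionary process is a non-goal.
All randomness flows from one integer seed through numpy's PCG64.

What the generator does **not** emulate: alignment error, sequencing error,
rate variation beyond the modelled site classes, indel evolution,
intron/exon structure, and base-composition heterogeneity across lineages.
Passing tests therefore demonstrate correctness of the machinery under the
model, not robustness to real-data pathologies.

## Problem sizes used in tests and the acceptance script

Exhaustive-enumeration likelihood checks use ≤ 4 taxa × ≤ 10 codons (the
enumeration oracle is quadratic in the 61-state space per internal node).
Parameter recovery uses 8 taxa × 2,000 codons (one-ratio, truth omega 0.3,
tolerance ±0.05) and 20 replicates of 600 codons for the two-ratio ordering
(truth 0.25 background / 0.7 foreground).  The type-I calibration of the
relaxation LRT runs 200 null replicates at 5 taxa × 200 codons, sizes at
which the chi-square(1) reference is already accurate (KS p ≈ 0.3 in
calibration runs) while keeping the full study inside a few minutes on one
core.  Injection roundtrips run 50 scenarios at 150 codons.  These sizes
are the package's standing choices for its own verification; all are
parameters of the relevant functions and can be scaled up freely.

## Known limitations

* Branch-site model A is not implemented (no results of it are part of the
  target analyses); FUBAR-style Bayesian site tests and Bayes empirical
  Bayes site identification are out of scope (naive empirical Bayes
  posteriors are provided instead).
* The scanner does not detect splice-site mutations and does not map
  truncations onto predicted membrane topology.
* The two-ratio foreground definition and the repair recipe are documented
  conventions, not reconstructions of any particular published pipeline's
  unstated choices; absolute lnL values are therefore comparable only
  within this package.
* Divergence-time estimation is out of scope; mapped origins are branches,
  not dates.
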