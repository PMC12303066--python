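# Methods

## Biological model and scope

`uorfpred` operationalizes the leaky-scanning / delayed-re-initiation model
of stress-resistant translation. When eIF2α is phosphorylated, ternary
complex becomes scarce; ribosomes that terminate at a short upstream ORF
re-acquire initiation competence more slowly and can scan past a second,
inhibitory uORF to initiate at the main ORF instead. Transcripts with this
architecture (ATF4 being the archetype) are therefore translated relatively
*better* under stress. The package predicts such transcripts from the
5′UTR sequence alone; it does not model IRES elements, non-AUG initiation,
or uORF peptide effects.

## 5′UTR derivation

Given a transcript's cDNA and CDS (e.g. from Ensembl's canonical
transcript), the 5′UTR is the cDNA prefix strictly before the first
occurrence of the CDS as a contiguous substring. When the CDS occurs more
than once, the first (5′-most) occurrence is used — the shortest 5′UTR
consistent with the subtraction — and the ambiguity is logged. A CDS not
found verbatim in its cDNA (an edge annotation artifact) raises an error at
the single-pair level and is skipped with a log line in batch derivation.
Coordinates are 0-based half-open; sequences are sense-strand; N bases are
preserved, never matched inside a codon or context position, and counted as
non-GC.

## uORF acceptance rules

Each reading frame is scanned 5′→3′ independently. An AUG is accepted iff:

1. **Kozak context.** Default `adequate`: purine at −3 *or* G at +4.
   Positions outside the 5′UTR never satisfy the condition (so an AUG at
   position 0 needs the +4 G), and N never matches. The rule is a
   configuration point (`adequate | strong | any`, where `strong` requires
   both positions) because "adequate context" conventions vary; `adequate`
   is the Kozak convention we adopt as default.
2. **Spacing.** Its start is ≥ 30 nt downstream of the previously
   *accepted* AUG — in the same frame by default (`spacing_scope="frame"`,
   matching the per-frame enumeration), with a `global` option comparing
   against the previously accepted AUG in any frame. The 30-nt floor
   reflects the minimum distance a ribosome needs to re-acquire initiation
   competence while leaky-scanning.
3. **Open-ORF exclusion.** It does not lie within the span of a previously
   accepted same-frame uORF that never reaches a stop codon (such a uORF's
   span extends to the 5′UTR end). Cross-frame overlap does not exclude.

Termination is the first in-frame TAA/TAG/TGA completing *within* the
5′UTR; a uORF whose stop codon would lie in the CDS counts as lacking a
stop, which is exactly the overlapping-uORF geometry the re-initiation
model cares about.

**Atf4-like count (B).** A frame contributes when it holds an accepted,
unterminated uORF whose start is at or after the stop-codon end of at least
one terminated accepted uORF in any frame. "Preceded" is interpreted as
stop-end ≤ start (re-initiation requires the terminating event upstream of
the next initiation). No minimum length is imposed on the open uORF.

## The classifier

The 11-column design (intercept, A, B, C, D and the six pairwise products)
is fit by unpenalized maximum likelihood (Newton/IRLS via statsmodels,
tolerance 1e-8, ≤ 100 iterations) on **raw, unstandardized** features, so
the coefficients apply directly to counts, nucleotides and percent — the
scale on which the score formula is written. B enters numerically (0–3),
not one-hot, since the formula multiplies it by scalars. An optional
`ridge_alpha` reproduces penalized library defaults; the default is 0
(documented prominently because general-purpose logistic implementations
often penalize silently). Non-convergence under quasi-separation emits a
warning rather than an error.

**4-subset averaging.** Examples (pre-filtered to ≥ 1 uORF; uORF-less
transcripts can never be positive, so they carry no signal for this model)
are dealt into four class-stratified subsets: within each class, indices
are shuffled with the seeded generator and dealt round-robin, so subset
class counts differ by at most one and remainders land in the lowest-index
subsets (e.g. 321/418 positives/negatives split as 81,80,80,80 /
105,105,104,104). Each of the four groups of three subsets trains a
sub-model evaluated on its held-out subset across the threshold grid; the
final coefficient vector is the exact element-wise mean of the four
sub-model vectors. The protocol is deterministic given the seed.

**Hit rule and threshold.** Positive ⇔ score > threshold (strict) ∧
A ≥ 1. The working threshold is chosen from the grid 0.00–0.95 (step 0.05)
as the cutoff maximizing LR⁺ = sensitivity/(1 − specificity) — we read
"likelihood ratio" as the positive likelihood ratio, which privileges
specificity, the stated priority when nominating targets. An infinite LR⁺
(specificity 1 with nonzero sensitivity) beats any finite value; ties break
by higher sensitivity, then lower threshold. Undefined PPV (no predicted
positives) is serialized as null/NaN, never 0, to avoid silently deflating
curves.

## Dataset labeling

Training rows (RNA-seq + Ribo-seq, stress vs control): keep
−0.2 < RNA log2FC < 0.2 ∧ (Ribo log2FC < −0.2 ∨ > 0.2) ∧ FDR < 0.05;
the Ribo-seq sign labels the gene (up under stress = positive). Testing
rows (translation efficiency, phosphorylation-deficient mutant vs wild
type): keep padj < 0.05; TE log2FC < −0.2 labels positive (translation
enhanced when phosphorylation is possible), > 0.2 negative, the dead zone
dropped. **All inequalities are strict**; values exactly at ±0.2 or 0.05
are excluded everywhere, matching the filters as written. Column names are
remappable for differing upstream layouts; species subsetting (e.g.
sex-restricted samples) is the caller's responsibility.

De-duplication removes from the training set every gene present in the
test set and tabulates the shared genes' labels as a 2×2 concordance
table. On a perfectly concordant x + y table the Pearson χ² equals x + y
(here 10 + 29 = 39, p ≈ 4.24e−10 at df 1). We use the Pearson 2×2 form
without Yates correction: a goodness-of-fit test against 50/50 agreement
gives the same statistic on a fully concordant table, and the uncorrected
form reproduces the printed p-value. Fisher's exact test is two-sided by
the point-probability method (scipy's convention); the odds ratio is
(a·d)/(b·c) with ∞/0 conventions at zero cells, and Yule's Q =
(OR − 1)/(OR + 1).

## Synthetic data

The generators define the test bed standing in for external databases.

**`random_utr`** builds a 5′UTR whose features are known by construction:
an ATG-free background sampled base-by-base at the target GC (rejecting
bases that would complete an ATG), then planted uORFs at starts ≥ 34 nt
apart (safely above the 30-nt floor in every frame), each with an enforced
Kozak context (A at −3, G at +4). Terminated uORFs are written as
`ATG GCC TAA`; open uORFs are placed downstream of every terminated one —
mimicking ATF4 — in distinct frames, and their frames are scrubbed of
in-frame stops through to the 5′UTR end. Scrubbing and stray-ATG repair
always rewrite an unprotected base to C, which can complete neither an ATG
nor a stop codon, so the passes converge; a final pass nudges unprotected
bases toward the GC target under the same safety checks. Feasibility
demands length ≥ 3 + (A−1)·34 + 12 and, for a nonzero Atf4-like target, at
least one terminated uORF (so n_uorfs ≥ atf4like_target + 1). The
construction guarantees A, B, C exactly and D within ~5 points for targets
away from the extremes. What it does *not* emulate: transcriptome-like
base composition, codon structure, conservation, or length/GC/uORF
correlations of real 5′UTRs — so closure tests validate the scanner's
self-consistency, not its performance on real transcripts.

**`simulate_labeled`** draws A ∈ {1..6}, B ∈ {0..min(3, A)}, C uniform in
20–600 nt, D uniform in 30–80 % — ranges spanning typical mammalian
5′UTRs — and Bernoulli labels at the logistic score of a known β. The
default ground-truth β used in tests and the acceptance script
(−2.0, 0.8, 0.5, 0.004, 0.01, 0.1, −0.001, −0.01, 0.002, 0.05, −0.0001)
puts each main effect and interaction at a magnitude that matters on its
covariate's scale without saturating the logistic, giving a roughly
balanced class mix.

**Expression-table generators** emit rows covering every filter region
(pass-positive, pass-negative, RNA-excluded, FDR-excluded, dead zone)
together with the label the filter must assign, plus exact-boundary rows
(±0.2, 0.05) that must be dropped under strictness.

All generators are pure functions of (spec, seed); no global random state.

## Numerical and testing choices

Scores are computed with the overflow-safe logistic (`scipy.special.expit`);
prescores of ±1000 stay inside (0, 1). Test oracles are independent
reimplementations: a literal-rule exhaustive uORF scanner, brute-force
confusion counting, hypergeometric enumeration for Fisher, and the direct
Σ(O−E)²/E formula — the production paths use the package (and scipy /
statsmodels for the standard statistics), never the oracle. Parameter
recovery is asserted within 3 standard errors at n = 5000 over fixed seeds,
with standard errors taken from an independent statsmodels fit. Problem
sizes in the suite and acceptance script (≤ 5000 simulated examples, 200
synthetic UTR specs, 500 oracle sequences) were chosen to make the checks
statistically meaningful while keeping the whole suite to a few seconds.

## Known limitations

* The Kozak "adequate" rule and spacing scope are conventions, exposed as
  options; a different upstream choice changes A and B.
* The model is purely sequence-intrinsic: trans factors, tissue context and
  mRNA stability are out of scope.
* Unpenalized MLE on the collinear interaction design can be unstable on
  small or quasi-separated datasets; the ridge option exists for that case.
* The Ensembl fetcher is a convenience; no network code is exercised in
  tests and no identifier translation is provided.
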