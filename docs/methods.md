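# Methods

## Digital differential expression of EST counts

Each cDNA library contributes single-pass sequence tags (ESTs); the
count of a contig's ESTs per library is its expression measurement.
With one pooled set of libraries per host condition there are no
biological replicates, so the contrast is the classical chi-square on
tag counts: under the null that a contig's expression does not depend on
host condition, its `T` ESTs split between conditions in proportion to
total sequencing depth,

    E_a = T · N_a / (N_a + N_b),   E_b = T · N_b / (N_a + N_b),

where `N_a`, `N_b` are the condition depths summed over **all** contigs
(including the one under test — the standard proportional-allocation
convention; excluding it changes depths by at most `T` and is easy to
reproduce by passing adjusted totals). Two statistics are available:

* **goodness of fit** (default): `χ² = Σ (O−E)²/E` over the two
  condition counts, df = 1. With more than two library groups the same
  formula applies with df = k−1; the conditions are pooled by default
  because the per-library split confounds life stage with condition.
* **2×2 contingency**: the contig's counts versus all other ESTs,
  conditions as columns, optionally with the Yates continuity
  correction. Offered because published per-contig statistics of this
  kind are often computed this way by general statistics packages, and
  the two statistics differ slightly at small counts.

P-values are the upper tail of the chi-square distribution,
`Q(df/2, χ²/2)`. Contigs with fewer than `min_count = 5` total ESTs are
not tested: below that the asymptotic approximation is meaningless. No
multiple-testing correction is applied by default — the method is a
screening step whose hits are validated downstream — but
Benjamini–Hochberg adjustment is available behind a flag.

**Accuracy of the chi-square tail.** For discrete counts the continuous
upper tail and the exact (Monte-Carlo multinomial) tail agree only to
the approximation's accuracy: the binomial atom at the observed value
contributes a discrepancy of roughly half its mass even when both
expected counts exceed 10 (a few percentage points for totals of
20–200). The test suite measures this directly; the approximation is
unbiased across instances but individual p-values should be read with
that granularity in mind.

## Catalogue classification and composition

Functional annotation of a sialotranscriptome is ordinarily manual.
To make it reproducible the classifier is an ordered list of keyword
rules (case-insensitive substrings of the description, optionally
conditioned on the signal-peptide flag), first match wins; unmatched
contigs fall back to `unknown` / `unknown_secreted` by signal peptide.
A bundled default rule file reproduces the standard secreted-protein
family vocabulary (cement proteins, Kunitz domain, lipocalins, basic
tail, GYY/GGY glycine-rich families, ...); it is a best-effort keyword
reconstruction, not a claim of fidelity to any manually curated dataset.
Family labels are free text keyed case-insensitively, since published
tables mix orthographies.

Composition tables report ESTs per group as `100 · count / grand_total`
rounded **half-up to 2 decimals**, matching printed-table precision;
`grand_total` defaults to the catalogue-wide EST total so that a
secreted-only breakdown still reports shares of the whole dataset.
Library totals are always recomputed from the count matrix, never
trusted from metadata.

## Antigen selection

Candidates must pass every enabled criterion: signal peptide (proxy for
secretion into saliva), direction `up_in_susceptible` (expression
suppressed by effective anti-tick immunity), p below alpha, and family
membership in a whitelist operationalizing "putative role in
haematophagous parasitism" (default: proteases, proteinase inhibitors,
glycine-rich/cement, immunoglobulin-binding proteins, lipocalins and
relatives — the judgement-based criterion made explicit as config).
Every contig keeps its per-criterion pass flags in an audit table, so
relaxing any one criterion provably never shrinks the selection.

Ranking uses the proportion fold-change
`(b/N_b) / (a/N_a + 0.5/N_a)`; the half-count pseudo-proportion keeps
contigs absent from the resistant libraries finite and ranked first.
Ties break by larger total EST count, then contig id — output order is
deterministic.

Molecular weights use average (not monoisotopic) residue masses plus one
water, reported in kDa to one decimal, matching SDS-PAGE-scale
reporting; an expression-vector histidine tag adds a flat 4.0 kDa
(configurable constant).

## Epitope scanning

**B-cell**: the Parker HPLC hydrophilicity scale, averaged over a
centered window of 7 residues (odd, configurable). Terminal positions
use shrunken windows (down to ⌈w/2⌉ residues) rather than padding —
padding invents residues and biases terminal scores toward the pad.
Predicted peptides are maximal runs of positions **strictly** above the
threshold (strict, so a flat profile with a mean threshold yields
nothing), kept if at least `min_len = 7` residues long. The threshold is
either a user value or the sequence-wide mean; no universal numeric
default exists for propensity scales, so it is exposed as config.

**MHC-II**: every 9-mer is scored additively against per-allele 20×9
position-specific scoring matrices supplied by the user (TSV, rows =
residues, columns = positions); hits are windows scoring at or above the
per-matrix threshold. Pocket-profile or IC50-regression matrices from
dedicated MHC-II tools are deliberately not bundled — published
per-antigen hit counts depend entirely on those proprietary matrices and
are not reproduced here. Coordinates are 1-based inclusive throughout.
Both scanners are pure functions of (sequence, parameters).

## Trial efficacy

Parasitism readouts per animal: engorged adult female count (NT), mean
engorged female weight, oviposition (O, egg-mass weight per surviving
tick) and egg fertility (F, larvae weight per gram of eggs). Excluded
animals (e.g. failed infestation chambers) never enter any statistic.
Efficacy is computed from group means,

    CRT = NT_V/NT_C,  CRO = O_V/O_C,  CRF = F_V/F_C,
    E = 100 × [1 − (CRT · CRO · CRF)],

so `1 − E/100` decomposes exactly and E is invariant to rescaling all
animals' measurements by a common factor. Tick weight is summarized,
reduced and tested but excluded from E — the formula tracks reproductive
output, where weight effects manifest through O and F. Report rendering
rounds E to the nearest integer and reductions to one decimal
(half-up); internal values are never rounded.

Group comparisons use a two-sample t-test; the default is Welch
(Satterthwaite df) because small two-group trials rarely justify equal
variances — published df values for 4-vs-3 comparisons are typically
below the pooled df 5, indicating unequal-variance corrections — with
the pooled Student variant available. Two constant equal samples return
p = 1 by convention.

## Synthetic data

The generators are pure functions of (spec, seed) via
`numpy.random.default_rng`; no global RNG state.

**Catalogue** (`simulate_catalogue`): the default design is eight
libraries — four life stages × two host conditions, 990 ESTs each, so
the catalogue totals ≈ 7,900 ESTs, the scale of a classical Sanger EST
survey. Baseline contig abundances are log-normal (σ = 1.5; log-series
available), mimicking the dominance of a few highly expressed salivary
transcripts. A fraction (default 10%) of contigs has its
susceptible-condition proportion multiplied by `fold_change` (default 4)
and renormalized; library counts are then multinomial at the library's
target depth, so per-library sequencing effort is exact — the reason
multinomial was chosen over independent Poisson counts. Descriptions and
families come from a fixed vocabulary aligned with the default rule
file; ~30% of contigs carry a signal peptide. Contigs drawn with zero
ESTs everywhere are dropped (they were never observed).

**Proteins** (`simulate_proteins`): residues i.i.d. from Swiss-Prot-like
background frequencies, with optional planted structure: a
signal-peptide-like N-terminus (Met + charged pair + 12-residue
hydrophobic core), GGX-repeat glycine-rich blocks (Gly fraction > 0.5 by
construction), and one 12-residue strongly hydrophilic block (from
D/E/N/K/S/Q) whose 1-based coordinates are recorded as truth for
scanner-recovery tests.

**Trial** (`simulate_trial`): defaults emulate a 4-vs-3 calf trial with
control means 1,233 ticks, 338 mg tick weight, 107.5 mg oviposition,
0.022 fertility, and vaccinated multipliers matching the published
reductions. Tick counts are negative-binomial matched to (mean, CV) —
parasite burdens are overdispersed — and continuous parameters are Gamma
(shape 1/CV²). Default CVs are 0.30 / 0.15 / 0.15 / 0.20: moderate
values typical of controlled challenge infestations, chosen over CVs
backed out of published standard errors because SEs estimated from 3–4
animals are themselves so noisy that they would dominate any calibration
statement one could make about the estimator (with a count CV of 0.7 and
fertility CV of 1.1, the null efficacy at 200 animals per group still
has a standard deviation of ~13 points, leaving no regime in which
parameter recovery is demonstrable).

**What the synthetic data does not emulate** — and hence what passing
tests do not show about real data: EST assembly artifacts (chimeras,
fragmented contigs), annotation ambiguity (the keyword rules classify
the synthetic vocabulary perfectly by construction), library-composition
differences across life stages within a condition, sequence realism
beyond residue frequencies (no homology, no real epitope conformational
structure), and correlated trial parameters (per-animal NT, O and F are
drawn independently, whereas a sick tick cohort covaries).

## Problem sizes in the test suite

Calibration and recovery tests run at sizes that keep the full suite
under a minute while leaving the statistical assertions well-powered:
2,000 null contigs for type-I calibration (binomial totals 20–200, both
expectations ≥ 10), 500 instances × 100,000 draws for the Monte-Carlo
p-value comparison, 200 synthetic proteins for epitope recovery
(recovery ≥ 95% of planted blocks), 200 animals per group for efficacy
parameter recovery (|E − 70| < 5 with multipliers 0.5/0.8/0.75), and
~5,000 ESTs per condition for differential-expression recovery (recall
> 0.5 at fold 4 with false-positive fraction near alpha).

## Known limitations

* The chi-square screen has no replicate-based error model; with one
  pooled library per condition its p-values are descriptive.
* Printed per-contig χ² values in published tables of this kind are
  generally not recoverable from the printed observed/expected cells
  alone (the depths used by the original software are unpublished);
  only the χ² → p internal consistency is checkable, and the package
  does not hard-code any published statistic as a correctness anchor.
* The family whitelist and the classification rules encode judgement;
  both are config, and results should be audited via the audit table.
* The MHC-II scanner is a generic additive-matrix engine; it does not
  predict binding affinity without externally supplied matrices.
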