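# Methods

`spectracount` implements a label-free spectral-counting pipeline for
differential protein abundance in a small-animal design: three groups
(sham-operation, UUO 1-week, UUO 3-week; UUO = unilateral ureteral
obstruction, the classic rat model of obstructive nephropathy), three
animals per group, three LC-MS/MS technical replicates per animal. The
spectral count — the number of MS/MS spectra (PSMs) matched to peptides
of a protein in one run — is used as a semi-quantitative proxy for
protein abundance.

## Identification gates

PSM-level input (a simplified tab-delimited export of validated search
results) passes two gates before quantification.

**Peptide gate.** PSMs with posterior probability below `peptide_prob`
(default 0.90) are discarded. The false discovery rate of the survivors
is then estimated from decoy matches as the global ratio
`decoys / targets`; if it exceeds `fdr` (default 0.001), the
probability cutoff is raised to the smallest observed probability whose
retained set satisfies the ceiling (exhaustive scan — the decoy ratio
is not monotone in the cutoff). The filter is idempotent, and raising
the probability floor can only shrink the retained set. Validation
tools often use a *local* FDR for this step; the global decoy ratio
implemented here is a transparent, testable estimator of the same
quantity, and the two coincide in the well-separated regime the
defaults target.

**Protein gate.** Within each run, PSMs are grouped by accession. A
protein is accepted when its probability (consumed from the export,
never recomputed) reaches `protein_prob` (default 0.95) and it has at
least `min_unique_peptides` (default 2, the two-peptide rule) distinct
peptide sequences that map *only* to it. A PSM shared between
accessions contributes to the spectral count of each of them but to no
unique-peptide tally; this keeps shared peptides quantitatively visible
while preventing them from certifying a protein's identity.

## Replicate aggregation

A protein's per-animal abundance is the arithmetic mean of its counts
over the three technical replicates, **provided the count is positive
in all three**; a protein absent from any replicate contributes exactly
0 for that animal, never a partial mean. Aggregates are kept as
rationals (no rounding). No between-sample normalisation is applied:
with totals differing between groups the conservative 2-fold threshold
below is the intended compensation, and scaling all counts by a
constant leaves both the fold change and the F statistic unchanged
(tested as an invariant).

The all-3-replicates rule is deliberately strict and double-edged: it
suppresses one-off spurious identifications, but a single missing
replicate zeroes an animal. The synthetic benchmark (analysis script
02) shows both edges: dropout deflates sensitivity by zeroing truly
changed proteins in UUO animals *and* inflates fold changes of nulls by
zeroing sham animals.

## Group statistics

For each protein the three groups' per-animal abundances enter a
classical fixed-effects one-way ANOVA, F = (SS_between/df_between) /
(SS_within/df_within), df = (2, 6) for the 3x3 design. The pairwise
comparison of interest (each UUO group vs sham) gets a post hoc p:

- **LSD** (Fisher's least significant difference, the default):
  t = |mean_i − mean_j| / sqrt(MSE·(1/n_i + 1/n_j)) with MSE and its
  df pooled over *all* groups in the matrix.
- **Dunnett's T3**: a Welch t with Welch–Satterthwaite df, adjusted for
  the family of m pairwise comparisons. In place of the exact
  studentized-maximum-modulus distribution the implementation uses the
  Šidák-style bound `1 − (1 − p)^m`, which never understates the
  adjusted p.
- **auto**: LSD unless a Levene pre-test (on absolute deviations from
  group means) rejects homogeneity at 0.05, then T3.

LSD is the default rather than auto for two reasons. First, every
reference-table p-value that can be recomputed from the printed counts
agrees with LSD — including proteins whose group variances differ by
an order of magnitude — so it is the test that actually produced those
tables. Second, with n = 3 per group the Levene pre-test fires almost
exclusively on *strong true effects* (count variance scales with the
mean), handing exactly the most changed proteins to a test whose Welch
df is ~2 and whose family adjustment then leaves essentially no power;
the auto policy at this sample size is a power trap, not a robustness
gain. Both alternatives remain one configuration flag away.

Degenerate inputs are defined, not exceptional: all values identical
gives F = 0 (p = 1); zero within-group variance with distinct means
gives F = ∞ (p = 0); a zero MSE gives post hoc p = 1 for equal means
and 0 otherwise.

## The differential filter cascade

The **fold change** is the ratio of group-mean abundances,
mean(UUO)/mean(sham); +∞ when the sham mean is 0 and the UUO mean
positive; a protein with both means 0 is flagged not quantifiable and
excluded. A protein is retained when:

1. it has ≥ 2 unique peptides (assumed satisfied when the input is a
   published table that lists only accepted proteins);
2. all three UUO animals lie strictly above the sham group mean
   (consistent upward trend) **and** at least one per-animal fold —
   the UUO animal's count over the sham *group mean*, since animals
   are unpaired — exceeds the fold threshold (default 2);
3. every UUO animal count is ≥ `min_uuo_count` (default 5; inclusive,
   because the published survivor sets contain per-animal counts of
   exactly 5).

It is called **significant** when additionally the group fold change
exceeds the threshold and the post hoc p is below alpha (0.05). Raising
either threshold can only shrink the survivor set (tested as an
invariant). Only up-regulation in UUO is tested; the design collects
urine from the obstructed ureter, and the study logic targets proteins
that rise with injury. No multiple-testing correction enters the
decision — mirroring the original procedure — but reports carry a
supplementary Benjamini–Hochberg q-value column for readers who want
one.

Reports round to the reference tables' precision (fold 2 dp, F 3 dp,
p 3 dp); a full-precision companion TSV is always written.

## Reference tables

Three transcribed, SHA-256-checksummed TSVs ship with the package:
per-run identification counts (T1, 27 runs), and the 1-week (T2,
7 proteins) and 3-week (T3) differential tables with per-animal
spectral counts. The source study reports 19 proteins at 3 weeks; the
text available for transcription preserves 18 of them, and the loader
checks for exactly those 18 rows. One transcribed value is internally
inconsistent at printed precision: Clusterin's fold change prints as
2.90 while its printed integer counts give 283/98 = 2.89; the
recomputation scripts report the discrepancy rather than patching
either number (the printed integers are most likely rounded replicate
means).

## Synthetic data

The generator emulates the study design with a hierarchical count
model, per protein:

- group mean = `base_mean` × `planted_fold` in affected groups
  (`planted_fold` = 1 marks a null protein);
- animal effect: multiplicative lognormal,
  `exp(N(0, σ) − σ²/2)` (mean-preserving), σ default **0.2** — the
  median coefficient of variation of the 24 UUO per-animal triples in
  the reference tables is ≈ 0.21, and that observed spread already
  includes replicate noise;
- replicate counts: negative binomial around the animal mean with size
  **r = 20** (variance μ + μ²/r — mild overdispersion; technical
  replicates in the reference data vary by a few percent at high
  counts, while Poisson noise dominates at low counts;
  `dispersion=inf` gives the exact Poisson oracle);
- dropout: each replicate count independently zeroed with probability
  `dropout_rate` (default 0).

Seeds are explicit function arguments; the same seed reproduces a
dataset byte for byte. The PSM-export generator expands each count into
that many PSM rows cycling through a configurable number of distinct
synthetic peptides, with Beta-distributed probabilities (targets high,
decoys low), so the identification gates can be exercised end to end.

**What the generator does not emulate:** shared peptides across real
protein families, correlated dropout (a bad injection affects all
proteins at once), saturation of counts for very abundant proteins,
between-group differences in total spectral load, and any structure in
protein probabilities. Passing recovery benchmarks therefore
demonstrates that the pipeline's logic is correct under its own
assumptions — not that three animals per group has high power on real
urine, where biological variability is the binding constraint.

## Problem sizes and numerical choices

The bundled recomputations are desk-scale (26 candidate rows,
milliseconds). The seeded recovery benchmark uses 20 planted fold-10
proteins among 1,000 nulls (base means lognormal around 8, the
low-count regime typical of urinary proteomes), one generation +
cascade pass, a few seconds on one CPU. Statistical agreement checks
run the brute-force sums-of-squares oracle against the implementation
at 1e-9 absolute tolerance. Ties in the FDR cutoff scan resolve to the
smallest qualifying cutoff; equality at thresholds is inclusive
(probability ≥ floor, count ≥ 5) except the fold threshold and trend,
which are strict (> 2, strictly above the sham mean), matching the
stated selection rules.

## Known limitations

- The decoy FDR is a global estimate; exports validated with a local
  FDR can differ near the cutoff.
- Dunnett's T3 uses a conservative bound, so its p-values are slightly
  larger than the exact studentized-maximum-modulus values.
- The preliminary screen the source study mentions (differential
  proteins "above internal experimental variation", 65/74 candidates
  before the conservative criteria) has no operational definition and
  is not implemented; the pipeline goes straight from the count matrix
  to the three-criterion cascade.
- With n = 3 per group, all tests here are fragile to a single outlier
  animal; the cascade's per-animal criteria are the main guard.
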