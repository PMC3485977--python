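# Methods

## Study design and data model

The package targets 1:1 matched case-control SNP studies: each case is
linked to one control by a pair id (age/sex matching is carried as
metadata but only the pairing structure itself enters the analysis).
Genotypes at biallelic markers are stored as counts of the alternate
allele (0/1/2, −1 for missing). Input formats are a delimited
genotype table (header `id, status, pair_id, sex, age` plus one
two-character allele column per marker, heterozygotes order-insensitive)
and PLINK PED/MAP. When allele assignments are not supplied, the
reference allele is inferred as the major allele of the observed
column, with lexicographic tie-breaking.

## Single-locus statistics

Genotype (2×3) and allele (2×2) case-control tables are tested with
the Pearson chi-square statistic without continuity correction;
genotype columns with a zero margin are dropped and the degrees of
freedom reduced rather than failing, so sparse simulated tables remain
testable. P-values come from the chi-square upper tail. No
multiple-testing adjustment is applied to the per-marker tests (the
design is a small candidate panel at per-marker α = 0.05); reports
carry a Bonferroni-adjusted α alongside as information.

Hardy-Weinberg equilibrium is checked per group with the 1-df
chi-square goodness of fit against n((1−q)², 2q(1−q), q²), q estimated
from the same counts. An exact test was considered and not adopted:
at the group sizes this package targets (hundreds per group) the
chi-square approximation is accurate, and the goodness-of-fit form is
what the reproduced analyses used.

LD r² is the squared Pearson correlation of the two additive genotype
vectors over subjects with both calls present, computed before
imputation — the "genotypic" r² PLINK reports without phasing. An
EM-haplotype r² would differ slightly, but for a collinearity screen
at r² > 0.85 on unphased data the distinction is immaterial and no
haplotype information is available in this design. From each flagged
pair the marker with the lower genotyping rate is dropped.

## Missing-genotype imputation

Missing calls are replaced by the marker's most frequent observed
genotype (mode substitution), computed over the whole cohort by
default. Pooling rather than imputing within status groups avoids
writing case/control information into the genotypes that the MDR
classifier would then "detect"; per-stratum imputation is available as
a flag for sensitivity analysis. Ties are broken toward the genotype
with fewer alternate alleles, making imputation deterministic.
Imputation is idempotent and never mutates its input.

## MDR engine

**Risk-cell classification.** For a k-marker model each of the 3^k
multilocus genotype cells is labelled from training data: high-risk if
cases/controls > T, low-risk if < T. T defaults to the training
split's overall case:control ratio — exactly 1 for paired data, which
generalizes cleanly to unmatched inputs. Threshold comparisons use
integer cross-multiplication (cases·D vs controls·C), so ties are
detected exactly. Tied cells default to *unassigned* (configurable to
high or low); unobserved cells are always unassigned. Unassigned
cells are predicted as control by default, or excluded from the
accuracy denominator with `empty_cell_prediction="exclude"`.

**Accuracy.** Balanced accuracy (sensitivity + specificity)/2, the MDR
convention; with 1:1 matched folds it coincides with raw accuracy,
which is also available.

**Cross-validation.** m folds × R repetitions (10 × 10 = 100
fold-evaluations by default, reported as CVC "/100"). In paired mode
each case-control pair is assigned intact to a fold and fold sizes
differ by at most one pair, so every training and test split is
internally 1:1. TA is the mean held-out accuracy over all m·R splits.
CVC counts the splits where the model attains the strictly highest
training accuracy among models of its size; exact ties award the win
to the lexicographically first subset, so within a size the CVCs
always sum to m·R. Per-size best models maximize CVC then TA; the
overall best maximizes TA, then CVC, then parsimony (smaller k).

Because risk labels depend only on per-cell training counts, the
engine never materializes per-subject predictions during the search:
it histograms (split × cell × class) counts once per model and
evaluates all m·R splits with array arithmetic. A full default search
over four markers (14 models, 100 splits, 818 subjects) takes a few
milliseconds, which is what makes full-search permutation testing
practical on one CPU. A test verifies that this vectorized path is
split-for-split identical to explicit fit/predict/score loops.

**Permutation test.** Each permutation randomizes labels — in paired
mode each pair's two labels are swapped independently with probability
½, preserving the matched design; unpaired mode shuffles labels freely
— and re-runs the complete search across all model sizes, recording
the permuted best TA. The reported p = (1 + #{null ≥ observed}) /
(1 + n_perm) (add-one Monte-Carlo estimator, never exactly 0). Because
the null re-selects a best model each time, it absorbs the optimism of
model selection; the mean null best-model TA therefore sits slightly
above 0.5 (≈ 0.53 at the default search space), which is correct
behaviour, not bias.

**Randomness.** One master seed; fold assignments and each
permutation's label swaps and folds draw from deterministic
`SeedSequence([seed, stream, index])` substreams, so results are
bit-reproducible and independent of execution order.

## Synthetic cohorts

The simulator emulates the matched design the pipeline assumes:
genotypes drawn independently per marker from HWE proportions,
1 case + 1 control per pair, pair-level sex (53.3% female pairs by
default, matching the reference cohort), and per-marker missingness
applied independently. The default four-marker panel uses the
reference cohort's control alternate-allele frequencies (0.322, 0.356,
0.471, 0.457) and per-marker missing rates (5.9–12.2%) so that null
simulations reproduce the study's conditions. Epistatic cohorts draw
population individuals under HWE, sample disease status from a 3×3
two-locus penetrance table, and ascertain cases and controls by
rejection sampling (exact, with a 10⁶-draw guard against near-degenerate
penetrances). `expected_cell_ratios` provides the closed-form
case:control ratio per cell — [f/(1−f)] normalized by the prevalence
odds — as an analytic oracle for risk-cell labels on large cohorts.

What the simulator deliberately omits: LD between markers, population
stratification, genotyping error correlated with status, and
covariate effects. Passing tests on simulated cohorts therefore
demonstrate the statistical machinery under the stated model, not
robustness to those real-data complications.

## Reference cohort reconstruction

The packaged reference cohort reproduces, exactly, the per-marker ×
per-sex × per-status genotype counts published for an Australian
essential-hypertension study (409 pairs; 218 female, 191 male).
Only those margins are published, so individual rows are completed
deterministically (blockwise genotype assignment within each group,
independently per marker; un-genotyped subjects appear as missing
calls). Every single-locus statistic computed from it is exact by
construction. Two caveats follow from the construction: the joint
genotype distribution across markers is an artifact (so MDR output on
this cohort is illustrative, not a reproduction), and blockwise
assignment induces artificial between-marker correlation (so LD
screening is only meaningful on real or simulated data, not on this
fixture).

## Numerical and design notes

- Chi-square tests delegate to `scipy.stats.chi2_contingency`
  (`correction=False`); HWE and LD are direct formula evaluations.
- Accuracy denominators of zero (possible in unpaired mode or with
  `exclude`) yield NaN for that split and are dropped from TA via
  `nanmean`; in paired mode denominators are always positive.
- Degenerate inputs fail loudly with typed errors: monomorphic
  markers (HWE, allele test), all-missing markers (imputation),
  incomplete pairs (paired CV), single-class data (accuracy).
- Three printed percentage cells of the published reference tables
  disagree with their own counts by 0.1 (truncation or typo);
  reproduction tests for percentages therefore assert agreement to
  within 0.1 percentage point, while all test statistics are asserted
  at the printed 2 decimals.
- Test and acceptance simulation sizes (10–100 cohorts of 409 pairs,
  200 permutations) were chosen as the smallest scales at which the
  calibration and recovery properties are statistically unambiguous.
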