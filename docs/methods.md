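# Methods

`hdlburden` re-implements, as a tested and reusable pipeline, the analytic
chain of a whole-exome study of hypoalphalipoproteinemia (low plasma HDL-C):
cohort selection by a hyperbolic quantile isopleth, two rare-variant filter
cascades, a ten-tool consensus deleteriousness classification, a
mutability-calibrated one-sided binomial gene-burden test, and gene-set
over-representation.  A synthetic cohort generator supplies inputs with the
statistical structure the analysis assumes, plus ground truth, so the
pipeline's calibration and power can be measured end to end.

## Cohort selection

Low HDL-C is frequently secondary to hypertriglyceridemia, so a raw HDL-C
percentile cutoff over-selects hypertriglyceridemic subjects.  Selection
instead uses a quantile curve in the (TG, HDL-C) plane of the hyperbolic
family

    y = m1 + (m2 * m3) / (m2 + x),      y = HDL-C, x = TG (mg/dl), m2 > 0,

fitted by minimizing the pinball (quantile) loss at level q (default 0.10)
so that a fraction q of the reference population lies below the curve.  No
published values exist for the constants of any real cohort's isopleth; the
generator's defaults (m1 = 20, m2 = 100, m3 = 45 mg/dl) are synthetic round
numbers chosen to give a plausible population curve (HDL-C ~ 62 mg/dl at low
TG falling toward ~29 mg/dl at TG 400), not a study's fitted curve.

Fitting: a nonlinear least-squares fit of the mean curve (m2 kept positive
through a log parameterization, multi-started over m2 scales) initializes a
Nelder-Mead polish of the nonsmooth pinball objective, seeded at the mean
curve shifted by the empirical q-quantile of its residuals.  On noiseless
data lying exactly on one family member the least-squares stage already
attains zero loss and is returned unpolished.  Degenerate inputs (fewer than
30 points, all TG equal) are rejected; a constant-HDL cloud collapses to
m3 ~ 0, a flat curve.  Selection uses strict `<` (a record exactly on the
curve stays in the reference population).

LDL-C, when not measured directly, is the Friedewald estimate
TC − HDL-C − TG/5, undefined at TG >= 400 mg/dl.  Subphenotype groups use
TG >= 150 mg/dl (NCEP ATP III hypertriglyceridemia) and LDL-C >= 160 mg/dl;
for participants under 18 a caller-supplied sex/age percentile lookup can
replace the adult LDL cutoff (the default applies the adult cutoff with a
logged notice, since no percentile table is bundled).  Group comparisons use
Welch t-tests (robust to unequal variances, asymptotically Student under
equality) on transformed values — log for BMI/TC/TG, square root for LDL-C —
and Fisher's exact test for categorical splits.  Summaries use per-variable
complete-case denominators, logged.

## Filter cascades

Candidate-gene branch, in fixed order (the first failed rule is the recorded
drop reason): QUAL > 40 (strict), DP >= 20, GQ >= 60 when the caller set
intersects {GATK-UG, GATK-HC, Freebayes}, more than one caller (single-caller
calls are treated as artifacts), coding consequence (synonymous / intronic /
intergenic / UTR removed); then removal of the top half — rounded up, for a
deterministic, conservative rule — of a caller-supplied ranked common-variant
list; then a platform filter dropping variants carried by more than 40% of
samples; then gnomAD MAF <= 0.01 for the heterozygous analysis set and
<= 0.05 (with at least one homozygous genotype) for the homozygous set.

Burden branch: VQSR pass, DP >= 8, GQ >= 20, MQ >= 40, >= 3 alt-supporting
reads, outside low-complexity regions (all thresholds inclusive); rarity
requires MAF at or below the chosen threshold (1e-5, 1e-4 or 1e-3) in every
one of ExAC, 1000 Genomes and ESP.  An absent population frequency is
treated as 0 everywhere: novel variants are by definition rare.  MAF
comparisons are `<=` at the cutoff in both branches.

Consequence classes: LoF = stop-gain, stop-loss, frameshift indel, splice
site, start-loss; D-Mis = missense called deleterious by MetaSVM; everything
else `other`.  Filters are idempotent, MAF and platform filters commute, and
stage tallies conserve counts — all asserted by tests.

## Consensus damage classification

Each variant's damaging vote count over ten predictors (SIFT, PolyPhen-HVAR,
MutationTaster, MutationAssessor, FATHMM, PROVEAN, MetaSVM, MetaLR, M-CAP,
FATHMM-MKL) scores damaging = 1, equivocal = 0.5 (vote totals are
half-integer in practice), tolerated = 0; a missing call contributes 0 rather
than renormalizing, keeping the 0–10 scale fixed, with the missing count
logged.  Percentile ranks are mid-rank (strictly-smaller fraction plus half
the ties) within the assessed set — by default all variants surviving the
candidate cascade in the current run — making them invariant under
duplication of the set.  Classes: >= 80th percentile probably damaging;
[50th, 80th) undetermined; < 50th likely benign; and any variant above the
50th percentile with an unequivocal ClinVar pathogenic entry (a label
containing pathogenic/likely pathogenic with no benign, conflicting or
uncertain token) is pathogenic.  Sub-50th variants stay likely benign even
with a ClinVar entry.  Carrier occurrences are counted per (carrier,
variant) pair; homozygous carriage counts once (a flag doubles it if
desired).

## Mutability and the burden test

Per-gene de novo mutability is summed from trinucleotide-context
substitution rates: for a coding sequence with one flanking base per side,
every one of the 3L possible single-nucleotide substitutions contributes its
context rate to the class (LoF / missense / synonymous) of its coding
consequence under the standard genetic code, frame from position 1;
stop-gain, stop-loss and start-loss count toward LoF.  The rate table holds
192 entries (64 contexts x 3 alternates) after strand-symmetrization; a
pyrimidine-centered 96-row table is expanded by reverse complement.  The
bundled synthetic table uses a 1.2e-8 per-site per-generation base rate,
transitions 3x transversions, and a 10x CpG transition boost — the canonical
features of human de novo SNV rates.

Two components are not derivable from the SNV context model and enter as
explicit model choices: frameshift/splice mutability is an additive per-gene
term defaulting to 1.25x the enumerated SNV LoF mutability, and the
damaging-missense (D-Mis) share of missense mutability defaults to 0.35.
Only relative mutabilities matter for the test, so these act as priors on
the per-gene success probabilities.  Coverage adjustment multiplies a gene's
class mutabilities by the fraction of its coding bases adequately covered
(suggested operationalization: depth >= 10 in >= 90% of samples), supplied
per gene; zero-coverage genes are excluded with a warning.

With N total retained damaging heterozygous occurrences across tested genes,

    p_i = Mutability_i / sum_j Mutability_j,     Expected_i = N * p_i,

and the per-gene p-value is P(X >= observed) for X ~ Binomial(N, p_i),
computed through the regularized-incomplete-beta survival function (stable
for small p_i and large N; an exhaustive term-summation oracle in the tests
agrees to 1e-10 relative error up to N = 1000).  Significance is flagged at
alpha divided by the number of genes with positive adjusted mutability.
Q–Q diagnostics plot observed versus expected −log10 p with expected
quantiles i/(n+1) (uniform order-statistic means); zero p-values are clamped
to the smallest positive double with a warning.

Gene-set over-representation: per set, hits against a gene universe of
stated size, expected = set_size x |hit list| / universe, fold =
hits/expected, one-sided (greater) Fisher exact p, Benjamini–Hochberg FDR
across sets.

## Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes and
nothing more.  Lipids: TG lognormal (median 120 mg/dl, log-sd 0.6); HDL-C on
the truth hyperbola plus centered Gaussian noise (sd 10 mg/dl — chosen so
the designed TG–HDL-C coupling remains the dominant source of HDL variance,
with corr(HDL-C, 1/(m2+TG)) ~ 0.53 at the defaults), floored at 1 mg/dl;
LDL-C Gaussian (130 +- 35 mg/dl); TC built as LDL + HDL + TG/5 so the
Friedewald estimate is exact below TG 400.  Demographics mirror a 204-person
lipid-clinic cohort (34.3% female, age 50 +- 15.7, prevalence-matched
clinical flags).

Variants: the damaging-count law is Poisson per (participant, gene) with
mean proportional to the gene's adjusted damaging mutability times a planted
enrichment multiplier (>= 1), aggregated per gene — the burden test's own
expectation model, so null and alternative hypotheses are realizable by
construction.  The cohort-wide simulated damaging total defaults to 480,
chosen so that after QC and rarity thinning (~17%) roughly 400 occurrences
are retained, i.e. an average-mutability gene has an expected count of ~2 in
a 200-gene run — the scale of a few-hundred-exome rare-variant study.  Each
damaging occurrence is a singleton variant (rare-variant regime),
heterozygous except for a 2% homozygous fraction.  Damaging missense
variants carry a deleterious MetaSVM call by construction (D-Mis is defined
by that call).  Benign background variants (3x the damaging load;
synonymous / tolerated missense / noncoding) have more carriers and higher
population MAFs, including occasional platform-like artifacts carried by
over 40% of samples and a ranked common-variant list derived from them.
Tool votes follow configurable operating points (default sensitivity 0.90,
false-positive rate 0.15, 4% equivocal, 2% missing); ClinVar labels attach
to a small fraction of variants.  QC fields (QUAL, DP, GQ, MQ, alt reads,
caller sets, LCR and VQSR flags) are drawn with small independent failure
rates so every filter rule is exercised.

All randomness flows from one seed through a single NumPy generator in fixed
stage order, so runs are bit-reproducible.  For planted-recovery
experiments, `simulate_planted_cohort` places the multiplier on the roster
gene whose mutability share is closest to the roster mean, pinning the
planted gene's null expectation at ~2 regardless of the seed's roster.

What the generator does *not* model — and hence what passing tests do not
show about real data: linkage disequilibrium and relatedness, shared
(recurrent) rare variants, correlation between a variant's ClinVar status
and its tool votes, population stratification of allele frequencies,
sequencing-level artifacts beyond independent per-field failures, and any
genotype-to-lipid causal effect (lipids and genotypes are independent under
the null generator; carrier-association power tests plant shifts
explicitly).

## Numerical and design choices

- Percentile reference population for classification is the current run's
  candidate-cascade survivors; mid-rank tie handling.
- "Top 50th percent" of the common list rounds half up.
- Drop reasons use a fixed rule order, giving reproducible reason tallies.
- Welch rather than Student t; two-sided tests except where one-sidedness is
  the method (binomial tail, Fisher greater).
- The genome-wide threshold is alpha / number of genes tested in the run.
- Expected Q–Q quantiles are i/(n+1).
- Problem sizes in the test-suite simulations (204 participants, 200 genes,
  ~2,000 variants; 50 recovery replicates) are the package's default study
  conditions, chosen to match the cohort scale the pipeline targets.

## Known limitations

- The per-gene D-Mis fraction and frameshift/splice term are priors, not
  enumerations; absolute expected counts inherit their error, though the
  test depends only on relative mutabilities.
- The common-variant list is caller-supplied (vendor catalogues are
  proprietary); results are list-dependent.
- Case-control burden against external call sets, CNV calling, trio
  analysis and ancestry adjustment are out of scope.
- Cohort-level tallies of any real study depend on its private genotypes
  and contemporary database versions and are not reproducible here; the
  package validates arithmetic identities, calibration and power on
  synthetic data instead.
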