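# Methods

## Phenotype

Usage of a V gene is the proportion of repertoire reads mapped uniquely to
it among all mapped reads of its receptor family. Genes undetected in an
individual are exact zeros, and each family (TRBV targets, IGHV controls) is
its own composition: detected-gene proportions sum to 1 per family, because
the two families come from separate sequencing libraries. The association
phenotype defaults to raw proportions; a log2(u + pseudo) view is available
(`phenotype_mode="log2"`), with family-specific pseudo-usage constants of
0.01 (target) and 1e-5 (control) chosen to sit below the typical detected
proportion of each family. The run records which mode was used.

## Dosage model

All three genetic levels reduce to the same representation: a count
d ∈ {0,1,2} of a reference symbol per individual. At the allele level the
symbol is the four-digit allele itself; at SNP and amino-acid levels every
symbol observed at a polymorphic site becomes its own variant with the other
symbols pooled as the alternative, so a k-symbol site yields k columns whose
per-individual dosages sum to 2. This expansion makes multi-allelic sites
first-class and means complementary columns of a bi-allelic site carry the
same test (opposite sign). MAF is computed from the dosage mean
(f = mean(d)/2, MAF = min(f, 1−f)); columns with MAF strictly below the
0.05 threshold are dropped, a column exactly at the threshold is kept.
Missing genotypes are errors, never imputed — upstream callers are expected
to provide best-guess complete genotypes.

Variant ids are `<locus>.<level>.<position>.<symbol>` (position 0 at the
allele level, where position has no meaning); the compact amino-acid label
style `HLA-A.I97M` is accepted on input, with the trailing residue read as
the counted symbol.

## Association scan

Each (variant, gene) pair is a simple OLS of phenotype on intercept +
dosage, no covariates (a covariate hook exists but defaults to empty);
two-sided p from t with n−2 df. The scan vectorizes the closed-form
cross-product identities over the whole variant × gene grid, which is
algebraically identical to per-pair OLS (tests verify agreement with
statsmodels OLS to 1e-10). Zero-variance dosage columns are skipped and
logged rather than raised, so scans over filtered matrices are restartable.
A perfect fit reports the smallest positive double rather than p = 0.

Multiplicity is controlled per genetic level (allele / SNP / amino-acid)
with Benjamini–Hochberg across all gene × variant tests of that level
jointly; a per-gene alternative can be had by scanning genes separately.
BH was chosen because the threshold is stated only as "5% FDR" in this
analysis tradition and BH is the default procedure of the standard QTL
engines. Inflation is genomic-control style:
λ = median(qchisq(1−p, 1)) / qchisq(0.5, 1), reported always, with a seeded
bootstrap 95% interval (200 resamples) instead of a display-significance
rule; QQ coordinates use the (i−0.5)/m expected quantiles.

## Conditional fine-mapping

Per gene, candidates are its FDR-significant variants (pooled across loci —
MHC LD spans loci, and restricting to one locus would miss cross-locus
redundancy). Forward stepwise selection: step 0 takes the smallest marginal
p; each later step refits every remaining candidate with all selected
variants as covariates (computed by Frisch–Waugh–Lovell residualization
against an orthonormal basis of the current design, vectorized over
candidates) and admits the smallest conditional p iff it is < 0.05 —
equality stops, closing the gap between the "< 0.05 admits" and "> 0.05
stops" conventions on the stop side. Ties break lexicographically on
variant id, making the procedure deterministic. A candidate whose residual
against the selected span has norm ≤ 1e-10 × its own norm is excluded at
that step (rank-deficiency guard; exact duplicates of a selected signal are
excluded this way).

A structural property of this rule worth stating: once all true signals are
selected, every remaining statistically distinct candidate group has a
uniform conditional p, so each contributes ≈ α = 5% probability of one
spurious extra signal. Recovery of "exactly the planted signals" therefore
depends on how many distinct linkage groups survive among the candidates —
in real MHC data amino-acid candidates collapse into a handful of tight
linkage groups, which is what keeps the procedure's output short.

## Variance explained

Per-signal attribution is the adjusted R² of that signal's single-predictor
model; the combined value is the adjusted R² of the joint model, with the
overall F-test BH-flagged across genes. Single-predictor (not sequential)
attribution is used because it is the convention under which top% + second%
can exceed the combined% for correlated predictors — the pattern this
reporting layout exhibits. Adjusted values can be negative and are reported
as computed. Rank-deficient joint designs are an error naming the dependent
columns.

## Structural overlay

Contacts are consumed as pre-annotated presence/absence tables per complex
(curated structure-database annotations); computing contacts from 3D
coordinates is out of scope because it would require inventing a distance
cutoff. Frequency = (#complexes of the locus with ≥1 contact at the
position) / (#complexes in the locus's roster); duplicate records count
once, and positions contacted by only one partner get frequency 0 for the
other. The association summary per position is the minimum p across genes
(switchable to per-gene output); overlay keeps the union of positions with
explicit nulls so nothing is silently dropped.

## Synthetic cohort generator

The generator reproduces the structure the analysis assumes, not any real
cohort's values:

- **Genotypes.** Two alleles per locus i.i.d. from pool frequencies
  (Hardy–Weinberg). The default pool has the eight classical loci with
  allele counts 23/46/21/28/16/4/14/15 (A/B/C/DRB1/DPB1/DPA1/DQB1/DQA1),
  matching the diversity a cohort of ~200 East-Asian newborns carries, and
  skewed frequencies from a symmetric Dirichlet(0.8) — the few-common,
  many-rare shape of real HLA spectra.
- **Translation table.** Each allele gets one residue per amino-acid
  position (default 25/locus) and one base per SNP position (default
  40/locus); per locus at least one position is polymorphic and one carries
  ≥3 residues when the allele count permits. Because positions partition the
  same allele set, positions are correlated exactly the way real MHC amino
  acids are — LD emerges from allele sharing, not from an imposed LD matrix.
- **Usage.** Latent log-score s_ig = log(baseline_g) + Σ β_v d_iv + ε,
  ε ~ N(0, noise_sd²); usage = softmax of s over the detected genes of each
  family, dropped-out genes exact zeros (dropout before normalization,
  mirroring proportions over mapped reads). Baselines come from a symmetric
  Dirichlet(5) per family. Defaults: n = 201 individuals, 48 target + 20
  control genes, noise_sd = 0.3 (≈ 30% coefficient of variation in usage, a
  moderate inter-individual spread; no published estimate exists to
  calibrate against), dropout = 0.02 (undetected genes are rare and
  scattered). Control genes cannot carry effects.
- **LD blocks** (`ld_block`). For recovery studies: a causal site plus
  passenger groups, each group an exact-copy set of positions whose tag
  haplotype matches the causal haplotype with probability r. The two-effect
  recovery condition uses two blocks (11 passengers each, r = 0.55, two
  planted effects of ~10% variance each); the single-effect condition uses
  one block of 20 perfect proxies (r = 1), the extreme-LD limit, which
  exercises the collinearity exclusion — at any r < 1 the expected
  exactly-one-signal rate equals 1 − α = 95% exactly (see the structural
  property above), i.e. the admission threshold's own boundary.
- **Calibration phenotypes** (`planted_phenotype`). A weighted sum of
  standardized dosages plus Gaussian noise scaled to the empirical signal
  variance, so the planted variance fraction is exact in expectation — used
  to verify that the combined adjusted R² recovers planted fractions of 0.1
  and 0.2 within ±0.05 over 100 replicates.

What passing these tests does *not* show about real data: the generator has
no imputation error, no read-sampling noise in usage (proportions are exact
softmax values), no population structure or batch effects, and its LD comes
only through allele sharing — real MHC LD also has haplotype structure
across loci. Null calibration and recovery rates are therefore statements
about the method under its own model assumptions.

## Study sizes used in the checks

Null calibration: 50 independent cohorts of 200 individuals, 300 post-filter
amino-acid variants, 48 + 20 genes (~1M tests pooled). Recovery: 100
replicates per condition at n = 200. Inflation: 10,000 uniform p-values.
Under the complete null the per-rep false-discovery proportion is 1 if
anything is flagged and 0 otherwise, so its mean across reps estimates the
realized FDR; the target-vs-control contrast uses a paired t-test of per-rep
p<0.05 fractions across the 50 reps, because the pooled tests within a rep
are strongly correlated and a pooled two-proportion z-test would be badly
anticonservative (measured per-rep sd of the fraction is ~10× the pooled
binomial SE).

## Pipeline and determinism

`run_all` executes simulate → encode → associate → condition → explain →
contacts from a single YAML config (all thresholds default to MAF 0.05,
FDR 0.05, α 0.05) and writes a manifest with config echo, package version,
SHA-256 of every output and per-stage counts. All randomness flows through
`numpy.random.default_rng` seeded from the config; TSVs are written with a
fixed float format, so identical config + seed reproduces byte-identical
stage outputs. Logs go to stderr, results to files, exit codes 0/1/2 for
ok / user error / internal error.

## Known limitations

- Allele-level encoding drops rare alleles via the MAF filter; it does not
  pool them into a rest-category.
- No covariates (sex, ancestry PCs, batch) in the default scan; real cohorts
  typically need them.
- The conditional procedure's α = 0.05 admission is liberal when many
  distinct candidate groups remain (see the structural property above);
  Bayesian fine-mapping or stricter entry thresholds are out of scope.
- Amino-acid position numbering is taken verbatim from the translation
  table; whether a given table uses precursor or mature-protein numbering is
  the caller's responsibility.
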