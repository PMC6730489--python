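# immunoqtl

QTL mapping of immune-repertoire V-gene usage against multi-level HLA
variation.

T cells recognize peptide–MHC complexes through their T-cell receptor, and
the germline-encoded CDR1/CDR2 loops of each TCRβ V gene (TRBV) contact the
MHC surface directly. Whether MHC polymorphism therefore biases which TRBV
genes a repertoire uses is a genetics question: treat each individual's TRBV
usage (the proportion of repertoire reads mapped to each V gene) as a
quantitative trait and test it against the individual's HLA variation. This
package implements that analysis for cohorts of HLA-genotyped individuals
with repertoire-derived V-gene usage — and, because such cohort data are
access-restricted, ships a synthetic cohort generator that reproduces the
data's statistical structure (Hardy–Weinberg HLA genotypes, allele-linked
amino-acid/SNP variation inducing MHC-like LD, compositional usage with
planted additive effects, and an IGHV-like control family that should show
nothing).

## The method

1. **Dosage encoding.** HLA genotypes (two four-digit alleles per locus) are
   coded at three levels — whole allele, SNP, amino-acid residue — as allelic
   dosage: the count d ∈ {0,1,2} of a reference symbol. A site with k > 2
   symbols is expanded into k variants, each taking one symbol as reference
   (a tri-allelic SNP becomes three SNPs). Variants with minor allele
   frequency < 0.05 are removed.
2. **Association scan.** For every (variant v, gene g) pair, the simple
   linear model u_g = α + β·d_v + ε is fit by OLS; two-sided p from t with
   n−2 df. Benjamini–Hochberg FDR is controlled at 5% within each genetic
   level, and a genomic-control inflation factor
   λ = median(χ²_obs)/qchisq(0.5, 1) with QQ coordinates summarizes each
   level (the IGHV control family should sit on the diagonal).
3. **Conditional fine-mapping.** Because MHC LD is extreme, each gene's
   FDR-significant amino-acid variants are reduced to independent signals by
   forward stepwise regression: start from the smallest marginal p, refit
   all remaining candidates with the selected set as covariates, admit the
   smallest conditional p while it is < 0.05.
4. **Variance partitioning.** Per gene, adjusted R² of each signal's
   single-predictor model and of the joint model (with overall F-test,
   BH-flagged across genes) quantifies how much usage variation the MHC
   explains.
5. **Structural overlay.** Per-position contact frequencies across solved
   TCR–pMHC complexes (fraction of a locus's complexes in which the position
   touches the TCRβ V region or the peptide) are joined with −log10 of the
   strongest association p per position.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort of 201 individuals (8 classical HLA loci with realistic allele
counts, 48 TRBV target genes + 20 IGHV controls, nine effects planted on
seven TRBV genes sized to explain roughly 5–25% of usage variance):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_encode_dosages.py
python analysis/03_scan_associations.py
python analysis/04_finemap_signals.py
python analysis/05_variance_explained.py
python analysis/06_contact_overlay.py
```

The scan stage prints, per level, the test count, significant variants per
family, and inflation:

```
allele     :   2856 tests | significant variants (TRBV)   2, (IGHV)   0 | lambda TRBV 1.13, IGHV 0.91
snp        :  35020 tests | significant variants (TRBV)  10, (IGHV)   0 | lambda TRBV 1.13, IGHV 0.98
amino_acid :  30940 tests | significant variants (TRBV)  18, (IGHV)   0 | lambda TRBV 1.11, IGHV 0.97
TRBV genes with >=1 amino-acid association: 6/48 -> ['TRBV10', 'TRBV12', 'TRBV13', 'TRBV20', 'TRBV28', 'TRBV9']
```

Only the TRBV family shows inflation (λ ≈ 1.1) and significant variants;
the IGHV controls are null — the qualitative signature the method is built
to detect. Fine-mapping then collapses each gene's correlated candidates to
independent signals, e.g.

```
TRBV13  : 2 signal(s) ['HLA-A.amino_acid.4.Q', 'HLA-A.amino_acid.20.C']  [planted=['HLA-A.amino_acid.20.C', 'HLA-A.amino_acid.4.F']]
TRBV9   : 1 signal(s) ['HLA-A.amino_acid.142.M']  [exact]
```

(`4.Q` is a perfect proxy of the planted `4.F` — the complementary residue
at the same position — which no statistical procedure can distinguish.)
The variance stage reports the usual layout: adjusted R² (%) of the top
signal, the second signal and both jointly, e.g. TRBV13 32.44 / 8.25 /
39.31 — per-signal values need not sum to the joint value when signals are
correlated. The contact stage checks that positions with strong
associations are contacted more often in complexes (here Spearman ρ = 0.38,
p = 2e-4, against a synthetic contact roster with elevated contact rates at
effect positions).

The same stages are available as a console tool operating on TSV inputs
(`immunoqtl simulate|encode|associate|condition|explain|contacts|run-all`),
so real genotype/usage tables can be substituted for the generator.

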