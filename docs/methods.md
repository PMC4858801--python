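# Methods

This note documents the models and procedures implemented in `wildrecomb`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter when
reading results.

## Crossover detection

**Subpedigrees.** A gamete transmitted from a focal individual (FID) to an
offspring is phased inside a five-member unit: FID, its father and mother,
the offspring, and the offspring's other parent.  Units are built for every
parent–offspring pair in which all five members are genotyped; units that
would contain the same animal twice (e.g. father–daughter matings) are
discarded.

**Mendelian QC.** For every parent–offspring pair in any unit, markers at
which the pair shares no allele (calls 0 vs 2) are set missing in both
members.  Units containing a pair whose pre-masking mismatch rate — counted
over markers where both calls are present — exceeds 0.1% are dropped.
Masking is symmetric and idempotent; on error-free data nothing is masked.

**Phasing rules.** Phasing is single-locus and deterministic.  The
transmitted allele is resolved when the offspring is homozygous, or
heterozygous with a homozygous mate; it must be carried by the FID.
Grandparental origin is assigned only at heterozygous FID markers, and only
when exactly one of the two transmitted/untransmitted → father/mother
assignments is consistent with the parental genotypes (a missing parent is
compatible with either allele).  These rules are verified in the test suite
against exhaustive enumeration of all gamete-level explanations of each
genotype configuration: the rules never contradict the enumeration, though
they are deliberately more conservative (they do not borrow grandparent
information to resolve the transmitted allele, and they use no linkage
information at all — see Limitations).

**Crossover calling and filters.** A crossover is a switch of grandparental
origin between adjacent informative markers.  Two filters, applied in fixed
order, remove apparent double crossovers that are characteristic of
phasing error:

1. every *internal* run of a single informative SNP is recoded missing
   (one pass; terminal runs are kept — a segment is only a double
   crossover if flanked by the opposite origin on both sides);
2. for the remaining internal runs, the base-pair span between the
   informative SNPs immediately flanking the run is pooled across all
   gametes, sexes and chromosomes, and runs with log10 span below
   (mean − 2.5 SD) are recoded missing.  With fewer than two double
   crossovers in the data the filter is skipped with a warning.

Both filters can only reduce a gamete's count, by exactly 2 per removed
run.  The per-gamete phenotype table records ACC, per-chromosome counts
(needed for the cis/trans separation), the number of informative SNPs, and
the informative genome length.

## Linkage maps

With phase-known gametes and markers taken in assembly order, the
recombination fraction of each adjacent-marker interval is estimated as the
fraction of gametes informative at *both* markers whose origins differ;
estimates ≥ 0.5 are truncated to 0.4999 with a warning, and intervals with
no informative pair are bridged with 0 cM and flagged.  Fractions are
converted with the Kosambi function d = 25 ln[(1+2r)/(1−2r)] (inverse
r = tanh(d/50)/2).  Markers whose sex-averaged distance to *both*
neighbours exceeds 3 cM are presumed mis-mapped and removed, re-estimating
until none remain; chromosome-terminal markers have one neighbour and are
exempt.  Sex-specific and sex-averaged maps share the same marker set.

Numerical behaviour worth knowing: the genome-total map length is a sum of
thousands of small binomial fractions, so at ~2,000 gametes with a ~6%
informative-pair rate its sampling SD is roughly 4% of the total (the test
suite asserts recovery within an analytically computed 3σ band rather than
a flat percentage).  With very few informative pairs per interval the
0.4999 truncation makes sex-stratified maps noisy upward; per-chromosome
sex-specific lengths should not be over-read at small sample sizes.

## Recombination landscape

Crossover probability per 1-Mb bin is the sum of interval fractions inside
the bin; an interval spanning one boundary contributes
r·N_boundary/N_adjSNP to the left bin (N_boundary = bases from the left
SNP to the boundary, N_adjSNP = bases to the closest SNP in the adjacent
bin) and the remainder to the adjacent bin, so bin totals conserve the
chromosome total exactly (to 1e-12); intervals spanning more than two bins
are split proportionally with a warning.  Distance to the nearest telomere
is measured from the bin midpoint (chosen for symmetry; the convention is
a parameter of the analysis, not of the data).

Telomere-distance models are Gaussian OLS fits of bin probability on one
of five distance transforms (x, 1/x, x²+x, x³+x²+x, log10 x) plus sex,
sex×distance interactions, SNPs per bin and GC content, compared by AIC on
identical rows; distance is limited to 60 Mb.  A male/female-ratio model
with the same candidates omits the sex terms.  Broad-scale regressions fit
chromosome map length on physical length, cM/Mb on a multiplicative
inverse of length (obligate crossing over makes small chromosomes
fast-recombining), and male on female map lengths.

## Variance components

**GRM.** Off-diagonals are allele-frequency-weighted cross-products
mean[(x_j−2p)(x_k−2p)/2pq]; diagonals are 1 + F̂ with the F^III-type
estimator F̂ = mean[(x² − (1+2p)x + 2p²)/2pq].  Missing genotypes
contribute nothing and pairwise marker counts are used.  An optional
`adjust` flag shrinks entries by the estimated 1/m sampling-variance share
of the off-diagonal variance (off by default; adjusted and raw matrices are
nearly perfectly correlated on realistic panels).  One exact identity used
in testing: at p = 0.5 a duplicated individual's off-diagonal equals its
diagonal; at other frequencies the two agree in expectation only.
Pedigree relationship matrices come from the tabular method.

**REML.** The engine maximises the restricted likelihood of
y = Xβ + Σᵢ uᵢ + e for arbitrary dense covariance structures by
average-information iteration with step-halving, an EM-flavoured
multiplicative fallback, and non-negativity floors at 1e-10 of the
phenotypic variance.  Because a component shrinking toward zero converges
geometrically and can stall just above the boundary (leaving the
log-likelihood fractionally below the nested model's — which would produce
negative LRT statistics), any component ending below 0.15·V_P triggers a
*boundary polish*: the model is refit with that component removed and the
better solution is kept, with the component flagged as boundary.
Convergence is a relative log-likelihood change below 1e-8 together with a
stabilised parameter vector.  Standard errors come from the inverse AI
matrix; ratio SEs (h², regional shares) use the delta method.  Closed-form
anchors verified in the tests: a residual-only model reproduces the OLS
residual variance exactly, and a balanced paternal half-sib design
reproduces 4× the ANOVA sire component to 1e-6 whenever that estimate is
interior.

The default animal model for ACC has fixed effects of sex (and optionally
the genomic inbreeding coefficient), an additive effect with GRM or
pedigree covariance, an individual-identity (permanent environment) effect
for repeated gametes per FID, and a residual; further identity-covariance
terms (birth year, parental identity) are available but off by default, as
they explain no variance under the simulated architectures.  LRTs for
random effects use the plain chi-square(1) reference by default; the 50:50
boundary mixture is available via `mixture=True`.

**Bivariate model.** Male and female ACC are two traits with cross-trait
genetic covariance C_A = r_A √(V_Am V_Af).  The free and r_A = 0 fits stay
inside the AI-REML engine (C_A is a linear component, allowed negative);
r_A fixed near 1 (0.999) and the equal-V_A constraint are nonlinear in the
components and are optimised on a transformed scale with Nelder–Mead.
LRTs against the free model use 1 df.  r_A is undefined (flagged) when
either sex's V_A sits on the zero boundary.

**Reference-panel selection.** Greedy forward selection maximising Σp with
p = A_sel⁻¹ c_sel, where c_sel is the mean relationship of selected
animals to the whole population; ties break by id order and singular
candidates are skipped with a warning.  On a star pedigree the common sire
is selected first, and the objective is non-decreasing in panel size.

## GWAS

Per SNP, genotype is a fixed factor with the observed two or three classes
(AB and BB effects against the AA intercept).  The null animal model is
fitted once per stratum by REML; per-SNP effects and the Wald chi-square
(df = classes − 1) are then computed by GLS under the fitted covariance.
This two-stage scheme is the package's design choice for tractability —
variance components barely move when one SNP enters the fixed effects —
and an exact per-SNP REML refit is available via `refit_variance=True`.
Under iid residuals the Wald statistic equals df × the OLS F statistic
exactly.

Genomic control: λ is the median Wald statistic over the median null
chi-square on the 2-df scale, with 1-df records mapped through their
p-value quantile; correction (dividing statistics by λ) is applied only
when λ > 1.  The effective number of tests gives the first SNP of each
chromosome weight 1 and every later SNP √(1 − max r²) against the
preceding ≤ 49 SNPs of the same chromosome (squared genotype-dosage
correlation); the genome-wide threshold is α/n_eff.  The published
effective-test count reproduces the published threshold to printed
precision.  V_SNP = 2pq[a + d(q−p)]² with a = half the AA–BB contrast and
d = a − (AB effect); with these sign conventions the formula equals the
regression (additive) variance of the locus exactly, which the tests
verify against brute-force Hardy–Weinberg enumeration (the class-mean
variance exceeds it by the dominance term (2pqd)²).  In trans mode the
response tested against each SNP excludes the crossover count of the
SNP's own chromosome.

## Regional heritability

Half-overlapping sliding windows of 150/50/20 SNPs (default 20, truncated
at chromosome ends; under-sized chromosomes form one flagged
whole-chromosome window) are each fitted with a four-component model:
window GRM, rest-of-genome GRM (exactly the complement marker set, same
F^III construction), permanent environment, residual.  Significance is an
LRT against the model without the window term; fits whose window component
lands on the zero boundary have the p-value masked as uninformative.  The
scan threshold is α/(n_windows/2), windows being half-overlapping so each
region is modelled twice.  Window components need not sum to the
whole-genome V_A (windows overlap); each fit's components do sum to its
own V_P, which agrees closely with the single-GRM fit on the same data.

## The synthetic-data generator

Defaults emulate the study conditions: a discrete-generation pedigree with
repeated offspring per pair and globally alternating offspring sexes (so
generations stay balanced and the default configuration yields 288
FID gametes); 26 autosomes with sheep-like physical lengths (~2.45 Gb);
~16 SNPs/Mb (≈ 39,000 markers, 50K-chip density) with uniform MAF in
(0.05, 0.5) drawn site-independently (no background LD); sex-specific maps
totalling 3748 (male) and 2860 (female) cM distributed proportionally to
physical length, with a 2.5× male rate elevation within 18 Mb of each
chromosome end; obligate crossing over (count = 1 + Poisson(max(0,
cM/100 − 1)), the default) or plain Poisson; crossover positions from
gamma(ν) spacings on the cM scale (ν = 1, no interference, by default —
with the default genome this reproduces a median inter-crossover distance
near 48 Mb); and genotyping error/missingness of 0.001/0.005.

The ACC architecture is latent: each parent carries a polygenic value g
(pedigree-recursive, V_A = 4.28 by default) and each meiosis an
independent deviate (V_RE = 25.28); the map is scaled by
(μ_sex + g + QTL + ε)/μ_sex, floored at 0.05.  An optional QTL adds a
per-B-copy effect, optionally sex-limited.  Two consequences deserve
emphasis:

- **Counting noise.** Realised counts add (mixed-)Poisson variance on top
  of the latent variance, so the mechanistic pathway cannot reproduce a
  phenotypic variance equal to its mean together with nonzero latent
  variance.  Where the exact decomposition *is* the condition of an
  experiment (heritability, GWAS, regional heritability), use
  `simulate_acc_phenotype`, which draws a Gaussian ACC on the same
  pedigree with exact V_A/V_PE/V_R and optional QTL.
- **Scale coupling.** The latent variances are absolute (crossovers²).  On
  a scaled-down genome (μ ≪ 30) the defaults are far too large relative
  to the mean: the 0.05 floor skews realised counts upward, and obligate
  mode pins sub-100 cM chromosomes at one crossover, suppressing the
  architecture entirely.  Scale v_a_acc/v_r_acc with the genome, or use
  obligate=False, in toy configurations.

Gene-dropping can track founder-haplotype labels, proving every allele
traceable to a founder (tested).  Fixed seeds give bit-identical outputs.

**Validation harness.** `validation_run` builds one pedigree, repeats the
gene-drop + full-detection pipeline, and reports adjusted R² of detected
on true ACC per replicate (across gametes) and per gamete (across
replicates), flagging gametes at adjusted R² ≤ 0.95.  At chip density with
error-free calls the per-replicate accuracy is ≈ 0.94–0.96.  It does not
reach 0.99 with single-locus phasing: only ~25% of markers are informative
(multipoint phasing roughly doubles this), so crossovers beyond the
terminal informative SNPs are lost; the span filter removes ~2% of
*genuine* double crossovers on error-free data, where the short-span tail
is genuine rather than artifactual; and male subtelomeric map inflation
widens informative spacing (in cM) exactly where male crossovers
concentrate.  Passing the validation therefore certifies the pipeline's
correctness and quantifies — rather than assumes — the sensitivity cost of
deterministic single-locus phasing.  The per-gamete R² is itself noisy at
ten replicates, so the flagged fraction at desk scale reflects replicate
count, not detection quality.

What the generator does *not* emulate: background LD among founders
(available only through the QTL's own transmission), X/PAR inheritance,
mutation, selection, assembly errors, genotype-calling artefacts beyond
symmetric error/missingness, and age or cohort effects on recombination.
Tests passing on these simulations certify the algorithms under the stated
generative model; they do not certify robustness to mis-mapped markers
beyond the 3-cM rule, to pedigree errors, or to informative-marker
ascertainment in real chip data.

## Problem sizes used in the shipped experiments

Chosen so every analysis remains a faithful, adequately powered miniature:
detection validation at full chip density with 10 replicates × 288
gametes; heritability recovery at ~3,200 gametes from 800 FIDs (where the
SE of h² matches the published scale, ~0.03); GWAS and regional
heritability on ~800-SNP panels with the female-limited QTL sized from the
published homozygote difference (4.91 crossovers) and regional share
(~8%); maps on ~2,000 gametes.  Larger runs change precision, not
procedure.
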