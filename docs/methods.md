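# Methods

This note documents the models implemented in `mitovar`, the defaults and why
they were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that were genuinely open.

## Genome model and conventions

The reference sequence is recorded on the light (L) strand; heavy-strand (H)
alleles, contexts and codons are complements. Coordinates are 1-based
inclusive and all arithmetic wraps modulo the genome length, so features and
the control region may span the origin. Translation uses the NCBI vertebrate
mitochondrial code (table 2: TGA=Trp, ATA=Met, AGA/AGG=stop); human mtDNA is
not translatable under the standard code, so no other table is offered. A
gene's `coding_strand` is the strand equal to the mRNA sense sequence. A
variant inside overlapping genes is annotated once per gene and downstream
counts use the most severe consequence (severity order: frameshift > nonsense
> stop_lost > missense > inframe indel > silent > tRNA > rRNA > intergenic).

## QC and contamination

Sample swaps are screened with the genotype mismatch rate
(N_het+N_wt)/(N_hom+N_het+N_wt) over common-SNP sites where the normal is
homozygous for the variant allele; pairs above 0.1 are flagged. The
contaminant fraction is C = 2(ΣRC_wt − Ne)/(ΣRD_hom − Ne) with
Ne = e·ΣRD_hom at sequencing error rate e = 0.001, pooled over sites with
depth ≥ 10 and normal VAF ≥ 0.90. The factor 2 reflects that an unrelated
contaminant carries the wild-type allele on ~half of its chromosomes at a
~50%-frequency SNP. The fraction's typeset form is ambiguous about
parenthesisation; the adopted form subtracts the expected error reads from
both numerator and denominator, which makes C = 0 exact for an error-only
sample. The 95% CI is Clopper–Pearson on ΣRC_wt (the binomial choice made
explicit), pushed through the estimator; Ne is computed in aggregate, not
per site. Somatic calls must exceed 5× the CI upper bound, or a fixed 10%
floor when no estimate is possible. Sample-level contamination indicators:
≥3 somatic calls matching known polymorphisms, or ≥2 back mutations
(apparent somatic reversions of inherited polymorphisms to the reference
allele), flag the sample.

## Filter chain

All criteria must hold simultaneously: ≥4 Q20 variant reads (≥3 rescued when
VAF ≥ 20%), VAF ≥ 3% (the VAF denominator is variant + reference Q20 reads),
strand balance (≤90% of variant reads on one sequencing strand, rescued when
|perfect-match bias − mismatch bias| < 0.1 — regions where only one read
orientation aligns), not in the 13-site blacklist of homopolymer/reference-
spacer artefacts (A302C…C3110A, stored as position+allele and configurable),
VAF above the contamination floor, and the allele below 1% VAF in the matched
normal. The 1% normal threshold is a package choice: the tumor/normal
comparison needs a numeric cutoff and 1% sits well below the 3% detection
floor while tolerating index-hopping-level noise. Indels pass the same
read-count/VAF thresholds as substitutions. Phasing classifies a nearby pair
from spanning-read haplotypes (a haplotype counts as observed at ≥2 reads,
configurable): co-clonal (only wt1-wt2 and subs1-subs2), different strand
(both single-mutant haplotypes, no double), sub-clonal (double plus exactly
one single-mutant haplotype; the variant also seen alone is the earlier,
clonal one), otherwise unresolved.

## Signatures

Classes are pyrimidine-centric: (substitution type, strand carrying the
pyrimidine, trinucleotide context read on that strand) — 12 classes without
context, 192 with. Rates are counts over per-strand context opportunities
counted on the circular reference, restricted to the analysis region. The
Ori-b–O_H segment (defaults 16,197 and 191, boundaries inclusive, both
configurable) is where leading/lagging polarity inverts; segment signatures
are computed separately and the whole-genome signature may exclude it. The
replicative/transcriptional comparison re-keys class strands to the coding
strand of the containing gene and chi-squares H-coding-gene class counts
against the L-coding-gene background under each keying (a 0.5 pseudocount
keeps expectations positive); the lower statistic marks the better model.

## Selection

Opportunities L_c,k count, for each class k and consequence c, the genomic
single-base changes in protein codons (3 per in-frame site, per containing
gene). Counts are modelled as independent Poissons with
λ_c,k = r_k · w_c · L_c,k (w_syn ≡ 1). For fixed w the rate MLE is closed
form, r_k = ΣN/(L_syn + Σ w_c L_c), so the selection coefficients are
optimised on the profile likelihood by coordinate-wise bounded scalar search
on log w, iterated to a log-likelihood improvement < 1e-8, from a
deterministic multistart grid (1, 0.25, 0.5, 2, 4). This replaces random
restarts: with rates profiled out the surface is one- or two-dimensional and
a fixed grid makes the fit reproducible without a seed. LRTs against w = 1
use χ² with one df per coefficient; CIs are profile-likelihood (deviance
drop 3.84), with the other coefficient re-optimised. Stop-loss sites are
folded into the missense class by default (configurable). Per-gene fits are
BH-corrected at FDR 0.05.

The anticodon test redistributes the observed tRNA mutation total over tRNA
positions in proportion to signature-weighted mutability and compares the
anticodon expectation to the observed count with a one-sided lower Poisson
tail P(X ≤ obs); the one-sided choice is deliberate since the hypothesis is
depletion (negative selection), and the tail is Poisson because the
expectation derives from a rate model rather than a fixed trial count.
Recurrence is keyed by position (allele-keyed mode available): a mutation is
recurrent when its position is mutated in more than one sample. Chance
recurrence is estimated by Monte-Carlo placement under a uniform or
signature-weighted null — both are provided because either could be meant by
"expected by chance"; the signature null is the stricter comparison and
yields the smaller enrichment. VAF comparisons between consequence groups
use two-sided Wilcoxon rank-sum tests.

## Evolution simulator

Per generation, a Poisson number of substitution events (default 10; the
granularity is a package choice, and only the rate scale — not the reported
compositions — depends on it) is applied sequentially with context
re-evaluation. Events pick a site proportional to its current
context-dependent total rate via rejection sampling (O(1) per event;
falls back to exact categorical sampling when the mutable fraction drops
below 2%, and stops in the absorbing state) and then an allele proportional
to class rates. Under the synonymous-only constraint, proposals altering any
protein's translation are rejected, giving a mutation–selection equilibrium
that preserves the proteome exactly. Stationarity is declared when the
total-variation distance between block-averaged 3-mer compositions (mean of
5 consecutive snapshots vs the previous 5, snapshots every 100 generations
by default) falls below the tolerance; block averaging is needed because
single-snapshot TV is floored by finite-length sampling noise of order
√(64/L). Codon-usage skews are computed at third codon positions on each
gene's coding strand: T>C skew = (N_C−N_T)/(N_C+N_T),
G>A skew = (N_A−N_G)/(N_A+N_G), plus NNA:NNG and NNT:NNC ratios per
synonymous codon family.

## Wright–Fisher drift

M genome copies per cell, X′ ~ Binomial(M, X/M) per division, absorbing at 0
and M. Sites evolve independently (single-site marginal model) and new
mutations enter on one copy with no recurrent hits at a site within a run.
New mutations arrive as Poisson(μLM) per cell division. The closed form
E[N] = μL(T−2M) is a delayed-accumulation approximation; for T < 2M the
implementation returns 0 with a warning rather than a negative count. Note
the conditional fixation time of a new mutant deviates from the diffusion
value 2M by O(1/M) at small M (~12% low at M = 10), which is why the
acceptance check uses a 15% band.

## Synthetic-data generator

The generator defines the conditions every test runs under. The default
signature preset mimics the replicative asymmetry qualitatively: C>T on the
H strand at relative rate 1 boosted 10× in NpCpG, T>C on the L strand at 1
boosted 6× in NpTpC, all other classes at 0.05 — within the enrichment
ranges the asymmetric process produces, but illustrative rather than
calibrated. Default synthetic genomes are 3 kb (protein 60%, tRNA 6%,
rRNA 10%, D-loop 8%, remainder intergenic) with valid reading frames, one
H-strand protein gene mirroring MT-ND6, and the D-loop wrapping the origin;
3 kb keeps whole-genome pileup simulation and opportunity enumeration fast
while leaving hundreds of codons per gene. Cohorts draw variant sites
proportional to rate × opportunity; VAFs come from a fixed value, a uniform
range, or Wright–Fisher outcomes of single-copy mutants conditioned on
survival; pileups are Poisson-depth, binomial in VAF (scaled by 1 −
contamination), with uniform sequencing errors and binomial strand splits.
Not emulated: read-level artefacts (mapping bias, homopolymer slippage,
index hopping), quality-score structure beyond a single Q20 tally, NuMT
contamination, and linked multi-site haplotypes outside the dedicated
phasing generator. Passing tests therefore demonstrate the statistical
machinery under its stated model, not robustness to alignment pathology on
real data.

## Problem sizes

Monte-Carlo sizes in the test-suite and acceptance script — 10,000 replicates
for fixation fractions, 100,000 for fixation times, 100 cohorts for CI
coverage, ~5,000 variants for signature recovery, 10 kb × ~250k events for
stationary composition — were chosen so that each check's Monte-Carlo error
is several times smaller than its acceptance band.

## Known limitations

No read alignment or BAM processing: the filter chain starts from allele
counts. The 192-rate selection model needs enough synonymous mass per class
to be identifiable on small cohorts; the 12-rate model is the default for
per-gene fits. The recurrence null treats samples as exchangeable and
ignores per-sample mutation-count heterogeneity. The drift model is neutral
by construction — selection on heteroplasmy is detected downstream through
VAF contrasts, not modelled forward.
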