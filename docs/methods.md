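# Methods

This note documents the models, estimators, numerical choices and known
limitations of `sealmhc`, and what the synthetic-data generator does and
does not emulate.

## The analysis problem

A classical MHC class II locus (DQB exon 2, 267 bp, 89 codons) is genotyped
in mother–pup pairs from two breeding colonies by cloning PCR amplicons and
Sanger-sequencing individual clones. Because each clone is one molecule,
the data contain PCR/sequencing artifacts and stochastic allelic dropout,
and the analysis has to (i) separate true alleles from artifacts, (ii)
validate the locus model (1–2 alleles per individual, Mendelian
transmission), and (iii) relate MHC variation to selection and to the
genomic background measured by microsatellites.

## Allele calling

Clones are grouped by exact sequence. A variant is discarded as a putative
artifact iff its total count is ≤ `max_artifact_count` (default 2), a
doubleton additionally occurs within a single individual, and it lies within
`max_nt_diff` (default 2) substitutions of a strictly more common *retained*
sequence. Comparison proceeds from most to least common so artifact chains
collapse onto their source allele. Low-count variants with no near
neighbour are retained but flagged as possible rare alleles. Alleles must
be carried by ≥ `min_individuals` (default 2); `min_clones` defaults to 1
because a minimum clone count is an observed property of real catalogs, not
a rule. Names are assigned in descending clone support (ties broken by
sequence) as `ArGa-DQB*01`, `ArGa-DQB*02`, ….

Genotypes are the catalog alleles observed among an individual's retained
clones. Individuals supporting > 2 alleles are retained but flagged; they
are excluded from diploid statistics (FST, heterozygosities, the GLM) and
included where only allele presence matters (detection curves, Mendelian
reporting). A mother–pup pair is Mendelian-compatible iff the allele sets
intersect. With finite clone libraries a heterozygote's second allele is
missed with probability 2^−k for k clones, so a few incompatible pairs are
expected even with perfect pedigrees — amplification bias makes this worse,
which the simulator reproduces (compatibility is non-increasing in the bias
strength).

## Selection tests

Codons are attributed to regions whole: the default partition ships the 24
class II β-chain antigen-contact positions quoted from the human structure
(9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65, 67, 68, 70, 71,
74, 78, 81, 82, 85) as data, overridable per analysis; homology of these
positions beyond humans is hypothetical.

Mean pairwise amino-acid divergence is the p-distance restricted to a codon
subset, averaged over all unordered sequence pairs; its SE is a bootstrap
over codon columns (999 replicates). A Poisson correction (−ln(1−p)) is
available by flag. Region contrasts use a paired t-test over sequence
pairs; pairs are not independent, so this mirrors the common
(anticonservative) field practice rather than a strict exchangeability
argument.

dN/dS follows the modified Nei–Gojobori method: per codon, potential
synonymous/non-synonymous sites are counted with transitions weighted by the
transition/transversion ratio R (default 2.0, the common MEGA choice;
analyses of generator output use R = 1 because the simulated substitution
process is uniform); changes to stop codons count as non-synonymous and each
codon is normalised to 3 sites. Observed differences average the
synonymous/non-synonymous step counts over all minimal substitution
pathways, equally weighted, excluding pathways through stop codons (if all
are blocked, all are used). Proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3), undefined (NaN) for p ≥ 3/4; dN and dS are means
over pairs. The codon Z-test bootstraps codon columns within the tested
region: Z = (dN − dS)/√(Var_B(dN) + Var_B(dS)), one- or two-tailed normal
p. Site counts were cross-checked against an independent implementation
(Biopython's NG86 routines) and pathway counts against brute-force
enumeration.

Calibration caveat: when a small codon set happens to contain non-synonymous
but *zero* synonymous variable sites, Var_B(dS) = 0 and the Z-test rejects
essentially automatically, although the exact probability of such a
configuration under neutrality is not small. On 200 neutral generator pools
the one-tailed test at α = 0.05 rejects at ≈ 0.09 — the centre of Z is
calibrated (mean 0.04, sd 1.02) but this degenerate tail is
anticonservative. This is a property of the bootstrap codon Z-test itself;
users needing strict type-I control on few codons should prefer an exact
count-based test.

## Population genetics

FST is Weir–Cockerham (1984) θ: per locus and allele, variance components
a (among populations), b (among individuals within populations) and c
(within individuals) from allele frequencies, heterozygote frequencies and
sample sizes; the multi-locus estimate is Σa / Σ(a+b+c) (ratio of sums).
θ of duplicated populations is not exactly 0: with zero among-population
variance the estimator retains its O(1/n) small-sample term (slightly
negative); tests assert this faithful behaviour. Significance comes from
permuting individuals' colony labels, p = (1 + #{θ* ≥ θ}) / (n_perm + 1)
(the +1 avoids p = 0; the study design's default is 9999 permutations, the
acceptance script uses 999 to keep a full run fast). The permutation test
assumes exchangeable individuals; with families (mother–pup pairs) nested
inside colonies it is anticonservative, so calibration checks use
unrelated/i.i.d. genotypes.

Diversity per colony: private alleles; allelic richness rarefied to the
smallest per-colony, per-locus gene count via the hypergeometric formula
Σ_a [1 − C(N−N_a, g)/C(N, g)]; H_o; unbiased H_e = 2n/(2n−1)·(1−Σp²);
F_is = 1 − H_o/H_e (undefined when H_e = 0).

Queller–Goodnight relatedness uses reference allele frequencies computed
over all individuals (focal pair included — configurable); locus numerators
and denominators are summed before dividing and the two directional
estimates averaged. In-sample frequencies give the estimator a small
downward bias of order −2/N, visible in small simulations and negligible at
the study scale. sMLH_i is the proportion of typed loci heterozygous in i
divided by the mean (over i's typed loci) of those loci's mean observed
heterozygosity; with complete data its population mean is exactly 1.

## Allele tree, UniFrac and association models

The allele tree is Saitou–Nei neighbour joining on nucleotide p-distances;
negative branch-length estimates are clamped to 0. Unweighted UniFrac
between two allele sets A, B follows the standard rooted definition at the
NJ tree's (arbitrary trifurcating) root: branch length below which exactly
one of the sets occurs, divided by branch length below which either occurs.
This is 0 iff the sets coincide and 1 for disjoint singletons, and it gives
sensible intermediate values for nested sets (a homozygote vs a heterozygote
sharing its allele), which a purely bipartition-based "separates both sets"
attribution would not — the latter scores every nested pair as maximally
distant, so it was rejected. A `unit_lengths` flag substitutes topological
(unit) branch lengths, since published analyses do not always state which
was used. The implementation is cross-checked against scikit-bio's
`unweighted_unifrac`.

UniFrac ~ relatedness is fitted as a linear mixed model over unordered
pairs (each pair once) with one multi-membership random intercept spanning
both member identities (a single variance shared by the two identity design
blocks), via REML. The fixed effect is tested as F = t² with denominator
df = n_pairs − 2; mixed-model df conventions vary and this matches the
reported df shape of pairwise designs. MHC heterozygosity ~ sMLH is a
binomial GLM; the package reports the likelihood-ratio χ² for the slope and
the residual deviance with its df (n − 2), the statistic that pairwise
χ²_{1,n−2} notations refer to. A constant response or constant predictor is
flagged (separation / inestimable) and no test is run.

## Primer bias and detection curves

Primer mismatches are Hamming distances on the exon sense strand: forward
primer compared directly, reverse primer reverse-complemented first, at
fixed binding-site coordinates when configured, otherwise at each primer's
minimum-Hamming window; the default combination is the sum over both sites
("max" available by flag, since a per-primer maximum is another plausible
reading). The repository ships a clearly-labelled synthetic placeholder
primer pair (two exact windows of the synthetic founder exon spanning a
141 bp product) for tests and examples; real analyses must supply the
assay's primers as configuration.

Detection curves resample whole genotypes (the individual is the sampling
unit; flagged individuals contribute all their alleles) with replacement,
n from 1 to the number of genotyped individuals, 999 replicates by default
(199 in the acceptance script), counting distinct alleles whose mismatch
load is ≤ the threshold; the spread reported is the bootstrap standard
deviation across replicates. Curves are exactly monotone in the threshold
for a fixed seed because draws are shared across thresholds.

## The synthetic-data generator

The generator emulates the study conditions: 19 alleles, two colonies of 14
mothers each with one pup (56 individuals, 28 scoreable pairs), clone counts
uniform on 7–32, a 10% per-clone artifact probability, and 41 transmitted
microsatellite loci. Allele frequencies default to equifrequent (the real
frequency spectrum is not published as numbers); any vector can be supplied.

Allele pools use a site model rather than a genealogy: 34 variable
nucleotide sites (the study's count) are placed on a fixed synthetic founder
exon, and each allele draws one of two states per site with probability 1/2,
mimicking ancient balanced polymorphisms at intermediate frequency — this
reproduces the high pairwise divergence concentrated at few sites that
star-like mutation schemes cannot. Placement favours the pABS by the
`pabs_nonsyn_multiplier` m: pABS codons are accepted m-fold more often, and
the change type is forced with probability 1 − 1/m (non-synonymous at pABS,
synonymous — purifying — elsewhere). At m = 1 placement is exactly uniform
among stop-free changes, which is the null used for type-I calibration; at
the default m = 5 about 85% of amino-acid-variable codons are pABS. All
state combinations within a codon are verified stop-free, so every allele
translates.

Mothers are two independent draws from the allele frequencies (HWE); each
pup receives one uniformly chosen maternal allele and one paternal allele
drawn from the frequencies (fathers are not simulated as individuals; only
maternal links are analysed). Clone templates are drawn from the
individual's two alleles with weights exp(−β·mismatches) when primers are
supplied; artifacts receive 1–2 substitutions at uniform positions with
uniform base choice. Microsatellite founders are i.i.d. multinomial per
locus (4–10 alleles, Dirichlet(1) frequencies) with one maternal allele
transmitted per locus.

Not emulated: chimeric PCR artifacts, coalescent-realistic genealogies,
microsatellite mutation, colony-specific allele frequencies, missing data,
and genotyping error in the microsatellites. Passing tests therefore show
the estimators are correct and well calibrated under clean HWE-with-
transmission structure, not that they are robust to those real-data
complications.

A quantitative consequence of the artifact model worth knowing: two clones
in *different* individuals can independently acquire the same single
substitution on the same template (probability ≈ 4·10⁻² per library at the
default rates), producing a cross-individual doubleton that is
indistinguishable from a rare real allele and is — correctly, per the
filtering rule — called. Parameter-recovery tests therefore score a library
as perfect when the catalog equals the set of alleles carried by ≥ 2
sampled individuals, and such collisions are the dominant (rare) failure
mode.

## Problem sizes used by the test suite and acceptance script

Simulation-heavy checks use 25–200 seeds at the scales stated in each test
(56 individuals for calling recovery and the GLM, 200 mother–pup pairs for
relatedness, 19-allele pools for the Z-tests, 30-individual single-locus
tables for permutation calibration); the mixed-model recovery checks use 20
individuals × 25 seeds. The acceptance script runs one full study-scale
dataset with 999 FST permutations and 199 detection-curve replicates.
These sizes are the package's own choices balancing statistical resolution
against a quick default run.
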