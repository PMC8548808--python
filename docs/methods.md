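# Methods

`paraploid` addresses a recurring problem in the population genomics of
replicated ecotypes: when highland/lowland (or lake/stream, dwarf/normal, ...)
phenotype pairs appear in parallel across drainages, the underlying history may
be (a) parallel selection on shared standing variation, (b) recurrent *de
novo* adaptation from independent mutations, (c) divergence in isolation
followed by secondary contact and genome-wide homogenization, or (d) a single
origin spread between drainages by adaptive introgression.  All four produce
superficially similar "islands of divergence"; the package implements the
statistics that tease them apart for mixed-ploidy, reduced-representation SNP
data, plus a synthetic-data generator that realises all four histories with
known ground truth.

## Synthetic data (simdata)

**Demography.**  Populations sit on a two-level tree of drainages × ecotypes
(default two drainages, highland/lowland, plus an outgroup).  Drift on each
branch is a Balding–Nichols pulse: the child frequency is Beta-distributed
with mean `p` (the parent frequency) and variance `F·p(1−p)`.  This was chosen
over an explicit Wright–Fisher chain because the first two moments are in
closed form, which gives the generator a directly testable oracle
(`Var = F·p(1−p)` is asserted by Monte-Carlo in the test suite).  Branch order
encodes the history: drainage-first for scenarios (a), (b), (d); ecotype-first
for (c).  The outgroup is one basal pulse with `F = 2·F_eco`.

**Defaults** (chosen once, as a plausible ddRAD study of the kind the package
targets): 5000 unlinked bi-allelic loci, 5% under divergent selection,
`F_eco = F_drainage = 0.1`, `F_terminal = 0.05`, admixture `m = 0.5`, selected
alleles driven to `sel_shift = 0.95`, 8 individuals per population, tetraploid,
negative-binomial depth with mean 25 and dispersion 5, per-read miscall rate
1e-3.  Neutral ancestral frequencies are Uniform(0.05, 0.95); ancestral
frequencies of selected loci are Uniform(0.05, 0.15) — an adaptive allele is
rare before selection acts, and in scenario (a) "standing variation" means
precisely a shared low-frequency ancestral variant.  Frequencies are clamped
to [0.001, 0.999] before sampling so loci stay informative at small n.

**Selection and contact.**
*Standing variation*: one shared locus set; every drainage's highland
population is driven to `sel_shift`.
*De novo*: disjoint locus sets per drainage, each driven only in its own
highland population.
*Secondary contact*: the highland **ecotype ancestor** is driven to
`sel_shift` before the drainage split (the ecotype difference evolved under
selection before contact); on contact each highland population receives a
fraction `m` of its frequencies from its drainage's lowland partner at neutral
loci only — selection constrains introgression at the adaptive loci.  Gene
flow is directional (lowland into highland): lowland fish dispersing upstream
and hybridizing into the resident highland form is the natural reading of
elevational secondary contact, and a symmetric simultaneous exchange at
`m = 0.5` would make the pair literally identical, leaving no admixture signal
for any statistic to detect.
*Adaptive introgression*: the donor drainage's highland population is driven
to `sel_shift` and the recipient's highland population receives the selected
loci with weight `m` (`p′ = (1−m)p_self + m·p_donor`; `m = 1` is a full copy),
so the admixture fraction is a recoverable parameter.

**Reads.**  Dosages are Binomial(k, p) (autopolyploid Hardy–Weinberg), total
depth is negative-binomial, and alternate read counts are
Binomial(depth, `f(1−e) + (1−f)e`) with `f = dosage/k`.  The error model is a
single symmetric per-read miscall rate; there is no overdispersion, reference
bias, allelic drop-out, linkage, or ohnolog divergence.  Consequently the
tests demonstrate that the *statistical machinery* behaves as designed under
its own model assumptions — they do not show robustness to the mapping
artefacts and paralogy of real ddRAD data (the Hind/He filter exists exactly
because real data contain such loci).

## Ploidy inference (ploidy)

At a heterozygous site of a ploidy-`k` individual, the alternate-read fraction
concentrates near dosage/k, so the allele-balance spectrum is unimodal at 0.5
for diploids, bimodal at 1/3, 2/3 for triploids, trimodal at 1/4, 1/2, 3/4 for
tetraploids.  Sites are retained when depth ≥ 10 and both alleles have ≥ 3
reads (declared defaults).  For each candidate `k` we fit by EM a Gaussian
mixture with means fixed at `i/k`, one shared variance (floor 1e-4;
per-component variances are unstable at small site counts), free weights, and
one Uniform(0,1) "noise" component that absorbs mis-mapped and paralogous
sites.  A single reference mixture with three *free* means (initialised at
data quantiles) provides `logL_free`.

Candidates are ranked by `logL_fixed(k) − logL_free − ½(k+1)·ln n`.  The
penalty counts the fixed model's fitted parameters (k−1 component weights,
noise weight, shared variance) and is essential: the tetraploid mean set
contains 0.5, so the unpenalised tetraploid fixed model is nested above the
diploid one and would never lose on likelihood alone.  A per-candidate free
model with matched component counts does not fix this — a single free-mean
Gaussian fits symmetric trimodal data no better than the fixed 0.5 component,
so the matched-count likelihood gap is blind to whether the extra modes are
*needed*.  Both the difference and the conventional printed ratio
`logL_fixed/logL_free` are reported for every model.  Calls are flagged
low-confidence when the top two penalized scores are within 2 log-units, fewer
than 50 sites survive filtering, or the winning fit puts ≥ 30% of its mass on
the noise component (the spectrum is then not a dosage mixture at all).

EM is deterministic (fixed initialisation: equal weights, variance 0.01,
noise weight 0.05), converges on ΔlogL < 1e-6 or 500 iterations, and its
log-likelihood trace is non-decreasing (asserted in tests).

## Genotyping and filtering (genotyping)

Population allele frequencies are estimated by EM: frequency → Binomial(k, q)
dosage prior → per-individual posteriors → frequency = mean posterior dosage
over ploidy, iterated to Δq < 1e-6.  Genotype posteriors are
`P(g|reads) ∝ Binomial(alt | depth, f_g) · Binomial(g | k, q)`; the MAP dosage
is stored with the full posterior, and zero-depth cells are missing.  Each
population is genotyped under its own frequency prior.

Hind/He per individual and locus is `2·r·a / (n(n−1))` (the probability two
reads drawn without replacement differ), divided by the population gene
diversity computed from **pooled read proportions** — not from called
genotypes, which would make the filter circular with the caller.  Its
Mendelian expectation is `(k−1)/k`; thresholds for "diploid-consistent" and
"tetraploid-consistent" loci are the 95% quantiles of Hind/He simulated for
well-behaved loci under the observed sample size and depth distribution.
Thresholds are inclusive upper bounds; loci above the tetraploid threshold are
discarded as likely paralog collapses.  Coverage filtering requires more than
50% of individuals genotyped and mean depth (over genotyped individuals) of at
least 20; the minor-allele-frequency filter is strict (> 0.05).

## Differentiation statistics (popstats)

All statistics are functions of allele frequencies only, hence valid across
ploidies without heterozygosity corrections: `Hs = 1 − Σp²`; Nei's
`G_ST = (Ht − mean Hs)/Ht` with `Ht` the diversity of the mean frequency;
Jost's `D = [(Ht − Hs)/(1 − Hs)]·[n/(n−1)]`; per-SNP
`D_XY = p₁(1−p₂) + (1−p₁)p₂`, averaged arithmetically across loci.
Frequencies come from MAP dosages by default (deterministic); note that for
two demes drifted independently with intensity `F`, `E[G_ST] = F/(2−F)`, so
parameter recovery goes through the closed-form inversion
`F = n·G_ST/(n−1+G_ST)` (`drift_from_gst`), and multi-locus G_ST is the
ratio-of-means form (averaging per-locus ratios is downward-biased).

## Admixture statistics (dstats)

Patterson's D uses the frequency formulation
`ABBA = (1−p₁)p₂p₃(1−p₄)`, `BABA = p₁(1−p₂)p₃(1−p₄)`,
`D = Σ(ABBA−BABA)/Σ(ABBA+BABA)` for the assumed topology (((P1,P2),P3),O).
f4(A,B;C,D) is the across-locus mean of `(p_A−p_B)(p_C−p_D)`; the admixture
fraction of a recipient X = m·B + (1−m)·Y is estimated as
`f4(B,A; X,C) / f4(B,A; B,C)` with C a sister of Y — on the synthetic data,
`f4(hX,lX; hY,lY) / f4(hX,lX; hX,lY)` recovers `m` on the introgressed locus
subset.  Standard errors come from a delete-one block jackknife over 50
contiguous locus blocks; loci are unlinked in simulation, so contiguous index
blocks stand in for genomic blocks.

## Partitioned analysis and the decision matrix (partition)

Per drainage, loci are partitioned by within-drainage (highland vs lowland)
F_ST into bins [0, 0.25), [0.25, 0.5), [0.5, 0.75), [0.75, 1], and by the
ratio of within-drainage heterospecific D_XY to conspecific-highland
among-drainage D_XY (denominators below 1e-6 excluded — near-zero conspecific
distances make the ratio unstable).  Each populated partition (≥ 25 loci) gets
a neighbor-joining tree on mean-D_XY distances (negative branch lengths
clamped to zero and flagged); its induced split over
{highland_X, lowland_X, highland_Y, lowland_Y} — read off patristic distances
by the four-point condition — is *drainage-grouped*, *species-grouped*
(ecotypes cluster), or *other* (ties included).

The decision matrix consumes three robust summaries:

1. **Shared ancestry at outlier loci.**  A top-bin species-grouped call counts
   only when corroborated: mean D_XY(highland_X, highland_Y) over the bin must
   be ≤ 0.75 × the within-drainage heterospecific D_XY over the same loci.
   Outlier loci are nearly monomorphic in the three unselected populations, so
   an uncorroborated quartet call there is long-branch noise.
2. **Genome-wide admixture.**  Patterson's D on the *neutral background*
   (loci in the lowest F_ST bin of both drainages) for the quartets
   (lowland_X, highland_X; lowland_Y, outgroup) and its mirror — a test of
   whether a lowland clade exists, which is exactly what a divergence-first
   history (with or without ongoing flow) implies and what independent
   emergence excludes.  "Significant" means |Z| > 3 for either quartet
   (conservative, two tests).
3. **Outlier-set overlap.**  Jaccard similarity of the two drainages' top-bin
   locus sets; "disjoint" means < 0.1 with ≥ 5 loci each.

Rules, in order: shared ancestry + drainage-grouped background + significant
admixture → *secondary contact*; drainage-grouped background + disjoint
outliers + no shared ancestry → *de novo emergence*; shared ancestry without
an admixture signal → *standing variation or adaptive introgression*
(irreducibly confounded at unlinked-SNP resolution: a parallel sweep of a
shared standing variant and an introgressed copy of the same allele produce
identical frequency patterns; only linked flanking haplotypes would separate
them, and the generator has no linkage); anything else → *inconclusive*.

## Problem sizes and what the batteries show

The evaluation module runs: ploidy recovery over individuals with 2000
heterozygous sites at 30× (the test suite uses 100 replicates of 20
individuals per ploidy; the acceptance script 30 replicates); Hind/He
calibration at n = 100, depth 50, 2000 loci; dosage accuracy at depth 200;
D-statistic type-I over 100 neutral replicates of 2000 loci (computed on true
simulated frequencies — the statistic's own input contract); and the
four-scenario classification battery end-to-end through read simulation and
Bayesian genotyping at 5000 loci, 5% selected, m = 0.5 (50 replicates per
scenario in the test suite, 25 in the acceptance script).  Under these
conditions scenario recovery is essentially perfect for (b) and (c), and (a)
and (d) land in their declared joint class; the species-grouped fraction of
partition trees rises monotonically across the four F_ST bins under secondary
contact.

## Known limitations

- No linkage: flanking-haplotype evidence, the one signal that could separate
  standing variation from adaptive introgression, cannot exist here.
- The generator's clean read model means filter behaviour on true paralogs is
  only exercised through the simulated thresholds, not through realistic
  collapsed loci.
- The classifier is defined for exactly two drainages with one ecotype pair
  each plus an outgroup; more drainages are simulated but not classified.
- Triploid support in ploidy selection assumes balanced trisomy; mosaic and
  sub-genome (ohnolog) structure are out of scope.
- Patterson's D calibration inherits drift-induced inflation at small deme
  sizes; the type-I rate is reported, not hidden, and the classifier uses a
  conservative |Z| > 3 cut.
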