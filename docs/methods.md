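# Methods

## The genotype-uniformity clock

**Model.** An obligately selfing population is treated as *N*<sub>e</sub>
independent lines; each line, each generation, at each of *l* SSR loci,
acquires a new allele destined for fixation with probability *μ*.  The
per-line rate comes from the half-fixation argument: a diploid line
produces new alleles at rate 2*μ*<sub>copy</sub> per locus, and a neutral
heterozygous mutation under selfing fixes with probability ½ (each selfed
generation resolves Aa to AA or aa with probability ¼ each, so the absorbed
state is equally likely to be either homozygote).  The effective rate thus
numerically equals the per-copy rate.  Uniformity then decays as
*P*<sub>i</sub>(t) = (1 − μ)^(l·t·Ne), and the clock reports the smallest
integer *t* with *P*<sub>i</sub> strictly below α.

**Assumptions.** Neutrality of SSR variation; independence across lines,
loci and generations; no outcrossing; mutation treated as always producing
a detectable new allele (size homoplasy ignored — conservative for the
clock, since homoplasy would only make uniformity easier to preserve, i.e.
the true threshold is no larger).  Equality *P*<sub>i</sub> = α is *not*
below threshold (strict inequality); with the defaults this yields
thresholds of 21, 101 and 202 generations for *N*<sub>e</sub> = 500, 100
and 50.

**Defaults.** μ = 4.96×10⁻⁵ (the lowest directly estimated *Arabidopsis
thaliana* dinucleotide-repeat rate; conservative — higher rates shorten the
window), *l* = 6 dinucleotide loci, α = 0.05,
generation time 5–10 years.  The empirical dinucleotide rate range
(5.0×10⁻⁵ – 2.0×10⁻³) is exposed as `MU_SENSITIVITY_RANGE` for scans.
*P*<sub>t</sub> and *P*<sub>i</sub> are computed in log space
(`exp(l·t·Ne·log1p(−μ))`) so that very large exponents cannot underflow.

## Forward simulator

Two modes, sharing a single seeded `numpy.random.Generator`:

- **effective** — the direct Monte-Carlo counterpart of the analytic model.
  Per replicate per generation the number of line×locus fixation events is
  drawn Binomial(*N*<sub>e</sub>·*l*, μ), which is distributionally
  identical to the per-channel Bernoulli draws and lets replicates be
  vectorised.
- **explicit** — each line is a diploid individual; every allele copy
  mutates at the per-copy rate (stepwise ±1 repeat unit with equal
  probability, or an infinite-alleles option in which every mutation is
  novel); each generation one surviving offspring is formed by random union
  of two gametes from the same parent.  Mutation counts are drawn
  Binomial(n_copies, μ) and placed uniformly at random (with replacement;
  the collision probability at these rates is negligible).  Back-mutation
  to the ancestral size is possible under the stepwise model; its effect on
  the uniformity curve at μ ≈ 5×10⁻⁵ is far below Monte-Carlo resolution.

A replicate counts as uniform at *t* if no line has deviated up to *t*
(deviation is sticky).  The default criterion, `fixed_only`, counts a line
as deviated only once a non-ancestral allele is homozygous, matching the
analytic model; `observed_genotype` also counts segregating heterozygotes.
Curve standard errors are per-generation binomial SEs over replicates.

The population-level simulator (`simulate_ssr_population`) is standard
Wright–Fisher with mixed mating: each offspring selfs with probability *s*,
otherwise unites gametes from two randomly drawn parents; founder events
restrict the parent pool to *k* random individuals for one generation.
Under *s* = 1 heterozygosity halves per generation; under *s* = 0 the
population sits at Hardy–Weinberg — both are test invariants.

## SSR statistics and trees

H_O is the fraction of fully genotyped individuals that are heterozygous;
H_E = 1 − Σp² (Nei's gene diversity) with the 2N/(2N−1) small-sample
correction available behind a flag (the plain form is the default since
the reported quantity is a population parameter, not an estimator
comparison).  Allelic richness uses Hurlbert rarefaction,
R_S = Σ<sub>i</sub> [1 − C(N−N<sub>i</sub>, g)/C(N, g)], defaulting g to
the smallest per-locus copy count in the group; the formula is tested
against brute-force enumeration of all subsamples.  F_IS = (H_E − H_O)/H_E
per locus, averaged over polymorphic loci (the variance-components
estimator of Weir–Cockerham is out of scope).  Missing genotypes are
excluded per locus; a complete-case filter is provided for panels scored
like the 18-locus SSR set.

Nei's D_A = 1 − (1/L) Σ<sub>loci</sub> Σ<sub>alleles</sub> √(x·y); loci
lacking data in either group are dropped with a warning and L adjusted.
Distance matrices can be built between populations, species, or individual
multilocus genotypes (each individual as its own frequency vector).
Neighbour joining is the Saitou–Nei algorithm with the standard
Q-criterion; a negative branch length at a join is clamped to zero with the
deficit moved to the sibling branch, preserving the joined pair's path
length.  On additive matrices the output path-length matrix equals the
input exactly (property-tested, and cross-checked against scikit-bio's
implementation).  Bootstrap support resamples loci with replacement and
reports bipartition frequencies.

## SNP pipeline

Genotypes are coded 0/1/2 with −1 missing, each SNP annotated with its
physical locus of origin and within-locus order.  The filtering cascade
applies, in a fixed order (the order matters for the per-rule counts and
is a package choice): (1) drop SNPs with observed heterozygosity ≥ 0.6
(collapsed-paralog signature); (2) drop SNPs whose minor allele — by
allele-copy count over the whole analysis set, ties resolved to the
alternate allele — is carried by fewer than 3 samples, counting a carrier
once whether heterozygous or homozygous; (3) drop SNPs called in less than
a proportion R of all samples; (4) optionally keep only the first SNP per
locus by within-locus position.  The report reconciles exactly
(removed + surviving = input) and the cascade is idempotent.

Polarization takes the majority allele of a designated ancestral
(chasmogamous) group as ancestral per SNP; exact 50/50 ties resolve to the
reference allele and are counted in the output, as are SNPs with no
ancestral-group calls.  Fixed differences require opposite monomorphism in
the two groups over called genotypes.  Per-site π uses the unbiased
pairwise form (n/(n−1))·2p(1−p).  The Evanno ΔK statistic is
|L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K)) with the sample sd (ddof = 1) over
runs, requiring ≥3 consecutive K and ≥2 runs each; sd = 0 yields a missing
value rather than an infinity.

## SNV syndrome metrics

Inputs are per-sample tables of heterozygous SNVs on an assembled
transcript set (lengths, synonymous/nonsynonymous class, and a signed
deleteriousness score for nonsynonymous variants).  A variant is
deleterious when |score| > 2.5, strictly — the absolute value because
ancestral and derived states cannot be distinguished at heterozygous
sites; the boundary case is counted as neutral and the strictness is
switchable.  Metrics: SNVs/kb of total transcript length, nonsynonymous
fraction of all SNVs, deleterious fraction (denominator excludes
nonsynonymous SNVs lacking a score, which are reported), deleterious/kb,
and the fraction of transcripts carrying ≥1 nonsynonymous SNV.  Sister
pairs are compared metric-wise by Student's equal-variance t-test (Welch
behind a flag); the degenerate all-equal case reports t = 0, p = 1.

## PGLS

The Brownian covariance of a rooted tree has C[i,j] equal to the
root-to-MRCA path length of tips i, j; non-ultrametric trees are accepted
as given.  Fitting whitens by the lower Cholesky factor of C and solves
ordinary least squares on the whitened system — never an explicit inverse;
matrices with 2-norm condition number above 10¹² are rejected.  Standard
errors use the residual variance on n − p degrees of freedom with
two-sided t tests.  With C = I the fit equals OLS to machine precision,
and because σ² is estimated from the residuals the overall scale of C is
absorbed entirely (coefficients, SEs and t all invariant).  Multiple
metrics are fitted independently with no multiple-testing correction,
which the output notes.

## Synthetic data generator

The generator emulates the sampling design of a sister-pair study of
complete cleistogamy; all defaults are fixed once as study conditions:

- **SSR scenario** — a chasmogamous population of census 250 evolving 400
  burn-in generations at selfing rate 0.95 (chasmogamous relatives of
  complete selfers show selfing-syndrome genetics, attributed to
  fly-mediated geitonogamy) from a 4-allele-per-locus founder pool; a
  cleistogamous lineage of census 50 founded from a single individual 10
  generations before sampling and propagated at s = 1; samples of 54 and 31
  individuals; an 18-locus panel with 6 dinucleotide loci at μ = 4.96×10⁻⁵
  and 12 slower loci at 10⁻⁵ (a motif-class contrast; the slower rate is a
  generator choice below the dinucleotide estimate).  The 10-generation
  founding sits at the young edge of plausible divergence times so that the
  defining observation — complete multilocus uniformity of the selfer — is
  reproduced with high probability per run.
- **SNP scenario** — 375 biallelic sites in groups of 3 per locus;
  ancestral frequencies uniform on (0.05, 0.95); the two daughter
  populations drift by binomial resampling of allele frequency for a
  configurable number of generations (250 vs 50 reproducing units);
  genotypes are drawn with the inbreeding coefficient implied by each
  selfing rate (F = s/(2−s)); 10% random dropout feeds the missingness
  filter, and 2% of sites are made near-obligate heterozygotes to mimic
  collapsed paralogs for the H_O filter.
- **Variant scenario** — per-transcript Poisson SNV counts at a configured
  per-kb density over gamma-distributed transcript lengths; effect class
  Bernoulli; nonsynonymous scores uniform on (−2.5, 0] (neutral class) or
  (−8, −2.5) (deleterious class) — arbitrary but threshold-respecting, so
  realized fractions match configuration in expectation.
- **PGLS scenario** — a birth–death tree (birth 1.0, death 0.2) with a
  uniform 0.1 tip extension (the sampler stops at a speciation event,
  leaving two zero-length tips that would make the covariance singular);
  traits are intercept + effect·selfing + MVN(0, σ²C) noise.

**What passing tests do not show about real data**: the generators contain
no genotyping error or allelic dropout beyond random missingness, no SSR
size homoplasy, no linkage beyond the locus-group labels, no selection,
migration or population structure within species, and variant tables with
independent Poisson sites.  Agreement here validates the statistical
machinery, not robustness to those artefacts.

## Problem sizes and numerics

Simulation-based checks use 20 000 replicates for uniformity curves
(binomial SE ≈ 0.0015 at P ≈ 0.05), 10⁵ replicates for the half-fixation
law (SE ≈ 0.0016), 200 replicates for PGLS coverage, and ≤8-taxon /
≤8-copy instances for exhaustive oracles — sizes at which the tested
tolerances (3 SE; 10⁻⁹ for tree additivity) are meaningful and the whole
suite runs in well under a minute of simulation time.  Determinism: every
stochastic routine takes an explicit integer seed and identical seeds give
bit-identical output.
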