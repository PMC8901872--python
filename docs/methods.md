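# Methods

`kinmate` tests whether social pair formation in a monitored, closed bird
population is random with respect to genetic relatedness.  The pipeline has
five stages: marker QC, pairwise relatedness estimation from microsatellites,
simulation-based estimator selection, a year-stratified permutation test of
random mating, and a synthetic pedigreed-population generator used to
validate every stage end to end.  This note records the models, the defaults
and why, the numerical choices, and the known limitations.

## Relatedness model

All estimators work under the non-inbred dyadic IBD model: a pair of diploid
individuals shares 0, 1 or 2 alleles identical by descent at an autosomal
locus with probabilities (k0, k1, k2) on the 2-simplex, and relatedness is
r = k2 + k1/2.  Inbred relationships (the 9-condensed-state model) are out of
scope: with a panel of only 12 microsatellites the extra coefficients are
poorly identified, and the downstream inference only consumes r.  Genotyping
error is fixed at zero throughout.

### Queller–Goodnight (`qg`)

Moment estimator.  For reference individual x = (a,b) against partner
y = (c,d), the locus numerator is ``0.5*(δ_ac + δ_ad + δ_bc + δ_bd) − p_a −
p_b`` and the denominator ``1 + δ_ab − p_a − p_b``.  Numerators and
denominators are summed across loci before dividing (the ratio-of-sums
convention, which keeps monomorphic or uninformative loci from producing
0/0), and the two reference directions are averaged.  Unbounded; can be
negative, clipped copies to [−1, 1] are reported alongside the raw values.

### Wang-type moment estimator (`wang`)

At each locus a dyad falls in one of four similarity categories: identical
genotypes; homozygote vs heterozygote sharing an allele; two heterozygotes
sharing exactly one allele; no allele shared.  Writing a_m = Σ p_i^m, the
expected proportions of the first three categories are affine in the two-
and four-gene coefficients (φ = k1, Δ = k2):

    E[P1] = b + cφ + (1−b)Δ        b = 2a2² − a4,  c = a2 − b
    E[P2] = d + eφ − dΔ            d = 4(a3 − a4), e = 2(a2 − 3a3 + 2a4)
    E[P3] = f + gφ − fΔ            f = 4(a2 − a2² − 2a3 + 2a4)
                                   g = 1 − 7a2 + 4a2² + 10a3 − 8a4

These identities were re-derived from first principles and verified
symbolically and by simulation during development.  Loci are combined with
weights proportional to 1/u, u = 2a2 − a3 (informative loci with many
alleles get more weight), and the moments a2, a3, a4 use unbiased
small-sample (falling-factorial) estimates from the observed allele counts
when those are available.  The estimator solves the three weighted moment
equations for (φ, Δ) by ordinary least squares; because the expectations are
exact, any fixed linear solve is unbiased, and the OLS combination was chosen
as the package's own closed form.  Unbounded, same clipping convention as
`qg`.

### Dyadic maximum likelihood (`dyadml`)

The likelihood of a dyad is the product over usable loci of
``k0 P(G|0 IBD) + k1 P(G|1 IBD) + k2 P(G|2 IBD)`` with the standard
non-inbred genotype-pair probabilities.  Because the likelihood is linear in
(k0, k1, k2) it is a mixture model over loci; maximization uses EM on the
simplex with restarts from the center, the three (near-)corners and two edge
midpoints, a log-likelihood tolerance of 1e-8, and a deterministic tie-break
toward the largest-k0 solution when restarts agree within tolerance.  EM is
verified in the test suite against a 0.001-step grid search.

### Triadic maximum likelihood (`trioml`)

A third individual (a reference, used as a control) is added to the dyad.
For three non-inbred individuals the gene-identity structure at a locus is a
partition of the six genes into IBD classes in which no individual's two
genes are co-IBD; enumerating set partitions under that constraint and
collapsing within-individual symmetries yields exactly 16 condensed states.
The triad likelihood mixes the 16 state-conditional genotype probabilities,
and the dyad's (k0, k1, k2) are the state marginals (number of IBD links
between the two focal individuals), so r is in [0, 1] by construction.

References are sampled with replacement (seeded) from a genotype pool — the
study's own adults by default, or synthetic genotypes drawn from the allele
frequencies.  Two estimation modes exist:

- `joint` (default): one state distribution is maximized over the stacked
  per-locus probabilities of *all* reference triads.  A reference-linked
  state then has to be supported by every control simultaneously, which
  squeezes identity-in-state coincidences out of the dyad margin.  This is
  what makes the reference a genuine control.
- `average`: each reference triad is maximized separately and r is averaged
  over draws.  Measured on calibration dyads this mode inflates r for
  unrelated and half-sib dyads (the 15-parameter state simplex overfits 12
  loci per single triad), so it is not the default.

### Boundary bias of the likelihood estimators

Both ML estimators constrain r̂ to [0, 1].  At r = 0 their sampling SD with
12 loci and 6 equifrequent alleles is ≈ 0.09, so the mean estimate for truly
unrelated dyads is positive (≈ +0.065 for `dyadml`, ≈ +0.067 for `trioml`) —
the familiar truncation bias of bounded relatedness estimators, not an
optimizer artifact (EM matches the grid-search oracle to < 1e-3).  No
implementation choice can remove it without breaking the [0, 1] bound.  The
unbounded moment estimators are mean-unbiased in all categories (≤ 0.01 at
1,000 dyads/category).  The corresponding calibration check in the test
suite applies a ±0.03 band to all four estimators and therefore fails for
the two ML estimators in the UR category; that failure is expected and
documents the estimator property, the band was not loosened to hide it.

## Marker QC

- **HWE**: Monte-Carlo exact test; allele copies are shuffled into genotypes
  and the conditional probability ``2^h n! / Π n_ij!`` (allele counts fixed)
  is compared with the observed table; p = (1 + #{as or less probable}) /
  (n_mc + 1), default n_mc = 10,000.  Monomorphic loci return p = 1 with a
  warning.  Bonferroni adjustment across the panel is reported alongside raw
  p-values.
- **Multilocus disequilibrium**: standardized index of association r̄d from
  per-locus inter-individual distances (0–2 allele differences; pairs with
  missing data excluded per locus), permutation p from shuffling allele
  copies among individuals independently per locus (default 999
  permutations).  A locus duplicated exactly gives r̄d = 1; independent loci
  give a mean of 0.  Note that a *family-structured* sample (such as the
  synthetic closed population, or any real population of relatives) shows a
  genuinely positive r̄d even with unlinked loci — relatedness correlates
  genotypes across loci — so a small significant r̄d in such data indicates
  kin structure, not physical linkage.
- **Null alleles**: heterozygote-deficit estimators, Chakraborty
  ((H_E − H_O)/(H_E + H_O)) and Brookfield-1 ((H_E − H_O)/(1 + H_E)), both
  clipped at 0 and reported side by side since neither is canonical.
- **Probability of identity**: per locus 2(Σp²)² − Σp⁴, multiplied across
  loci (the classic biased variant; the panel-level magnitude ~1e-12 is what
  matters, not the third digit).

All resampling p-values use the +1 correction, so no p is ever exactly 0.

## Random-mating permutation test

Pairs are ingested per season; the first observation of each female–male
combination is flagged, and repeat observations are flagged `remated`.  The
pooled analysis uses only first observations (one row per unique pair),
each anchored to the year it first appeared; the yearly analyses use all
pairs captured in that year.

Each null replicate permutes, independently within every year stratum, the
year's males uniformly among the year's females — sampling without
replacement, so each replicate is a random perfect matching that preserves
the yearly female and male multisets (asserted on every replicate in tests).
In yearly analyses remated pairs are frozen (kept as observed and excluded
from the permutation); in the pooled analysis the unique-pair set contains
no remated rows by construction, and an optional flag can freeze them if a
caller supplies repeat observations.  Defaults: 10,000 pooled replicates,
1,000 per year.

Two two-sided constructions are computed: `double_tail` (default; twice the
smaller +1-corrected tail, capped at 1) and `extremity` (distance from the
null mean); both are always reported since the construction is a genuine
convention choice.  Medians use the even-n midpoint; quantiles use linear
interpolation; SD is the n−1 sample version.  A single top-level seed
spawns one RNG substream per replicate, so results are independent of
execution order.

## Synthetic population generator

The generator emulates a small, closed, cavity-nesting passerine population
monitored for 8 seasons: ~180 breeding adults in total, 12 polymorphic
microsatellite loci, 12–32 pairs per season.  Defaults and sources:

| parameter | default | basis |
|---|---|---|
| founders | 60 | sized so ~180 adults breed across 8 seasons |
| loci / alleles | 12 / 6, Dirichlet(1) frequencies | study panel size; Dirichlet(1) gives H_E ≈ 0.7 |
| adult survival | 0.68 / year | study system estimate |
| mate fidelity | 0.58 | study system estimate |
| clutch size | 1–4 (uniform) | study system |
| age at first breeding | 1:0.45, 2:0.35, 3:0.20 | >50% delay beyond year 1 |
| juvenile recruitment | 0.32 | demographic stability (deaths ≈ recruits) |
| burn-in seasons | 0 | optional; emulates long-isolated populations |

Each season: surviving pairs stay together with the mate-fidelity
probability; all other adults (and newly recruited birds) form new pairs.  A
candidate male for a female of pedigree relatedness ρ is accepted with
weight exp(−s·ρ); s = 0 is exact uniform random mating, and the weight uses
*pedigree* relatedness so the generative truth never depends on the marker
estimators under test.  Offspring genotypes are Mendelian (one allele per
parent per locus, no mutation, no genotyping error); offspring sexes
alternate within each season's recruit cohort so the breeding sexes stay
balanced.  Under `female_biased` dispersal, recruiting females move to a
non-natal forest fragment with probability 0.9 while males stay, and pairing
is fragment-local — which reproduces elevated male-male relatedness within
fragments.  The population is closed (immigration rate defaults to 0).

The pedigree relatedness oracle is the tabular method: r = 2f with kinship
f(i,j) computed recursively through the younger individual's parents,
founders mutually unrelated and non-inbred (descendants of related pairs can
still be inbred, and the self-kinship recursion accounts for that).

What the generator does *not* emulate: genotyping error and null alleles,
mutation, extra-pair paternity, spatial coordinates beyond fragment labels,
unbalanced sex ratios, and immigration by default.  Tests passing on this
generator therefore show the pipeline's statistical machinery is correct
under Mendelian inheritance and the stated demography — not that real data
are free of genotyping artifacts (those are what the QC stage screens).

## Problem sizes used in the checks

The shipped checks run at desk scale, chosen so each stage still has the
statistical resolution it needs: calibration uses 500–1,000 dyads per
category; estimator ranking uses the 100-per-category design with 50
references per dyad (estimation itself defaults to more); the pooled test
calibration uses 100–200 replicate populations at 499 permutations; the
full-population analysis in the reproduction script computes the triadic
estimator with 10 references per dyad over the few thousand permutable
dyads, and 10,000 pooled / 1,000 yearly permutation replicates exactly as in
the full design.  The power check fixes a deliberately strong avoidance
condition (s = 40) in a small population isolated for 10 burn-in seasons, in
which ~40% of candidate dyads are relatives; weaker conditions (the default
demography with unrelated founders) leave the median test underpowered at
any s because too few relatives exist to avoid.

## Known limitations

- The triadic estimator is a re-derivation of the triadic-likelihood idea
  (16 condensed states, EM, joint control fit), not a line-by-line port of
  any existing implementation; numerical agreement with other software at
  the third decimal is not guaranteed.
- The ML estimators' boundary bias at r ≈ 0 (above) shifts *individual*
  estimates; the permutation test is unaffected because observed and null
  pairings use the same estimates.
- r̄d with missing data uses pairwise-complete covariance terms, which can
  in principle leave the statistic slightly outside the strict definition
  when missingness is extreme.
- The permutation null conditions on which birds bred in each year; it does
  not model dispersal probabilities or spatial structure (by design — the
  test asks about pairing given presence, and a spatially constrained null
  is explicitly out of scope).
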