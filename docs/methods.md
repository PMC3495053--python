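# Methods

`xlinkmeta` re-creates, as a tested pipeline, the analysis style used by
multi-site linkage consortia for X-linked prostate-cancer susceptibility:
each site computes per-family multipoint linkage curves on a shared
consensus marker map, and a coordinating centre combines the family-level
statistics into heterogeneity LODs and allele-sharing LODs over predefined
family subsets. Because consortium pedigree data of this kind are not
public, the package ships a cohort simulator with the same statistical
structure, and every stage is validated against exhaustive-enumeration
oracles and parameter-recovery studies on simulated cohorts.

## Consensus map

Markers are ordered by physical position (UCSC Goldenpath hg13 bp) and
carry deCode genetic-map positions where available. Markers absent from
the reference map receive a position by linear interpolation in bp between
the nearest flanking reference-mapped markers, using `bp_start` as the
abscissa; interpolated values are kept at full precision and rounded
half-up to 2 decimals for display, which reproduces the published
positions of the bundled 40-marker Xq panel for the genome-wide-screening
(GWS) markers. One fine-mapping marker (DXS1232) was published with a
position that bp-linear interpolation between its flanking anchors does
not reproduce (144.25 vs ~144.75); the bundled loader keeps the published
value as-is and the map builder documents the recomputed one. Two other
fine-mapping markers differ from the published table by 0.01 cM at the
rounding boundary.

Sites that lack the first or last consensus marker receive a dummy
non-informative anchor marker (a single allele at frequency 1) at the
terminal position, so that every site's curves span the identical 1-cM
evaluation grid. Dummy markers provably contribute no linkage information
(tested to 1e-9).

Centimorgan coordinates are treated as female-meiosis distances: on the
non-pseudoautosomal X only maternal meioses recombine, so the map the HMM
consumes is the female map. The Haldane map function (no interference)
converts distances to recombination fractions.

## Per-family engine

The engine is the inheritance-vector HMM restricted to the X chromosome: a
son receives a single maternal recombinant X and no paternal X; a daughter
receives her father's X unchanged plus a maternal recombinant. Each
non-founder therefore contributes exactly one inheritance bit (its
maternal meiosis), giving 2^b states for b non-founders; a guard rejects
families beyond 2^20 states. Transitions flip each bit independently with
the Haldane probability of the inter-position distance; emissions sum
founder-allele assignments over the phase choices of unphased female
genotypes at site-specific allele frequencies (estimated by direct allele
counting, men one allele and women two, ignoring relatedness — the
consortium convention). Posteriors come from a normalized
forward–backward pass over the merged marker/grid positions.

The parametric LOD uses a dominant, X-linked, sex-limited (female
penetrance zero), two-liability-class, affecteds-only model: phenotype-
unknown individuals contribute 1, and only affected men's penetrances
enter. The default parameters are a rare risk allele q = 0.003 with an
early-onset class (onset < 65: carrier 0.90, phenocopy 0.02) and a
late-onset class (0.60, 0.07); all are overridable, and no validation
result in this package depends on these particular numbers. Two founder
models are available for the linked hypothesis:

* `population` (default): founder X alleles carry the risk allele i.i.d.
  at frequency q — the classic admixture parametrization;
* `segregating`: exactly one risk allele, uniform over the X-haplotype
  slots of the founder woman whose X can reach the most men in the
  pedigree. This is the correctly specified hypothesis for cohorts (such
  as the bundled simulator's) in which every linked family carries a
  mutation introduced through a female ancestor, and is what the
  parameter-recovery studies use.

The likelihood `P(phenotypes | v)` factorizes over founder slots in the
population model and over the carrier slot in the segregating model; the
LOD at position x is `log10 E[P(ph|v) | markers, x] − log10 E[P(ph|v)]`
with the second expectation over the uniform inheritance distribution.

Allele sharing uses the Whittemore–Halpern scores over the affected men's
X alleles (males contribute their single maternal allele), with both the
`pairs` and the `all` scoring functions (default `all`; the two coincide
for families with two affecteds). Scores are standardized exactly against
the uniform inheritance distribution; families with zero score variance
(e.g. a single affected) are flagged uninformative and contribute a flat
zero curve.

Both statistics are validated position-by-position, to 1e-9 LOD units,
against brute-force enumeration over joint inheritance-vector sequences
and founder genotype assignments on nuclear and three-generation test
families.

## Meta-combination

The heterogeneity LOD maximizes `sum_i log10(a·10^lod_i + 1−a)` over the
admixture proportion a in [0,1]; the Kong–Cox allele-sharing LOD maximizes
`sum_i log10(1 + d·g·Zbar_i)` over d ≥ 0 with equal weights g = 1/sqrt(m)
over the m informative families, d capped at the positivity boundary
(hard ceiling 4, configurable). Both objectives are concave, so a light
coarse grid plus bounded scalar refinement finds the maximum; solver
values are tested against 0.001-step grid search to 1e-4. Peaks are
reported at grid resolution with ties broken toward the smaller cM
position, and support intervals as the widest contiguous span within
`drop` (default 2) LOD units of the peak.

### Estimating the linked proportion under ascertainment

The admixture maximizer `alpha_hat` of the markers-only HLOD is *not* a
consistent estimator of the fraction of linked families when families are
ascertained for multiple cases: ascertainment makes the true mixture
weight vary with the affection pattern, while the admixture model holds it
constant, and the estimate inflates toward 1 (we observe 0.75–1.0 at a
true fraction 0.5). The package therefore also provides a full-likelihood
admixture: each family curve can carry a position-independent phenotype
log10 likelihood ratio (linked vs unlinked, with survival factors
`1 − lifetime risk` for men not recorded affected), and `hlod_full`
maximizes `sum_i log10(a·10^(lod_i + rho_i − gamma) + 1−a)`, where `gamma`
is one design constant — log10 of the ratio of marginal multiple-case
ascertainment probabilities (linked over unlinked) under the cohort's
family-structure distribution, computed by Monte Carlo from the simulator
configuration. With the generator-matched penetrance model this estimator
recovers the generating linked fraction (mean within 0.05 of 0.5 in the
acceptance study); it requires the liability classes to be parametrized
as joint affected-and-class rates, for which a helper derives the matched
model from the simulator config. Treating non-affected men as unaffected
is exact for simulated cohorts and an approximation where affection is
censored.

## Family stratification

Families are labelled by the Carter criteria (three consecutive affected
generations on a line of descent; an affected individual with at least two
affected first-degree relatives; two or more affecteds with onset ≤ 55),
by consistency with X-linked transmission, by mean onset age of affected
men (< 65), and by affected-count bins 2–3 / 4–5 / 6+. Transmission
consistency is structural: an affected father–son pair, an affected
paternal uncle or paternal grandfather, or a bilineal affected man (pure
maternal-side and pure paternal-side affected relatives simultaneously)
makes a family inconsistent; exclusively maternal-side evidence makes it
consistent; bare sibships and paternal evidence short of the explicit
triggers are unclear. Side assignment uses ancestor lines — a relative
(with their ancestors) touching only the mother's ancestor line is
maternal — which correctly treats relatives reached through a full
sibling (nephews, descendants) as side-uninformative; an earlier
path-based formulation leaked through sibships and was replaced. The nine
size-by-transmission cells partition every cohort; families with fewer
than two confirmed affected men are excluded with a warning.

## Cohort simulator

The simulator emulates a multi-site collection of multiple-case prostate
cancer families segregating an X-linked dominant risk allele under locus
heterogeneity. Four structural templates (weights 0.45 / 0.20 / 0.20 /
0.15 by default) cover nuclear sibships of 3–6 sons, a paternal
three-generation line, an extended maternal branch (grandmother with 1–2
affected-eligible uncles and 1–2 daughters and their sibships, capped at
nine maternal meioses), and bare sibships whose parents are never
genotyped. A family is linked with probability `linked_fraction`; linked
families carry exactly one risk allele planted on one X haplotype of the
template's connecting founder woman and dropped jointly with the markers
(Haldane recombination on maternal meioses only); unlinked families carry
no risk allele. Carrier men are affected with probability 0.75 and
non-carriers 0.045 (the class means of the default penetrance model);
affected men draw onset ages from truncated normals (carrier mean 62,
phenocopy mean 70, SD 7, range 40–90) and the liability class is onset <
65. Ascertainment is rejection sampling on at least two affected men; for
unlinked families affection is independent of the genotypes, so the
phenotype pattern is rejected before the gene drop (an exact shortcut).
Markers carry 6–10 alleles with Dirichlet(1) frequencies drawn per
cohort; eleven default site panels thin the GWS panel to ~75% with some
sites missing a terminal marker; observed calls are masked independently
at the missing rate (default 5%).

What the simulator does not emulate: linkage disequilibrium between
markers (linkage equilibrium is also what the analysis assumes),
pseudoautosomal recombination, genotyping error, site-specific allele
spectra beyond sampling noise, age censoring of unaffected men, and the
real collection's larger multigenerational pedigrees — affected counts
here concentrate in the 2–3 bin, as X-linked male-limited transmission
dilutes carriers through male lines. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the simulated
conditions, not field performance on consortium data.

## Problem sizes and numerical choices

The validation studies use 20 replicate two-arm cohorts of 200 families
(the acceptance script uses 8 replicates), which keeps a full run in
minutes on one core while leaving the binomial/recovery bands meaningful.
Posterior normalization is enforced to 1e-9; emission phase sums are exact
(no sampling); zero-likelihood positions raise a transmission-
inconsistency error naming the marker; flat curves make support intervals
undefined rather than silently empty; peak ties resolve to the smaller cM
position for determinism. All randomness flows from explicit seeds and
the pipeline's outputs are byte-identical under a fixed config and seed.

## Known limitations

Families beyond the state guard require splitting (no Elston–Stewart
large-pedigree path). The plain HLOD's `alpha_hat` should be read as a
test statistic's nuisance maximizer, not an estimate of the linked
fraction (see above). The ascertainment constant `gamma` assumes the
structure distribution is known, which is true for simulated cohorts
only; real collections would need it estimated from the sampling design.
Allele frequencies estimated by counting related individuals are slightly
anti-conservative for sharing evidence, as in the original consortium
procedure.
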