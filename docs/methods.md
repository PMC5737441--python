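# Methods

This note documents the models, estimators and numerical choices
behind `nerka`, what the synthetic data do and do not emulate, and the
design decisions taken where the design was genuinely open.

## Data model

Genotypes are diploid, biallelic SNP dosages in {0, 1, 2} counting
copies of the alternate allele, with −1 for missing, in a dense
individuals × loci int8 matrix.  Locus ids of the form
`<tag>_<offset>` carry RAD-tag provenance; ids without an integer
suffix are single-SNP tags.  In GENEPOP input the alternate allele of
a locus is the lexicographically larger of its two allele codes (the
format carries no reference/alternate notion, so this only fixes a
sign convention; minor-allele frequency is computed allele-agnostically
afterwards).  A locus with a single observed code is read as
monomorphic-alternate unless the code is the minimal 01/001, which is
taken as reference — this makes write → read lossless for the
canonical writer (ref "01", alt "02", missing "0000").  Population
names default to the prefix of each block's first individual label
before the last underscore, overridable by a sample-attribute file.

## QC filters

The retention cascade runs in a fixed order: locus call rate → pooled
MAF → HWE → individual call rate → (optional) one SNP per tag.
Boundaries follow the stated rules exactly: call-rate and MAF keeps
are inclusive (≥ 0.8, ≥ 0.05); individual removal is strict
(< 0.5 removed).  MAF is computed on the pooled sample because it is a
panel-level filter.

The HWE test is the exact conditional test: given n diploids and the
minor-allele count, heterozygote counts of matching parity are
enumerated with probabilities ∝ n!/(n_AA! n_Aa! n_aa!)·2^{n_Aa}, and
the two-sided p sums all configurations no more probable than the one
observed (probability ordering, with a 1+1e−12 relative tolerance so
floating-point ties count).  Enumerations are cached by (n, minor
count); log-factorials via `gammaln`.  The FDR correction
(Benjamini–Hochberg, via statsmodels) runs within each population
across loci — the natural reading of a per-population HWE screen — and
a pooled-vector mode is available behind a flag.  A locus is removed
only when BH-significant in ≥ 3 populations; this targets paralogous
sequence variants (which fail HWE everywhere they are typed) rather
than local inbreeding or Wahlund effects, and under null simulation it
removes ≈ 0% of loci.  A population with zero calls at a locus
contributes p = 1 (no evidence).  Read-depth filters are out of scope:
depth is a read-level quantity absent from a genotype matrix.

## Diversity and differentiation

Expected heterozygosity uses Nei's unbiased small-sample correction
H_e = 2p̂(1−p̂)·2n/(2n−1) by default (the plug-in form is a flag).
Differentiation is the Weir & Cockerham (1984) estimator: per-locus
variance components a (among populations), b (among individuals within
populations), c (within individuals) computed from per-population
sample sizes, allele frequencies and observed heterozygosities, with
θ̂ = a/(a+b+c) per locus and the multilocus estimate the ratio of
summed components over loci with a nonzero denominator.  Negative
estimates are preserved — truncation would bias both the ratio-of-sums
estimator and the island smoother.  θ̂ is undefined exactly for loci
monomorphic across the compared sample; pairwise matrices exclude loci
monomorphic within the pair.  Note the finite-sample behaviour of
self-comparisons: duplicated samples give E[θ̂] ≈ −1/(2(n−1)), not 0.

## Linkage disequilibrium and Ne

LD between unphased dosage vectors is the Burrows composite
disequilibrium Δ̂ = (1/2n)Σxy − 2p̂_A p̂_B computed on
pairwise-complete individuals, squared and divided by the
HW-departure-corrected denominator (p̂(1−p̂)+D̂_A)(p̂(1−p̂)+D̂_B) —
algebraically the squared sample correlation of the dosage vectors.
This denominator (rather than the plain p(1−p) product) is the form
used by LD-based Nₑ estimation software and has the correct invariants:
a duplicated locus gives r² = 1 exactly and the value is invariant to
allele relabelling.  Pairs need ≥ 5 complete individuals; pairs where
either locus is below the MAF screen or monomorphic are skipped with a
reason (fixed loci make the statistic undefined).

Nₑ uses the one-sample LD method in its transparent form: r̄² is the
unweighted mean over retained pairs (same-tag pairs excluded — physical
linkage violates the unlinked assumption; the pipeline additionally
runs Nₑ on the one-SNP-per-tag neutral track), the sampling floor is
removed as r²_drift = r̄² − 1/S with S the mean pairwise-complete
sample size, and N̂ₑ = 1/(3·r²_drift), reported as +∞ when the drift
signal is non-positive (the "infinite upper bound" regime of large
populations).  The CI is a delete-one-locus jackknife on r̄² (leave-out
means via row sums, jackknife SE, ±1.96·SE) mapped through the same
monotone formula.  The refined small-sample corrections of
Waples (2006) and the parametric CI are documented extension points;
the simple form is used because it is directly oracle-testable.

The validation oracle is a forward Wright–Fisher simulation: a
monoecious population of Nₑ diploids in which each offspring draws a
mother and father uniformly (shared across loci) and receives one
Mendelian allele per parent per locus.  The shared pedigree is what
creates the O(1/Nₑ) cross-locus associations the estimator measures;
resampling gametes independently per locus would generate no LD at all
and no estimator could recover Nₑ from such data.  With Nₑ = 50,
S = 50, 3,000 loci and 4 generations the estimator recovers ≈ 50
(median over seeds), and at Nₑ = 10,000 the signal sits below the
sampling floor, giving very large or infinite estimates.

## Outlier scans

**Permutation F_ST scan.**  The observed statistic is per-locus θ̂
between the pooled side-A and side-B individuals of a comparison.  The
null permutes individual side labels jointly across all loci
(preserving LD within individuals), one-tailed for high θ̂ since
divergent selection is the target; p = (1+#{θ̂* ≥ θ̂})/(n_perm+1), BH
q-values across loci, flags at q ≤ 0.2.  Permutations are evaluated in
chunks of matrix products (label-matrix × call/dosage/heterozygote
matrices), so 10³–10⁴ permutations on a few thousand loci take
seconds.  The null hypothesis is full exchangeability: in the presence
of genome-wide drift between the sides, many loci genuinely violate it,
so flags are candidates relative to "no differentiation", not relative
to the drift background — this is the transparent, exactly calibratable
replacement for a Bayesian F_ST outlier model with genome-wide
background parameters (whose reversible-jump MCMC is out of scope).
Its calibration is therefore measured on panmictic panels, where
p-values are uniform.  Pooling sides across populations is the default;
per-population stratified permutation is a flag.

**PCA scan.**  Dosages are per-locus mean-imputed (the standard
genotype-PCA missing policy), centered and scaled by √(p̂(1−p̂));
monomorphic loci are reported but not tested.  After PCA (scikit-learn,
full SVD), each locus is regressed on the K retained orthogonal score
vectors; the K-vector of standardized coefficients z gets a Mahalanobis
distance under the empirical mean/covariance of all loci, an inflation
factor λ = median(d²)/median(χ²_K) rescales the statistic, and p-values
come from χ²_K.  At K = 1 the distance degenerates to the squared
standardized association.  K defaults to a deterministic scree rule —
the largest K with ev[K]/ev[K+1] ≥ 1.1, capped (default 10) — standing
in for the visual scree inspection; K is always overridable.

Both scans share one BH routine and one flag threshold; the shared
ledger unions flags per locus across comparisons and methods and
reports the sharing histogram and catchments spanned.

## Islands of divergence

Only mapped loci with defined θ̂ enter the scan.  Windows of 5 cM step
1 cM from the first to the last mapped position per linkage group; a
locus at distance d from the window center gets weight
exp(−d²/2σ²) with σ = (window/2)/3, so the kernel has effectively
decayed (≈ 0.011) at the window edge — the "3σ" truncation convention
of kernel-smoothed genome scans.  The smoothed statistic is the
weighted mean; empty windows are recorded with n = 0.

The null for a window resamples its n member values from the
genome-wide pool of defined per-locus θ̂ (negative values included)
with replacement and recombines them with the window's actual weights;
B₁ = 1,000 replicates, escalated to B₂ = 10,000 fresh replicates for
windows whose *observed* statistic exceeds the 90th percentile of all
observed window statistics (the escalation quantile applies to the
observed distribution, not the bootstrap one).  p uses the add-one
estimator, so the floor is 1/(B+1), and exact ties (a constant pool)
count as exceedances.

Islands are maximal runs of consecutive windows with p ≤ α (default
0.05) on one linkage group, with extent = outermost significant centers
± window/2 and labels `<LG>_<ordinal>` in position order.  The default
minimum run length is **4 windows**.  This choice is deliberate: with a
5 cM window and 1 cM step, adjacent windows share ~80% of their loci,
and a single locus in the pool's upper tail lifts the ~3 windows in
which it carries near-unit weight above α simultaneously.  Measured on
simulated panels (see below), a 2-window rule yields ~0.7–1.2 spurious
islands per signal-free linkage group — even with no drift at all —
while a 4-window rule requires support from more than one locus and
reduces the spurious rate to ≤ 0.1 per null linkage group with no loss
of power against a planted 4 cM island (which spans ~7–11 significant
windows).  Shorter runs are still reported, labelled provisional, and
the rule is a flag.  Outlier–island overlap annotation uses closed
intervals (a locus exactly on a boundary counts as inside).

## Synthetic data: what it emulates, and what it does not

`simulate_panel` mirrors a paired-ecotype study design: by default 14
sampling units (populations) in seven lakes and two rivers across
three catchments, with the study's sample sizes (23–48, 504
individuals).  Allele frequencies follow a three-level Balding–Nichols
hierarchy — ancestral p ~ U[0.1, 0.9], then Beta(p(1−F)/F,
(1−p)(1−F)/F) draws at catchment (F = 0.05), lake (F = 0.03) and
population (F = 0.02) levels, chosen as typical intra-species salmonid
values and giving pairwise population θ̂ of a few percent within lakes,
consistent with weakly to moderately diverged intralake ecotype pairs.
Because the Balding–Nichols parameterization has E = p and
Var = Fp(1−p), the parametric F_ST equals the drift parameter, which is
what the recovery tests exploit.

Divergent selection is represented minimally as frequency
displacement: populations on opposite sides of an ecotype axis
(shore/stream or kokanee/anadromous) use clipped p_lake ± δ as their
Beta center.  The analysis consumes only allele frequencies, so a
displacement is the sufficient construct; δ defaults in tests are
0.3–0.45, the upper end of which reproduces near-fixed contrasts
(dosage frequencies > 90% on one side, < 10% on the other) like those
reported for the strongest real shore/stream outliers.  Frequencies are
clipped to [0.01, 0.99] before genotype draws to avoid degenerate Beta
shapes; monomorphic samples still arise by sampling and exercise the
filters.  Genotypes are Hardy–Weinberg binomial(2, p) draws with
independent missingness (default 3%); loci are grouped into RAD tags
with 1/2/3-SNP proportions matching the real panel's tag distribution
(≈ 89.4/11.2/0.62%), tags share map positions, and a `map_fraction`
(default 0.44, the fraction of tags mappable in the real study) of
non-island tags receive uniform positions on four 100 cM linkage
groups.

Fidelity limits, hence what passing tests do not show: linkage is
positional only — island members share elevated divergence but no
haplotype LD is simulated, so the island scan is validated for its
per-locus-F_ST + position semantics, not against recombination
landscapes; there is no migration, admixture or temporal dynamics; no
read-depth or genotyping-error model (missingness is uniform, not
coverage-driven); and ecotype effects are symmetric displacements, not
selection coefficients with demography.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical parameters and seed give
bit-identical outputs, and the pipeline derives stage seeds from its
master seed by fixed offsets.  The validation experiments use the
problem sizes at which their quantities stabilize: 2,000-locus panels
for calibration and recovery (10 seeds), 3,000 loci for Wright–Fisher
Nₑ recovery, 200 random instances for the Weir–Cockerham oracle,
exhaustive enumeration to n = 10 for the HWE oracle, and 100 random
windows for the smoother oracle.

## Known limitations

- The permutation outlier test's FDR is controlled against full
  exchangeability, not against a drift-aware null; between
  well-differentiated sides its flag list includes drift outliers by
  design, and cross-comparison sharing is the intended downstream
  filter.  A background-model (Bayesian) scan is an extension point.
- The Nₑ mapping omits the refined quadratic sample-size correction;
  estimates for very small S carry the corresponding bias.
- The scree rule is a fixed surrogate for visual inspection and can
  pick a K a human would not; it is always overridable.
- GENEPOP monomorphic-locus coding is convention-bound (see Data
  model); round-trips through other software that rewrites allele codes
  may flip dosage polarity at monomorphic loci (MAF-based analyses are
  unaffected).
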