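# Methods

This note records the statistical model, the estimation machinery, the
synthetic-data design and the numerical choices behind `compbias`, in the
spirit of a package vignette. It states no empirical result beyond what
the test suite and `scripts/acceptance.py` themselves compute.

## Composition statistics

For each genome (by default each replicon; an aggregation switch merges
replicons per genome) the package counts non-overlapping in-frame triplets
over all provided ORFs. Stop codons are kept among the 64 categories;
triplets containing an ambiguity code are skipped, not redistributed —
any redistribution rule would be an invention. Nucleotide marginals are
taken from the bases of the counted codons by default, which makes the
factorised null `F(X)F(Y)F(Z)` strictly positive wherever a codon was
observed and so guarantees a finite KL; a whole-replicon-marginals mode
exists because "genomic" base frequencies are also a defensible choice,
and the two differ only marginally for gene-dense prokaryotic genomes.

AAUB and CUB are sample standard deviations (denominator *n − 1*) of the
20 and 64 frequencies. The population denominator would scale both by a
constant; every downstream use (ordering, regression, ANOVA) is invariant
to that scale, so the choice is recorded here rather than configurable.
KL is reported in bits (`log₂`), with nats available. Values within 1e−12
below zero are clamped to zero.

Translation uses NCBI genetic code 11 (bacteria/archaea) by default and is
configurable. CDS whose length is not a positive multiple of 3 are dropped
and counted, never truncated — truncation silently shifts frames. A
terminal stop is dropped; internal stops and N-containing codons yield no
residue. How the original analyses of real corpora handled such records is
generally unknowable; dropping with an audit count is the conservative
option.

## Multivariate stages

PCA is computed on the correlation matrix: columns centred and scaled to
unit sample variance, then SVD. Zero-variance columns (possible in tiny
fixtures) are dropped with a warning rather than producing divide-by-zero.
Eigenvector signs are arbitrary, so PC1 is oriented to correlate
positively with %AT when %AT is supplied, and every other component so
that its largest-magnitude loading is positive — results are then
reproducible run to run. Clustering is agglomerative complete linkage on
Euclidean row distances (scipy); rows are sorted by genome id first so tie
breaking is deterministic. Only rows (genomes) are clustered by default;
column clustering of the heatmap is left to the caller. The dendrogram is
exported as Newick with height differences as branch lengths.

## The penalized LMM engine

All additive and mixed models reduce to one Gaussian form

    y = Xβ + Σₖ Zₖ bₖ + ε,   bₖ ~ N(0, τₖ² I),   ε ~ N(0, σ² I).

Smooth terms are cubic P-splines (B-spline basis on equally spaced knots,
second-order difference penalty, default basis dimension 10). The penalty
null space {1, x} lives in the fixed effects; the penalised range space is
whitened through the penalty eigendecomposition into an i.i.d. random
block, so smoothness selection *is* variance-component estimation — the
standard mixed-model representation of penalized regression splines, and
the same estimation principle as mgcv/gamm4's REML smoothness selection.

Taxonomic structure contributes indicator blocks for nested levels
(phylum ⊃ genus ⊃ species/strain; labels concatenated down the hierarchy
so nesting is explicit, genomes with missing intermediate labels forming
singleton groups), each with a random intercept and a random slope on
genomic %AT (the slope covariate is standardized internally; reported SDs
are back-transformed). Intercept/slope covariances are not modelled — the
independent-components form (lme4's `(1|g) + (0+w|g)`) keeps every
variance parameter a single ratio. A level whose groups are *all*
singletons is dropped with a notice: its intercepts are exactly confounded
with the residual (lme4 likewise refuses `nlevels == nobs`). This happens
by construction in cohorts with one genome per species.

Variance ratios γₖ = τₖ²/σ² are estimated by numerically maximising the
profiled REML (default) or ML likelihood over log γₖ in [−12, 12]
(L-BFGS-B with a Nelder–Mead fallback; non-convergence is flagged on the
fit, not raised). β and σ² have closed forms given γ. Two algebraically
identical evaluation paths keep iterations cheap: an n-side Cholesky of
the marginal correlation using precomputed ZₖZₖᵀ Gram matrices when
n ≤ q, and a q-side Woodbury path on precomputed cross-products when
q < n — the latter makes each iteration independent of n, which is what
allows the large-n null-calibration simulations below. BLUPs, effective
degrees of freedom and the posterior covariance (used for the mgcv-style
±2 SE smooth bands) come from the augmented Henderson system.

Wald t statistics for fixed effects use df = n − total edf. AIC is always
computed from an ML evaluation of the variance parameters (REML fits are
internally re-optimised under ML), counted as
`2·(p + #variance ratios + 1) − 2·logLik_ML`, because REML likelihoods are
not comparable across fixed-effect structures. `compare_aic` refuses
non-converged fits and fits on different observation sets.

The %AT-on-codons regression is OLS through a pivoted rank-revealing QR:
the 64 codon frequencies sum to one, so at least one column is always
aliased; aliased terms are reported as such and excluded from estimation.
The phylum ANOVA is dummy-coded OLS with ranked per-phylum means, with the
"highest/lowest AAUB" queries restricted to phyla above a configurable
size threshold (default > 20 genomes). The KL-versus-genome-size model
keeps the full random structure and enters size as a *linear* fixed
effect: p-values for penalized smooths need reference-distribution
machinery this package does not claim, while the linear Wald p-value is
exactly the quantity whose calibration the tests verify.

## The synthetic cohort generator

The generator reproduces the statistical structure the analysis assumes,
not biological sequences. Taxonomy: phylum %AT means uniform on the
configured range plus an optional normal deviation (σ_phylum, default
0.02), genus and species deviations normal with σ_genus = 0.02 and
σ_species = 0.01 — a few percent %AT spread within taxa, against a
25–86 %AT gradient across phyla, clipped to (0.05, 0.95). Codon
distributions are exponential tilts of the factorised distribution,
`p_c ∝ p⁰_c · exp(β·w_c)`, with a fixed, shipped 64-vector of standard
normal weights. Tilting preserves support (KL finite), grows KL smoothly
in β over the operating range β ∈ [0, 2] (beyond β ≈ 3 the distribution
collapses onto the top-weight codons and KL saturates), and — because the
weights are non-separable across codon positions — creates genuine
between-position dependence rather than a marginal shift. Each genome's
analytic KL is the exact divergence of its tilted distribution from its
own marginals' product.

Defaults define the study conditions: 30 phyla × 5 genera × 4 species
(600 genomes, one per species), 20 000 codons per genome (a deliberate
scale-down from the ~10⁶ codons of a real genome; the sampling noise this
adds to measured KL is ~63/(2·n·ln 2) ≈ 2×10⁻³ bits), base tilt
β = 0.4 — putting analytic KL in the empirically typical 0–0.15-bit
range — decaying linearly to zero across the %AT range (`bias_link="at"`),
so KL falls as genomes become AT-rich *by construction*. β is jittered
log-normally with a phylum-shared component (σ = 0.15) and a per-genome
component (σ = 0.10): the shared component plants the cluster effects the
GAMM must detect, the genome component decouples AAUB from %AT enough to
identify the AAUB coefficient in the KL model. Genome size is
3·n_codons / coding-fraction with coding fraction uniform on (0.75, 0.95),
independent of the codon distribution — so KL is unrelated to size under
the generator, making it the null case for the size regression.

Sequences can be materialised as CDS records of ~300 codons wrapped in
ATG…TAA for I/O realism (the wrapper codons slightly perturb frequencies),
or left as exact multinomial counts (`pack=False` / counts mode) for
frequency arithmetic; the two routes are counted identically and a test
pins their agreement.

What the generator does *not* emulate: phylogenetic sequence evolution
(no substitution models on trees — clustering enters only through the
hierarchical random effects, which is all the fitted models assume), gene
structure, amino-acid biochemistry (the tilt weights are arbitrary, so
*which* residues become preferred is meaningless even though *how biased*
usage is behaves realistically), horizontal transfer, or annotation error.
Passing tests therefore demonstrate that the statistics and fitters
recover known structure of the assumed form — not that real corpora obey
that form.

## Simulation scales used by the checks

The test suite fixes its problem sizes as follows, chosen so each check
has the statistical power its threshold presumes: statistic oracles on
1000 random proportion vectors; sampling consistency at 10⁶ (null) and
10⁵ codons × 20 seeds (tilted); structure recovery on the default
600-genome cohort, with the AIC contest repeated over 20 cohort seeds;
null variance calibration on 30 groups × 800 observations × 20 seeds
(REML null fluctuations of a variance ratio scale like
σ²·√(2/(m−1))/n_per ≈ 5×10⁻⁴σ² there, so the 10⁻³ threshold is a ~2σ
bound; the ratio compares each component's variance to σ² with slopes
taken on the standardized covariate — the only dimensionless comparison);
slope recovery at 30 phyla × 10 genomes, asserted on the median of 10
replicates; clustering against a brute-force O(n³) oracle on 10-genome
instances; and the size-regression type-I error over 100 cohorts of 120
genomes at 3000 codons each (constant codon count, so the small KL
estimation bias is constant and cannot masquerade as a size effect).

## Known limitations

- Gaussian responses only; no GLM families, no spatial/temporal
  correlation structures, no intercept–slope covariances.
- Smooth-term p-values are not provided (smooth uncertainty is reported
  as ±2 SE bands and edf instead).
- Marginal (not conditional) AIC; the variance-ratio count treats
  boundary estimates as full parameters.
- The %AT-on-codons OLS reports coefficients for the QR-selected basis of
  the collinear codon simplex; individual codon coefficients are only
  interpretable up to that aliasing, exactly as in any full-simplex
  regression.
- Profiles are per-replicon by default; merging replicons changes nothing
  in the statistics beyond pooling counts.
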