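# Methods

This note documents the statistical model behind `seedbank`, the
defaults it ships with, and what the synthetic-data generator does and
does not emulate.

## Sampling model and density conversion

The observational unit is a 1 m² quadrat. Eighteen soil cores (15 cm,
the plow layer) per quadrat are pooled, divided into parts, and the
seeds of a subset of parts identified and counted. Each counted part is
treated as representing a fixed ground area — 0.016 m² by default, with
three parts counted — so a quadrat's counts convert to densities as

    density (seeds·m⁻²) = count / (parts_examined × part_area_m2)

i.e. a divisor of 0.048 m² at the defaults. The 0.016 m² constant is
honored as stated by the survey protocol rather than re-derived from
core geometry (18 cores of 3.5 cm diameter give ≈ 0.017 m² per quadrat,
which does not divide into 5 × 0.016 m²); both geometry parameters are
configurable per quadrat.

## Phytosociological parameters

For a stratum (all quadrats of a production mode, or of one field) and
each species observed in it:

* AF = occupied quadrats / total quadrats; RF = AF / Σ AF
* AD = total seeds / total sampled area; RD = AD / Σ AD
* AA = total seeds / occupied quadrats; RA = AA / Σ AA
* IV = RF + RD + RA ∈ [0, 3]; Σ IV = 3 per stratum.

The AD denominator is the stratum's total sampled area
(n_quadrats × parts × part area), consistent with the density
conversion. Species absent from a stratum are dropped from its table
(their relative parameters would be 0). Mode-level tables pool all nine
quadrats of all fields of the mode's sites; per-field tables feed the
ordination. Dominance ranking sorts by IV descending with
lexicographic species-id tie-break, making top-k lists deterministic.

Note that a guild's share of total IV is frequency-weighted: with equal
total abundance, a guild spread over more species collects more of the
RF term. Symmetry checks therefore require balanced per-guild pools.

## Diversity indices

Per quadrat with counts n_i, N = Σ n_i, p_i = n_i/N:

* Shannon H′ = −Σ p_i ln p_i (natural log)
* Simpson diversity λ = 1 − Σ p_i²
* Evenness E = (1/D − 1)/(e^{H′} − 1) with D = Σ p_i² (default)
* Ecological dominance C = Σ n_i(n_i − 1)/(N(N − 1)).

The default evenness is the modified-Hill (Alatalo) ratio of the
Simpson and Shannon effective species numbers, shifted by one; it
equals 1 for perfectly even communities of any richness. An alternative
variant (`literal`) replaces D by λ itself; on an even community
of S species it degenerates to 1/(S−1)² and is retained only for
auditability against sources whose printed formula is ambiguous. C is
the finite-sample probability that two seeds drawn without replacement
are conspecific; it converges to D = 1 − λ at rate O(1/N). E is
undefined (NaN in profiles, error in the scalar function) for
single-species quadrats and C for N < 2.

## Ordination and inference

The community matrix holds per-field IV compositions (rows sum to 3).
Bray–Curtis dissimilarity d_ij = 1 − 2Σ min(x_i, x_j)/Σ(x_i + x_j).

NMDS is Kruskal's non-metric scaling: each run alternates (a) isotonic
(pool-adjacent-violators) regression of configuration distances on the
dissimilarity ranks, with primary tie treatment (tied dissimilarities
may receive unequal disparities, ordered by current distance), and (b)
a Guttman majorization step toward the disparities. Stress-1 =
√(Σ(d − d̂)²/Σ d²). Because stress-1 is scale-invariant, the
disparities are renormalized to the dissimilarity norm each iteration
to pin the configuration scale. Run 1 starts from classical metric
scaling (principal coordinates); the remaining runs (default 250) from
seeded random Gaussian configurations; the lowest-stress run is
returned, centered, rotated to principal axes, with a deterministic
sign convention. Convergence: |Δstress| < 1e−7 or 300 iterations.

One-way PERMANOVA partitions squared distances: SS_total =
Σ_{i<j} d²_ij/n, SS_within = Σ_g Σ_{i<j∈g} d²_ij/n_g, pseudo-F =
(SS_between/(g−1))/(SS_within/(n−g)). The null distribution uses free
permutation of row labels (no strata) — the mode effect is a
single-factor test and the region factor is descriptive only. The
p-value is (b+1)/(m+1), so p = 1/(n_perm+1) is the attainable floor
(0.001 at the default 999 permutations). On Euclidean distances of
univariate data the pseudo-F reduces exactly to the classical ANOVA F
(tested to 1e−9, plus exact agreement with scikit-bio's
implementation).

Group confidence ellipses use covariance eigen-axes scaled by
√χ²₂(level); groups with < 3 members or rank-deficient covariance are
flagged degenerate and omitted.

## Driver attribution (aggregated boosted trees)

Per guild response (its % of total IV per field), a stagewise
least-squares gradient-boosting ensemble is fitted: 500 trees of depth
3, shrinkage 0.01, bag fraction 0.5, min leaf 2 (all configurable).
Each stage fits a regression tree to current residuals on a random
subsample and adds shrinkage × prediction. A predictor's influence is
the sum of squared-error split improvements over all its splits and
trees, normalized to 100% per response; the three guild profiles are
averaged with equal weight and renormalized. The rice-variety
categorical predictor is one-hot encoded and its indicator columns'
influences pooled. Influence is an in-sample variance-decomposition
descriptor: no train/test split is used. Defaults follow standard
aggregated-boosted-tree practice since only the tree count is
conventionally fixed at 500. Observations may be keyed by field
(site covariates replicated across a site's three fields — the default,
n = 36 at the survey's scale) or by site.

## Planting-year trends

Sites are grouped by consecutive planting years into classes <5, 5–7,
≥8. Responses are compared by one-way ANOVA with unconditional LSD
pairwise t-tests on the pooled MSE (df = N − g) at α = 0.05, plus
Shapiro–Wilk (on residuals) and Levene (median-centered) diagnostics.
Total seed density and evenness are log(x+1)-transformed by
convention. Compact letters use the insert-and-absorb algorithm:
starting from one letter covering all classes, every significant pair
splits the columns containing both, subsets are absorbed, and letters
are ordered by descending class mean — classes sharing no letter
differ at α. Quadrats are the default observational unit (keying by
field means is possible by pre-aggregating the profile).

## Synthetic survey generator

The generator emulates the survey design: 4 production modes ×
`sites_per_mode` sites × 3 fields × 9 quadrats.

* **Practices** — site covariates are mode-typical means taken from the
  published site table (monoculture fertilizer ≈ 2× the other modes;
  coculture modes ≈ +30% irrigation and ≈ half the hand-weeding hours)
  with 5% CV multiplicative Gaussian noise; consecutive years uniform
  on 3..10; variety a fair coin between the two planted cultivars.
* **Composition** — guild log-shares = log(mode profile) + covariate
  effects × z-scored covariates + N(0, site_sd²) + N(0, field_sd²),
  softmaxed. Default mode profiles are the published guild IV shares
  (the monoculture grass/sedge split is not itemized in the source and
  is split near-evenly, 0.29/0.28). The default covariate-effect matrix
  is a modest stylization (fertilizer → broadleaf over sedge;
  irrigation → sedge/grass over broadleaf; weeding mildly against
  grass) at 0.1–0.4 log-units per SD.
* **Within-guild abundances** — symmetric Dirichlet (α = 0.5) over the
  guild's pool (the packaged 61-species pool by default, or synthetic
  balanced pools), giving realistic dominance skew.
* **Counts** — per quadrat and species, negative binomial
  (gamma–Poisson) with mean = total density × site factor × relative
  abundance × sampled area, shape k = 2 (None = Poisson limit). The
  site density factor is lognormal with unit mean (σ = 0.3). The
  default total density is 20 000 seeds·m⁻², a realistic order of
  magnitude for intensively cropped paddy soil.
* **Year gradient** — optionally, `richness_fraction_by_year_class`
  restricts each field's community to a fraction of every guild pool
  by the site's year class. Rising richness under a fixed dominance
  skew raises Simpson λ and lowers dominance C and modified-Hill
  evenness E, reproducing the reported qualitative directions; the
  demonstration setting is (0.2, 0.6, 1.0).

What the generator does **not** emulate: spatial autocorrelation within
the inverted-W quadrat layout (quadrats are exchangeable within a
field), within-field covariate variation (practices are site-level),
taxon-specific seed biology, and any dependence of total density on
year class or mode beyond the lognormal site factor. Passing tests
therefore certify the estimators and inference machinery under a
plausible hierarchical count model — not the field study's effect
sizes, which cannot be reproduced without the undeposited raw data.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator`; the pipeline
  fans a single seed into per-stage child streams via
  `SeedSequence.spawn`, so stages are individually reproducible.
* Relative phytosociological parameters are validated to Σ = 1 within
  1e−9; guild shares to 100 within 1e−6.
* Degenerate inputs fail loudly with `ValidationError` naming the
  offending quadrat/stratum: empty quadrats (indices undefined),
  all-zero strata, all-zero distance-row pairs, single-group PERMANOVA,
  constant boosting responses, year classes with < 2 observations.
* Problem sizes used in the shipped checks: oracle equivalence on 1000
  random ≤5×4 surveys; PERMANOVA calibration on 1000 null datasets
  (n = 24, 199 permutations); driver recovery on 20 seeded surveys of
  96 fields; year-gradient demonstration on 64 sites. These sizes give
  standard errors several times smaller than the effects being
  checked.

## Known limitations

* NMDS uses a fixed iteration budget per run; extremely large or
  near-degenerate distance matrices may return `converged=False` (the
  flag is reported, not raised).
* The ABT influence of strongly collinear covariates (e.g. mode-typical
  practices that co-vary by design) is shared between them, as with any
  tree-based attribution; the recovery guarantee holds when one
  covariate carries the signal.
* LSD letters control per-comparison error only (the unconditional-LSD
  convention), not familywise error.
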