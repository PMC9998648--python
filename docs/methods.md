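# Methods

## The twin design and its assumptions

The package implements the Falconer (closed-form) variant of the classical
twin design. Phenotypic variance is partitioned into additive genetic (A),
dominance/nonadditive genetic (D), shared environmental (C) and unique
environmental (E) sources. Under random mating, no gene–environment
correlation or interaction, and equal shared environments for MZ and DZ
pairs, the intra-pair correlations are

    r_MZ = a² + d² + c²
    r_DZ = a²/2 + d²/4 + c²

C and D are not jointly identifiable from same-sex twin pairs alone, so the
observed (r_MZ, r_DZ) pair is gated into one of three scenarios before any
decomposition (epistasis when r_MZ > 4 r_DZ > 0; ADE when
0 < 2 r_DZ < r_MZ ≤ 4 r_DZ; ACE when 0 < r_DZ < r_MZ ≤ 2 r_DZ; everything
else — including r_MZ ≤ r_DZ and non-positive correlations — is left
unmodeled). The gate boundaries r_MZ = 2 r_DZ and r_MZ = 4 r_DZ are
assigned to ACE (C = 0) and ADE (A = 0) respectively: the strict published
inequalities leave the boundaries unassigned, and this choice makes the
component estimates continuous across the gates. Inside each gate the
Falconer components are non-negative and sum to one algebraically; no
truncation is ever needed.

Falconer estimates are method-of-moments, not likelihood fits: they carry
no confidence intervals and no goodness-of-fit test. Structural equation
modelling is deliberately out of scope; with small cohorts (tens of pairs)
SEM is underpowered and the closed forms are the defensible choice.

## Connectivity and graph features

FC matrices are Pearson correlations between ROI-mean BOLD series. The
link-significance test is the exact two-sided t test with df = T − 2; the
choice of sidedness and the absence of an autocorrelation correction are
conventions (documented here because different toolboxes differ), and no
multiple-comparison correction is applied at the masking stage. Binarization
keeps links with weight strictly above the positive threshold τ (default
0.5); ties at τ are excluded, a measure-zero event recorded for
reproducibility.

Graph conventions: betweenness is unnormalized (raw unordered source–target
pair counts); local efficiency of a node is the global efficiency of the
subgraph induced by its neighbours; characteristic path length averages
finite distances only, with a `disconnected` flag whenever pairs were
excluded; network-level "degree" is the mean nodal degree. Louvain
modularity uses resolution γ = 1 with 10 seeded restarts, keeping the best
partition; Q is always recomputed from the returned partition, so the
reported value is self-consistent regardless of the heuristic's internals.
Modularity of an edgeless graph is undefined and surfaces as NaN in the
feature table (and as an error when called directly).

The feature table has C(N,2) + 6N + 5 columns — 4550 for N = 90, of which
540 are node-level. One published account of this feature set prints 4500
link-level features for N = 90; C(90,2) = 4005, and the package uses the
combinatorial count. The discrepancy is documented rather than reproduced.

## Twin statistics

Intra-pair correlations are partial correlations: twin-1 and twin-2 feature
vectors are each residualized on [intercept, age, sex] at the pair level
(same-sex pairs share one age and one sex) and the residuals correlated.
Covariate columns that are constant in a zygosity group (e.g. sex in a
single-sex cohort) are dropped with a warning and the covariate count k
reduced. Twins enter in manifest order by default; because within-pair
ordering is arbitrary, an optional double-entry mode enters every pair in
both orders (an intraclass-style estimate) while keeping the true pair
counts in the variance formulas.

The r_MZ vs r_DZ comparison uses Fisher's z with variance 1/(n − 3 − k) per
group — the standard correction for partial correlations — and a one-sided
upper-tail normal test, since only r_MZ > r_DZ is biologically
interpretable under the model (the printed Z/p pairs this reproduces,
2.94 → 0.0016 and 2.59 → 0.005, are one-sided normal tails). Bonferroni
families are defined per (spatial scale × scenario condition); this reading
of "comparisons per condition" is an interpretation and is isolated in one
place. An optional pre-filter (default off) additionally requires r_MZ and
r_DZ to be individually significantly positive before a feature is gated.

Group sizes must satisfy n ≥ k + 4 so the Fisher variance is defined.

## Synthetic data

The feature-level generator draws standard-normal latent factors with exact
within-pair correlations (A: 1 MZ / 0.5 DZ; D: 1 / 0.25; C: 1 / 1; E: 0)
and combines them with weights √a², √c², √d², √e²; covariates enter
additively (β_age · age + β_sex · 1[M]). Defaults are a small same-sex
cohort — 18 MZ and 25 DZ pairs, ages uniform on 10–30 years shared within
pair, pair sex Bernoulli(0.5) — matching the cohort geometry the analysis
targets. The implied-correlation identity r_MZ − r_DZ = a²/2 + 3d²/4 holds
analytically and is property-tested.

The time-series generator targets a base correlation template (RSN-style
blocks) perturbed per link on the Fisher scale by twin-structured noise,
mapped through tanh, projected to the nearest positive-definite correlation
matrix (eigenvalue clipping at 1e−8, diagonal re-normalization — adequate
because the perturbed matrices are already near-PD), and sampled as T
multivariate-normal time points. The pipeline's simulated default uses
three equal blocks at r = 0.6 and link perturbation σ = 0.3 on the Fisher
scale, chosen once as a realistic block structure that yields non-degenerate
binarized graphs.

What the generators do **not** emulate: hemodynamics, scanner and motion
artefacts, autocorrelated BOLD noise, spatial smoothness, and
non-Gaussian phenotypes. Passing tests therefore validate the statistical
machinery under the stated model, not robustness to fMRI noise sources.

All randomness flows from one integer seed through `numpy.SeedSequence`
spawning, so subject-level draws do not depend on evaluation order and
every pipeline run is exactly reproducible from its run manifest.

## Power analysis

Power is estimated by Monte Carlo (default 10,000 replicates): bivariate
normal twin pairs at the true intra-pair correlation, Fisher z test,
rejection fraction, Wilson 95% interval. Two rejection rules are exposed
because "power to detect heritability" admits both readings: `MZ_NONZERO`
(one-sided test of r_MZ > 0, variance 1/(n − 3); the default) and
`MZ_GT_DZ` (one-sided comparison against the DZ group). No covariate
correction is applied in the power simulation — the simulated feature has
no age/sex structure. With 18 MZ pairs and r_MZ = 0.60 the default rule
gives power near 87%.

## Problem sizes used in the test suite

Statistical properties are exercised at sizes chosen to make sampling error
small relative to the tested tolerances while keeping the suite quick:
parameter recovery at 5000 + 5000 pairs over 20 seeds; the null
false-positive rate over 20 seeds × 4550 independent features at 18/25
pairs; metric oracles exhaustively over all graphs with ≤ 6 nodes;
modularity optimality by exhaustive partition search on ≤ 6-node graphs.

A caveat on recovery tolerances: the Falconer estimators are unbiased but
their sampling standard error at n = 5000 pairs per group is ≈ 0.028 for
the ACE additive component and ≈ 0.054 for the ADE additive component
(error propagation from SE(r) = (1 − r²)/√n), so per-seed componentwise
tolerances much below ~2.5 of these SEs cannot be met reliably by any
correct implementation.

## Known limitations

- Falconer formulas inherit the equal-environments and no-assortative-mating
  assumptions; violations bias components in known directions (assortative
  mating inflates C at the expense of A).
- The epistasis gate detects r_MZ > 4 r_DZ but cannot quantify nonadditive
  variance; such features get no decomposition.
- The Fisher normal approximation is asymptotic; at very small pair counts
  (near the n = k + 4 floor) its type-I control degrades.
- The link-level significance mask uses per-link α with no correction, so
  masked matrices retain ~α false-positive links by design.
- The default AAL-to-RSN map is an editable placeholder assembled from
  canonical network descriptions, not a validated atlas assignment.
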