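# twinconn

Twin-based genetic and environmental decomposition of resting-state
functional-connectivity (FC) features.

## What this is for

The classical twin design compares the resemblance of monozygotic (MZ)
twins, who share their full genome, with that of dizygotic (DZ) twins, who
share on average half of their segregating genes. For any quantitative
phenotype, the gap between the MZ and DZ intra-pair correlations bounds how
much of the phenotypic variance is genetic. `twinconn` applies this design
to brain functional connectivity at three spatial scales: individual
links of the FC matrix, node-level graph features of each region of
interest (ROI), and whole-network features.

It is intended for researchers analysing ROI-level resting-state BOLD time
series from same-sex twin cohorts, and for methodologists who want a fully
synthetic, seedable test bed for Falconer-style twin analyses.

## The model

For each subject, pairwise Pearson correlations between ROI-mean BOLD time
series give an N×N FC matrix (default N = 90 AAL cortical/subcortical
ROIs). Non-significant links (two-sided t test, df = T−2, p ≥ 0.05) are set
to zero; a binarized matrix keeps links with weight > 0.5. From these,
C(N,2) link weights, 6N node features (degree, strengths of positive and
negative weights, clustering coefficient, local efficiency, betweenness
centrality) and 5 network features (global efficiency, characteristic path
length, mean degree, density, Louvain modularity Q) are assembled — 4550
features for N = 90.

For each feature, the intra-pair partial correlation (net of age and sex)
is computed separately in MZ and DZ pairs. The ratio r_MZ/r_DZ gates three
scenarios:

| condition | scenario | decomposition |
|---|---|---|
| r_MZ > 4 r_DZ > 0 | epistasis | not linearly decomposable |
| 0 < 2 r_DZ < r_MZ ≤ 4 r_DZ | ADE | A = 4r_DZ − r_MZ, D = 2r_MZ − 4r_DZ, E = 1 − r_MZ |
| 0 < r_DZ < r_MZ ≤ 2 r_DZ | ACE | A = 2(r_MZ − r_DZ), C = 2r_DZ − r_MZ, E = 1 − r_MZ |

with broad-sense heritability H² = A + D = r_MZ (ADE) and narrow-sense
heritability h² = A (ACE). Differences between r_MZ and r_DZ are tested
one-sided via Fisher's z transform, Z = (atanh r_MZ − atanh r_DZ) /
√(1/(n_MZ−3−k) + 1/(n_DZ−3−k)) with k the number of covariates, Bonferroni
corrected within each (scale × scenario) family. A Monte Carlo module
estimates the power of a given MZ/DZ pair count to detect heritability.

Because real twin imaging data are rarely shareable, the package includes
first-class synthetic generators: a biometrical feature simulator with
exact latent-factor correlations (A: 1 MZ / 0.5 DZ, D: 1 / 0.25, C: 1 / 1)
and a BOLD-like time-series simulator with twin-structured link
perturbations on the Fisher scale.

## Worked example

```python
import pandas as pd
from twinconn import (VarianceComponentsSpec, SimulationConfig,
                      simulate_feature_cohort, run_twin_analysis,
                      ade_decompose, monte_carlo_power)

# simulate one feature with 40% additive genetic, 20% shared-environment
# and 40% unique-environment variance in 5000 MZ + 5000 DZ pairs
spec = VarianceComponentsSpec(a2=0.4, c2=0.2, e2=0.4)
manifest, values = simulate_feature_cohort(
    spec, SimulationConfig(n_mz=5000, n_dz=5000, seed=7))
features = pd.DataFrame({"link:Insula_L|Insula_R": pd.Series(values)})
results = run_twin_analysis(features, manifest)
print(results[["feature_id", "rMZ", "rDZ", "scenario", "A", "C", "E", "Z", "p"]]
      .round(4).to_string(index=False))
```

```
            feature_id    rMZ    rDZ scenario      A      C      E       Z   p
link:Insula_L|Insula_R 0.6139 0.3933      ACE 0.4412 0.1728 0.3861 14.9659 0.0
```

The implied correlations are r_MZ = a² + c² = 0.6 and r_DZ = a²/2 + c² =
0.4; the fitted ACE components recover the simulated (0.4, 0.2, 0.4) within
sampling error, and the one-sided Fisher test of r_MZ > r_DZ is
overwhelmingly significant at this sample size.

```python
dec = ade_decompose(0.6191, 0.27025)
print(f"A = {100*dec.A:.2f}%, D = {100*dec.D:.2f}%, "
      f"E = {100*dec.E:.2f}%, H2 = {100*dec.H2:.2f}%")

power = monte_carlo_power(n_mz=18, r_mz_true=0.60, n_sims=10_000, seed=1)
print(f"power = {100*power.power:.2f}% "
      f"(95% CI {100*power.ci_low:.1f}-{100*power.ci_high:.1f}%)")
```

```
A = 46.19%, D = 15.72%, E = 38.09%, H2 = 61.91%
power = 87.03% (95% CI 86.4-87.7%)
```

The first line is the ADE decomposition at intra-pair correlations
(0.6191, 0.27025): 46% additive genetic, 16% dominance, 38% unique
environment, broad-sense heritability 62%. The second estimates the power
of 18 MZ pairs to detect a strong (60%) broad-sense heritability at
α = 0.05.

A shell interface mirrors the pipeline stages:

```bash
twinconn simulate --spec a2=0.4,c2=0.2,e2=0.4 --n-mz 18 --n-dz 25 --seed 7 --out data/
twinconn fc --timeseries data/timeseries --out fc/
twinconn metrics --fc fc/ --out features.tsv
twinconn twin --features features.tsv --manifest data/manifest.tsv --out results.tsv
twinconn summarize --results results.tsv --out rsn_summary.tsv
twinconn run --config config.yaml          # everything at once
```

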