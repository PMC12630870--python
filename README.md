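# ndmap — individualized normative deviation mapping for multi-site fMRI cohorts

Group-average case-control contrasts blur over the marked heterogeneity of
focal epilepsies: two patients with temporal lobe epilepsy (TLE) rarely share
the same set of functionally abnormal brain regions. `ndmap` implements, on
parcellated resting-state fMRI, the individual-patient alternative: build a
normative model of regional brain function in healthy controls, express every
patient region as a covariate-adjusted deviation (W-score), and analyse the
resulting person-specific deviation maps — their population prevalence, their
constraint by the structural connectome, their coupling with structural
abnormality, and their clinical discriminative value.

It is written for neuroimaging methodologists and clinician-scientists who
work with subjects × regions metric matrices (any parcellation), and ships a
fully synthetic multi-site cohort generator so every stage can be exercised —
and its statistical behaviour verified — without access to patient MRI.

## The model

Three metrics summarise function at increasing spatial scale for each region
(node) of a parcellation:

- **SV** (signal variability): `SV = sqrt(Σ_{i=1}^{T-1} (x_{i+1} − x_i)²) / (T−1)`
  for a BOLD series x of length T (a `rmssd` variant is available);
- **ReHo** (regional homogeneity): Kendall's coefficient of concordance
  `W = 12 (Σ R_i² − T R̄²) / (K² (T³ − T))` over a vertex's K within-region
  neighbour series, averaged per region;
- **NS** (node strength): `NS_i = Σ_{j≠i} corr(x_i, x_j)`, the signed sum of
  Pearson functional connectivity, split into short- (≤ 75 mm) and long-range
  parts by centroid distance.

After ComBat harmonization across sites (parametric empirical-Bayes
location/scale model preserving age, sex and diagnosis), a per-region linear
normative model `y = β₀ + β₁·age + β₂·sex + ε` is fit on controls, and each
patient's deviation is

    W = (observed − predicted) / SD(control residuals).

Regions with |W| ≥ 1.96 (the two 2.5% normative tails) are *extreme
deviations*; the per-region fraction of patients flagged is the *prevalence
map*. A Mahalanobis composite aggregates the three metrics per region.
Downstream, the prevalence map is related to a structural connectome
(neighbourhood deviation `p̄_i = (1/N_i) Σ_j p_j C_ij`, epicenter likelihood =
Spearman ρ between a region's connectivity profile and the map, both against
spatial-autocorrelation-preserving spin nulls), predicted from structural
deviation maps (CT/FA/MD) with dominance analysis of predictor importance,
and fed to a nested cross-validated linear SVM for diagnosis, lateralization
and outcome tasks with permutation significance.

## Worked example

```python
import numpy as np
from ndmap import (SimulationConfig, simulate_atlas, simulate_connectome,
                   simulate_cohort, compute_metrics, deviation_set,
                   spin_permute, epicenter_map, node_vs_neighbor_coupling)

atlas = simulate_atlas(n_cortical=20, n_subcortical=6, seed=0)
sc = simulate_connectome(atlas, density=0.35, seed=1)
cfg = SimulationConfig(seed=42, n_sites=1, n_hc_per_site=80, n_tle_per_site=60,
                       n_fcd_per_site=0, effect_size_w=2.0,
                       epicenter_seed_region=5, prop_left_focus=1.0)
subjects, vertex_data, struct, truth = simulate_cohort(cfg, atlas, sc)
metrics = compute_metrics(vertex_data, atlas)
patients, controls = deviation_set(
    {m: metrics[m] for m in ("SV", "ReHo", "NS")}, subjects)

prev = patients.extreme.mean(axis=(0, 2))          # mean over patients, metrics
print("median prevalence: %.1f%%" % (100 * np.median(prev)))
print("top-3 regions by prevalence:", atlas.region_ids[np.argsort(-prev)[:3]].tolist())

null = spin_permute(atlas, n_iter=1000, seed=7)
rho, p_spin, _ = node_vs_neighbor_coupling(prev, sc, null)
print("node-neighbour coupling: rho = %.2f, p_spin = %.4f" % (rho, p_spin))

epi = epicenter_map(prev, sc, null)
best = np.argsort(-epi.likelihood)[0]
print("top epicenter: region %d (likelihood %.2f, p = %.4f)"
      % (atlas.region_ids[best], epi.likelihood[best], epi.p_value[best]))
```

Output:

```
median prevalence: 5.6%
top-3 regions by prevalence: [7, 5, 17]
node-neighbour coupling: rho = 0.57, p_spin = 0.0689
top epicenter: region 5 (likelihood 0.76, p = 0.0020)
```

The cohort was generated with a deviation effect diffusing through the
connectome from region 5 (two residual SDs at the seed), so the prevalence
map concentrates around regions 5 and 7, median prevalence stays near the
5% normative tail rate, and the epicenter analysis recovers region 5 as the
most likely origin. `truth.true_effect_map` carries the injected ground
truth for such parameter-recovery checks.

The same workflow runs from the shell on a YAML config:

```bash
ndmap run-all --config config.yaml --out runs/demo      # simulate → classify
ndmap variants --config config.yaml --base runs/demo --out runs/variants
```

Each run writes metric/W/prevalence TSVs, epicenter tables, JSON stage
reports and a manifest with SHA-256 hashes of every output (rerunning a
config reproduces the hashes bit-for-bit).

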