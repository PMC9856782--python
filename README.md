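# fdnet

Fractal-dimension (FD) cortical morphometry and FD-based structural
covariance network analysis.

Cortical atrophy in neurodegenerative disease (e.g. mild cognitive
impairment) changes the *shape complexity* of cortical subregions before
volume loss is obvious. `fdnet` quantifies that complexity per region with
the 3D box-counting fractal dimension, then treats across-subject
correlations of regional FD as a structural covariance network and compares
its modular organisation between groups. It is written for neuroimaging
researchers who already have a labeled cortical parcellation (68-region
Desikan–Killiany layout) per subject — or who want to validate the whole
chain on synthetic data first.

## The methods

**Box-counting FD.** For a voxelized object, the covering count N(r) over
cubes of side r follows N(r) ∝ r^−FD. With counts taken at r = 10…2 voxels,
FD is the slope of the least-squares line through (log₂(1/r), log₂N(r)),
estimated on the contiguous sub-window (≥4 points) with the highest R².
Phantoms with known dimension validate the estimator: a solid cube → 3, a
one-voxel slab → 2, a Menger sponge → log20/log3 ≈ 2.727.

**Covariance network.** For a group, the 68×68 Pearson correlation matrix
of regional FD across subjects is proportionally thresholded: the strongest
20% of the 2278 region pairs (positive values only) are retained as weighted
edges.

**Modules and node roles.** Newman modularity on the weighted network,

  Q = 1/2m Σᵢⱼ [Aᵢⱼ − kᵢkⱼ/2m] δ(cᵢ,cⱼ),

is maximized with seeded Louvain. Node roles use the binary adjacency:
within-module degree z-score Zᵢ = (Kᵢ − K̄_c)/σ_Kc and participation
coefficient Pᵢ = 1 − Σ_c (K_ci/Kᵢ)². With the four anatomical lobes playing
the role of modules these become intra-/inter-lobular connectivity.

**Group comparison.** Per-region two-sample t-tests with Benjamini–Hochberg
FDR and Cohen's d; network-level properties (Q, mean P, mean Z) are compared
with a pool-and-resplit permutation test (subsample 10 per group, 1000
iterations, 95th-percentile critical values, one-tailed).

## Worked example

```python
from fdnet import (SimulationSpec, simulate_two_groups, GroupComparisonModel,
                   estimate_fd, make_menger_sponge)

# validate the FD estimator on a phantom of known dimension
fit = estimate_fd(make_menger_sponge(4))
print(fit.fd)            # 2.8125  (Hausdorff dimension is 2.7268)

# simulate a 30 vs 30 cohort with planted covariance modules and effects,
# then run the full contrast
control, patient = simulate_two_groups(SimulationSpec(n_subjects=30, seed=42))
res = GroupComparisonModel(control, patient, n_perm=200, seed=42).fit()
print(res.summary())
```

prints (abridged):

```
Modules: control 5 (Q=0.7102)  patient 6 (Q=0.6618)

Lobe connectivity ratios (patient/control, %):
           intra_ratio_pct  inter_ratio_pct
frontal               99.6            118.3
temporal              93.1            103.2
parietal              85.9            120.6
occipital             88.2            294.1

Permutation test (200 iterations, subsample 10):
              observed_a  observed_b  observed_diff  critical_95       p
modularity_q      0.7102      0.6618         0.0484       0.1417  0.3433
```

The control network decomposes into 5 modules and the patient network into
6 with lower modularity — the patient group's weaker covariance fragments
the network — while the permutation test (correctly) does not declare this
single simulated difference significant at these settings. Intra-lobular
ratios below 100% show the planted FD reductions weakening within-lobe
covariance.

With real data, replace the simulation with per-subject NIfTI label volumes:

```bash
fdnet fd subj*.nii.gz --group-label control --out control.csv
fdnet compare control.csv patient.csv --seed 1 --out-dir results/
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's analytic reference quantity
from scratch (the participation coefficient of a provincial node — one whose
retained links all stay inside its own module — on a constructed two-module
network) and writes it as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/fdnet/` — `volume`/`synthetic` (phantoms, cohort simulator), `fd`
  (box counting + slope fit), `atlas` (region table, NIfTI/CSV I/O),
  `network` (correlation + thresholding), `modules` (modularity, Louvain,
  brute-force oracle), `metrics` (Z, P, lobe tables), `stats` (t/FDR/d,
  permutation test), `model` (Model/Results objects), `cli`, `report`.
- `docs/methods.md` — modelling assumptions, parameter defaults, numerical
  choices and limitations.
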