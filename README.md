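# faebm — event-based progression modelling for white-matter FA biomarkers

`faebm` infers the order in which regional white-matter biomarkers turn
abnormal in a neurodegenerative disease from purely **cross-sectional**
patient/control data, and assigns each subject a disease stage along the
inferred sequence. It targets diffusion-MRI fractional anisotropy (FA)
readings averaged over canonical tracts (corticospinal tract segments,
corpus callosum subdivisions, cingulum, SLF, ILF, IFOF, UF), but works
with any biomarker table in which disease shifts a marker from a
"healthy" to a "diseased" distribution.

## The model

A disease is modelled as a fixed sequence of *events*
S = (s(1), …, s(N)), an event being the transition of biomarker s(i)
from its healthy distribution P(x | ¬E) to its diseased distribution
P(x | E). A subject at stage k has experienced exactly the first k
events. With a uniform prior over stages, the likelihood of patient j's
measurements x_j under an ordering S is

```
P(x_j | S) = 1/(N+1) · Σ_{k=0}^{N}  Π_{i≤k} P(x_{j,s(i)} | E) · Π_{i>k} P(x_{j,s(i)} | ¬E)
```

and P(X | S) is the product over patients. The per-biomarker densities
come from a two-component Gaussian mixture fitted by EM, with the
healthy component anchored to the control cohort: the 95% confidence
intervals of the control Gaussian's mean (Student-t) and SD (chi-square)
form a box the healthy component may not leave. To blunt the influence
of outliers the mixture is refitted on 1000 bootstrap resamples,
replicates whose mixing proportion collapsed are excluded, and the
element-wise median of the surviving parameters is used.

The posterior P(S | X) over orderings (uniform prior, patient data only)
is sampled by a Metropolis chain with pairwise-swap proposals,
initialized from a greedy hill climb, and summarized as a **positional
variance diagram** (PVD): a doubly stochastic matrix whose (i, p) entry
is the posterior confidence that event i occupies sequence position p.
Bootstrap cross-validation (resampling both groups, one direct mixture
fit per replicate under weak constraints, re-estimating the most likely
ordering) yields a deliberately more conservative PVD. Finally, every
subject gets the maximum-likelihood stage `argmax_k` of the same
staged product, and a stage cut-off turns staging into a
patient/control classifier.

## Worked example

```python
import numpy as np, faebm

regions = faebm.canonical_region_set("combined")        # 11 WM regions
config = faebm.SimulationConfig(
    region_set=regions,
    true_ordering=np.random.default_rng(1).permutation(11),
    n_patients=150, n_controls=130, seed=1,
)
table, truth = faebm.generate_cohort(config)

fits, controls = faebm.fit_mixture_models(table, B=200, seed=1)
patients = table.patients()
init = faebm.greedy_ascent(patients, fits, restarts=10, seed=1)
posterior = faebm.mcmc_sample(patients, fits, init=init,
                              n_iter=20_000, burn_in=2_000, seed=1)
print("truth:", truth["true_ordering_labels"][:3], "…")
print("MAP:  ", list(posterior.map_ordering.region_labels(table.region_labels))[:3], "…")

assignments = faebm.stage_table(table, posterior.map_ordering, fits)
sens, spec = faebm.classify_by_stage(assignments, cutoff=1)
print(f"stage>=1 classifier: sensitivity {sens:.2f}, specificity {spec:.2f}")
```

Output:

```
truth: ['SLF', 'UF', 'CC_splenium'] …
MAP:   ['SLF', 'UF', 'CC_splenium'] …
stage>=1 classifier: sensitivity 0.89, specificity 0.94
```

The MAP sequence recovers the generating event order; the stage-1
cut-off classifier is imperfect by construction, because under a uniform
stage distribution about 1/(N+1) of patients truly have no events yet
and are indistinguishable from controls.

The same analysis is available from the shell:

```
faebm simulate --mode combined --seed 1 --out cohort.csv
faebm run --config pipeline.yaml        # fit → order → crossval → stage
faebm report --run-dir runs/example     # PVD heatmaps + stage bar chart
```

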