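# elscape — energy-landscape analysis of binarized network dynamics

`elscape` quantifies how the collective state of a small network wanders
among attractors.  It targets the kind of multichannel recordings used in
resting-state neuroimaging (nine network-averaged signals) and in studies of
transformer hidden-state trajectories (hundreds to thousands of channels
reduced to nine clusters), and it characterizes each recording by how
*polarized* its attractor dynamics are — an approach that has been used to
separate receptive from expressive aphasia and to place large language
models on the same map.

## The model

A binarized recording is a sequence of activity patterns
V_t = (σ_1(t), …, σ_N(t)) with σ_i ∈ {−1, +1} and N = 9.  A pairwise
maximum-entropy (Ising) model is fitted to the observed first and second
moments ⟨σ_i⟩ and ⟨σ_i σ_j⟩:

    E(V) = − Σ_i h_i σ_i − ½ Σ_ij J_ij σ_i σ_j,     P(V) = e^{−E(V)} / Z

where h_i is the basal activity of node i and J_ij a symmetric pairwise
coupling.  Fitting is plain gradient ascent on the log-likelihood with model
moments computed by exact enumeration of all 2^N patterns; fit quality is
r_D = (D_1 − D_2)/D_1, the fraction of the independent model's
Kullback–Leibler divergence from the data removed by the pairwise model.

The fitted energy landscape over the 2^N-pattern hypercube is summarized by
its local minima (attractors), the basin of each minimum under steepest
descent, and a disconnectivity tree whose internal nodes carry the minimax
energy barrier at which groups of minima disconnect.  Dynamics are simulated
with a Metropolis–Hastings walk (neighbor proposals, acceptance
min(1, e^{E(V_i)−E(V_j)}), 10^5 steps, 100-step burn-in); the walk is
reduced to an attractor label sequence and summarized by per-attractor
dwelling times and pairwise transition counts.  The polarization of those
two vectors is measured by the Gini coefficient
G = Σ_ij |x_i − x_j| / (2 n² μ) ∈ [0, 1): uniform dynamics give G ≈ 0,
dynamics dominated by a few deep attractors push G toward 1.

Because the real recordings behind this kind of analysis are not
redistributable, the package ships a first-class synthetic generator: latent
±1 dynamics sampled exactly (or by Glauber dynamics) from known model
parameters, with two landscape regimes — `uniform_shallow` (equally weak
ferromagnetic blocks, attractors of similar depth) and `polarized` (one
strong block among weak ones, coexisting deep and shallow attractors) — and
an emission model that duplicates channels with random gain/offset and
Gaussian noise to emulate high-dimensional recordings.

## Worked example

```python
import numpy as np
from elscape import (make_regime_params, sample_mem_series,
                     subject_indices, PipelineConfig)

params = make_regime_params("polarized", n_nodes=9, seed=0)
series = sample_mem_series(params, n_timepoints=100_000, seed=1)
idx = subject_indices(series, PipelineConfig(), seed=2)
print(f"r_D={idx.r_d:.4f} minima={idx.n_minima} "
      f"gini_dwell={idx.gini_dwell:.4f} gini_trans={idx.gini_trans:.4f}")
```

prints

```
r_D=0.9982 minima=8 gini_dwell=0.0238 gini_trans=0.7057
```

i.e. the pairwise model removes 99.8% of the independent model's divergence
from this recording, the fitted landscape has 8 attractors, and the
transition counts are strongly polarized (G = 0.71): the walk exchanges
freely within each deep half of the landscape but rarely crosses the high
barrier between them.

The full study lives in `analysis/` as numbered drivers
(`01_simulate_cohort.py` … `06_llm_route.py`): simulate 20 subjects per
regime, fit both model orders, build the landscapes, run the walks, and
compare the regimes.  On the default seeds the transition-frequency Gini
separates the regimes at t = 52.2 (df = 38, η² = 0.986, Bonferroni
p ≈ 10⁻³⁸) while the dwelling-time Gini does not (t = 1.3), and within the
polarized group the transition Gini tracks the ground-truth landscape
heterogeneity (Pearson r = 0.58, p = 0.007, n = 20).  Intermediate tables
are written under `results/`.

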