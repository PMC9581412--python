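# ligandmsm

Markov state model (MSM) analysis of heterogeneous protein–ligand binding
modes, for computational chemists and structural bioinformaticians working
with molecular-dynamics (MD) trajectory ensembles of a small ligand exploring
discrete poses in a protein pocket (the motivating system is a drug-sized
amphipathic ligand binding the C-terminal domain of calmodulin).

The pipeline resolves the binding-mode kinetics in seven stages:

1. **Featurization** — per-frame minimum distances between protein residues
   and selected ligand atoms, transformed into quasi-binary contacts: an
   indicator `d < i` or the inverse distance `1/d` for `d < i`, with cutoff
   `i` (default 6 Å, inverse).  Residue–residue inverse distances that cross a
   6.5 Å threshold feed the later importance stage.
2. **Feature selection** — candidate transforms scored by the cross-validated
   VAMP2 score, `1 + Σ σ_k²` over the leading singular values of the
   propagator approximation; the transform with the highest lag-averaged mean
   wins.
3. **tICA** — the generalized eigenproblem `C(τ) v = λ C(0) v` of the lagged
   and instantaneous feature covariances projects frames onto the slowest
   linear coordinates (tICs).
4. **MSM estimation** — k-means microstates in tIC space, sliding-window
   transition counts, and the maximum-likelihood *reversible* transition
   matrix via the detailed-balance fixed point; validated with implied
   timescales `t_i = −τ/ln λ_i(τ)`, GMRQ cross-validation and the
   Chapman-Kolmogorov test.  Stationary weights `π_state/count_state` turn any
   per-frame observable into an equilibrium average `⟨O⟩ = Σ π_i O_i / Σ π_i`.
5. **Macrostates** — PCCA+ groups microstates into metastable sets (the count
   chosen at the spectral gap of the relaxation timescales); frames with a
   membership above 0.8 form *core states*; mean first passage times between
   macrostates come from the exact hitting-time linear solve, π-averaged over
   the source set.
6. **Adaptive-sampling seeds** — either a uniform grid over the (tIC1, tIC2)
   extent, or microstates drawn with probability ∝ 1/π so rare regions get
   re-simulated.
7. **Importance profiles** — one-vs-rest random forests (Gini importance) and
   a symmetrized Kullback-Leibler baseline rank the residue pairs that
   distinguish the macrostates; per-residue profiles are the pairwise sums,
   min-max normalized to [0, 1].

A synthetic-data module generates surrogate inputs with exactly known
kinetics — block-structured reversible Markov chains, Gaussian feature
emissions, and a toy bead "protein + ligand" complex whose ligand switches
between designed binding modes with an induced-fit pocket response — so every
stage can be checked against analytic or brute-force references.

## Worked example

```python
import numpy as np
import ligandmsm as lm

# a 12-microstate chain with 3 designed metastable blocks
spec = lm.MetastableChainSpec(12, 3, intra_rate=0.3, inter_rate=0.01, seed=1)
T, blocks = lm.build_metastable_chain(spec)
truth = lm.analytic_ground_truth(T, blocks)
trajs = lm.sample_discrete_trajectories(T, n_trajs=5, n_steps=40_000, seed=2)

model = lm.estimate_msm_from_assignments(trajs, lag=1, n_states=12)
print("slowest timescale:", model.timescales(1)[0], "vs true", truth.timescales_true[0])

chi = lm.pcca_memberships(model, 3)          # fuzzy macrostate memberships
sets = lm.crisp_sets(chi, model.active_set)
mfpt, _ = lm.mfpt_between_macrostates(model, sets)
print("MFPT (frames):\n", np.round(mfpt, 1))
```

prints

```
slowest timescale: 68.85536144837296 vs true 66.16540720164689
MFPT (frames):
[[  0.  206.2 177.4]
 [226.9   0.  181.4]
 [217.7 200.9   0. ]]
```

The estimated slowest relaxation timescale sits within ~4% of the designed
value, and the macrostate-to-macrostate mean first passage times (in frames,
here 1 frame = 1 lag; exact values 208.1/213.6/181.4 for the three designed
blocks) agree with the hitting-time solution of the generating chain to
within ~10%.

The full workflow on the toy complex is one call (or `ligandmsm run cfg.yaml`
from the shell):

```python
res = lm.run_pipeline(lm.PipelineConfig(toy_n_trajs=4, toy_n_steps=6000,
                                        tica_lag_ns=10, msm_lag_ns=10,
                                        n_microstates=60), "out/")
print(res["spectral_gap"].recommended_n)     # -> 3 designed binding modes
```

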