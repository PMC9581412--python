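# Methods

This note records the models, estimators and numerical conventions behind
`ligandmsm`, and what the synthetic test bed does and does not establish.

## Kinetic model

The object of study is a discrete-state, discrete-time Markov model of ligand
binding-mode dynamics.  Trajectory frames are mapped to microstates; the
transition matrix `T(τ)` at lag `τ` is estimated from sliding-window
transition counts (every `(t, t+τ)` pair inside a trajectory, never across
trajectory boundaries).  Estimation is *reversible*: the maximum-likelihood
`T` under the detailed-balance constraint `π_i T_ij = π_j T_ji` is found by
the standard self-consistent iteration on symmetric pair weights
`x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j)`, iterated to a relative
stationary-distribution change below 1e-10 (cap 10⁴ iterations).  Counts are
first restricted to the largest set of states connected by *bidirectional*
counts; when several components exist, the one with the most counts wins.
Frames outside the active set carry zero weight everywhere downstream.

Reversibility makes the spectrum real; the decomposition is computed on the
π-symmetrized matrix `D^{1/2} T D^{-1/2}` with `eigh`, giving π-orthonormal
left/right eigenvectors.  Eigenvector signs are fixed by making the
largest-magnitude entry positive, so repeated runs and platforms agree.

Equilibrium expectations of any observable use frame weights
`π_state / count_state`, normalized over included frames.  Weighted
percentiles interpolate the weighted empirical CDF with order statistic
`x_(i)` at position `(S_i − w_i/2)/S_n`; free-energy surfaces are
`F = −ln(weight mass per bin)` in units of k_BT, shifted so the minimum is 0,
on a 60×60 grid spanning the data extent (empty bins are reported unbounded).

## Featurization

Ligand-contact features are minimum distances (Å) between each protein
residue (minimum over its atoms) and a small set of named ligand atoms,
passed through a quasi-binary transform: `binary` (indicator `d < cutoff`) or
`inverse` (`1/d` if `d < cutoff`, else 0).  The default is inverse at 6 Å.
The inverse transform maps beyond-cutoff distances to 0 rather than to
`1/cutoff`; this keeps "no contact" at a common value across cutoffs and
makes binary a thresholded version of inverse.  Candidate transforms
(4 cutoffs × 2 transforms) are compared by cross-validated VAMP2 and the
lag-averaged argmax is selected.

Residue–residue features for the importance stage are inverse minimum
distances over heavy atoms (hydrogens excluded, the standard contact
convention), restricted to pairs whose distance is below 6.5 Å in at least
one frame *and* above it in another — i.e. contacts that actually break and
form.  Sequence-adjacent pairs are excluded by default (they never carry
state information and dominate the inverse-distance scale).  No cutoff
zeroing is applied to retained pairs.

Distances are computed in plain Euclidean space; periodic-boundary imaging
is expected to be resolved by whatever produced the coordinates.

## tICA and VAMP2

Covariances use the symmetrized (reversible) estimator: each `(t, t+τ)` pair
contributes in both time directions, the mean is taken under the same pair
measure, and `C(τ)` is symmetrized.  This guarantees `C(0) ± C(τ) ⪰ 0`, so
tICA eigenvalues lie in [−1, 1] and cross-validation scores respect their
variational bounds by construction rather than by clipping.  The generalized
eigenproblem is regularized with `ε = 1e-6 · trace(C0)/dim` (duplicated or
constant features stay finite); eigenvalues above 1 are clipped with a
warning.

The VAMP2 score of a feature set is `1 + Σ_k σ_k²` over the top
`n_eigenvalues − 1` generalized singular values of the train-estimated
singular functions evaluated on held-out covariances; the explicit 1 is the
constant function, so featureless (i.i.d.) inputs score ≈ 1.  Splitting is by
whole trajectory with a seeded shuffle; a single long trajectory is split
into contiguous blocks instead.  GMRQ scoring follows the same pattern at the
MSM level: the trace of the test Rayleigh quotient of the training model's
top eigenfunctions (constant included), with test microstates unseen in
training dropped with a warning.

## Macrostates

The macrostate count is read off the relaxation-timescale spectrum: the
recommended `n` maximizes `t_n / t_{n+1}`; a best ratio below 2 is flagged
low-confidence and the user may override.  PCCA+ runs an inner-simplex
vertex search on the leading right eigenvectors, inverts the vertex
submatrix, clips negative memberships and renormalizes rows — the
feasibility-repaired variant without the final crispness optimization, which
is deterministic and accurate on gapped systems (the only regime where
macrostates are meaningful).  Core frames are those with membership > 0.8
(argmax ties break to the lower index); the rest are transition frames.

MFPTs between macrostates solve the hitting-time system `h = 0` on the
target, `(I − T) h = τ·1` elsewhere, by a dense linear solve, then average
`h` over the source set with stationary weights.  Macrostate sets for MFPTs
are the crisp argmax partition of the microstates; cores remain a
frame-level reporting device.  Uncertainties on populations, timescales, CK
curves and MFPTs come from a trajectory-level bootstrap (default 100
resamples; smaller where a config chooses so).

## Adaptive-sampling seeds

Two selection rules: (i) `n` grid targets uniformly spanning the rectangular
(tIC1, tIC2) extent, each mapped to its nearest data frame with duplicates
resolved by next-nearest; (ii) microstates drawn with replacement with
probability `∝ 1/π_i`, a member frame chosen uniformly per draw.  An
inverse-visit-counts variant of (ii) is exposed as a flag.

## Importance profiles

Per macrostate, a binary random forest (state vs rest) is trained on the
residue-pair features of core frames only; transition frames never enter.
Forests use 100 trees, unlimited depth, √d features per split, and a seed per
(state, fold); Gini importances are averaged over the cross-validation folds
and held-out accuracy is logged.  The model-free baseline is the symmetrized
KL divergence `(KL(P‖Q) + KL(Q‖P))/2` between in-state and rest histograms on
50 shared-range bins with a pseudo-count of 1 per bin, which sends identical
or constant features to exactly 0.  Per-residue scores sum a residue's pair
importances and are min-max normalized per state (a flat but nonzero profile
maps to all ones).

## Synthetic data

The generators define the conditions under which the pipeline is validated.

*Metastable chains* place microstates in near-equal blocks, draw per-state
weights `w_i ∈ [1−s, 1+s]` (spread `s`, default 0.5), and set
`T_ij = base · w_j` with one base rate per pair class so the flux
`w_i T_ij` is symmetric — detailed balance holds exactly with `π ∝ w`, and
the intra/inter base rates reproduce the requested per-row leaving masses on
average.  The reference quantities (π, timescales, block MFPTs) are computed
from the dense matrix, not simulated.  The standard validation chain is 12
microstates in 3 blocks with leaving masses 0.3 (intra) and 0.01 (inter),
sampled as 5 trajectories × 40 000 steps — enough for ~2% timescale noise
while keeping the whole suite fast.

*Toy complexes* put one bead per residue on a ring (3.8 Å spacing, matching
Cα virtual-bond geometry) and a short rigid ligand chain placed at one of a
few designed pose offsets; modes switch by a metastable chain, coordinates
get isotropic Gaussian jitter (0.3 Å), and pocket residues within the
contact cutoff of the active pose shift 1 Å toward it — a minimal induced-fit
response that makes the protein's internal geometry mode-dependent, so the
residue-pair importance stage has designed discriminative residues.  The
end-to-end checks use 3 modes, 16 residues, 3 ligand atoms, 4–5 trajectories
of 6 000–20 000 frames.

What this does *not* establish: the emissions are Gaussian and memoryless
given the hidden state, the toy geometry has no excluded volume, solvent, or
conformational strain, and frames are exactly Markovian at lag 1.  Passing
these tests therefore demonstrates estimator correctness and pipeline wiring,
not robustness to the non-Markovian projections, force-field artifacts and
sampling pathologies of real MD data.

## Defaults that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| feature transform / cutoff | inverse, 6 | Å | highest lag-averaged VAMP2 among the 8 candidates on the motivating system |
| pair filter cutoff | 6.5 | Å | contact make/break threshold for importance features |
| tICA lag | 20 | ns | slow-mode separation on the motivating system |
| number of tICs | 10 | — | GMRQ-sufficient kinetic subspace |
| microstates k | 200 | — | GMRQ-selected; scaled down proportionally on toy data |
| MSM lag | 15 | ns | implied-timescale convergence |
| core threshold | 0.8 | membership | noise-reduced state definitions |
| CV folds | 5 | — | standard; 3 on small toy runs |
| bootstrap resamples | 100 | — | SD estimates; 10–25 in fast configs |

All lags are declared in ns and must be integer multiples of the frame
spacing; every stochastic stage takes an explicit seed, and a fixed config
reproduces artifacts bit-for-bit.

## Known limitations

- PCCA+ omits the final crispness optimization; on systems without a clear
  spectral gap memberships can be sensitive to eigenvector noise.
- The bootstrap treats trajectories as exchangeable units; with very few
  trajectories the intervals are coarse.
- `run_pipeline` orchestrates the generated toy complex; external MD data is
  analyzed through the library/CLI stages (`featurize` → … → `characterize`)
  rather than the single orchestrator call.
- Representative-frame selection aligns to the ensemble mean structure (two
  passes); for ensembles with arbitrary global rotations the initial mean can
  be degenerate — pre-align such data first.
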