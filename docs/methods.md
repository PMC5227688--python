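# Methods

## Model

A drug–target network is a binary matrix `Y` (n_d drugs × n_t targets),
`Y_ij = 1` if drug *i* is known to interact with target *j*. Known
interactions are reliable; zeros are unlabeled, not confirmed
negatives. The model treats prediction as weighted logistic matrix
factorization on this implicit-feedback matrix, with two additions that
inject the similarity networks into the predictor itself.

Latent matrices `U` (n_d × r) and `V` (n_t × r) define logits

    x = α·UVᵀ + β·S_d·UVᵀ + γ·UVᵀ·S_t,   α + β + γ = 1,

where `S_d` and `S_t` are the *fused* drug and target networks
(below). The β term scores a pair highly when the drug's neighbors
like the target; the γ term, when the drug likes the target's
neighbors — a "trust ensemble" borrowed from social recommender
systems. Probabilities are `P = σ(x)`.

The objective is the augmented, penalized Bernoulli log-likelihood

    LL = Σ_ij [ c·Y_ij·x_ij − (1 + c·Y_ij − Y_ij)·log(1 + e^{x_ij}) ]
         − (λ_u/2)‖U‖²_F − (λ_v/2)‖V‖²_F ,

in which each observed interaction counts `c ≥ 1` times. The weight
counteracts the ~30:1 class imbalance of typical interaction matrices;
`c` enters as a cell weight in the likelihood rather than physical row
duplication, which reproduces the augmented objective exactly at
linear memory. The penalties are the negative log of zero-mean
spherical Gaussian priors on the latent rows.

Gradients (ascent direction), with `Q = c·Y − (1 + c·Y − Y)∘P`:

    ∂LL/∂U = (αI + β·S_dᵀ)·Q·V + γ·Q·S_tᵀ·V − λ_u·U
    ∂LL/∂V = Qᵀ·(αI + β·S_d)·U + γ·S_tᵀ·Qᵀ·U − λ_v·V

These are verified against central finite differences in the test
suite and by the acceptance script (max relative error ~1e-8 at step
1e-6).

## Pipeline

**Step 1 — profile inference.** Entities with all-zero profiles
("new" drugs/targets, which arise whenever rows, columns or cells are
masked) receive inferred profiles: the similarity-weighted mean of the
profiles of their `K = 5` most similar *known* neighbors, normalized by
the summed similarity. Neighbor pools exclude self and other new
entities (they have no information to lend); ties are broken by
ascending index for determinism. If every candidate similarity is
zero the profile stays zero with a warning — probability mass is not
invented. Inferred profiles are convex combinations of binary rows,
hence lie in [0, 1], and the operation is idempotent. They are used
as-is (not thresholded) in the kernel step.

**Step 2 — kernels.** The Gaussian interaction-profile (GIP) kernel
over rows (or columns) of the completed matrix uses
`K[i,j] = exp(−γ‖y_i − y_j‖²)` with bandwidth `γ = n / Σ_i ‖y_i‖²`,
i.e. the inverse mean squared profile norm. This makes the kernel
invariant to a global rescaling of the profiles (asserted as a
property test). The chemical and sequence similarity matrices are
converted to kernels by symmetrization, unit diagonal, and — only if
indefinite — eigenvalue clipping at zero followed by rescaling the
diagonal back to 1, the minimal change that makes a similarity matrix
a legal PSD kernel. Both the bandwidth convention and the PSD repair
are configurable (`psd_repair=False` passes through).

**Step 3 — cross-diffusion.** Kernel pairs `(K_d, K_c)` and
`(K_t, K_p)` are each fused by similarity network fusion. Global
transition matrices keep half their mass on self
(`P_ii = 1/2`, `P_ij = K_ij / 2Σ_{l≠i}K_il`); local affinity matrices
keep each row's `k = 3` nearest neighbors (self excluded) and
renormalize. Each of `t = 2` iterations simultaneously updates
`P1 ← L1·P2·L1ᵀ`, `P2 ← L2·P1·L2ᵀ` from the previous iterates, each
followed by the stabilization `(P + Pᵀ)/2 + I/2`, renormalized
row-stochastic. The fused output is the row-normalized average of the
two status matrices, symmetrized, with unit diagonal restored. The
order mean → row normalization → symmetrization → unit diagonal was
chosen because it guarantees the output invariants (symmetric,
nonnegative, unit diagonal) for any input pair; row-stochastic rather
than max-scaling normalization keeps the network terms of the
predictor on a fixed scale regardless of n. The whole update is
checked against a straight-line scalar-loop oracle on a fixed 3×3
pair, and is permutation-equivariant and exchange-symmetric
(`fuse(K1,K2) = fuse(K2,K1)`) by construction.

**Step 4 — fitting, smoothing, prediction.** `U`, `V` are initialized
from a seeded standard normal scaled by `1/√r` and updated by AdaGrad
ascent: per-element squared gradients accumulate from zero and the
update is `η·g/√(G + ε)`, `ε = 1e-8`, both matrices updated
simultaneously from the current iterate. The learning rate
(`η = 0.1`) and iteration count (100) follow the published defaults of
the logistic-MF lineage this model extends; fits are bit-reproducible
given the seed. After fitting, each new entity's latent row is
replaced by the similarity-weighted mean of its `K = 5` nearest known
neighbors' rows *in the fused network* — only `U`/`V` rows are
replaced; the `S_d`/`S_t` rows used by the predictor are left as
computed. Prediction applies the logistic link to the mixed logits;
ranked tables break score ties by drug then target identifier.

## Parameters

| name | default | meaning |
|---|---|---|
| `num_latent` (r) | 50 | latent dimension of U, V |
| `c` | 5 | weight on observed interactions (≥ 1) |
| `alpha, beta, gamma` | 0.5, 0.25, 0.25 | predictor mixing; must sum to 1 |
| `lambda_u, lambda_v` | 5, 1 | Gaussian-prior penalties |
| `k_smooth` (K) | 5 | neighbors for inference and smoothing |
| `learn_rate` | 0.1 | AdaGrad step size |
| `max_iter` | 100 | ascent iterations |
| `k_neighbors` | 3 | KNN size of the diffusion's local graphs |
| `n_iterations` | 2 | diffusion steps |

All similarity inputs are unitless in [0, 1]; logits and LL are in
nats.

## Evaluation protocol

Repeated 10-fold cross-validation under three settings: CVP (folds
over all n_d·n_t cells, positives and negatives together), CVR (folds
over drug rows), CVC (folds over target columns). Held-out cells are
zeroed in the training matrix and the *entire* pipeline — inference,
kernels, diffusion, fit, smoothing — is recomputed per fold from the
masked matrix, so the kernels cannot leak test information (audited in
the suite). Held-out cells are pooled per fold for AUC and AUPR:
pooling is the only way AUPR is well defined when an individual
held-out row or column is all-negative. AUPR defaults to the
step-wise sum `Σ(R_k − R_{k−1})·P_k` (identical to average
precision); a trapezoidal variant is available behind
`interpolate=True` — the two differ by ~1–2% on coarse curves, so the
choice is explicit. Per-trial shuffles derive their seeds as
`seed + trial`; per-fold model seeds as `seed + 1000·trial + fold`.

## Synthetic data generator

The generator emulates the data-generating process the model assumes,
so recovery tests are meaningful: latents `U*, V*` are standard normal
scaled by `1/√rank`; interaction probabilities are
`σ(s·√rank·⟨u_i, v_j⟩ + b)` and `Y` is a Bernoulli draw. The `√rank`
factor standardizes the inner products to unit variance so the logit
scale `s = 3` sets class separability independent of rank; it is
calibrated so the Bayes-optimal ranking (scoring by the true
probabilities) achieves AUC ≈ 0.95–0.96 — separable but not trivially
so. The intercept `b` is solved by bisection so the expected density
matches the requested sparsity (default 0.03, the density of the
classic benchmark subgroups). Similarity matrices are RBF kernels on
the true latent rows with median-heuristic bandwidth, plus optional
symmetrized Gaussian noise, clipped to [0, 1] with unit diagonal —
the simplest construction under which "similar drugs interact with
similar targets" is literally true, which is the assumption the β/γ
predictor terms encode.

What the generator does **not** emulate: the block/family structure,
degree heterogeneity and near-deterministic labels of curated
interaction databases, or the feature distributions of real
fingerprints and sequence families. Its labels are genuinely noisy
Bernoulli draws. Consequently recovery levels on synthetic data are
*not* forecasts of benchmark performance in either direction: at the
default study size (100×80, 3% density ≈ 240 interactions, ~2.4 per
drug) the realized labels are so sparse that cross-validated AUC
plateaus around 0.75–0.80 against a Bayes ceiling of ≈ 0.96, while the cold-start experiments show the intended, large
smoothing gain (held-out-row AUC ≈ 0.71 → 0.80). Passing tests
demonstrate internal correctness and the qualitative behavior of each
mechanism, not benchmark-level accuracy.

## Numerical choices

* `log(1 + e^x)` via `logaddexp`, logistic via a piecewise form; both
  exact to float precision for |x| up to ~745, no overflow.
* Degenerate rows: a transition-matrix row with no off-diagonal mass
  becomes the self-indicator; a KNN row with all-zero neighbor
  similarities falls back to uniform weights; both warn.
* Fits abort with a diagnostic naming the iteration if the objective
  becomes non-finite.
* Similarity validation: symmetry within 1e-8, values in [0, 1] within
  1e-6, unit diagonal; file readers symmetrize `(S + Sᵀ)/2` and log
  the maximum asymmetry.
* Problem sizes in the suite: unit tests run on matrices ≤ 40×30;
  statistical tests (recovery, null, cold-start) use 100×80 with a
  single 10-fold trial or 10 generator seeds — large enough for stable
  AUC estimates, small enough for interactive runs. The acceptance
  script uses 5×10-fold CVP on the same size.

## Known limitations

* Hyperparameters are fixed at the published empirical defaults; no
  search helper beyond manual overrides is included.
* Diffusion fuses exactly two kernels per entity type; multi-kernel
  fusion with learned weights is out of scope.
* The λ penalties are treated as the primitive regularization
  parameters; no fully Bayesian treatment of the prior variances.
* Smoothing replaces latent rows only; fused-network rows of new
  entities are used as computed.
* Chemical similarity from structures (fingerprint computation) and
  alignment-based sequence similarity are consumed as precomputed
  inputs; only Tanimoto-from-fingerprints and the k-mer spectrum
  kernel are built in.
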