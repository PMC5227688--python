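# dnilmf

Drug–target interaction (DTI) prediction by **dual-network integrated
logistic matrix factorization**: a recommender-style model for bipartite
drug–protein networks that folds drug–drug and target–target similarity
networks directly into the interaction predictor.

## Who this is for

Computational chemists and bioinformaticians who have a binary
interaction matrix `Y` (drugs × targets), a chemical-structure
similarity matrix `S_cs` between the drugs, and a sequence similarity
matrix `S_ts` between the targets — the standard benchmark layout — and
want ranked predictions for unobserved pairs, including for *new* drugs
or targets that have no known interactions at all (the cold-start
scenarios that arise whenever the network is split for validation).

## The model

The pipeline has four steps.

1. **Profile inference.** A drug or target whose row/column of `Y` is
   all zero gets an inferred interaction profile: the similarity-weighted
   mean of the profiles of its `K = 5` most similar known neighbors.
2. **Kernels.** From the completed profile matrix `Yi` the Gaussian
   interaction-profile (GIP) kernels `K_d` (drugs) and `K_t` (targets)
   are computed, `K[i,j] = exp(−γ‖y_i − y_j‖²)` with `γ = n / Σ‖y_i‖²`;
   `S_cs` and `S_ts` are repaired into valid kernels `K_c`, `K_p` by
   eigenvalue clipping.
3. **Diffusion.** Each kernel pair is fused by nonlinear cross-diffusion
   (similarity network fusion): each kernel's global transition matrix is
   iteratively propagated through the other's 3-nearest-neighbor graph
   for 2 iterations, yielding fused networks `S_d` and `S_t`.
4. **Factorization.** Interaction logits mix the latent factorization
   with both networks,

   ```
   x = α·UVᵀ + β·S_d·UVᵀ + γ·UVᵀ·S_t,      α + β + γ = 1,
   P(interaction) = 1 / (1 + e⁻ˣ),
   ```

   and `U`, `V` maximize a c-augmented Bernoulli log-likelihood (each
   observed interaction weighted `c = 5` fold against the unobserved
   majority) with Gaussian priors `λ_u‖U‖²_F/2`, `λ_v‖V‖²_F/2`, by
   AdaGrad gradient ascent. After fitting, latent vectors of new
   entities are replaced by similarity-weighted means of their nearest
   known neighbors in the fused networks.

Defaults: `numLatent = 50`, `c = 5`, `α = 0.5`, `β = γ = 0.25`,
`λ_u = 5`, `λ_v = 1`, `K = 5`.

Evaluation follows the field's protocol: repeated 10-fold
cross-validation over pairs (CVP), drug rows (CVR) or target columns
(CVC), scored by AUC and — because interaction matrices are extremely
imbalanced — AUPR.

## Worked example

The package ships a generator that produces datasets with exactly the
structure the model assumes (low-rank Bernoulli interactions plus
similarity networks coherent with the latent factors), so everything
below runs with no downloads:

```python
from dnilmf import (SyntheticSpec, generate, Hyperparams, DiffusionConfig,
                    run_cv, run_pipeline_fold, rank_novel, dataset_summary)

spec = SyntheticSpec(n_drugs=100, n_targets=80, rank=5,
                     target_sparsity=0.03, similarity_noise=0.1, seed=7)
ds, truth = generate(spec)
print(dataset_summary(ds))

res = run_cv(ds, Hyperparams(seed=7), setting="CVP", n_folds=10, n_trials=1, seed=7)
print(f"CVP: AUPR {res.mean_aupr:.3f} ± {res.sd_aupr:.3f}, "
      f"AUC {res.mean_auc:.3f} ± {res.sd_auc:.3f}")

model = run_pipeline_fold(ds.Y, ds.S_cs, ds.S_ts, Hyperparams(seed=7), DiffusionConfig())
for r in rank_novel(model, ds, top_n=3).records:
    print(r["rank"], r["drug_id"], r["target_id"], round(r["score"], 3))
```

prints

```
{'n_drugs': 100, 'n_targets': 80, 'n_interactions': 237, 'sparsity': 0.029625, 'sparsity_3dp': 0.03}
CVP: AUPR 0.107 ± 0.035, AUC 0.745 ± 0.045
1 D0058 T0025 0.862
2 D0058 T0040 0.819
3 D0015 T0048 0.76
```

The summary line reports the dataset density (3% of all drug–target
pairs are interactions). The cross-validated AUPR of 0.107 is ≈ 3.6×
the 0.03 prevalence — held-out interactions are strongly enriched at
the top of the ranking — while AUC 0.745 sits between chance (0.5) and
the Bayes-optimal ranking of this generator (≈ 0.96), reflecting how
little evidence ~2.4 interactions per drug leave for ranking cells that
were masked to zero during training. The last three lines are the
highest-scoring pairs *not* present in `Y`: the model's novel
predictions with their interaction probabilities.

The same pipeline is scriptable from the shell:

```bash
dnilmf simulate --drugs 100 --targets 80 --rank 5 --sparsity 0.03 --seed 7 --out-dir data/
dnilmf cv --adjacency data/Y.tsv --drug-sim data/S_cs.tsv --target-sim data/S_ts.tsv \
          --setting CVP --folds 10 --trials 5 --seed 42 --out results.json
dnilmf fit --adjacency data/Y.tsv --drug-sim data/S_cs.tsv --target-sim data/S_ts.tsv \
           --checkpoint model.npz
dnilmf predict --checkpoint model.npz --adjacency data/Y.tsv --top 50 --out novel.csv
```

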