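# buds — Bayesian Unidimensional Scaling

`buds` recovers a hidden one-dimensional ordering of samples — a
pseudotime, a depth gradient, an ideological spectrum — from their
pairwise dissimilarities, **with uncertainty**. It is aimed at
microbiome, gene-expression and similar high-dimensional datasets where
observations are generated by a continuous process but standard
ordinations (PCoA, t-SNE) give only point estimates and horseshoe-shaped
projections.

## The model

Each sample i gets a latent coordinate τ_i ∈ [0, 1]. Observed
dissimilarities are Gamma-distributed around latent 1-D distances, with
per-pair noise scales estimated from the data:

    d_ij ~ Gamma(μ_ij = b + ρ·|τ_i − τ_j|,  σ²_ij = s²_ij·σ_ε²)
    τ_i ~ Beta(α_τ, β_τ)
    α_τ, β_τ ~ Cauchy⁺(1, γ),  ρ ~ Cauchy⁺(1, γ),  b, σ_ε ~ Cauchy⁺(0, γ)

(shape = μ²/σ², rate = μ/σ²; all prior scales γ default to 2.5). The
relative noise scales s²_ij come from the empirical variance of distances
to the K nearest neighbors of each pair's endpoints, mean-normalized to 1,
so dissimilarities in sparse regions of the data count for less. The
posterior is fit by mean-field variational inference (an ensemble-MCMC
backend is available for calibration studies), and the draws feed every
downstream product: 95% HPD intervals per sample, heatmap seriation,
covariate association, feature trends, posterior trajectory plots, and
DiSTATIS registration of simulated posterior dissimilarity matrices into
density clouds and per-sample confidence contours.

See `docs/methods.md` for the full account of the model, its
assumptions and numerical choices.

## Worked example

```python
from scipy.stats import spearmanr
from buds import fit, generate_model_draw, orient, summarize

D, tau_true, _ = generate_model_draw(n=50, b=0.05, rho=1.0,
                                     sigma_eps=0.3, seed=11)
samples = orient(fit(D, seed=11, draws=500), D)
est = summarize(samples, mass=0.95)
print(spearmanr(est.tau_hat, tau_true).statistic)
```

Running `python examples/02_fit_latent_ordering.py` (which adds interval
summaries) prints:

```
Spearman rho(tau_hat, tau_true) = +0.995
posterior scalars: b = 0.063, rho = 0.929, sigma_eps = 0.315
95% HPDI widths: median 0.063, max 0.090
first 5 samples (tau_hat [hpdi]):
  s0: 0.173 [0.146, 0.205]
  ...
```

The Spearman correlation near 1 says the planted ordering was recovered
(its sign is an arbitrary reflection); the posterior scalars sit close to
the generating values (b = 0.05, ρ = 1, σ_ε = 0.3); each sample's
position on the latent interval comes with a 95% highest-density
interval, wider where the data are sparse.

The other scripts in `examples/` walk through the remaining
capabilities: metrics and noise scales (`01`), seriation / covariate
association / feature trends (`03`), and trajectory, DiSTATIS and
contour products (`04`). The same pipeline is scriptable from the shell:

```bash
buds simulate --mode counts --n 60 --seed 1 --out-prefix sim
buds dist --input sim.X.tsv --metric jaccard --kind counts \
          --K 10 --out D.tsv --scales-out S.tsv
buds fit --dist D.tsv --scales S.tsv --seed 1 --out-prefix run
buds products --input sim.X.tsv --kind counts --tau run.tau.tsv \
          --out-prefix prod
buds embed --dist D.tsv --draws run.draws.tsv --seed 1 --out-prefix emb
```

Real data enters as a features × samples TSV/CSV (first column = feature
ids, header = sample ids), or as a precomputed square dissimilarity
matrix.

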