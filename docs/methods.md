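# Methods

## Model

A count matrix Y (genes g = 1..G, samples j = 1..n, sample j belonging
to group i(j) ∈ 1..I) is modelled per gene and cluster as negative
binomial,

    y_gj | cluster k  ~  NB(mean = exp(s_j + μ_g + μ_{k,i(j)}),  var = m + φ_g m²),

with s_j a per-sample log offset from normalization, μ_g the gene's log
baseline expression, φ_g its dispersion, and μ_k = (μ_k1..μ_kI) the
cluster's vector of log group effects, constrained to Σ_i μ_ki = 0. The
mixture has weights π_k; posteriors p_gk follow by Bayes' rule with the
per-gene likelihood taken as the product over samples. DE calling picks
k\* = argmin_k ‖μ_k‖₂ as the non-DEG cluster and ranks genes ascending by
p_{g,k\*}.

Assumptions worth stating plainly: genes are exchangeable given their
(β, baseline, dispersion); a single cluster captures "no DE" (only the
argmin cluster is treated as non-DEG even if several norms are small —
the full norm vector is logged so users can audit); μ_g and φ_g are
treated as known during EM (profile approach, estimated once in
`prepare_data`); replicates are biological and independent.

## Estimation pipeline

1. **Normalization** produces size factors with geometric mean 1;
   s_j = log size factor.
   * Upper quartile: per-sample 75th percentile (linear interpolation
     between order statistics) over genes with nonzero total.
   * TMM: gene-wise log ratios M and abundances A against a reference
     sample (the one whose Q75 fraction is nearest the mean); 30% two-
     sided trim on M, 5% on A; inverse-delta-method-variance weighted
     mean of the surviving M. Verified against edgeR's
     `calcNormFactors` to 4+ decimals.
   * DEGES: TMM, then `n_iter` times (default 1): score each gene by
     |Δ adjusted log group means| / delta-method SE under a pooled
     method-of-moments dispersion, drop the top `elim_fraction`
     (default 0.25), recompute TMM on the rest with full-matrix library
     sizes. The scorer only needs a sensible ranking, not calibrated
     p-values; `n_iter=0` is exactly TMM.
2. **Preparation**: adjusted group means m_gi = Σ_j y_gj / Σ_j sf_j over
   group members; λ_gi = log(m_gi + 0.5) (the 0.5 pseudo-fraction keeps
   zero group means finite); μ_g = mean_i λ_gi and β̂_gi = λ_gi − μ_g
   (rows sum to zero exactly). Dispersions: per-gene method of moments
   on within-group residuals (small-sample corrected, floored at 1e-8),
   then shrunk 50/50 toward a mean–dispersion trend fitted by lowess in
   log–log space. Raw moment estimates at 3 replicates are far too noisy
   to use alone; the 50/50 blend keeps gene-specific signal while
   preventing zero-dispersion likelihood blow-ups.
3. **Initialization**: K-means++ in β̂ space (first center uniform, next
   centers ∝ squared distance to the nearest chosen center), seeded.
4. **EM**: E-step by log-sum-exp with per-gene-cluster log-likelihoods
   floored at −1e10; M-step sets π_k to mean posterior (optionally fixed
   at 1/K) and updates each center row by up to 2 sum-to-zero-
   constrained damped Newton steps (diagonal Hessian, Lagrange
   multiplier for the constraint, steps clipped to ±2, halved until the
   cluster's expected complete-data log-likelihood does not decrease).
   The constrained-with-halving update — rather than an unconstrained
   step followed by re-centering — is what keeps the observed-data
   log-likelihood trace monotone *and* centers exactly sum-zero; because
   μ_g is fixed, the model is not invariant to shifting a center row, so
   re-centering after a free step could lose likelihood. Stopping:
   relative log-likelihood change < 1e-6 (default) or 1000 iterations
   (flagged, not an error). A cluster whose maximum posterior falls
   below 1e-6 is re-seeded at the worst-explained gene, at most three
   times, and only if this does not lower the likelihood.

Degenerate inputs: all-zero genes are rejected by `prepare_data`
(filtered upstream with a logged count); K exceeding the number of
distinct β̂ rows is an error; ties in the norm argmin go to the lowest
index with a warning. Score ties in the ranking (posterior saturation at
0/1 is routine) are broken by descending ‖β̂_g‖, then gene id, so ranks
are reproducible; benchmark AUCs are computed on this rank vector.

## Simulator

`simulate_counts` draws, per gene, a (baseline mean, dispersion) pair
with replacement from a gene-parameter pool, marks the first
⌊G·p_deg⌋ genes as DEGs in contiguous blocks sized by largest-remainder
rounding of the assignment proportions (block i up-regulated in group
i), multiplies the up-group NB mean by the fold change (fixed, or
offset + Gamma(shape, scale) per gene), and samples counts. One seeded
generator drives pool sampling, fold-change draws and count draws in
that order, so equal seeds give byte-identical matrices. Baseline
parameters are re-drawn from the pool each trial.

The packaged default pool (2,000 pairs,
`data/synthetic_gene_param_pool.tsv`) is synthetic, drawn once from a
documented model — ln mean ~ N(2.5, 1.8²) clipped to [0.2, 5·10⁴];
dispersion trend 0.1 + 2/mean with log-normal scatter (σ = 0.4), clipped
to [0.01, 5] — chosen to resemble a real bulk RNA-seq matrix after
all-zero-gene removal: median count ≈ 12, roughly a third of genes with
mean < 5, biological CV ≈ 0.32 for highly expressed genes and rising at
low counts. It can be regenerated with `make_gene_parameter_pool()` or
replaced by a user TSV (`mean`, `dispersion` columns).

What the simulator does *not* emulate: sample-to-sample library-size
variation (all samples share expected depth, so true size factors are
1 — which is also what makes normalization accuracy directly
measurable), batch effects, gene–gene correlation, and the exact
empirical mean–dispersion table of any particular organism. Benchmark
statistics that sit on quantile knife-edges inherit the pool's shape:
the rate at which upper-quartile normalization misidentifies the non-DEG
cluster under strongly asymmetric DE flips when the half-log Q75
inflation crosses ln(FC)/4, and how far absorbed DEG blocks interleave
with non-DEGs in K < K_truth fits depends on the pool's dispersion
tails. Passing tests therefore demonstrate the mechanisms, not exact
rates on any real dataset.

## Defaults that matter

| parameter | default | units | why |
|---|---|---|---|
| K | 3 | clusters | one pattern per direction + non-DE for two groups |
| normalization | deges | — | robust to asymmetric DE; `uq` is the classic variant |
| elim_fraction | 0.25 | fraction | matches the DE-abundance regime DEGES targets |
| deges_iter | 1 | iterations | one elimination round; more rarely changes factors |
| TMM trims | 0.30 / 0.05 | quantiles | standard double-trim for M / A |
| pseudo | 0.5 | counts | keeps log of zero group means finite |
| dispersion shrink | 0.5 | weight | balance per-gene signal vs n=3 noise |
| max_iter / tol | 1000 / 1e-6 | — | relative log-likelihood stop; tightening to 1e-8 changes benchmark medians by < 0.001 |
| restarts | 1 | starts | K-means++ is near-deterministic on separated data; knob exposed |

Mixing proportions are estimated (initialized 1/K); `fixed_mixing=True`
fixes them.

## Benchmark harness

`run_benchmark` runs grid cells over seeded trials; trial t always uses
seed master + t, so methods compared on the same cell see identical
simulated data and any trial can be reproduced alone. AUC uses DEGs as
positives, "more DE = smaller score", ties counted 1/2 (Mann–Whitney);
`confusion_table` cross-tabulates hard cluster assignments against truth
patterns with per-cluster norms. Acceptance runs use 20 trials per cell
at G = 10,000 — enough that medians are stable to ~0.01 while a full
four-condition sweep stays under a minute.

## Known limitations

* With p_deg ≥ 0.5 the minimum-norm rule often picks a DEG cluster;
  the method is intended for datasets where DEGs are the minority.
* K must be chosen; K < K_truth merges a DEG block into the non-DEG
  cluster and caps the attainable AUC.
* Posterior saturation means the tail of the ranking is ordered mostly
  by the tie-break, not by the model.
* The EM finds local optima; a single K-means++ start is usually enough
  on well-separated data but `restarts` exists for a reason.
* No FDR/q-values: the method outputs a ranking and hard pattern calls,
  not calibrated error rates.
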