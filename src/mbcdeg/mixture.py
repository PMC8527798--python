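"""Negative-binomial mixture clustering of per-gene group-effect vectors.

Genes are represented by log-scale group effects ``beta_g = (beta_g1, ...,
beta_gI)`` relative to the gene's overall mean, constrained to sum to zero
across groups. A K-component mixture is fitted in which component k has a
center ``mu_k`` (also sum-zero) and the count of gene g in sample j of
group i is negative binomial with mean

    m_gjk = exp(s_j + mu_g + mu_{k,i})

where ``s_j`` is the sample's log size-factor offset, ``mu_g`` the gene's
log baseline expression and ``phi_g`` its dispersion (variance
``m + phi * m^2``). ``mu_g`` and ``phi_g`` are estimated once during data
preparation and held fixed (profile approach); the EM algorithm updates
the centers, mixing proportions and posterior membership probabilities.

The M-step center update is an equality-constrained damped Newton step on
each center row (sum-to-zero enforced through a Lagrange multiplier),
with step halving against the cluster's expected complete-data
log-likelihood, so the observed-data log-likelihood trace is
non-decreasing and centers remain exactly sum-zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix
from .normalization import NormalizationResult

__all__ = [
    "ClusterInput",
    "ClusterModel",
    "prepare_data",
    "kmeans_plus_init",
    "em_cluster",
    "NBMixtureCluster",
]

_LL_FLOOR = -1e10


@dataclass
class ClusterInput:
    """Per-gene model quantities consumed by the EM clustering.

    ``beta_hat`` rows sum to zero; genes with all-zero counts must have
    been filtered before preparation.
    """

    counts: np.ndarray
    groups: np.ndarray
    log_offsets: np.ndarray
    gene_baseline: np.ndarray
    gene_dispersion: np.ndarray
    beta_hat: np.ndarray
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        self.log_offsets = np.asarray(self.log_offsets, dtype=float)
        self.gene_baseline = np.asarray(self.gene_baseline, dtype=float)
        self.gene_dispersion = np.asarray(self.gene_dispersion, dtype=float)
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        if np.any(self.gene_dispersion < 0):
            raise ValueError("gene dispersions must be non-negative")
        if np.max(np.abs(self.beta_hat.sum(axis=1))) > 1e-8:
            raise ValueError("beta_hat rows must sum to zero")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_groups(self) -> int:
        return self.beta_hat.shape[1]


@dataclass
class ClusterModel:
    """A fitted K-component NB mixture over group-effect vectors."""

    K: int
    centers: np.ndarray
    mixing: np.ndarray
    posterior: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)


def prepare_data(
    counts: CountMatrix,
    norm: NormalizationResult,
    pseudo: float = 0.5,
    dispersion_shrink: float = 0.5,
    lowess_frac: float = 0.3,
) -> ClusterInput:
    """Derive per-gene baseline, dispersion and group effects.

    Offset-adjusted group means are ``m_gi = sum_j(y_gj) / sum_j(sf_j)``
    over samples j of group i; a pseudo-fraction ``pseudo`` is added
    before taking logs so genes with a zero group mean stay finite. The
    gene baseline is the across-group mean of the log-adjusted means and
    ``beta_hat`` the (exactly sum-zero) residuals. Dispersions come from
    a per-gene method-of-moments estimator on within-group residuals,
    floored at 1e-8 and shrunk (weight ``dispersion_shrink`` on the
    per-gene value) toward a mean-dependent trend fitted by lowess over
    genes — per-gene moment estimates at 3 replicates are too unstable to
    use raw.
    """
    y = counts.counts.astype(float)
    if np.any(y.sum(axis=1) == 0):
        g = int(np.argmax(y.sum(axis=1) == 0))
        raise ValueError(
            f"gene {counts.gene_ids[g]!r} has all-zero counts; "
            "filter such genes before clustering"
        )
    sf = norm.size_factors
    idx = counts.group_indices()
    n_groups = len(idx)
    group_means = np.stack(
        [y[:, ix].sum(axis=1) / sf[ix].sum() for ix in idx], axis=1
    )
    lam = np.log(group_means + pseudo)
    gene_baseline = lam.mean(axis=1)
    beta_hat = lam - gene_baseline[:, None]

    # method-of-moments dispersion on within-group residuals
    num = np.zeros(counts.n_genes)
    den = np.zeros(counts.n_genes)
    for i, ix in enumerate(idx):
        n_i = len(ix)
        mu_hat = group_means[:, [i]] * sf[ix][None, :]
        resid2 = (y[:, ix] - mu_hat) ** 2
        corr = n_i / max(n_i - 1, 1)
        num += resid2.sum(axis=1) * corr - mu_hat.sum(axis=1)
        den += (mu_hat**2).sum(axis=1)
    disp_raw = np.clip(num / np.maximum(den, 1e-12), 1e-8, None)

    # mean-dispersion trend via lowess in log-log space
    logm = gene_baseline
    logd = np.log(disp_raw + 1e-3)
    span = logm.max() - logm.min()
    fitted = lowess(
        logd,
        logm,
        frac=lowess_frac,
        delta=0.01 * span if span > 0 else 0.0,
        return_sorted=False,
    )
    trend = np.clip(np.exp(fitted) - 1e-3, 1e-4, None)
    dispersion = np.clip(
        dispersion_shrink * disp_raw + (1.0 - dispersion_shrink) * trend, 1e-8, None
    )

    return ClusterInput(
        counts=y,
        groups=counts.groups,
        log_offsets=norm.log_offsets,
        gene_baseline=gene_baseline,
        gene_dispersion=dispersion,
        beta_hat=beta_hat,
        gene_ids=counts.gene_ids,
    )


def kmeans_plus_init(
    data: ClusterInput, K: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """K-means++ seeding of K cluster centers in beta-hat space.

    The first center is a uniformly drawn gene vector; each subsequent
    center is drawn with probability proportional to the squared
    Euclidean distance to the nearest already-chosen center. Centers are
    re-centered to sum to zero per row (a no-op up to rounding, since the
    beta rows are themselves sum-zero).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    x = data.beta_hat
    if K > len(np.unique(x, axis=0)):
        raise ValueError("K exceeds the number of distinct beta vectors")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = x.shape[0]
    centers = np.empty((K, x.shape[1]))
    first = int(rng.integers(g))
    centers[0] = x[first]
    d2 = np.sum((x - centers[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers[k] = x[int(rng.integers(g))]
        else:
            probs = d2 / total
            centers[k] = x[int(rng.choice(g, p=probs))]
        d2 = np.minimum(d2, np.sum((x - centers[k]) ** 2, axis=1))
    return centers - centers.mean(axis=1, keepdims=True)


def _cluster_loglik(
    y: np.ndarray,
    base_log_mean: np.ndarray,
    r: np.ndarray,
    center: np.ndarray,
    groups: np.ndarray,
) -> np.ndarray:
    """Per-gene NB log-likelihood (without gene constants) at one center."""
    log_m = base_log_mean + center[groups][None, :]
    m = np.exp(log_m)
    return np.sum(y * log_m - (y + r) * np.log(r + m), axis=1)


def em_cluster(
    data: ClusterInput,
    init_centers: np.ndarray,
    model: str = "nbinom",
    max_iter: int = 1000,
    tol: float = 1e-6,
    fixed_mixing: bool = False,
    newton_steps: int = 2,
) -> ClusterModel:
    """Fit the NB mixture by EM from the given initial centers.

    E-step: posterior ``p_gk`` proportional to ``pi_k`` times the product
    over samples of NB densities at the cluster's center, computed via
    log-sum-exp. M-step: ``pi_k`` is the mean posterior (unless
    ``fixed_mixing``); each center row takes up to ``newton_steps``
    sum-zero-constrained damped Newton steps on the posterior-weighted NB
    log-likelihood. Iteration stops when the relative log-likelihood
    change falls below ``tol`` or after ``max_iter`` iterations (the
    latter flags ``converged=False`` rather than raising).

    A cluster whose maximum posterior falls below 1e-6 is re-seeded at the
    gene worst explained by the current model (at most 3 re-seeds, and
    only when re-seeding does not lower the observed-data log-likelihood).
    """
    if model != "nbinom":
        raise ValueError("only the negative-binomial model is supported")
    centers = np.asarray(init_centers, dtype=float).copy()
    if centers.ndim != 2 or centers.shape[1] != data.n_groups:
        raise ValueError("init_centers must be K x n_groups")
    if np.max(np.abs(centers.sum(axis=1))) > 1e-6:
        raise ValueError("init_centers rows must sum to (approximately) zero")
    centers -= centers.mean(axis=1, keepdims=True)
    K = centers.shape[0]
    y = data.counts
    g, n = y.shape
    groups = data.groups
    phi = np.maximum(data.gene_dispersion, 1e-12)
    r = (1.0 / phi)[:, None]
    base_log_mean = data.log_offsets[None, :] + data.gene_baseline[:, None]
    # per-gene terms independent of the cluster center
    const = np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0), axis=1
    ) + n * (r[:, 0] * np.log(r[:, 0]))
    const_total = float(const.sum())

    group_cols = [np.flatnonzero(groups == i) for i in range(data.n_groups)]
    mixing = np.full(K, 1.0 / K)
    loglik_trace: list[float] = []
    reseeds = 0
    converged = False

    def e_step(centers, mixing):
        ll = np.stack(
            [
                _cluster_loglik(y, base_log_mean, r, centers[k], groups)
                for k in range(K)
            ],
            axis=1,
        )
        ll = np.maximum(ll, _LL_FLOOR)
        if not np.all(np.isfinite(ll)):
            gi, ki = np.argwhere(~np.isfinite(ll))[0]
            name = data.gene_ids[gi] if data.gene_ids is not None else gi
            raise FloatingPointError(
                f"non-finite likelihood for gene {name!r} in cluster {ki + 1}"
            )
        logpost = np.log(mixing)[None, :] + ll
        norm = logsumexp(logpost, axis=1)
        post = np.exp(logpost - norm[:, None])
        total = float(norm.sum()) + const_total
        return ll, post, total

    ll_gk, post, total_ll = e_step(centers, mixing)
    it = 0
    for it in range(1, max_iter + 1):
        # ---- M-step ----
        if not fixed_mixing:
            mixing = np.clip(post.mean(axis=0), 1e-12, None)
            mixing = mixing / mixing.sum()
        for k in range(K):
            w = post[:, [k]]
            center = centers[k].copy()
            q_old = float(w[:, 0] @ _cluster_loglik(y, base_log_mean, r, center, groups))
            for _ in range(newton_steps):
                log_m = base_log_mean + center[groups][None, :]
                m = np.exp(log_m)
                frac = m / (r + m)
                grad_gj = y - (y + r) * frac
                hess_gj = -(y + r) * r * frac / (r + m)
                grad = np.array(
                    [(w * grad_gj[:, ix]).sum() for ix in group_cols]
                )
                hess = np.array(
                    [(w * hess_gj[:, ix]).sum() for ix in group_cols]
                )
                hess = np.minimum(hess, -1e-12)
                lam = np.sum(grad / hess) / np.sum(1.0 / hess)
                step = -(grad - lam) / hess
                step = np.clip(step, -2.0, 2.0)
                step -= step.mean()
                if np.max(np.abs(step)) < 1e-12:
                    break
                # damped: halve until the cluster Q-function does not drop
                accepted = False
                for _ in range(12):
                    cand = center + step
                    q_new = float(
                        w[:, 0]
                        @ _cluster_loglik(y, base_log_mean, r, cand, groups)
                    )
                    if q_new >= q_old - 1e-9 * (abs(q_old) + 1.0):
                        center, q_old, accepted = cand, q_new, True
                        break
                    step *= 0.5
                if not accepted:
                    break
            centers[k] = center
        # ---- E-step ----
        ll_gk, post, total_ll = e_step(centers, mixing)
        loglik_trace.append(total_ll)

        # empty-cluster rescue
        weak = np.flatnonzero(post.max(axis=0) < 1e-6)
        if len(weak) and reseeds < 3:
            cand_centers = centers.copy()
            worst_gene = int(np.argmin(post.max(axis=1)))
            for k in weak[: 3 - reseeds]:
                cand_centers[k] = data.beta_hat[worst_gene]
                cand_centers[k] -= cand_centers[k].mean()
            _, _, cand_ll = e_step(cand_centers, mixing)
            if cand_ll >= total_ll:
                reseeds += len(weak[: 3 - reseeds])
                centers = cand_centers
                ll_gk, post, total_ll = e_step(centers, mixing)
                loglik_trace[-1] = total_ll

        if len(loglik_trace) >= 2:
            prev = loglik_trace[-2]
            if abs(total_ll - prev) <= tol * (abs(prev) + 1.0):
                converged = True
                break

    if not converged and max_iter > 0:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations", RuntimeWarning
        )
    return ClusterModel(
        K=K,
        centers=centers,
        mixing=mixing,
        posterior=post,
        loglik_trace=np.asarray(loglik_trace),
        converged=converged,
        n_iter=it,
    )


class NBMixtureCluster(BaseEstimator):
    """Scikit-learn style estimator for the NB mixture clustering.

    Parameters
    ----------
    n_clusters : int
        Number of mixture components K.
    max_iter, tol : EM stopping rule (relative log-likelihood change).
    fixed_mixing : bool
        Keep mixing proportions at 1/K instead of estimating them.
    restarts : int
        Number of K-means++ initializations; the fit with the highest
        final log-likelihood is kept.
    random_state : int
        Seed for initialization.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        max_iter: int = 1000,
        tol: float = 1e-6,
        fixed_mixing: bool = False,
        restarts: int = 1,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.tol = tol
        self.fixed_mixing = fixed_mixing
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X: ClusterInput, y=None):
        """Fit the mixture to prepared cluster input."""
        if not isinstance(X, ClusterInput):
            raise TypeError(
                "NBMixtureCluster.fit expects a ClusterInput; use prepare_data()"
            )
        rng = np.random.default_rng(self.random_state)
        best: ClusterModel | None = None
        for _ in range(max(1, int(self.restarts))):
            centers0 = kmeans_plus_init(X, self.n_clusters, seed=rng)
            model = em_cluster(
                X,
                centers0,
                max_iter=self.max_iter,
                tol=self.tol,
                fixed_mixing=self.fixed_mixing,
            )
            if best is None or (
                len(model.loglik_trace)
                and model.loglik_trace[-1] > best.loglik_trace[-1]
            ):
                best = model
        self.model_ = best
        self.centers_ = best.centers
        self.mixing_ = best.mixing
        self.posterior_ = best.posterior
        self.loglik_trace_ = best.loglik_trace
        self.converged_ = best.converged
        self.labels_ = best.posterior.argmax(axis=1)
        return self

    def fit_predict(self, X: ClusterInput, y=None) -> np.ndarray:
        return self.fit(X).labels_
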