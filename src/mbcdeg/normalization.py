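"""Per-sample scaling-factor estimation for count matrices.

Three methods are provided:

* **upper quartile** — each sample is scaled by the 75th percentile of its
  counts (over genes expressed somewhere in the matrix). This is the
  default scaling used by the clustering pipeline ("MBCdeg1").
* **TMM** — trimmed mean of M-values against a reference sample, the
  standard relative scaling factor for composition-biased libraries.
* **DEGES** — DEG-elimination strategy: alternate TMM with removal of the
  genes most likely to be differentially expressed, then renormalize on
  the remainder. Robust when differential expression is abundant and
  one-sided ("MBCdeg2").

All methods return a :class:`NormalizationResult` whose ``size_factors``
have geometric mean 1 and whose ``log_offsets`` (the per-sample offsets
``s_j`` of the clustering model) are their logarithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix

__all__ = [
    "NormalizationResult",
    "upper_quartile_factors",
    "tmm_factors",
    "deges_factors",
    "factors_to_offsets",
    "UpperQuartileNormalizer",
    "TMMNormalizer",
    "DEGESNormalizer",
]


@dataclass
class NormalizationResult:
    """Per-sample scaling factors and model offsets.

    ``factors`` are the method's raw scaling factors (geometric mean 1).
    For the upper-quartile method the factor is itself an absolute depth
    proxy, so ``size_factors == factors``; for TMM/DEGES the factor is a
    relative (composition) adjustment and ``size_factors`` are
    ``factor * library_size``, rescaled to geometric mean 1. In both
    cases ``log_offsets = log(size_factors)``.
    """

    method: str
    factors: np.ndarray
    size_factors: np.ndarray
    log_offsets: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        self.log_offsets = np.asarray(self.log_offsets, dtype=float)
        if np.any(self.factors <= 0) or np.any(self.size_factors <= 0):
            raise ValueError("factors and size factors must be positive")
        if not np.allclose(self.log_offsets, np.log(self.size_factors)):
            raise ValueError("log_offsets must equal log(size_factors)")


def _geomean_one(x: np.ndarray) -> np.ndarray:
    return x / np.exp(np.mean(np.log(x)))


def _as_counts(counts) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(counts, CountMatrix):
        return counts.counts.astype(float), counts.sample_ids
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("counts must be 2-D (genes x samples)")
    return arr, None


def upper_quartile_factors(counts) -> NormalizationResult:
    """Upper-quartile (75th percentile) scaling factors.

    The percentile is taken per sample over genes with a nonzero total
    across samples, with linear interpolation between order statistics,
    then rescaled to geometric mean 1. A sample whose filtered upper
    quartile is zero raises an error naming the sample.
    """
    arr, sample_ids = _as_counts(counts)
    expressed = arr.sum(axis=1) > 0
    if not expressed.any():
        raise ValueError("no expressed genes in count matrix")
    q = np.quantile(arr[expressed], 0.75, axis=0, method="linear")
    if np.any(q <= 0):
        j = int(np.argmax(q <= 0))
        name = sample_ids[j] if sample_ids is not None else f"column {j}"
        raise ValueError(f"upper quartile of sample {name!r} is zero")
    factors = _geomean_one(q)
    return NormalizationResult(
        method="upper_quartile",
        factors=factors,
        size_factors=factors,
        log_offsets=np.log(factors),
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
    min_genes: int,
) -> float:
    """Log2 TMM factor of one sample against the reference."""
    ok = (obs > 0) & (ref > 0)
    if ok.sum() < min_genes:
        raise ValueError(
            f"only {int(ok.sum())} genes usable for TMM (need >= {min_genes})"
        )
    p_obs = obs[ok] / lib_obs
    p_ref = ref[ok] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic binomial (delta-method) variance of M
    w = (lib_obs - obs[ok]) / (lib_obs * obs[ok]) + (lib_ref - ref[ok]) / (
        lib_ref * ref[ok]
    )
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if keep.sum() < min_genes:
        raise ValueError(
            f"only {int(keep.sum())} genes left after TMM trimming "
            f"(need >= {min_genes})"
        )
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(
    counts,
    reference: int | str = "auto",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_genes: int = 10,
    library_sizes: np.ndarray | None = None,
) -> NormalizationResult:
    """Trimmed-mean-of-M-values relative scaling factors.

    For every sample, gene-wise log-ratios (M) and mean log-abundances (A)
    against a reference column are computed on library-size-normalized
    fractions; the extreme ``trim_m`` / ``trim_a`` quantile tails of each
    are discarded and the factor is the precision-weighted mean of the
    remaining M values. Factors are rescaled to geometric mean 1;
    ``size_factors`` fold the library sizes back in.

    ``reference="auto"`` picks the sample whose 75th-percentile fraction
    is closest to the across-sample mean.
    """
    arr, _ = _as_counts(counts)
    if arr.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    libs = arr.sum(axis=0) if library_sizes is None else np.asarray(
        library_sizes, dtype=float
    )
    if np.any(libs <= 0):
        raise ValueError("zero library size")
    if reference == "auto":
        expressed = arr.sum(axis=1) > 0
        uq = np.quantile(arr[expressed] / libs, 0.75, axis=0)
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = int(reference)
    log2f = np.array(
        [
            0.0
            if j == ref_j
            else _tmm_pair(arr[:, j], arr[:, ref_j], libs[j], libs[ref_j], trim_m, trim_a, min_genes)
            for j in range(arr.shape[1])
        ]
    )
    factors = _geomean_one(2.0 ** log2f)
    res = factors_to_offsets(factors, libs)
    return NormalizationResult(
        method="tmm",
        factors=factors,
        size_factors=res.size_factors,
        log_offsets=res.log_offsets,
    )


def _de_scores(
    arr: np.ndarray, groups: np.ndarray, size_factors: np.ndarray, pseudo: float = 0.5
) -> np.ndarray:
    """Two-group DE score used by DEGES for gene elimination.

    Absolute difference of offset-adjusted log group means divided by its
    delta-method standard error under a method-of-moments NB dispersion.
    For more than two groups, the score is the range of adjusted log
    means over groups divided by the largest pairwise standard error.
    Only a sensible *ranking* is required, not calibrated p-values.
    """
    adj = arr / size_factors
    n_groups = int(groups.max()) + 1
    idx = [np.flatnonzero(groups == i) for i in range(n_groups)]
    means = np.stack([adj[:, ix].mean(axis=1) for ix in idx], axis=1)
    # pooled method-of-moments dispersion, clipped at 0
    num = np.zeros(arr.shape[0])
    den = np.zeros(arr.shape[0])
    for i, ix in enumerate(idx):
        n_i = len(ix)
        resid2 = (adj[:, ix] - means[:, [i]]) ** 2
        corr = n_i / max(n_i - 1, 1)
        num += resid2.sum(axis=1) * corr - n_i * means[:, i]
        den += n_i * means[:, i] ** 2
    phi = np.clip(num / np.maximum(den, 1e-12), 0.0, None)
    var = np.stack(
        [
            (1.0 / np.maximum(means[:, i], pseudo) + phi) / len(idx[i])
            for i in range(n_groups)
        ],
        axis=1,
    )
    logm = np.log(means + pseudo)
    spread = logm.max(axis=1) - logm.min(axis=1)
    se = np.sqrt(var.sum(axis=1))
    return spread / np.maximum(se, 1e-12)


def deges_factors(
    counts,
    groups: np.ndarray | None = None,
    n_iter: int = 1,
    elim_fraction: float = 0.25,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_genes: int = 10,
) -> NormalizationResult:
    """DEG-elimination-strategy scaling factors.

    Starting from plain TMM, each iteration scores every gene for putative
    differential expression under the current factors, removes the top
    ``elim_fraction`` of genes, and recomputes TMM on the remainder (library
    sizes are kept at their full-matrix values so the factors stay
    applicable to the full gene set). ``n_iter=0`` reproduces TMM exactly.
    """
    if isinstance(counts, CountMatrix):
        if groups is None:
            groups = counts.groups
    if groups is None:
        raise ValueError("group labels are required for DEGES")
    arr, _ = _as_counts(counts)
    groups = np.asarray(groups, dtype=int)
    if not 0.0 <= elim_fraction < 1.0:
        raise ValueError("elim_fraction must lie in [0, 1)")
    libs = arr.sum(axis=0)
    res = tmm_factors(arr, trim_m=trim_m, trim_a=trim_a, min_genes=min_genes)
    for _ in range(int(n_iter)):
        scores = _de_scores(arr, groups, res.size_factors)
        cutoff = np.quantile(scores, 1.0 - elim_fraction)
        keep = scores < cutoff
        if not keep.any():
            raise ValueError("DEG elimination would remove all genes")
        res = tmm_factors(
            arr[keep],
            trim_m=trim_m,
            trim_a=trim_a,
            min_genes=min_genes,
            library_sizes=libs,
        )
    return NormalizationResult(
        method="deges",
        factors=res.factors,
        size_factors=res.size_factors,
        log_offsets=res.log_offsets,
    )


def factors_to_offsets(factors, library_sizes) -> NormalizationResult:
    """Convert relative factors into size factors and model log offsets.

    ``size_factor_j = factor_j * library_size_j``, rescaled to geometric
    mean 1; ``log_offsets = log(size_factors)``.
    """
    factors = np.asarray(factors, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    if np.any(libs <= 0):
        raise ValueError("zero library size")
    size_factors = _geomean_one(factors * libs)
    return NormalizationResult(
        method="size_factors",
        factors=_geomean_one(factors),
        size_factors=size_factors,
        log_offsets=np.log(size_factors),
    )


def normalize(counts, method: str = "deges", groups=None, **kwargs) -> NormalizationResult:
    """Dispatch to one of the factor methods by name (uq|tmm|deges)."""
    method = {"uq": "upper_quartile"}.get(method, method)
    if method == "upper_quartile":
        return upper_quartile_factors(counts)
    if method == "tmm":
        return tmm_factors(counts, **kwargs)
    if method == "deges":
        return deges_factors(counts, groups=groups, **kwargs)
    raise ValueError(f"unknown normalization method {method!r}")


class _NormalizerBase(TransformerMixin, BaseEstimator):
    """Shared fit/transform plumbing for the scaling-factor estimators."""

    def fit(self, X, y=None, **fit_params):
        res = self._compute(X, **fit_params)
        self.result_ = res
        self.factors_ = res.factors
        self.size_factors_ = res.size_factors
        self.log_offsets_ = res.log_offsets
        self.n_features_in_ = _as_counts(X)[0].shape[0]
        return self

    def transform(self, X):
        """Divide each sample's counts by its fitted size factor."""
        if not hasattr(self, "size_factors_"):
            raise ValueError("normalizer is not fitted")
        arr, _ = _as_counts(X)
        return arr / self.size_factors_


class UpperQuartileNormalizer(_NormalizerBase):
    """Upper-quartile scaling (the MBCdeg1 default)."""

    def _compute(self, X, **fit_params):
        return upper_quartile_factors(X)


class TMMNormalizer(_NormalizerBase):
    """Trimmed mean of M-values scaling."""

    def __init__(self, reference="auto", trim_m=0.30, trim_a=0.05, min_genes=10):
        self.reference = reference
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.min_genes = min_genes

    def _compute(self, X, **fit_params):
        return tmm_factors(
            X,
            reference=self.reference,
            trim_m=self.trim_m,
            trim_a=self.trim_a,
            min_genes=self.min_genes,
        )


class DEGESNormalizer(_NormalizerBase):
    """DEG-elimination-strategy scaling (the MBCdeg2 normalizer)."""

    def __init__(self, n_iter=1, elim_fraction=0.25, trim_m=0.30, trim_a=0.05,
                 min_genes=10):
        self.n_iter = n_iter
        self.elim_fraction = elim_fraction
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.min_genes = min_genes

    def fit(self, X, y=None, *, groups=None):
        return super().fit(X, groups=groups)

    def _compute(self, X, groups=None):
        return deges_factors(
            X,
            groups=groups,
            n_iter=self.n_iter,
            elim_fraction=self.elim_fraction,
            trim_m=self.trim_m,
            trim_a=self.trim_a,
            min_genes=self.min_genes,
        )
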