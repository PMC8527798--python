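"""Differential-expression calling from a fitted NB mixture.

The cluster whose center has the smallest Euclidean (L2) norm across
groups is taken to hold the non-differential genes; every gene is then
scored by its posterior probability of belonging to that cluster — a
*small* posterior means a *high* degree of differential expression — and
the genes are ranked ascending by that score. For two-group designs,
genes outside the non-DEG cluster are labelled DEG1 or DEG2 by the sign
pattern of their assigned cluster's center.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import CountMatrix
from .mixture import ClusterInput, ClusterModel, NBMixtureCluster, prepare_data
from .normalization import DEGESNormalizer, TMMNormalizer, UpperQuartileNormalizer

__all__ = [
    "DEResult",
    "cluster_norms",
    "identify_nondeg_cluster",
    "rank_genes",
    "assign_patterns",
    "MBCdeg",
    "run_mbcdeg",
]

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Ranked differential-expression calls.

    ``table`` has one row per gene: gene_id, score (posterior in the
    non-DEG cluster), rank (1 = most differentially expressed),
    assigned_cluster (1-based argmax-posterior cluster) and pattern.
    """

    table: pd.DataFrame
    cluster_norms: np.ndarray
    nondeg_cluster: int
    centers: np.ndarray
    mixing: np.ndarray

    def summary(self) -> dict:
        """JSON-serializable model summary."""
        return {
            "n_genes": int(len(self.table)),
            "K": int(self.centers.shape[0]),
            "centers": self.centers.tolist(),
            "cluster_norms": self.cluster_norms.tolist(),
            "nondeg_cluster": int(self.nondeg_cluster) + 1,
            "mixing": self.mixing.tolist(),
            "pattern_counts": self.table["pattern"].value_counts().to_dict(),
        }


def cluster_norms(centers: np.ndarray) -> np.ndarray:
    """Euclidean norm of each cluster center across groups."""
    centers = np.asarray(centers, dtype=float)
    return np.linalg.norm(centers, axis=1)


def identify_nondeg_cluster(norms: np.ndarray) -> int:
    """Index (0-based) of the minimum-norm cluster.

    Ties are broken by the lowest index, with a warning, since the choice
    then determines the whole gene ranking.
    """
    norms = np.asarray(norms, dtype=float)
    if np.any(np.isnan(norms)):
        raise ValueError("NaN in cluster norms")
    k = int(np.argmin(norms))
    if np.sum(norms == norms[k]) > 1:
        warnings.warn(
            "multiple clusters tie for the smallest center norm; "
            "using the lowest index",
            RuntimeWarning,
        )
    return k


def rank_genes(
    model: ClusterModel,
    nondeg: int,
    gene_ids: np.ndarray | None = None,
    beta_hat: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rank genes ascending by non-DEG-cluster posterior (most DE first).

    Ties in the posterior (saturation at 0/1 is common) are broken by
    descending gene-effect norm ``||beta_g||`` when ``beta_hat`` is given,
    then by gene id, so rankings are reproducible.
    """
    post = model.posterior
    g = post.shape[0]
    if gene_ids is None:
        gene_ids = np.array([f"gene_{i + 1}" for i in range(g)], dtype=object)
    score = post[:, nondeg]
    beta_norm = (
        np.linalg.norm(beta_hat, axis=1) if beta_hat is not None else np.zeros(g)
    )
    df = pd.DataFrame(
        {
            "gene_id": list(map(str, gene_ids)),
            "score": score,
            "assigned_cluster": post.argmax(axis=1) + 1,
            "_beta_norm": beta_norm,
        }
    )
    df = df.sort_values(
        ["score", "_beta_norm", "gene_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, g + 1)
    order = pd.Index(df["gene_id"]).get_indexer(list(map(str, gene_ids)))
    df = df.iloc[order].reset_index(drop=True)
    return df.drop(columns="_beta_norm")


def assign_patterns(model: ClusterModel, nondeg: int, n_groups: int) -> np.ndarray:
    """Per-gene pattern labels from cluster membership.

    Genes assigned (argmax posterior) to the non-DEG cluster are
    ``nonDEG``. For two groups, other genes are ``DEG1`` if their
    cluster's center is up in group 1 (``mu_k1 > mu_k2``) else ``DEG2``.
    For more than two groups the label is the assigned cluster index with
    its center signature, e.g. ``cluster2(+,-,0)``.
    """
    assigned = model.posterior.argmax(axis=1)
    labels = np.empty(len(assigned), dtype=object)
    for k in range(model.K):
        mask = assigned == k
        if not mask.any():
            continue
        if k == nondeg:
            labels[mask] = "nonDEG"
        elif n_groups == 2:
            labels[mask] = "DEG1" if model.centers[k, 0] > model.centers[k, 1] else "DEG2"
        else:
            sig = ",".join(
                "+" if c > 0.05 else ("-" if c < -0.05 else "0")
                for c in model.centers[k]
            )
            labels[mask] = f"cluster{k + 1}({sig})"
    return labels


_NORMALIZERS = {
    "uq": UpperQuartileNormalizer,
    "upper_quartile": UpperQuartileNormalizer,
    "tmm": TMMNormalizer,
    "deges": DEGESNormalizer,
}


class MBCdeg(BaseEstimator):
    """Cluster-based differential-expression caller.

    Normalizes a count matrix, clusters the genes' log group-effect
    vectors with a K-component negative-binomial mixture, declares the
    minimum-norm cluster non-differential, and ranks genes by their
    posterior probability of belonging to it. ``normalization="uq"``
    gives the MBCdeg1 variant, ``"deges"`` MBCdeg2.

    Parameters
    ----------
    k : int
        Number of mixture components (3 covers up-in-group-1,
        up-in-group-2 and non-DE patterns of a two-group design).
    normalization : {"uq", "tmm", "deges"}
    deges_iter, elim_fraction : DEGES settings (ignored otherwise).
    max_iter, tol, restarts, fixed_mixing : EM settings.
    random_state : int
        Seed for cluster initialization.

    Attributes (after ``fit``)
    --------------------------
    centers_, mixing_, posterior_, norms_, nondeg_cluster_ (0-based),
    scores_, ranks_, patterns_, labels_, result_ (:class:`DEResult`).
    """

    def __init__(
        self,
        k: int = 3,
        normalization: str = "deges",
        deges_iter: int = 1,
        elim_fraction: float = 0.25,
        max_iter: int = 1000,
        tol: float = 1e-6,
        restarts: int = 1,
        fixed_mixing: bool = False,
        random_state: int = 0,
    ):
        self.k = k
        self.normalization = normalization
        self.deges_iter = deges_iter
        self.elim_fraction = elim_fraction
        self.max_iter = max_iter
        self.tol = tol
        self.restarts = restarts
        self.fixed_mixing = fixed_mixing
        self.random_state = random_state

    def _make_normalizer(self):
        try:
            cls = _NORMALIZERS[self.normalization]
        except KeyError:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; "
                f"choose from {sorted(_NORMALIZERS)}"
            ) from None
        if cls is DEGESNormalizer:
            return cls(n_iter=self.deges_iter, elim_fraction=self.elim_fraction)
        return cls()

    def fit(self, X, y=None, *, groups=None, gene_ids=None):
        """Fit on a :class:`CountMatrix`, or an array plus ``groups``."""
        if isinstance(X, CountMatrix):
            cm = X
        else:
            arr = np.asarray(X)
            if groups is None:
                raise ValueError("groups are required when X is a plain array")
            if gene_ids is None:
                gene_ids = [f"gene_{i + 1}" for i in range(arr.shape[0])]
            cm = CountMatrix(
                arr,
                gene_ids,
                [f"sample_{j + 1}" for j in range(arr.shape[1])],
                groups,
            )
        cm, removed = cm.drop_all_zero_genes()
        if removed:
            logger.info("dropped %d all-zero genes before clustering", removed)

        self.normalizer_ = self._make_normalizer()
        if isinstance(self.normalizer_, DEGESNormalizer):
            self.normalizer_.fit(cm, groups=cm.groups)
        else:
            self.normalizer_.fit(cm)
        data = prepare_data(cm, self.normalizer_.result_)

        clusterer = NBMixtureCluster(
            n_clusters=self.k,
            max_iter=self.max_iter,
            tol=self.tol,
            fixed_mixing=self.fixed_mixing,
            restarts=self.restarts,
            random_state=self.random_state,
        ).fit(data)
        model = clusterer.model_

        norms = cluster_norms(model.centers)
        nondeg = identify_nondeg_cluster(norms)
        table = rank_genes(model, nondeg, cm.gene_ids, beta_hat=data.beta_hat)
        table["pattern"] = assign_patterns(model, nondeg, cm.n_groups)
        for k in range(model.K):
            table[f"pp_cluster{k + 1}"] = model.posterior[:, k]

        logger.info(
            "cluster center norms: %s; non-DEG cluster: %d; converged: %s",
            np.round(norms, 4).tolist(),
            nondeg + 1,
            model.converged,
        )
        self.input_ = data
        self.model_ = model
        self.centers_ = model.centers
        self.mixing_ = model.mixing
        self.posterior_ = model.posterior
        self.converged_ = model.converged
        self.norms_ = norms
        self.nondeg_cluster_ = nondeg
        self.scores_ = table["score"].to_numpy()
        self.ranks_ = table["rank"].to_numpy()
        self.patterns_ = table["pattern"].to_numpy()
        self.labels_ = model.posterior.argmax(axis=1)
        self.gene_ids_ = cm.gene_ids
        self.result_ = DEResult(
            table=table,
            cluster_norms=norms,
            nondeg_cluster=nondeg,
            centers=model.centers,
            mixing=model.mixing,
        )
        return self

    def fit_predict(self, X, y=None, **fit_params) -> np.ndarray:
        """Fit and return per-gene pattern labels."""
        return self.fit(X, **fit_params).patterns_


def run_mbcdeg(
    counts: CountMatrix,
    k: int = 3,
    normalization: str = "deges",
    seed: int = 0,
    **kwargs,
) -> DEResult:
    """One-call pipeline: normalize, cluster, call DE. Returns DEResult."""
    est = MBCdeg(k=k, normalization=normalization, random_state=seed, **kwargs)
    est.fit(counts)
    return est.result_
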