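"""Simulation of RNA-seq count matrices with known differential-expression truth.

The generator reproduces the standard two-condition (or multi-condition)
benchmark design for count-based differential expression: a fixed fraction
``p_deg`` of genes is differentially expressed, the DEGs are partitioned
among the groups by the assignment proportions ``deg_assign`` (block ``i``
is up-regulated in group ``i``), and the up-regulated group's negative
binomial mean is multiplied by a fold change — either a fixed value or a
draw from a shifted gamma distribution.

Per-gene baseline means and dispersions are sampled from a gene-parameter
pool. The packaged default pool is synthetic: it is drawn once from a
documented parametric model (log-normal means; dispersion decreasing with
mean plus log-normal scatter) calibrated to look like a typical bulk
RNA-seq matrix after all-zero genes are removed. A user-supplied pool
(TSV with columns ``mean`` and ``dispersion``) may be used instead.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "GammaFC",
    "SimulationConfig",
    "SimulationTruth",
    "make_fc_matrix",
    "simulate_counts",
    "make_gene_parameter_pool",
    "load_gene_parameter_pool",
    "largest_remainder_partition",
]

_POOL_RESOURCE = "synthetic_gene_param_pool.tsv"

NONDEG_LABEL = "nonDEG"


@dataclass(frozen=True)
class GammaFC:
    """Shifted-gamma fold-change spec: FC = offset + Gamma(shape, scale).

    With the conventional values (offset=1.2, shape=2.0, scale=0.5) the
    fold changes have minimum 1.2 and mean 2.2.
    """

    offset: float = 1.2
    shape: float = 2.0
    scale: float = 0.5

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValueError("gamma fold-change offset must be >= 1")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.offset + self.shape * self.scale

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.offset + rng.gamma(self.shape, self.scale, size=size)


FCSpec = Union[float, GammaFC]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one simulated count matrix.

    Parameters
    ----------
    n_genes : int
        Number of genes G.
    replicates : sequence of int
        Samples per group (n_1, ..., n_I).
    p_deg : float
        Fraction of genes that are truly differentially expressed.
    deg_assign : sequence of float
        Proportion of DEGs up-regulated in each group; must sum to 1.
    fc_spec : float or GammaFC
        Fixed fold change (>= 1) or a shifted-gamma spec.
    seed : int
        Seed for the single generator driving pool sampling, fold-change
        draws and count draws (consumed in that order).
    """

    n_genes: int
    replicates: tuple[int, ...]
    p_deg: float
    deg_assign: tuple[float, ...]
    fc_spec: FCSpec = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicates", tuple(int(r) for r in self.replicates))
        object.__setattr__(self, "deg_assign", tuple(float(p) for p in self.deg_assign))
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.replicates) < 1 or any(r < 1 for r in self.replicates):
            raise ValueError("every group needs at least one replicate")
        if not 0.0 <= self.p_deg <= 1.0:
            raise ValueError("p_deg must lie in [0, 1]")
        if len(self.deg_assign) != len(self.replicates):
            raise ValueError("deg_assign must give one proportion per group")
        if any(p < 0 for p in self.deg_assign):
            raise ValueError("deg_assign proportions must be non-negative")
        if abs(sum(self.deg_assign) - 1.0) > 1e-12:
            raise ValueError("deg_assign must sum to 1")
        if isinstance(self.fc_spec, (int, float)) and self.fc_spec < 1:
            raise ValueError("fixed fold change must be >= 1")

    @property
    def n_groups(self) -> int:
        return len(self.replicates)

    @property
    def n_samples(self) -> int:
        return sum(self.replicates)


@dataclass
class SimulationTruth:
    """Per-gene true pattern labels and the fold-change matrix.

    ``pattern[g]`` is ``"DEGi"`` (1-based group) for a gene up-regulated
    in group i and ``"nonDEG"`` otherwise. ``fc_matrix`` is genes x groups
    with the multiplier applied to the NB mean (1 everywhere except the
    up-group of a DEG).
    """

    pattern: np.ndarray
    fc_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=object)
        self.fc_matrix = np.asarray(self.fc_matrix, dtype=float)
        if self.fc_matrix.shape[0] != len(self.pattern):
            raise ValueError("pattern and fc_matrix row counts differ")

    @property
    def is_deg(self) -> np.ndarray:
        """Boolean DEG indicator per gene."""
        return self.pattern != NONDEG_LABEL

    def pattern_counts(self) -> dict[str, int]:
        """Counts per pattern label in DEG1..DEGI, nonDEG order."""
        n_groups = self.fc_matrix.shape[1]
        labels = [f"DEG{i + 1}" for i in range(n_groups)] + [NONDEG_LABEL]
        return {lab: int(np.sum(self.pattern == lab)) for lab in labels}


def largest_remainder_partition(total: int, proportions: Sequence[float]) -> np.ndarray:
    """Split ``total`` into integer parts proportional to ``proportions``.

    Uses largest-remainder rounding so the parts always sum to ``total``
    exactly; ties in remainders go to the earlier index.
    """
    props = np.asarray(proportions, dtype=float)
    quotas = total * props
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    if short:
        remainders = quotas - base
        # stable sort => earlier index wins on equal remainders
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def _resolve_fc_spec(fc_spec: FCSpec) -> FCSpec:
    if isinstance(fc_spec, GammaFC):
        return fc_spec
    fc = float(fc_spec)
    if fc < 1:
        raise ValueError("fixed fold change must be >= 1")
    return fc


def make_fc_matrix(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationTruth:
    """Build the per-gene truth labels and fold-change matrix.

    The first ``floor(G * p_deg)`` genes are DEGs, laid out as contiguous
    blocks: block i (sized by largest-remainder rounding of the
    ``deg_assign`` proportions) is up-regulated in group i. A fixed
    fold-change spec fills each DEG's up-group cell with that value; a
    :class:`GammaFC` spec draws one multiplier per DEG.
    """
    fc_spec = _resolve_fc_spec(config.fc_spec)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g, n_groups = config.n_genes, config.n_groups
    n_deg = int(np.floor(g * config.p_deg))
    block_sizes = largest_remainder_partition(n_deg, config.deg_assign)

    pattern = np.full(g, NONDEG_LABEL, dtype=object)
    fc_matrix = np.ones((g, n_groups), dtype=float)
    start = 0
    for i, size in enumerate(block_sizes):
        stop = start + int(size)
        pattern[start:stop] = f"DEG{i + 1}"
        if isinstance(fc_spec, GammaFC):
            fc_matrix[start:stop, i] = fc_spec.draw(rng, stop - start)
        else:
            fc_matrix[start:stop, i] = fc_spec
        start = stop
    return SimulationTruth(pattern=pattern, fc_matrix=fc_matrix)


def make_gene_parameter_pool(
    n: int = 2000,
    seed: int = 20210825,
    meanlog: float = 2.5,
    sdlog: float = 1.8,
    mean_range: tuple[float, float] = (0.2, 5e4),
    disp_asymptote: float = 0.1,
    disp_slope: float = 2.0,
    disp_scatter: float = 0.4,
    disp_range: tuple[float, float] = (0.01, 5.0),
) -> pd.DataFrame:
    """Draw a synthetic (mean, dispersion) gene-parameter pool.

    Means are log-normal (``ln m ~ N(meanlog, sdlog^2)``, clipped to
    ``mean_range``), mimicking the right-skewed expression distribution of
    a real count matrix after all-zero genes are dropped (median around
    a dozen counts, a long high-expression tail). Dispersions follow the
    familiar decreasing mean-dispersion trend
    ``phi = asymptote + slope / mean`` with multiplicative log-normal
    scatter, clipped to ``disp_range``; the asymptote of 0.1 corresponds
    to a biological coefficient of variation of about 0.32 for highly
    expressed genes.
    """
    rng = np.random.default_rng(seed)
    means = np.exp(rng.normal(meanlog, sdlog, size=n))
    means = np.clip(means, *mean_range)
    trend = disp_asymptote + disp_slope / means
    disps = trend * np.exp(rng.normal(0.0, disp_scatter, size=n))
    disps = np.clip(disps, *disp_range)
    return pd.DataFrame({"mean": means, "dispersion": disps})


def load_gene_parameter_pool(path: str | Path | None = None) -> pd.DataFrame:
    """Load a gene-parameter pool TSV (columns ``mean``, ``dispersion``).

    With no path, loads the packaged synthetic default pool.
    """
    if path is None:
        ref = importlib.resources.files("mbcdeg.data") / _POOL_RESOURCE
        with importlib.resources.as_file(ref) as p:
            pool = pd.read_csv(p, sep="\t")
    else:
        pool = pd.read_csv(path, sep="\t")
    missing = {"mean", "dispersion"} - set(pool.columns)
    if missing:
        raise ValueError(f"gene-parameter pool lacks columns: {sorted(missing)}")
    if (pool["mean"] <= 0).any() or (pool["dispersion"] < 0).any():
        raise ValueError("pool means must be positive and dispersions non-negative")
    return pool[["mean", "dispersion"]].reset_index(drop=True)


def simulate_counts(
    config: SimulationConfig,
    pool: pd.DataFrame | None = None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate a count matrix with known DE truth.

    For each gene a (baseline mean, dispersion) pair is sampled with
    replacement from the gene-parameter pool; each sample's count is a
    negative binomial draw with mean ``baseline * fc_matrix[g, group(j)]``
    and the gene's dispersion (variance ``m + phi * m^2``). One seeded
    generator drives pool sampling, fold-change draws and count draws, in
    that order, so equal seeds give identical output.
    """
    if pool is None:
        pool = load_gene_parameter_pool()
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    rows = rng.integers(0, len(pool), size=g)
    base_mean = pool["mean"].to_numpy()[rows]
    dispersion = pool["dispersion"].to_numpy()[rows]

    truth = make_fc_matrix(config, rng=rng)

    groups = np.repeat(np.arange(config.n_groups), config.replicates)
    mean = base_mean[:, None] * truth.fc_matrix[:, groups]
    phi = dispersion[:, None]
    with np.errstate(divide="ignore"):
        r = np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), np.inf)
    counts = np.empty(mean.shape, dtype=np.int64)
    nb = phi > 0
    nb_full = np.broadcast_to(nb, mean.shape)
    if nb.any():
        p = np.broadcast_to(r, mean.shape)[nb_full] / (
            np.broadcast_to(r, mean.shape)[nb_full] + mean[nb_full]
        )
        counts[nb_full] = rng.negative_binomial(
            np.broadcast_to(r, mean.shape)[nb_full], p
        )
    if (~nb).any():
        counts[~nb_full] = rng.poisson(mean[~nb_full])

    gene_ids = np.array([f"gene_{i + 1}" for i in range(g)], dtype=object)
    sample_ids = np.array(
        [
            f"G{i + 1}_rep{j + 1}"
            for i, n in enumerate(config.replicates)
            for j in range(n)
        ],
        dtype=object,
    )
    cm = CountMatrix(counts, gene_ids, sample_ids, groups)
    return cm, truth
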