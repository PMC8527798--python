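"""Reading and writing count matrices, group maps and result files.

Count matrices are tab-delimited text with gene identifiers in the first
column and sample identifiers in the header (CSV is auto-detected from a
``.csv`` extension). Results are written as a TSV of per-gene calls plus
a JSON model summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import DEResult
from .containers import CountMatrix
from .simulate import SimulationTruth

__all__ = [
    "read_counts",
    "write_counts",
    "read_group_map",
    "write_results",
    "read_results",
    "write_truth",
    "collapse_technical_replicates",
]

logger = logging.getLogger(__name__)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_groups(sample_ids: Sequence[str], group_spec) -> np.ndarray:
    """Map a group spec (list of labels or sample->label mapping) to indices."""
    if isinstance(group_spec, Mapping):
        missing = [s for s in sample_ids if s not in group_spec]
        if missing:
            raise ValueError(f"no group label for sample(s): {missing}")
        labels = [group_spec[s] for s in sample_ids]
    else:
        labels = list(group_spec)
        if len(labels) != len(sample_ids):
            raise ValueError(
                f"{len(labels)} group labels for {len(sample_ids)} samples"
            )
    order = list(dict.fromkeys(labels))  # first-appearance order
    return np.array([order.index(l) for l in labels], dtype=int)


def read_counts(
    path: str | Path,
    group_spec=None,
    drop_all_zero: bool = True,
) -> CountMatrix:
    """Read a counts table and attach group labels.

    ``group_spec`` is either a sequence of per-sample labels (by column
    position) or a mapping/two-column file of sample -> group. Genes with
    zero counts in every sample are removed (logged) unless
    ``drop_all_zero=False``. Non-integer or negative cells and duplicate
    gene identifiers are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene IDs in {path.name}: {dupes}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(
            ~np.vectorize(lambda v: isinstance(v, (int, float, np.number)))(values)
        )
        i, j = bad[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if not np.array_equal(values, np.rint(values)):
        i, j = np.argwhere(values != np.rint(values))[0]
        raise ValueError(
            f"non-integer count at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    sample_ids = [str(c) for c in df.columns]
    if group_spec is None:
        groups = np.zeros(len(sample_ids), dtype=int)
    elif isinstance(group_spec, (str, Path)):
        groups = _parse_groups(sample_ids, read_group_map(group_spec))
    else:
        groups = _parse_groups(sample_ids, group_spec)
    cm = CountMatrix(
        values.astype(np.int64),
        np.array([str(i) for i in df.index], dtype=object),
        np.array(sample_ids, dtype=object),
        groups,
    )
    if drop_all_zero:
        before = cm.n_genes
        cm, removed = cm.drop_all_zero_genes()
        if removed:
            logger.info(
                "removed %d all-zero genes (%d -> %d)", removed, before, cm.n_genes
            )
    return cm


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> group TSV (no header required)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group map needs two columns: sample_id, group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    cm.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id")


def write_truth(truth: SimulationTruth, prefix: str | Path, gene_ids=None) -> None:
    """Write truth labels (<prefix>_truth.tsv) and FC matrix (<prefix>_fc.tsv)."""
    prefix = Path(prefix)
    g = len(truth.pattern)
    if gene_ids is None:
        gene_ids = [f"gene_{i + 1}" for i in range(g)]
    pd.DataFrame({"gene_id": gene_ids, "pattern": truth.pattern}).to_csv(
        f"{prefix}_truth.tsv", sep="\t", index=False
    )
    fc = pd.DataFrame(
        truth.fc_matrix,
        index=gene_ids,
        columns=[f"group{i + 1}" for i in range(truth.fc_matrix.shape[1])],
    )
    fc.to_csv(f"{prefix}_fc.tsv", sep="\t", index_label="gene_id")


def write_results(result: DEResult, prefix: str | Path) -> tuple[Path, Path]:
    """Write per-gene results TSV and model-summary JSON.

    Scores are written at full float precision so a round-trip read
    reproduces ranks and scores exactly.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    results_path = Path(f"{prefix}_results.tsv")
    model_path = Path(f"{prefix}_model.json")
    result.table.to_csv(
        results_path, sep="\t", index=False, float_format="%.17g"
    )
    model_path.write_text(json.dumps(result.summary(), indent=2) + "\n")
    logger.info("wrote %s and %s", results_path, model_path)
    return results_path, model_path


def read_results(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so written scores reload bit-identically
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def collapse_technical_replicates(
    cm: CountMatrix, replicate_map: Mapping[str, str] | str | Path
) -> CountMatrix:
    """Sum columns that are technical replicates of the same sample.

    ``replicate_map`` maps each sample id to its collapsed id (a
    two-column file is accepted). Collapsed samples inherit the group of
    their members, which must agree.
    """
    if isinstance(replicate_map, (str, Path)):
        replicate_map = read_group_map(replicate_map)
    targets = [replicate_map.get(str(s), str(s)) for s in cm.sample_ids]
    order = list(dict.fromkeys(targets))
    cols = []
    groups = []
    for t in order:
        members = [j for j, tt in enumerate(targets) if tt == t]
        member_groups = {int(cm.groups[j]) for j in members}
        if len(member_groups) > 1:
            raise ValueError(
                f"technical replicates of {t!r} span multiple groups"
            )
        cols.append(cm.counts[:, members].sum(axis=1))
        groups.append(member_groups.pop())
    return CountMatrix(
        np.stack(cols, axis=1),
        cm.gene_ids,
        np.array(order, dtype=object),
        np.array(groups, dtype=int),
    )
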