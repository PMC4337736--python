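"""Per-dataset differential expression and fold-change ranking.

Fold change is the difference of case and control group means on log2 data.
A two-sided Welch t-test with Benjamini-Hochberg adjustment provides the
secondary significance filter (p < 0.05 and FDR < 0.05); ranking itself is
driven purely by |log2 fold change|.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gwsig.dataset_io import ExpressionDataset
from gwsig.errors import ConfigurationError

P_THRESHOLD = 0.05
FDR_THRESHOLD = 0.05


@dataclass
class RankedGeneList:
    """Per-dataset gene ranking, rank 1 = largest |log2 fold change|."""

    dataset_id: str
    ranks: pd.Series  # gene id -> integer rank in 1..m

    def __post_init__(self) -> None:
        r = np.sort(self.ranks.to_numpy())
        if len(r) == 0 or not np.array_equal(r, np.arange(1, len(r) + 1)):
            raise ConfigurationError(
                f"ranks for dataset '{self.dataset_id}' are not a "
                f"permutation of 1..{len(r)}"
            )

    @property
    def m(self) -> int:
        return len(self.ranks)

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)


def compute_de_table(dataset: ExpressionDataset) -> pd.DataFrame:
    """Compute per-gene fold change, Welch t-test p, and BH FDR.

    Returns a DataFrame indexed by gene with columns ``log2_fc``,
    ``p_value``, ``fdr``, ``passes_deg_filter``.  A gene whose two groups
    both have zero variance gets p = 1 when the means are equal and p = 0
    otherwise (the difference is then certain).
    """
    case = dataset.values[:, dataset.case_mask]
    control = dataset.values[:, dataset.control_mask]
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ConfigurationError(
            f"dataset '{dataset.dataset_id}': need at least 2 samples per group"
        )

    log2_fc = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(case, control, axis=1, equal_var=False)
        p_value = np.asarray(result.pvalue, dtype=float)

    zero_var = (case.var(axis=1) == 0) & (control.var(axis=1) == 0)
    if zero_var.any():
        p_value = p_value.copy()
        p_value[zero_var & (log2_fc == 0)] = 1.0
        p_value[zero_var & (log2_fc != 0)] = 0.0
    if np.isnan(p_value).any():  # defensive: no formula leaves p undefined
        p_value = np.where(np.isnan(p_value), 1.0, p_value)

    _, fdr, _, _ = multipletests(p_value, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": p_value,
            "fdr": fdr,
            "passes_deg_filter": (p_value < P_THRESHOLD) & (fdr < FDR_THRESHOLD),
        },
        index=pd.Index(dataset.genes, name="gene"),
    )
    table.attrs["dataset_id"] = dataset.dataset_id
    return table


def rank_by_fold_change(
    table: pd.DataFrame,
    restrict_to: Optional[Iterable[str]] = None,
    *,
    dataset_id: Optional[str] = None,
) -> RankedGeneList:
    """Rank genes by |log2_fc| descending; ties go to the smaller gene id.

    ``restrict_to`` limits ranking to a subset of the table's genes (e.g.
    the cross-study common genes); it must be a non-empty subset.
    """
    if dataset_id is None:
        dataset_id = table.attrs.get("dataset_id", "unknown")
    genes = pd.Index(table.index)
    if restrict_to is not None:
        wanted = pd.Index(sorted(set(restrict_to)))
        missing = wanted.difference(genes)
        if len(missing):
            raise ConfigurationError(
                f"restrict_to contains genes absent from the table: "
                f"{list(missing[:5])!r}"
            )
        if len(wanted) == 0:
            raise ConfigurationError("restrict_to is empty; nothing to rank")
        table = table.loc[wanted]
    if len(table) == 0:
        raise ConfigurationError("empty table; nothing to rank")

    order = sorted(
        table.index, key=lambda g: (-abs(float(table.at[g, "log2_fc"])), str(g))
    )
    ranks = pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order, name="gene")
    )
    return RankedGeneList(dataset_id=dataset_id, ranks=ranks)


def write_de_table(
    table: pd.DataFrame, ranked: RankedGeneList, path: str | Path
) -> None:
    """Write gene, log2_fc, p_value, fdr, passes_deg_filter, rank as TSV."""
    out = table.copy()
    out["rank"] = ranked.ranks.reindex(out.index).astype("Int64")
    out.to_csv(path, sep="\t", lineterminator="\n", float_format=lambda x: repr(float(x)))
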