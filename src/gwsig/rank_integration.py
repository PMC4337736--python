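"""Rank integration across studies: GWRS, weighted GWGS, top-K signature.

The genome-wide relative significance (GWRS) of gene i in dataset j is

    s_ij = -2 * ln(r_ij / m)

where r_ij is the gene's fold-change rank (1 = most differentially
expressed) among the m genes common to all datasets.  The genome-wide
global significance (GWGS) aggregates these as a weighted sum

    s_i = sum_j w_j * s_ij

with weights normalised to sum to 1 (equal by default).  Since r/m behaves
like a p-value under the null, n * s_i with equal weights is Fisher's
combined statistic -2 * sum_j ln(r_ij / m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from gwsig.differential_expression import RankedGeneList
from gwsig.errors import ConfigurationError

DEFAULT_SIGNATURE_SIZE = 200


@dataclass
class Signature:
    """Ordered top-K gene list (descending GWGS) with scores."""

    genes: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ConfigurationError("signature genes and scores differ in length")

    @property
    def k(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def intersect_genes(universes: Sequence[Iterable[str]]) -> list[str]:
    """Intersect gene universes; returns the common genes in lexicographic order."""
    if len(universes) < 2:
        raise ConfigurationError(
            f"need at least 2 gene universes to intersect, got {len(universes)}"
        )
    common = set(universes[0])
    for u in universes[1:]:
        common &= set(u)
    if not common:
        raise ConfigurationError(
            "gene universes have an empty intersection; the pipeline cannot proceed"
        )
    return sorted(common)


def gwrs_score(r: int, m: int) -> float:
    """GWRS for rank r among m genes: -2*ln(r/m); strictly decreasing in r."""
    if m < 1:
        raise ConfigurationError(f"m must be >= 1, got {m}")
    if not 1 <= r <= m:
        raise ConfigurationError(f"rank r={r} outside the valid range 1..{m}")
    return -2.0 * math.log(r / m)


def gwrs_matrix(
    ranked_lists: Sequence[RankedGeneList],
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Build the genes x datasets GWRS score matrix.

    Every ranked list must rank exactly the same gene universe (the common
    genes); ``genes`` optionally fixes the row order.
    """
    if not ranked_lists:
        raise ConfigurationError("no ranked lists provided")
    if genes is None:
        genes = sorted(ranked_lists[0].genes)
    genes = list(genes)
    m = len(genes)
    columns = {}
    for rl in ranked_lists:
        if rl.m != m or set(rl.genes) != set(genes):
            raise ConfigurationError(
                f"dataset '{rl.dataset_id}' ranks a different gene universe "
                f"({rl.m} genes) than expected ({m})"
            )
        r = rl.ranks.reindex(genes).to_numpy(dtype=float)
        columns[rl.dataset_id] = -2.0 * np.log(r / m)
    return pd.DataFrame(columns, index=pd.Index(genes, name="gene"))


def normalize_weights(weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ConfigurationError(f"weights must be non-negative, got {list(w)}")
    total = w.sum()
    if total <= 0:
        raise ConfigurationError("weights must not all be zero")
    return w / total


def gwgs_scores(
    gwrs: pd.DataFrame, weights: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Aggregate GWRS columns into GWGS and assign the global rank.

    Weights default to equal and are normalised to sum to 1.  Returns the
    GWRS columns plus ``gwgs`` and ``global_rank`` (1 = largest GWGS; ties
    broken by lexicographically smaller gene id).
    """
    n = gwrs.shape[1]
    if n == 0:
        raise ConfigurationError("GWRS matrix has no dataset columns")
    if weights is None:
        weights = [1.0] * n
    if len(weights) != n:
        raise ConfigurationError(
            f"{len(weights)} weights for {n} datasets"
        )
    w = normalize_weights(weights)
    out = gwrs.copy()
    out["gwgs"] = gwrs.to_numpy() @ w
    order = sorted(out.index, key=lambda g: (-float(out.at[g, "gwgs"]), str(g)))
    rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    out["global_rank"] = rank.reindex(out.index).astype(int)
    return out


def select_top_k(table: pd.DataFrame, k: int = DEFAULT_SIGNATURE_SIZE) -> Signature:
    """Select the k genes with the smallest global rank (all genes if k >= m)."""
    if k < 1:
        raise ConfigurationError(f"signature size k must be >= 1, got {k}")
    k = min(k, len(table))
    top = table[table["global_rank"] <= k].sort_values("global_rank")
    return Signature(
        genes=[str(g) for g in top.index],
        scores=[float(s) for s in top["gwgs"]],
    )


def write_gwgs_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", lineterminator="\n", float_format=lambda x: repr(float(x)))


def write_signature(signature: Signature, path: str | Path, scored_path=None) -> None:
    """Write the signature as a one-column gene list, optionally with scores."""
    Path(path).write_text("\n".join(signature.genes) + "\n", encoding="utf-8")
    if scored_path is not None:
        frame = pd.DataFrame({"gene": signature.genes, "gwgs": signature.scores})
        frame.to_csv(scored_path, sep="\t", index=False, lineterminator="\n", float_format=lambda x: repr(float(x)))
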