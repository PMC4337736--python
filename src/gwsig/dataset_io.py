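"""Expression-matrix I/O and probe-to-gene collapsing.

Matrices are tab-separated text with gene identifiers in the first column
and sample identifiers in the header row; a companion two-column file maps
each sample to its group (``case`` or ``control``).  All tables are written
in UTF-8 with Unix newlines and shortest-round-trip floating precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gwsig.errors import ParseError

logger = logging.getLogger(__name__)

GROUP_LABELS = ("case", "control")


@dataclass
class ExpressionDataset:
    """One study's log2 gene-by-sample expression matrix with group labels.

    Parameters
    ----------
    dataset_id : str
        Label identifying the study.
    genes : list of str
        Ordered unique gene identifiers (matrix rows).
    samples : list of str
        Ordered unique sample identifiers (matrix columns).
    values : ndarray of shape (n_genes, n_samples)
        Log2 expression values; must be finite.
    group : list of str
        Per-sample label, ``"case"`` or ``"control"``.
    weight : float
        Non-negative relative weight of this dataset in the integration.
    """

    dataset_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    group: list[str]
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_genes, n_samples = len(self.genes), len(self.samples)
        if self.values.shape != (n_genes, n_samples):
            raise ParseError(
                f"dataset '{self.dataset_id}': value matrix shape "
                f"{self.values.shape} does not match {n_genes} genes x "
                f"{n_samples} samples"
            )
        dup = _duplicates(self.genes)
        if dup:
            raise ParseError(
                f"dataset '{self.dataset_id}': duplicate gene ids {dup!r}; "
                "collapse probe-level rows with collapse_probes() first"
            )
        dup = _duplicates(self.samples)
        if dup:
            raise ParseError(
                f"dataset '{self.dataset_id}': duplicate sample ids {dup!r}"
            )
        if len(self.group) != n_samples:
            raise ParseError(
                f"dataset '{self.dataset_id}': {len(self.group)} group labels "
                f"for {n_samples} samples"
            )
        bad = sorted(set(self.group) - set(GROUP_LABELS))
        if bad:
            raise ParseError(
                f"dataset '{self.dataset_id}': unknown group labels {bad!r}; "
                f"expected one of {GROUP_LABELS}"
            )
        for label in GROUP_LABELS:
            n = sum(g == label for g in self.group)
            if n < 2:
                raise ParseError(
                    f"dataset '{self.dataset_id}': group '{label}' has {n} "
                    "samples; at least 2 are required"
                )
        if not np.all(np.isfinite(self.values)):
            bad_idx = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"dataset '{self.dataset_id}': non-finite value at gene "
                f"'{self.genes[bad_idx[0]]}', sample '{self.samples[bad_idx[1]]}'"
            )
        if not (np.isfinite(self.weight) and self.weight >= 0):
            raise ParseError(
                f"dataset '{self.dataset_id}': weight must be a finite "
                f"non-negative number, got {self.weight!r}"
            )

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([g == "case" for g in self.group], dtype=bool)

    @property
    def control_mask(self) -> np.ndarray:
        return ~self.case_mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


def read_expression_matrix(
    matrix_path: str | Path,
    groups_path: str | Path,
    dataset_id: str,
    *,
    weight: float = 1.0,
    log2_transform: bool = False,
) -> ExpressionDataset:
    """Read a gene-by-sample matrix and its sample-to-group file.

    Group labels are stripped, lower-cased, and must normalise to ``case``
    or ``control``.  With ``log2_transform=True`` the values are transformed
    as ``log2(x + 1)`` on read (inputs are otherwise assumed to be on the
    log2 scale already).
    """
    matrix_path, groups_path = Path(matrix_path), Path(groups_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if raw.index.name is None and raw.shape[1] == 0:
        raise ParseError(f"{matrix_path}: empty or malformed matrix file")
    genes = [str(g) for g in raw.index]
    samples = [str(s) for s in raw.columns]

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        column = raw[col]
        try:
            # float() round-trips repr exactly; pd.to_numeric's fast parser
            # can be off by one ulp
            values[:, j] = column.to_numpy(dtype=np.float64)
        except (ValueError, TypeError):
            for gene, cell in column.items():
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ParseError(
                        f"{matrix_path}: non-numeric or missing value at gene "
                        f"'{gene}', sample '{col}'"
                    ) from None
            raise
        if column.isna().any():
            gene = column.index[column.isna()][0]
            raise ParseError(
                f"{matrix_path}: non-numeric or missing value at gene "
                f"'{gene}', sample '{col}'"
            )

    group_map = _read_group_file(groups_path)
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise ParseError(
            f"{groups_path}: no group label for sample(s) {missing!r}"
        )
    group = [group_map[s] for s in samples]

    if log2_transform:
        if (values < 0).any():
            raise ParseError(
                f"{matrix_path}: negative values are incompatible with "
                "log2(x+1) transformation"
            )
        values = np.log2(values + 1.0)

    return ExpressionDataset(
        dataset_id=dataset_id,
        genes=genes,
        samples=samples,
        values=values,
        group=group,
        weight=weight,
    )


def _read_group_file(path: Path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    mapping: dict[str, str] = {}
    for _, row in table.iterrows():
        sample, label = str(row.iloc[0]), str(row.iloc[1]).strip().lower()
        if label not in GROUP_LABELS:
            raise ParseError(
                f"{path}: sample '{sample}' has group '{row.iloc[1]}'; "
                f"expected one of {GROUP_LABELS}"
            )
        mapping[sample] = label
    return mapping


def write_expression_matrix(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    groups_path: str | Path,
) -> None:
    """Write the matrix and group files read back by read_expression_matrix."""
    frame = dataset.to_frame()
    frame.index.name = "gene"
    # repr gives shortest-round-trip precision, so read() inverts write()
    frame.to_csv(
        matrix_path,
        sep="\t",
        lineterminator="\n",
        float_format=lambda x: repr(float(x)),
    )
    groups = pd.DataFrame({"sample": dataset.samples, "group": dataset.group})
    groups.to_csv(groups_path, sep="\t", index=False, lineterminator="\n")


def collapse_probes(
    probe_values: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Collapse a probe-by-sample matrix to a gene-by-sample matrix.

    Rules:

    * probes absent from ``mapping`` (or mapped to no gene) are dropped;
    * a probe mapped to several genes contributes its row to every one of
      them;
    * when several probes map to one gene, the gene receives the row of the
      probe whose mean expression across samples is maximal, ties broken by
      the lexicographically smallest probe id.

    Returns a DataFrame indexed by gene id (lexicographic order).
    """
    dup = _duplicates(list(probe_values.index))
    if dup:
        raise ParseError(f"duplicate probe ids in input: {dup!r}")
    means = probe_values.mean(axis=1)
    # gene -> (negated mean, probe id); min() implements max-mean with the
    # lexicographic tie-break in one key comparison
    best: dict[str, tuple[float, str]] = {}
    n_unmapped = 0
    for probe in probe_values.index:
        targets = mapping.get(probe, ())
        if not targets:
            n_unmapped += 1
            continue
        key = (-float(means.loc[probe]), str(probe))
        for gene in targets:
            gene = str(gene)
            if gene not in best or key < best[gene]:
                best[gene] = key
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", n_unmapped)
    if not best:
        raise ParseError(
            "collapse_probes: no probe mapped to any gene; output would be empty"
        )
    genes = sorted(best)
    rows = [probe_values.loc[best[g][1]].to_numpy(dtype=float) for g in genes]
    out = pd.DataFrame(rows, index=genes, columns=probe_values.columns)
    out.index.name = "gene"
    return out
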