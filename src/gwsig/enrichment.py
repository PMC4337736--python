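"""Gene-set enrichment of a signature: Fisher exact and EASE scoring.

Sets come from GMT files; enrichment is tested against a background
universe (by default the cross-study common genes).  The Fisher p is the
one-sided hypergeometric upper tail P(X >= k); the EASE score is the same
tail after removing one gene from the observed overlap (k -> k-1), a
deliberately conservative variant, so p_ease >= p_fisher always.

Significance profiles follow strict thresholds: ``go`` requires overlap
k > 5 and p_ease < 0.01; ``kegg`` requires k > 2 and p_ease < 0.05.
BH FDR across all tested sets is reported but does not gate significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from gwsig.errors import ConfigurationError, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ParseError(f"gene set '{self.set_id}' is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ParseError(f"gene set '{self.set_id}' has duplicate members")


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe for testing."""

    sets: list[GeneSet]
    background: Optional[list[str]] = None

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate gene-set id(s): {dup!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def ids(self) -> list[str]:
        return [s.set_id for s in self.sets]


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 overlap counts: background N, signature n, set K, overlap k."""

    N: int
    n: int
    K: int
    k: int

    def __post_init__(self) -> None:
        for name in ("N", "n", "K", "k"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(
                    f"contingency count {name}={v!r} must be a non-negative integer"
                )
        if self.n > self.N or self.K > self.N:
            raise ConfigurationError(
                f"n={self.n} and K={self.K} must not exceed N={self.N}"
            )
        if self.k > min(self.n, self.K):
            raise ConfigurationError(
                f"overlap k={self.k} exceeds min(n={self.n}, K={self.K})"
            )


@dataclass
class EnrichmentRecord:
    set_id: str
    description: str
    counts: ContingencyCounts
    p_fisher: float
    p_ease: float
    fdr: float = float("nan")
    significant: bool = False


# profile -> (overlap threshold, exclusive, on p_ease)
FILTER_PROFILES: dict[str, tuple[int, float]] = {
    "go": (5, 0.01),
    "kegg": (2, 0.05),
}


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: id, description, member genes...).

    Duplicate members within a set are removed with a warning; a duplicate
    set id or a line with fewer than 3 fields is an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, description, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "%s:%d: set '%s' has duplicate members; deduplicated",
                    path, lineno, set_id,
                )
            sets.append(GeneSet(set_id, description, tuple(unique)))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


def hypergeometric_tail(counts: ContingencyCounts) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if counts.k == 0:
        return 1.0
    return float(hypergeom.sf(counts.k - 1, counts.N, counts.K, counts.n))


def ease_p(counts: ContingencyCounts) -> float:
    """EASE score: the hypergeometric tail with the overlap reduced by one."""
    if counts.k <= 1:
        return 1.0
    reduced = ContingencyCounts(counts.N, counts.n, counts.K, counts.k - 1)
    return hypergeometric_tail(reduced)


def enrich_signature(
    signature: Iterable[str],
    collection: GeneSetCollection,
    profile: str = "go",
    background: Optional[Sequence[str]] = None,
) -> list[EnrichmentRecord]:
    """Test every gene set against the signature.

    One record per set that intersects the background; records are sorted
    by ascending p_ease (ties by set id).  Signature genes outside the
    background are dropped with a warning; an empty signature is an error.
    """
    if profile not in FILTER_PROFILES:
        raise ConfigurationError(
            f"unknown filter profile '{profile}'; choose from "
            f"{sorted(FILTER_PROFILES)}"
        )
    min_k_exclusive, alpha = FILTER_PROFILES[profile]

    sig_genes = set(signature)
    if not sig_genes:
        raise ConfigurationError("signature is empty; nothing to test")
    if background is None:
        background = collection.background
    if background is None:
        raise ConfigurationError(
            "no background universe: pass background= or set collection.background"
        )
    bg = set(background)
    dropped = sig_genes - bg
    if dropped:
        logger.warning(
            "enrich_signature: %d signature gene(s) outside the background "
            "were dropped", len(dropped),
        )
    sig = sig_genes & bg
    if not sig:
        raise ConfigurationError("no signature gene lies in the background")

    N, n = len(bg), len(sig)
    records: list[EnrichmentRecord] = []
    for s in collection:
        members = set(s.genes) & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & sig)
        counts = ContingencyCounts(N=N, n=n, K=K, k=k)
        records.append(
            EnrichmentRecord(
                set_id=s.set_id,
                description=s.description,
                counts=counts,
                p_fisher=hypergeometric_tail(counts),
                p_ease=ease_p(counts),
            )
        )
    if records:
        _, fdr, _, _ = multipletests(
            [r.p_ease for r in records], method="fdr_bh"
        )
        for r, q in zip(records, fdr):
            r.fdr = float(q)
            r.significant = r.counts.k > min_k_exclusive and r.p_ease < alpha
    records.sort(key=lambda r: (r.p_ease, r.set_id))
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in records],
            "description": [r.description for r in records],
            "k": [r.counts.k for r in records],
            "K": [r.counts.K for r in records],
            "n": [r.counts.n for r in records],
            "N": [r.counts.N for r in records],
            "p_fisher": [r.p_fisher for r in records],
            "p_ease": [r.p_ease for r in records],
            "fdr": [r.fdr for r in records],
            "significant": [r.significant for r in records],
        }
    )


def write_enrichment_table(
    records: Sequence[EnrichmentRecord], path: str | Path
) -> None:
    records_to_frame(records).to_csv(
        path, sep="\t", index=False, lineterminator="\n",
        float_format=lambda x: repr(float(x)),
    )
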