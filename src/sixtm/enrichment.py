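"""Gene-set fold enrichment and exact binomial significance.

The statistic asks whether receptor genes (for example the small set of
GPCR genes with annotated N-terminally truncated 6TM variants) are
over-represented within disorder gene sets (pain, psychiatric disorders,
addiction) relative to a genome of N genes:

    fold = prob(GPCR & Disorder) / [prob(GPCR) * prob(Disorder)]
         = k * N / (m * n)

with m receptor genes, an n-gene disorder set and k genes in both.
Significance is the one-sided upper binomial tail P(X >= k) for
X ~ Binomial(n, m/N): the expected frequency of receptor genes in the
genome compared with their observed frequency within the disorder set.
The tail is summed directly with log-space terms.  No multiple-testing
correction is applied; fold values are conventionally reported to one
decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TRUNCATED_6TM_GENES",
    "GeneSetUniverse",
    "EnrichmentResult",
    "load_gene_list",
    "fold_enrichment",
    "binomial_tail_p",
    "run_enrichment",
    "results_table",
]

# Human GPCR genes with annotated transcripts coding for N-terminally
# truncated 6TM receptor variants (curated; four are opioid receptors).
TRUNCATED_6TM_GENES: tuple[str, ...] = (
    "CCKAR",
    "CCKBR",
    "GLP2R",
    "OPRD1",
    "OPRK1",
    "OPRL1",
    "OPRM1",
    "OR2AJ1",
    "OR56A5",
    "OR9Q2",
    "QRFPR",
    "TACR2",
)


def _normalize(symbols: Iterable[str], name: str) -> frozenset[str]:
    seen: set[str] = set()
    for s in symbols:
        u = s.strip().upper()
        if not u:
            continue
        if u in seen:
            raise ValueError(f"duplicate gene symbol {u!r} in set {name!r}: sets must be sets")
        seen.add(u)
    return frozenset(seen)


@dataclass(frozen=True)
class GeneSetUniverse:
    """A genome-wide gene universe with a receptor set and disorder sets.

    Symbols are matched case-insensitively; duplicates within a set are
    rejected at construction.
    """

    N: int
    gpcr: frozenset[str]
    disorder_sets: Mapping[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gpcr", _normalize(self.gpcr, "gpcr"))
        object.__setattr__(
            self,
            "disorder_sets",
            {name: _normalize(genes, name) for name, genes in self.disorder_sets.items()},
        )
        if self.universe is not None:
            object.__setattr__(self, "universe", _normalize(self.universe, "universe"))
        sizes = [len(self.gpcr)] + [len(s) for s in self.disorder_sets.values()]
        if self.N < max(sizes, default=0):
            raise ValueError(f"universe size N={self.N} smaller than a member set")
        if self.universe is not None:
            for name, genes in {"gpcr": self.gpcr, **self.disorder_sets}.items():
                extra = genes - self.universe
                if extra:
                    raise ValueError(
                        f"set {name!r} contains symbols outside the universe: {sorted(extra)[:5]}"
                    )


@dataclass(frozen=True)
class EnrichmentResult:
    disorder_name: str
    k: int
    n: int
    m: int
    N: int
    fold: float
    p: float
    overlap: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.k > min(self.m, self.n):
            raise ValueError("overlap cannot exceed either set size")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be a probability")

    @property
    def fold_rounded(self) -> float:
        """Fold enrichment rounded to one decimal, as conventionally reported."""
        return round(self.fold, 1)


def load_gene_list(path: str | Path, name: str | None = None) -> frozenset[str]:
    """Read a plain-text gene list (one symbol per line, '#' comments)."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line)
    return _normalize(symbols, name or str(path))


def fold_enrichment(k: int, n: int, m: int, N: int) -> float:
    """Observed/expected joint frequency ratio: k*N / (m*n)."""
    if N <= 0:
        raise ValueError("genome size N must be positive")
    if m <= 0 or n <= 0:
        raise ValueError("set sizes m and n must be positive")
    if k < 0:
        raise ValueError("overlap k must be non-negative")
    return (k * N) / (m * n)


def binomial_tail_p(k: int, n: int, p0: float) -> float:
    """Exact one-sided upper tail P(X >= k), X ~ Binomial(n, p0).

    Direct summation of the tail with each term evaluated in log space,
    so tiny tails (e.g. 1e-31) come out at full relative precision.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a probability")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if k == 0:
        return 1.0
    if p0 == 0.0:
        return 0.0
    if p0 == 1.0:
        return 1.0
    log_p, log_q = math.log(p0), math.log1p(-p0)
    lgn = math.lgamma(n + 1)
    total = 0.0
    for i in range(k, n + 1):
        log_term = (
            lgn - math.lgamma(i + 1) - math.lgamma(n - i + 1) + i * log_p + (n - i) * log_q
        )
        total += math.exp(log_term)
    return min(total, 1.0)


def run_enrichment(universe: GeneSetUniverse) -> list[EnrichmentResult]:
    """Fold enrichment and binomial p for every disorder set in a universe.

    For each disorder set D: k = |gpcr & D|, fold = k*N/(m*n) and
    p = P(X >= k) under X ~ Binomial(n, m/N).
    """
    m = len(universe.gpcr)
    if m == 0:
        raise ValueError("receptor gene set is empty")
    results = []
    for name, genes in universe.disorder_sets.items():
        n = len(genes)
        overlap = universe.gpcr & genes
        k = len(overlap)
        results.append(
            EnrichmentResult(
                disorder_name=name,
                k=k,
                n=n,
                m=m,
                N=universe.N,
                fold=fold_enrichment(k, n, m, universe.N),
                p=binomial_tail_p(k, n, m / universe.N),
                overlap=frozenset(overlap),
            )
        )
    return results


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (fold shown rounded to one decimal)."""
    rows = [
        {
            "disorder": r.disorder_name,
            "overlap_k": r.k,
            "set_n": r.n,
            "gpcr_m": r.m,
            "genome_N": r.N,
            "fold": r.fold_rounded,
            "p_binomial": r.p,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
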