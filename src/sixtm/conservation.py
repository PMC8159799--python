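"""Per-exon evolutionary divergence and conservation summaries.

Divergence between orthologous exon sequences is measured from a pairwise
nucleotide alignment by counting transitions (A<->G, C<->T) and
transversions (all other mismatches) over aligned, gap-free, N-free
columns and applying the Kimura two-parameter correction

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

where P and Q are the transition and transversion proportions per aligned
site.  Conservation of an exon is summarised as the mean (with its
standard error) of per-base phylogenetic conservation scores in [0, 1]
over the exon's positions; a configurable flank (default 100 nt) defines
retrieval context only and never enters the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .genomic_io import ExonInterval, ScoreTrack

__all__ = [
    "PairwiseAlignment",
    "DivergenceStats",
    "ConservationSummary",
    "SaturationError",
    "read_pairwise_fasta",
    "align_nucleotide",
    "substitution_counts",
    "k2p_distance",
    "exon_divergence",
    "conservation_summary",
]

_ALN_ALPHABET = frozenset("ACGTN-")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Divergence too high for the two-parameter correction to be defined."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped nucleotide alignment: query (e.g. human) vs subject (e.g. macaque)."""

    query: str
    subject: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "query", self.query.upper())
        object.__setattr__(self, "subject", self.subject.upper())
        if len(self.query) != len(self.subject):
            raise ValueError(
                f"gapped lengths differ: {len(self.query)} vs {len(self.subject)}"
            )
        for name, seq in (("query", self.query), ("subject", self.subject)):
            bad = set(seq) - _ALN_ALPHABET
            if bad:
                raise ValueError(f"{name} contains invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class DivergenceStats:
    """Counts and Kimura two-parameter distance for one exon alignment."""

    lenQ: int  # ungapped query length (nt), N included
    lenS: int  # ungapped subject length (nt), N included
    lenA: int  # aligned columns: both non-gap and non-N
    TT: int  # transitions
    TV: int  # transversions
    P: float  # TT / lenA
    Q_frac: float  # TV / lenA
    K: float  # substitutions per site

    def __post_init__(self) -> None:
        if not 0.0 <= self.P + self.Q_frac <= 1.0:
            raise ValueError("P + Q must lie in [0, 1]")
        if self.K < 0:
            raise ValueError("K must be non-negative")


@dataclass(frozen=True)
class ConservationSummary:
    exon_label: str
    n_positions: int
    mean_score: float
    sem: float
    sd: float


def read_pairwise_fasta(path) -> PairwiseAlignment:
    """Read an aligned FASTA file with exactly two records."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, got {len(records)}")
    return PairwiseAlignment(str(records[0].seq), str(records[1].seq))


def align_nucleotide(query: str, subject: str) -> PairwiseAlignment:
    """Basic global nucleotide alignment (match +1, mismatch -1, gap -2).

    Intended for small demonstration inputs; production exon alignments
    are expected to be supplied pre-computed.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(query.upper(), subject.upper())[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]))


def substitution_counts(aln: PairwiseAlignment) -> tuple[int, int, int, int, int]:
    """Count (lenQ, lenS, lenA, TT, TV) over an alignment.

    Columns containing a gap or an N are excluded from ``lenA`` and from
    the substitution counts; ungapped lengths count every residue
    including N.
    """
    lenQ = sum(1 for c in aln.query if c != "-")
    lenS = sum(1 for c in aln.subject if c != "-")
    lenA = TT = TV = 0
    for q, s in zip(aln.query, aln.subject):
        if q in "-N" or s in "-N":
            continue
        lenA += 1
        if q == s:
            continue
        if (q in _PURINES and s in _PURINES) or (q in _PYRIMIDINES and s in _PYRIMIDINES):
            TT += 1
        else:
            TV += 1
    return lenQ, lenS, lenA, TT, TV


def k2p_distance(P: float, Q_frac: float) -> float:
    """Kimura two-parameter distance from transition/transversion fractions."""
    if P < 0 or Q_frac < 0 or P + Q_frac > 1:
        raise ValueError(f"invalid proportions P={P}, Q={Q_frac}")
    a = 1.0 - 2.0 * P - Q_frac
    b = 1.0 - 2.0 * Q_frac
    if a <= 0 or b <= 0:
        raise SaturationError(
            f"divergence saturated (1-2P-Q={a:g}, 1-2Q={b:g}); distance undefined"
        )
    return -0.5 * math.log(a * math.sqrt(b))


def exon_divergence(aln: PairwiseAlignment) -> DivergenceStats:
    """Full divergence summary for one exon alignment."""
    lenQ, lenS, lenA, TT, TV = substitution_counts(aln)
    if lenA == 0:
        raise ValueError("no aligned (gap-free, N-free) columns; divergence undefined")
    P = TT / lenA
    Q = TV / lenA
    return DivergenceStats(lenQ, lenS, lenA, TT, TV, P, Q, k2p_distance(P, Q))


def conservation_summary(
    track: ScoreTrack,
    exon: ExonInterval,
    flank_nt: int = 100,
) -> ConservationSummary:
    """Mean conservation score of an exon, with its standard error.

    ``flank_nt`` describes the retrieval context customarily fetched on
    each side of the exon; flanking positions are never included in the
    mean.  Positions without a stored score are skipped; an exon with no
    scored positions is an error.
    """
    if exon.chrom != track.chrom:
        raise ValueError(f"exon chrom {exon.chrom!r} does not match track {track.chrom!r}")
    if flank_nt < 0:
        raise ValueError("flank_nt must be non-negative")
    scores = [
        track.values[p] for p in range(exon.start, exon.end + 1) if p in track.values
    ]
    if not scores:
        raise ValueError(f"exon {exon.label or exon.chrom}: no scored positions")
    arr = np.asarray(scores, dtype=float)
    n = arr.size
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return ConservationSummary(
        exon_label=exon.label or f"{exon.chrom}:{exon.start}-{exon.end}",
        n_positions=n,
        mean_score=float(arr.mean()),
        sem=sd / math.sqrt(n) if n > 1 else 0.0,
        sd=sd,
    )
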