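"""UniProt-style screen for truncated GPCR splice isoforms.

Each splice isoform is globally aligned to its gene's canonical 7TM
receptor; the canonical TM domains are mapped through the alignment to
decide which helices the isoform retains.  Where a helix is spliced out
but replaced by novel sequence, the replacement is checked for de novo
helix-forming potential.  The screen then selects isoforms that keep at
least four TM helices while missing the first or the seventh -- the
signature of N- or C-terminally truncated 6TM (and 5TM) receptor
variants.  Isoforms flagged as database fragments are excluded before
any analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genomic_io import IsoformRecordSet
from .topology import predict_tm_helices

__all__ = [
    "AlignmentResult",
    "TruncationCall",
    "align_isoform",
    "tm_presence",
    "extract_replaced_segments",
    "classify_truncation",
    "run_screen",
]

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

SELECTED_CATEGORIES = frozenset(
    {"N_trunc_6TM", "C_trunc_6TM", "N_trunc_5TM", "C_trunc_5TM"}
)


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise protein alignment (canonical vs isoform)."""

    aligned_canonical: str
    aligned_isoform: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_canonical) != len(self.aligned_isoform):
            raise ValueError("gapped strings must have equal length")

    @property
    def canonical(self) -> str:
        return self.aligned_canonical.replace("-", "")

    @property
    def isoform(self) -> str:
        return self.aligned_isoform.replace("-", "")


@dataclass(frozen=True)
class TruncationCall:
    """Per-isoform TM-presence vector and truncation category."""

    isoform_id: str
    tm_present: tuple[bool, ...]  # effective presence, TM1..TM7, rescue included
    n_tm: int
    category: str
    de_novo_helix_rescue: bool = False


def _make_aligner(gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_isoform(
    canonical: str,
    isoform: str,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Globally align an isoform to its canonical sequence (BLOSUM62, affine gaps).

    Deterministic: of co-optimal alignments the aligner's first enumeration
    is taken, which places gaps as late as possible in the isoform.
    """
    for name, seq in (("canonical", canonical), ("isoform", isoform)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq) - _AA20
        if bad:
            raise ValueError(f"{name} sequence contains non-amino-acid characters {sorted(bad)}")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(canonical, isoform)[0]
    return AlignmentResult(str(aln[0]), str(aln[1]), float(aln.score))


def _canonical_columns(aln: AlignmentResult) -> list[int]:
    """Column index of each canonical residue (0-based, by residue order)."""
    cols = []
    for col, ch in enumerate(aln.aligned_canonical):
        if ch != "-":
            cols.append(col)
    return cols


def tm_presence(
    aln: AlignmentResult,
    tm_domains: Sequence[tuple[int, int]],
    coverage_min: float = 0.5,
) -> tuple[bool, ...]:
    """Decide which canonical TM domains the isoform retains.

    TMk is present iff at least ``coverage_min`` of its canonical residues
    are aligned to non-gap isoform residues.  Fractional coverage tolerates
    small splice-boundary shifts inside a helix while rejecting whole-helix
    deletions.
    """
    cols = _canonical_columns(aln)
    present = []
    for start, end in tm_domains:
        if end > len(cols):
            raise ValueError(f"TM domain [{start},{end}] outside canonical length {len(cols)}")
        covered = sum(
            1 for r in range(start - 1, end) if aln.aligned_isoform[cols[r]] != "-"
        )
        present.append(covered / (end - start + 1) >= coverage_min)
    return tuple(present)


def extract_replaced_segments(
    aln: AlignmentResult,
    tm_domains: Sequence[tuple[int, int]],
    presence: Sequence[bool],
) -> dict[int, str]:
    """For each absent TM, the maximal isoform-only run adjacent to it.

    Returns a map TM number (1-based) -> isoform peptide segment.  A TM
    with no adjacent isoform-only (insertion) columns has no entry: the
    helix was deleted without replacement.
    """
    cols = _canonical_columns(aln)
    iso = aln.aligned_isoform
    can = aln.aligned_canonical
    ncol = len(can)

    def insertion_run(col: int, direction: int) -> str:
        chars = []
        c = col
        while 0 <= c < ncol and can[c] == "-":
            if iso[c] != "-":
                chars.append(iso[c])
            c += direction
        return "".join(chars if direction > 0 else chars[::-1])

    segments: dict[int, str] = {}
    for k, ((start, end), pres) in enumerate(zip(tm_domains, presence), start=1):
        if pres:
            continue
        left = insertion_run(cols[start - 1] - 1, -1)
        right = insertion_run(cols[end - 1] + 1, +1)
        best = max((left, right), key=len)
        if best:
            segments[k] = best
    return segments


def classify_truncation(
    isoform_id: str,
    presence: Sequence[bool],
    replaced_segments: Mapping[int, str] | None = None,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
) -> TruncationCall:
    """Assign a truncation category from the TM-presence vector.

    A missing TM whose replacing segment itself forms a predicted helix is
    rescued: it counts toward ``n_tm`` and the isoform is not considered
    truncated at that position.
    """
    presence = list(presence)
    if len(presence) != 7:
        raise ValueError("presence vector must have 7 entries (TM1..TM7)")
    rescued = False
    effective = list(presence)
    for k, segment in (replaced_segments or {}).items():
        if effective[k - 1]:
            continue
        if predict_tm_helices(segment, window=window, threshold=threshold, min_len=min_len):
            effective[k - 1] = True
            rescued = True
    n_tm = sum(effective)
    p = effective
    if all(p):
        category = "full_7TM"
    elif not p[0] and all(p[1:]):
        category = "N_trunc_6TM"
    elif not p[6] and all(p[:6]):
        category = "C_trunc_6TM"
    elif not p[0] and not p[1] and all(p[2:]):
        category = "N_trunc_5TM"
    elif not p[5] and not p[6] and all(p[:5]):
        category = "C_trunc_5TM"
    else:
        category = "other"
    return TruncationCall(isoform_id, tuple(effective), n_tm, category, rescued)


def is_selected(call: TruncationCall) -> bool:
    """Screen selection rule: >= 4 TM helices and TM1 or TM7 missing."""
    if call.category == "excluded_fragment":
        return False
    return call.n_tm >= 4 and (not call.tm_present[0] or not call.tm_present[6])


def run_screen(
    records: Iterable[IsoformRecordSet],
    coverage_min: float = 0.5,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[list[tuple[str, TruncationCall]], list[tuple[str, TruncationCall]], pd.DataFrame]:
    """Run the truncation screen over a collection of receptor record sets.

    Returns ``(selected, all_calls, summary)`` where both call lists pair
    each :class:`TruncationCall` with its gene symbol, and ``summary``
    tabulates per-gene, per-category counts.  Fragment-flagged isoforms are
    excluded before analysis and reported as ``excluded_fragment``.
    """
    all_calls: list[tuple[str, TruncationCall]] = []
    selected: list[tuple[str, TruncationCall]] = []
    for rs in records:
        for iso in rs.isoforms:
            if iso.fragment:
                call = TruncationCall(iso.id, (False,) * 7, 0, "excluded_fragment")
                all_calls.append((rs.gene, call))
                continue
            aln = align_isoform(rs.canonical_sequence, iso.sequence, gap_open, gap_extend)
            presence = tm_presence(aln, rs.tm_domains, coverage_min)
            segments = extract_replaced_segments(aln, rs.tm_domains, presence)
            call = classify_truncation(iso.id, presence, segments)
            all_calls.append((rs.gene, call))
            if is_selected(call):
                selected.append((rs.gene, call))
    summary = pd.DataFrame(
        [(gene, c.category) for gene, c in all_calls], columns=["gene", "category"]
    )
    summary = (
        summary.groupby(["gene", "category"]).size().rename("count").reset_index()
        if len(summary)
        else pd.DataFrame(columns=["gene", "category", "count"])
    )
    return selected, all_calls, summary
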