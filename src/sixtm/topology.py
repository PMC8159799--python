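"""Receptor topology classification for spliced transcripts.

Given a spliced mRNA, this module decides which receptor products the
transcript can encode: the full seven-transmembrane (7TM) receptor, an
N-terminally truncated 6TM receptor, a 1TM fragment terminated by a
premature termination codon (PTC), or nothing.  It also flags transcripts
as nonsense-mediated decay (NMD) candidates, supports near-cognate start
codons (CUG/GUG decoded as Met), and models translational reinitiation
downstream of a PTC.

Transmembrane helices are predicted with a deterministic Kyte-Doolittle
sliding-window hydropathy scan.  The defaults (window 19, threshold 1.6,
minimum helix length 15) follow common practice for single-sequence TM
prediction; all four knobs are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .genomic_io import GenomeSequence, IsoformRecordSet, TranscriptModel, spliced_sequence

__all__ = [
    "OpenReadingFrame",
    "TMHelix",
    "TopologyCall",
    "scan_orfs",
    "flag_nmd",
    "predict_tm_helices",
    "classify_products",
]

_STOPS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_START_CODONS = {
    "aug_only": ("ATG",),
    "aug_gug_cug": ("ATG", "CTG", "GTG"),
}
_RNA = {"ATG": "AUG", "CTG": "CUG", "GTG": "GUG"}


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ORF in transcript coordinates (1-based).

    ``stop_pos`` is the last base of the stop codon when one is found
    (``has_stop``), otherwise the last base of the final complete codon
    read before the transcript end (or an untranslatable N-containing
    codon) interrupted translation.
    """

    start_pos: int
    stop_pos: int
    peptide: str
    start_codon: str  # AUG / CUG / GUG
    has_stop: bool

    def __post_init__(self) -> None:
        if self.has_stop and (self.stop_pos - self.start_pos + 1) % 3 != 0:
            raise ValueError("ORF with stop codon must span whole codons")
        if len(self.peptide) < 1:
            raise ValueError("ORF peptide must be non-empty")


@dataclass(frozen=True)
class TMHelix:
    """A predicted transmembrane helix (1-based residue coordinates)."""

    start_res: int
    end_res: int
    peak_hydropathy: float

    def __len__(self) -> int:
        return self.end_res - self.start_res + 1


@dataclass(frozen=True)
class TopologyCall:
    """Products a transcript can encode, with supporting evidence."""

    transcript_id: str
    products: frozenset[str]  # subset of {"7TM", "6TM", "1TM"}
    nmd_candidate: bool
    orfs: tuple[OpenReadingFrame, ...] = ()
    helix_counts: Mapping[str, int] = field(default_factory=dict)


def scan_orfs(mrna: str, start_policy: str = "aug_only") -> list[OpenReadingFrame]:
    """Enumerate ORFs from every qualifying start codon, 5'-most first.

    Translation uses the standard genetic code; the initiator codon is
    always reported as Met, including the near-cognate starts CUG and GUG
    under the ``aug_gug_cug`` policy.  Translation of a frame stops at the
    first stop codon, at the transcript end, or at a codon containing N
    (untranslatable).
    """
    if start_policy not in _START_CODONS:
        raise ValueError(f"unknown start policy {start_policy!r}")
    starts = _START_CODONS[start_policy]
    mrna = mrna.upper().replace("U", "T")
    table = standard_dna_table.forward_table
    orfs: list[OpenReadingFrame] = []
    for i in range(len(mrna) - 2):
        codon = mrna[i : i + 3]
        if codon not in starts:
            continue
        peptide = ["M"]
        stop_pos = i + 3
        has_stop = False
        j = i + 3
        while j + 3 <= len(mrna):
            c = mrna[j : j + 3]
            if c in _STOPS:
                stop_pos = j + 3
                has_stop = True
                break
            aa = table.get(c)
            if aa is None:  # codon containing N: untranslatable, frame ends here
                break
            peptide.append(aa)
            stop_pos = j + 3
            j += 3
        orfs.append(
            OpenReadingFrame(
                start_pos=i + 1,
                stop_pos=stop_pos,
                peptide="".join(peptide),
                start_codon=_RNA[codon],
                has_stop=has_stop,
            )
        )
    return orfs


def flag_nmd(tx: TranscriptModel, orf: OpenReadingFrame, junction_rule_nt: int = 50) -> bool:
    """Apply the 50-nt rule for nonsense-mediated decay candidacy.

    True iff the last base of the ORF's stop codon lies at least
    ``junction_rule_nt`` nucleotides upstream of the final exon-exon
    junction.  Single-exon transcripts can never be NMD candidates.
    """
    if not orf.has_stop:
        raise ValueError("ORF has no stop codon; PTC status cannot be assessed")
    if len(tx.exons) < 2:
        return False
    last_junction = tx.length - len(tx.exons[-1])  # transcript coord of junction
    return (last_junction - orf.stop_pos) >= junction_rule_nt


def predict_tm_helices(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
) -> list[TMHelix]:
    """Predict TM helices by sliding-window Kyte-Doolittle hydropathy.

    The mean hydropathy is computed for every full window; a residue is a
    qualifying center when its window mean is >= ``threshold``.  Each
    maximal run of qualifying centers is reported as one helix; where a
    run reaches the first or last valid center it is extended to the
    window edge (the sequence terminus), since no centers exist there to
    delimit it.  Overlapping spans are merged and helices shorter than
    ``min_len`` are dropped.  Proteins shorter than the window yield an
    empty list.
    """
    n = len(protein)
    if n < window:
        return []
    try:
        scores = [KYTE_DOOLITTLE[aa] for aa in protein]
    except KeyError as exc:
        raise ValueError(f"unknown amino acid {exc.args[0]!r} for hydropathy scale") from None
    half = window // 2
    # window means indexed by 1-based center position c in [half+1, n-half]
    first_c, last_c = half + 1, n - half
    acc = sum(scores[:window])
    means = {first_c: acc / window}
    for c in range(first_c + 1, last_c + 1):
        acc += scores[c + half - 1] - scores[c - half - 2]
        means[c] = acc / window

    spans: list[tuple[int, int, float]] = []
    run_start = None
    peak = float("-inf")
    for c in range(first_c, last_c + 2):
        qualifying = c <= last_c and means[c] >= threshold
        if qualifying:
            if run_start is None:
                run_start = c
                peak = means[c]
            else:
                peak = max(peak, means[c])
        elif run_start is not None:
            s = 1 if run_start == first_c else run_start
            e = n if c - 1 == last_c else c - 1
            spans.append((s, e, peak))
            run_start = None
            peak = float("-inf")

    merged: list[tuple[int, int, float]] = []
    for s, e, p in spans:
        if merged and s <= merged[-1][1]:
            ps, pe, pp = merged.pop()
            s, e, p = ps, max(pe, e), max(pp, p)
        merged.append((s, e, p))
    return [TMHelix(s, e, p) for s, e, p in merged if e - s + 1 >= min_len]


def _tm_presence_vs_canonical(peptide: str, canonical: IsoformRecordSet, **aligner_kwargs):
    # Local import: screen depends on this module's helix predictor.
    from .screen import align_isoform, tm_presence

    aln = align_isoform(canonical.canonical_sequence, peptide, **aligner_kwargs)
    return tm_presence(aln, canonical.tm_domains)


def classify_products(
    tx: TranscriptModel,
    genome: Mapping[str, GenomeSequence],
    canonical_ref: IsoformRecordSet,
    start_policy: str = "aug_only",
    junction_rule_nt: int = 50,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
) -> TopologyCall:
    """Classify which receptor products a transcript can encode.

    The primary ORF is the one opening at the 5'-most qualifying start
    codon.  Its translation is helix-typed and compared against the
    canonical receptor:

    * 7 helices covering TM1..TM7 -> a 7TM product;
    * 6 helices with TM1 absent and TM2..TM7 covered -> a 6TM product;
    * exactly 1 helix with the ORF ending at a PTC (a stop upstream of the
      final exon-exon junction) -> a 1TM fragment, after which reinitiation
      is modelled: the first AUG downstream of both the PTC and the second
      exon's start is tested for a 6TM product.

    The NMD flag applies the 50-nt junction rule to the primary ORF.
    """
    helix_kwargs = dict(window=window, threshold=threshold, min_len=min_len)
    mrna = spliced_sequence(tx, genome)
    orfs = scan_orfs(mrna, start_policy)
    if not orfs:
        return TopologyCall(tx.id, frozenset(), False)

    primary = orfs[0]
    products: set[str] = set()
    helix_counts: dict[str, int] = {}
    supporting = [primary]
    nmd = flag_nmd(tx, primary, junction_rule_nt) if primary.has_stop else False

    helices = predict_tm_helices(primary.peptide, **helix_kwargs)
    presence = _tm_presence_vs_canonical(primary.peptide, canonical_ref)

    if len(helices) == 7 and all(presence):
        products.add("7TM")
        helix_counts["7TM"] = 7
    elif len(helices) == 6 and not presence[0] and all(presence[1:]):
        products.add("6TM")
        helix_counts["6TM"] = 6

    # PTC: the primary ORF terminates upstream of the final exon junction.
    is_ptc = (
        primary.has_stop
        and len(tx.exons) >= 2
        and primary.stop_pos <= tx.length - len(tx.exons[-1])
    )
    if is_ptc and len(helices) == 1:
        products.add("1TM")
        helix_counts["1TM"] = 1
        # Reinitiation: first AUG at/after the second exon boundary and
        # downstream of the PTC.
        exon2_start = len(tx.exons[0]) + 1
        for orf in orfs:
            if (
                orf.start_codon == "AUG"
                and orf.start_pos > primary.stop_pos
                and orf.start_pos >= exon2_start
            ):
                re_helices = predict_tm_helices(orf.peptide, **helix_kwargs)
                re_presence = _tm_presence_vs_canonical(orf.peptide, canonical_ref)
                if len(re_helices) == 6 and not re_presence[0] and all(re_presence[1:]):
                    products.add("6TM")
                    helix_counts["6TM"] = 6
                    supporting.append(orf)
                break

    return TopologyCall(
        transcript_id=tx.id,
        products=frozenset(products),
        nmd_candidate=nmd,
        orfs=tuple(supporting),
        helix_counts=helix_counts,
    )
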