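"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators cover the pipeline: multi-exon 7TM receptor loci whose
transcript variants have known product classes; isoform benchmark sets
with planted truncations; nucleotide alignment pairs evolved under a
two-parameter (transition/transversion) substitution model; and gene-set
universes with planted overlap for the enrichment statistics.  All
generators are seed-deterministic: the same spec yields byte-identical
output.

Receptor loci are built at the codon level with a restricted codon table
so that the only AUG codons in any generated transcript are the planted
initiators (and 5' UTRs contain no AUG/CUG/GUG at all).  Hydrophobic
helices are Leu/Ile/Val/Phe runs, loops are Ser/Thr/Asn/Gly runs; each
generated protein is verified against the package's own hydropathy
predictor and loops are redrawn if an invariant is violated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .enrichment import TRUNCATED_6TM_GENES, GeneSetUniverse
from .conservation import PairwiseAlignment, k2p_distance
from .genomic_io import (
    ExonInterval,
    GenomeSequence,
    IsoformRecord,
    IsoformRecordSet,
    TranscriptModel,
    write_genome,
    write_gtf,
    write_isoform_records,
)
from .topology import predict_tm_helices

__all__ = [
    "LocusSpec",
    "K2PSimSpec",
    "EnrichmentSimSpec",
    "GeneratedLocus",
    "gen_receptor_locus",
    "gen_isoform_benchmark",
    "gen_k2p_pair",
    "gen_enrichment_universe",
    "synthetic_disorder_universe",
]

TRUTH_SCHEMA_VERSION = 1

# Fixed codon choices.  The table is restricted so that, combined with
# {C,A}-only untranslated regions, no ATG can arise anywhere in a
# generated transcript except the planted initiators: no codon starts
# with "TG" and none ends with "AT".
_CODON = {
    "F": "TTT",
    "L": "CTT",
    "I": "ATT",
    "V": "GTT",
    "S": "TCT",
    "T": "ACT",
    "N": "AAC",
    "G": "GGC",
    "M": "ATG",
}
_STOP = "TAA"
_TM_RESIDUES = "LIVF"
_LOOP_RESIDUES = "STNG"
_UTR_BASES = "CA"


def _codons(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)


def _rand_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


# ---------------------------------------------------------------------------
# Receptor loci


@dataclass(frozen=True)
class LocusSpec:
    """Parameters of one synthetic 7TM receptor locus."""

    seed: int
    n_tm_exon1: int = 1  # TM helices encoded by exon 1
    tm_len: int = 21  # residues per helix
    loop_len: int = 15  # residues per loop / tail
    cassette_ptc: bool = True  # emit the PTC-bearing cassette-exon transcript
    utr_len: int = 60  # 5' UTR length, nt

    def __post_init__(self) -> None:
        if not 1 <= self.n_tm_exon1 <= 3:
            raise ValueError("n_tm_exon1 must be between 1 and 3")
        if self.tm_len < 15 or self.loop_len < 12:
            raise ValueError("tm_len >= 15 and loop_len >= 12 required for clean helix calls")


@dataclass
class GeneratedLocus:
    """A synthetic receptor locus: genome, transcript models and truth labels."""

    spec: LocusSpec
    genome: dict[str, GenomeSequence]
    transcripts: list[TranscriptModel]
    canonical_record: IsoformRecordSet
    truth: dict

    @property
    def chrom(self) -> str:
        return self.canonical_record.gene

    def transcript(self, name: str) -> TranscriptModel:
        for tx in self.transcripts:
            if tx.id == name:
                return tx
        raise KeyError(name)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(self.genome, outdir / "genome.fa")
        write_gtf(self.transcripts, outdir / "transcripts.gtf")
        write_isoform_records([self.canonical_record], outdir / "canonical.json")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)
            fh.write("\n")


def _build_protein_segments(spec: LocusSpec, rng: np.random.Generator):
    """Draw tails, helices and loops; return tagged residue segments."""
    tms = [_rand_seq(rng, _TM_RESIDUES, spec.tm_len) for _ in range(7)]
    loops = [_rand_seq(rng, _LOOP_RESIDUES, spec.loop_len) for _ in range(6)]
    ntail = _rand_seq(rng, _LOOP_RESIDUES, spec.loop_len)
    ctail = _rand_seq(rng, _LOOP_RESIDUES, spec.loop_len)
    return tms, loops, ntail, ctail


def gen_receptor_locus(spec: LocusSpec, max_redraws: int = 100) -> GeneratedLocus:
    """Generate a planted 7TM locus with its transcript variants.

    The locus carries three exons plus an optional PTC-bearing cassette
    exon between exons 1 and 2.  Exon 1 encodes the N-tail and the first
    ``n_tm_exon1`` helices; exon 2 opens with an in-frame AUG (a Met
    residue inside the first cytosolic loop) and encodes helices up to
    TM4; exon 3 encodes the rest and the stop codon.  Emitted transcripts:

    * ``canonical`` (exons 1-2-3): encodes the full 7TM receptor;
    * ``exon1_skipped`` (exons 2-3): translation opens at the exon-2 AUG,
      encoding an N-terminally truncated 6TM receptor;
    * ``cassette_ptc`` (exons 1-C-2-3, if requested): the cassette carries
      an in-frame premature stop, yielding a 1TM fragment, an NMD-candidate
      flag, and a reinitiated 6TM product from the exon-2 AUG.

    Generated proteins are verified against the package's hydropathy
    predictor (exactly 7 / 7-n / n helices for the three products) and the
    sequences are redrawn on violation, at most ``max_redraws`` times.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = spec.n_tm_exon1
    for _attempt in range(max_redraws):
        tms, loops, ntail, ctail = _build_protein_segments(spec, rng)
        # Split the loop after the last exon-1 helix: 7 residues stay in
        # exon 1, the rest follow the exon-2 Met (>= 5-residue margins).
        la, lb = loops[n1 - 1][:7], loops[n1 - 1][7:]
        # Loop 4 is split across the exon-2/exon-3 boundary (no new Met).
        l4a, l4b = loops[3][:7], loops[3][7:]

        # Tagged assembly: (residues, tm_index | None), split into the three
        # coding exons; TM coordinates fall out of the cumulative offsets.
        exon1_tagged: list[tuple[str, int | None]] = [("M", None), (ntail, None)]
        for i in range(n1):
            exon1_tagged.append((tms[i], i))
            if i < n1 - 1:
                exon1_tagged.append((loops[i], None))
        exon1_tagged.append((la, None))

        exon2_tagged: list[tuple[str, int | None]] = [("M", None), (lb, None)]
        for i in range(n1, 4):
            exon2_tagged.append((tms[i], i))
            if i < 3:
                exon2_tagged.append((loops[i], None))
        exon2_tagged.append((l4a, None))

        exon3_tagged: list[tuple[str, int | None]] = [
            (l4b, None),
            (tms[4], 4),
            (loops[4], None),
            (tms[5], 5),
            (loops[5], None),
            (tms[6], 6),
            (ctail, None),
        ]

        tm_domains: list[tuple[int, int]] = []
        cursor = 0
        for seg, tm_idx in exon1_tagged + exon2_tagged + exon3_tagged:
            if tm_idx is not None:
                tm_domains.append((cursor + 1, cursor + len(seg)))
            cursor += len(seg)

        exon1_pep = "".join(s for s, _ in exon1_tagged)
        exon2_pep = "".join(s for s, _ in exon2_tagged)
        exon3_pep = "".join(s for s, _ in exon3_tagged)
        canonical_pep = exon1_pep + exon2_pep + exon3_pep
        skipped_pep = exon2_pep + exon3_pep

        cassette_pep_a = _rand_seq(rng, _LOOP_RESIDUES, 4)
        cassette_pep_b = _rand_seq(rng, _LOOP_RESIDUES, 5)
        ptc_pep = exon1_pep + cassette_pep_a  # product of the PTC-terminated frame

        ok = (
            len(tm_domains) == 7
            and len(predict_tm_helices(canonical_pep)) == 7
            and len(predict_tm_helices(skipped_pep)) == 7 - n1
            and len(predict_tm_helices(ptc_pep)) == n1
        )
        if ok:
            break
    else:
        raise RuntimeError(f"locus verification failed after {max_redraws} redraws")

    gene = f"SYNOPR{spec.seed}"
    utr5 = _rand_seq(rng, _UTR_BASES, spec.utr_len)
    utr3 = _rand_seq(rng, _UTR_BASES, 30)
    exon1_nt = utr5 + _codons(exon1_pep)
    cassette_nt = _codons(cassette_pep_a) + _STOP + _codons(cassette_pep_b)
    exon2_nt = _codons(exon2_pep)
    exon3_nt = _codons(exon3_pep) + _STOP + utr3
    pad = _rand_seq(rng, _UTR_BASES, 10)
    intron = lambda: _rand_seq(rng, _UTR_BASES, 60)

    pieces = [pad, exon1_nt, intron(), cassette_nt, intron(), exon2_nt, intron(), exon3_nt, pad]
    coords = []
    pos = 1
    for piece in pieces:
        coords.append((pos, pos + len(piece) - 1))
        pos += len(piece)
    genome_seq = "".join(pieces)
    chrom = gene
    e1 = ExonInterval(chrom, *coords[1], "+", "exon1")
    cas = ExonInterval(chrom, *coords[3], "+", "cassette")
    e2 = ExonInterval(chrom, *coords[5], "+", "exon2")
    e3 = ExonInterval(chrom, *coords[7], "+", "exon3")

    transcripts = [
        TranscriptModel("canonical", (e1, e2, e3), "+", gene),
        TranscriptModel("exon1_skipped", (e2, e3), "+", gene),
    ]
    truth_tx = {
        "canonical": {"products": ["7TM"], "nmd": False},
        "exon1_skipped": {"products": [f"{7 - n1}TM"], "nmd": False},
    }
    if spec.cassette_ptc:
        transcripts.append(TranscriptModel("cassette_ptc", (e1, cas, e2, e3), "+", gene))
        truth_tx["cassette_ptc"] = {"products": [f"{n1}TM", f"{7 - n1}TM"], "nmd": True}

    record = IsoformRecordSet(gene, canonical_pep, tuple(tm_domains))
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "seed": spec.seed,
        "gene": gene,
        "transcripts": truth_tx,
    }
    return GeneratedLocus(
        spec=spec,
        genome={chrom: GenomeSequence(chrom, genome_seq)},
        transcripts=transcripts,
        canonical_record=record,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Isoform benchmark


_BENCH_CATEGORIES = (
    "full",
    "N_trunc_6TM",
    "C_trunc_6TM",
    "N_trunc_5TM",
    "C_trunc_5TM",
    "rescue",
    "fragment",
)


def gen_isoform_benchmark(
    seed: int,
    category_mix: Mapping[str, int],
    tm_len: int = 21,
    loop_len: int = 15,
    max_redraws: int = 100,
) -> tuple[list[IsoformRecordSet], dict]:
    """Generate one-isoform-per-gene record sets with planted truncations.

    ``category_mix`` maps category names (``full``, ``N_trunc_6TM``,
    ``C_trunc_6TM``, ``N_trunc_5TM``, ``C_trunc_5TM``, ``rescue``,
    ``fragment``) to gene counts.  Truncations are whole-TM deletions with
    at least 5 residues of flanking loop removed alongside, so category
    recovery by the screen is unambiguous.  ``rescue`` isoforms replace
    TM1 with a fresh hydrophobic run (expected call: a 7-helix receptor);
    ``fragment`` isoforms carry the database-fragment flag and must be
    excluded by the screen.

    Returns ``(records, truth)`` where truth maps isoform ids to their
    expected category and selection status.
    """
    unknown = set(category_mix) - set(_BENCH_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown benchmark categories: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    records: list[IsoformRecordSet] = []
    truth_isoforms: dict[str, dict] = {}
    gene_idx = 0
    for category in _BENCH_CATEGORIES:
        for _ in range(category_mix.get(category, 0)):
            gene_idx += 1
            gene = f"SYNGENE{gene_idx:03d}"
            for _attempt in range(max_redraws):
                tms = [_rand_seq(rng, _TM_RESIDUES, tm_len) for _ in range(7)]
                loops = [_rand_seq(rng, _LOOP_RESIDUES, loop_len) for _ in range(6)]
                ntail = _rand_seq(rng, _LOOP_RESIDUES, 20)
                ctail = _rand_seq(rng, _LOOP_RESIDUES, 20)
                seq = ntail
                tm_domains = []
                for i in range(7):
                    tm_domains.append((len(seq) + 1, len(seq) + tm_len))
                    seq += tms[i]
                    if i < 6:
                        seq += loops[i]
                seq += ctail
                if len(predict_tm_helices(seq)) == 7:
                    break
            else:
                raise RuntimeError(f"benchmark gene verification failed after {max_redraws} redraws")

            iso_id = f"{gene}-iso1"
            fragment = False
            if category == "full":
                iso_seq = seq
                expected = "full_7TM"
            elif category == "N_trunc_6TM":
                iso_seq = seq[tm_domains[0][1] + 5 :]
                expected = "N_trunc_6TM"
            elif category == "C_trunc_6TM":
                iso_seq = seq[: tm_domains[6][0] - 6]
                expected = "C_trunc_6TM"
            elif category == "N_trunc_5TM":
                iso_seq = seq[tm_domains[1][1] + 5 :]
                expected = "N_trunc_5TM"
            elif category == "C_trunc_5TM":
                iso_seq = seq[: tm_domains[5][0] - 6]
                expected = "C_trunc_5TM"
            elif category == "rescue":
                s, e = tm_domains[0]
                iso_seq = seq[: s - 1] + _rand_seq(rng, _TM_RESIDUES, tm_len) + seq[e:]
                expected = "full_7TM"
            else:  # fragment
                iso_seq = seq[tm_domains[0][1] + 5 :]
                fragment = True
                expected = "excluded_fragment"

            records.append(
                IsoformRecordSet(
                    gene, seq, tuple(tm_domains), (IsoformRecord(iso_id, iso_seq, fragment),)
                )
            )
            truth_isoforms[iso_id] = {
                "gene": gene,
                "category": expected,
                "selected": expected in ("N_trunc_6TM", "C_trunc_6TM", "N_trunc_5TM", "C_trunc_5TM"),
            }
    truth = {"schema_version": TRUTH_SCHEMA_VERSION, "seed": seed, "isoforms": truth_isoforms}
    return records, truth


# ---------------------------------------------------------------------------
# Two-parameter substitution pairs


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class K2PSimSpec:
    """Parameters for one simulated orthologous sequence pair.

    ``P_target`` and ``Q_target`` are the per-site probabilities of a
    transition and a transversion (realized-proportion targets), so the
    closed-form distance K(P_target, Q_target) is the exact expectation
    oracle for the estimator.
    """

    seed: int
    length: int = 10_000
    P_target: float = 0.05
    Q_target: float = 0.02

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValueError("length must be >= 100")
        if self.P_target < 0 or self.Q_target < 0 or self.P_target + self.Q_target >= 0.5:
            raise ValueError("require P, Q >= 0 and P + Q < 0.5 (safe of saturation)")


def gen_k2p_pair(spec: K2PSimSpec) -> tuple[PairwiseAlignment, dict]:
    """Evolve a random sequence pair under the two-parameter model.

    Per site, independently: a transition with probability ``P_target``, a
    transversion with probability ``Q_target`` (the two transversion
    targets equiprobable), identity otherwise.  No indels are introduced.
    Returns the (gap-free) alignment and a truth dict containing the
    planted proportions and the closed-form expected distance.
    """
    rng = np.random.default_rng(spec.seed)
    bases = "ACGT"
    query = _rand_seq(rng, bases, spec.length)
    u = rng.random(spec.length)
    pick = rng.integers(0, 2, size=spec.length)
    subject_chars = []
    for i, q in enumerate(query):
        if u[i] < spec.P_target:
            subject_chars.append(_TRANSITION[q])
        elif u[i] < spec.P_target + spec.Q_target:
            subject_chars.append(_TRANSVERSIONS[q][pick[i]])
        else:
            subject_chars.append(q)
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "seed": spec.seed,
        "P_target": spec.P_target,
        "Q_target": spec.Q_target,
        "K_expected": k2p_distance(spec.P_target, spec.Q_target)
        if (spec.P_target, spec.Q_target) != (0.0, 0.0)
        else 0.0,
    }
    return PairwiseAlignment(query, "".join(subject_chars)), truth


# ---------------------------------------------------------------------------
# Enrichment universes


@dataclass(frozen=True)
class EnrichmentSimSpec:
    """A synthetic gene universe with a planted (or null) overlap.

    With ``k_planted`` set, the receptor/disorder overlap is exactly that
    many genes; with ``k_planted=None`` the overlap is drawn from the null
    hypergeometric distribution Hypergeom(N, m, n).
    """

    seed: int
    N: int = 19_020
    m: int = 12
    n: int = 800
    k_planted: int | None = None

    def __post_init__(self) -> None:
        if self.k_planted is not None and self.k_planted > min(self.m, self.n):
            raise ValueError("k_planted cannot exceed min(m, n)")
        if self.m > self.N or self.n > self.N:
            raise ValueError("set sizes cannot exceed the universe")


def gen_enrichment_universe(spec: EnrichmentSimSpec) -> tuple[GeneSetUniverse, dict]:
    """Build a synthetic symbol universe with known overlap."""
    rng = np.random.default_rng(spec.seed)
    symbols = [f"G{i:05d}" for i in range(spec.N)]
    gpcr = symbols[: spec.m]
    non_gpcr = symbols[spec.m :]
    k = (
        spec.k_planted
        if spec.k_planted is not None
        else int(rng.hypergeometric(spec.m, spec.N - spec.m, spec.n))
    )
    disorder = gpcr[:k] + non_gpcr[: spec.n - k]
    universe = GeneSetUniverse(
        N=spec.N,
        gpcr=frozenset(gpcr),
        disorder_sets={"disorder": frozenset(disorder)},
        universe=frozenset(symbols),
    )
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "seed": spec.seed,
        "k": k,
        "null_draw": spec.k_planted is None,
    }
    return universe, truth


def synthetic_disorder_universe() -> tuple[GeneSetUniverse, GeneSetUniverse]:
    """Synthetic stand-in for the curated disorder gene lists.

    Only the 12-gene truncated-6TM receptor list is real
    (:data:`sixtm.enrichment.TRUNCATED_6TM_GENES`).  The 824-gene GPCR set
    and the pain (800), psychiatric (1383) and addiction (383) lists are
    synthetic placeholder symbols with planted overlaps: 7/4/3 of the 6TM
    genes fall in the three disorder sets, and 119/93/17 GPCR genes
    overall (the addiction overlap sits at the chance level
    824*383/19020 ~= 16.6, i.e. no enrichment).  Set sizes and overlap
    counts, not gene identities, drive the statistics, so the arithmetic
    on this universe matches a run on the curated lists with the same
    counts.

    Returns ``(six_tm_universe, all_gpcr_universe)`` sharing the same
    disorder sets.
    """
    N = 19_020
    six_tm = list(TRUNCATED_6TM_GENES)
    oprs = ["OPRM1", "OPRD1", "OPRK1", "OPRL1"]
    other_gpcr = [f"SYNGPCR{i:04d}" for i in range(1, 813)]  # 812 + 12 = 824
    gpcr824 = six_tm + other_gpcr

    pain_6tm = oprs + ["CCKAR", "CCKBR", "TACR2"]  # 7 of the 12
    psych_6tm = oprs  # 4
    addiction_6tm = ["OPRM1", "OPRD1", "OPRK1"]  # 3

    pain = pain_6tm + other_gpcr[:112] + [f"SYNPAIN{i:04d}" for i in range(800 - 119)]
    psych = psych_6tm + other_gpcr[112:201] + [f"SYNPSY{i:04d}" for i in range(1383 - 93)]
    addiction = addiction_6tm + other_gpcr[201:215] + [f"SYNADD{i:04d}" for i in range(383 - 17)]

    disorder_sets = {
        "pain": frozenset(pain),
        "psychiatric": frozenset(psych),
        "addiction": frozenset(addiction),
    }
    return (
        GeneSetUniverse(N=N, gpcr=frozenset(six_tm), disorder_sets=disorder_sets),
        GeneSetUniverse(N=N, gpcr=frozenset(gpcr824), disorder_sets=disorder_sets),
    )
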