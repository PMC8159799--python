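"""Genomic file formats and spliced-transcript assembly.

This module carries the plumbing for the rest of the package: genome
sequences (FASTA), exon/transcript models (GTF/GFF3 or BED), per-base
conservation score tracks (bedGraph or fixed-step wiggle), and receptor
isoform records with annotated transmembrane (TM) domains.

Coordinate convention
---------------------
All in-memory coordinates are 1-based, fully closed intervals (the
GTF/genome-browser convention).  BED input, which is 0-based half-open,
is converted at the parsing boundary and never stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "ExonInterval",
    "TranscriptModel",
    "ScoreTrack",
    "IsoformRecord",
    "IsoformRecordSet",
    "read_genome",
    "write_genome",
    "load_gene_models",
    "write_gtf",
    "spliced_sequence",
    "load_score_track",
    "write_bedgraph",
    "load_isoform_records",
    "write_isoform_records",
]

_NUC_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _NUC_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ExonInterval:
    """A 1-based closed genomic interval on a named chromosome/contig."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"exon {self.label or self.chrom}: require 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced mRNA model: ordered exons on one strand of one chromosome.

    Exons are stored in transcription (5'->3') order: ascending genomic
    start on the plus strand, descending on the minus strand.
    """

    id: str
    exons: tuple[ExonInterval, ...]
    strand: str
    gene: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise ValueError(f"transcript {self.id!r} has no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"transcript {self.id!r} spans chromosomes {sorted(chroms)}")
        if any(e.strand != self.strand for e in self.exons):
            raise ValueError(f"transcript {self.id!r}: exon strand differs from transcript")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"transcript {self.id!r}: exons [{a.start},{a.end}] and "
                    f"[{b.start},{b.end}] overlap"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != self.exons:
            raise ValueError(
                f"transcript {self.id!r}: exons not in 5'->3' order for strand {self.strand}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class ScoreTrack:
    """Sparse per-base scores in [0, 1], addressed by 1-based position."""

    chrom: str
    values: dict[int, float] = field(default_factory=dict)

    def set(self, pos: int, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise ValueError(
                f"score {score} at {self.chrom}:{pos} out of range: values range from 0 to 1"
            )
        self.values[pos] = score

    def get(self, pos: int) -> float | None:
        return self.values.get(pos)


@dataclass(frozen=True)
class IsoformRecord:
    id: str
    sequence: str
    fragment: bool = False


@dataclass(frozen=True)
class IsoformRecordSet:
    """A canonical 7TM receptor plus its splice isoforms.

    ``tm_domains`` are seven 1-based closed residue ranges on the canonical
    sequence (TM1..TM7), non-overlapping and ascending.  Exactly seven
    ranges are required -- that is the GPCR contract this package screens
    against.
    """

    gene: str
    canonical_sequence: str
    tm_domains: tuple[tuple[int, int], ...]
    isoforms: tuple[IsoformRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "tm_domains", tuple(tuple(d) for d in self.tm_domains))
        object.__setattr__(self, "isoforms", tuple(self.isoforms))
        if len(self.tm_domains) != 7:
            raise ValueError(
                f"gene {self.gene!r}: canonical record must carry exactly 7 TM domains, "
                f"got {len(self.tm_domains)}"
            )
        prev_end = 0
        for i, (s, e) in enumerate(self.tm_domains, start=1):
            if not (1 <= s <= e <= len(self.canonical_sequence)):
                raise ValueError(f"gene {self.gene!r}: TM{i} range [{s},{e}] out of bounds")
            if s <= prev_end:
                raise ValueError(f"gene {self.gene!r}: TM domains overlap or are unordered at TM{i}")
            prev_end = e


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a FASTA file into a {id: GenomeSequence} store."""
    store: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        store[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not store:
        raise FormatError(f"{path}: no FASTA records found")
    return store


def write_genome(store: Mapping[str, GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in store.values():
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 70):
                fh.write(seq.residues[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GTF / GFF3 / BED transcript models


def _parse_gtf_attributes(raw: str, lineno: int, gff3: bool) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if gff3:
        for part in raw.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                raise FormatError(f"line {lineno}: malformed GFF3 attribute {part!r}")
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    else:
        for part in raw.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            if " " not in part:
                raise FormatError(f"line {lineno}: malformed GTF attribute {part!r}")
            k, v = part.split(" ", 1)
            attrs[k.strip()] = v.strip().strip('"')
    return attrs


def _transcripts_from_exons(
    exons_by_tx: dict[str, list[tuple[ExonInterval, str]]],
    tx_order: list[str],
) -> list[TranscriptModel]:
    models = []
    for tx_id in tx_order:
        pairs = exons_by_tx[tx_id]
        strand = pairs[0][0].strand
        gene = pairs[0][1]
        exons = sorted((e for e, _ in pairs), key=lambda e: e.start)
        if strand == "-":
            exons = exons[::-1]
        models.append(TranscriptModel(tx_id, tuple(exons), strand, gene))
    return models


def load_gene_models(
    annotation_path: str | Path, genome_path: str | Path
) -> tuple[list[TranscriptModel], dict[str, GenomeSequence]]:
    """Load transcript models (GTF/GFF3 or BED) together with their genome.

    The annotation format is chosen from the file extension (``.bed`` vs
    ``.gtf``/``.gff``/``.gff3``).  Every exon is checked against the genome:
    an unknown chromosome or an out-of-bounds interval is a hard error
    naming the offending id.
    """
    genome = read_genome(genome_path)
    suffix = Path(annotation_path).suffix.lower()
    if suffix == ".bed":
        transcripts = _load_bed(annotation_path)
    elif suffix in (".gtf", ".gff", ".gff3"):
        transcripts = _load_gtf(annotation_path, gff3=suffix in (".gff", ".gff3"))
    else:
        raise FormatError(f"unrecognized annotation extension {suffix!r}")
    for tx in transcripts:
        if tx.chrom not in genome:
            raise FormatError(f"transcript {tx.id!r}: unknown chromosome {tx.chrom!r}")
        bound = len(genome[tx.chrom])
        for e in tx.exons:
            if e.end > bound:
                raise FormatError(
                    f"transcript {tx.id!r}: exon [{e.start},{e.end}] exceeds "
                    f"{tx.chrom!r} length {bound}"
                )
    return transcripts, genome


def _load_gtf(path: str | Path, gff3: bool) -> list[TranscriptModel]:
    exons_by_tx: dict[str, list[tuple[ExonInterval, str]]] = {}
    tx_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_raw = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            attrs = _parse_gtf_attributes(attr_raw, lineno, gff3)
            tx_id = attrs.get("transcript_id") or attrs.get("Parent")
            if not tx_id:
                raise FormatError(f"line {lineno}: exon without transcript_id/Parent")
            gene = attrs.get("gene_id") or attrs.get("gene") or ""
            label = attrs.get("exon_id") or attrs.get("ID") or ""
            exon = ExonInterval(chrom, start, end, strand, label)
            if tx_id not in exons_by_tx:
                exons_by_tx[tx_id] = []
                tx_order.append(tx_id)
            exons_by_tx[tx_id].append((exon, gene))
    return _transcripts_from_exons(exons_by_tx, tx_order)


def _load_bed(path: str | Path) -> list[TranscriptModel]:
    """Read BED3/BED6 exon rows; rows sharing a name form one transcript."""
    exons_by_tx: dict[str, list[tuple[ExonInterval, str]]] = {}
    tx_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 6):
                raise FormatError(f"line {lineno}: expected 3 or 6 BED columns")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            name = fields[3] if len(fields) == 6 else f"bed_{lineno}"
            strand = fields[5] if len(fields) == 6 else "+"
            # BED is 0-based half-open; store 1-based closed.
            exon = ExonInterval(chrom, start0 + 1, end0, strand, name)
            if name not in exons_by_tx:
                exons_by_tx[name] = []
                tx_order.append(name)
            exons_by_tx[name].append((exon, ""))
    return _transcripts_from_exons(exons_by_tx, tx_order)


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF exon rows (lossless round-trip)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            for e in tx.exons:
                attrs = f'gene_id "{tx.gene}"; transcript_id "{tx.id}";'
                if e.label:
                    attrs += f' exon_id "{e.label}";'
                fh.write(
                    f"{e.chrom}\tsixtm\texon\t{e.start}\t{e.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Spliced sequence


def spliced_sequence(tx: TranscriptModel, genome: Mapping[str, GenomeSequence]) -> str:
    """Assemble the mature mRNA sequence (DNA alphabet) of a transcript.

    Exon substrings are concatenated in genomic order; on the minus strand
    the concatenation is reverse-complemented, so the result always reads
    5'->3' in transcript orientation.
    """
    if tx.chrom not in genome:
        raise KeyError(f"transcript {tx.id!r}: unknown chromosome {tx.chrom!r}")
    residues = genome[tx.chrom].residues
    parts = []
    for e in sorted(tx.exons, key=lambda x: x.start):
        if e.end > len(residues):
            raise ValueError(
                f"transcript {tx.id!r}: exon [{e.start},{e.end}] out of bounds "
                f"for {tx.chrom!r} (length {len(residues)})"
            )
        parts.append(residues[e.start - 1 : e.end])
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


# ---------------------------------------------------------------------------
# Score tracks


def load_score_track(path: str | Path) -> dict[str, ScoreTrack]:
    """Load a bedGraph or fixed-step wiggle file into per-chromosome tracks.

    Interval rows are expanded to per-base values; any score outside
    [0, 1] is rejected (conservation scores' values range from 0 to 1).
    """
    tracks: dict[str, ScoreTrack] = {}

    def track(chrom: str) -> ScoreTrack:
        if chrom not in tracks:
            tracks[chrom] = ScoreTrack(chrom)
        return tracks[chrom]

    with open(path) as fh:
        mode = "bedgraph"
        chrom = ""
        pos = step = 1
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "wiggle"
                decl = dict(p.split("=", 1) for p in line.split()[1:])
                try:
                    chrom = decl["chrom"]
                    pos = int(decl["start"])
                    step = int(decl.get("step", "1"))
                except (KeyError, ValueError):
                    raise FormatError(f"line {lineno}: malformed fixedStep declaration") from None
                continue
            if mode == "wiggle":
                try:
                    score = float(line)
                except ValueError:
                    raise FormatError(f"line {lineno}: non-numeric wiggle value") from None
                try:
                    track(chrom).set(pos, score)
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: {exc}") from None
                pos += step
            else:
                fields = line.split("\t")
                if len(fields) != 4:
                    raise FormatError(f"line {lineno}: expected 4 bedGraph columns")
                try:
                    start0, end0, score = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError:
                    raise FormatError(f"line {lineno}: non-numeric bedGraph fields") from None
                t = track(fields[0])
                for p in range(start0 + 1, end0 + 1):  # 0-based half-open -> 1-based closed
                    try:
                        t.set(p, score)
                    except ValueError as exc:
                        raise FormatError(f"line {lineno}: {exc}") from None
    if not tracks:
        raise FormatError(f"{path}: no score rows found")
    return tracks


def write_bedgraph(tracks: Mapping[str, ScoreTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in tracks:
            vals = tracks[chrom].values
            for pos in sorted(vals):
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{vals[pos]:g}\n")


# ---------------------------------------------------------------------------
# Isoform records


def _record_set_from_dict(obj: dict) -> IsoformRecordSet:
    canonical = obj["canonical"]
    tm = tuple(zip(canonical["tm_starts"], canonical["tm_ends"]))
    isoforms = tuple(
        IsoformRecord(i["id"], i["sequence"], bool(i.get("fragment", False)))
        for i in obj.get("isoforms", [])
    )
    return IsoformRecordSet(obj["gene"], canonical["sequence"], tm, isoforms)


def load_isoform_records(path: str | Path) -> list[IsoformRecordSet]:
    """Load isoform record sets from JSON or TSV.

    JSON: a list of objects ``{gene, canonical: {sequence, tm_starts,
    tm_ends}, isoforms: [{id, sequence, fragment}]}``.

    TSV columns: gene, isoform_id, sequence, is_canonical, fragment,
    tm_starts, tm_ends (comma-separated integers, canonical rows only).

    The canonical entry of every gene must carry exactly seven TM domains;
    fragment flags are preserved for downstream exclusion.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        return [_record_set_from_dict(obj) for obj in data]

    by_gene: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene", "isoform_id", "sequence", "is_canonical", "fragment", "tm_starts", "tm_ends"]
        if header != expected:
            raise FormatError(f"header must be {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise FormatError(f"line {lineno}: expected 7 columns")
            gene, iso_id, seq, is_canon, fragment, tm_s, tm_e = fields
            if gene not in by_gene:
                by_gene[gene] = {"canonical": None, "isoforms": []}
                order.append(gene)
            if is_canon.lower() in ("1", "true", "yes"):
                starts = [int(x) for x in tm_s.split(",") if x]
                ends = [int(x) for x in tm_e.split(",") if x]
                by_gene[gene]["canonical"] = (seq, tuple(zip(starts, ends)))
            else:
                by_gene[gene]["isoforms"].append(
                    IsoformRecord(iso_id, seq, fragment.lower() in ("1", "true", "yes"))
                )
    out = []
    for gene in order:
        entry = by_gene[gene]
        if entry["canonical"] is None:
            raise FormatError(f"gene {gene!r}: no canonical row")
        seq, tm = entry["canonical"]
        out.append(IsoformRecordSet(gene, seq, tm, tuple(entry["isoforms"])))
    return out


def write_isoform_records(records: Sequence[IsoformRecordSet], path: str | Path) -> None:
    """Write record sets to the JSON schema read by :func:`load_isoform_records`."""
    data = []
    for rs in records:
        data.append(
            {
                "gene": rs.gene,
                "canonical": {
                    "sequence": rs.canonical_sequence,
                    "tm_starts": [s for s, _ in rs.tm_domains],
                    "tm_ends": [e for _, e in rs.tm_domains],
                },
                "isoforms": [
                    {"id": i.id, "sequence": i.sequence, "fragment": i.fragment}
                    for i in rs.isoforms
                ],
            }
        )
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")
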