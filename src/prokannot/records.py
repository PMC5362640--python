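"""Domain types and readers/writers for the annotation toolkit.

All coordinates in the public data model are 1-based and inclusive, matching
GenBank, GFF3, AGP and the NCBI feature table.  Conversions to Biopython's
0-based half-open locations happen only inside the format readers/writers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    AfterPosition,
    BeforePosition,
    ExactPosition,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord as BioSeqRecord

__all__ = [
    "SeqRecord",
    "Feature",
    "GeneCall",
    "GeneModel",
    "ContigMap",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_genbank",
    "read_gff_gene_model",
    "write_gff_gene_model",
    "read_contig_map",
    "write_contig_map",
    "extract_db_fasta",
    "translate_cds",
]

IUPAC_NT = set("ACGTUNRYSWKMBDHV")

GENETIC_CODE_TABLE = 11  # bacterial/archaeal/plant-plastid code


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when in-memory objects violate a domain invariant."""


@dataclass
class Feature:
    """A typed genomic interval with 1-based inclusive coordinates."""

    key: str
    start: int
    end: int
    strand: str = "+"
    partial5: bool = False
    partial3: bool = False
    qualifiers: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"feature {self.key}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in "+-":
            raise ValidationError(f"feature {self.key}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def qualifier(self, name: str) -> str | None:
        for qname, value in self.qualifiers:
            if qname == name:
                return value
        return None

    def set_qualifier(self, name: str, value: str) -> None:
        for i, (qname, _) in enumerate(self.qualifiers):
            if qname == name:
                self.qualifiers[i] = (name, value)
                return
        self.qualifiers.append((name, value))


@dataclass
class SeqRecord:
    """A named nucleotide sequence with an ordered feature list."""

    id: str
    sequence: str
    description: str = ""
    features: list[Feature] = field(default_factory=list)
    molecule_topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        bad = set(self.sequence.upper()) - IUPAC_NT
        if bad:
            raise ValidationError(f"{self.id}: non-IUPAC characters {sorted(bad)}")
        for feat in self.features:
            if feat.end > len(self.sequence):
                raise ValidationError(
                    f"{self.id}: feature {feat.key} {feat.start}..{feat.end} "
                    f"beyond sequence length {len(self.sequence)}"
                )

    def subsequence(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self.sequence[start - 1 : end]


@dataclass
class GeneCall:
    """One gene prediction; caller_tag records the contributing caller(s)."""

    start: int
    end: int
    strand: str
    caller_tag: str = "internal"
    gene_number: int | None = None
    partial5: bool = False
    partial3: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def stop_coordinate(self) -> int:
        """Genomic coordinate of the translation stop end (3' end)."""
        return self.end if self.strand == "+" else self.start

    def span_key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.strand)


@dataclass
class GeneModel:
    """Ordered collection of gene calls for one sequence."""

    calls: list[GeneCall] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def sorted(self) -> "GeneModel":
        return GeneModel(sorted(self.calls, key=lambda c: (c.start, c.end, c.strand)))


@dataclass
class ContigMap:
    """Placement of each contig inside a concatenated pseudo-molecule."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        prev_stop = 0
        for contig_id, start, stop in self.entries:
            if start > stop:
                raise ValidationError(f"{contig_id}: start {start} > stop {stop}")
            if start <= prev_stop:
                raise ValidationError(f"{contig_id}: overlaps previous entry")
            prev_stop = stop

    def spacer_intervals(self) -> list[tuple[int, int]]:
        """Gaps between consecutive contigs (the spacer placements)."""
        gaps = []
        for (_, _, stop), (_, nstart, _) in zip(self.entries, self.entries[1:]):
            if nstart > stop + 1:
                gaps.append((stop + 1, nstart - 1))
        return gaps


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[SeqRecord]:
    """Read a (multi-record) FASTA file; sequences are upper-cased.

    ``alphabet="nt"`` enforces the IUPAC nucleotide alphabet (position of
    the first offending character is reported); ``"aa"`` skips validation
    for protein databases.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: FASTA must begin with '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "nt":
            for pos, ch in enumerate(seq, start=1):
                if ch not in IUPAC_NT:
                    raise FormatError(
                        f"{path}: record {rec.id}: non-IUPAC character {ch!r} "
                        f"at position {pos}"
                    )
        records.append(SeqRecord(id=rec.id, sequence=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank


def _feature_from_bio(bfeat: SeqFeature, seq_len: int, record_id: str) -> Feature:
    loc = bfeat.location
    start = int(loc.start) + 1
    end = int(loc.end)
    if end > seq_len or start < 1:
        raise FormatError(
            f"{record_id}: feature {bfeat.type} at {start}..{end} exceeds "
            f"sequence length {seq_len}"
        )
    strand = "-" if loc.strand == -1 else "+"
    qualifiers: list[tuple[str, str]] = []
    # compound locations collapse to their outer span; the original string is kept
    if len(getattr(loc, "parts", [loc])) > 1:
        qualifiers.append(("original_location", str(loc)))
    low_partial = isinstance(loc.parts[0].start, BeforePosition)
    high_partial = isinstance(loc.parts[-1].end, AfterPosition)
    if strand == "+":
        partial5, partial3 = low_partial, high_partial
    else:
        partial5, partial3 = high_partial, low_partial
    for name, values in bfeat.qualifiers.items():
        for value in values:
            qualifiers.append((name, str(value)))
    return Feature(
        key=bfeat.type,
        start=start,
        end=end,
        strand=strand,
        partial5=partial5,
        partial3=partial3,
        qualifiers=qualifiers,
    )


def read_genbank(path: str | Path) -> list[SeqRecord]:
    """Read a (multi-record) GenBank flat file with features."""
    path = Path(path)
    text = path.read_text()
    if "LOCUS" not in text:
        raise FormatError(f"{path}: missing LOCUS line")
    if "ORIGIN" not in text:
        raise FormatError(f"{path}: missing ORIGIN section")
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        features = [
            _feature_from_bio(bf, len(seq), rec.id)
            for bf in rec.features
            if bf.type != "source"
        ]
        topology = rec.annotations.get("topology", "linear")
        records.append(
            SeqRecord(
                id=rec.id,
                sequence=seq,
                description=rec.description,
                features=features,
                molecule_topology=topology,
            )
        )
    return records


def _feature_to_bio(feat: Feature, seq_len: int) -> SeqFeature:
    if feat.end > seq_len:
        raise ValidationError(
            f"feature {feat.key} {feat.start}..{feat.end} beyond length {seq_len}"
        )
    if feat.strand == "+":
        low_partial, high_partial = feat.partial5, feat.partial3
    else:
        low_partial, high_partial = feat.partial3, feat.partial5
    start_pos = BeforePosition(feat.start - 1) if low_partial else ExactPosition(feat.start - 1)
    end_pos = AfterPosition(feat.end) if high_partial else ExactPosition(feat.end)
    strand = 1 if feat.strand == "+" else -1
    quals: dict[str, list[str]] = {}
    for name, value in feat.qualifiers:
        quals.setdefault(name, []).append(value)
    return SeqFeature(
        SimpleLocation(start_pos, end_pos, strand=strand),
        type=feat.key,
        qualifiers=quals,
    )


def _to_bio_record(rec: SeqRecord) -> BioSeqRecord:
    bio = BioSeqRecord(
        Seq(rec.sequence),
        id=rec.id,
        name=re.sub(r"[^A-Za-z0-9_.-]", "_", rec.id)[:16] or "SEQ",
        description=rec.description,
    )
    bio.annotations["molecule_type"] = "DNA"
    bio.annotations["topology"] = rec.molecule_topology
    bio.annotations["date"] = "01-JAN-2000"  # fixed so reruns are byte-identical
    bio.features = [_feature_to_bio(f, len(rec.sequence)) for f in rec.features]
    return bio


def write_genbank(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records to a (multi-record) GenBank flat file."""
    bio_records = [_to_bio_record(rec) for rec in records]
    with open(path, "w") as fh:
        SeqIO.write(bio_records, fh, "genbank")


# ---------------------------------------------------------------------------
# GFF gene models


def read_gff_gene_model(path: str | Path) -> GeneModel:
    """Import an external gene model from 9-column GFF3 (gene/CDS rows).

    Rows of type ``gene`` or ``CDS`` become calls tagged ``external``;
    identical spans contributed by both a gene and its CDS row collapse to
    one call.  Coordinates stay 1-based inclusive as in GFF3.
    """
    path = Path(path)
    calls: list[GeneCall] = []
    seen: set[tuple[int, int, str]] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise FormatError(f"{path}:{lineno}: expected ≥8 tab-separated columns")
        ftype = cols[2]
        if ftype not in ("gene", "CDS"):
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end < start:
            raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
        strand = cols[6]
        if strand not in "+-":
            raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        key = (start, end, strand)
        if key in seen:
            continue
        seen.add(key)
        calls.append(GeneCall(start=start, end=end, strand=strand, caller_tag="external"))
    return GeneModel(calls)


def write_gff_gene_model(model: GeneModel, seqid: str, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for i, call in enumerate(model.calls, start=1):
        lines.append(
            "\t".join(
                [
                    seqid,
                    "prokannot",
                    "gene",
                    str(call.start),
                    str(call.end),
                    ".",
                    call.strand,
                    ".",
                    f"ID=gene{i};caller={call.caller_tag}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Contig-order file


def write_contig_map(contig_map: ContigMap, path: str | Path) -> None:
    lines = ["contig_id\tstart\tstop"]
    for contig_id, start, stop in contig_map:
        lines.append(f"{contig_id}\t{start}\t{stop}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_contig_map(path: str | Path) -> ContigMap:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != ["contig_id", "start", "stop"]:
        raise FormatError(f"{path}: missing contig-order header")
    entries = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        entries.append((cols[0], int(cols[1]), int(cols[2])))
    cmap = ContigMap(entries)
    cmap.validate()
    return cmap


# ---------------------------------------------------------------------------
# GenBank -> FASTA extraction for custom database building


def translate_cds(nt: str, partial5: bool = False) -> str:
    """Translate a CDS with the bacterial code; alternative start codons
    become M at position 1 of a complete CDS.  Internal stops translate to
    ``*`` and are left for the caller to flag."""
    seq = Seq(nt)
    prot = str(seq.translate(table=GENETIC_CODE_TABLE))
    if prot.endswith("*"):
        prot = prot[:-1]
    if not partial5 and prot and nt[:3].upper() in ("ATG", "GTG", "TTG", "ATT", "CTG", "ATC", "ATA"):
        prot = "M" + prot[1:]
    return prot


def extract_db_fasta(
    records: Sequence[SeqRecord],
    mode: str = "nucleotide",
    log: list[str] | None = None,
) -> list[SeqRecord]:
    """Extract database FASTA entries from annotated records.

    ``nucleotide`` mode emits one entry per record (full sequence).
    ``protein`` mode emits one translated entry per CDS feature (bacterial
    genetic code); entries with internal stop codons are flagged in the
    description and retained; CDS whose length is not a multiple of three
    and that are not partial are skipped with an integrity warning.
    """
    if mode not in ("nucleotide", "protein"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    if mode == "nucleotide":
        return [
            SeqRecord(id=rec.id, sequence=rec.sequence, description=rec.description)
            for rec in records
        ]
    out: list[SeqRecord] = []
    for rec in records:
        cds_feats = [f for f in rec.features if f.key == "CDS"]
        if not cds_feats and log is not None:
            log.append(f"{rec.id}: no CDS features; nothing extracted in protein mode")
        for n, feat in enumerate(cds_feats, start=1):
            gene_number = feat.qualifier("gene_number") or str(n)
            nt = rec.subsequence(feat.start, feat.end)
            if feat.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            if len(nt) % 3 != 0:
                if feat.partial5 or feat.partial3:
                    nt = nt[: len(nt) - len(nt) % 3]
                else:
                    if log is not None:
                        log.append(
                            f"{rec.id} gene {gene_number}: CDS length {len(nt)} "
                            f"not divisible by 3 and not partial; skipped"
                        )
                    continue
            prot = translate_cds(nt, partial5=feat.partial5)
            desc = feat.qualifier("product") or ""
            if "*" in prot:
                desc = (desc + " [internal stop codon]").strip()
            out.append(
                SeqRecord(
                    id=f"{rec.id}_{gene_number}",
                    sequence=prot,
                    description=desc,
                )
            )
    return out
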