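"""Collapsed-read metagenome profiling against thematic protein databases.

Identical reads are collapsed to one representative (their multiplicity is
carried as a frequency), each representative is searched against the
database, and the per-read best hit — when below an upper e-value bound —
contributes the read's frequency to its subject in one of two e-value
bins: a stringent bin [0, range_split) and a relaxed bin
[range_split, evalue_max).  The result is a high-level overview of how
often, and at what similarity, members of a protein family occur in a
read set — not a taxonomic or assembly analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .homology import HomologyHit, SearchEngine
from .records import SeqRecord

__all__ = ["CollapsedRead", "ProfileTables", "collapse_reads", "profile", "six_frame_translations"]

DEFAULT_RANGE_SPLIT = 1e-50


@dataclass
class CollapsedRead:
    representative_id: str
    sequence: str
    frequency: int
    member_ids: list[str] = field(default_factory=list)


@dataclass
class ProfileTables:
    """Raw hits plus the two frequency summaries and the per-read overview."""

    hits: list[HomologyHit] = field(default_factory=list)
    summary_stringent: dict[str, int] = field(default_factory=dict)
    summary_relaxed: dict[str, int] = field(default_factory=dict)
    overview: list[dict] = field(default_factory=list)

    def summary_tsv(self, which: str) -> str:
        table = self.summary_stringent if which == "stringent" else self.summary_relaxed
        lines = ["subject_id\tfrequency"]
        for subject in sorted(table, key=lambda s: (-table[s], s)):
            lines.append(f"{subject}\t{table[subject]}")
        return "\n".join(lines) + "\n"

    def overview_tsv(self) -> str:
        cols = ["read_id", "frequency", "subject_id", "evalue", "pct_identity", "bin"]
        lines = ["\t".join(cols)]
        for row in self.overview:
            lines.append("\t".join(str(row[c]) for c in cols))
        return "\n".join(lines) + "\n"


def collapse_reads(reads: Sequence[SeqRecord]) -> list[CollapsedRead]:
    """Group exactly identical read sequences (case-insensitive); the
    representative is the first-seen id and frequencies sum to the input
    read count."""
    groups: dict[str, CollapsedRead] = {}
    order: list[str] = []
    for read in reads:
        key = read.sequence.upper()
        if key in groups:
            groups[key].frequency += 1
            groups[key].member_ids.append(read.id)
        else:
            groups[key] = CollapsedRead(
                representative_id=read.id,
                sequence=key,
                frequency=1,
                member_ids=[read.id],
            )
            order.append(key)
    return [groups[k] for k in order]


def six_frame_translations(nt: str) -> list[str]:
    """All six conceptual translations of a nucleotide read (translation-
    search style), stop codons rendered as '*'."""
    out = []
    for seq in (nt, str(Seq(nt).reverse_complement())):
        for offset in range(3):
            frame = seq[offset:]
            frame = frame[: len(frame) - len(frame) % 3]
            if frame:
                out.append(str(Seq(frame).translate(table=11)))
    return out


def profile(
    collapsed: Sequence[CollapsedRead],
    engine: SearchEngine,
    database_ref,
    evalue_max: float,
    range_split: float = DEFAULT_RANGE_SPLIT,
    translated: bool = True,
) -> ProfileTables:
    """Search collapsed reads and accumulate best-hit frequencies per
    subject into the stringent/relaxed e-value bins.

    ``translated`` searches all six reading-frame translations of each read
    against a protein database (translation-search style) and keeps the
    single best hit over frames.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    if range_split >= evalue_max:
        raise ValueError("range_split must be below evalue_max")
    tables = ProfileTables()
    for read in collapsed:
        if translated:
            queries = [
                SeqRecord(id=f"{read.representative_id}|f{i}", sequence=prot.replace("*", "X"))
                for i, prot in enumerate(six_frame_translations(read.sequence))
                if prot.replace("*", "")
            ]
        else:
            queries = [SeqRecord(id=read.representative_id, sequence=read.sequence)]
        hits = engine.search(queries, database_ref) if queries else []
        best: HomologyHit | None = None
        for h in hits:
            if h.evalue >= evalue_max:
                continue
            if best is None or (h.evalue, -h.bitscore, h.subject_id) < (
                best.evalue,
                -best.bitscore,
                best.subject_id,
            ):
                best = h
        if best is None:
            tables.overview.append(
                {
                    "read_id": read.representative_id,
                    "frequency": read.frequency,
                    "subject_id": "unassigned",
                    "evalue": "",
                    "pct_identity": "",
                    "bin": "",
                }
            )
            continue
        tables.hits.append(best)
        if best.evalue < range_split:
            bin_name = "stringent"
            tables.summary_stringent[best.subject_id] = (
                tables.summary_stringent.get(best.subject_id, 0) + read.frequency
            )
        else:
            bin_name = "relaxed"
            tables.summary_relaxed[best.subject_id] = (
                tables.summary_relaxed.get(best.subject_id, 0) + read.frequency
            )
        tables.overview.append(
            {
                "read_id": read.representative_id,
                "frequency": read.frequency,
                "subject_id": best.subject_id,
                "evalue": f"{best.evalue:.3g}",
                "pct_identity": f"{best.pct_identity:.1f}",
                "bin": bin_name,
            }
        )
    return tables
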