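"""Contig concatenation, N-run patching, coordinate mapping and rotation.

Draft genomes are concatenated in input order with a "non-bleeding" spacer
that carries a stop codon in every one of the six reading frames, so no
predicted gene can run across a contig join.  The default spacer is the
32-nt sequence 5'-NNNNNNNNNNTTAGTTAGTTAGNNNNNNNNNN-3' whose 12-nt core
TTAGTTAGTTAG alone stops all six frames under the bacterial genetic code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .records import ContigMap, Feature, SeqRecord, ValidationError

__all__ = [
    "Spacer",
    "DEFAULT_SPACER",
    "SPACER_CORE",
    "concatenate",
    "verify_spacer_stops",
    "replace_n_runs",
    "rotate",
    "map_to_contig",
    "SPACER_MARKER",
]

SPACER_CORE = "TTAGTTAGTTAG"
DEFAULT_SPACER_SEQ = "N" * 10 + SPACER_CORE + "N" * 10

STOP_CODONS = {"TAA", "TAG", "TGA"}  # bacterial code (table 11)

_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SPACER_MARKER = "spacer"


@dataclass
class Spacer:
    sequence: str = DEFAULT_SPACER_SEQ

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if verify_spacer_stops(self.sequence) != 6:
            raise ValidationError(
                "spacer does not guarantee a stop codon in all six reading frames"
            )


DEFAULT_SPACER = Spacer()


def _codon_is_certain_stop(codon: str) -> bool:
    """True iff every resolution of the (possibly ambiguous) codon is a stop."""
    expansions = itertools.product(*(_AMBIG.get(b, b) for b in codon.upper()))
    return all("".join(c) in STOP_CODONS for c in expansions)


def verify_spacer_stops(spacer_seq: str, flank_len: int = 60) -> int:
    """Count reading frames (of 6) in which the spacer guarantees a stop.

    The spacer is embedded between stop-free poly-A flanks and all three
    forward frames plus the three frames of the reverse complement are
    scanned; codons containing ambiguity codes count as stops only when all
    of their resolutions are stops.
    """
    if len(spacer_seq) < 3:
        raise ValueError("spacer must be at least one codon long")
    embedded = "A" * flank_len + spacer_seq.upper() + "A" * flank_len
    rc = str(Seq(embedded).reverse_complement())
    frames_with_stop = 0
    for seq in (embedded, rc):
        for offset in range(3):
            found = False
            for i in range(offset, len(seq) - 2, 3):
                if _codon_is_certain_stop(seq[i : i + 3]):
                    found = True
                    break
            if found:
                frames_with_stop += 1
    return frames_with_stop


def concatenate(
    records: Sequence[SeqRecord], spacer: Spacer = DEFAULT_SPACER
) -> tuple[SeqRecord, ContigMap]:
    """Concatenate records in order with the spacer between them.

    Returns the pseudo-molecule (carrying a ``contig_boundary`` feature over
    each spacer interval) and the contig map recording every placement.
    """
    if not records:
        raise ValueError("concatenate requires at least one record")
    parts: list[str] = []
    entries: list[tuple[str, int, int]] = []
    features: list[Feature] = []
    pos = 0
    for i, rec in enumerate(records):
        if i > 0:
            features.append(
                Feature(
                    key="contig_boundary",
                    start=pos + 1,
                    end=pos + len(spacer),
                    strand="+",
                    qualifiers=[("note", "inter-contig spacer")],
                )
            )
            parts.append(spacer.sequence)
            pos += len(spacer)
        entries.append((rec.id, pos + 1, pos + len(rec.sequence)))
        parts.append(rec.sequence)
        pos += len(rec.sequence)
    out = SeqRecord(
        id=records[0].id if len(records) == 1 else f"{records[0].id}_concat",
        sequence="".join(parts),
        description=f"concatenation of {len(records)} contig(s)",
        features=features,
    )
    return out, ContigMap(entries)


def replace_n_runs(
    record: SeqRecord, min_run: int = 12, spacer: Spacer = DEFAULT_SPACER
) -> tuple[SeqRecord, list[tuple[int, int]]]:
    """Write the spacer's 12-nt stop core centered into every N-run ≥ min_run.

    The contig is not broken and the sequence length is unchanged; the list
    of patched intervals (1-based inclusive) is returned.
    """
    core = SPACER_CORE
    if min_run < len(core):
        raise ValueError(f"min_run must be ≥ {len(core)} (length of the stop core)")
    seq = list(record.sequence)
    replaced: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            run_len = j - i
            if run_len >= min_run:
                offset = i + (run_len - len(core)) // 2
                seq[offset : offset + len(core)] = core
                replaced.append((i + 1, j))
            i = j
        else:
            i += 1
    patched = SeqRecord(
        id=record.id,
        sequence="".join(seq),
        description=record.description,
        features=list(record.features),
        molecule_topology=record.molecule_topology,
    )
    return patched, replaced


def map_to_contig(pos: int, contig_map: ContigMap) -> tuple[str, int] | str:
    """Locate a concatenated-space position on its contig.

    Returns ``(contig_id, local 1-based position)``, or :data:`SPACER_MARKER`
    for positions inside a spacer interval.
    """
    total = contig_map.entries[-1][2] if contig_map.entries else 0
    if not 1 <= pos <= total:
        raise IndexError(f"position {pos} outside concatenated range 1..{total}")
    for contig_id, start, stop in contig_map:
        if start <= pos <= stop:
            return contig_id, pos - start + 1
    return SPACER_MARKER


def rotate(
    record: SeqRecord,
    new_start: int,
    reset_locus_tags: bool = False,
    force_linear: bool = False,
    log: list[str] | None = None,
) -> SeqRecord:
    """Rotate a circular record so that ``new_start`` becomes position 1.

    All features shift with the sequence; gene-number qualifiers are kept.
    A feature spanning the new origin is split into two partial features
    (partial3 on the piece moved to the sequence end, partial5 on the piece
    now at the start) and a warning is logged.  Rotating a linear molecule
    is refused unless ``force_linear`` is set.
    """
    L = len(record.sequence)
    if not 1 <= new_start <= L:
        raise ValueError(f"new_start {new_start} outside 1..{L}")
    if record.molecule_topology != "circular" and not force_linear:
        raise ValueError(
            f"{record.id}: refusing to rotate a linear molecule (use force_linear)"
        )
    shift = L - new_start + 1

    def move(p: int) -> int:
        return (p - new_start) % L + 1

    new_seq = record.sequence[new_start - 1 :] + record.sequence[: new_start - 1]
    new_features: list[Feature] = []
    for feat in record.features:
        if new_start == 1 or not (feat.start < new_start <= feat.end):
            new_features.append(
                Feature(
                    key=feat.key,
                    start=move(feat.start),
                    end=move(feat.end),
                    strand=feat.strand,
                    partial5=feat.partial5,
                    partial3=feat.partial3,
                    qualifiers=[tuple(q) for q in feat.qualifiers],
                )
            )
        else:
            # split across the new origin
            left = Feature(
                key=feat.key,
                start=move(feat.start),
                end=L,
                strand=feat.strand,
                partial5=feat.partial5,
                partial3=True,
                qualifiers=[tuple(q) for q in feat.qualifiers],
            )
            right = Feature(
                key=feat.key,
                start=1,
                end=move(feat.end),
                strand=feat.strand,
                partial5=True,
                partial3=feat.partial3,
                qualifiers=[tuple(q) for q in feat.qualifiers],
            )
            new_features.extend([left, right])
            if log is not None:
                log.append(
                    f"{record.id}: feature {feat.key} {feat.start}..{feat.end} "
                    f"spans the new origin; split into two partial features"
                )
    new_features.sort(key=lambda f: (f.start, f.end))
    out = SeqRecord(
        id=record.id,
        sequence=new_seq,
        description=record.description,
        features=new_features,
        molecule_topology=record.molecule_topology,
    )
    if reset_locus_tags:
        from .submission import reset_locus_tags as _reset

        prefix = _existing_tag_prefix(record) or f"{record.id}_"
        out = _reset(out, prefix)
    return out


def _existing_tag_prefix(record: SeqRecord) -> str | None:
    for feat in record.features:
        tag = feat.qualifier("locus_tag")
        if tag and "_" in tag:
            return tag.rsplit("_", 1)[0] + "_"
    return None
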