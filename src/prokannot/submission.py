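"""NCBI submission preparation: 5-column feature table, AGP scaffold file
and locus-tag management."""

from __future__ import annotations

from typing import Sequence

from .records import ContigMap, Feature, SeqRecord, ValidationError

__all__ = [
    "write_feature_table",
    "write_agp",
    "reset_locus_tags",
    "link_entities",
]


def _tbl_coordinates(feat: Feature) -> tuple[str, str]:
    """5'→3' coordinate pair with '<'/'>' partial prefixes; minus-strand
    features list the high coordinate first."""
    if feat.strand == "+":
        first, second = feat.start, feat.end
    else:
        first, second = feat.end, feat.start
    c1 = f"{'<' if feat.partial5 else ''}{first}"
    c2 = f"{'>' if feat.partial3 else ''}{second}"
    return c1, c2


def write_feature_table(
    record: SeqRecord,
    selected_keys: Sequence[str],
    qualifier_options: Sequence[str] | None = None,
) -> str:
    """Emit the NCBI 5-column feature table (.tbl) for a record.

    Only features whose key is selected are written; ``qualifier_options``
    whitelists the qualifier names emitted per feature (None emits all
    except internal bookkeeping qualifiers).
    """
    if not selected_keys:
        raise ValueError("feature-table emission requires a non-empty key selection")
    selected = set(selected_keys)
    skip_quals = {"colour", "gene_number", "original_location"}
    lines = [f">Feature {record.id}"]
    for feat in record.features:
        if feat.key not in selected:
            continue
        c1, c2 = _tbl_coordinates(feat)
        lines.append(f"{c1}\t{c2}\t{feat.key}")
        for name, value in feat.qualifiers:
            if name in skip_quals:
                continue
            if qualifier_options is not None and name not in qualifier_options:
                continue
            lines.append(f"\t\t\t{name}\t{value}")
    return "\n".join(lines) + "\n"


def write_agp(contig_map: ContigMap, object_id: str, spacer_len: int) -> str:
    """Emit AGP v2.0 scaffold lines for a concatenated pseudo-molecule.

    One W (WGS contig) line per contig placement and one N gap line of
    ``spacer_len`` between consecutive contigs (gap_type contig, linkage
    no, evidence na); object coordinates tile the concatenated length
    exactly.
    """
    contig_map.validate()
    lines = ["##agp-version\t2.0"]
    part = 0
    prev_stop = 0
    for contig_id, start, stop in contig_map:
        if part > 0:
            gap_start, gap_end = prev_stop + 1, start - 1
            if gap_end - gap_start + 1 != spacer_len:
                raise ValidationError(
                    f"gap before {contig_id} is {gap_end - gap_start + 1} nt, "
                    f"expected spacer length {spacer_len}"
                )
            part += 1
            lines.append(
                "\t".join(
                    [
                        object_id,
                        str(gap_start),
                        str(gap_end),
                        str(part),
                        "N",
                        str(spacer_len),
                        "contig",
                        "no",
                        "na",
                    ]
                )
            )
        part += 1
        lines.append(
            "\t".join(
                [
                    object_id,
                    str(start),
                    str(stop),
                    str(part),
                    "W",
                    contig_id,
                    "1",
                    str(stop - start + 1),
                    "+",
                ]
            )
        )
        prev_stop = stop
    return "\n".join(lines) + "\n"


def _numbered_tags(n_genes: int, prefix: str, start_at: int = 1, log: list[str] | None = None):
    width = 4
    if start_at + n_genes - 1 > 9999:
        width = 5
        if log is not None:
            log.append("more than 9999 locus tags; widening numbers to 5 digits")
    return [f"{prefix}{start_at + i:0{width}d}" for i in range(n_genes)]


def reset_locus_tags(
    record: SeqRecord, prefix: str, start_at: int = 1, log: list[str] | None = None
) -> SeqRecord:
    """Rewrite locus_tag qualifiers as prefix + zero-padded counter in
    coordinate order; a gene/CDS pair at one location shares one tag.
    Numbering starts at 0001 and the operation is idempotent."""
    if not prefix:
        raise ValueError("locus-tag prefix must be non-empty")
    spans: list[tuple[int, int, str]] = []
    for feat in record.features:
        if feat.key in ("gene", "CDS"):
            span = (feat.start, feat.end, feat.strand)
            if span not in spans:
                spans.append(span)
    spans.sort()
    tags = _numbered_tags(len(spans), prefix, start_at, log)
    tag_by_span = dict(zip(spans, tags))
    new_features = []
    for feat in record.features:
        f = Feature(
            key=feat.key,
            start=feat.start,
            end=feat.end,
            strand=feat.strand,
            partial5=feat.partial5,
            partial3=feat.partial3,
            qualifiers=[tuple(q) for q in feat.qualifiers],
        )
        if f.key in ("gene", "CDS"):
            f.set_qualifier("locus_tag", tag_by_span[(f.start, f.end, f.strand)])
        new_features.append(f)
    return SeqRecord(
        id=record.id,
        sequence=record.sequence,
        description=record.description,
        features=new_features,
        molecule_topology=record.molecule_topology,
    )


def link_entities(
    records: Sequence[SeqRecord], shared_prefix: str, linked: bool = True
) -> list[SeqRecord]:
    """Locus-tag a multi-entity submission.

    Linked mode numbers tags continuously across records in order; unlinked
    mode restarts each record at 0001.
    """
    if not records:
        raise ValueError("link_entities requires at least one record")
    out = []
    counter = 1
    for rec in records:
        n_genes = len(
            {
                (f.start, f.end, f.strand)
                for f in rec.features
                if f.key in ("gene", "CDS")
            }
        )
        start_at = counter if linked else 1
        out.append(reset_locus_tags(rec, shared_prefix, start_at=start_at))
        counter += n_genes
    return out
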