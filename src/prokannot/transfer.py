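"""Three-pass annotation transfer between assembly versions.

Curated gene names and products accumulate on early draft assemblies; when
the assembly changes, each old gene is re-located in the new gene model by
(1) exact nucleotide identity, (2) anchored protein containment (genes
extended or truncated at one end, anchored at the C-terminus because start
codon choice varies more than stops between assemblies), then (3) protein
alignment with a minimum percent-identity threshold.  Old genes with more
than one equally good candidate are AMBIGUOUS (multi-copy genes such as
integrases), genes with none are NO_MATCH; both are logged and never
guessed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .homology import naive_search
from .records import Feature, GeneModel, SeqRecord, translate_cds

__all__ = [
    "TransferOutcome",
    "TransferReport",
    "classify_match",
    "transfer_annotations",
]


class TransferOutcome:
    PASS1_IDENTICAL = "PASS1_IDENTICAL"
    PASS2_EXTENDED = "PASS2_EXTENDED"
    PASS2_TRUNCATED = "PASS2_TRUNCATED"
    PASS3_ALIGNED = "PASS3_ALIGNED"
    AMBIGUOUS = "AMBIGUOUS"
    NO_MATCH = "NO_MATCH"


@dataclass
class TransferReport:
    """Per-old-gene transfer outcomes; the outcome classes partition the
    old gene set, so the counts always sum to the old gene count."""

    outcomes: dict[int, tuple[str, float | None]] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    @property
    def counts(self) -> Counter:
        return Counter(kind for kind, _ in self.outcomes.values())

    def to_tsv(self) -> str:
        lines = ["old_gene_number\toutcome\tpct_identity"]
        for num in sorted(self.outcomes):
            kind, ident = self.outcomes[num]
            lines.append(f"{num}\t{kind}\t{'' if ident is None else f'{ident:.1f}'}")
        return "\n".join(lines) + "\n"


def classify_match(old_protein: str, new_protein: str) -> str:
    """IDENTICAL / EXTENDED / TRUNCATED / DIVERGED for a protein pair.

    Containment must be anchored at an end (prefix or suffix); the leading
    Met is ignored when testing suffix anchoring because an extension at
    the 5' end replaces the initiator.
    """
    if not old_protein or not new_protein:
        raise ValueError("proteins must be non-empty")

    def anchored_in(short: str, long_: str) -> bool:
        if len(short) >= len(long_):
            return False
        if long_.startswith(short) or long_.endswith(short):
            return True
        core = short[1:] if short.startswith("M") else short
        return bool(core) and long_.endswith(core)

    if old_protein == new_protein:
        return "IDENTICAL"
    if anchored_in(old_protein, new_protein):
        return "EXTENDED"
    if anchored_in(new_protein, old_protein):
        return "TRUNCATED"
    return "DIVERGED"


def _gene_sequences(record: SeqRecord, model: GeneModel) -> dict[int, tuple[str, str]]:
    """(nucleotide, protein) per gene number of a consolidated model."""
    out = {}
    for call in model:
        nt = record.subsequence(call.start, call.end)
        if call.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        nt = nt[: len(nt) - len(nt) % 3]
        prot = translate_cds(nt, partial5=call.partial5).replace("*", "")
        out[call.gene_number] = (nt, prot)
    return out


def _cds_features(record: SeqRecord) -> dict[int, tuple[Feature, Feature | None]]:
    """Map gene_number -> (CDS feature, paired gene feature) of a record."""
    genes: dict[int, Feature] = {}
    cds: dict[int, Feature] = {}
    counter = 0
    for feat in record.features:
        if feat.key not in ("gene", "CDS"):
            continue
        num_q = feat.qualifier("gene_number")
        if num_q is not None:
            num = int(num_q)
        else:
            if feat.key == "CDS":
                counter += 1
            num = counter if feat.key == "CDS" else counter + 1
        (cds if feat.key == "CDS" else genes)[num] = feat
    return {num: (cds[num], genes.get(num)) for num in cds}


def transfer_annotations(
    old_record: SeqRecord,
    new_record: SeqRecord,
    new_model: GeneModel,
    min_pct_identity: float = 80.0,
) -> tuple[SeqRecord, TransferReport]:
    """Transfer gene/CDS annotations from an old assembly onto the new one.

    The new record receives gene and CDS features built from ``new_model``;
    genes matched to an old gene inherit its gene name, product and
    remaining qualifiers.  Returns the annotated new record and the
    per-gene :class:`TransferReport`.
    """
    if not len(new_model):
        raise ValueError("new record has no gene model; transfer impossible")
    old_cds = _cds_features(old_record)
    if not old_cds:
        raise ValueError("old record carries no annotated gene/CDS pairs")
    old_model = GeneModel(
        [
            _call_from_feature(feat, num)
            for num, (feat, _) in sorted(old_cds.items())
        ]
    )
    old_seqs = _gene_sequences(old_record, old_model)
    new_seqs = _gene_sequences(new_record, new_model)
    report = TransferReport()
    assignments: dict[int, int] = {}  # old gene -> new gene
    claimed: set[int] = set()

    # Pass 1: exact nucleotide identity, unique target
    nt_index: dict[str, list[int]] = {}
    for num, (nt, _) in new_seqs.items():
        nt_index.setdefault(nt, []).append(num)
    remaining = []
    for old_num in sorted(old_seqs):
        nt, _ = old_seqs[old_num]
        targets = nt_index.get(nt, [])
        if len(targets) == 1 and targets[0] not in claimed:
            assignments[old_num] = targets[0]
            claimed.add(targets[0])
            report.outcomes[old_num] = (TransferOutcome.PASS1_IDENTICAL, 100.0)
        else:
            remaining.append(old_num)

    # Pass 2: anchored containment (extended/truncated genes)
    still_remaining = []
    for old_num in remaining:
        _, old_prot = old_seqs[old_num]
        matches = []
        for new_num, (_, new_prot) in new_seqs.items():
            if new_num in claimed or not old_prot or not new_prot:
                continue
            kind = classify_match(old_prot, new_prot)
            if kind in ("EXTENDED", "TRUNCATED"):
                matches.append((new_num, kind))
        if len(matches) == 1:
            new_num, kind = matches[0]
            assignments[old_num] = new_num
            claimed.add(new_num)
            outcome = (
                TransferOutcome.PASS2_EXTENDED
                if kind == "EXTENDED"
                else TransferOutcome.PASS2_TRUNCATED
            )
            report.outcomes[old_num] = (outcome, None)
        elif len(matches) > 1:
            report.outcomes[old_num] = (TransferOutcome.AMBIGUOUS, None)
            report.log.append(
                f"gene {old_num}: ambiguous anchored matches to new genes "
                f"{sorted(n for n, _ in matches)}"
            )
        else:
            still_remaining.append(old_num)

    # Pass 3: protein alignment against untransferred new genes
    candidates = [
        SeqRecord(id=str(num), sequence=new_seqs[num][1])
        for num in sorted(new_seqs)
        if num not in claimed and new_seqs[num][1]
    ]
    for old_num in still_remaining:
        _, old_prot = old_seqs[old_num]
        if not old_prot or not candidates:
            report.outcomes[old_num] = (TransferOutcome.NO_MATCH, None)
            report.log.append(f"gene {old_num}: no match in new assembly")
            continue
        hits = naive_search([SeqRecord(id="q", sequence=old_prot)], candidates)
        qualifying = [h for h in hits if h.pct_identity >= min_pct_identity]
        if not qualifying:
            report.outcomes[old_num] = (TransferOutcome.NO_MATCH, None)
            report.log.append(f"gene {old_num}: no match in new assembly")
            continue
        best_key = min((h.evalue, -h.bitscore, -h.pct_identity) for h in qualifying)
        best = [h for h in qualifying if (h.evalue, -h.bitscore, -h.pct_identity) == best_key]
        if len(best) > 1:
            report.outcomes[old_num] = (TransferOutcome.AMBIGUOUS, None)
            report.log.append(
                f"gene {old_num}: {len(best)} equally good candidates "
                f"({sorted(h.subject_id for h in best)}); not transferred"
            )
            continue
        new_num = int(best[0].subject_id)
        assignments[old_num] = new_num
        claimed.add(new_num)
        report.outcomes[old_num] = (TransferOutcome.PASS3_ALIGNED, best[0].pct_identity)

    annotated = _apply_assignments(new_record, new_model, old_cds, assignments)
    return annotated, report


def _call_from_feature(feat: Feature, num: int):
    from .records import GeneCall

    return GeneCall(
        start=feat.start,
        end=feat.end,
        strand=feat.strand,
        caller_tag="annotated",
        gene_number=num,
        partial5=feat.partial5,
        partial3=feat.partial3,
    )


_TRANSFER_QUALS = ("gene", "product", "locus_tag", "EC_number", "note", "function")


def _apply_assignments(
    new_record: SeqRecord,
    new_model: GeneModel,
    old_cds: dict[int, tuple[Feature, Feature | None]],
    assignments: dict[int, int],
) -> SeqRecord:
    by_new = {new_num: old_num for old_num, new_num in assignments.items()}
    features: list[Feature] = []
    for call in new_model:
        gene_quals: list[tuple[str, str]] = [("gene_number", str(call.gene_number))]
        cds_quals: list[tuple[str, str]] = [("gene_number", str(call.gene_number))]
        old_num = by_new.get(call.gene_number)
        if old_num is not None:
            old_cds_feat, old_gene_feat = old_cds[old_num]
            for name, value in old_cds_feat.qualifiers:
                if name in _TRANSFER_QUALS:
                    cds_quals.append((name, value))
            src = old_gene_feat or old_cds_feat
            for name, value in src.qualifiers:
                if name in ("gene", "locus_tag"):
                    gene_quals.append((name, value))
        else:
            cds_quals.append(("product", "unknown"))
        loc = dict(
            start=call.start,
            end=call.end,
            strand=call.strand,
            partial5=call.partial5,
            partial3=call.partial3,
        )
        features.append(Feature(key="gene", qualifiers=gene_quals, **loc))
        features.append(Feature(key="CDS", qualifiers=cds_quals, **loc))
    keep = [f for f in new_record.features if f.key not in ("gene", "CDS")]
    all_feats = sorted(
        features + keep,
        key=lambda f: (f.start, f.end, 0 if f.key == "gene" else 1 if f.key == "CDS" else 2),
    )
    return SeqRecord(
        id=new_record.id,
        sequence=new_record.sequence,
        description=new_record.description,
        features=all_feats,
        molecule_topology=new_record.molecule_topology,
    )
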