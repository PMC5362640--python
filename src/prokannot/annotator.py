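"""The automated annotation rule engine.

Products follow three literal rules: a gene with no homology hits at all is
"unknown"; a gene with only above-threshold hits is "conserved
hypothetical"; otherwise the best below-threshold hit names the product.
A below-threshold TIGRfam profile hit overrides the homology-based name
for both the gene and CDS features, optionally contributing its curated
gene designation and E.C. numbers.  Profile databases are searched as a
cascade: once a gene has a below-threshold hit in an earlier database,
later databases are not queried for it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from .homology import HitClass, ProfileHit, SearchEngine
from .records import Feature, FormatError, GeneModel, SeqRecord

__all__ = [
    "AnnotationDecision",
    "CogRecord",
    "UNKNOWN_PRODUCT",
    "CONSERVED_HYPOTHETICAL",
    "decide_annotation",
    "cascade_profile_search",
    "load_cog_table",
    "translate_cog",
    "emit_features",
    "update_genbank_annotation",
    "sanitize_product",
    "DEFAULT_FEATURE_COLORS",
]

UNKNOWN_PRODUCT = "unknown"
CONSERVED_HYPOTHETICAL = "conserved hypothetical"

# colour codes per feature key, constant across a file (viewer convention)
DEFAULT_FEATURE_COLORS: dict[str, str] = {
    "gene": "7",
    "CDS": "10",
    "rRNA": "2",
    "tRNA": "4",
    "ncRNA": "12",
    "repeat_region": "6",
    "terminator": "3",
    "sig_peptide": "5",
    "misc_feature": "8",
    "contig_boundary": "11",
}


@dataclass
class AnnotationDecision:
    gene_number: int
    product: str
    gene_name: str = ""
    source: str = "none"  # blast | tigrfam | none
    ec_numbers: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.product:
            raise ValueError("product must be non-empty")
        if self.source == "none" and self.product != UNKNOWN_PRODUCT:
            raise ValueError("source=none implies product 'unknown'")


@dataclass
class CogRecord:
    cog_code: str
    categories: str
    descriptor: str


_ORGANISM_BRACKET = re.compile(r"\s*\[[^\]]*\]\s*$")
_DB_TAG = re.compile(r"^(?:[a-z]{2,5}\|\S+\|\S*\s*|\S+\.\d+\s+)")


def sanitize_product(description: str) -> str:
    """Strip subject-id/database tags and a trailing organism bracket from a
    hit description to obtain a product string."""
    text = description.strip()
    text = _DB_TAG.sub("", text)
    text = _ORGANISM_BRACKET.sub("", text)
    text = re.sub(r"\s+", " ", text).strip()
    return text or UNKNOWN_PRODUCT


def decide_annotation(
    blast_class: HitClass | None,
    tigrfam_hits: Sequence[ProfileHit] | None,
    threshold: float,
    gene_number: int = 0,
    prefer_tigrfam_names: bool = True,
    add_ec: bool = True,
) -> AnnotationDecision:
    """Apply the annotation rules to one gene.

    ``blast_class=None`` / ``tigrfam_hits=None`` mean the respective
    analysis was not selected for the run.
    """
    product = UNKNOWN_PRODUCT
    gene_name = ""
    source = "none"
    ec: list[str] = []
    provenance: list[str] = []
    if blast_class is not None:
        if blast_class.kind == HitClass.NONE:
            product = UNKNOWN_PRODUCT
        elif blast_class.kind == HitClass.ABOVE_ONLY:
            product, source = CONSERVED_HYPOTHETICAL, "blast"
        else:
            hit = blast_class.hit
            desc = hit.description
            # stitle-style descriptions repeat the subject id up front
            if desc.startswith(hit.subject_id):
                desc = desc[len(hit.subject_id) :].strip()
            product = sanitize_product(desc or hit.subject_id)
            source = "blast"
            provenance.append(f"blast:{hit.subject_id}")
    if tigrfam_hits:
        below = [h for h in tigrfam_hits if h.evalue < threshold]
        if below:
            best = min(below, key=lambda h: (h.evalue, -h.score, h.family_accession))
            desc = best.description
            if best.gene_name and desc.startswith(best.gene_name + ":"):
                desc = desc[len(best.gene_name) + 1 :].strip()
            product = desc or best.family_name
            source = "tigrfam"
            provenance.append(f"tigrfam:{best.family_accession}")
            if prefer_tigrfam_names and best.gene_name:
                gene_name = best.gene_name
            if add_ec:
                ec = list(best.ec_numbers)
    return AnnotationDecision(
        gene_number=gene_number,
        product=product,
        gene_name=gene_name,
        source=source,
        ec_numbers=ec,
        provenance=provenance,
    )


def cascade_profile_search(
    gene_query: SeqRecord,
    databases_in_order: Sequence[tuple[str, object]],
    engine: SearchEngine,
    threshold: float,
    log: list[str] | None = None,
) -> tuple[str | None, dict[str, list]]:
    """Query profile databases in selection order, stopping at the first
    database that yields a below-threshold hit; databases after it stay
    untouched for this gene.  If none qualify, every database's results
    are retained and the used-database is None."""
    all_results: dict[str, list] = {}
    for db_name, db_ref in databases_in_order:
        try:
            hits = engine.search([gene_query], db_ref)
        except Exception as exc:
            if log is not None:
                log.append(f"{gene_query.id}: engine failure on {db_name}: {exc}")
            continue
        all_results[db_name] = hits
        if any(h.evalue < threshold for h in hits):
            return db_name, {db_name: hits}
    return None, all_results


# ---------------------------------------------------------------------------
# COG code translation

_COG_CODE = re.compile(r"^(?:ar)?(?:COG|POG)\d{4,5}$")


def load_cog_table(path=None) -> dict[str, CogRecord]:
    """Load the packaged (or a user-supplied) COG descriptor TSV."""
    if path is None:
        text = (
            resources.files("prokannot").joinpath("data/cog_descriptors.tsv").read_text()
        )
    else:
        from pathlib import Path

        text = Path(path).read_text()
    table: dict[str, CogRecord] = {}
    lines = text.splitlines()
    if not lines or not lines[0].startswith("cog_code"):
        raise FormatError("COG table must start with a cog_code header")
    for line in lines[1:]:
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise FormatError(f"COG table row has {len(cols)} columns, expected 3")
        table[cols[0]] = CogRecord(cog_code=cols[0], categories=cols[1], descriptor=cols[2])
    return table


def translate_cog(
    code: str, cog_table: Mapping[str, CogRecord], log: list[str] | None = None
) -> CogRecord:
    """Translate a COG code into its human-readable descriptor; unknown
    codes pass through with descriptor "uncharacterized" and a warning."""
    if not _COG_CODE.match(code):
        raise FormatError(f"malformed COG code {code!r}")
    record = cog_table.get(code)
    if record is None:
        if log is not None:
            log.append(f"COG code {code} not in descriptor table")
        return CogRecord(cog_code=code, categories="", descriptor="uncharacterized")
    return record


# ---------------------------------------------------------------------------
# Feature emission


def emit_features(
    model: GeneModel,
    decisions: Mapping[int, AnnotationDecision],
    analysis_results: Mapping[int, Sequence[Feature]] | None = None,
    colors: Mapping[str, str] = DEFAULT_FEATURE_COLORS,
    strict_keys: bool = False,
) -> list[Feature]:
    """Emit the annotated feature list for a consolidated gene model.

    Every gene yields a gene feature (short name) and a CDS feature
    (verbose product) with identical locations and a shared sequential
    gene-number qualifier, followed by that gene's analysis features in
    start order.  Analysis features carry a constant colour qualifier per
    feature key; with ``strict_keys`` their original keys are kept for the
    companion viewer, otherwise they are emitted as misc_feature with a
    note naming the analysis.
    """
    analysis_results = analysis_results or {}
    out: list[Feature] = []
    for call in model:
        if call.gene_number is None:
            raise ValueError("emit_features requires a consolidated model")
        decision = decisions.get(call.gene_number)
        if decision is None:
            raise ValueError(f"no annotation decision for gene {call.gene_number}")
        common = [("gene_number", str(call.gene_number))]
        name = decision.gene_name or f"gene_{call.gene_number}"
        gene_quals = [("gene", name)] + common + [("colour", colors.get("gene", "7"))]
        cds_quals = (
            [("gene", name), ("product", decision.product)]
            + common
            + [("EC_number", ec) for ec in decision.ec_numbers]
            + [("colour", colors.get("CDS", "10"))]
        )
        loc = dict(
            start=call.start,
            end=call.end,
            strand=call.strand,
            partial5=call.partial5,
            partial3=call.partial3,
        )
        out.append(Feature(key="gene", qualifiers=gene_quals, **loc))
        out.append(Feature(key="CDS", qualifiers=cds_quals, **loc))
        extras = sorted(analysis_results.get(call.gene_number, []), key=lambda f: (f.start, f.end))
        for feat in extras:
            key = feat.key if strict_keys else "misc_feature"
            quals = list(feat.qualifiers)
            if not strict_keys and feat.key != "misc_feature":
                quals.insert(0, ("note", f"analysis:{feat.key}"))
            quals.append(("colour", colors.get(feat.key, colors.get("misc_feature", "8"))))
            quals.append(("gene_number", str(call.gene_number)))
            out.append(
                Feature(
                    key=key,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    partial5=feat.partial5,
                    partial3=feat.partial3,
                    qualifiers=quals,
                )
            )
    return out


def update_genbank_annotation(
    existing_record: SeqRecord,
    analyses_to_update: Sequence[str],
    new_features: Sequence[Feature],
    preserve_gene_cds: bool = False,
    new_gene_cds: Sequence[Feature] | None = None,
) -> SeqRecord:
    """Update selected analysis features of an annotated record.

    Features whose key belongs to ``analyses_to_update`` are replaced by the
    matching entries of ``new_features``; all other features are preserved
    untouched.  Existing gene/CDS features are kept verbatim when
    ``preserve_gene_cds`` (protecting manual curation); otherwise they may
    be replaced by ``new_gene_cds`` when supplied.
    """
    has_model = any(f.key in ("gene", "CDS") for f in existing_record.features)
    if not has_model:
        raise ValueError(
            f"{existing_record.id}: cannot update a record without a gene model"
        )
    selected = set(analyses_to_update)
    kept: list[Feature] = []
    for feat in existing_record.features:
        if feat.key in selected:
            continue
        if feat.key in ("gene", "CDS") and not preserve_gene_cds and new_gene_cds is not None:
            continue
        kept.append(feat)
    added = [f for f in new_features if f.key in selected]
    if not preserve_gene_cds and new_gene_cds is not None:
        added += list(new_gene_cds)
    merged = sorted(
        kept + added,
        key=lambda f: (f.start, f.end, 0 if f.key == "gene" else 1 if f.key == "CDS" else 2),
    )
    return SeqRecord(
        id=existing_record.id,
        sequence=existing_record.sequence,
        description=existing_record.description,
        features=merged,
        molecule_topology=existing_record.molecule_topology,
    )
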