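"""Run orchestration: input grouping, the annotation pipeline, the
per-entity result store with integrity-checked reuse, and error logging.

The result directory layout mirrors the output contract: one directory per
annotation entity holding the annotated GenBank file, the underlying FASTA
sequence, the contig-order file and per-analysis subdirectories with one
result file per gene (keyed by the sequential gene number, so raw evidence
for any gene can be retrieved later).  An error log is appended per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

from . import assembly_ops, gene_model, intergenic
from .annotator import (
    AnnotationDecision,
    decide_annotation,
    emit_features,
)
from .config import RunConfig
from .homology import (
    HitClass,
    NaiveEngine,
    classify_hits,
    keyword_filter,
    parse_tabular_hits,
    write_tabular_hits,
)
from .records import (
    ContigMap,
    GeneModel,
    SeqRecord,
    read_fasta,
    read_genbank,
    read_gff_gene_model,
    translate_cds,
    write_contig_map,
    write_fasta,
    write_genbank,
)

__all__ = ["Entity", "group_inputs", "run_annotate", "annotate_entity"]


@dataclass
class Entity:
    """One annotation unit: an ordered list of input records that is
    concatenated (or a single record analysed on its own)."""

    name: str
    records: list[SeqRecord] = field(default_factory=list)


def _read_any(path: Path) -> list[SeqRecord]:
    head = path.read_text().lstrip()[:5]
    if head.startswith(">"):
        return read_fasta(path)
    return read_genbank(path)


def group_inputs(files: Sequence[str | Path], grouping: str = "separate") -> list[Entity]:
    """Build annotation entities from input files.

    ``separate`` yields one entity per record; ``grouped`` combines all
    files, in order, into a single concatenated entity.
    """
    files = [Path(f) for f in files]
    if not files:
        raise ValueError("no input files given")
    if grouping == "grouped":
        records: list[SeqRecord] = []
        for f in files:
            records.extend(_read_any(f))
        if not records:
            raise ValueError("input files contain no records")
        return [Entity(name=files[0].stem, records=records)]
    entities = []
    for f in files:
        for rec in _read_any(f):
            entities.append(Entity(name=rec.id, records=[rec]))
    if not entities:
        raise ValueError("input files contain no records")
    return entities


def _gene_queries(record: SeqRecord, model: GeneModel) -> list[SeqRecord]:
    queries = []
    for call in model:
        nt = record.subsequence(call.start, call.end)
        if call.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        nt = nt[: len(nt) - len(nt) % 3]
        prot = translate_cds(nt, partial5=call.partial5).replace("*", "")
        if prot:
            queries.append(SeqRecord(id=f"gene_{call.gene_number}", sequence=prot))
    return queries


def _result_file_ok(path: Path, gene_number: int) -> bool:
    """Integrity check for a cached result file: it must parse and name the
    expected gene number in its header line."""
    if not path.exists():
        return False
    try:
        text = path.read_text()
        lines = text.splitlines()
        if not lines or lines[0] != f"# gene {gene_number}":
            return False
        parse_tabular_hits("\n".join(lines[1:]))
        return True
    except Exception:
        return False


def annotate_entity(
    entity: Entity,
    config: RunConfig,
    out_dir: Path,
    engine=None,
    error_log: list[str] | None = None,
) -> Path:
    """Annotate one entity and populate its result directory.

    Cached per-gene homology result files are reused when they pass the
    integrity check; corrupted or missing files trigger a fresh search for
    that gene only.  Returns the entity directory.
    """
    error_log = error_log if error_log is not None else []
    entity_dir = Path(out_dir) / entity.name
    entity_dir.mkdir(parents=True, exist_ok=True)

    # 1. concatenate
    if len(entity.records) > 1 and config.concatenate:
        record, contig_map = assembly_ops.concatenate(entity.records)
    else:
        record = entity.records[0]
        contig_map = ContigMap([(record.id, 1, len(record.sequence))])
    if config.replace_n_runs:
        record, _ = assembly_ops.replace_n_runs(record, min_run=config.n_run_min)

    # 2. gene model
    if config.external_gene_model:
        model = read_gff_gene_model(config.external_gene_model)
    else:
        model = gene_model.call_orfs(
            record.sequence,
            min_len_nt=config.min_gene_len_nt,
            start_codons=config.start_codons,
        )
    model, removed = gene_model.enforce_no_bleeding(model, contig_map, log=error_log)

    # 3. intergenic rescue
    if config.igorf_enabled and engine is not None and config.protein_db:
        regions = intergenic.intergenic_regions(
            model,
            len(record.sequence),
            mode=config.igorf_mode,
            reach_nt=config.igorf_reach,
        )
        candidates = intergenic.find_igorfs(
            record.sequence, regions, config.igorf_min_len, contig_map
        )
        rescued = intergenic.rescue_igorfs(
            candidates,
            record.sequence,
            engine,
            config.igorf_evalue,
            database_ref=None,
            log=error_log,
        )
        if rescued:
            model = gene_model.merge_models([model, GeneModel(rescued)])
    model = gene_model.consolidate(model)

    # 4. per-gene homology with result reuse
    decisions: dict[int, AnnotationDecision] = {}
    blast_dir = entity_dir / "Blast_results"
    analyses_selected = engine is not None and config.protein_db is not None
    if analyses_selected:
        blast_dir.mkdir(exist_ok=True)
        queries = {q.id: q for q in _gene_queries(record, model)}
        for call in model:
            num = call.gene_number
            qid = f"gene_{num}"
            result_path = blast_dir / f"gene_{num}.tsv"
            if config.reuse_results and _result_file_ok(result_path, num):
                hits = parse_tabular_hits(
                    "\n".join(result_path.read_text().splitlines()[1:])
                )
            else:
                query = queries.get(qid)
                try:
                    hits = engine.search([query], None) if query else []
                except Exception as exc:
                    error_log.append(f"{entity.name} gene {num}: engine failure: {exc}")
                    hits = []
                result_path.write_text(f"# gene {num}\n" + write_tabular_hits(hits))
            hits = keyword_filter(hits, config.stop_keywords)
            blast_class = classify_hits(hits, config.blast_evalue)
            decisions[num] = decide_annotation(
                blast_class,
                None,
                config.tigrfam_evalue,
                gene_number=num,
                prefer_tigrfam_names=config.prefer_tigrfam_names,
                add_ec=config.add_ec_numbers,
            )
    else:
        for call in model:
            decisions[call.gene_number] = decide_annotation(
                None, None, config.tigrfam_evalue, gene_number=call.gene_number
            )

    # 5. emit the annotated record and accompanying files
    features = emit_features(model, decisions, strict_keys=config.strict_feature_keys)
    boundary_feats = [f for f in record.features if f.key == "contig_boundary"]
    annotated = SeqRecord(
        id=record.id,
        sequence=record.sequence,
        description=record.description,
        features=sorted(
            features + boundary_feats,
            key=lambda f: (f.start, f.end, 0 if f.key == "gene" else 1),
        ),
        molecule_topology=record.molecule_topology,
    )
    write_genbank([annotated], entity_dir / f"{entity.name}.gbk")
    write_fasta([record], entity_dir / f"{entity.name}.fna")
    write_contig_map(contig_map, entity_dir / "contig_order.tsv")
    return entity_dir


def run_annotate(
    input_files: Sequence[str | Path],
    config: RunConfig,
    out_dir: str | Path,
    engine=None,
) -> list[Path]:
    """Annotate every entity built from the input files; the error log is
    appended to ``error.log`` under the output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    error_log: list[str] = []
    if engine is None and config.engine == "naive" and config.protein_db:
        engine = NaiveEngine(read_fasta(config.protein_db, alphabet="aa"))
    entities = group_inputs(input_files, config.grouping)
    dirs = []
    for entity in entities:
        try:
            dirs.append(
                annotate_entity(entity, config, out_dir, engine=engine, error_log=error_log)
            )
        except Exception as exc:
            error_log.append(f"{entity.name}: fatal: {exc}")
            raise
        finally:
            if error_log:
                with open(out_dir / "error.log", "a") as fh:
                    fh.write("\n".join(error_log) + "\n")
                error_log.clear()
    return dirs
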