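"""Pluggable homology/profile search: hit containers, tabular parsing,
keyword filtering, best-hit classification, rRNA boundary extrapolation and
a deterministic built-in protein searcher.

All pipeline logic consumes only :class:`HomologyHit` / :class:`ProfileHit`
rows, so any engine that can produce BLAST outfmt-6-style tables (the real
BLAST+ binaries, or the built-in :func:`naive_search`) plugs in unchanged.
The built-in searcher is an ungapped seed-and-extend aligner (identical
3-mer seeds, BLOSUM62 scoring, X-drop) with Karlin–Altschul ungapped
statistics; it exists so every stage of the pipeline is testable offline
and deterministically.
"""

from __future__ import annotations

import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from math import log
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from Bio.Align import substitution_matrices

from .records import Feature, FormatError, SeqRecord

__all__ = [
    "HomologyHit",
    "ProfileHit",
    "SearchEngine",
    "NaiveEngine",
    "BlastEngine",
    "HitClass",
    "parse_tabular_hits",
    "write_tabular_hits",
    "parse_profile_tblout",
    "keyword_filter",
    "classify_hits",
    "extrapolate_rrna",
    "naive_search",
]


@dataclass
class HomologyHit:
    """One row of a tabular (outfmt-6 dialect) homology search result."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    subject_len: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(
                f"{self.query_id}/{self.subject_id}: qstart {self.qstart} > qend {self.qend}"
            )
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")

    @property
    def subject_strand(self) -> str:
        return "-" if self.sstart > self.send else "+"


@dataclass
class ProfileHit:
    """One profile (HMM family) search result row."""

    query_id: str
    family_accession: str
    family_name: str
    evalue: float
    score: float
    description: str = ""
    ec_numbers: list[str] = field(default_factory=list)
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


class SearchEngine(Protocol):
    """Contract every search backend fulfils: deterministic for fixed input."""

    name: str

    def search(
        self, queries: Sequence[SeqRecord], database_ref, params: dict | None = None
    ) -> list[HomologyHit]: ...


# ---------------------------------------------------------------------------
# Tabular IO (BLAST outfmt-6 dialect: 12 standard columns, optional
# subject-length and description columns 13/14)

_FLOAT = re.compile(r"^[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?$")


def parse_tabular_hits(text: str) -> list[HomologyHit]:
    hits: list[HomologyHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise FormatError(f"line {lineno}: expected ≥12 tab-separated columns, got {len(cols)}")
        try:
            hit = HomologyHit(
                query_id=cols[0],
                subject_id=cols[1],
                pct_identity=float(cols[2]),
                aln_length=int(cols[3]),
                mismatches=int(cols[4]),
                gap_opens=int(cols[5]),
                qstart=int(cols[6]),
                qend=int(cols[7]),
                sstart=int(cols[8]),
                send=int(cols[9]),
                evalue=float(cols[10]),
                bitscore=float(cols[11]),
                subject_len=int(cols[12]) if len(cols) > 12 and cols[12] != "" else None,
                description="\t".join(cols[13:]) if len(cols) > 13 else "",
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unparseable numeric field ({exc})") from exc
        hits.append(hit)
    return hits


def write_tabular_hits(hits: Iterable[HomologyHit]) -> str:
    lines = []
    for h in hits:
        cols = [
            h.query_id,
            h.subject_id,
            f"{h.pct_identity:.2f}",
            str(h.aln_length),
            str(h.mismatches),
            str(h.gap_opens),
            str(h.qstart),
            str(h.qend),
            str(h.sstart),
            str(h.send),
            f"{h.evalue:.3g}",
            f"{h.bitscore:.1f}",
            "" if h.subject_len is None else str(h.subject_len),
            h.description,
        ]
        lines.append("\t".join(cols))
    return "\n".join(lines) + ("\n" if lines else "")


_EC_RE = re.compile(r"\b(\d+\.\d+\.\d+\.(?:\d+|-))\b")
_GENE_NAME_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]{2,7}):\s")


def parse_profile_tblout(text: str) -> list[ProfileHit]:
    """Parse HMMER3 tblout-style rows into profile hits.

    Column layout (hmmscan convention): target (family) name, target
    accession, query name, query accession, full-sequence e-value and score;
    the free-text description starts at column 19.  Family descriptions of
    the form ``gene: description`` yield a gene name, and embedded
    ``n.n.n.n`` EC numbers are collected.
    """
    hits: list[ProfileHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split(None, 18)
        if len(cols) < 6:
            raise FormatError(f"line {lineno}: too few columns for tblout")
        desc = cols[18].strip() if len(cols) > 18 else ""
        gene_match = _GENE_NAME_RE.match(desc)
        try:
            hits.append(
                ProfileHit(
                    query_id=cols[2],
                    family_accession=cols[1],
                    family_name=cols[0],
                    evalue=float(cols[4]),
                    score=float(cols[5]),
                    description=desc,
                    ec_numbers=_EC_RE.findall(desc),
                    gene_name=gene_match.group(1) if gene_match else None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unparseable numeric field ({exc})") from exc
    return hits


# ---------------------------------------------------------------------------
# Filtering and classification


def keyword_filter(
    hits: Sequence[HomologyHit], stop_keywords: Sequence[str]
) -> list[HomologyHit]:
    """Drop hits whose description contains any stop keyword
    (case-insensitive substring); order is preserved."""
    if not stop_keywords:
        return list(hits)
    lowered = [k.lower() for k in stop_keywords]
    return [
        h for h in hits if not any(k in h.description.lower() for k in lowered)
    ]


@dataclass
class HitClass:
    """Outcome of best-hit classification against an e-value threshold."""

    kind: str  # "BEST" | "ABOVE_ONLY" | "NONE"
    hit: HomologyHit | None = None

    BEST = "BEST"
    ABOVE_ONLY = "ABOVE_ONLY"
    NONE = "NONE"


def classify_hits(hits: Sequence[HomologyHit], evalue_threshold: float) -> HitClass:
    """NONE when no hits exist; BEST(h) for the minimal
    (evalue, -bitscore, subject_id) hit below the threshold; ABOVE_ONLY when
    hits exist but none falls below the threshold."""
    if not hits:
        return HitClass(HitClass.NONE)
    below = [h for h in hits if h.evalue < evalue_threshold]
    if not below:
        return HitClass(HitClass.ABOVE_ONLY)
    best = min(below, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return HitClass(HitClass.BEST, best)


# ---------------------------------------------------------------------------
# rRNA extrapolation


def extrapolate_rrna(hit: HomologyHit, query_len: int) -> Feature:
    """Extrapolate a full-length rRNA gene from a partial alignment.

    The alignment of the genome (query) against a full-length reference rRNA
    (subject) is extended outwards so that the predicted feature covers the
    whole subject: on the plus strand predicted start = qstart − (sstart−1)
    and predicted end = qend + (subject_len − send).  Predictions are
    clamped to the sequence with partial flags.  Minus-strand alignments
    (sstart > send) mirror the computation.
    """
    if hit.subject_len is None:
        raise ValueError("rRNA extrapolation requires the subject length")
    if hit.qstart > hit.qend:
        raise ValueError("inverted query coordinates")
    slen = hit.subject_len
    if hit.sstart <= hit.send:
        strand = "+"
        pred_start = hit.qstart - (hit.sstart - 1)
        pred_end = hit.qend + (slen - hit.send)
    else:
        strand = "-"
        pred_start = hit.qstart - (slen - hit.sstart)
        pred_end = hit.qend + (hit.send - 1)
    clamped_low = pred_start < 1
    clamped_high = pred_end > query_len
    start = max(1, pred_start)
    end = min(query_len, pred_end)
    if strand == "+":
        partial5, partial3 = clamped_low, clamped_high
    else:
        partial5, partial3 = clamped_high, clamped_low
    return Feature(
        key="rRNA",
        start=start,
        end=end,
        strand=strand,
        partial5=partial5,
        partial3=partial3,
        qualifiers=[
            ("note", f"extrapolated from alignment to {hit.subject_id}"),
            ("reference", hit.subject_id),
            ("pct_identity", f"{hit.pct_identity:.1f}"),
            ("evalue", f"{hit.evalue:.3g}"),
        ],
    )


# ---------------------------------------------------------------------------
# Built-in deterministic protein searcher

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_LAMBDA = 0.267  # ungapped Karlin-Altschul parameters for BLOSUM62
_K = 0.041
_XDROP = 20
_WORD = 3


def _score(a: str, b: str) -> float:
    try:
        return _BLOSUM62[a, b]
    except KeyError:
        return -4.0


def _extend(q: str, s: str, qpos: int, spos: int) -> tuple[int, int, int, float]:
    """Ungapped X-drop extension of a seed at (qpos, spos).

    Returns (qstart, qend, identities, score) with 0-based inclusive qstart
    and exclusive qend on the query.
    """
    # seed score
    seed_score = sum(_score(q[qpos + i], s[spos + i]) for i in range(_WORD))
    # extend right
    best = running = seed_score
    best_right = qpos + _WORD
    i = 0
    while qpos + _WORD + i < len(q) and spos + _WORD + i < len(s):
        running += _score(q[qpos + _WORD + i], s[spos + _WORD + i])
        if running > best:
            best = running
            best_right = qpos + _WORD + i + 1
        if running < best - _XDROP:
            break
        i += 1
    # extend left
    total_best = best
    running = best
    best_left = qpos
    i = 1
    while qpos - i >= 0 and spos - i >= 0:
        running += _score(q[qpos - i], s[spos - i])
        if running > total_best:
            total_best = running
            best_left = qpos - i
        if running < total_best - _XDROP:
            break
        i += 1
    diag = spos - qpos
    identities = sum(
        1 for k in range(best_left, best_right) if q[k] == s[k + diag]
    )
    return best_left, best_right, identities, total_best


def naive_search(
    queries: Sequence[SeqRecord],
    database: Sequence[SeqRecord],
    params: dict | None = None,
) -> list[HomologyHit]:
    """Deterministic ungapped seed-and-extend protein search.

    Identical 3-mer seeds are extended with BLOSUM62 scores under an X-drop
    of 20; bit score = (λ·S − ln K)/ln 2 with λ=0.267, K=0.041 and e-value =
    m·n·2^(−bitscore) where m is the query length and n the total residue
    count of the database.  One best HSP is reported per query/subject pair;
    hits are sorted by (evalue, −bitscore, subject_id).
    """
    if not database:
        raise ValueError("naive_search requires a non-empty database")
    params = params or {}
    evalue_max = params.get("evalue_max")
    min_raw = params.get("min_raw_score", 25)
    total_residues = sum(len(r.sequence) for r in database)
    # index database 3-mers
    index: dict[str, list[tuple[int, int]]] = {}
    for si, subj in enumerate(database):
        s = subj.sequence.upper()
        for p in range(len(s) - _WORD + 1):
            index.setdefault(s[p : p + _WORD], []).append((si, p))
    hits: list[HomologyHit] = []
    for query in queries:
        q = query.sequence.upper()
        best_per_subject: dict[int, tuple[float, int, int, int, int]] = {}
        covered: dict[tuple[int, int], int] = {}  # (subject, diagonal) -> qend seen
        for qpos in range(len(q) - _WORD + 1):
            for si, spos in index.get(q[qpos : qpos + _WORD], ()):  # deterministic order
                diag = spos - qpos
                if covered.get((si, diag), -1) >= qpos + _WORD:
                    continue
                qs, qe, ident, score = _extend(q, database[si].sequence.upper(), qpos, spos)
                covered[(si, diag)] = qe
                if score < min_raw:
                    continue
                prev = best_per_subject.get(si)
                if prev is None or score > prev[0]:
                    best_per_subject[si] = (score, qs, qe, ident, diag)
        for si, (score, qs, qe, ident, diag) in best_per_subject.items():
            bitscore = (_LAMBDA * score - log(_K)) / log(2)
            evalue = len(q) * total_residues * 2.0 ** (-bitscore)
            if evalue_max is not None and evalue >= evalue_max:
                continue
            aln_len = qe - qs
            hits.append(
                HomologyHit(
                    query_id=query.id,
                    subject_id=database[si].id,
                    pct_identity=100.0 * ident / aln_len if aln_len else 0.0,
                    aln_length=aln_len,
                    mismatches=aln_len - ident,
                    gap_opens=0,
                    qstart=qs + 1,
                    qend=qe,
                    sstart=qs + diag + 1,
                    send=qe + diag,
                    evalue=evalue,
                    bitscore=round(bitscore, 1),
                    subject_len=len(database[si].sequence),
                    description=database[si].description,
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.evalue, -h.bitscore, h.subject_id))
    return hits


class NaiveEngine:
    """Built-in engine wrapping :func:`naive_search` over an in-memory
    protein database; call counts are tracked for cache/cascade auditing."""

    name = "naive"

    def __init__(self, database: Sequence[SeqRecord] | None = None) -> None:
        self.database = list(database) if database else None
        self.call_count = 0

    def search(
        self, queries: Sequence[SeqRecord], database_ref=None, params: dict | None = None
    ) -> list[HomologyHit]:
        self.call_count += 1
        db = list(database_ref) if database_ref is not None else self.database
        if db is None:
            raise ValueError("no database configured for naive engine")
        return naive_search(queries, db, params)


class BlastEngine:
    """Adapter shelling out to NCBI BLAST+ (blastp/blastn) and parsing its
    tabular output; requires the binaries on PATH and a formatted database."""

    def __init__(self, program: str = "blastp", path: str | None = None) -> None:
        self.name = program
        self.program = path or program

    def search(
        self, queries: Sequence[SeqRecord], database_ref, params: dict | None = None
    ) -> list[HomologyHit]:
        from .records import write_fasta

        params = params or {}
        with tempfile.TemporaryDirectory() as tmp:
            qpath = Path(tmp) / "queries.fasta"
            write_fasta(queries, qpath)
            cmd = [
                self.program,
                "-query",
                str(qpath),
                "-db",
                str(database_ref),
                "-outfmt",
                "6 qseqid sseqid pident length mismatch gapopen qstart qend "
                "sstart send evalue bitscore slen stitle",
            ]
            if "evalue_max" in params:
                cmd += ["-evalue", str(params["evalue_max"])]
            if "threads" in params:
                cmd += ["-num_threads", str(params["threads"])]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(f"{self.name} failed: {proc.stderr.strip()}")
            return parse_tabular_hits(proc.stdout)
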