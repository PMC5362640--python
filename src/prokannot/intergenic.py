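"""Intergenic region extraction and igORF rescue.

Regions between called genes are scanned for open reading frames that a
gene caller may have missed — typically halves of frameshifted genes,
genes broken by premature stop codons, or partial ORFs at contig edges.
Candidates with a homology hit below an e-value threshold are rescued into
the gene model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .gene_model import DEFAULT_START_CODONS, STOP_CODONS
from .homology import SearchEngine, classify_hits, HitClass
from .records import ContigMap, GeneCall, GeneModel, SeqRecord, translate_cds

__all__ = [
    "IntergenicRegion",
    "intergenic_regions",
    "find_igorfs",
    "rescue_igorfs",
    "DEFAULT_MIN_IGORF_NT",
    "DEFAULT_REACH_NT",
]

DEFAULT_MIN_IGORF_NT = 60
DEFAULT_REACH_NT = 30


@dataclass
class IntergenicRegion:
    start: int
    end: int
    strand_scope: str  # "sense" (+ strand only), "antisense" (- only), "both"


def _complement_regions(
    spans: list[tuple[int, int]], seq_len: int, reach_nt: int, scope: str
) -> list[IntergenicRegion]:
    """Complement of the union of spans, each region widened by reach_nt
    into the flanking genes and clamped to the sequence."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    gaps: list[tuple[int, int]] = []
    prev_end = 0
    for s, e in merged:
        if s > prev_end + 1:
            gaps.append((prev_end + 1, s - 1))
        prev_end = max(prev_end, e)
    if prev_end < seq_len:
        gaps.append((prev_end + 1, seq_len))
    regions = []
    for s, e in gaps:
        regions.append(
            IntergenicRegion(
                start=max(1, s - reach_nt),
                end=min(seq_len, e + reach_nt),
                strand_scope=scope,
            )
        )
    return regions


def intergenic_regions(
    model: GeneModel,
    seq_len: int,
    mode: str = "flattened",
    reach_nt: int = DEFAULT_REACH_NT,
) -> list[IntergenicRegion]:
    """Regions between genes, for the igORF search.

    ``flattened`` mode takes the complement of the union of all gene spans
    regardless of orientation (strand_scope=both).  ``oriented`` mode runs a
    separate computation per strand against only same-strand genes,
    yielding a sense and an antisense region set.  Each region is extended
    ``reach_nt`` nucleotides into the flanking genes.
    """
    if reach_nt < 0:
        raise ValueError("reach_nt must be ≥ 0")
    if mode == "flattened":
        spans = [(c.start, c.end) for c in model]
        return _complement_regions(spans, seq_len, reach_nt, "both")
    if mode == "oriented":
        plus = [(c.start, c.end) for c in model if c.strand == "+"]
        minus = [(c.start, c.end) for c in model if c.strand == "-"]
        return _complement_regions(plus, seq_len, reach_nt, "sense") + _complement_regions(
            minus, seq_len, reach_nt, "antisense"
        )
    raise ValueError(f"unknown intergenic mode {mode!r}")


def _region_orfs(
    sub: str,
    min_len: int,
    starts: frozenset[str],
    open_ended_ok: bool,
) -> list[tuple[int, int, bool]]:
    """ORFs in the three forward frames of a region subsequence.

    Returns (start, end, partial3) with 1-based coordinates local to the
    region.  When ``open_ended_ok``, a trailing start..region-end segment
    lacking a stop codon is reported with partial3=True.
    """
    orfs: list[tuple[int, int, bool]] = []
    for offset in range(3):
        first_start = None
        i = offset
        for i in range(offset, len(sub) - 2, 3):
            codon = sub[i : i + 3]
            if codon in STOP_CODONS:
                if first_start is not None and i + 3 - first_start >= min_len:
                    orfs.append((first_start + 1, i + 3, False))
                first_start = None
            elif first_start is None and codon in starts:
                first_start = i
        if first_start is not None and open_ended_ok:
            end = len(sub) - (len(sub) - offset) % 3
            if end - first_start >= min_len:
                orfs.append((first_start + 1, end, True))
    return orfs


def find_igorfs(
    sequence: str,
    regions: Sequence[IntergenicRegion],
    min_igorf_nt: int = DEFAULT_MIN_IGORF_NT,
    contig_map: ContigMap | None = None,
    start_codons=DEFAULT_START_CODONS,
) -> list[GeneCall]:
    """ORFs fully contained in intergenic regions, tagged ``igORF``.

    The ORF definition matches the baseline caller; additionally, stop-less
    open-ended segments are reported with a partial flag when the region
    abuts a contig boundary (sequence edge or spacer interval), mirroring
    incomplete ORFs at contig edges in fragmented drafts.
    """
    seq = sequence.upper()
    L = len(seq)
    boundaries = {1, L}
    if contig_map is not None:
        for _, s, e in contig_map:
            boundaries.update((s, e))
    starts = frozenset(s.upper() for s in start_codons)
    calls: list[GeneCall] = []
    seen: set[tuple[int, int, str]] = set()
    for region in regions:
        sub = seq[region.start - 1 : region.end]
        at_boundary_right = region.end in boundaries
        at_boundary_left = region.start in boundaries
        if region.strand_scope in ("both", "sense"):
            for s, e, partial3 in _region_orfs(
                sub, min_igorf_nt, starts, open_ended_ok=at_boundary_right
            ):
                key = (region.start + s - 1, region.start + e - 1, "+")
                if key not in seen:
                    seen.add(key)
                    calls.append(
                        GeneCall(
                            start=key[0],
                            end=key[1],
                            strand="+",
                            caller_tag="igORF",
                            partial3=partial3,
                        )
                    )
        if region.strand_scope in ("both", "antisense"):
            rc = str(Seq(sub).reverse_complement())
            for s, e, partial3 in _region_orfs(
                rc, min_igorf_nt, starts, open_ended_ok=at_boundary_left
            ):
                g_end = region.end - s + 1
                g_start = region.end - e + 1
                key = (g_start, g_end, "-")
                if key not in seen:
                    seen.add(key)
                    calls.append(
                        GeneCall(
                            start=g_start,
                            end=g_end,
                            strand="-",
                            caller_tag="igORF",
                            partial3=partial3,
                        )
                    )
    return sorted(calls, key=lambda c: (c.start, c.end, c.strand))


def rescue_igorfs(
    candidates: Sequence[GeneCall],
    sequence: str,
    engine: SearchEngine,
    evalue_threshold: float,
    database_ref=None,
    params: dict | None = None,
    log: list[str] | None = None,
    result_store: dict | None = None,
) -> list[GeneCall]:
    """Keep igORF candidates whose best homology hit falls strictly below
    the e-value threshold; per-candidate hits land in ``result_store``."""
    accepted: list[GeneCall] = []
    for i, cand in enumerate(candidates, start=1):
        nt = sequence[cand.start - 1 : cand.end]
        if cand.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        prot = translate_cds(nt, partial5=cand.partial5)
        prot = prot.replace("*", "")
        if not prot:
            continue
        query = SeqRecord(id=f"igorf_{i}", sequence=prot)
        try:
            hits = engine.search([query], database_ref, params)
        except Exception as exc:  # engine failure: candidate stays unevaluated
            if log is not None:
                log.append(f"igORF {cand.start}..{cand.end}: engine failure: {exc}")
            continue
        if result_store is not None:
            result_store[(cand.start, cand.end, cand.strand)] = hits
        verdict = classify_hits(hits, evalue_threshold)
        if verdict.kind == HitClass.BEST:
            accepted.append(cand)
    return accepted
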