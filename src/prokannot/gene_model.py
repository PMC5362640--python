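"""Baseline ORF calling and additive merging of multiple gene models.

When several gene callers contribute predictions, the merged ("additive")
model keeps the highest number of the largest potential genes: calls are
grouped by (strand, stop coordinate) and the longest call of each group is
retained, while groups with distinct stops are all kept even when they
overlap.  False positives are tolerated deliberately — removing a bad gene
during expert curation is cheaper than spotting a missing one.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from Bio.Seq import Seq

from .records import ContigMap, GeneCall, GeneModel

__all__ = [
    "call_orfs",
    "merge_models",
    "consolidate",
    "enforce_no_bleeding",
    "DEFAULT_START_CODONS",
    "DEFAULT_MIN_LEN_NT",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
DEFAULT_MIN_LEN_NT = 90


def _frame_orfs(
    seq: str,
    offset: int,
    min_len_nt: int,
    start_codons: frozenset[str],
) -> list[tuple[int, int]]:
    """ORFs (1-based inclusive, stop included) in one forward frame.

    Each maximal stop-to-stop segment contributes the longest ORF running
    from its first start codon to its terminating stop.  Codons containing
    N (or other non-ACGT characters) are neither starts nor stops.
    """
    orfs: list[tuple[int, int]] = []
    first_start: int | None = None
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if first_start is not None:
                length = i + 3 - first_start
                if length >= min_len_nt:
                    orfs.append((first_start + 1, i + 3))
            first_start = None
        elif first_start is None and codon in start_codons:
            first_start = i
    return orfs


def call_orfs(
    sequence: str,
    min_len_nt: int = DEFAULT_MIN_LEN_NT,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    caller_tag: str = "internal",
) -> GeneModel:
    """Six-frame ORF caller used as the built-in baseline gene caller.

    Every call is complete (starts at a start codon, ends at a stop codon,
    length divisible by 3).  Reverse-strand ORFs are reported in forward
    coordinates with strand '-'.
    """
    starts = frozenset(s.upper() for s in start_codons)
    seq = sequence.upper()
    L = len(seq)
    calls: list[GeneCall] = []
    for offset in range(3):
        for s, e in _frame_orfs(seq, offset, min_len_nt, starts):
            calls.append(GeneCall(start=s, end=e, strand="+", caller_tag=caller_tag))
    rc = str(Seq(seq).reverse_complement())
    for offset in range(3):
        for s, e in _frame_orfs(rc, offset, min_len_nt, starts):
            calls.append(
                GeneCall(start=L - e + 1, end=L - s + 1, strand="-", caller_tag=caller_tag)
            )
    return GeneModel(sorted(calls, key=lambda c: (c.start, c.end, c.strand)))


def _merge_tags(tags: Iterable[str]) -> str:
    seen: list[str] = []
    for tag in tags:
        for part in tag.split(","):
            if part and part not in seen:
                seen.append(part)
    return ",".join(sorted(seen))


def merge_models(models: Sequence[GeneModel]) -> GeneModel:
    """Form the additive gene model from several callers' models.

    Calls sharing (strand, stop coordinate) are alternative starts of the
    same gene: the longest is kept (identical spans deduplicate, merging
    their caller tags).  Calls with distinct stops are all retained.
    The operation is commutative, associative and idempotent.
    """
    groups: dict[tuple[str, int], list[GeneCall]] = {}
    for model in models:
        for call in model:
            groups.setdefault((call.strand, call.stop_coordinate), []).append(call)
    merged: list[GeneCall] = []
    for (strand, _stop), group in groups.items():
        best_len = max(c.length for c in group)
        winners = [c for c in group if c.length == best_len]
        merged.append(
            GeneCall(
                start=winners[0].start,
                end=winners[0].end,
                strand=strand,
                caller_tag=_merge_tags(c.caller_tag for c in winners),
                partial5=winners[0].partial5,
                partial3=winners[0].partial3,
            )
        )
    return GeneModel(sorted(merged, key=lambda c: (c.start, c.end, c.strand)))


def consolidate(model: GeneModel) -> GeneModel:
    """Sort by leftmost coordinate and assign sequential gapless gene numbers."""
    calls = sorted(model.calls, key=lambda c: (c.start, c.end, c.strand))
    out = []
    for n, call in enumerate(calls, start=1):
        out.append(
            GeneCall(
                start=call.start,
                end=call.end,
                strand=call.strand,
                caller_tag=call.caller_tag,
                gene_number=n,
                partial5=call.partial5,
                partial3=call.partial3,
            )
        )
    return GeneModel(out)


def enforce_no_bleeding(
    model: GeneModel, contig_map: ContigMap, log: list[str] | None = None
) -> tuple[GeneModel, list[GeneCall]]:
    """Drop calls that overlap an inter-contig spacer interval."""
    spacers = contig_map.spacer_intervals()
    kept: list[GeneCall] = []
    removed: list[GeneCall] = []
    for call in model:
        crosses = any(call.start <= ge and gs <= call.end for gs, ge in spacers)
        if crosses:
            removed.append(call)
            if log is not None:
                log.append(
                    f"gene call {call.start}..{call.end}({call.strand}) "
                    f"spans a contig boundary; removed"
                )
        else:
            kept.append(call)
    return GeneModel(kept), removed
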