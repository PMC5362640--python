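"""Deterministic synthetic-fixture generators with known truth.

Every generator is a pure function of its parameters and an integer seed;
each draws from its own named pseudo-random stream so adding a generator
never perturbs existing fixtures.  Genomes are built from a stop-dense
background (no open reading frame of the caller's minimum length can
survive outside a planted gene) with non-overlapping planted genes, each
preceded by an in-frame stop codon so the baseline ORF caller recovers the
planted span exactly.  Assembly perturbations (extension, truncation,
substitution, duplication, frameshift) return machine-readable truth
consumed directly by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .gene_model import DEFAULT_MIN_LEN_NT, call_orfs
from .records import GeneCall, GeneModel, SeqRecord, translate_cds
from .transfer import TransferOutcome

__all__ = [
    "make_genome",
    "make_draft",
    "MutationPlan",
    "mutate_assembly",
    "plant_frameshift",
    "make_reads",
]

_STREAMS = {
    "genome": 11,
    "draft": 23,
    "mutate": 37,
    "frameshift": 41,
    "reads": 53,
}

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_BG_CORE = "TTAGTTAGTTAG"  # stops all six frames every 30 nt of background


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _background(rng: np.random.Generator, length: int) -> str:
    """Stop-dense background: random 18-mers interleaved with a 12-nt
    all-frame stop core, so no ORF can span more than ~48 nt of it."""
    parts = []
    while sum(len(p) for p in parts) < length:
        parts.append(_random_nt(rng, 18))
        parts.append(_BG_CORE)
    return "".join(parts)[:length]


def _random_gene(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + sense codons + stop."""
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _protected_positions(truth: GeneModel) -> set[int]:
    """Positions that repairs must not touch: each gene's start codon, its
    terminal stop, and the in-frame stop planted immediately upstream."""
    protected: set[int] = set()
    for call in truth:
        if call.strand == "+":
            protected.update(range(call.start - 3, call.start + 3))  # prefix stop + ATG
            protected.update(range(call.end - 2, call.end + 1))  # terminal stop
        else:
            protected.update(range(call.end - 2, call.end + 4))
            protected.update(range(call.start, call.start + 3))
    return protected


def _gene_intact(seq: str, call: GeneCall) -> bool:
    nt = seq[call.start - 1 : call.end]
    if call.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    if len(nt) % 3 or nt[:3] != "ATG" or nt[-3:] not in _STOPS:
        return False
    return all(nt[i : i + 3] not in _STOPS for i in range(3, len(nt) - 3, 3))


def _plant_stop_at(
    seq: list[str],
    pos0: int,
    strand: str,
    truth: GeneModel,
    protected: set[int],
    rng: np.random.Generator,
) -> bool:
    """Try to write a stop codon at 0-based position pos0 on the given
    strand without breaking any planted gene; returns success."""
    if pos0 < 0 or pos0 + 3 > len(seq):
        return False
    window = set(range(pos0 + 1, pos0 + 4))  # 1-based positions touched
    if window & protected:
        return False
    original = seq[pos0 : pos0 + 3]
    stops = list(_STOPS)
    rng.shuffle(stops)
    for stop in stops:
        triplet = stop if strand == "+" else str(Seq(stop).reverse_complement())
        seq[pos0 : pos0 + 3] = list(triplet)
        ok = True
        for call in truth:
            if call.start <= pos0 + 3 and pos0 + 1 <= call.end:
                if not _gene_intact("".join(seq), call):
                    ok = False
                    break
        if ok:
            return True
        seq[pos0 : pos0 + 3] = original
    return False


def make_genome(
    n_genes: int = 10,
    genome_len: int = 12000,
    seed: int = 0,
    gene_len_codons: int = 100,
    min_orf_nt: int = DEFAULT_MIN_LEN_NT,
) -> tuple[SeqRecord, GeneModel]:
    """Generate a genome with planted genes that the baseline ORF caller
    recovers exactly (and nothing else at ``min_orf_nt``)."""
    cassette_len = 3 + gene_len_codons * 3  # upstream stop + gene
    if n_genes * cassette_len >= genome_len:
        raise ValueError("infeasible packing: genes do not fit the genome length")
    rng = _rng(seed, "genome")
    bg_len = (genome_len - n_genes * cassette_len) // (n_genes + 1)
    parts: list[str] = []
    calls: list[GeneCall] = []
    pos = 0
    proteins: set[str] = set()
    for i in range(n_genes):
        bg = _background(rng, bg_len)
        parts.append(bg)
        pos += len(bg)
        while True:
            gene = _random_gene(rng, gene_len_codons)
            prot = translate_cds(gene[:-3] + gene[-3:])
            if prot not in proteins:
                proteins.add(prot)
                break
        strand = "+" if i % 2 == 0 else "-"
        cassette = _STOPS[rng.integers(0, 3)] + gene
        if strand == "-":
            cassette = str(Seq(cassette).reverse_complement())
            start, end = pos + 1, pos + len(cassette) - 3
        else:
            start, end = pos + 4, pos + len(cassette)
        parts.append(cassette)
        pos += len(cassette)
        calls.append(
            GeneCall(start=start, end=end, strand=strand, caller_tag="truth", gene_number=i + 1)
        )
    parts.append(_background(rng, genome_len - pos))
    seq = list("".join(parts))
    truth = GeneModel(calls)
    protected = _protected_positions(truth)

    # repair pass: break any spurious ORF by planting stops in its frame;
    # windows already planted are avoided so overlapping ORFs in different
    # frames cannot clobber each other's repairs back and forth
    truth_spans = {c.span_key() for c in truth}
    step = min_orf_nt - 3  # planted stops this often leave no >= min_orf_nt fragment
    planted: set[int] = set()
    for _ in range(300):
        found = call_orfs("".join(seq), min_orf_nt)
        spurious = [c for c in found if c.span_key() not in truth_spans]
        if not spurious:
            missing = truth_spans - {c.span_key() for c in found}
            if missing:
                raise RuntimeError(f"planted genes not recovered: {missing}")
            break
        for orf in spurious:
            targets = list(range(9, orf.length - 9, step)) or [orf.length // 2]
            for off in targets:
                base = orf.start - 1 + off
                base -= (base - (orf.start - 1)) % 3  # stay in the ORF's frame
                done = False
                for avoid_planted in (True, False):
                    jitters = [0]
                    for j in range(3, orf.length, 3):
                        jitters += [j, -j]
                    for jitter in jitters:
                        p = base + jitter
                        if p < orf.start - 1 or p + 3 > orf.end:
                            continue
                        if avoid_planted and set(range(p + 1, p + 4)) & planted:
                            continue
                        if _plant_stop_at(seq, p, orf.strand, truth, protected, rng):
                            planted.update(range(p + 1, p + 4))
                            done = True
                            break
                    if done:
                        break
    else:
        raise RuntimeError("could not eliminate spurious ORFs (infeasible packing)")
    record = SeqRecord(
        id=f"synth_{seed}",
        sequence="".join(seq),
        description=f"synthetic genome, {n_genes} planted genes",
    )
    return record, truth


def make_draft(
    record: SeqRecord,
    truth: GeneModel,
    n_contigs: int,
    seed: int = 0,
    intragenic_cut: bool = False,
) -> list[SeqRecord]:
    """Cut a genome into contigs at intergenic positions (order preserved);
    with ``intragenic_cut`` one cut lands inside a gene, producing a truth
    boundary-partial gene."""
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if n_contigs == 1:
        return [record]
    rng = _rng(seed, "draft")
    L = len(record.sequence)
    gene_spans = sorted((c.start, c.end) for c in truth)
    gaps = []
    prev = 0
    for s, e in gene_spans:
        if s - 1 - (prev + 1) > 40:  # leave margin around cassettes
            gaps.append((prev + 20, s - 20))
        prev = e
    if L - prev > 40:
        gaps.append((prev + 20, L - 20))
    if len(gaps) < n_contigs - 1:
        raise ValueError("not enough intergenic room for the requested cuts")
    gap_idx = sorted(rng.choice(len(gaps), size=n_contigs - 1, replace=False))
    cuts = []
    for gi in gap_idx:
        lo, hi = gaps[gi]
        cuts.append(int(rng.integers(lo, hi + 1)))
    if intragenic_cut and gene_spans:
        s, e = gene_spans[len(gene_spans) // 2]
        cuts[-1] = (s + e) // 2
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [L]
    return [
        SeqRecord(id=f"{record.id}_c{i + 1}", sequence=record.sequence[a:b])
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]))
    ]


@dataclass
class MutationPlan:
    """Which perturbations to apply between two assembly versions."""

    extend: int = 0  # genes extended by extra codons at the 5' end
    truncate: int = 0  # genes truncated by codons at the 5' end
    substitute_frac: float = 0.0  # fraction of genes receiving substitutions
    substitute_nt_rate: float = 0.01  # per-nt substitution rate in those genes
    duplicate: int = 0  # genes duplicated elsewhere in the assembly
    edit_codons: int = 10  # codons added/removed by extend/truncate


def mutate_assembly(
    record: SeqRecord,
    truth: GeneModel,
    plan: MutationPlan,
    seed: int = 0,
) -> tuple[SeqRecord, GeneModel, dict[int, str]]:
    """Apply the plan to a genome+truth pair; returns the new record, the
    new (consolidated) gene model, and per-old-gene expected transfer
    outcome classes."""
    rng = _rng(seed, "mutate")
    calls = sorted(truth, key=lambda c: c.start)
    expected = {c.gene_number: TransferOutcome.PASS1_IDENTICAL for c in calls}

    plus_genes = [c.gene_number for c in calls if c.strand == "+"]
    rng.shuffle(plus_genes)
    needed = plan.extend + plan.truncate
    if needed > len(plus_genes):
        raise ValueError("not enough forward-strand genes for the requested edits")
    extend_ids = set(plus_genes[: plan.extend])
    truncate_ids = set(plus_genes[plan.extend : needed])
    pool = [c.gene_number for c in calls if c.gene_number not in extend_ids | truncate_ids]
    rng.shuffle(pool)
    n_sub = round(plan.substitute_frac * len(calls))
    substitute_ids = set(pool[:n_sub])
    dup_pool = [g for g in pool[n_sub:]]
    if plan.duplicate > len(dup_pool):
        raise ValueError("not enough untouched genes to duplicate")
    duplicate_ids = set(dup_pool[: plan.duplicate])

    def gene_nt(call: GeneCall) -> str:
        nt = record.subsequence(call.start, call.end)
        return str(Seq(nt).reverse_complement()) if call.strand == "-" else nt

    replacements: dict[int, str] = {}
    for num in extend_ids:
        call = next(c for c in calls if c.gene_number == num)
        nt = gene_nt(call)
        novel = "".join(rng.choice(_SENSE_CODONS, size=plan.edit_codons))
        replacements[num] = nt[:3] + novel + nt[3:]
        expected[num] = TransferOutcome.PASS2_EXTENDED
    for num in truncate_ids:
        call = next(c for c in calls if c.gene_number == num)
        nt = gene_nt(call)
        replacements[num] = nt[:3] + nt[3 + 3 * plan.edit_codons :]
        expected[num] = TransferOutcome.PASS2_TRUNCATED
    for num in substitute_ids:
        call = next(c for c in calls if c.gene_number == num)
        nt = gene_nt(call)
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        n_subs = max(1, round(plan.substitute_nt_rate * len(nt)))
        idx = rng.choice(range(1, len(codons) - 1), size=min(n_subs, len(codons) - 2), replace=False)
        for j in idx:
            old_aa = str(Seq(codons[j]).translate(table=11))
            while True:
                cand = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
                if cand != codons[j] and str(Seq(cand).translate(table=11)) != old_aa:
                    codons[j] = cand
                    break
        replacements[num] = "".join(codons)
        expected[num] = TransferOutcome.PASS3_ALIGNED
    for num in duplicate_ids:
        expected[num] = TransferOutcome.AMBIGUOUS

    # rebuild the genome left to right
    parts: list[str] = []
    new_calls: list[GeneCall] = []
    pos_new = 0
    prev_end = 0
    for call in calls:
        parts.append(record.sequence[prev_end : call.start - 1])
        pos_new += call.start - 1 - prev_end
        nt = replacements.get(call.gene_number, gene_nt(call))
        placed = str(Seq(nt).reverse_complement()) if call.strand == "-" else nt
        new_calls.append(
            GeneCall(
                start=pos_new + 1,
                end=pos_new + len(placed),
                strand=call.strand,
                caller_tag="truth",
            )
        )
        parts.append(placed)
        pos_new += len(placed)
        prev_end = call.end
    parts.append(record.sequence[prev_end:])
    pos_new += len(record.sequence) - prev_end

    # append duplicated cassettes at the end, behind fresh background
    for num in sorted(duplicate_ids):
        call = next(c for c in calls if c.gene_number == num)
        nt = gene_nt(call)
        spacer_bg = _background(rng, 60)
        prefix = _STOPS[rng.integers(0, 3)]
        parts.append(spacer_bg + prefix + nt + _background(rng, 30))
        start = pos_new + len(spacer_bg) + 3 + 1
        new_calls.append(
            GeneCall(start=start, end=start + len(nt) - 1, strand="+", caller_tag="truth")
        )
        pos_new += len(spacer_bg) + 3 + len(nt) + 30

    new_seq = "".join(parts)
    from .gene_model import consolidate

    new_model = consolidate(GeneModel(new_calls))
    new_record = SeqRecord(
        id=f"{record.id}_v2",
        sequence=new_seq,
        description="mutated assembly version",
    )
    return new_record, new_model, expected


def plant_frameshift(
    record: SeqRecord, truth: GeneModel, gene_number: int, seed: int = 0
) -> tuple[SeqRecord, GeneModel, dict]:
    """Introduce a single-base deletion mid-gene (forward-strand genes).

    The codon layout around the deletion is engineered so the shifted frame
    stops immediately, splitting the gene into two recoverable ORF halves.
    Returns the mutated record, the truth model with the broken gene
    removed and downstream genes shifted, and a truth dict with the two
    half spans (1-based, mutated coordinates).
    """
    call = next(c for c in truth if c.gene_number == gene_number)
    if call.strand != "+":
        raise ValueError("frameshift planting supports forward-strand genes")
    k = call.length // 3
    m = k // 2  # 1-based codon index to disrupt
    s = call.start
    seq = list(record.sequence)
    p0 = s - 1 + 3 * (m - 1)  # 0-based start of codon m
    seq[p0 : p0 + 3] = list("CTA")
    seq[p0 + 3 : p0 + 6] = list("ATG")
    del seq[p0]  # deletion: CTA|ATG -> TAA TG..., stop in the original frame
    new_seq = "".join(seq)
    remaining = []
    for c in truth:
        if c.gene_number == gene_number:
            continue
        shift = -1 if c.start > call.start else 0
        remaining.append(
            GeneCall(
                start=c.start + shift,
                end=c.end + shift,
                strand=c.strand,
                caller_tag=c.caller_tag,
            )
        )
    from .gene_model import consolidate

    info = {
        "gene_number": gene_number,
        "deletion_pos": p0 + 1,
        "half1": (s, p0 + 3),  # ends at the new in-frame stop
        "half2_end": call.end - 1,  # the original stop, shifted by the deletion
        "half2_max_start": p0 + 3,  # the engineered ATG (an earlier start may exist)
        "original_span": (call.start, call.end),
    }
    mutated = SeqRecord(id=f"{record.id}_fs", sequence=new_seq, description="frameshift fixture")
    return mutated, consolidate(GeneModel(remaining)), info


def make_reads(
    db_records: list[SeqRecord],
    n_reads: int,
    read_len: int = 240,
    dup_rate: float = 0.2,
    seed: int = 0,
    background_frac: float = 0.2,
) -> tuple[list[SeqRecord], dict[str, str | None]]:
    """Sample nucleotide reads encoding windows of protein database entries
    plus random background reads; a ``dup_rate`` fraction are exact
    duplicates of earlier reads.  Returns reads and a truth table mapping
    read id -> source subject id (None for background)."""
    if not db_records:
        raise ValueError("read sampling requires database entries")
    rng = _rng(seed, "reads")
    n_dups = int(round(dup_rate * n_reads))
    n_unique = n_reads - n_dups
    n_bg = int(round(background_frac * n_unique))
    reads: list[SeqRecord] = []
    truth: dict[str, str | None] = {}
    aa_len = max(10, read_len // 3)
    # codons per amino acid for reverse translation
    by_aa: dict[str, list[str]] = {}
    for codon in _SENSE_CODONS:
        by_aa.setdefault(str(Seq(codon).translate(table=11)), []).append(codon)
    for i in range(n_unique):
        rid = f"read_{i + 1}"
        if i < n_bg:
            reads.append(SeqRecord(id=rid, sequence=_random_nt(rng, read_len)))
            truth[rid] = None
            continue
        subj = db_records[int(rng.integers(0, len(db_records)))]
        plen = len(subj.sequence)
        win = min(aa_len, plen)
        off = int(rng.integers(0, plen - win + 1))
        peptide = subj.sequence[off : off + win]
        nt = "".join(
            by_aa[aa][rng.integers(0, len(by_aa[aa]))] if aa in by_aa else "GCT"
            for aa in peptide
        )
        if rng.integers(0, 2):
            nt = str(Seq(nt).reverse_complement())
        reads.append(SeqRecord(id=rid, sequence=nt))
        truth[rid] = subj.id
    for j in range(n_dups):
        src = reads[int(rng.integers(0, n_unique))]
        rid = f"read_dup_{j + 1}"
        reads.append(SeqRecord(id=rid, sequence=src.sequence))
        truth[rid] = truth[src.id]
    return reads, truth
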