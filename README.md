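# prokannot

An annotation toolkit for draft and complete prokaryotic (bacterial,
archaeal, viral) genomes, built for the workflow where automated annotation
is a starting point for expert curation rather than a final answer.

Draft genomes arrive as dozens-to-hundreds of contigs that change between
assembly versions. `prokannot` covers the bespoke computational stages of
that workflow:

- **Spacer concatenation** — contigs are joined into one pseudo-molecule
  with a 32-nt spacer, `5'-NNNNNNNNNNTTAGTTAGTTAGNNNNNNNNNN-3'`, whose core
  places a stop codon in **all six reading frames** (bacterial code, table
  11), so no predicted gene can bleed across a contig join. Runs of N
  (assembly gaps) can be patched in place with the same stop core without
  breaking the contig. A contig-order file records every placement.
- **Additive gene models** — predictions from multiple gene callers (a
  built-in six-frame ORF caller, plus external models in GFF) are merged by
  keeping, for every (strand, stop codon) group, the longest call:
  the most inclusive model with sequential gapless gene numbers. False
  positives are accepted deliberately; deleting a bad gene during curation
  is cheaper than finding a missing one.
- **Intergenic ORF (igORF) rescue** — regions between called genes
  (optionally reaching into flanking genes) are scanned for ORFs that
  callers miss: halves of frameshifted genes, genes with premature stops,
  partial ORFs at contig edges. Candidates with a homology hit below an
  e-value threshold are added to the model.
- **Rule-based annotation** — per gene: no homology hits → product
  `unknown`; only above-threshold hits → `conserved hypothetical`;
  otherwise the best hit (min e-value, ties by bit score) names the
  product. A below-threshold TIGRfam hit overrides both gene name and
  product and can contribute E.C. numbers. Profile databases cascade:
  a gene with a hit in Pfam-A is never searched against Pfam-B. COG codes
  translate to human-readable descriptors. Search engines are pluggable;
  a deterministic built-in protein searcher (ungapped seed-and-extend,
  BLOSUM62, Karlin–Altschul statistics) makes every stage testable offline.
- **Structural helpers** — full-length rRNA genes extrapolated from partial
  alignments to reference rRNAs; rotation of circular GenBank records to a
  new origin with feature shifting and locus-tag reset.
- **Annotation transfer** — curated names move between assembly versions in
  three passes: exact nucleotide identity, anchored protein containment
  (extended/truncated genes), then protein alignment with a minimum
  percent-identity threshold. Ambiguous matches (multi-copy genes such as
  integrases) and orphans are logged, never guessed.
- **NCBI submission files** — 5-column feature tables (.tbl), AGP v2.0
  scaffold files whose components exactly tile the concatenated length, and
  locus-tag management across linked multi-replicon submissions.
- **Metagenome profiling** — identical reads collapse to one query carrying
  their frequency; per-read best hits below an e-value ceiling accumulate
  frequencies per subject into a stringent and a relaxed e-value bin.
- **Synthetic fixtures** — a deterministic generator plants genes,
  frameshifts, assembly edits and read sets with machine-readable truth,
  so the entire pipeline is verifiable without external data.

## Worked example

Annotate a 3-contig synthetic draft genome against a small protein
database (both generated by the fixture tools):

```bash
prokannot synth --what draft --seed 1 --n-genes 10 --genome-len 12000 \
    --n-contigs 3 --out-prefix demo          # demo_contigs.fasta + truth GFF
prokannot annotate demo_contigs.fasta --grouped --protein-db db.fasta --out results
```

or from Python:

```python
from prokannot.config import RunConfig
from prokannot.pipeline import run_annotate

cfg = RunConfig(grouping="grouped", protein_db="db.fasta")
(entity_dir,) = run_annotate(["demo_contigs.fasta"], cfg, "results")
```

The entity directory contains the annotated GenBank file, the concatenated
FASTA, the contig-order file and per-gene homology result files
(`Blast_results/gene_<n>.tsv`, reused on reruns after an integrity check).
The GenBank output begins:

```
     contig_boundary 592..623
                     /note="inter-contig spacer"
     gene            851..1150
                     /gene="gene_1"
                     /gene_number="1"
     CDS             851..1150
                     /gene="gene_1"
                     /product="ABC transporter permease 1"
                     /gene_number="1"
```

Every gene is a gene/CDS pair at identical coordinates — the gene feature
carries the short name, the CDS the verbose product — sharing a sequential
gene number that keys the raw per-gene evidence files. The
`contig_boundary` feature marks the spacer; the contig-order file places
each input contig:

```
contig_id	start	stop
synth_1_c1	1	591
synth_1_c2	624	9491
synth_1_c3	9524	12064
```

Gaps between entries are exactly the 32-nt spacer. Here all ten planted
genes are recovered at their exact coordinates and named from their
database self-hits; a gene without a database hit would read
`/product="unknown"`.

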