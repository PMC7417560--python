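# circscreen

Design junction-spanning shRNAs against circRNA back-splice junctions and
screen them for off-target effects.

A circRNA's back-splice junction (BSJ) is the only sequence that
distinguishes the circle from its linear host mRNA. `circscreen` builds the
BSJ context from genome + circRNA annotations, designs 21-nt guides that
straddle the junction (plus shifted alternate designs), and then verifies
specificity three ways:

1. **Complementarity scan** — exact search for transcripts sharing a
   contiguous perfect-complementarity stretch of ≥ 12 nt with the guide
   (k-mer seed-and-extend, with a dynamic-programming longest-common-substring
   oracle kept alongside for validation).
2. **Seed enrichment** — hypergeometric word-enrichment landscapes testing
   whether guide/star seed sites are over-represented in the 3′ UTRs of the
   most downregulated genes of a ranked differential-expression (DE) list.
3. **DE verdicts** — per putative off-target, a call of
   `unchanged` / `changed` (|log2FC| > 1 and adjusted p < 0.05) /
   `not_testable` (adjusted p = NA) / `not_detected`, plus
   transcriptome-level significance filtering (fold change > 1.5, p < 0.05)
   and cross-strain exclusion of ubiquitously changing genes.

A deterministic `fixtures` module synthesizes every input (toy genomes with
circRNA loci, transcriptomes with planted off-target stretches, DE tables
with planted effects, rankings with planted seed enrichment), so the whole
pipeline is testable offline.

## CLI

```bash
# emit a synthetic input bundle + ground truth
circscreen simulate --seed 3 --outdir fixtures/

# design guides (TSV: circ_id, design_id, guide, passenger, side_5p, side_3p, warnings)
circscreen design --genome genome.fa --circ circs.bed --shift 3 --out designs.tsv

# complementarity off-target scan against a transcriptome FASTA
circscreen scan --designs designs.tsv --transcriptome tx.fa --min-len 12 --out hits.tsv

# seed-enrichment landscapes over a ranked DE table (TSV: gene_id, log2fc, pvalue, padj)
circscreen enrich --ranked de.tsv --utrs utrs.fa --designs designs.tsv \
    --bin-step 50 --out landscape.tsv --plot landscape.png

# DE-based off-target verdicts and per-design report
circscreen verify --designs designs.tsv --hits hits.tsv --de de_strainA.tsv --out report.json
```

Input conventions: BED coordinates are 0-based half-open, GTF 1-based
closed; DE tables are TSV with header `gene_id  log2fc  pvalue  padj`
(`NA` for missing). All sequences are handled as uppercase DNA (U→T).

## Layout

```
src/circscreen/
  annotation_io.py    readers (FASTA/GTF/BED/DE TSV), spliced/circular/UTR sequences
  junction_design.py  junction context, guide enumeration, primary/shifted designs
  offtarget_scan.py   complementarity scan + DP oracle, seed extraction, site counting
  seed_enrichment.py  exact hypergeometric tails, ranked landscapes, verdicts
  de_screen.py        significance filters, cross-strain exclusion, reports
  fixtures.py         deterministic synthetic-data generators
  cli.py              click command group
tests/                unit, property (hypothesis) and acceptance suites
scripts/acceptance.py acceptance-target recomputation
```
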