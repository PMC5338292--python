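# ohgt — organellar horizontal gene transfer toolkit

Detection and provenance analysis of plastid-derived sequences in plant
mitochondrial genomes (MTPTs), with:

* a desk-scale seed-and-extend nucleotide search producing BLAST-tabular
  hits (word size 20 for mt-vs-pt scans, 7 for the reverse direction);
* MTPT calling with the >200 bp / >70% identity filters, ancient-homology
  exclusion (*atp1*, *rrn18*, *rrn26*) and <100 bp gap merging;
* native-vs-foreign classification by phylogenetic placement: progressive
  alignment, neighbor joining on GTR distances, nonparametric bootstrap,
  and a "smallest supported clade" rule with a BS > 70 threshold;
* 1 kb flanking-region analysis with the six-category evidence code for
  the mitochondrion-to-mitochondrion transfer hypothesis;
* a reverse-direction detector for mitochondrion-derived regions in
  plastomes (PTMTs) with the strict bit-score-comparison rule;
* a synthetic organellar-corpus simulator with a complete transfer truth
  log (native IGT, mt-to-mt HGT with co-transferred tracts, direct
  pt-to-mt HGT, reverse mt-to-pt inserts) for recovery scoring;
* a packaged 46-record catalogue of published foreign MTPTs
  (`src/ohgt/data/table1_foreign_mtpts.tsv`) used by the summary stage.

## Command line

All stages are exposed under one executable:

```bash
ohgt simulate --seed 1 --config sim.yaml --out corpus/
ohgt search --query mt.fasta --subject pt.fasta --task mt2pt --out hits.tsv
ohgt call-mtpt --hits hits.tsv --mt-id sp01_mt --genome-length 48000 \
    --annotations corpus/annotations.gff3 --out calls.tsv
ohgt classify-origin --panel panel.fasta --focal focal \
    --taxonomy taxonomy.tsv --recipient-lineage "asterids; lamiids; Solanales" \
    --bootstrap 1000 --seed 1 --out placement.json
ohgt classify-flanks --calls foreign.tsv --genome mt.fasta \
    --mt-panel mt_panel.fasta --taxonomy taxonomy.tsv --out flanks.tsv
ohgt call-ptmt --pt pt.fasta --mt-panel mt.fasta --pt-panel pt_panel.fasta \
    --annotations annotations.gff3 --out ptmt.tsv
ohgt summarize --table1          # packaged catalogue: 46 / 30 (65%) / 24 (52%)
ohgt run-all --seed 1 --out run/ # simulate + all stages + manifest
```

`run-all` writes every stage report (hit tables, call TSVs, per-genome
statistics with tie-corrected Spearman tests, flank evidence, PTMT calls,
recovery scores) plus `manifest.json` with content digests; reruns with
the same config and seed are bit-identical.

Exit codes: 0 success, 2 validation error, 3 stage failure.

## Library layout

| module | contents |
| --- | --- |
| `ohgt.genome_io` | FASTA/GFF3/BLAST-tabular/taxonomy/newick IO, coordinate conventions, domain types |
| `ohgt.homology_search` | seed-and-extend local search, Karlin-Altschul scores |
| `ohgt.mtpt_caller` | hit filtering, ancient-locus exclusion, gap merging, content statistics, Spearman |
| `ohgt.origin_classifier` | panels, progressive aligner, NJ + bootstrap, placement classifier |
| `ohgt.flank_classifier` | flank windows, six-category evidence, corpus summary, catalogue fixture |
| `ohgt.ptmt_caller` | reverse-direction detector |
| `ohgt.synthetic_data` | species-tree/genome simulator, event implantation, recovery scoring |
| `ohgt.pipeline` | orchestration, manifests, reports |

## Notes on fidelity

The search module replaces an external BLASTN dependency; scoring
constants are the classic `-task blastn` defaults (+2/−3, gap 5/2,
λ = 0.625, K = 0.41) and no low-complexity masking is applied. Tree
inference replaces a maximum-likelihood search with neighbor joining on
GTR distances plus bootstrap; externally computed newick trees with
support labels can be supplied via `--tree`. E-values use raw sequence
lengths rather than BLAST's edge-corrected effective lengths.
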