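# dmrscan

Two-condition differential DNA methylation analysis for whole-genome
bisulfite data, built around a sliding-window Fisher-exact DMR caller with
replicate-consistency scoring, plus the surrounding analyses a ripening- or
development-style methylome study needs: genomic-context annotation and
enrichment, 24-nt siRNA cluster association, and differential-expression /
GO integration. A synthetic-study generator with planted ground truth makes
the whole pipeline testable end to end without external data.

## What it does

- **methylome I/O** (`dmrscan.methylome`) — per-cytosine call tables
  (chrom, 1-based pos, strand, CG/CHG/CHH context, methylated count, total
  count), validation, strand-aware context classification, bisulfite
  conversion-rate QC on an unmethylated control contig (pass at >= 99.6%),
  count-weighted methylation levels, all-library depth filtering
  (default >= 4), and replicate pooling.
- **DMR calling** (`dmrscan.dmr`) — per-context 200-bp windows stepped by
  50 bp, two-sided Fisher exact tests on pooled methylated/unmethylated
  counts, Benjamini-Hochberg FDR per context (candidates at FDR < 0.05),
  cross-context merging, shrinking to the first/last differentially
  methylated cytosine (per-site Fisher p < 0.05), and final filters
  (DMC count > 3, |pooled level difference| > 0.15). Each DMR gets a
  robust index |log2FC1 − log2FC2| / |log2FC1 + log2FC2| over the two
  replicates (NA on low depth); lower is more reproducible, and reports are
  ranked accordingly.
- **genomic context** (`dmrscan.context`) — gene association via
  strand-aware [TSS−2 kb, TES+2 kb] windows, element-class distribution
  (gene body / TSS-up / TES-down / intergenic) against exact genome
  background fractions, length-matched random-region sampling, Fisher
  enrichment tests, metagene profiles (length-normalised bodies + fixed
  flank bins), and per-gene methylation-change matrices.
- **siRNA analysis** (`dmrscan.sirna`) — small-RNA length filtering and
  size histograms, 5′-nucleotide composition, RPM normalisation, long-TE
  cluster exclusion (containment in TEs >= 4 kb, configurable),
  cluster–DMR overlap, and siRNA metaprofiles around anchor regions.
- **expression integration** (`dmrscan.expression`) — DEG classification
  (adjusted p < 0.01), hypomethylated-DEG flagging via promoter/body
  hypo-DMRs, and GO term Fisher enrichment with the combined gate
  |log2 fold| > 1 and p < 0.05.
- **synthetic data** (`dmrscan.simulate`) — seeded generator for a
  complete miniature study: random reference plus unmethylated control
  contig, gene/TE annotation, beta-binomial methylomes at ~10× per-strand
  Poisson coverage around context baselines (CG/CHG/CHH = 40/11/2%),
  planted hypo/hyper DMRs preferentially near TSSs, co-located siRNA
  clusters that lose abundance in the second condition, a DEG table linked
  to promoter hypomethylation, and truth tables for every planted signal.

## CLI

```bash
# generate a synthetic study with planted signal
dmrscan simulate --seed 1 --genome-length 200000 --n-hypo 10 --n-hyper 2 --out study/

# call DMRs between two replicated conditions
dmrscan call-dmrs \
  --condition-a study/methylome_immature_rep1.tsv \
  --condition-a study/methylome_immature_rep2.tsv \
  --condition-b study/methylome_ripe_rep1.tsv \
  --condition-b study/methylome_ripe_rep2.tsv \
  --out-prefix dmrs

# annotate, enrich, profile, integrate
dmrscan annotate-dmrs --dmrs dmrs.tsv --gff3 study/annotation.gff3 --out pairs.tsv
dmrscan metagene --methylome study/methylome_immature_rep1.tsv \
  --gff3 study/annotation.gff3 --out profile.tsv
dmrscan sirna-overlap --dmrs dmrs.tsv --clusters study/sirna_clusters.bed \
  --chrom-sizes sizes.tsv
dmrscan integrate-expression --degs study/deg_table.tsv --dmrs dmrs.tsv \
  --gff3 study/annotation.gff3 --go-map study/go_map.tsv
```

`call-dmrs` exposes the full parameter set (`--window 200 --step 50
--min-depth 4 --dmc-alpha 0.05 --fdr 0.05 --min-dmc 4 --min-diff 0.15
--epsilon 0.01`) and echoes parameters and stage counts to a JSON manifest.

## Conventions

Files use 1-based inclusive positions for per-cytosine calls (TSV) and the
usual 0-based half-open convention for BED/GFF-derived intervals; all
internal interval math is 0-based half-open. CG sites are kept per strand
(never collapsed). Weighted methylation level always means
Σ methylated / Σ total over the selection, not a mean of per-site ratios.
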