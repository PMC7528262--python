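# cnvdiff

Comparative copy-number-variation (CNV) analysis between two cattle lineages
(taurine vs indicine), built as a reusable pipeline:

1. **Call integration** — per-animal CNV calls from two callers (a
   split-read/paired-end caller with single-base boundaries, read as a
   structural-variant VCF; and a read-depth caller, read as whitespace-
   delimited text with a normalized depth column) are intersected by type.
   Confident calls keep the boundary caller's interval and derive an integer
   copy-number class in {0,1,2,3,≥4} from the depth caller's normalized depth.
2. **CNVR construction** — identical calls across animals collapse into
   distinct CNVs; overlapping distinct CNVs merge (single linkage, ≥1 bp)
   into CNV regions (CNVRs), kept when supported by ≥4 animals.
3. **Segmentation & genotyping** — each CNVR is dissected at the union of
   member-call breakpoints into boundary-consistent segments (> 50 bp);
   every animal is genotyped at every segment (diploid class 2 by default).
4. **Population differentiation** — per-segment F_ST over genotype-class
   frequencies between the two subspecies, with top-percentile ranking of
   lineage-differential segments, per-population loss/normal/gain rates, and
   PCA plumbing.
5. **Annotation** — gene/exon overlap (≥1 bp), feature-class
   observed/expected enrichment, 1-Mb window CNV density and cluster
   detection (> 80% covered), breed/subspecies sharing summaries, and
   lineage-specific sequence intervals (> 500 bp, depth ≥ 2) from remapped
   coverage.
6. **Synthetic data** — a two-subspecies, multi-breed simulator that emits
   per-animal paired dual-caller call sets (VCF + depth text) with known
   truth, including boundary jitter between callers and planted
   lineage-differential deletions, for end-to-end recovery testing.

Internally all coordinates are 0-based half-open; the 1-based external
formats (VCF, depth-caller text) are converted at the I/O boundary.

## Command-line pipeline

```sh
cnvdiff simulate  --config sim.cfg --out-dir simdata/
cnvdiff integrate --sample-sheet simdata/samples.tsv --vcf-dir simdata/vcf \
                  --depth-dir simdata/depth --chrom-sizes simdata/chrom.sizes \
                  --out calls.tsv
cnvdiff cnvr      --calls calls.tsv --sample-sheet simdata/samples.tsv \
                  --min-support 4 --out cnvr.bed
cnvdiff segment   --cnvr cnvr.bed --calls calls.tsv \
                  --sample-sheet simdata/samples.tsv \
                  --out segments.bed --matrix genotypes.tsv
cnvdiff fst       --matrix genotypes.tsv --sample-sheet simdata/samples.tsv \
                  --pop-a taurine --pop-b indicine --top 0.001 --out fst.tsv
cnvdiff annotate  --cnvr cnvr.bed --calls calls.tsv --gff genes.gff3 \
                  --chrom-sizes simdata/chrom.sizes \
                  --sample-sheet simdata/samples.tsv --out-dir reports/
```

`sim.cfg` is a flat key-value file mirroring `SimulationConfig`
(e.g. `seed 1`, `chrom_count 5`, `n_shared_cnvrs 200`, `boundary_jitter_sd 20`).

## Layout

- `src/cnvdiff/intervals.py` — interval primitives and union arithmetic
- `src/cnvdiff/io_formats.py` — VCF / depth-text / GFF3 / BED / bedGraph /
  sample-sheet / genotype-matrix readers and writers
- `src/cnvdiff/call_integration.py` — confident calls, distinct CNVs, CNVRs
- `src/cnvdiff/segmentation.py` — segment dissection and genotyping
- `src/cnvdiff/popdiff.py` — F_ST, ranking, status rates, PCA
- `src/cnvdiff/annotation.py` — genome summaries
- `src/cnvdiff/synthetic_data.py` — simulator with truth tracking
- `tests/` — unit, property (hypothesis) and acceptance suites backed by
  per-base brute-force oracles
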