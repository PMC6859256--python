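# trnafrag

Identification and quantification of tRNA-derived small non-coding RNAs
from small RNA-seq alignments.

Small RNA-seq libraries contain abundant fragments produced from tRNA
genes by specific ribonucleases, not by random degradation. `trnafrag`
models four classes in genome space and quantifies them conservatively:

| class | origin | locus definition |
|---|---|---|
| tRF-5 | Dicer cleavage in the mature tRNA D-loop | 5'-anchored, within the gene |
| tRF-3 | cleavage in the T-loop (carries non-templated CCA) | 3'-anchored, within the gene |
| tsRNA (tRF-1) | RNase Z release of the pre-tRNA 3' trailer | begins at/after the gene 3' end, typically poly-U tailed |
| 5' leader RNA | bounded by the RNase P cleavage site | the 20-nt region immediately upstream of the gene 5' end |

The pipeline starts from coordinate-space BAM alignments (adaptor
trimming and alignment are upstream, external steps) and runs:

1. **annotation** — build a custom catalog: 5' leader loci derived from
   the tRNA gene catalog, plus imported tRF-5/tRF-3/tsRNA coordinate
   records (tRF-1 is accepted as an alias of tsRNA); GTF/BED writers and
   readers that round-trip losslessly.
2. **counting** — union-overlap assignment of reads to loci with strict
   ambiguity removal: multi-mapping reads (NH > 1) and reads overlapping
   two or more loci are discarded and tallied, so that per sample
   `sum(counts) + ambiguous + multimapped + unassigned = mapped reads`
   holds exactly.
3. **normalization** — RPM = `counts x 1e6 / total mapped reads`, and
   TPM = length-normalized rates rescaled so each sample sums to 1e6;
   features with mean log2(TPM + 1) < 1 are removed (strict-less).
4. **classification** — length subclasses tRF-5a (14–16 nt), tRF-5b
   (22–24), tRF-5c (28–30), tRF-3a (17–19), tRF-3b (21–23); sequence
   flags for the tsRNA 3' poly-U signature.
5. **statistics** — two-group differential expression with an
   empirical-Bayes moderated t (variance shrinkage
   `s~² = (d0·s0² + d·s²)/(d0 + d)`, moment-matched prior, BH FDR), and a
   Pearson/Spearman correlation screen that reports only pairs with
   |r| > 0.5.
6. **simulation** — synthetic genomes, catalogs and truth-aligned reads
   with class-faithful end anchors, known abundances, sequencing error,
   and designated multi-mapping/ambiguous fractions, so the whole
   pipeline is testable without downloads.

## Worked example

```sh
trnafrag simulate --seed 7 --n-reads 20000 --out-dir demo
trnafrag count --bam demo/sample_0.bam --annotation demo/annotation.gtf \
    --out demo/counts.tsv
```

```
simulated dataset in demo
counted 1 sample(s); diagnostics in demo/counts.tsv.diagnostics.tsv
```

`demo/counts.tsv.diagnostics.tsv` then reads:

```
# trnafrag counting diagnostics
sample_id	total_mapped	n_assigned	n_ambiguous_feature	n_multimapped_discarded	n_unassigned	n_unmapped
sample_0	20000	17678	391	1011	920	0
```

Of 20 000 mapped reads, 17 678 were uniquely assigned to one fragment
locus; 391 overlapped two abutting loci (almost always the tRF-3/trailer
junction) and 1 011 were multi-mappers — both discarded under the
conservative policy — and 920 background reads overlapped no locus.
The four tallies sum exactly to the mapped total. Normalizing with
`trnafrag normalize --method tpm ...` yields columns summing to 1e6, and
`trnafrag filter` removes features below mean log2(TPM+1) = 1.

A full run (`annotate → count → normalize → filter → classify`, plus
optional DE and correlation stages) is available as
`trnafrag pipeline --config cfg.json`.

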