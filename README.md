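# nascentlnc

Analysis toolkit for nascent-transcriptome lncRNA profiling: de novo
transcript-unit discovery from strand-specific run-on coverage, promoter- vs
enhancer-associated lncRNA classification from histone-mark signal,
super-enhancer calling with differential activity scoring, negative-binomial
exact-test differential expression, and integration of steady-state RNA
levels to flag stable lncRNAs and co-regulated neighboring coding genes.
Includes a synthetic-data generator that plants ground truth (classes, fold
changes, SE clusters, stability factors) for end-to-end validation.

## Layout

| module | role |
|---|---|
| `genomic_io` | intervals, coverage tracks, BED / bedGraph / count-matrix I/O (0-based half-open everywhere) |
| `synthetic_data` | miniature genome simulator with planted truth tables |
| `transcript_discovery` | bin/threshold/merge unit calling; coding-overlap, small-RNA and known/novel (>70% overlap) rules |
| `quantification` | strand-aware region counting, RPKM, expression filter (RPKM > 0.5 in ≥ 3 samples) |
| `differential_expression` | TMM normalization, common NB dispersion (conditional ML), exact test on group sums, BH FDR, 2-fold + FDR < 5% classification |
| `epigenomic_classification` | log2 H3K4me3/H3K4me1 ratio over ±1 kb of the TSS; positive → promoter, negative → enhancer |
| `superenhancer` | H3K27ac peak calling, 12.5 kb stitching, rank-signal inflection cutoff, GRO-based differential SE activity, gained/lost sets |
| `integration` | nearest coding gene within 100 kb, Spearman concordance, stability calls (RNA-Seq RPKM > 2) |
| `pipeline_cli` | orchestration, run config, `nascentlnc` command line |

## CLI

Generate a synthetic dataset and run the whole pipeline:

```bash
cat > run.yaml <<'YAML'
seed: 1
outdir: runs/demo
simulation:
  n_coding: 20
  n_p_lnc: 30
  n_erna: 40
  n_superenhancer_clusters: 3
YAML
nascentlnc pipeline --config run.yaml
```

This writes every intermediate artifact (`annotation.bed`, `truth.tsv`,
`units.bed`, `counts.tsv`, `de_units.tsv`, `epiclass.tsv`, `se_A.bed`,
`se_B.bed`, `de_se.tsv`, `pairs.tsv`, `stability_{A,B}.tsv`, ...) plus a
machine-readable `report.json` into the run directory. Runs are fully
deterministic given the seed, and any single stage can be re-run from the
directory's on-disk artifacts:

```bash
nascentlnc simulate --outdir runs/demo2 --seed 7
nascentlnc discover --outdir runs/demo2
nascentlnc quantify --outdir runs/demo2
nascentlnc diffexp --outdir runs/demo2
nascentlnc classify --outdir runs/demo2
nascentlnc superenhancer --outdir runs/demo2
nascentlnc integrate --outdir runs/demo2
```

Per-module parameters (bin sizes, thresholds, stitch distance, ...) are all
exposed in the YAML run config; unknown keys are rejected and the resolved
config is written next to the outputs.

## Conventions

- All coordinates are 0-based half-open (BED); 1-based appears nowhere.
- Strand-specific coverage is stored as two bedGraph files
  (`*.plus.bedGraph` / `*.minus.bedGraph`); minus-strand signal is
  non-negative.
- NB dispersion φ uses the variance = μ + φμ² parameterization.
- Enhancer-region counts sum both strands (eRNA transcription is divergent);
  transcript-unit counts are strand-matched.
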