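# epimem

Computational assessment of engineered epigenetic memory and its
specificity after transient ("hit-and-run") epigenome editing. The
package implements the downstream analysis layer — array-style beta-value
differential methylation, promoter DMP calling, persistence concordance,
H3K27ac promoter peak-loss detection, PAM-constrained off-target
enumeration, bisulfite amplicon methylation calling, ddCq relative
expression — plus an integrative per-gene off-target triage, exercisable
end to end on generated synthetic data with planted ground truth.

## Modules

| module | purpose |
| --- | --- |
| `epimem.synthetic` | toy genomes, annotations, probe manifests, beta matrices with planted hypermethylated promoters (48% vs 7% background by default), replicate peak sets with planted promoter losses, bisulfite clone reads, Cq tables |
| `epimem.offtarget` | mismatch-tolerant protospacer search with an IUPAC PAM (NGG default), interval expansion (±146 bp default) and intersection |
| `epimem.methylation` | beta values M/(M+U), Δβ ≥ 0.2 probe calls, the >3-hyper-probe promoter rule, persistence overlap/concordance, Venn partition, hyper-CpG × off-target intersection |
| `epimem.peaks` | top-N robust peaks, naive-overlap reproducibility, control-specific peaks, ±1 kb TSS-proximal assignment, CPM-normalized fold change, the >2-fold reduced-promoter report |
| `epimem.bisulfite` | per-CpG calls from converted clone reads, conversion-efficiency QC, aggregation, lollipop grid/plot |
| `epimem.expression` | dCq/ddCq, fold change `2^(−ddCq)`, condition summaries |
| `epimem.triage` | integration of methylation, peak-loss and sequence-prediction evidence into a classified, ranked per-gene report; end-to-end pipeline |

Peak signal comparison uses counts-per-million scaling of the narrowPeak
`signalValue` column (library sizes default to each replicate's total
signal); no differential-binding model is refit. Promoter probes are
those annotated TSS1500/TSS200/5UTR; positions are 1-based in manifests
and converted to 0-based half-open intervals internally. Concordance uses
the min-set denominator by default (configurable).

## CLI

```sh
# synthetic scenario with planted ground truth
epimem simulate --config sim.yaml --outdir scenario/ --seed 1

# individual stages
epimem offtarget --genome g.fa --guide GATTACAGATTACAGATTG --pam NGG \
    --max-mismatch 3 --out sites.bed
epimem methdiff --betas betas.tsv --samples samples.tsv --manifest manifest.tsv \
    --treated treated --control dCas9 --delta 0.2 --min-probes 3
epimem peaks --control c1.narrowPeak --control c2.narrowPeak \
    --treated t1.narrowPeak --treated t2.narrowPeak \
    --annotation annotation.tsv --top-n 15000 --tss-window 1000 --fc 2
epimem bisulfite --reference amp.fa --reads clones.fa --min-conversion 0.0
epimem expression --cq cq.tsv --reference-gene GAPDH --control-condition dCas9

# end-to-end
epimem run --config run.yaml --outdir results/
```

`run.yaml` holds `epimem.triage.RunConfig` fields (target_gene plus
thresholds, all defaulting to the documented values: Δβ 0.2, min_probes 3,
±1 kb TSS window, top-N 15 000, fold-change 2, flank 146 bp, 3 mismatches,
NGG) and a `paths:` section with keys `betas`, `samples`, `manifest`,
`annotation`, `genome`, `guides`, `control_peaks` (list), `treated_peaks`
(list). `tests/test_cli.py::test_simulate_and_run` builds a complete
working example.

## File formats

Genome FASTA; annotation TSV (`gene, contig, tss, strand`; TSS 1-based)
plus BED6 export; probe manifest TSV
(`probe, contig, pos_1based, gene, region_group`); beta matrix TSV (probes
× samples, `NA` for missing) with a sample sheet TSV
(`sample, condition, timepoint_days, replicate`); peaks as 10-column
narrowPeak; off-target sites as BED6+2; Cq tables as TSV
(`sample, condition, gene, tech_rep, cq`). All outputs are plain TSV/BED/
FASTA/JSON.

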