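# hmcdiff

Analysis of 5-hydroxymethylcytosine (5-hmC) sequencing profiles: permutation
enrichment of pulldown peaks over genomic annotations, gene-level 5-hmC
density quantification, expression integration, replicate-consensus peak
overlap, tumor/normal differential 5-hmC with expression concordance, and
TAB-seq base-resolution quantification of cytosine modification states.

5-hmC is the oxidation product of 5-methylcytosine made by the TET enzymes
and marks active genes and regulatory elements during cell differentiation;
its genome-wide redistribution is a feature of cancers. `hmcdiff` provides
the bespoke statistics used to analyze selective-chemical-labeling (hMe-Seal)
pulldown data — MACS-style peaks annotated with tag counts — together with a
synthetic-data generator so every stage runs and is testable without any
external download.

## The core statistic

For peak *i* with `t_i` sequencing tags over length `L_i` (density
`d_i = t_i / L_i`), the observed tag mass over an annotation *A* is

```
Observed(A) = Σ_i |peak_i ∩ A| · d_i
```

The expected value is the mean of the same quantity over 1,000 genome-wide
random relocations of the peaks (lengths and tag counts preserved);
enrichment is `Observed / Expected` and the empirical p-value is the add-one
estimator `(1 + #{null ≥ observed}) / (1 + n_shuffles)`, floored at 1/1001.
Biological replicates are tested independently and their ratios averaged.

Other stages: genes are quantified as `tags / gene length` (union-mode
counting, peak-bearing genes only) and binned at the 0–25/25–75/75–98/98–100
density percentiles; expression–bin association uses Pearson chi-squared;
tumor/normal gain/loss calls contrast consensus peak presence between sample
groups, with concordance assessed by Wilcoxon rank-sum tests under
Bonferroni correction; TAB-seq clone counts yield %C/%5-mC/%5-hmC per CpG by
the subtraction `%5-mC = %modified − %5-hmC`.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Simulate a 5 Mb genome in which 60% of peak tag mass is planted inside CpG
islands covering 5% of the genome, then test islands and the derived CpG
shores for enrichment:

```sh
cat > sim.yaml <<'EOF'
chrom_lengths: [3000000, 2000000]
n_islands: 100
island_width_median: 2500
island_width_sigma: 0.0
annotation_enrichment: 0.6
EOF
hmcdiff simulate --config sim.yaml --seed 7 --out-dir demo/sim
hmcdiff annotate --gtf demo/sim/genes.gtf --islands demo/sim/islands.bed \
    --chrom-sizes demo/sim/genome.chrom.sizes --out-dir demo/ann
hmcdiff enrich --peaks demo/sim/peaks.bed \
    --annotation demo/sim/islands.bed --annotation demo/ann/shores.bed \
    --chrom-sizes demo/sim/genome.chrom.sizes \
    --n-shuffles 1000 --seed 7 --out demo/enrich.tsv
```

`demo/enrich.tsv` then contains:

```
annotation  observed  expected  enrichment  p_empirical  p_depletion
islands     6361.0    492.46    12.92       0.000999     1.0
shores      428.17    737.57    0.58        0.962        0.039
```

Islands hold 12.9× the tag mass expected under random peak placement
(planted ratio q/f = 0.6/0.05 = 12), at the smallest p-value 1,000 shuffles
can produce (1/1001 < 0.001); the shores, which by construction exclude
island bases, show mild depletion. Integrating gene-level density with the
simulated expression table,

```sh
hmcdiff gene-quant --tags demo/sim/tags.bed --peaks demo/sim/peaks.bed \
    --gtf demo/sim/genes.gtf --out demo/gq.tsv
hmcdiff integrate --gene-quant demo/gq.tsv \
    --expression demo/sim/expression.tsv --out-prefix demo/integrate
```

prints per-bin median FPKM rising monotonically with 5-hmC density
(14.4 → 113.2 → 1760.7 → 4017.7 across the four bins), the planted monotone
link. The TAB-seq stage compares the two simulated conditions on pooled
clone counts:

```sh
hmcdiff tabseq --table demo/sim/tabseq.tsv \
    --compare proliferating differentiated --out demo/tab.tsv
# proliferating vs differentiated (tab): chi2=45.24 df=1 p=1.747e-11
```

a gain of 5-hmC (5% → 25% planted truth) detected at df 1.

The full staged pipeline (`hmcdiff run --config run.yaml --out-dir out/`)
chains simulate → annotate → enrich → gene-quant → integrate → tabseq and
writes a manifest of outputs; rerunning with the same config and seed
reproduces every number.

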