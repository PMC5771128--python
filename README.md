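# nomeprofile

Promoter-anchored analysis of the interplay between **nucleosome occupancy**,
**CpG methylation** and **CpG density** from NOME-seq data — plus a bespoke
selector of non-promoter control regions whose CpG content exactly matches
each promoter's, and a synthetic methylome generator so the entire pipeline
runs end-to-end with known ground truth.

## The scientific problem

Around transcription start sites (TSSs), three signals form characteristic
patterns: a nucleosome-decreased region (NDR) upstream, phased nucleosomes
downstream, a peak of CpG density at the TSS, and a dip of CpG methylation.
Are these causally linked, or do they merely co-occur because of
transcription?  NOME-seq answers both halves from one readout: the GpC
methyltransferase M.CviPI marks accessible GpC dinucleotides before
bisulfite conversion, so

* methylation level at a site = methylated reads / total reads, and
* nucleosome occupancy = 1 − GpC methylation level,

while endogenous CpG methylation is read from CpG sites of the same data.
The decisive comparison is between promoters and *non-promoter* regions of
identical CpG organization: CpG clusters (runs of CpGs with gaps < 20 bp,
merged when < 50 bp apart) give candidate regions, and each promoter is
paired with a 2,001 bp candidate window whose center is shifted until the
CpG counts on each side of the center equal the counts on each side of the
TSS — exactly, and outside ±1,000 bp of every TSS.  If occupancy patterns
follow CpG organization, matched controls should reproduce them; if they
follow transcription, controls should be flat.  This package implements that
entire analysis: site discovery, window averaging with masking and
double-count rules, 30 bp smoothing, cluster detection, exact-count
matching, and expression/density/methylation stratification, for users in
epigenomics and regulatory genomics.

## Worked example

Everything below runs from nothing — the first command fabricates the
genome, promoter annotation and per-site read counts:

```sh
nomeprof simulate --seed 7 --outdir demo               # 2 Mb, 200 promoters
nomeprof profile  --genome demo/genome.fa --sites demo/sites.tsv \
                  --anchors demo/promoters.bed --out-prefix demo/promoters
nomeprof match    --genome demo/genome.fa --promoters demo/promoters.bed \
                  --outdir demo/match
nomeprof stratify --genome demo/genome.fa --sites demo/sites.tsv \
                  --promoters demo/promoters.bed \
                  --matches demo/match/matches.tsv --outdir demo/strata
nomeprof plot     --profile demo/strata/promoters.smooth.tsv --out demo/fig.png
```

which prints

```
wrote 7 files to demo (200 promoters, 123375 sites)
profiled 200 windows -> demo/promoters.smooth.tsv
199 matched / 200 promoters (12034 candidates, 1 unmatched)
8 strata -> demo/strata/summary.tsv
plot -> demo/fig.png
```

`demo/strata/summary.tsv` then contains one summary point per stratum:

```
label                     mean_density  mean_methylation  mean_occupancy  n_regions
promoters                 0.0265161     0.567438          0.782706        200
controls                  0.0266069     0.570265          0.795944        199
high_expression           0.03146       0.505703          0.767459        10
high_expression_controls  0.0316387     0.506195          0.801967        10
low_expression            0.0194956     0.658536          0.799106        10
low_expression_controls   0.0196953     0.635814          0.789148        10
low_density_promoters     0.0229401     0.611154          0.78828         111
low_methylation_controls  0.0295852     0.530577          0.799674        111
```

Read it as the analysis would: mean methylation falls as mean CpG density
rises, in promoters and controls alike (0.66 at density 0.019 down to 0.51
at 0.031), while the mean occupancy of every control stratum sits at the
flat ≈ 0.80 background regardless of its density or methylation — only
promoter strata depart from it, and the more so the higher the expression
(0.767 for the top-5% stratum; window means dilute the NDR, which in the
smoothed high-expression profile dips far deeper near −100 bp).  The
smoothed promoter profile's methylation minimum and density peak sit at the
TSS; the control profile pairs a flat occupancy track with a coincident
density-peak/methylation-dip at its center.

The same plumbing is importable without the shell: `simulate_dataset`,
`run_profile`, `run_match`, `run_stratify` in `nomeprofile` /
`nomeprofile.cli`.

Real data enter through documented text formats: FASTA for the genome, a
site table (TSV: chrom, pos, context CpG|GpC, meth_reads, total_reads, with
a bedGraph import for pre-computed levels), and BED6+expression for
promoters.

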