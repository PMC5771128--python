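# Methods

## The analysis

NOME-seq treats chromatin with the GpC methyltransferase M.CviPI before
bisulfite conversion, so a single sequencing readout reports two signals per
cytosine: endogenous methylation at CpG sites and enzymatic accessibility at
GpC sites.  A GpC is methylated only where no nucleosome protects the DNA,
so nucleosome occupancy at a position is defined as

    occupancy = 1 − (methylated GpC reads / total GpC reads).

The pipeline aligns ±1,000 bp windows to oriented anchor points —
transcription start sites (TSSs), or the centers of matched control regions —
and averages three tracks position by position:

* **occupancy**: mean over windows with a covered GpC at that position;
  windows without a measurement are disregarded, never zero-filled;
* **CpG methylation**: methylated/total read fraction, same masking rule;
* **CpG density**: fraction of windows carrying a CpG at that position, with
  the full window count as denominator.  When promoter windows overlap, a
  CpG already counted in an earlier promoter window is excluded from later
  windows' numerators (no double counting).  This dedup rule concerns
  promoter windows; control-region profiles, whose windows may legitimately
  overlap, are averaged without it.

Tracks are smoothed with a centered 30 bp moving average (the window at
position i spans i−15 … i+14, truncated at profile edges, with undefined
positions excluded from each local mean rather than imputed).

Minus-strand windows are reversed so that positive relative positions always
mean downstream of the TSS.  Phased nucleosomes downstream of active TSSs
only superpose coherently under this orientation; an `--no-orient` escape
hatch disables it.  Control regions are unstranded and use the plus
orientation.

### Control-region matching

To separate the effect of transcription from that of CpG organization, each
promoter is paired with a non-promoter region of identical CpG content.
Candidates are CpG clusters: maximal runs of CpG sites with successive gaps
< 20 bp, merged transitively when neighbouring clusters lie closer than
50 bp.  A ±1,000 bp window is placed on each merged cluster's midpoint and
its center is shifted — offsets tried in order 0, −1, +1, −2, … up to the
halfwidth — until the number of CpGs strictly left and strictly right of the
center exactly equals the promoter's upstream/downstream counts (a site
exactly at the center belongs to neither side, mirroring the TSS itself).
Windows intersecting ±1,000 bp of any TSS are rejected, so controls are
genuinely non-promoter.  Promoters are processed in ascending genomic order
and take the first usable candidate in genomic order, each candidate at most
once; this first-fit rule makes runs reproducible.  Matched controls may
overlap each other (only promoter overlap is forbidden); `--disjoint-controls`
additionally enforces mutual disjointness.

### Stratification

Expression strata take the ⌊q·N⌋ promoters of highest/lowest expression
(default q = 0.05), ties broken by genomic order.  The low-density stratum
keeps promoters whose ±1,000 bp mean CpG density is strictly below the grand
mean over all promoters; the low-methylation control stratum keeps control
regions whose mean CpG methylation is strictly below the mean over all
controls.  A profile is summarized to one point by averaging each track over
positions — count-weighted for occupancy and methylation (consistent with
how the profile means were accumulated), unweighted for density.

### Locating profile features

Raw argmin/argmax of a noisy averaged track wanders by tens of base pairs on
a flat-topped extremum, which is estimator noise rather than a property of
the data.  The package therefore provides, and its tests use:

* `locate_extremum` — parabola-vertex refinement of an extremum location,
  fit over ±200 bp of the raw extremum;
* `fit_gaussian_dip` — weighted least-squares fit of b − d·exp(−(x−µ)²/2s²)
  to the upstream occupancy flank; positions are weighted by contributing
  window counts since a position averaged over n windows has variance ∝ 1/n;
* `dominant_period` — discrete power-spectrum peak of the detrended
  downstream track (moving-average detrend, 301 bp), reported as n/bin.

## The synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
every planted parameter recoverable:

* **Sequence**: i.i.d. bases at GC fraction 0.41.  All CG and GC
  dinucleotides are first stripped (second base rewritten to A, which can
  never create a new CG/GC), then replanted at controlled rates: GpC blocks
  at a uniform 0.042/bp genome-wide — matching the plain f(C)·f(G)
  expectation from the C+G content, so accessibility is measurable
  everywhere — and CpG blocks at 0.009/bp background plus island bumps.
  Plants live on a 4 bp lattice (CpG blocks at offsets ≡ 0 mod 4, GpC at
  ≡ 2 mod 4) with single-letter boundary guards.  This makes planting
  collision-free and the planted lists provably identical to a re-scan of
  the final sequence; no cytosine is ever in both contexts (the ambiguous
  GCG configuration cannot arise).  The 4 bp quantization is invisible to
  every analysis stage, none of which resolves sub-30 bp spacing structure.
* **Islands**: each promoter and each of 2×N orphan (non-promoter) anchors
  receives a CpG island whose rate profile is a sharp Laplace peak
  (scale 150 bp) on a broad Gaussian base (σ = 450 bp), truncated at
  ±1,000 bp, with peak rate 0.08/bp at a maximally expressed anchor.  The
  peak-on-heavy-tails shape reproduces a density profile that peaks at the
  TSS yet stays above background across the window, and the sharp peak makes
  "where is the density maximum" a well-posed question at realistic window
  counts.  Island amplitude scales with the anchor's expression weight down
  to a floor of 0.45, so lowly expressed promoters are CpG-poorer but still
  unambiguous islands; orphan intensities are drawn from the same
  distribution.  Orphan islands are what the control matcher finds: a
  background-only genome would leave promoter-sized CpG counts unmatchable.
* **Expression**: log-normal values (µ_log = 1, σ_log = 1.2); the weight
  used by the occupancy and island models is the empirical-CDF rank in
  [0, 1].
* **Methylation**: the true methylation probability of a CpG is a logistic,
  strictly decreasing function of its local CpG density (sites/bp in a
  151 bp window): m(ρ) = 0.85 − 0.75·logistic((ρ − 0.05)/0.02).  This plants
  the density–methylation anti-correlation everywhere, promoter or not.
  The 151 bp locality makes the methylation dip track the island peak
  tightly; with a much wider window the dip becomes flat-topped and its
  location ill-determined at these sample sizes.
* **Occupancy**: baseline 0.80 away from promoters.  Around a TSS, with x
  the strand-oriented offset and e the expression weight:
  O(x) = 0.80 − e·0.5·exp(−(x+100)²/(2·60²))
       + e·0.15·cos(2πx/200)·exp(−x/600)·[x>0], clamped to [0, 1] —
  an expression-scaled nucleosome-decreased region (NDR) centered 100 bp
  upstream plus decaying phased oscillations (period 200 bp) downstream.
  Orphan islands carry no occupancy feature, which is exactly the
  flat-control property the analysis is meant to detect.
* **Reads**: per site, total ~ Poisson(coverage, default 20) and methylated
  ~ Binomial(total, p) with p = m(ρ) at CpGs and 1 − O at GpCs.  All stages
  consume one NumPy Generator in a fixed stage order, so a config (including
  its seed) yields byte-identical output.

Default problem size is one 2 Mb chromosome with 200 promoters and 400
orphan islands, anchors ≥ 2.1 kb apart (windows never straddle two
anchors); the parameter-recovery checks use 300 promoters at coverage 20.
These sizes keep the full test suite and the acceptance script at a few
minutes on one CPU while leaving every recovery statistic well-powered.

### What the generator does not model

No bisulfite conversion failure or sequencing error, no strand asymmetry or
symmetric-CpG merging, no diploidy/SNPs, no repeats or N gaps, no
enhancers/gene bodies, no coupling of methylation to occupancy (by
construction, methylation depends on density alone — the null hypothesis the
real analysis supports).  Passing tests therefore demonstrate that the
pipeline recovers planted structure of this form from binomially sampled
reads; they do not validate the biological conclusions on real data, where
the paired real inputs (a reference genome, per-site NOME-seq calls, and a
promoter/expression annotation) must be supplied in the documented formats.

## Numerical and design choices

* Coordinates are 0-based; BED output is half-open.  A site's coordinate is
  its cytosine's position on the 5′→3′ strand: match start for CG, match
  start + 1 for GC.  N bases break dinucleotides and are excluded from
  composition denominators; soft-masked lowercase is uppercased.
* The "expected" dinucleotide frequency is f(first)·f(second) from observed
  mononucleotide frequencies over non-N bases.  On real mammalian genomes
  this naive expectation gives ≈ 0.04 for CpG; published under-representation
  figures computed with other normalizations can differ, so the
  observed/expected ratio is reported, not asserted.
* Zero-coverage sites are kept in site tables (density needs their
  positions) but yield missing levels; there is no default minimum-coverage
  filter, only an optional `min_total` threshold (default 1).
* Missing values propagate as NaN and are excluded from every mean;
  positions with no contributing window have count 0 and undefined mean.
* Quantile strata use ⌊q·N⌋ with a deterministic genomic-order tie-break;
  threshold strata use strict "<".
* The matcher's shift search is capped at the halfwidth so a control window
  never fully detaches from its source cluster.
* Every CLI run writes a resolved copy of its configuration next to its
  outputs; identical config + seed gives byte-identical outputs.

## Known limitations

* First-fit candidate assignment is order-dependent by design
  (reproducibility over optimality); a different promoter order could match
  a different control set.
* Exact per-side count matching can leave promoters unmatched when the
  candidate pool is poor; unmatched promoters are reported, not dropped
  silently.
* `mean_region_methylation` weights covered CpG sites equally, so deeply and
  shallowly covered sites count the same.
* The strand-symmetry of profiles is exact for the CpG density track but
  carries an intrinsic 2 bp offset for GpC-derived occupancy, because the
  reported cytosine is the left base of a CpG but the right base of a GpC
  and mirroring swaps left and right.
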