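# Methods

`azadem` re-implements, as a tested pipeline over synthetic data, the
genomic analyses used to characterize genome-wide DNA demethylation by
the DNMT1 inhibitor 5-aza-2'-deoxycytidine (5-aza-CdR, decitabine) in a
cultured human cell line: untreated control, two drug doses (0.25 and
1.0 uM) sampled acutely after 3 days of exposure and again after 30
days of drug-free recovery.

## Methylation scores

**LUMA (global).** The luminometric methylation assay estimates percent
genomic 5mC from pyrosequencing incorporation after methylation-
sensitive (HpaII) versus insensitive (MspI) digestion of CCGG sites,
each co-digested with EcoRI as a loading normalizer:

```
meth% = 100 * (1 - (HpaII_CG/HpaII_norm) / (MspI_CG/MspI_norm))
```

where `*_CG` is the (C+G) incorporation and `*_norm` the EcoRI (A+C)/2
value of the same reaction. Triplicate reactions are converted
individually and averaged (per-reaction normalization), and the result
is clamped to [0, 100] against replicate noise. A zero MspI
incorporation is an assay failure (no unmethylated reference), not a
value. The (A+C)/2 normalizer is implemented exactly as defined even
though EcoRI's AATT overhang makes it look unusual; it cancels in the
ratio and is exposed in `LumaRun` should a different normalizer be
wanted.

**Angle score (per site).** For one CCGG site with HpaII count `h'` and
MspI count `m'` and library sizes `H`, `M`:

```
score = 100 * (2/pi) * arctan( (h'/H) / (m'/M) )    in [0, 100]
```

Higher scores mean *less* methylation: a fully methylated site yields no
HpaII signal (score 0), equal normalized signal scores 50, and
`score(h,m) + score(m,h) = 100` by arctangent complementarity. Sites
with MspI counts below `min_mspi` (default 1) carry no reference signal
and are filtered — absent from the track, which is distinct from a true
score of 0. The specific transform (library-size-normalized count ratio
through a scaled arctangent) is pinned here as the package's convention:
it is monotone in the HpaII signal, anti-monotone in the MspI reference,
and endpoint-correct on the published 0-100 scale.

## SOM compartmentalization

The genome is tiled into 100-kb windows on a 50-kb lattice (only fully
contained windows are used). Each window carries four features: mean
control angle score, mean treated (1.0 uM acute) angle score, mean FPKM
of genes whose TSS lies in the window, and the cumulative CCGG count.
Windows lacking sites or genes are excluded from training and counted.
Features are z-scored (their natural ranges differ by orders of
magnitude) and a Kohonen self-organizing map is batch-trained with a
Gaussian lattice neighborhood whose radius decays linearly from
max(grid)/2 toward zero; late epochs are therefore plain Lloyd steps.
Defaults: 20x20 grid, 100 epochs (the pipeline's run configuration uses
8x8/50 on the bundled ~200-window fixture, where a 400-node map would be
badly under-determined). Training records the RMS quantization error per
epoch; a monotone-distortion safeguard halves the epoch's radius (to a
pure Lloyd step in the limit) whenever a wide-neighborhood update would
raise it, so the recorded error is non-increasing by construction. The
U-matrix (mean Euclidean distance of each node to its 4-connected
neighbors) visualizes partition boundaries.

Windows are tagged by quintile (five equal-frequency bins; "top" = bin
5) of (a) methylation level, computed as `100 - control score` so that
tag 5 marks the most methylated windows, (b) mean expression, and (c)
demethylation response. The response tag uses the precision-standardized
response `(treated - control) / sqrt(1/n_ctrl + 1/n_trt)` rather than
the raw per-window delta: CCGG density differs systematically between
compartments, so the raw delta's extremes are otherwise dominated by
sparse, noisy windows and the response tag would correlate with
expression through site density alone, even with no true effect. The raw
delta is still reported per window. Association between two top-quantile
tags is measured by a 2x2 cross-tabulation with Fisher's exact test
(two-sided); the sample odds ratio ad/bc is reported as infinite when
the off-diagonal product is zero and as undefined on degenerate margins.
On the default fixture this is the headline result: windows with the
strongest demethylation response are significantly enriched among the
top-expression (euchromatic) windows, which are also the most methylated
at baseline.

## Promoter CG classes

Promoters are anchored at the TSS (or at ChIP peak summits) with a
+/-1.5 kb flank. The CG dinucleotide observed/expected ratio of the
region is `(#CG * L) / (#C * #G)` with an overlapping dinucleotide scan;
N bases are dropped from all counts and from L, and sequences without C
or G score 0 by convention. The ratio distribution over a promoter set
is bimodal; the HCG/LCG cutoff is placed at the lowest point of a
Gaussian KDE (Silverman bandwidth, 512-point lattice over [0, max])
between the two highest modes. A unimodal density is an error carrying
the single mode's location (the caller may force a manual cutoff); more
than two modes sets a diagnostic flag. Ties at the cutoff classify as
HCG. The "methylated LCG" subset takes LCG promoters whose methylation
score falls below `mean - 1.96 sd` of the HCG promoters' scores — a
normal reference band, deliberately not a confidence interval of the
mean, which would shrink with n and sweep in nearly every LCG promoter.
Expression of the subset is compared to background by a two-sided
rank-sum test; the report states the comparison without asserting
"comparability".

## Response trajectory clustering

Each promoter is summarized by two deltas relative to control, at the
acute and recovery stages. Methylation trajectories are expressed in
methylation-level units — the negated angle-score change — so that loss
of methylation is negative; expression trajectories use log2 FPKM
changes (pseudocount 0.1). k-means (Lloyd + k-means++, best of 25
restarts, seeded) is fit with k = 7 by design: one no-change cluster
plus three each for gain and loss, separating early/persistent
(delta at both stages), late (recovery only) and transient (acute only)
changes. The centroid of smallest norm is labeled no-change; the
remaining six are matched one-to-one against the six sign-pattern
prototypes by optimal assignment on scaled Euclidean distance, so every
semantic label is used exactly once. Cluster proportions are percentages
of all units from the outset, and aggregates (total loss, total gain)
are computed from unit counts, not from rounded percentages.

For the linked expression analysis, genes behind the loss clusters are
clustered in expression-trajectory space (k = 4 by default; the spec of
the methylation side does not constrain it) and an induced fraction is
reported against the *original* unit count, making it directly
comparable with the methylation-cluster percentages. Induction is a
deliberately plain stand-in for a full differential-expression engine:
per-gene Welch t-test on log2(FPKM + 0.1) across the four
pseudo-replicates, Benjamini-Hochberg correction at q < 0.05, and a
log2 fold-change floor of 1.

## Peak dynamics

Treated peaks overlapping any control peak by at least `min_overlap` bp
(default 1) are concordant, the rest new; control-only peaks are lost.
Genic context is mutually exclusive with priority promoter (TSS +/- 2
kb) > intragenic (gene body minus promoter) > intergenic, judged by the
peak summit when present and by any-bp overlap otherwise; a peak inside
one gene's body but within another gene's promoter window is a promoter
peak. The methylation shift at new intragenic peaks is the per-peak mean
angle-score delta over sites within +/-500 bp of the summit, tested
one-sided (delta > 0 = demethylation) by Wilcoxon signed rank; siteless
peaks are excluded and counted, and a single usable peak skips the test
with a warning. "Silent" means FPKM below 0.5 (configurable — the
notion of complete silencing has no canonical threshold) in *all*
replicates; the activation report lists genes silent before and
expressed after treatment. Intragenic placement of new peaks is compared
with a uniform null whose probability is the annotated intragenic
fraction of the genome (binomial test, one-sided).

## Intron retention

With exon density sum `E = sum(exonic coverage / exonic length)` and
intron density sum `I = sum(intronic coverage / intronic length)`:

```
IRS = 2 I / (E + I)      in [0, 2]
```

scale-invariant in coverage; intron-less genes and genes with no signal
are undefined and excluded with a reason (excluded + scored = input).
Condition ratios are `(IRS_t + eps) / (IRS_c + eps)` with eps = 0.01
(zero-control regularization); genes are flagged increased/decreased
when the log ratio departs from the sample mean by more than 2 standard
deviations. The log scale symmetrizes the two directions — the raw-ratio
convention leaves which condition sits in the numerator, and the scale
of "2 sd", underdetermined, so both are pinned and configurable. The
shift verdict is an exact binomial test of increased vs decreased counts
against 0.5 at alpha = 0.05; zero flags is a valid "no flags" outcome.

## Synthetic study design

The generator is first-class, tested code; its defaults *are* the study
conditions. A 2 x 5 Mb genome is split into contiguous 500-kb domains,
40% euchromatic. Euchromatin carries both the highest expression
(lognormal FPKM, median ~20 vs ~0.12) and the highest baseline
methylation (angle score 30 vs 70) — the deliberately paradoxical
co-enrichment the compartment analysis must recover. CCGG sites are
laid out more densely in euchromatin (1.5 kb vs 4 kb spacing, a SOM
feature), with two extra sites per promoter and three per planted peak;
the FASTA has CCGG scrubbed from the background and planted exactly at
site positions. Per-site counts are Poisson around an MspI mean of 30,
with the HpaII mean set through the inverse angle transform of a
planted true score (site-level sd 8); synthetic libraries are
depth-matched against the MspI reference by construction, so equal
library sizes are recorded per condition.

Demethylation shifts the planted score by (+18, +3) at 0.25 uM and
(+32, +5) at 1.0 uM in (eu-, hetero-)chromatin — dose-monotone by
validation. At recovery, an `imprinted_fraction` (0.6) of loci retains
`recovery_fraction` (0.6) of its acute shift; the rest remethylate to
5% of the shift. This heterogeneous retention is what makes the
seven-cluster trajectory semantics (persistent vs transient loss)
non-degenerate; setting both fractions to 1 reproduces full retention
(recovery distributionally identical to acute). Promoter sites override
the compartment baseline with CG-class-driven scores: HCG promoters are
unmethylated (82) in either compartment, while 40% of LCG promoters are
heavily methylated (35) — the methylated-LCG subset.

Promoter CG ratios are drawn from a two-component Gaussian mixture
(means 0.2/0.6, sd 0.05) with the high component more frequent in
euchromatin (0.85 vs 0.35); promoter sequence is synthesized by
scrubbing all CG dinucleotides from an i.i.d. backbone and planting the
target number of CG pairs at even offsets, with one calibration pass
correcting the G-depletion bias of the scrub. 1% of coding and 3% of
non-coding genes are differentially expressed (4-fold, random
direction) in all treated conditions; expression is emitted as 4
pseudo-replicates per condition with lognormal noise (sd 0.15 in log).
30 treatment-only peaks are planted in the bodies of robustly silent
genes (> 2 kb from the TSS, error if too few silent hosts exist), with
local demethylation (+35 capped score shift) and activation (FPKM set
to 5) of exactly half the hosts; control peaks sit at the promoters of
active genes. LUMA runs are synthesized by inverting the LUMA formula
from a planted global percentage anchored at 68% for the untreated
control and scaled across conditions by the compartment-weighted
planted methylation level.

What the generator does **not** emulate: read-level sequencing (no
FASTQ, no alignment, no mapping biases), isoform structure (one exon
chain per gene), replicate structure beyond i.i.d. lognormal noise,
copy-number or batch effects, and any coupling between CG content and
the background nucleotide composition beyond the planted promoters.
Passing tests therefore demonstrate that the implementations recover
what they claim from data with the assumed statistical structure — not
robustness to the full messiness of sequencing data.

## Problem sizes and numerics

The bundled fixture (2 x 5 Mb, ~400 genes, ~5,000 sites, ~200 windows)
and the run defaults (8x8 SOM, 50 epochs; 25 k-means restarts; 2,000
IRS genes) were chosen as the smallest sizes at which every planted
effect is comfortably detectable; all are configuration, not code.
Numerical conventions worth knowing: angle scores use `arctan2` (safe at
zero MspI normalization when filtering is disabled); LUMA clamps to
[0, 100]; k-means ties and empty clusters follow scikit-learn's
handling; the KDE lattice is fixed at 512 points for reproducibility;
classification ties at the CG cutoff go to HCG; duplicate centroids in
labeling warn and resolve by cluster index; the intragenic-null
probability counts gene bodies minus promoter flanks clipped at zero.
Seeds fan out from one global seed by stage-name CRC32, all below 2^31.

## Known limitations

* The SOM partition itself is visual/exploratory (U-matrix plus
  overlays); compartment inference for testing runs through the
  quantile cross-tabulation, not through a segmentation of the map.
* The induced-fraction rule is a simple replicate t-test, not a count
  model; it is calibrated for the generator's lognormal replicates.
* `bimodal_cutoff` assumes the two classes dominate the two highest
  modes; heavy multimodality beyond two modes is only flagged.
* Genome-scale realism (repeat content, CpG islands with island-level
  structure, chromatin domains of varying size) is out of scope.
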