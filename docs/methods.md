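# Methods

## The measurement model

MeDIP-chip is a qualitative enrichment assay: an anti-5-methylcytosine
immunoprecipitate (IP) and total genomic DNA (Input) are labeled and
co-hybridized, and each probe reports log2(IP/Input). At a methylated promoter
the fragment population overlapping the probes is enriched, shifting probe
log2 ratios upward; at an unmethylated promoter the ratio fluctuates around
the array baseline. The pipeline therefore treats methylation detection as a
distribution-shift problem per promoter, not as quantitation — hit counts
over replicate arrays, not effect magnitudes, carry the downstream analysis.

## Normalization

Each array is centered by subtracting the Tukey biweight mean of its log2
ratios (bisquare weights with tuning constant c = 5 on the MAD scale,
iterated to |Δcenter| < 1e−6, at most 50 iterations; constant input is
degenerate and returns that constant). The biweight mean is used instead of
the arithmetic mean because the enriched minority of probes would otherwise
drag the center upward and shrink all scores. Centering is per array over all
probes by default; a per-promoter mode exists behind a flag but is only for
diagnostics — centering within the promoter would subtract away exactly the
promoter-wide enrichment the peak caller looks for.

## Window scoring and peak calling

A window of fixed width (default 500 bp, configurable within the 200–750 bp
band) walks each promoter region in 100 bp steps. The probes inside the
window are compared with all other probes on the same array by a one-sided
two-sample Kolmogorov–Smirnov test with the "window stochastically larger"
alternative — enrichment only; hypomethylation is inferred later from hit
patterns, not from depletion peaks. The two-sample form makes no assumption
about the noise law. Windows with fewer than `min_probes` (default 4) probes
are skipped.

P-values use the one-sided asymptotic bound P = exp(−2·n_eff·D₊²) with
n_eff = m(N−m)/N. This bound is deliberately conservative at the window sizes
a tiling design produces (4–6 probes); an exact option (`method="exact"`,
delegating to scipy for windows under 10 probes) is available but is *less*
conservative and therefore not the default. Ties enter the empirical CDFs
as-is.

Peaks are maximal runs of consecutive windows whose scores all exceed the
threshold (default 2, i.e. P < 0.01), collapsed to the maximal-score window.
Runs shorter than `min_run` (default 3) windows are discarded. The rationale
is geometric: an enrichment at least as wide as the narrowest allowed window
(200 bp) stays fully inside a 500 bp window for (500−200)/100 + 1 = 4
consecutive steps, and promoter-wide methylation yields runs spanning every
window of the region, so genuine events always produce sustained runs. A
single above-threshold window, by contrast, is the signature of small-sample
KS noise: with ~19 windows per promoter each tested at P < 0.01, accepting
isolated windows inflates the per-gene false-positive rate to several percent
per array, while the run requirement brings it below ~0.5% without measurable
sensitivity loss. `min_run=1` restores the literal one-window rule.

A gene scores a hit on an array when at least one peak center lies inside its
promoter region. No multiple-testing correction is applied — the fixed
−log10 P > 2 rule is the scheme's operating point, and the threshold is
configurable.

## Hit scoring and condition comparison

Hit counts over a replicate set classify each gene: unmethylated (0 hits),
methylated (hits in all arrays of the set — 3/3 or 2/2), partly methylated
otherwise. The mean total hit count of a set is the global-methylation
measure (unitless, semi-quantitative). Condition means are compared with the
classic pooled-variance unpaired two-tailed t-test (Welch is not used; the
pooled form is the conventional default for this design). Zero-variance
degenerate groups: equal means report P = 1, unequal means P = 0.

## Differential scheme

D_MV = injury_hits/3 − sham_hits/2 is computed as an exact rational
(`fractions.Fraction`), so classification never depends on floating-point
rounding. The five distinct positive values {1, 2/3, 1/2, 1/3, 1/6} map to
MV {+5, +4, +3, +2, +1} and mirror to the negatives — the only antisymmetric,
order-preserving reading of a rank-based ±5 scale. D_MV = 0 occurs only for
(3,2) ('M', persistently methylated) and (0,0) ('U', persistently
unmethylated); a defensive 'neutral-0' label exists for patterns that cannot
arise. An alternate preset (`preset="figure"`) reproduces a published worked
example that assigns (2/3 injury, 0/2 sham) → +1 instead of the rank
mapping's +4; the two presets agree on every pattern the acceptance checks
exercise (±5, 'M', 'U'). The rank mapping is the default and the choice is
config-visible rather than buried.

The strict filter accepts only MV = +5 with naive hits 0–1 (hyper) or
MV = −5 with naive hits 2–3 (hypo) — the naive constraint removes genes whose
sham state already disagreed with the uninjured baseline. Lenient mode drops
the naive constraint. DM genes between injury models are those passing the
strict filter under exactly one model at a given day; days are never pooled.

## CpG statistics

Island detection follows the CpGPlot convention: sliding 100 bp window, step
1; positions where obs/exp CpG > 0.6 **and** GC > 0.5 form candidate runs; a
run of passing starts [a, b] spans the island [a, b + 100); islands shorter
than 200 bp (option 100) are dropped and island statistics are recomputed
over the island extent. Only CG pairs fully inside a window count, and
ambiguous bases (N) count as neither C nor G and break pairs. Islands closer
than `max_gap` (default 100 bp — "very close proximity" quantified as one
window width) merge with statistics recomputed over the union.

Promoter CpG density is obs/exp CpG = (#CpG · L)/(#C · #G) over the symmetric
3 kb TSS window; a window truncated at a sequence end substitutes its actual
length L, keeping the statistic a proper obs/exp normalization. #C = 0 or
#G = 0 makes the ratio undefined and it is reported as missing, never as 0.

## QC statistics

The weighted geometric mean CpG count, (c200·c400²·c700²·c1000)^(1/6),
summarizes the CpG content of the sonicated fragment population around an
amplicon (sizes 200/400/700/1000 bp weighted 1:2:2:1 for the roughly Gaussian
fragment-size distribution; the weights are taken as given, not derived). It
is computed in log space with an exact zero short-circuit. Enrichment-vs-CpG
and replicate-pair correlations are plain Pearson; zero-variance inputs are
reported missing rather than 0.

## Synthetic data generator

The generator emulates the study conditions: 13 condition sets / 33 arrays
(SNA, DCA × injury, sham × days 1, 3, 7, plus naive; triplicate
injury/naive, duplicate sham), default 1,000 genes on one chromosome, each
promoter spanning −1500/+800 bp around its TSS and tiled by 20 probes at
uniform spacing with ±10% jitter. Probe signal is
0 + effect·[methylated] + N(0, sd) with effect 1.5 log2 units and sd 0.3 —
a clearly-enriched promoter against typical probe noise — and independent
noise per replicate. Ground truth plants 10% hyper and 10% hypomethylated
genes (half responding to both injuries, the rest split between SNA-only and
DCA-only, which is what creates DM genes), and 2% of the remaining genes are
constitutively methylated, matching the small always-methylated fraction real
promoter arrays show.

Promoter sequences for the island detector embed one island per sequence in
CpG-depleted background (G down-weighted ×0.25 after C, GC 42%). The island
is built from tiles each carrying one CG dinucleotide plus composition-
balanced fill (exact counts, CpG-free), so the local obs/exp and GC of every
100 bp sub-window sit near the targets (defaults obs/exp 0.8, GC 0.6, 300 bp)
— mimicking the homogeneous CpG spacing of real islands and making detection
a property of the criteria rather than of fill luck.

What the generator does *not* model: dye bias, spatial artifacts, WGA
amplification bias, copy-number variation, probe-specific affinity, or
partial/intermediate methylation levels. Passing tests therefore demonstrate
the correctness and calibration of the analysis logic under the assumed
signal-plus-Gaussian-noise model, not performance on raw NimbleGen scans.

## Problem sizes and determinism

Default test and demonstration sizes (1,000 genes × 33 arrays for recovery;
50 repeats of 250 genes × 5 arrays for null calibration) were chosen so a
complete run takes well under a minute per stage on one core while leaving
hundreds of genes per truth class. All randomness flows from a single
mandatory integer seed through `numpy` `SeedSequence` spawns (design, truth
and signals use distinct streams), so identical configs are bit-identical,
and the pipeline manifest records SHA-256 checksums of every output to make
rerun identity checkable.

## Known limitations

- The KS bound is conservative; at very high probe densities the score is
  biased low relative to the exact P, which is the safe direction for the
  fixed threshold-2 rule but means scores are not comparable across very
  different window occupancies.
- Hit-based D_MV saturates: promoters partially methylated in both arms are
  invisible to the ±5 strict filter by construction.
- The island detector reports islands only after the ≥200 bp filter; a true
  island fragmented by a local composition dip below the thresholds can lose
  a fragment before merging.
- GFF I/O assumes well-formed single-score tracks; it is not a general GFF3
  feature parser.
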