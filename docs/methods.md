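# Methods

## Data model and coordinates

A probe panel tiles each targeted CNV region with `n_probes_inside ≥ 10`
uniformly spaced probes and 5 probes on each flank, laid over a flank
window of 25% of the region width (configurable; at least as many base
pairs as flank probes). Flank windows are clipped at the midpoint between
adjacent regions so probe labels never interleave, and truncated at
position 1 for telomeric regions, which may then carry fewer flank
probes. Each region plus its flanks is one *pseudochromosome*; all
downstream per-sample computation happens within a pseudochromosome, so
unprobed gaps between regions can never influence a call.

Printed tables and every on-disk file use 1-based inclusive coordinates;
all in-memory intervals are 0-based half-open, converted only at the I/O
boundary. BED-like call files carry both (`start0` and `start_bp`),
named in the header.

## Synthetic cohorts

The generator emulates targeted-array intensity data, not scanner
physics. Per sample and region, carrier status is an independent
Bernoulli draw at the group's carrier frequency; autosomal carriers get
CN 1 (loss) or CN 3 (gain), X carriers shift the sex baseline (male X
baseline is CN 1) by ±1. LRR is drawn around per-copy-number cluster
means CN0 −3.5, CN1 −0.66, CN2 0, CN3 +0.4, CN4 +0.68 — the widely used
positions for Illumina-style arrays — with Gaussian noise of sd 0.15 by
default, a typical dispersion for a well-behaved array and the level at
which the planted-recovery guarantees below are stated. Probes inside a
carried region show the carrier copy number; flank probes always show the
baseline. BAF is generated by drawing each of the CN allele copies as B
with the probe's allele frequency (uniform 0.05–0.95 per probe,
Hardy–Weinberg at CN 2), giving `#B/CN` cluster positions (e.g. 1/3 and
2/3 for CN-3 heterozygotes) plus truncated Gaussian noise; CN 0 yields
uniform noise. Batch effects are additive per-batch LRR offsets drawn
Normal(0, 0.05) when more than one batch is configured — enough to
exercise the correction code, small against the ±0.3 classification
thresholds.

What the generator does not emulate — GC waves, probe-specific bias,
mosaicism, genotyping error, relatedness, population structure — bounds
what green tests show about real arrays: they validate the algorithms
under the stated noise model, not robustness to artifacts outside it.

## Preprocessing

Quantile normalization replaces each sample's values (per allele channel)
by the across-sample mean order statistic of matching rank, ties
averaged. Log ratios are `log2((A+B)/reference)` with the per-probe
population median total as the reference; zero totals are floored at −10
and flagged. PCA batch correction removes the leading principal
components of the probe-centered sample × probe matrix via SVD. Two
safeguards apply: a component whose squared probe-loading mass
concentrates more than 50% on a single pseudochromosome is left in place
(such an axis is a shared CNV, not a batch effect), and correction is
applied to autosomes only, because on a mixed-sex cohort the dominant
X-chromosome axis is sex itself and removing it would erase the
hemizygous male baseline. `transform` centers its input by the input's
own probe means before projecting, which makes the correction idempotent.

PCA correction is **off by default** in the end-to-end pipeline: it
belongs to genome-wide discovery preprocessing, and on a targeted panel —
where most probes sit inside candidate CNV regions — the leading
components can mix several rare-CNV axes in a way the single-region guard
cannot recognize (observed directly at desk scale: a component spreading
its mass over two or three pseudochromosomes regressed out planted
carriers). Users with visible batch structure can enable it explicitly.

## HMM caller

States are integer copy numbers 0–4. LRR emissions are Gaussians at the
cluster means (sd 0.25, deliberately wider than the generator's 0.15 to
tolerate dispersion); BAF emissions are genotype mixtures with binomial
(p = 1/2) weights — the decoder does not know per-probe allele
frequencies — a uniform density for CN 0, and a 1% uniform floor against
outliers. CN 4 is weakly identifiable from CN 3 on BAF alone; both map to
"gain" downstream, so nothing rests on that distinction. Transitions use
a distance-dependent self-probability `p_stay(d) = 1 − (1 − ρ)·min(d/D, 1)`
with ρ = 0.999 and D = 100 kb; the leave mass is split over other states
in proportion to the initial distribution (96% on the baseline state).
Decoding is exact log-domain Viterbi per pseudochromosome, ties broken
toward the diploid state; non-finite probes contribute no emission
information. On male X the prior peak moves to CN 1. Maximal runs of
non-baseline states with ≥3 probes become calls; same-type runs separated
by a single masked probe are merged first.

Correctness is anchored by an exhaustive oracle: for small n the full
5^n path table is enumerated and compared path-for-path; at n = 12 all
path scores are enumerated (chunked, max folded) and the Viterbi score
must match the enumerated maximum.

## Segmentation caller

Per pseudochromosome, RSS-optimal segmentations for every segment count
K = 1..5 (replication profile; minimum segment 1 marker) are computed by
dynamic programming over prefix sums. The largest K whose boundaries
validate is accepted:

* **K = 2** is gated by a maximally-selected-split permutation test: the
  observed statistic is the RSS reduction of the best breakpoint, and
  each permutation re-finds its own best breakpoint, so breakpoint
  selection is built into the null and the gate holds its nominal level
  on homogeneous data.
* **K ≥ 3** is gated by pairwise permutation tests between every adjacent
  pair of segments in the final configuration.

This architecture, rather than gating greedy binary splits one at a time,
is forced by the panel geometry: a 10-probe CNV sits in the middle of a
~20-marker pseudochromosome, and the first binary split of
flank|CNV|flank (5 vs 15 markers) has a combinatorial p-value floor near
0.03 — no single split can ever reach the 0.001 threshold, whereas the
pairwise tests of the 3-segment configuration (flank vs CNV) reach
1/C(15,5) ≈ 3.3·10⁻⁴.

The pairwise test redistributes pooled values between the two sides,
sizes preserved. When the number of distinct assignments C(n, k) is at
most 20,000 the p-value is computed by **exact enumeration**
(#extreme/#assignments); otherwise by 1,999 Monte-Carlo shuffles with the
add-one estimator. Exactness matters at panel scale: the achievable
p-values (~3·10⁻⁴) sit close to the 0.001 threshold, and Monte-Carlo
noise around them would reject about half of the true boundaries.

Measured under the default conditions: false-split rate 0.000–0.001 on
1,000 pure-noise pseudochromosomes (nominal 0.001), recovery of a planted
10-probe CN-1 region at noise sd 0.15 in 98.8% of 500 carriers, and the
noise-free step vector splits exactly once at the true breakpoint.
Segment means at or beyond ±0.3 (midpoints between the CN2 and CN1/CN3
LRR means) classify as loss/gain, inclusively; on male X the comparison
is taken relative to the −0.66 baseline. The discovery profile (5,000
marker windows, ≤20 segments per window, minimum 10 markers) is
implemented with consecutive windows for genome-wide input; the
replication profile is the default for targeted panels.

## Consensus and carrier status

Same-sample, same-type overlapping calls from the two callers contribute
their base-pair intersection to the consensus set; calls without a
partner survive in caller-only sets. CNVRs are connected components of
the interval-overlap graph per pseudochromosome and type, with union-span
coordinates by default (the common core is also available — published
replication coordinates are sometimes narrower than discovery ones, and
the choice between union and core is genuinely open). Loss and gain
regions are kept separate because the association tests are per type.
Carrier membership uses the ≥1-shared-probe rule rather than a reciprocal
overlap fraction (none is prescribed for this design; a configurable
reciprocal-overlap alternative is provided). Provenance per carrier is
"hmm", "segment" or "both".

## Association and selection

For each (CNVR, type), the 2×2 table of carriers/non-carriers ×
case/control is tested with the exact two-sided Fisher test in the
point-probability form: the sum of hypergeometric probabilities, computed
in log-gamma space, of all margin-fixed tables whose point probability is
at most the observed one within relative tolerance 1e−7. This variant
reproduces the published p-values to three significant figures wherever
they are internally consistent. The sample odds ratio `(a·d)/(b·c)` is
reported as the risk indicator (∞ when only cases carry; degenerate
tables flagged); no multiple-testing correction gates anything — a
Bonferroni column is emitted for convenience only. X regions yield
combined, male-only and female-only results; empty strata are flagged
rather than dropped.

Selection for molecular validation defaults to the conjunction
`OR ≥ 2.0 (inclusive) AND case carriers ≥ 2`; the disjunction is
available (`combine="or"`), since the two readings of the published gate
cannot be distinguished from the text. Up to six case carriers are
listed per selected region, dual-caller-supported samples first, sample
id as the deterministic tie-break.

The study's printed per-region counts are bundled as data
(`cnvpanel.tables`) and every statistic is recomputed from them at test
time: 55 of 56 odds ratios match to 2 decimal places (one printed OR is
inconsistent with its own printed counts), 49 p-values match the
two-sided test and 5 match a one-sided test exactly (flagged per row);
2 match no standard Fisher variant and are flagged irreproducible.

## QC

Samples whose total call count across both callers exceeds
median + 5·MAD are excluded before association. With MAD = 0 (near
homogeneous cohorts) the scale falls back to one call, so identical-count
cohorts exclude nobody while gross outliers are still caught; cohorts of
fewer than 10 samples disable the rule with a warning. Laboratory QC,
relatedness and ancestry filters are accepted as a user-supplied
exclusion list.

## Calibration checks and their form

Two null-calibration properties are asserted. The segmenter's
false-split rate on noise must stay within 0.005 at the 0.001 nominal
level (measured above). For association, p-values under permuted labels
are checked with a **one-sided** Kolmogorov–Smirnov test in the
anti-conservative direction: the exact Fisher test is discrete and
conservative, so its p-values are stochastically *larger* than uniform by
construction, and a two-sided KS against U(0,1) would reject a correct
implementation with non-trivial probability purely from discreteness.
The one-sided form asserts exactly the property a valid p-value must
have — P(p ≤ α) ≤ α.

Parameter recovery is scored with the exact conditional-likelihood
confidence interval of the odds ratio (scipy's conditional MLE interval,
an independent code path from the sample-OR computation): on a
1,000-sample cohort with 20 planted regions, the generating OR must fall
inside the exact 95% CI of the estimated table for ≥90% of regions.

## Problem sizes and determinism

The bundled analyses run at desk scale by choice: the study-emulating
cohort uses the 56 published regions at one eighth of the study's sample
count (193 cases / 720 controls), the recovery experiment 1,000 samples ×
20 regions, calibration 1,000 replicates. All randomness flows from a
single seed through `numpy.random.SeedSequence` spawns; a pipeline run
writes a manifest with the seed and a configuration hash, and identical
configurations reproduce every output byte for byte.

## Known limitations

The commercial segmentation tool this caller is modeled on does not
publish its internal algorithm, and the upstream HMM caller's exact
parameters are not recoverable; both callers are archetypes configured
with every published parameter, not replicas.
Family-based joint calling, Baum–Welch training, breakpoint refinement,
mosaicism and burden tests are out of scope. The BAF decoder's p = 1/2
genotype weights lose a little power at extreme allele frequencies.
Duplication recovery by the segmenter alone is weaker than deletion
recovery (the +0.4 CN-3 shift is harder to split at panel marker counts);
the HMM compensates in the union carrier matrix, and the consensus
intersection inherits the HMM's duplications only when the segmenter
agrees.
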