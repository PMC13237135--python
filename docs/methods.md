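# Methods

## The scoring model

`dmskit` scores pooled saturation-mutagenesis (deep mutational scanning)
screens in which a library of programmed variants of one gene — silent,
missense, nonsense and frameshift — competes in a proliferation assay. The
re-expressed wild-type protein suppresses growth, so loss-of-function (LOF)
variants *enrich* over the selection window while functional variants are
depleted. Abundance is read out by sequencing at the start (t = 0) and end
(t = end) of selection across independent replicate screens (in the
motivating application, three patient-derived cell lines).

For variant *v* in replicate *r* the log2 fold-change is

    L2FC(v, r) = log2((n_end + pc) / N_end) − log2((n_0 + pc) / N_0)

with read counts *n*, library sizes *N* and pseudocount *pc* = 1 (the
pseudocount keeps dropout variants finite; library-size normalisation and
the pseudocount are configurable because the upstream convention varies
between count pipelines).

Pooled screens show regional technical artifacts: contiguous codon blocks
whose variants share a systematic L2FC offset (tile-cloning and
amplification effects). The score therefore normalises each variant against
the *local* behaviour of silent mutations, which are assumed
fitness-neutral. For each codon *c* and replicate, all silent variants
within ±2 codons (a five-codon window) are pooled; their mean and sample SD
(n − 1) form the rolling baseline, and

    z(v, r) = (L2FC(v, r) − rolling_mean_silents) / rolling_sd_silents .

The final functional z-score is the arithmetic mean of z over replicates,
with the cross-replicate SD retained as a consistency diagnostic. Variants
with mean z > 2 (strict) are called LOF; under a normal null this
threshold corresponds to a two-sided tail probability of 0.0455.

Two exact invariances follow from the construction and are enforced by
tests: adding a constant to every L2FC of a contiguous codon block leaves
the z-scores of variants whose whole window lies inside the block
unchanged (artifact cancellation), and any global transform
`L2FC → a·L2FC + b` with `a > 0` leaves all z-scores unchanged.

### Windowing details

* Windows truncate at the gene ends; there is no wraparound.
* A silent variant contributes to the baseline of its own codon.
* If a window holds fewer than `min_silent` silent variants (default 2) it
  expands symmetrically one codon at a time until the minimum is reached;
  expansions are logged. This keeps the baseline defined at positions that
  lack nearby synonymous variants.
* A baseline SD below `sd_floor` (default 1e-6, e.g. a window of identical
  values) is replaced by the floor and the affected scores are flagged
  rather than silently inflated.
* Variants with no defined baseline in a replicate score as missing (NaN)
  there; the cross-replicate mean uses the remaining replicates, and
  variants with fewer than `min_replicates` defined replicates are missing
  overall.

### Residue intolerance and substitution summaries

Per-residue intolerance averages the mean z over the observed missense
substitutions at that codon (at most 19; nonsense and frameshift records
are excluded). The intolerance cutoff is mean + 2 SD of the residue
averages over all eligible residues, with a strict `>`. Whether the SD
pool should include only residues with positive averages is genuinely open
in the source analysis; both modes are implemented and the default uses
all residues. The per-substitution summary reports, for each alternative
amino acid, its mean z and the number of distinct residues at which that
substitution exceeds z = 2.

## The synthetic screen generator

The generator is first-class, tested code: it produces screens with known
ground truth so that scoring is validated by parameter recovery rather
than against restricted data.

* **Library.** Per codon: 19 missense records, one nonsense, one
  frameshift, and `silents_per_codon` silent records (default 1, the
  22-records-per-codon scheme; 385 codons give 8470 records, approximating
  a real single-gene saturation library). Codon-replacement libraries
  program several synonymous codons per position, so `silents_per_codon`
  may realistically be raised to 3–5.
* **Selection.** Each variant carries a true effect in log2 enrichment
  units per doubling; over `g` doublings (default 6, the midpoint of the
  emulated 4–8) its expected frequency is multiplied by `2^(g·s)`.
  Defaults plant 5% of missense variants as LOF at s = 1; nonsense and
  frameshift variants are LOF. An optional terminal-escape boundary
  downgrades truncating variants beyond a codon index to partial effect
  (retention 0.5); it defaults to off.
* **Artifacts.** Regional artifacts are additive log2 shifts constant
  within configurable codon blocks, applied to the end-timepoint
  expectation — exactly the structure the rolling baseline is designed to
  cancel, which makes the shift-invariance property exact.
* **Noise.** Start and end counts are multinomial draws at the configured
  depth (default 1e6 reads per sample), so column sums are conserved
  exactly. One RNG stream per replicate is spawned from the master seed;
  a fixed seed gives bit-identical output.

What the generator does *not* emulate: read-level errors, lentiviral
template switching, cloning/tile bias, cell-count bottlenecks, or
overdispersion beyond multinomial sampling. Passing recovery tests
therefore demonstrates correctness of the scoring arithmetic and its
calibration under the stated noise model, not robustness to every real
screen pathology.

### Null calibration and the silent density

With *k* silent observations in a window, the null z-statistic is
`sqrt(1 + 1/k)` times a t variate with k − 1 degrees of freedom, giving a
standard deviation of `sqrt((1 + 1/k)(k − 1)/(k − 3))`: about 1.56 at
k = 5 (one silent per codon) and 1.065 at k = 25. The calibration study
condition therefore uses five silent variants per codon over 200 codons at
depth 1e6 with three replicates, where the per-replicate null z
distribution is standard-normal-like (|mean| < 0.05, |SD − 1| < 0.1) and
the fraction of variants with mean z > 2 stays well below the nominal
0.0455 tail (averaging across R replicates shrinks the null spread by
√R, so the threshold is conservative on null data). With the sparser
default library the t-inflation widens the per-replicate null but the
measured LOF false-call rate remains ~1–2%, still inside the nominal tail.

The recovery study condition (planted LOF at 1 log2/doubling, 6
doublings, depth 1e6, 3 replicates, 200 codons) separates planted from
neutral variants by ~6 log2 units against a baseline noise SD of ~0.15,
and is recovered at sensitivity 1.0 with no silent false calls.

## Predictor concordance

Pathogenicity predictors are thresholded at their published operating
points — CADD scaled PHRED ≥ 20, REVEL ≥ 0.75, AlphaMissense ≥ 0.564, all
non-strict. Concordance with the screen is binary-call agreement in both
directions (damaging/damaging or tolerated/tolerated); a pathogenic-only
mode is available since "concordant prediction" is not otherwise pinned
down. Percentages are reported to one decimal. ClinVar-style pathogenic
fractions are plain ratios reported at display precision.

## Interval algebra and quadrant concordance

Coordinates are BED: 0-based, half-open. `merge` unions intervals whose
same-chromosome gap is ≤ distance (a gap of exactly the distance merges,
the bedtools `-d` convention); it is idempotent. `reproducible` keeps
intervals of one replicate overlapping any interval of the other by ≥ 1 bp
and merges the result. `partition_consensus` labels consensus peaks
gained, then lost, then persistent; the gained-before-lost priority
resolves the rare double overlap and makes the labels an exact partition.
The spike-in factor for exogenous-genome normalisation is
`1 / ((ecoli_reads / human_reads) · 100)`.

Accessibility/expression concordance places each (peak L2FC, gene L2FC)
pair in a sign quadrant (zero L2FCs are excluded and logged; upstream
filters at |L2FC| > 1 make them impossible in practice). The default test
is a two-sided Fisher exact test on the signed 2×2 table (scipy's
hypergeometric implementation, cross-checked in tests against a full
enumeration oracle); an observed-versus-expected mode against an even
split is provided since the source description admits either
construction. Complete concordance yields an infinite odds ratio and a
`degenerate` flag — formal testing is uninformative there.

## MD trajectory statistics

Energies are consumed as per-frame scalars exported from the MD engine;
computing nonbonded energies from force-field parameters is out of scope.
Per replicate the frames are averaged, ΔE = E_mutant − E_WT (positive =
destabilising), and ΔΔE subtracts the ΔE of a neutral control variant
matched by replicate id to cancel simulation-specific drift. Contact
frequency is the fraction of frames in which any heavy-atom pair (element
≠ H) of two residues lies strictly within 4.0 Å; Δf = f_WT − f_mut
(positive = contact lost in the mutant) and ΔΔf subtracts the control
difference. The two families deliberately keep their opposite printed
sign conventions.

Significance uses a two-tailed one-sample t test against zero over
replicates (12 replicates give df = 11) combined with an effect-size
magnitude threshold: 0.5 kcal/mol for van der Waals, 1.0 kcal/mol for
electrostatics, 0.20 for contact-loss maps (whether the 20% filter applies
to ΔΔf or raw Δf is open; the default filters on control-normalised ΔΔf).
Zero spread across replicates is reported as degenerate rather than given
a fake p value. Contact gains (ΔΔf < −0.20) are reported separately from
losses.

## Proteomics

LFQ intensities are log2-transformed; proteins missing in more than three
samples (counted across all samples, following the literal filter
description) are removed, with exactly three missing retained. Missing
values are imputed per sample column from a down-shifted normal with
`loc = mu − 1.8·sigma` and `scale = 0.3·sigma` where mu, sigma are the
column's observed moments — width and downshift as SD multiples, the
Perseus convention; an absolute-log2-units mode is provided because the
verbal description is ambiguous. Observed entries are never altered and
imputation is deterministic given the seed. Group comparison uses the
Student (pooled-variance) two-sample t test — again the Perseus default,
with Welch behind a flag — and the dual criterion |log2FC| > 1.5 and
p < 0.05 without multiple-testing correction.

## Numerical and design conventions

* Strict inequalities at all call thresholds (z > 2, residue cutoff,
  |ΔΔE| > 0.5/1.0, contact loss > 0.20); non-strict ≥ at the predictor
  thresholds, as published.
* Sample SD (ddof = 1) throughout.
* All randomness flows from explicit seeds; replicate streams are spawned
  from a master `SeedSequence`.
* Problem sizes in the test suite and acceptance script (200-codon genes,
  depth 1e6, three replicates, 500-protein matrices, ≤ 500-interval oracle
  sets) are chosen so each stochastic check completes in seconds while
  leaving wide margins to its acceptance band.

## Known limitations

* The multinomial noise model understates real screen dispersion; the
  calibration results bound the *statistical* false-positive rate, not
  biological artifact rates.
* Concordance joins are at the variant-identifier level; mapping
  protein-level scores to nucleotide-level predictor records (one protein
  variant, several SNVs) must be resolved by the caller's choice of
  identifiers.
* The contact kernel is exact but quadratic per frame; it is intended for
  region-scale analyses (tens of residues), not whole-proteome contact
  maps.
* `preprocess`/`impute` assume samples share a common intensity scale;
  no cross-sample normalisation is applied.
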