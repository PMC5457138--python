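# Methods

## Coordinate model

All coordinates are 0-based half-open, matching BED and bedGraph. A
transcript occupies `[min(tss, pa), max(tss, pa))`; the TSS is the first
transcribed base and `pa` is the boundary just past the transcript in the
direction of transcription. On the minus strand the first transcribed
base is `tss − 1` (`tss` is the exclusive span bound), so the
transcript-oriented index `i` maps to `tss + i` (plus) or `tss − 1 − i`
(minus). The pA-site anchor is transcript index `length`, i.e. the first
base after the cleavage site on either strand. This removes the ±1
ambiguity that plagues mixed 1-based/0-based conventions; the strand-flip
invariance tests exercise it genome-wide.

Coverage tracks are strictly strand-specific (one bedGraph per strand);
unstranded input is rejected rather than split heuristically, and
chromosome names must match exactly between files.

## Crosslink-site calling

The null model is a single pooled background mismatch rate p₀ applied to
every U site: p-value = P(K ≥ k | n, p₀) by the exact binomial tail.
This is deliberately the simplest null consistent with a uniform error
process; per-position error profiles and SNP masking are out of scope.
p₀ is estimated as the pooled k/n over U sites outside all annotated
transcripts on the matching strand. Because a clean library can estimate
p₀ = 0 — which would make every single transition "significant" — a
configurable floor (default 10⁻³) is applied inside `call_sites`; the
floor can be disabled for exact-null experiments. The cutoff is a raw
p < α (default 0.005, strict inequality, ties excluded) with minimum
coverage 2; Benjamini–Hochberg correction exists behind a flag but is off
by default, matching the stringent-raw-cutoff convention for this assay.
Type-I error control is verified on ≥10⁵ simulated null sites.

## Occupancy and normalization

Occupancy at a U site is k divided by the denominator coverage at the
same position: RNA-Seq (steady-state RNA concentration) or Pol II
PAR-CLIP (nascent RNA concentration). Sites with denominator below
`min_denominator` (default 1 read) are masked — dropped, not clamped and
never zero-filled — so they are invisible to all downstream averages.
The denominator is used raw, without smoothing. Occupancy uses transition
counts; the processing index deliberately uses read counts instead (see
below). Cross-factor comparability is not attempted via library-size
normalization; factors are compared through the ratio to a background
factor (`classify_enrichment`, thresholds fold > 2 and > 4, strict).

## Metagene computations

Anchored matrices take the signal at offsets −up..down−1 around the TSS,
the pA site, or each intron's 5′ splice site, in transcript orientation;
off-chromosome positions are missing. Length scaling linearly
interpolates each transcript's TSS→pA vector onto the median length
(interpolating across undefined positions from the defined ones, since
occupancy is sparse at U sites). Averaging is column-wise over defined
values; smoothing uses a 61-nt window (30 nt either side) with
*truncated* windows at the edges (the mean over the in-range part), which
keeps the operation mean-preserving and bit-reproducible. Smoothing is
applied after averaging by default; `smooth_first` applies it per row
first, since both orders are legitimate presentation choices. Min–max
rescaling maps the profile to [0, 1]; in joint mode several class
profiles share one min/max so relative amplitudes survive. A constant
profile has no dynamic range and rescales to all zeros with a warning.
Heat maps bin smoothed per-transcript rows (sorted by length, 5′-aligned)
in 20 nt × 10 transcript cells and scale the 97% quantile of cell values
to 1, clipping above; intron profiles are displayed unbinned.

## Processing index

PI = log₂(N_down / max(1, N_up − N_down)) with N_up and N_down the
annotation-wide unweighted means of per-transcript mean read counts over
pA−75..pA−25 and pA+25..pA+75 (inclusive, transcript orientation). The
window bounds span 51 positions; we divide by 51 (a true mean) by
default and provide `literal_50` for the conventional 1/50 constant —
the PI is insensitive to the shared divisor except through the max(1,·)
guard. N_down = 0 yields a −∞ sentinel, never a silent floor; an optional
pseudocount exists for plotting only. Transcripts whose windows leave the
chromosome are skipped with a warning.

## Colocalization

Score(A→B) = log₂(c/b): c is the mean over A's 3000 strongest sites
(occupancy descending, ties broken by genomic coordinate) of B's maximum
*unsmoothed* occupancy within ±20 nt on the same strand; windows where B
is undefined contribute 0; b is the median over all defined B occupancies
(U sites, not the whole genome). Fewer than 3000 sites means all are
used. The asymmetric score matrix is row z-scored (disable with
`normalize=False`), converted to Euclidean distances and clustered with
average linkage; scipy's UPGMA implementation stands behind
`average_linkage`, verified against hand-computed merge sequences.

A caution on null calibration: c is a maximum over ~10 U sites per
window, so any per-site measurement noise biases c above the median and
the null score above 0 by ≈ log₂(1 + 1.5·CV). The calibration checks
therefore use high per-site coverage (binomial CV ≈ 2%), which isolates
the score's behavior from shot noise; on low-coverage data the score
carries a small positive offset that cancels in relative comparisons
between factor pairs.

## ChIP enrichment

SES scaling: sample `n_bins` bins of `bin_len` nt (deterministically from
a seed, with replacement when the genome is small), sort by IP signal,
and take k* = argmax of (cumulative Input fraction − cumulative IP
fraction); the scale is the IP/Input ratio of the sums through k*. Bins
up to k* are background-dominated, so scaled Input matches IP outside
enriched regions and log₂((IP+pc)/(scale·Input+pc)) has median ≈ 0 in
background. This is a from-definition implementation of the SES idea;
fragment-size heuristics of particular ChIP toolchains are not
reproduced. Percent input: the input Ct is reduced by log₂(1/fraction)
cycles to represent 100% of chromatin, then
percent = 100 · 2^(adjusted − Ct_IP).

## Binding model and fitting

The quadratic isotherm is the exact solution of single-site binding when
the labeled ligand concentration L is not negligible relative to K_d
(here L = 8 nM against K_d of tens to hundreds of nM). Its discriminant
(x+L+K)² − 4xL = (x−L)² + K² + 2K(x+L) is positive for all valid inputs;
a clip guards floating-point rounding only. Fitting is bounded
least squares over (K_d, B_max), initialized at B_max = max(y) and K_d =
x at half-max by interpolation, with five log-spaced K_d perturbations
spanning two decades; the best converged start wins and non-convergence
is flagged, never silently estimated. Replicates are pooled into one
joint fit with shared parameters; both parameters are always free.
Standard errors come from the Gauss–Newton covariance at the optimum.
Fits with K_d < L/2 are flagged depletion-limited: in that stoichiometric
regime the curve shape pins down B_max but not K_d.

## Synthetic data

The generator packs mRNAs (lengths 800–5000 nt) and CUTs (350–1500 nt)
on one chromosome with ≥200-nt gaps — so generated mRNAs pass the
standard 800–5000/150-nt filter by construction — including ~30%
divergent mRNA/CUT promoter pairs (TSS distance < 350 nt) and ~25%
single-intron mRNAs (introns 150–650 nt; enriched over the ~4% genomic
frequency so intron-anchored code paths are exercised). Counts are
negative-binomial (dispersion 10) around mean depth 30 per transcribed
base; U sites occupy 25% of transcribed positions uniformly at random
(no sequence model). Transitions are Binomial(n, p₀ + occ·(rate − p₀))
with background p₀ = 0.005 and crosslink rate 0.2.

Two distinct depletion axes reproduce the structure that motivates Pol II
normalization: CUTs are *transcribed* at 0.5× the mRNA rate (affecting
Pol II, factor coverage and raw signal alike) and their RNA is *unstable*
(RNA-Seq additionally ×0.2 on CUT bodies and on the 200-nt post-pA
run-through, which Pol II covers at full depth). A uniform-occupancy
factor then shows raw CUT:mRNA ≈ 0.5, RNA-Seq-normalized ≈ 5 and
Pol II-normalized ≈ 1 (the small upward bias ≈3–9% comes from Jensen's
inequality on 1/denominator at depth 30 and sits inside the 10%
tolerance). ChIP tracks are unstranded (duplicated per strand): Input is
flat background (`chip_background` = 10 per base with the shared
dispersion), IP adds 4× enrichment starting 200 nt into mRNA bodies, which places the ChIP onset visibly downstream of the
PAR-CLIP onset in anchored profiles. Every operation draws from its own
stream seeded by (seed, operation name), so outputs are bitwise
reproducible and adding operations never perturbs existing fixtures.

What the generator does *not* emulate: sequence composition and
mappability, isoform heterogeneity, per-position error structure, SNPs,
crosslinking sequence preferences, or competitor RNA effects. Passing
tests therefore demonstrate the correctness and calibration of the
computations under the stated statistical assumptions, not robustness to
every bias of real libraries.

## Problem sizes

The test suite and the reproduction script run simulations at a few
hundred kilobases with tens to a few hundred transcripts — ≥10⁵ U sites
where a calibration claim needs that many observations (null site-call
rate, colocalization null), 100 Monte-Carlo titrations for K_d recovery.
These sizes make every documented check a matter of seconds while keeping
the statistical tolerances meaningful.

## Known limitations

- Table-level site counts of real libraries depend on the full mismatch
  null of upstream tooling (sequencing error spectra, SNP handling) and
  are not reproducible from the simplified pooled-p₀ null.
- SES scales are approximate relative to specific external
  implementations (fragment-size handling differs).
- The colocalization score's small positive null offset at low coverage
  (see above) is inherent to max-statistics; compare scores, not their
  absolute zero.
- The CLI `coloc` command reads pre-normalized occupancy tables and does
  not re-check that both factors share a normalization scheme.
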