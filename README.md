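# parclip-tools

A Python toolkit for analyzing protein–RNA interaction maps of RNA
polymerase II elongation factors in yeast, built around PAR-CLIP
(photoactivatable-ribonucleoside-enhanced crosslinking and
immunoprecipitation). In PAR-CLIP, 4-thiouracil incorporated into nascent
RNA crosslinks bound proteins to uridines, which sequencing reports as
T-to-C transitions; the per-U-site transition count is the raw binding
signal. This package implements the downstream computational pipeline for
such data — from transition tables to publication-level summaries — plus a
synthetic-data generator so every stage is testable without sequencing
data.

## What it computes

- **Crosslink-site calling** (`parclip.sites`): exact one-sided binomial
  test of the transition count k out of n reads against a pooled
  background mismatch rate p₀ (estimated from non-transcribed U sites),
  with a raw p-value cutoff (default α = 0.005) and a minimum coverage of
  2 reads. Factors are classified by fold enrichment of
  transcript-averaged signal over a background factor (> 2 moderate,
  > 4 high).
- **Occupancy normalization** (`parclip.normalize`): occupancy ∝ k divided
  by the local RNA concentration, estimated from RNA-Seq coverage or from
  Pol II (Rpb1) PAR-CLIP coverage. The Pol II denominator is robust for
  unstable species (CUTs — cryptic unstable transcripts — and post-pA
  regions) that RNA-Seq under-measures.
- **Metagene profiling** (`parclip.metagene`): transcript-anchored
  matrices (TSS, pA site, 5′ splice site), median-length scaling, 61-nt
  sliding-window smoothing, per-factor or joint min–max rescaling, and
  20 nt × 10 transcript heat-map binning with 97%-quantile saturation.
- **Processing index** (`parclip.processing`):
  PI = log₂(N_down / max(1, N_up − N_down)) from mean read counts in the
  51-nt windows pA−75..−25 and pA+25..+75; positive PI means preferential
  binding to uncleaved pre-mRNA.
- **Colocalization** (`parclip.coloc`): for factors A and B,
  score = log₂(c/b) where c is the mean over A's 3000 strongest sites of
  B's maximum occupancy within ±20 nt and b is B's median occupancy; the
  score matrix is clustered by average linkage (UPGMA) on Euclidean
  distances.
- **ChIP enrichment** (`parclip.chip`): signal-extraction-scaling (SES)
  background matching between IP and Input, log₂(IP/Input) tracks, and
  ChIP-qPCR percent-input arithmetic.
- **Binding curves** (`parclip.binding`): the single-site quadratic
  (ligand-depletion) isotherm
  y = B_max · ((x+L+K_d) − √((x+L+K_d)² − 4xL)) / 2L and least-squares
  fitting of K_d,app and B_max to fluorescence-anisotropy titrations.
- **Synthetic data** (`parclip.simulate`): annotations with bidirectional
  mRNA/CUT promoters and introns, U-site transition tables with a uniform
  background error rate, strand-specific coverage tracks (RNA-Seq with
  CUT/post-pA depletion, Pol II with run-through, ChIP IP/Input), and
  noisy titration series — all bitwise-reproducible from a seed.

## Worked example

```python
from parclip import (SimConfig, simulate_annotation, simulate_usite_counts,
                     simulate_coverage, uniform_profile, estimate_error_rate,
                     call_sites, compare_normalizations, processing_index,
                     filter_transcripts)

cfg = SimConfig(seed=1)                       # a Spt5-like uniform binder
layout, ts = simulate_annotation(cfg)
usites = simulate_usite_counts(cfg, layout, ts, uniform_profile(1.0))
p0 = estimate_error_rate(usites, ts)
called = call_sites(usites, p0)
print(f"p0 = {p0:.4f}; called {len(called)} / {len(usites)} sites")

rnaseq = simulate_coverage(cfg, layout, ts, "rnaseq")
polII = simulate_coverage(cfg, layout, ts, "polII")
tbl = compare_normalizations(usites, rnaseq, polII, ts, layout)
r = tbl.pivot(index="scheme", columns="klass", values="mean_occupancy")
print((r["CUT"] / r["mRNA"]).round(2).to_dict())

mrnas = filter_transcripts(ts, 800, 5000, 150, klass="mRNA")
print(f"PI = {processing_index(polII, mrnas).pi:.2f}")
```

prints

```
p0 = 0.0052; called 28676 / 54647 sites
{'polII': 1.06, 'raw': 0.5, 'rnaseq': 5.82}
PI = 4.91
```

The estimated background rate matches the simulated 0.5% mismatch rate.
The CUT:mRNA occupancy ratios show why the denominator matters for a
factor that binds all nascent RNA equally: raw counts under-report CUTs
(they are less transcribed, ratio 0.5), RNA-Seq normalization
over-reports them (unstable CUT RNA deflates the denominator, ratio
5.8), while Pol II normalization recovers the true uniform occupancy
(ratio ≈ 1). The strongly positive processing index reflects a factor
that travels with polymerase past the cleavage site, i.e. binds uncleaved
pre-mRNA.

The same pipeline is scriptable from the shell; see `parclip --help`
(subcommands `simulate`, `filter-transcripts`, `bidir`, `call-sites`,
`normalize`, `metagene`, `pi`, `coloc`, `chip-enrich`, `percent-input`,
`fit-binding`).

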