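# mitoflux

Analysis pipeline for the quantitative core of a multi-omics study of
mitochondrial DNA depletion: how cells respond to losing their respiratory
chain, read out through spent-media exometabolomics, time-course expression
profiling, cis-motif enrichment (the ATF4-driven retrograde response),
stable-isotope tracing of serine/one-carbon metabolism, serial-passage growth
curves, and qPCR mtDNA copy-number assays.

It is written for computational biologists who need these bespoke
calculations as tested, reusable functions rather than one-off scripts:

- **`media_flux`** — uptake/release calls from spent vs base media, with
  evaporation correction `R = R_measured · (1 − f_evap · t/T)`, growth-deficit
  estimation `Δg = Δ mean log₂(extract totals)/t_treat`, an AUC exposure ratio
  `α = ∫₀ᵀ 2^{g(t)·t}dt (treated) / ∫₀ᵀ 2^{g·t}dt (control)`, and the
  piecewise growth adjustment
  `R_adj = 1 + α(R − 1)` for `R > 1`, with two selectable dialects of the
  uptake branch on `0 < R < 1` (`R^α − R(α − 1)` as printed in the source
  protocol, or the continuous `R^α`).
- **`expression`** — three-criterion probeset filtering (SD ≥ 7.5% of mean,
  max ≥ 50, DFT power in coefficients 2–6 ≥ power in 7–12), ranking of genes
  by treated/untreated intensity ratio with normalized ranks `(i − ½)/N`, and
  a pooled late-vs-pre Welch comparison.
- **`motifs`** — exhaustive word-based motif enrichment in the motifADE
  style: all ungapped 6–8-mers plus single-gap 9-mers, strand-canonical
  bidirectional scanning of masked TSS-flanking sequence, two-sided
  Mann-Whitney U on the ranks of motif-bearing genes (exact for small
  groups), Bonferroni adjustment over the motifs tested, Δ-median effect
  sizes, and an exact binomial test for consensus-site (e.g. `TGATGHAAH`)
  enrichment in top-ranked genes.
- **`tracer`** — calibration-curve fitting and isotopologue arithmetic:
  serine synthesis from emerging M+3, net consumption from disappearing M+0,
  the M+1/M+3 scrambling ratio (a methylene-THF readout), all in
  pmol per 10⁶ cells per hour.
- **`growth`** — cumulative log₂ growth curves from serial passages,
  least-squares rate fits over days 2–6, qPCR dilution-ladder calibration
  `Ct = b + m·log₁₀(copies)` with efficiency `10^(−1/m) − 1`, and
  reference-normalized mtDNA/nuclear copy ratios.
- **`synthetic`** — seeded generators for every input above with known
  ground truth, so the whole pipeline is testable end-to-end without any
  external download.

## Worked example

```sh
mitoflux run-all --seed 7 --out runs/demo
```

simulates the full study (2,000 genes, 18 time points, 40 metabolites, three
tracer replicates, two qPCR channels) and runs every stage. Highlights of
what it prints to `runs/demo/`:

- `motif_enrichment.tsv` — the top canonical 6-mers are `ATGCAA` and
  `GCATCA` (p_adj 1.9e-13 and 7.4e-12, Δ median ≈ −0.24 and −0.22): both are
  sub-words of the planted ATF4-like 8-mer `TGATGCAA`, recovered from rank
  data alone. Negative Δ median means motif-bearing genes concentrate at the
  upregulated end.
- `consensus_test.json` — 29 of the 50 top-ranked genes carry the
  `TGATGHAAH` consensus against a 14% background (exact binomial tail
  5.5e-13).
- `media_flux.csv` — per metabolite the evaporation-corrected ratio `R`, the
  growth-adjusted `R_adj` and the released/uptaken call; the day-2 condition
  recovers `Δg ≈ −0.299` doublings/day (truth −0.30) and `α ≈ 0.845`.
- `growth_rates.csv` — control 0.491 ± 0.016 vs depleted 0.194 ± 0.008
  doublings/day (truths 0.5 and 0.2).
- `tracer_rates.csv` — control serine synthesis 1047 ± 67 pmol/10⁶ cells/hr
  (truth 1000), doubled under depletion.
- `relative_copy_number.csv` — ladder-calibrated relative mtDNA levels
  1.0, 0.5, 0.1, 0.01, exactly the generated depletion series.

Every run writes a `manifest.json` with the seed, stage parameters and
SHA-256 checksums; rerunning with the same seed reproduces identical bytes.

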