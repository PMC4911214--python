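# Methods

This note documents the models implemented in `mitoflux`, the choices made
where the underlying protocols left the design open, what the synthetic data
do and do not emulate, and the numerical conventions used throughout.

## Biological setting

Depleting mitochondrial DNA (e.g. with a dominant-negative polymerase-gamma
or ethidium bromide) removes the mtDNA-encoded respiratory-chain subunits.
Cells mount a retrograde response: the stress transcription factor ATF4
activates serine biosynthesis and transsulfuration genes, serine accumulates
in spent media, mitochondrial one-carbon flux (serine → glycine +
methylene-THF → formate) stalls, and growth slows. The pipeline implements
the quantitative steps used to establish that picture: media flux calls
corrected for growth and evaporation, rank-based discovery of the ATF4
cis-motif, tracer readouts of serine synthesis and SHMT2 reversibility, and
growth/copy-number assays.

## Spent-media flux adjustment (`media_flux`)

Abundance ratios R = spent/base confound three things: the flux of interest,
evaporative concentration, and how much cumulative cell exposure the medium
received.

**Evaporation** is modeled linear in time: R is multiplied by
(1 − f_evap·t/T). Only the endpoint loss is measured in practice (12% over a
3-day window is the default), so linearity is the simplest interpolation and
reproduces the measured endpoint exactly at t = T.

**Growth deficit.** Cell-extract totals (summed metabolite abundance per
sample, before geometric-mean normalization) are used as a cell-number
proxy. Δg is the difference of mean log₂ totals divided by the treatment
duration, in doublings/day. The mean of per-sample log totals (rather than
the log of summed totals) keeps single outlier samples from dominating.

**AUC exposure ratio.** With N(t) = 2^{g·t} and the treated culture
switching from g_ctrl to g_ctrl + Δg at T − t_treat,
α = ∫₀ᵀN_treated/∫₀ᵀN_control has a closed form via
∫₀ᵗ2^{gs}ds = (2^{gt} − 1)/(g ln 2) (limit t as g → 0, computed with
`expm1` for stability). α = 1 exactly when Δg = 0. The control growth rate
g_ctrl is an explicit input (default 0.5 doublings/day, typical for
HEK-293-derived lines; obtainable from the growth module) because the
adjustment protocol never states it.

**The adjustment function.** Released metabolites scale linearly:
R_adj = 1 + α(R − 1). Uptaken ones cannot — a linear scale-up could imply
more uptake than the base medium contains — so an ad-hoc branch is applied
on 0 < R < 1. The formula as printed in the source protocol, R^α − R(α−1),
does not satisfy the protocol's own three matching criteria: its left limit
at R → 1⁻ is 2 − α, not 1, for α ≠ 1 (a typesetting loss of a superscript is
plausible). Both readings are therefore implemented as dialects:

- `literal` (default): R^α − R(α−1), kept because it is what is printed; a
  warning is logged when it is used with α ≠ 1.
- `power`: R^α, which satisfies all three criteria — value 1 and slope α at
  R = 1 from both sides, continuity on (0, ∞), and R_adj → 0 as R → 0
  (near-total uptake stays near-total uptake).

Neither dialect is asserted to be the original authors' intent. Calls are
released/uptaken/neutral with a symmetric neutral band of ±0.05 around 1
(no threshold is stated anywhere; 0.05 is small against the ≥20% planted
effects the generator produces).

Whether evaporation correction was applied before or after ratio formation
is not stated in the protocol; it is applied to the ratio here (the two are
equivalent when base media does not evaporate).

## Expression filtering and ranking (`expression`)

Inputs are linear-scale summarized intensities (array normalization itself
is out of scope). Three filters remove uninformative probesets:
(a) SD across samples ≥ 7.5% of the mean (zero-mean probesets fail by
definition), (b) maximum ≥ 50, (c) DFT power in coefficients 2–6 at least
that in coefficients 7–12. Coefficients are 0-based bins of the full complex
DFT, the literal reading of "second through sixth coefficients"; for an
N = 18 real series, bins 10–12 mirror bins 6–8, which slightly weights the
high band — the alternative half-spectrum reading is not used because the
protocol names coefficients, not frequencies. Neither band contains bin 0,
so criterion (c) is invariant to DC shifts. Sample SD (ddof = 1) is used.

Ranking: score = mean(treated days 1–10)/mean(untreated), descending; ties
broken lexicographically by probeset id for determinism; normalized rank
(i − ½)/N. Ratios are computed on linear intensities (whether the original
ranking used log-scale values is unstated; ratio-of-averages on linear scale
is implemented). The pooled day-6 comparison (days 5–7 vs days −1/0) reports
fold changes and Welch's unequal-variance t on log₂ values — the protocol
names no test, and Welch is the safe default for n = 2–3 pools; a
zero-variance comparison is capped at ±10⁶ rather than reported infinite.

## Motif enrichment (`motifs`)

Candidate motifs are every ungapped word of length 6–8 (86,016) plus 9-mers
with a single interior wildcard (7 × 4⁸ = 458,752). In bidirectional mode
each word is collapsed to the lexicographic minimum of itself and its
reverse complement (2,080 canonical 6-mers). Presence is per gene
(≥ 1 match anywhere in the TSS-flanking window), not match counts. A masked
base `N` in the sequence matches nothing — including the gap wildcard — so
repeats and non-conserved positions (conservation is represented abstractly
as pre-applied masking; no alignment is computed) cannot create presence.

The test statistic is a two-sided Mann-Whitney U comparing ranks of genes
with vs without the motif: exact null distribution when the smaller group
has ≤ 8 members, otherwise the normal approximation with continuity
correction (ranks are distinct, so tie corrections are moot). The
approximation agrees with enumeration to < 0.02 for group sizes 3–8; for
sizes 1–2 it is inherently coarser, which is why the exact path always
covers them at the default threshold. Multiplicity adjustment is Bonferroni
over the number of motifs tested. Effect size is
Δ median = (median rank of motif genes − (N+1)/2)/N ∈ [−0.5, 0.5], negative
toward the upregulated end. Reports sort by ascending adjusted p, then
|Δ median| descending, then motif string. Consensus-site enrichment in the
top n genes uses the exact binomial upper tail at an explicit background
rate (the genome-wide figure depends on window and masking and is therefore
an input, default 0.14).

The promoter window half-width is configurable (default 2,000 bp for real
data; the generator uses 500 bp windows).

## Tracer arithmetic (`tracer`)

Short labelings are treated as quasi-linear: amounts that appear or
disappear are divided by cell number and duration, with no isotopic
steady-state model — the readouts are "amount emerged/consumed", not fitted
fluxes. Units: 1 µM in 1 mL is 1 nmol; rates are pmol per 10⁶ cells per
hour, using end-of-labeling cell counts. M+3 serine at t = 0 is assumed
zero (unlabeled start). Net consumption is reported as-is (no correction
for simultaneous release of newly synthesized unlabeled serine); negative
consumption means net release. The M+1/M+3 scrambling ratio cancels any
calibration-slope error common to both isotopologues. Calibration curves
are ordinary least squares of response vs concentration over an external
standard ladder (defaults 0.1–50 µM); inverted concentrations below zero
floor at 0 with a warning. No natural-abundance isotope correction is
applied; outputs carry a flag recording that.

## Growth and copy number (`growth`)

Per-passage folds harvest/seed accumulate into a cumulative log₂ curve
(independent of seeding density). Rates are least-squares slopes over days
2–6 by default, omitting days 0–2 where treatment effects are not fully
developed; each replicate trace is fitted individually, then averaged, with
SEM over replicates. Log base 2 keeps "doublings/day" consistent with the
media-flux α.

qPCR ladders are fitted as Ct vs log₁₀(copies) (≥ 3 points spanning ≥ 2
decades required; non-negative slope rejected as non-amplifying);
efficiency is 10^(−1/slope) − 1. The nuclear channel has no absolute
standard (it is calibrated against bulk DNA), so it is treated as a relative
scale: per-sample target/nuclear ratios are divided by a reference sample's
ratio, which cancels the unknown scale and any affine shift common to both
channels. Replicate wells are combined by mean Ct.

## Synthetic data (`synthetic`)

One root seed derives a named substream per generator (BLAKE2-hashed name
into a `SeedSequence`), so outputs are byte-reproducible and adding a
generator never perturbs another. Defaults mirror the emulated study:
18 time points with two pre-treatment samples (days −1/0, treated days 1–25),
2,000 genes, 500 bp promoters with ~10% of positions masked in 20 bp blocks
(masking drawn before motif insertion, at an unmasked offset, so planted
occurrences survive), responder decile with 60% insertion vs 5% background,
4-fold saturating induction with a 3-day time constant; 40 metabolites over
a 3-day window with 12% evaporation, n = 2 replicates, Δg = −0.3 on a 0.5
doublings/day control rate; tracer truths of 1,000 (synthesis) and 10,000
(consumption) pmol/10⁶ cells/hr, scrambling ratio 0.2 (×3 under depletion,
emulating methylene-THF accumulation), remethylation 1,000-fold slower than
formate-driven serine labeling, 10% flux CV, n = 3; growth 0.5 vs 0.2
doublings/day, 2-day passages, 5% count noise; mtDNA at 1,000 copies/cell
with a 1.0/0.5/0.1/0.01 depletion series and perfect-doubling ladders over
five decades.

Noise models: multiplicative log-normal (unit mean) for abundances,
intensities, counts and per-replicate fluxes; additive Gaussian for Ct.
Tracer noise is applied to the per-replicate flux, with concentrations
following exactly — i.e. replicate-to-replicate flux variability, not
concentration read noise (applying the same CV to the large M+0 pool
instead would inflate consumption-rate noise ~4-fold and would model a
different instrument).

What the generators deliberately do not emulate: chromatograms, spectra or
array images; probe-to-gene mapping ambiguity; correlated noise across
metabolites or time points; natural-abundance isotopologue background;
saturation/background nonlinearity in qPCR; real promoter base composition
(background sequence is i.i.d. uniform). Passing tests therefore show the
estimators are correct under their stated models, not that those models
capture every artifact of real instruments.

## Problem sizes and numerical conventions

The test suite runs reduced studies (60–150 genes, 120–200 bp promoters)
except where a check is about discovery power, which uses the full 2,000 ×
500 bp configuration over 20 seeds (the planted canonical 6-mer must rank
first among all 2,080 in ≥ 95% of seeds). Null calibration uses 2,000
random gene sets of 20 in a list of 200. Exponential integrals use `expm1`;
geometric means are computed in log space; TSV round trips use round-trip
float parsing so written tables re-read bit-exactly.

## Known limitations

- The literal uptake dialect is discontinuous at R = 1 for α ≠ 1; results
  near the neutral boundary depend on the dialect chosen.
- Δg from extract totals assumes the extracted metabolome per cell is
  treatment-invariant in total; a treatment that changes total metabolite
  content per cell biases Δg.
- The Fourier criterion's literal coefficient indexing double-counts
  mirrored bins for real input of length 18; both stated readings change
  only criterion (c) marginal cases.
- Motif presence/absence ignores match multiplicity and position relative
  to the TSS.
- Consumption rates are net; synthesis of unlabeled serine during the
  labeling is not deconvolved.
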