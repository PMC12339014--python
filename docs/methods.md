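# Methods

## Scope and data model

`orbidelta` computes molecular-average δ¹³C values of intact ions measured
on an Orbitrap analyser, using sample–standard bracketing against a working
standard of known composition. The unit of raw data is one scan's
(intensity S, noise N) reading per monitored isotopologue, carried in an
open tab-delimited scan table (metadata lines prefixed `#`, header
`scan  time_min  tic  S_<label>  N_<label> …`). Centroided mzML can be
reduced to this table by m/z-window matching; proprietary vendor files are
out of scope, so any acquisition that can export centroids with noise
figures can feed the pipeline.

## Isotopologue fine structure

Monitored species are defined by expanding the molecular formula (plus the
adduct atom) over an isotope table by per-element multinomial expansion.
Abundances are exact expansion terms normalised over the complete
isotopologue population; the pruning threshold (default 10⁻⁶) only
shortens the returned list. The bundled table carries current IUPAC
standard masses and abundances and is swappable (a file override and an
in-memory API exist) because δ work is exactly the business of deviating
from standard composition. The adduct proton adds one expandable H site;
sodium is monoisotopic. Species that would coincide within one resolution
element are reported separately — at r = 60 000 the four monitored species
of methyl stearate are resolved.

For sodiated methyl stearate the expansion gives M₀ 80.76 %, ¹³C₁ 16.60 %,
¹³C₂ 1.62 %, ¹⁸O₁ 0.33 %. Published validation work on this compound
prints M₀ 80.18 %, ¹³C 5.35 %, ¹³C₂ 0.15 % alongside ¹⁸O 0.33 %; the first
three are mutually inconsistent with any standard isotope table (a 19-carbon
molecule at natural abundance cannot have a ¹³C₁/M₀ ratio of 0.067), while
the ¹⁸O value reproduces exactly. We therefore treat the ¹⁸O figure as the
check and document rather than chase the others.

## Ion counts and ratios

The noise-equivalent-charge relation `count = S/N · c · (Rₙ/r)^a · μ^b`
uses c = 3 and Rₙ = 240 000. The flattened form in which this relation is
usually quoted reads as if a = b = 1, but the protocol literature it derives
from applies square-root transient-averaging scaling; we default to
a = b = ½ and expose both through `IonCountConfig`. The choice is
immaterial for every δ value because the ratio of ion counts cancels all
instrument factors within a scan — it only rescales absolute count and
shot-noise estimates.

Two aggregators are provided: `ratio_of_sums` (Σnum/Σden over retained
scans; default, lower bias at small counts) and `mean_of_ratios`. They
coincide exactly on proportional per-scan counts, and the test suite checks
both against Poisson simulations at known truth.

Outlier rejection is a single pass: a retained scan is dropped when its TIC
or its ratio deviates from the block median by more than k robust standard
deviations (1.4826·MAD), defaults k_tic = 5, k_ratio = 3. The rule is
deliberately conservative — the published pipeline names outlier filtering
without specifying a criterion — and `k = inf` disables it. Scans with a
zero base-peak signal are masked with reason `zero_base_peak` before any
statistics are computed.

## Sessions, bracketing, calibration

Time intervals are half-open `[start, end)`; a boundary scan belongs to the
later block. Dual-inlet sessions default to seven 5-min blocks
(R,S,R,S,R,S,R, 35 min total) with 30 s trimmed from each block edge for
valve transients. Flow-injection sessions default to 15-min injections; the
usable window is the longest contiguous TIC run at ≥ 50 % of the median
top-half TIC (nominally the 10-min plateau), edge-trimmed the same way.

Each sample block's reference ratio is the mean of its two neighbouring
reference blocks (`adjacent_mean`, default) or their time-linear
interpolation (`interpolate`); the session δ is the mean over sample blocks
with SD and a t-based 95 % half-width across them. Replicate sessions are
combined with the same t machinery (`combine_replicates`), and group
comparisons use two-sided Welch's t — the conservative default where the
underlying report gives p-values without naming a test. Degenerate
zero-variance equal-mean groups return p = 1 by convention.

VPDB anchoring uses the exact multiplicative composition
δ_s/V = δ_s/std + δ_std/V + δ_s/std·δ_std/V/1000 and its algebraic inverse;
round trips and chained conversions hold to 10⁻⁹ ‰. A single working
standard is supported by design (no two-anchor scale normalisation).

The bundled validation dataset (`data/fame_standards.tsv`) lists nine
methyl stearate standards with their GC-C-IRMS reference values and
Orbitrap measurements per introduction method and adduct, including the
published residue column. Recomputing residues as measured − expected
reproduces the published values for standards 1–8 of the dual-inlet
[M+Na]⁺ set; standard 9's printed residue (0.7 ‰) is inconsistent with its
own δ columns (which give 1.2 ‰) in every section of the source table, so
the evaluation tool reports both recomputed and as-printed MAEs rather than
forcing agreement.

## Synthetic sessions

The simulator is the package's ground-truth test bed. Per scan and species
the expected ion count is `flux · abundance · drift(t) · plateau(t)`;
realised counts are Poisson draws; counts are inverted through the same
ion-count relation the analysis uses, so disabling Poisson noise recovers
the configured δ to < 10⁻⁶ ‰ (an exact forward–inverse check). The
configured δ is realised by shifting only the ¹³C/¹²C ratio of the isotope
table (anchor 0.0111802 at VPDB); ¹⁸O and ²H stay at reference composition,
as the measurement targets δ¹³C.

The noise column N is an arbitrary-unit scale with log-normal jitter
(σ = 0.1) that cancels from every ratio; given exact count inversion the
scan's S/N is fully determined by the realised count, so no independent
"target S/N" knob exists. Defaults mirror the validated acquisition:
resolution 60 000, two microscans, 1 s scan period, AGC-limited total flux
5×10⁵ ions/scan (the monoisotopic peak then carries ≈4×10⁵ ions), sodiated
methyl stearate, dual-inlet 7-block layout, working standard −27.8 ‰.
Optional features: linear or exponential flux drift common to all species
(cancelled by bracketing; verified to < 0.05 ‰ bias at 1 %/h), trapezoidal
injection plateaus with 1-min ramps, a contaminant centroid 0.5 Da above
the base peak carrying a configured fraction of window intensity, and a
10:1 sodium:proton adduct split for spectra generation.

`predict_precision` gives the counting-statistics expectation
SE_δ ≈ 1000·√2·√(1/C_minor + 1/C_major)/√n_S (C = retained ions per block
per species, n_S = sample blocks; √2 for reference-and-sample noise). It
agrees with the empirical SD over 50 seeded sessions within 25 %, slightly
overestimating because neighbouring sample blocks share reference blocks.

What the simulator does not model: space charge and peak coalescence,
AGC/injection-time feedback, ESI suppression beyond the constant
contaminant fraction, isotope fractionation in the source, and
chromatographic structure (injections produce plateaus, not resolved
peaks). Passing synthetic tests therefore demonstrates correctness of the
estimation pipeline at the shot-noise limit, not robustness to every
instrument systematic.

## Numerical and design choices

- Aggregation dispersion is always the SD of retained per-scan ratios
  (ddof = 1); SE = SD/√n.
- Replicate confidence intervals use the sample SD, so two replicates
  {−1, 1} give a 95 % half-width of t₀.₉₇₅,₁·√2/√2 = 12.706.
- m/z matching tolerance defaults to 5 ppm; monitored-species windows must
  be disjoint at the configured tolerance or extraction refuses to run.
- Missing peaks yield S = 0 with the scan's median noise, flagged — scan
  accounting is preserved and downstream masking decides.
- Contamination screening flags (median or max per-scan fraction ≥ 10 %)
  but never rejects a run automatically.
- Problem sizes in the test suite (session counts, scan counts, simulation
  replicates) are chosen so the full suite and the acceptance script each
  run in seconds while keeping every statistical check at ≥3σ separation
  from its threshold.

## Known limitations

- Bulk molecular-average δ¹³C only: no position-specific or clumped
  (Δ-value) analysis.
- Single-standard calibration; no multi-point normalisation.
- No dead-time, space-charge or AGC-nonlinearity corrections.
- mzML ingestion expects centroided MS1 spectra; noise is taken from a
  non-standard "noise array" when present, else a user-supplied
  spectrum-level fallback is replicated per species and flagged.
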