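# Methods

`seedqnmr` implements an internal-standard ¹H-qNMR workflow for profiling
the seed metabolome of a legume germplasm panel, with horsegram
(*Macrotyloma uniflorum*) as the reference system. This note documents the
models, the constants that matter, and what the synthetic data do and do
not establish.

## The chemical signature

The reference data are a 45-metabolite ¹H signature of horsegram seed
extracts (CD₃OD/D₂O 80:20, 600 MHz, TSP-referenced), shipped as
`data/signature_table.tsv`: 17 amino acids, 7 sugars, 7
flavonoids/polyphenols, 10 organic acids / phenolic acids / sugar alcohols
/ steroids, and 4 vitamins. Each entry records its characteristic shifts
and multiplicities, the single quantification signal, the proton count of
the assigned group behind that signal, and an average molecular weight.
The class tallies (17/7/10/7/4) are enforced as a load-time invariant.

Editorial choices embedded in the table, all flagged in its `source`
column:

* **17th amino acid.** Only 16 amino-acid shifts are printed in the
  source signature; the roster requires 17. The library encodes
  **arginine** at δ 1.68 (m, γ-CH₂) — legume seeds are arginine-rich and
  the shift is the standard reference value — flagged `supplement`.
* **Vitamin shift mapping.** Three shifts are printed for four vitamin
  names. The table maps thiamine → 8.04 (s), riboflavin → 7.31 (s),
  niacin → 8.80 (dd), and assigns tocopherol an imputed chroman-methyl
  singlet at δ 1.24, flagged `inferred`.
* **Composite entries.** "Quercetin conjugates" (δ 6.20/6.21) and
  "apigenin derivatives" (δ 6.51/6.579/6.656/6.8561) are single entries;
  the 7-flavonoid tally forces this reading.
* **Roster boundaries.** Choline and inositol sit in the organic/phenolic/
  steroid/sugar-alcohol class (the class's 10 members reproduce the
  quantified roster of the richest line in the source data); the fatty-acid
  signal at δ 0.625 is a spectral annotation, not one of the 45 quantified
  metabolites, and is omitted.
* **TSP molecular weight** is taken as 196.36 g/mol
  (3-(trimethylsilyl)-1-propanesulfonic acid, free acid). It lives in the
  table, so the sodium-salt or propionate values can be substituted without
  code changes.

Proton counts refer to the assigned group of the quantification signal
(e.g. methionine S-CH₃ → 3, leucine's overlapping methyl doublets → 6,
anomeric sugar protons → 1, choline N(CH₃)₃ → 9, TSP Si(CH₃)₃ → 9). They
are data, not code constants, because the qNMR equation consumes them.

## Quantification model

For an analyte signal with integral `A_X` against the TSP reference
integral `A_ST`:

```
m_X = m_ST · (A_X / A_ST) · (MW_X / MW_ST) · (N_ST / N_X)
```

with `m_ST` = 0.7 mg TSP per 500 mg extracted sample. Concentrations are
reported as mg analyte per g of the extracted sample (m_X / 0.5 g); the
workflow does not distinguish extract mass from seed mass. Only the
quantification shift contributes to the mass; additional shifts corroborate
presence. A metabolite is called *present* when its assigned signal has
detection SNR ≥ 3 — an operational detection limit, chosen because the
source protocol reports presence/absence without stating one.

## Spectral processing

* **Calibration** shifts the axis so the strongest peak within ±0.3 ppm of
  0 (required SNR ≥ 10) sits at exactly 0 ppm. Idempotent.
* **Noise** is estimated as 1.4826 × MAD of the linearly detrended
  9.2–9.5 ppm region, which is signal-free by construction (the assignment
  range ends at 9 ppm).
* **Peak picking** detects local maxima on a matched-filtered copy of the
  trace (Gaussian, σ = 3 axis points ≈ the linewidth) with two criteria:
  prominence ≥ 3 × noise within a ±0.025 ppm window, and height above the
  rolling local median by the same margin. The double criterion keeps the
  false-positive rate on pure noise near zero at SNR 5 while the filter
  roughly doubles detection SNR. Apex, FWHM and area are then measured on
  the raw trace: trapezoidal integration over ±3 estimated FWHM with a
  local linear baseline anchored at the window edges, divided by the
  analytic capture fraction of a truncated, baseline-subtracted Lorentzian
  ((2/π)·atan(2k) − (4k/π)/(1+4k²) ≈ 0.792 at k = 3) so that reported
  areas estimate full integrals. The correction is one multiplicative
  constant; integral ratios — all the qNMR equation uses — never depend
  on it.
* **Bucketing** integrates the piecewise-linear spectrum into 0.04-ppm
  buckets over 0–9 ppm (225 buckets, half-open intervals, last closed);
  bucket sums telescope to the exact total integral. Normalization is by
  total area (pattern analysis) or by the TSP integral (absolute scale);
  TSP-area normalization is the default companion to quantification.
* **Assignment** matches each picked peak to the nearest quantification
  shift within ±0.02 ppm; ambiguous peaks go to the nearest shift and the
  conflict is logged. Areas of all peaks assigned to one shift are summed,
  which collects the split components of multiplets.

## The synthetic-spectrum generator

The simulator inverts the quantification equation: each present metabolite
receives a multiplet at its quantification shift whose total area makes
the equation recover its true mass exactly, plus a TSP reference singlet
(area 100, arbitrary units) at 0 ppm.

* **Lineshape**: Lorentzian, FWHM 0.6 Hz by default — a well-shimmed
  600 MHz small-molecule spectrum. The value also keeps the rendered
  multiplet components baseline-resolved at the fixed coupling constant
  (below): at ≥ 1 Hz the inner components of four-line patterns overlap
  enough to bias local-baseline integration by tens of percent.
* **Multiplets**: one scalar coupling J = 7 Hz for every splitting.
  Doublets/triplets use binomial ratios; `dd` and `m` are rendered as four
  equal sub-peaks spanning 2J — a deterministic stand-in for patterns
  whose true couplings the source does not give.
* **Corroborating signals**: non-quantification shifts are rendered (with
  the same multiplet area) only when ≥ 0.04 ppm — twice the assignment
  tolerance — from every other library signal. Closer duplicates
  (quercetin's 6.21 beside its own 6.20; apigenin's 6.8561 beside caffeic
  acid's 6.88) are skipped so the rendered spectrum stays consistent with
  one-signal-per-metabolite assignment. Rendered secondaries never fall
  within tolerance of any quantification shift.
* **Axis**: 32768 points over −0.5 to 9.5 ppm (≈ 0.18 Hz per point,
  ≥ 130 points per 0.04-ppm bucket).
* **Noise and baseline**: additive Gaussian noise (SD 0.5 intensity units
  against a TSP peak height of ≈ 640) and a random cubic baseline
  (amplitude 2), both drawn from the seed. Identical seed + inputs are
  bit-identical.
* **Panel composition**: each line carries a per-class Bernoulli subset of
  the 45 metabolites (amino acids/sugars 0.85, organics 0.75, flavonoids
  0.70, vitamins 0.60 — expected ≈ 35 of 45 per line, 5th–95th percentile
  ≈ 30–40) at per-class lognormal masses (σ = 0.6; medians 0.45–2.2 mg per
  500 mg) chosen so per-line grand totals land at the tens-of-mg/g scale
  (roughly 60–140 mg/g) reported for diverse legume panels.
* **Two-regime panels** (for chemotype-recovery checks) model two
  abundance chemotypes sharing one roster: a common presence probability
  of 0.9 and a 4-fold class-median enrichment in the second regime, with
  within-regime lognormal σ = 0.25. Distinct rosters are deliberately not
  the discriminating feature; with sparse, class-default rosters the
  presence/absence noise dominates Euclidean distances and average-linkage
  clustering occasionally isolates a metabolite-poor line instead of
  splitting the regimes.

What the simulator does **not** emulate: peak phase and lineshape
distortions, solvent and satellite signals, true J-coupling topologies and
strong-coupling (second-order) effects, ¹³C satellites, chemical-shift
drift with pH/temperature, and genuinely overlapped sugar multiplets that
would require deconvolution. Passing round-trip tests therefore
demonstrates the internal consistency of assignment + integration +
quantification under realistic noise, not instrument-grade accuracy on
real extracts; on real data the assignment tolerance and the one-signal
rule are the vulnerable steps.

## Protein

Crude protein follows micro-Kjeldahl arithmetic: %N = (V_sample −
V_blank) · normality · 1.4007 / sample mass (g), protein % = %N × 6.25.
The constant 1.4007 is the standard milliequivalent mass of nitrogen
scaled to express %N directly; 6.25 is the conventional seed-storage
conversion factor. The pipeline draws synthetic titres per line spanning a
13–40% protein range typical of a diverse panel.

## Multivariate analyses

All ordinations report descending eigenvalues and % variance, mirroring
desktop chemometrics packages (PAST-style output).

* **PCA** on the lines × metabolites mg/g matrix; default is
  covariance-based (center only), since all variables share the mg/g
  scale; autoscaling (correlation-based) is available. Implemented by SVD;
  the sign of each component is fixed so its largest-magnitude loading is
  positive.
* **PCoA** is classical scaling: eigendecomposition of the double-centered
  −½D² matrix. Negative eigenvalues of non-Euclidean dissimilarities are
  reported but excluded from % variance, per standard practice. On
  Euclidean distances the coordinates equal covariance-PCA scores up to
  sign (tested to 1e−8).
* **Correspondence analysis** decomposes the standardized residuals of the
  unit-total table by SVD; total inertia equals χ²/N (cross-checked
  against an independent χ² computation).
* **Hierarchical clustering** is UPGMA (average linkage) on Euclidean
  distances of the same matrix fed to PCA, delegated to SciPy's
  agglomeration. Tree node heights are ultrametric — half the cophenetic
  merge distance — and the Newick export writes branch lengths as
  parent−child height differences.

## Numerical choices and degenerate inputs

Constant matrices and zero-variance columns under autoscaling raise
degenerate-input errors; zero row/column margins are rejected by CA;
asymmetric or negative-diagonal matrices are rejected by PCoA. Eigenvalue
retention uses a relative 1e−12 threshold on singular values; PCoA treats
eigenvalues below 1e−10 × max as zero. Merge ties in clustering resolve by
SciPy's deterministic lowest-index order. All simulation randomness flows
through `numpy.random.default_rng(seed)`; per-line seeds are drawn from
the panel seed so panels are reproducible line-by-line.

## Problem sizes used in the shipped checks

The test suite and the acceptance script simulate panels of 5–20 lines for
recovery statistics (the 20-line default-noise panel yields ≈ 900
presence/absence calls), 20 two-regime panels of 16 lines for chemotype
recovery, and one 96-line panel for panel-level summaries. These sizes
give stable statistics while keeping a full run in seconds on one CPU.

## Known limitations

* Real spectra need phase/baseline correction upstream; the package
  assumes phased, absorptive input.
* One signal per metabolite: genuinely overlapped quantification signals
  (e.g. crowded sugar regions) are assigned to the nearest shift, not
  deconvolved.
* The 45-entry roster, its proton counts and the imputed entries encode
  one reading of an incompletely specified source signature; the TSV is
  the single place to amend it.
* mg/g values are per gram of extracted sample; mapping to per-gram-seed
  requires the extraction yield, which the workflow does not model.
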