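# seedqnmr

Internal-standard ¹H-qNMR metabolite profiling and chemotyping of legume
seed germplasm panels.

Crop germplasm collections are screened for nutritional quality by
measuring which metabolites each accession's seeds contain and in what
amounts. One-dimensional ¹H-NMR of a seed extract does this in a single
experiment: every metabolite with an assignable signal can be identified
from its chemical shift and quantified absolutely against a spiked
internal standard, with no per-compound calibration. `seedqnmr`
implements that workflow end to end for a horsegram
(*Macrotyloma uniflorum*) style panel:

* a packaged 45-metabolite chemical-shift signature (17 amino acids,
  7 sugars, 7 flavonoids/polyphenols, 10 organic acids / phenolic acids /
  sugar alcohols / steroids, 4 vitamins) plus the TSP internal-standard
  record, with shift matching and δ-region classification;
* a forward simulator producing spectra with known ground truth
  (Lorentzian multiplets, TSP reference singlet, noise, baseline), so the
  whole pipeline is testable without instrument data;
* spectral processing: TSP calibration, 0.04-ppm bucketing,
  normalization, SNR-based peak picking with baseline-corrected
  integration;
* absolute quantification by the internal-standard mass equation

  ```
  m_X = m_ST · (A_X / A_ST) · (MW_X / MW_ST) · (N_ST / N_X)
  ```

  (m = mass, A = signal integral, MW = molecular weight, N = number of
  protons behind the integrated signal; ST = the TSP standard, 0.7 mg per
  500 mg sample), reported as mg metabolite per g sample;
* panel profiling: per-line metabolite counts, per-class mg/g totals,
  chemo-marker presence frequencies, and micro-Kjeldahl crude protein
  (%N × 6.25 from titre volumes);
* chemometrics: PCA, principal coordinates analysis, correspondence
  analysis (eigenvalues and % variance reported PAST-style) and UPGMA
  hierarchical clustering with Newick export.

## Worked example

```python
import seedqnmr as sq

library = sq.load_signature_library()
print(f"{len(library)} metabolites:", library.class_tallies())

truth = sq.LineGroundTruth(
    "demo", {"methionine": 1.3, "sucrose_stachyose": 2.4, "rutin": 1.1}
)
spectrum = sq.simulate_spectrum(truth, sq.AcquisitionParams(), seed=1)
profile = sq.quantify_spectrum(spectrum, library=library)
for name, present in profile.present.items():
    if present:
        print(f"{name:20s} {profile.conc_mg_per_g[name]:5.2f} mg/g"
              f"  (true {truth.masses_mg[name] / 0.5:.2f})")

p = sq.KjeldahlParams(V_sample=5.0, V_blank=0.2, normality=0.1,
                      sample_mass_g=0.25)
print(f"crude protein: {sq.kjeldahl_protein(p):.2f} %")
```

prints

```
45 metabolites: {'amino_acid': 17, 'organic_phenolic_steroid_sugar_alcohol': 10, 'sugar': 7, 'flavonoid_polyphenol': 7, 'vitamin': 4}
methionine            2.67 mg/g  (true 2.60)
sucrose_stachyose     4.79 mg/g  (true 4.80)
rutin                 2.19 mg/g  (true 2.20)
crude protein: 16.81 %
```

The simulated line contained three metabolites at known masses (mg per
500 mg sample); quantification recovers their concentrations within a few
percent at the default noise level, and the Kjeldahl titres (5.0 mL
against a 0.2 mL blank, 0.1 N HCl, 250 mg seed) give 16.81% crude
protein.

The same pipeline runs from the shell. A full 96-line simulated panel —
spectra, quantification, summaries, ordinations and tree — takes a few
seconds:

```
$ seedqnmr all --seed 1 --n-lines 96 --out runs/demo
processed 96 lines -> runs/demo (config ff19e25290c08eae)
```

In that run the per-line metabolite counts span 27–40 (mean 35.1), grand
totals span 72–142 mg/g, and crude protein spans 13.1–39.2% —
`runs/demo/` then holds `panel_matrix.csv`, `panel_summary.csv`,
`chemomarkers.csv`, PCA/PCoA/CA tables, a Newick UPGMA tree and a JSON
manifest recording the seed and config hash. Each stage is also
independently invocable (`seedqnmr simulate|process|quantify|summarize|
ordinate|cluster`).

## Layout

```
src/seedqnmr/
  signature.py     45-metabolite signature library (data/signature_table.tsv)
  simulate.py      forward spectrum/panel simulator
  processing.py    calibration, bucketing, normalization, peak picking
  quantify.py      qNMR mass equation and spectrum quantification
  profiling.py     panel summaries, chemo-markers, Kjeldahl protein
  chemometrics.py  PCA / PCoA / CA / UPGMA with Newick export
  pipeline.py      end-to-end orchestration and manifests
  cli.py           `seedqnmr` command-line interface
docs/methods.md    models, constants, design choices, limitations
```
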