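# hemafluor

Blood fluorescence/absorption analysis: synthetic excitation–emission
matrices and full-range patient spectra, spectral preprocessing,
photophysics, erythrocyte biophysics, and three-band clinical diagnostics
cross-validated against complete-blood-count (CBC) records.

## What it does

- **`hemafluor.synthetic`** — generators for every pipeline input: EEMs of
  the endogenous blood fluorophores (tryptophan, NADH, flavins), hemoglobin
  absorption spectra versus oxygenation and glycation, full-range
  200–900 nm two-patient spectra, scattering profiles encoding cell
  diameter, and age-consistent CBC records. All deterministic under a seed.
- **`hemafluor.photophysics`** — fluorescence intensity, Beer–Lambert
  absorbance and its inversion to hemoglobin g/L (molar mass 64 500 g/mol),
  Stokes shift, trapezoidal band integration, penetration depth.
- **`hemafluor.preprocessing`** — maximum-intensity normalization,
  rolling-minimum baseline correction, Gaussian smoothing, prominence-gated
  peak detection with least-squares Gaussian refinement, and EEM peak
  mapping against a fluorophore library.
- **`hemafluor.biophysics`** — erythrocyte shape factor, deformability index
  from scattering integrals and from zeta-potential models (exponential and
  logarithmic, defaults a=1.5, b=−0.05/mV, c=0.5), DLVO interaction energy
  decomposition with aggregation-regime classification, empirical diameter
  calibration R = k·λpeak, internal composition index.
- **`hemafluor.diagnostics`** — integrals of the 400–600 nm
  (hemoglobin/oxyhemoglobin), 600–700 nm (deoxyhemoglobin) and 800–900 nm
  (plasma/water) diagnostic bands, patient-vs-patient comparison with a
  fixed interpretation vocabulary, RBC-count/MCH arithmetic with
  age-binned reference ranges, and CBC concordance flags.
- **`hemafluor.io` / `hemafluor.pipeline` / `hemafluor.cli`** — two-column
  ASCII/CSV spectrum files with `#` metadata headers, CSV EEM matrices,
  CSV/JSON CBC records, YAML configuration, and an end-to-end orchestrator
  that is byte-deterministic given config + seed.

## CLI

```bash
# synthetic inputs
hemafluor simulate eem --source deuterium+halogen --out eem.csv
hemafluor simulate absorption --oxygen 0.9 --glycation 5 --out abs.csv
hemafluor simulate patient --hb 16.4 --oxygen 0.95 --plasma 0.7 --out p1.tsv
hemafluor simulate cbc --age 20 --sex F --out cbc.json
hemafluor simulate scattering --diameter 7.2 --k 0.009 --out scatter.tsv

# preprocessing and analysis
hemafluor preprocess --in p1.tsv --out clean.tsv --baseline-window 50 --smooth-sigma 2
hemafluor analyze bands --in clean.tsv
hemafluor analyze biophysics --zeta-sweep -60:0:1 --model exponential --out di.csv

# two-patient comparison (optionally with a two-record CBC file)
hemafluor compare --a p1.tsv --b p2.tsv --cbc cbc.csv --out report.json

# end-to-end demo on the bundled two-patient fixture
hemafluor report --seed 1 --out results/
```

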