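# eemquant

Quantifying tissue fluorophores — NADH, FAD and protoporphyrin IX (PpIX) —
from a miniaturised multi-spectral fiber-probe that measures weak
autofluorescence and strong diffuse reflectance (DRS) simultaneously.
Concentrations of these biomarkers differ between tumour and healthy brain
tissue, so an instrument that recovers them quantitatively during resection
can help surgeons find tumour margins.  This package provides, for
researchers developing or validating such probes:

* a **forward simulator** of the acquisition: eight pulsed sources
  (300–680 nm), per sample nine illumination states (1 dark + 8 sources),
  each yielding a photodiode DRS value and eight SiPMT channel voltages,
  with realistic attenuation by phantom optical properties, illumination-
  leakage crosstalk, shared per-flash source fluctuation, ambient
  background and detector saturation at ca. 5 V;
* the **inverse pipeline** that recovers concentrations from raw frames:
  ambient (dark-state) subtraction, anti-Stokes channel masking
  (36 informative (source, channel) pairs), DRS normalisation
  `nFL = FL / (Ex · Em)`, and multi-response partial least squares (PLS2,
  NIPALS) with leave-one-out cross-validation and an MSE-elbow rule for
  the component count;
* **characterisation tools**: percentage crosstalk matrix from a
  fluorophore-free standard, excitation-specificity slopes,
  cross-fluorophore prediction independence, and the detector's linear
  input range.

The statistical core: with `X` the n×36 normalised feature matrix and `Y`
the n×3 concentration matrix, NIPALS PLS2 extracts components
`t_a = X w_a` maximising covariance with `Y`; concentrations are predicted
as `Ŷ = (X − x̄) W (PᵀW)⁻¹ Qᵀ + ȳ`, the component count k is the smallest
with `(MSE(k) − MSE(k+1))/MSE(1) < τ` on the LOOCV curve, and recovery is
scored by the per-fluorophore coefficient of determination R² of the LOOCV
predictions.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate the 125-sample three-fluorophore phantom factorial (5 levels each
of NADH, FAD, PpIX at fixed 0.5 % ink / 4 % intralipid) and run the full
recovery:

```python
import eemquant as eq
from eemquant.workflow import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, design=eq.fluorophore_factorial()))
print(report["selected_k"], {k: round(v, 4) for k, v in report["r2"].items()})
```

prints

```
4 {'NADH': 0.9997, 'FAD': 0.9978, 'PpIX': 0.9994}
```

i.e. the elbow rule picks 4 PLS components (three carry the three
concentrations; the fourth absorbs the saturation nonlinearity of the
clipped FAD emission cells), and the LOOCV R² of the recovered
concentrations is ≥ 0.997 for all three fluorophores under the default
noise model.  The same analysis is available as numbered scripts:

```bash
python analysis/01_simulate_phantoms.py   # raw frames for both phantom studies
python analysis/02_build_features.py      # masked, normalised 125 x 36 matrix
python analysis/03_fit_pls.py             # LOOCV MSE curve, elbow, R²
python analysis/04_characterize.py        # crosstalk, independence, absorber bias
```

and as a CLI (`eemquant simulate | process | fit | characterize | run`),
e.g.

```bash
eemquant make-design --which factorial --out design.csv
eemquant run --design design.csv --seed 1 --out-dir out/
```

The characterisation step reports, for example, that the crosstalk from the
340 nm source into the 470 nm channel (the NADH pair) is ~1×10⁻³ % of the
matched channel, that every cross-fluorophore prediction slope on the
factorial is statistically indistinguishable from zero, and that the
normalised FAD response stays linear in concentration at every absorber
level while its slope grows monotonically with the ink fraction (the
residual over-estimation left by the Ex·Em normalisation).

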