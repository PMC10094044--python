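# sdms — stochastic-dynamic mass spectrometric quantification

`sdms` is a toolkit for quantifying and structurally assigning small-molecule
analytes (pharmaceuticals such as paracetamol, atenolol, propranolol, and
benzalkonium-chloride biocides) from scan-level tandem-MS data, aimed at
analysts working with SRM/SIM/CID acquisitions of complex environmental and
biological matrices (mussel-tissue biota, sewage sludge) where classical
peak-area quantification degrades.

Instead of integrating the chromatographic or isotope-shape area, the method
quantifies the *fluctuation* of the per-scan intensity over short spans of
scan time.  The central statistic is the second-order stochastic-dynamic
diffusion parameter

```
D″_SD,tot = Σᵢ D″_SD,i = Σᵢ 2.6388·10⁻¹⁷ × ( ⟨Iᵢ²⟩ − ⟨Iᵢ⟩² )    [cm²·s⁻¹]
```

with the companion first-order form

```
D_SD,i = 1.3194·10⁻¹⁷ × Aᵢ × ( ⟨Iᵢ²⟩ − ⟨Iᵢ⟩² ) / ⟨(Iᵢ − ⟨Iᵢ⟩)²⟩
```

where `Aᵢ` is the amplitude of a sine-squared model
`y₀ + A·sin²(π(x − x_c)/w)` fitted to the squared-deviation trace
`(I − ⟨I⟩)² = f(t)`.  Around this core the package provides:

- **scan_io** — scan-series containers, a fixed CSV dialect
  (`scan,time_min,mz,intensity`), a minimal centroided-mzML reader, and
  m/z-window extraction of per-scan intensity traces;
- **chemometrics** — Shapiro–Wilk / Welch-t / ANOVA grouping of pooled m/z
  measurands into tautomer-resolved subsets, OLS calibration
  `ln[D″_SD] = f(conc.)` and `D″_SD = f(conc.)`, and the classical
  trapezoidal-integration (TIA) comparator with Savitzky–Golay smoothing and
  baseline correction;
- **stochastic_core** — the diffusion parameters above, plus the
  collision-energy intensity relation
  `⟨I_TOT,q⟩ = ½ × (A_I^q/A_D^q) × D″_SD,tot` linking fitted CE-profile
  amplitudes to theoretical mean intensities;
- **qc_diffusion** — the quantum-chemical diffusion parameter
  `D_QC = (Π νᵢ⁰ / Π νᵢˢ) × exp(−ΔH‡/RT)` from supplied ground- and
  transition-state vibrational wavenumbers, and the `D″_SD = f(D_QC)`
  correlation used to assign 3D structures among tautomer candidates;
- **mass_annotation** — elemental-composition arithmetic for adducts
  (`[2M+Na]+`, `[M+NH4]+`, …), neutral losses, and isotope patterns;
- **synth_generator** — seeded simulators of scan series with controlled
  variance structure, used by the test-suite and usable for method studies;
- **cli_app** — the `sdms` command-line entry point
  (`extract`, `dsd`, `group`, `calibrate`, `eq4`, `dqc`, `correlate`,
  `mass`, `simulate`).

## Worked example: calibration of a biocide fragment window

Simulate an SRM calibration series (2–80 ng/mL, 800 scans per level),
extract the m/z 212.209 ± 0.15 window, compute D″_SD over 5-scan spans, and
fit the log-linear calibration model:

```python
from sdms import (CalibrationScenario, MeasurandWindow, SpanSpec, calibrate,
                  d_sd_second, extract_window, simulate_calibration)

scenario = CalibrationScenario(scans_per_level=800, seed=1)
concs, d_tots = [], []
for conc, series in simulate_calibration(scenario).items():
    trace = extract_window(series, MeasurandWindow(212.209, 0.15))
    tot = d_sd_second(trace, SpanSpec(span_length=5))
    concs.append(conc); d_tots.append(tot.d_second_tot)
    print(f"c = {conc:5.1f} ng/mL   D''_SD,tot = {tot.d_second_tot:.4e} cm^2/s")
model = calibrate(concs, d_tots, transform="log_e")
print(f"ln[D''_SD] = {model.intercept:.3f} + {model.slope:.4f} * c   "
      f"|r| = {abs(model.pearson_r):.5f}")
```

Output:

```
c =   2.0 ng/mL   D''_SD,tot = 3.2909e-08 cm^2/s
c =   6.0 ng/mL   D''_SD,tot = 4.4858e-08 cm^2/s
c =  10.0 ng/mL   D''_SD,tot = 6.2135e-08 cm^2/s
c =  20.0 ng/mL   D''_SD,tot = 1.4527e-07 cm^2/s
c =  40.0 ng/mL   D''_SD,tot = 7.0684e-07 cm^2/s
c =  80.0 ng/mL   D''_SD,tot = 1.6078e-05 cm^2/s
ln[D''_SD] = -17.375 + 0.0795 * c   |r| = 0.99993
```

D″_SD,tot grows exponentially with concentration because the generator's
intensity variance follows a log-linear law (planted slope 0.08 per ng/mL);
the log-transformed calibration recovers that slope as 0.0795 with
|r| = 0.99993 — the near-exact linearity regime the method is designed for.

The same operations are available from the shell, e.g.

```sh
sdms mass --formula C8H9NO2 --adduct "[2M+Na]+"     # -> 325.0
sdms dsd run.csv --mz 212.209 --tol 0.15 --spans 5 --out report.json
```

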