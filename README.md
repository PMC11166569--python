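# tensiopipe

Analysis pipeline for force-controlled micropipette (FluidFM-style)
single-cell mechanosensitivity assays, plus the synthetic-data generators
needed to exercise it end-to-end without instrument data.

The package covers five analysis domains and one simulator:

| module | what it does |
| --- | --- |
| `tensiopipe.synthdata` | generators for activation-pressure records, TCSPC histograms, calcium movies, FLIM scenes/kymographs and force-indentation curves |
| `tensiopipe.activation` | cumulative frequencies of critical aspiration pressures, Boltzmann (sigmoid) fits with the composite goodness-of-model error, the p\_C,50(F) line, total activation pressures, the additive stimulus-to-tension model |
| `tensiopipe.flim` | Poisson-MLE bi-exponential reconvolution fitting of TCSPC decays, two-stage per-pixel lifetime imaging, lifetime-to-tension calibration and conversion, area-integrated tension changes, line-scan kymograph analysis |
| `tensiopipe.calcium` | movie preprocessing (5th-percentile baseline, Gaussian low-pass), response/rupture classification, wave-front propagation speed |
| `tensiopipe.mechanics` | contact-point detection and Hertz-type stiffness fitting (sphere or flat punch) |
| `tensiopipe.cgtension` | coarse-grained membrane/cytoskeleton spring-network simulator: pre-tensioned triangulated patch, point anchors, cylindrical-pipette indentation and aspiration, local tension maps and radial confinement profiles |

Units: µm, nN, mbar, ns; membrane tension in mN/m (= nN/µm).

## CLI

All functionality is exposed through the `tensiopipe` entry point:

```bash
# generate synthetic inputs
tensiopipe simulate pressures --out records.csv --seed 1
tensiopipe simulate tcspc --out decay.csv --irf-out irf.csv --seed 1
tensiopipe simulate calcium --out movie.tif --seed 1
tensiopipe simulate hertz --out curve.csv --seed 1

# analysis
tensiopipe fit-activation --records records.csv --out fits.json
tensiopipe flim-fit --histogram decay.csv --irf irf.csv --out fit.json
tensiopipe flim-tension --lifetimes 4.0,4.5,5.0 --tensions 3.3,4.0,4.6 --out cal.json
tensiopipe calcium-speed --movie movie.tif --origin 60,60 --out speed.json
tensiopipe classify --movie movie.tif --out verdict.json
tensiopipe hertz-fit --curve curve.csv --out stiffness.json
tensiopipe cg-sim --force 25 --out run.h5 --profile-out profile.csv
```

Generator and simulator parameters can be supplied as YAML via `--config`.

## Notes

- TCSPC fitting maximizes the Poisson likelihood of the IRF-convolved decay
  and includes a free sub-bin IRF shift, which removes the alignment bias
  of binned reconvolution. Pixels below the photon threshold (default
  1,000; 500 for kymograph lines) are masked rather than fitted.
- The simulator is a deliberately simplified quasi-static spring network:
  no solvent, no thermal noise, cortex and cytoskeleton collapsed into
  anchor springs. It reproduces the qualitative behaviors (aspiration dome,
  monotone load-tension response, anchored-versus-free tension confinement)
  rather than any quantitative particle-model parameterization.
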