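# viscogel

Design of dextran-permeated agarose hydrogels from their viscoelastic
relaxation behaviour and the cell-perceived Deborah number.

The package implements an in-silico design workflow for viscoelastic cell
substrates:

- **mechanics** — an adapted standard-linear-solid (aSLS) model whose dashpot
  viscosity `eta1 + phi*eta2` accounts for dextran in the liquid phase;
  time-dependent modulus and stress response under constant strain rate
  (epsilon-dot method), descriptor identities (`E_eq`, `E_inst`, `tau_rel`)
  and the apparent modulus from the 5 %-strain slope.
- **transport** — network mesh size from the current modulus, hindered
  apparent diffusivity (Stokes–Einstein with mesh screening and Brinkman
  drag), and a 3-D reaction–diffusion solver (method of lines, 7-point
  Laplacian, adaptive integration) with a zero-order solute sink; one-way
  coupled virtual compression tests.
- **fitting** — non-linear least-squares extraction of `E0`, `E1` and the
  lumped `eta_eff` from stress curves, with the `eta1`/`eta2` split
  identified across formulations by regression on the dextran fraction.
- **design** — Deborah number `De = tau_rel / tau_L`, classification of
  formulations against a cell's focal-adhesion sensing window
  (`tau_b`, `tau_L`), and two-step selection of agarose (tissue-stiffness
  match) then dextran (target De regime) concentrations.
- **synthetic** — seeded generators for noisy stress curves, segmented-cell
  measurement tables and initial concentration fields, so the full pipeline
  runs with no external data.
- **cell_metrics** — cell shape index `4*pi*A/P^2` and the YAP
  nuclear/cytosolic ratio from region-measurement tables.

## CLI

```sh
viscogel --version
viscogel simulate --config run.yaml --seed 1 --strain-rate 0.01 --t-end 30 \
         --replicates 5 --out-dir curves/
viscogel fit --curves curves/curve_000.csv --curves curves/curve_001.csv \
         --phi 0.02 --seed 1 --out fit.json
viscogel design --calibration calibration.csv --tissue-low 2000 --tissue-high 6000 \
         --tau-b 1 --tau-l-min 10 --tau-l-max 100 --regime near_one --out report.json
viscogel metrics --table cells.csv --out summary.csv
viscogel pde --config run.yaml --d-app 2e-10 --t-end 500 --out traces.csv
```

File dialects are documented in [FORMATS.md](FORMATS.md).

## Python API sketch

```python
from viscogel import (ASLSParams, LoadingProtocol, stress_response,
                      descriptors_from_params, CellSensingWindow,
                      deborah_number, classify_regime)

gel = ASLSParams(E0=4000, E1=6000, eta1=6000, eta2=0, phi=0)   # tau_rel = 1 s
d = descriptors_from_params(gel)
window = CellSensingWindow(tau_b=1, tau_L_min=10, tau_L_max=100)
print(deborah_number(d.tau_rel, window.tau_L_max))   # 0.01
print(classify_regime(d.tau_rel, window))            # Regime.BELOW_ONE
```

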