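# File dialects

All files are UTF-8 text with `.` as decimal separator. SI units throughout
(Pa, s, m, K) except concentrations, which are in mg/mL.

## Mechanical curve CSV

One file per constant-strain-rate test.

```
time_s,strain,stress_Pa
0.0,0.0,0.0
0.2,0.002,39.7
...
```

- `time_s` strictly increasing, starting at 0.
- `strain` optional; when absent it is reconstructed as `strain_rate * t`
  (the reader then requires an explicit strain rate) and flagged in metadata.
- Written with full `repr` precision; read/write round-trips to 1e-12 relative.

## Calibration table CSV

Either lumped-parameter columns

```
agarose_mg_ml,dextran_mg_ml,E0_Pa,E1_Pa,eta1_Pa_s,eta2_Pa_s,phi
```

or descriptor columns

```
agarose_mg_ml,dextran_mg_ml,E_eq_Pa,E_inst_Pa,tau_rel_s[,E_app_Pa]
```

`(agarose_mg_ml, dextran_mg_ml)` pairs must be unique.

## Cell measurement CSV

```
condition,A,P,A_N,GI_nuc,GI_cyt
```

Areas/perimeter in consistent units (µm² / µm or px² / px); `GI_*` are mean
gray intensities (a.u.).

## Simulation traces CSV

```
time_s,total_mass_mg,D_app_m2s,xi_m
```

`xi_m` is NaN when the run was not coupled to mechanics.

## Run configuration YAML

Sections (all optional, unknown sections/keys rejected):

```yaml
asls:      {E0: 4000, E1: 6000, eta1: 10000, eta2: 0, phi: 0}
transport: {r_h: 1.0e-9, kappa: 1.0e-14, mu: 1.0e-3, T: 298.15,
            p: 0.95, alpha: 0.65, k_r: 0.0, c0: 10.0}
grid:      {extents: [1.0e-3, 1.0e-3, 1.0e-3], n: [21, 21, 21],
            boundary: no-flux, bc_value: 0.0}
fit:       {tol: 1.0e-12, max_iter: 2000, n_starts: 8, seed: 0}
design:    {tau_b: 1, tau_L_min: 10, tau_L_max: 100,
            E_low: 2000, E_high: 6000, label: adipose}
noise:     {kind: multiplicative-gaussian, level: 0.01}
```

## Reports

Design reports and fit results are JSON with sorted keys; see
`viscogel design --help` and `viscogel fit --help`.
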