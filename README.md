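# amha

Three-state social-contagion analysis of drinking behaviour on longitudinal
social networks. Individuals are classified as **A**bstaining, **M**oderate or
**H**eavy drinkers from self-reported weekly drinks (7/14 drinks-per-week
thresholds for women/men); state changes are modelled as a multi-state
SIS-type process with spontaneous rates (α) and per-neighbour social rates
(β), calibrated by weighted least squares on observed wave-to-wave
transitions and exercised by mean-field and stochastic network simulation,
including multiplicative intervention experiments.

Because the original longitudinal study data are access-restricted, the
package ships a first-class synthetic-data generator that produces
FHS-like panels and networks from known ground-truth parameters; every
analysis stage is validated against that ground truth.

## Layout

| module                | contents |
|-----------------------|----------|
| `amha.data_model`     | panel/network types, state classification, study filters, transition extraction, CSV/GraphML I/O |
| `amha.descriptives`   | transition/stability matrices, wave-to-wave state correlation, cutoff sweeps, spatial correlation & clustering, χ² adjacency tests, degree distributions, per-wave summaries |
| `amha.calibration`    | rate estimation: per-neighbour-count aggregation, WLS fits (α = intercept, β = slope), logistic cross-check, significance filtering, per-wave trend diagnostics |
| `amha.mean_field`     | well-mixed ODE system: derivatives, integration, steady states |
| `amha.network_sim`    | discrete-time stochastic dynamics on a static network; forecasting from an observed wave |
| `amha.interventions`  | multiplicative rate scaling, log-grid sweeps of the endemic heavy fraction, strategy comparison |
| `amha.synthetic_data` | seeded scenario generation: assortative network, initial states, evolved panels with exact transition logs |
| `amha.cli`            | `amha` command binding the full pipeline |

## CLI

```bash
# end-to-end demo on synthetic data
amha pipeline --n-persons 2000 --n-waves 5 --seed 7 --out runs/demo

# individual stages
amha synth --n-persons 5000 --n-waves 7 --seed 1 --out runs/s
amha filter --panel runs/s/panel.csv --network runs/s/edges.csv --out runs/f
amha describe --panel runs/f/panel_filtered.csv --network runs/f/edges_filtered.csv --out runs/d
amha calibrate --panel runs/f/panel_filtered.csv --network runs/f/edges_filtered.csv --out runs/c
amha simulate --network runs/f/edges_filtered.csv --states runs/f/panel_filtered.csv \
      --params runs/c/params.json --dt 1 --years 30 --reps 33 --seed 1 --out runs/sim
amha intervene --network runs/f/edges_filtered.csv --states runs/f/panel_filtered.csv \
      --params runs/c/params.json --set social_negative --grid "0.125:3:7(log)" --out runs/int
```

Every stage writes plain CSV/JSON plus a manifest (inputs, seed, version,
output hashes); reruns with the same seed are byte-identical.

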