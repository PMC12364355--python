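# myelopt

Optimal control of a three-compartment bone-marrow model of multiple
myeloma under anti-CD38 (Daratumumab-style) therapy.

The model tracks healthy marrow cells (`A`), drug-susceptible CD38+
myeloma (`P`) and drug-shielded CD38− myeloma (`N`), each as a fraction of
the marrow carrying capacity. It couples logistic space competition,
reversible CD38 expression switching (`delta_P`, `delta_N`), three drug
actions (mortality of `P`, drug-induced P→N switching, off-target
mortality of `A`) and a saturating Michaelis–Menten immune response. On
top of the dynamics sits a Pontryagin-based optimal-control solver
(forward–backward sweep) for linear, quadratic and mixed running costs,
an independent direct-transcription oracle, and experiment drivers that
map the qualitative treatment regimes (bang-bang, bang-singular, gapped,
cyclic, indefinite maintenance) over the parameter space.

## Layout

| module                 | contents |
|------------------------|----------|
| `myelopt.model`        | parameters (default and Null-N presets), rhs, Jacobian, healthy/cancerous equilibria |
| `myelopt.simulate`     | fixed-step RK4 integrator, `TimeGrid`/`Trajectory`/`ControlSignal` containers, steady-state search |
| `myelopt.cost`         | running-cost specs, trapezoidal cost evaluation and the reporting decomposition |
| `myelopt.solver`       | Hamiltonian, adjoint system, pointwise control rules, the forward–backward sweep with PMP diagnostics |
| `myelopt.oracle`       | brute-force validation: piecewise-constant direct transcription, finite-difference gradients |
| `myelopt.experiments`  | scenario driver, control-form classifier, parameter sweeps, cyclic-regime grid, horizon-extension checks |
| `myelopt.cli`          | `myelopt` command-line interface |
| `myelopt._kernels`     | numba-compiled RK4/adjoint hot loops used by the above |

## CLI

```sh
myelopt equilibrium --preset default            # steady states as JSON
myelopt simulate --x0 0,0.1,0 --u 0 --T 100     # forward run -> trajectory.csv
myelopt solve --preset null_n --cost linear --T 200   # one OCP -> solution.csv + summary.json
myelopt sweep --parameter alpha --values 0,0.005,0.01,0.015 --cost linear
myelopt suite                                   # full cyclic-regime grid (slow)
myelopt check --oracle --T 20                   # transcription-oracle gap report
```

Every command writes a `manifest.json` (config echo, versions, wall time)
next to its outputs; floats are printed with 12 significant digits so
reruns diff cleanly. A YAML config can replace flags (`--config run.yaml`;
unknown keys are rejected).

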