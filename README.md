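# borderzone

Spiral- and scroll-wave dynamics in a mathematical model of the
recovering ischaemic border zone: a rectangular network of
Beeler-Reuter-Pumir neonatal myocytes with moving macroscopic gradients
of cell-to-cell coupling and excitability plus frozen per-cell Gaussian
heterogeneity, together with the analysis machinery for the resulting
re-entry: phase-singularity (tip) and scroll-filament detection,
empirical estimation of the specific drift forces from direct
simulations, and the asymptotic drift ODE for pinning/unpinning of
spiral waves near localized inhomogeneities.

## Layout

| module | contents |
| --- | --- |
| `borderzone.brp_kinetics` | single-cell ionic model (Beeler-Reuter with neonatal modifications; excitability parameter alpha scales the inward rectifier), rest-state and automaticity analysis |
| `borderzone.tissue_model` | grid/topology, moving border-zone profiles D(y,t), alpha(y,t), heterogeneity sampling, divergence-form coupling operator |
| `borderzone.simulator` | explicit 2D/3D stepping (Rush-Larsen gates, numba-compiled kernel with a numpy reference path), advection perturbation E dV/dx, stimulation, spiral initiation, CV measurement, checkpointed runs |
| `borderzone.wave_analysis` | two-isoline tip detection, 3D filament extraction, track linking, rotation period and drift velocity from sliding period-averages, regime classification, transition curves, spiral counting |
| `borderzone.force_estimation` | empirical specific forces: electrophoretic/curvature-equivalent b2, alpha-gradient force, disk-inhomogeneity interaction curve |
| `borderzone.drift_ode` | asymptotic centre-motion model: equilibria, tear-off threshold, closed-form + Jacobian stability, adaptive integration, superposition |
| `borderzone.protocols` | end-to-end moving-border protocols (2D/3D), escape curve vs border speed, deliberately arranged pinning experiments |
| `borderzone.synthetic` | analytic spiral/scroll phase-field fixtures for detector tests |

## CLI

```sh
borderzone simulate --config configs/default.yaml --seed 1 --out out/
borderzone tips snapshot.npz --out tips.csv
borderzone filaments snapshot3d.npz
borderzone forces b2 --config configs/default.yaml
borderzone ode equilibria --model model.json
borderzone transition --config configs/default.yaml
borderzone escape --config configs/default.yaml
borderzone pinning --config configs/default.yaml
borderzone fixtures scroll-ring --param nx=41 --param ny=41 --param nz=14 \
    --param x0=20 --param y0=20 --param z0=7 --param ring_radius=8
```

`configs/default.yaml` bundles the calibrated desk-scale
parameter set (cell kinetics, operating points, protocol geometry).

## Known-red acceptance tests

Two acceptance properties are not satisfied by the bundled cell-model
parameterization and their tests fail deliberately rather than being
weakened: (1) the electrophoretic drift response grows, instead of
freezing to zero, as coupling is lowered through the range where rotors
still exist (`TestDiscretenessArrest`), because plane-wave propagation
fails below d_cells ≈ 0.08 and the one-cell-core arrest regime is
unreachable; and (2) the moving-border sweep never leaves a persistent
spiral behind at any border speed at desk scale
(`TestEscapeCurve::test_interior_maximum_positive`), because a broken
wavelet in this weakly excitable medium retracts rather than curling
into a rotor.  All other acceptance tests pass.

## Notes on units

Voltages are mV, times ms. Space is handled in *cell units* throughout
the analysis (one cell = `h` mm, default 0.025 mm); diffusivity appears
as `d_cells = D/h^2` (1/ms) so results transfer across `h`. The
advection magnitude E is mm/ms.
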