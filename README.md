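# guvflux

Quantification of passive proton permeation across single giant
unilamellar vesicles (GUVs) from confocal time-lapse recordings — and a
forward simulator of the whole assay for validating the analysis with
known ground truth.

## The problem

In the single-vesicle acid-addition assay, pH-dye (pyranine/HPTS) loaded
GUVs rest in an observation chamber while a small volume of acid is
pipetted into the surrounding buffer. The external pH falls gradually;
protons leak across each vesicle's bilayer, and the lumenal dye reports
the internal pH frame by frame. Because both sides of the membrane are
read out simultaneously, the assay yields, per vesicle:

* the inward proton flux density
  `J = (d[H+]T_in/dt) · (V/A)` with `V/A = r/3`, where the cumulative
  permeated-proton concentration `[H+]T_in` is reconstructed from the
  lumenal pH fall and the buffer capacity β(pH);
* the flux profile `J(Δ[H+])` against the gradient
  `Δ[H+] = [H+]_o − [H+]_i`;
* the permeability coefficient `P_H+` from the linear (small-gradient)
  regime, `J = P_H+ · Δ[H+]`;
* the transmembrane potential Δψ(t) by numerically inverting the
  Goldman–Hodgkin–Katz flux equation
  `J = P·u·([H+]_o − [H+]_i·e^u)/(e^u − 1)`, `u = ΔψF/RT`;
* the proton motive force `pmf = Δψ − 2.303 (RT/F)(pH_i − pH_o)`;
* for weak acids, the split of proton delivery into the ionic (H+) and
  neutral (HA) routes from the difference of fitted slopes,
  `P_HA = P_total − P_H+`.

For strong acids (HCl, HNO3) protons cross as H+ and charge the
membrane, so the flux saturates as Δψ builds; for a weak acid (formic
acid) most protons ride across as the neutral species and the potential
stays small.

## Package layout

| module | contents |
| --- | --- |
| `guvflux.simulate` | forward model: external acidification course, GHK ion fluxes, capacitive Δψ buildup, weak-acid speciation, buffered lumen (numba-compiled fixed-step integrator) |
| `guvflux.render` | synthetic two-channel (membrane ring + lumen) TIFF time-lapse rendering with seeded Poisson/read noise |
| `guvflux.calibration` | pyranine intensity ↔ pH sigmoid with resolvable-window flagging; analytic buffer capacity β(pH) with a tabulated-curve hook |
| `guvflux.imaging` | Hough-circle vesicle detection, nearest-neighbour tracking with stable IDs, lumen/background intensity measurement |
| `guvflux.fluxes` | proton accounting, Savitzky–Golay smoothing, flux computation, flux profiles, linear-regime permeability fits |
| `guvflux.electrochem` | GHK flux and its root-finding inversion, pmf, weak-acid decomposition, small physical utilities |
| `guvflux.model` | `ProtonPermeationModel` / `ProtonPermeationResults` — the fitting interface tying it together |
| `guvflux.pipeline`, `guvflux.cli` | YAML-configured, seeded pipeline stages and the `guvflux` command-line tool |

## Worked example

Simulate three vesicles under the default HCl scenario (10 mM HEPES
buffer at pH 7.6 acidified to 6.9, P_H+ = 1.9×10⁻³ cm/s) and run the
trace-level analysis:

```python
from guvflux import SimulationConfig, simulate_acidification
from guvflux.model import ProtonPermeationModel
from guvflux.simulate import make_cohort

cohort = make_cohort(3, SimulationConfig(), seed=42)
traces = [simulate_acidification(c) for c in cohort]
model = ProtonPermeationModel.from_traces(traces, cohort[0].buffer)
results = model.fit()
print(results.summary())
```

```
Proton permeation linear-regime fit
===================================
vesicles:            3
pooled points:       12
P (pooled):          0.00183 cm/s
SE (pooled):         3.3e-05 cm/s
R^2 (through origin):   0.9964
P (median vesicle):  0.00183 cm/s
P (mean vesicle):    0.00183 cm/s
gates: |dpH_i| < 0.1/frame, delta_H <= 0.1 x max

Per-vesicle estimates (cm/s)
----------------------------
  vesicle   0:  P = 0.00183  (se 6.4e-05, n=4)
  vesicle   1:  P = 0.00183  (se 6.4e-05, n=4)
  vesicle   2:  P = 0.00183  (se 6.4e-05, n=4)
```

The fitted `P` of 1.83×10⁻³ cm/s recovers the simulator's ground truth
of 1.9×10⁻³ cm/s to ~4% — the residual bias is the flux saturation that
the small-gradient gate cannot remove entirely. Inverting the GHK
equation along each profile gives the potential buildup and pmf:

```python
pots = results.invert_potential()
print(f"max dpsi (vesicle 0): {max(pots[0].dpsi)*1e3:.1f} mV")
print(f"max mean pmf: {results.max_mean_pmf()*1e3:.2f} mV")
```

```
max dpsi (vesicle 0): 15.7 mV
max mean pmf: -2.52 mV
```

i.e. the membrane polarizes to ~16 mV while the chemical gradient term
overtakes the electrical one, pulling the net pmf negative.

The same analysis runs from images alone: render the cohort with
`guvflux.render`, measure it with `guvflux.imaging.measure_stack`, and
construct the model with `ProtonPermeationModel.from_tracks`. From a
shell:

```sh
guvflux simulate --seed 1 --outdir out            # traces.csv (+ stack.tif with --mode image)
guvflux analyze  --indir out --outdir out/ana     # profiles, P fits, dpsi/pmf tables
guvflux recover  --seed 1 --scenario strong       # parameter-recovery harness
```

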