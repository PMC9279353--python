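# Methods

This note documents the forward model, the analysis procedure, the
numerical choices, and what the synthetic-data tests do and do not
establish about real recordings.

## Forward model of the assay

One vesicle of radius `r` (area-to-volume ratio `A/V = 3/r`) sits in a
buffered solution whose pH follows a delayed exponential acidification
course after acid addition:

```
pH_o(t) = pH_final + (pH_initial − pH_final) · exp(−(t − t_arr)/τ),  t ≥ t_arr
```

The course emulates the diffusive spread of a pipetted acid bolus; its
parameters (defaults 7.6 → 6.9, arrival 30 s, τ = 100 s) are not a
measured property but are chosen to keep the background pH inside the
dye's resolvable window for the whole run. The amount of acid that must
have been added to reach a given external pH follows from the charge
balance of the buffer (`acid_to_titrate`); for a weak acid the demand is
divided by the dissociated fraction. That amount fixes the external
concentrations of the conjugate anion and, for weak acids, of the
neutral species via Henderson–Hasselbalch speciation (protonation
equilibria are treated as instantaneous on both faces).

Protons and counterions cross the membrane by electrodiffusion with the
GHK flux density (inward positive, Δψ = ψ_in − ψ_out, `u = ΔψF/RT`):

```
J = P · u · (C_o − C_i e^u)/(e^u − 1)        (cation; u → −u for an anion)
```

which reduces to Fick's law `J = P (C_o − C_i)` at Δψ = 0 and is
strictly decreasing in Δψ, the property that makes root-finding
inversion unique. The neutral weak-acid route is plain diffusion,
`J_HA = P_HA ([HA]_o − [HA]_i)`.

The membrane is a capacitor: net charge flux polarizes it,

```
dΔψ/dt = F (J_H+ − J_anion) / C_spec,       C_spec = 1 μF/cm² (textbook bilayer value)
```

and the lumen is buffered:

```
d[H+]T_in/dt = (J_H+ + J_HA) · 3/r,   dpH_i/dt = −(d[H+]T_in/dt)/β(pH_i).
```

The buffer capacity is the analytic monoprotic form

```
β(pH) = ln10 · ( [H+] + K_w/[H+] + Σ_i C_i·Ka_i·[H+]/(Ka_i+[H+])² )
```

with all concentrations in mol/cm³ (so `[H+] = 10^−pH/1000`); an
empirically tabulated β(pH) curve (two-column CSV) can replace it. The
default buffer is 10 mM HEPES, pKa 7.5, at 294.15 K; the ~10 μM of
pyranine contributes negligibly and is ignored. K_w follows a van't
Hoff extrapolation from 25 °C.

State per vesicle: lumen pH, Δψ, the internal pool of the acid's
conjugate species, and the cumulative permeated-proton concentration.
`clamp_potential=True` freezes Δψ ≡ 0 (the Fick limit), which serves as
a ground-truth twin for saturation comparisons and as the linear-regime
reference scenario.

### Counterion permeability — the key free parameter

The counterion permeability P_anion controls the assay's phenomenology,
because buffering amplifies the anion gradient roughly 10⁵-fold over
the proton gradient (most added acid is absorbed by the buffer,
releasing one anion per absorbed proton). Three regimes exist:

* P_anion ≈ 0: the membrane charges to the proton Nernst potential
  within seconds and the flux collapses — no linear regime;
* P_anion ≳ 10⁻⁶ cm/s: anion conductance dominates, Δψ swings negative
  and the proton flux is *enhanced* severalfold over Fick — no
  saturation;
* P_anion ≈ P_H+·ln10·[H+]₀/β(pH₀) ≈ 2×10⁻⁸ cm/s for the default
  parameters: anion and proton conductances match at the baseline pH.
  Early fluxes are Fick-like; as the exterior acidifies, [H+] grows
  faster than the anion pool and the proton route becomes
  conductance-limited — a Fick-like linear regime at small Δ[H+] with
  progressive saturation and a positive Δψ of tens of mV at large
  gradients.

Only the third regime reproduces the behaviour the assay is built
around, so 2×10⁻⁸ cm/s is the package default for Cl⁻, NO₃⁻ and
formate alike (the two inorganic anions are treated as equivalent; the
formate value is then ~4 orders of magnitude below the neutral-form
permeability, consistent with the usual ion/neutral contrast).

### Integrator

Fixed-step explicit Euler, default dt = 1 ms, compiled with numba. The
fastest system timescale is the capacitive charging time
`τ_ψ = C_spec·RT/(F²·ΣP·C) ≈ 0.5–5 s` at the default parameters, so the
step has a ~500× stability margin; halving dt changes the final lumen
pH by far less than 10⁻⁴ (tested). Recorded fluxes are evaluated at the
recorded state, so per-sample identities (Fick limit under clamping,
β-bookkeeping) hold to round-off. A transparent fixed-step scheme was
preferred over an adaptive integrator because every recorded step is
then testable against the model's algebra.

## Image rendering

Channel 0 is a membrane ring (annulus of configurable thickness at the
vesicle equator), channel 1 the lumen disc filled with the calibration
intensity of the lumen pH over a background at the intensity of the
external pH. Noise is per-pixel Poisson (with a photons-per-intensity
scale) plus Gaussian read noise, drawn from an explicit seed; unseeded
noisy renders are an error, and fixed seeds render bit-identically.
There is no PSF, z-sectioning, bleaching, vesicle deformation or
osmotic response — so passing image-level tests demonstrates the
correctness of the measurement chain, not robustness to real optics.

## Calibration

Pyranine is modelled as a single-site titration sigmoid
`I = I_min + (I_max − I_min)/(1 + 10^(pKa_app − pH))` with apparent pKa
7.3. Inversion is algebraic; readings outside the resolvable window
(6.0 < pH < 7.6) are returned with `resolvable=False` rather than
silently, and intensities at or beyond the plateaus raise an error
naming the quench bound. The defaults are placeholders for a measured
curve — a tabulated calibration can be supplied instead. In profile
construction the *hard* cut is the quench bound: readings marginally
above 7.6 (noise around the baseline, where every run starts) still
invert through the sigmoid and are retained; without this the first
frames of every noisy run would be discarded.

## Image analysis

Detection: Canny edges followed by a circular Hough transform;
candidate peaks are suppressed when two centres fall within the smaller
of their radii (higher accumulator score wins). The Hough peak sits on
an *edge* of the membrane ring (inner or outer, depending on noise,
±2 px), so the radius is refined to the rounded centre-of-mass of the
radial mean-intensity profile around the detected centre; the residual
bias is ≤ 0.5 px (< 5% over the working range, tested). Sub-pixel
centre refinement is not attempted.

Tracking: greedy linking in ascending centroid-distance order, gated by
a maximum displacement (default 10 px) and a maximum frame gap
(default 1); leftover detections open new, never-reused IDs. Detections
are canonically sorted first, so the result is independent of input
ordering within a frame.

Measurement: lumen intensity is the mean over the concentric disc of
radius 0.7·r (the shrink excludes the ring and rim); the background is
the mean over all pixels outside every disc dilated 1.2×.

## Flux analysis

`[H+]T_in` accumulates `β(pH̄)·(pH_i(t) − pH_i(t+1))` per frame with β
at the interval-midpoint pH, starting at zero. The series is smoothed
with a Savitzky–Golay filter — default window 9 frames, order 2 — and
differentiated (central differences, second-order edges) to give
`J = d[H+]T_in/dt · r/3`. The window was set by the bias/variance
trade-off at the arrival edge: the flux has a derivative kink at proton
arrival, and wider windows (15+) push the edge-frame flux bias high
enough to distort the GHK-inverted potential there by > 1 mV, while
window 9 keeps the worst-case inversion error below 0.5 mV on noiseless
traces and still suppresses photon noise usefully.

Profiles are trimmed to the frames after proton arrival (first frame
where pH_o drops > 0.02 below its baseline) and before either series
hits the quench bound.

The permeability fit is ordinary least squares *through the origin* of
J on Δ[H+] (zero flux at zero gradient is physically forced), pooled
across profiles ("concatenate fit"), restricted to the linear regime by
two gates: per-frame |ΔpH_i| < 0.1 (the classical rule — vacuous
at these frame rates, where per-frame changes are ~10⁻⁴, but kept for
data where it bites) and Δ[H+] ≤ 0.1 × the profile's maximum gradient,
which is the operative small-gradient restriction here. The reported
standard error is the usual through-origin OLS slope SE.

## Potential inversion and pmf

Δψ(t) is found by bracketed root finding (Brent, ±300 mV bracket,
10⁻⁹ V tolerance) of the GHK equation at each retained frame, using
either each vesicle's fitted P (default) or a supplied coefficient;
frames whose flux leaves the attainable range come back as NaN rather
than failing the trace. pmf follows as
`Δψ − 2.303(RT/F)(pH_i − pH_o)`; the cohort statistic reported is the
maximum over time of the per-frame cohort mean.

Near u = 0 the GHK expression switches to its second-order series below
|u| = 10⁻⁶ (direct and series forms agree to ~10⁻¹² there), and the
direct branch uses `expm1` for accuracy at small u.

## Weak-acid decomposition

With a strong-acid cohort measuring the pure H⁺ route, the neutral
contribution of a weak acid is the slope difference
`P_HA = P_total − P_H+`, with ratio `P_HA/P_H+` and ionic fraction
`P_H+/P_total`. These "effective" permeabilities are referenced to the
proton gradient. The simulator's intrinsic neutral-form permeability
(acting on Δ[HA]) maps to the effective one through the titration
chemistry: near the baseline `[HA]_o ≈ κ·Δ[H+]` with tangent
`κ = β(pH)/(ln10·Ka)`; because the added acid and [H+]_o grow together,
the relation is superlinear and a finite fitting window senses a larger
secant. `gate_averaged_kappa` evaluates that secant in closed form from
the external course, weighted exactly as the regression weights its
points; the recovery harness uses it to construct cohorts whose
ground-truth effective ratio is the nominal 4.

## Recovery harnesses (study conditions)

* **Strong acid, trace level**: 10 vesicles, radii uniform 9–13 μm,
  P_H+ = 1.9×10⁻³ cm/s, default course, 5 s frames, 360 s. Median
  per-vesicle P error ~4%; GHK inversion with the true P tracks the
  simulated Δψ within 0.43 mV worst-case.
* **Weak acid**: two 5-vesicle cohorts (HCl and formic acid at
  effective ratio 4); the decomposition recovers the ratio to ~3% and
  the ionic fraction to ±0.005.
* **Image level**: 5 vesicles, 256×256 px at 0.5 μm/px, 100 frames at
  3 s, default noise, simulated in the potential-clamped (Fick) mode
  with a deeper course (7.6 → 6.3). Clamping makes the whole profile
  linear so the fit may use the full gradient range — necessary because
  at photon-realistic noise the small-gradient window's per-point flux
  SNR is below 1, and deliberate: the potential physics is validated at
  trace level, while this scenario isolates the imaging chain. All five
  tracks are re-detected over every frame and P is recovered to 0.5–3%.

Problem sizes (cohort sizes, frame counts, 1 ms steps) were chosen so
each harness represents the assay faithfully while completing in
seconds.

## Known limitations

* The electrical model has a single counterion; Na⁺/K⁺ leak and surface
  potentials of charged lipids are not modelled, and C_spec is fixed.
* The pmf of the default strong-acid scenario peaks near zero and turns
  negative as ΔpH outruns Δψ; scenarios with larger positive pmf
  require deeper, faster acidification than the default course.
* Radii are integer pixels × pixel size; vesicles touching or leaving
  the frame, multilamellar vesicles and z-drift are out of scope.
* The calibration sigmoid is a stand-in for a measured curve; absolute
  pH accuracy of real data depends on supplying one.
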