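# Methods

## Scope and model overview

`pvlkit` quantifies the thrombogenic potential of paravalvular leak (PVL)
flows with the device-thrombogenicity-emulation (DTE) chain: Lagrangian
platelet trajectories → scalar stress per sample → stress accumulation
(SA) per platelet → probability-density "footprint" of a cohort, split by
whether a platelet ever entered the leak channels. Patient-specific
computational fluid dynamics is out of scope; the package instead ships a
controllable synthetic flow model whose role is to generate trajectory
cohorts with the statistical structure the analysis stages assume, at
desk scale, with closed-form oracles available for every step.

## Hydrodynamic metrics

Phases are segmented on the pressure gradient (ventricular minus aortic),
not on flow: systole is the maximal set of intervals with ΔP > 0, with
zero crossings located by linear interpolation between samples and a
20 ms minimum phase duration to suppress chatter. The orifice-area
formula uses the pulse-duplicator unit convention (mL/s, mmHg, g/cm³ →
cm², constant 51.6); EROA applies the identical formula to the diastolic
reverse flow averaged over the whole diastolic interval, mirroring the
symmetric construction of the forward metric. Integrals are composite
trapezoids on the native sampling grid; mismatched grids are linearly
interpolated.

The closing/leak split of the diastolic reverse volume has no standard
definition, so the package defines one and exposes it as configuration:
the leak plateau level is the median reverse-flow magnitude over the
final two-thirds of diastole; the closing transient runs from diastole
onset until the reverse-flow magnitude — having first risen above
1.25 × plateau — falls back to within 25 % of the plateau. Reverse flow
that never leaves the plateau band is pure leak (closing = 0). The 25 %
band is the `plateau_frac` parameter. Cardiac output is reported in two
conventions (net volume per beat and total forward volume per beat);
net is the default because measurement practice differs between rigs.

## Stress kernel

The scalar stress is the von-Mises-type second-invariant reduction of
the symmetric stress tensor, divided by √3 so that pure shear τ maps to
σ = τ. It is implemented in normal-stress-difference form,
σ = √[((σxx−σyy)² + (σyy−σzz)² + (σzz−σxx)²)/6 + τxy² + τyz² + τzx²],
which is algebraically identical to the usual expansion but returns
exactly zero for hydrostatic states instead of a floating-point
cancellation residue. Because the reduction annihilates hydrostatic
contributions, the synthetic model supplies only the deviatoric viscous
stress µ(∇u + ∇uᵀ); whether a flow solver exports total or viscous
stresses is immaterial to SA.

SA uses the left-rectangle rule Σ σᵢ·Δtᵢ on the export grid — matching
the discrete definition used in Lagrangian blood-damage post-processing —
with per-interval Δt so nonuniform export cadences integrate correctly;
a trapezoid variant is available by flag for comparison, never silently.
SA accumulates over a platelet's whole tracked life and is not reset at
region boundaries; per-residence SA is reported separately on each entry
record. The activation threshold is the Hellums criterion, stored as
35 dyne·s/cm² and converted (0.1 Pa per dyne/cm²) to 3.5 Pa·s.

## Synthetic flow generator

The generator is piecewise-analytic rather than a numerical solve: its
defaults encode the study conditions (70 BPM; systolic gradient averages
+25 to +48 mmHg over a 210 ms systole; diastolic averages −82 to
−88 mmHg; 3 µm neutrally buoyant platelets seeded on a 200 µm grid
across the LVOT cross-section every 0.5 ms through systole, i.e. 7845
grid points × 420 injections at full scale; blood analog µ = 3.5 mPa·s,
ρ = 1120 kg/m³).

*Bulk flow.* A two-branch lumped circuit: Q(t) = ΔP/R_valve(t) + ΔP/R_leak.
The valve branch re-expresses the time-switched Darcy porosity leaflet
(inverse permeability 0 open, ≥10¹⁰ 1/m² closed) as resistances —
R_closed = 10⁴ mmHg/(mL/s) keeps fully-closed transvalvular leakage
around 0.006 mL/beat, comfortably below the 0.1 mL/beat negligibility
bound. Conductance switches over a 10 ms smoothstep ramp (numerical
smoothness; its overlap with the falling gradient produces a physical
closing transient), topped up by an explicit exponential closing pulse
(τ = 15 ms) so presets can hit a target closing volume exactly.
Calibration is closed-form: R_leak scales linearly to the target leak
volume; the open conductance solves a quadratic so the systolic RMS of
the summed branches matches the RMS implied by the target EOA (presets
therefore reproduce their EOA targets to <1 %).

*Velocity field.* Cylindrical LVOT (radius 10 mm) below the valve plane
and an aortic segment above the sinus carry Poiseuille profiles scaled
to the instantaneous total flux; the open-valve orifice (radius 7 mm)
carries a Poiseuille jet scaled to the valve branch; each leak channel is
a curved slab at the lumen wall (azimuthal arc width w, radial gap h,
axial length 20 mm) carrying a plane-Poiseuille profile across the gap,
scaled to its area share of the leak branch. Channel areas in the
presets are chosen so the peak diastolic centerline velocity sits in the
jet regime of narrowed leak paths (~2.5–4 m/s), which puts the channel
Reynolds number (hydraulic diameter ~1 mm) at ≈1200 at peak — inside
the laminar regime the model assumes; `reynolds_check` asserts this for
any configuration. Gradients are analytic in all Poiseuille regions and
the axial profiles are divergence-free.

The sinus annulus between orifice and wall is modeled as quasi-stagnant
secondary flow, the one deliberately phenomenological ingredient: a
systolic washout drift toward the aorta (fraction `wash_frac = 0.08` of
the mean jet speed, giving roughly one-cycle residence) and a diastolic
entrainment drift toward the nearest channel centerline whose magnitude
decays exponentially with distance (`feed_frac = 0.10` of the mean
channel speed, e-folding length one channel width). These two fractions
were fixed once so that the reduced anatomy-A cohort lands inside the
physiological entrainment ranges (6.5–23.2 % entering, 1.5–8.1 %
re-entering); they are exposed in the preset files. The drift region
reports zero velocity gradient (its stresses are negligible next to the
channels), so sinus residence contributes essentially no SA — a known
idealization.

*Advection.* Fixed-step RK4 at dt = 0.5 ms with export every 2 steps
(1 ms cadence) by default. Inertial mode applies Stokes drag
dv/dt = (u−v)/τp, τp = ρp d²/18µ ≈ 0.2 µs, via an exponential update on
top of the RK4 fluid path — unconditionally stable despite τp ≪ dt and
reducing exactly to the tracer scheme as τp → 0. Particles are released
with the local fluid velocity at their injection time; tracking stops at
the aortic outlet or ventricular inlet. The trajectory arrays, not the
integrator, hold all state, so identical configurations and seeds
reproduce output bit-exactly.

*What the generator does not emulate.* Channel tortuosity and
convergent/divergent narrowings (stress along a real channel varies;
here it is uniform per cross-section), FSI leaflet motion, turbulence,
red-blood-cell effects, and any patient geometry. Consequently absolute
SA magnitudes (PVL-group means of ~10–25 Pa·s at the reduced scale) are
not calibrated to patient values; tests built on the generator
demonstrate the pipeline's correctness and the qualitative structure
(periphery-biased entrainment, multi-cycle re-entry, right-shifted PVL
footprint), not clinical magnitudes.

## Event detection

The PVL domain is the union of the channel slabs plus a collar of one
channel width beyond each mouth — entrainment at the exits counts,
general sinus residence does not; the collar width is configurable. An
entry opens after `debounce = 2` consecutive in-region samples (2 ms at
the default cadence) and closes after the same number outside; 0 or 1
disables debouncing. A trajectory ending in-region yields an open record
that counts as an entry. Re-entry requires at least two records, which
by construction implies an intervening exit. Percentages are over all
seeded platelets (not only those still tracked), and phase at entry is
looked up in the pressure-gradient segmentation at the entry time modulo
the period.

## Footprint statistics

Default binning: 100 equal-width bins from 0 to the 99.9th percentile of
the pooled sample, plus one overflow bin to the sample maximum, so the
diagnostically relevant tail above ~5 Pa·s stays explicitly represented;
log-spaced binning is available by flag. Densities are normalized to
unit integral. The two groups (PVL vs non-PVL) usually differ in size by
an order of magnitude, so the larger group is resampled with replacement
to the smaller group's size `n_boot` times (default 500–1000; minimum
100) and reported as the per-bin bootstrap mean with a 2.5–97.5
percentile band; `n_boot = 0` bypasses resampling. The resampling scheme
is this package's own definition of the size-matching comparison; it is
seeded and deterministic. Threshold comparison is closed (≥). Bimodal
densities are reported as-is.

## Cohort correlations

The packaged case table (five anatomies × {in vitro, in silico}) is
validated on load by checksum and by recomputing RF from closing, leak
and SV for every row (tolerance ±0.1 %SV — the printed cells carry
1-decimal rounding). Correlations use unweighted OLS with intercept on
the in silico rows only (entrainment percentages and EROA exist only
there); r is the Pearson coefficient. Recomputed from the rounded table
cells, the four headline fits give r² = 0.754 / 0.829 / 0.307 / 0.564.
The secondary EROA- and leak-flow fits against mean SA use the three
cases with a tabulated mean SA and are reported for completeness only —
three points determine a line and a half. The stagnation filter for mean
PVL jet exit velocity discards magnitudes below 0.3 m/s before
averaging and warns (returning 0) if nothing survives.

## Numerical and design notes

* Waveform evaluation extends periodically, but query points inside the
  covered span are interpolated directly so the cycle endpoint is not
  wrapped back to the start.
* Negative-flow integrals refine the integration grid with interpolated
  zero crossings before clipping, so closing + leak equals the clipped
  diastolic integral to integration tolerance.
* Reduced-scale runs (the `reduced=True` preset variant: 2 mm spacing,
  42 ms cadence → 405 platelets, three cycles, export every 2 ms) are
  the problem sizes used by the analysis drivers and the acceptance
  script; they run in ~15 s per case while preserving every qualitative
  property the tests assert. Full-scale seeding (≈3.3 M platelets per
  case) uses the same code paths.
* Degenerate inputs fail loudly: monophasic gradients cannot be
  segmented, empty SA samples cannot be binned, zero-variance predictors
  cannot be fit, and trajectory files with non-monotone time name the
  offending particle.

## Known limitations

The synthetic sinus drift is phenomenological (see above); entrainment
percentages respond to `feed_frac`/`wash_frac` and should be read as
adjustable study conditions, not predictions. The lumped model cannot
represent pressure recovery or inertial (Womersley) effects; EROA of a
generated case therefore deviates a few percent from the value its
calibration targets imply. Mean-SA correlations on three points are
descriptive only.
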