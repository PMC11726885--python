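# Methods

## Scope and intent

`coroflow` reproduces the *procedure* of a patient-specific coronary
CFD study — anatomy variants, boundary-condition calibration, a
pulsatile simulation, wall-shear index post-processing, and a six-case
anatomy × plaque × waveform design — at zero-dimensional (lumped
parameter) order. It does not attempt to reproduce 3D finite-element
results: surface WSS maps, local vortex structures and
patient-specific absolute values depend on the true lumen geometry,
which is replaced here by a synthetic centerline+radius fixture.

## Synthetic anatomy

A tree is five segments (AORTA, LM, LAD, LCX, RCA), each a 1D radius
profile r(s) with a parent attachment. The packaged `paper_twin`
parameter set: aortic radius 1.4 cm (length 6 cm), LM 1.0 cm at
0.185 cm radius, LAD/LCX/RCA lengths 4/4/5 cm with proximal radii
0.16/0.14/0.17 cm tapering linearly to 70% distally; the AOCA variant
re-attaches the LCX at the right sinus with 7 cm length, representing
the retroaortic course purely as extra path length (curvature and
torsion have no 0D analogue). These calibres are standard adult values;
they are a fixture, not patient measurements.

The plaque is a cosine diameter taper: inside a window of length L
centered at c, radii are multiplied by
1 − (d/100)·½(1 + cos(2π(s−c)/L)), reaching 1 − d/100 exactly at the
center (diameter convention — clinical CTA reporting; an area
convention would read ~26% for the same lumen). The packaged patient
plaque is d = 14%, L = 0.4 cm, centered 1.2 cm beyond the left ostium
(LAD-local arc 0.2 cm behind the 1.0 cm LM). The removal operator
replaces radii inside a window with the chord between the shoulder
radii, which restores a linearly tapering healthy profile exactly.

Measuring severity on an edited profile needs a healthy reference at
the narrowing. Because the baseline taper makes the distal tip the
*absolute* radius minimum, the degree operator maximizes the relative
shortfall against the upper convex hull of the profile — the hull
reproduces any linear baseline exactly, returns 0 on unnarrowed
segments, and reads the inserted degree back to machine precision on
the packaged shapes.

## Waveforms

All drivers are C¹ piecewise-cosine (sin²) constructions sampled at
500 points/cycle over T = 1.0 s:

* aortic inflow: one ejection pulse over 35% of the cycle, scaled so
  the cycle mean equals the cardiac output (default 83.3 mL/s = 5 L/min,
  a standard resting value; the source study does not state it);
* left coronary shape: one diastole-dominant peak (plus a 5% baseline
  so the shape is strictly positive); right coronary shape: a smaller
  systolic peak plus a diastolic peak (double-peaked);
* P_im: a systolic pressure pulse, left peak 120 mmHg / right peak
  25 mmHg (ventricular systolic pressures; amplitudes are not stated in
  the source study and are fixture choices).

Only the qualitative shapes (peak counts, systolic timing, mean-flow
normalization) are constrained; the tests assert exactly those
contracts. The swap experiment exchanges the left/right shapes (and,
in `swap_pim` mode, the P_im pair); it is an involution.

## Boundary-condition calibration

Mean arterial pressure is the clinical estimate DBP + (SBP−DBP)/3
(90.67 mmHg at 122/75). With cardiac output Q and coronary fraction
f = 0.04, the default `parallel` mode sets R_cor = P_mean/(f·Q) and
R_aorta = P_mean/((1−f)·Q): coronary and aortic beds are parallel
conductances fed at P_mean, which routes f of the cardiac output
through the coronaries by construction. The alternative `as_printed`
mode applies the series decomposition R_total = R_cor + R_aorta with
R_cor = (1−f)R_total; both modes satisfy the flow-ratio rule
R_cor : R_aorta = (1−f) : f, but only the parallel mode closes the loop
on the 4% calibration, which is why it is the default.

R_cor is distributed over the coronary outlets with conductance
∝ (distal radius)^2.6; the parallel recombination of the allocated
resistances recovers R_cor to 1e−9 relative. The aortic outlet splits
into R_p : R_d = 0.09 : 0.91 with C = 0.001 cm⁵/dyn; coronary outlets
split into 0.35 : 0.50 : 0.15 resistances and 0.11 : 0.89 compliances.

**Per-outlet total compliance** (c_total, default 1e−6 cm⁵/dyn) is not
a literature-fixed ratio but a scale choice. It was set so that the
intramyocardial capacitor couples P_im into the microcirculation at a
strength producing mild systolic flow suppression (~0.4 mL/s against
~1.1 mL/s mean branch flow, ωC_imR_eff ≈ 0.25 at systolic frequencies)
rather than order-of-magnitude flow reversal: with per-outlet
resistances ~1e5 dyn·s/cm⁵, a much larger compliance would let the
120 mmHg P_im swing drive reverse ostial currents tens of times the
mean branch flow, which is unphysiological and inconsistent with the
near-zero OSI regime these models are meant to emulate.

## 0D solver

Modified nodal analysis with three element types (resistor, capacitor
— optionally referenced to an external pressure waveform — and
periodic flow source), ground = venous pressure 0 mmHg. Units are CGS
internally (1 mmHg = 1333.22 dyn/cm²); flows are mL/s ≡ cm³/s.

Time integration is the trapezoidal rule (second order) with a
backward-Euler starting step, fixed Δt = 2 ms × 500 steps × 12 cycles.
The conductance matrix is constant and LU-factorized once per scheme;
capacitors use companion models, so mass balance holds at every step to
solver precision (measured residual < 1e−12 relative).

Simulations start from the DC (resistive cycle-mean) operating point.
This matters: the aortic Windkessel time constant R_d·C ≈ 1.4 s decays
only ~½ per cycle, so a zero start would still carry ~5e−4 of cycle
throughput as capacitor charge imbalance after 12 cycles; the DC start
brings the 12-cycle cycle-to-cycle convergence metric to ~5e−5 (< the
1e−3 tolerance) and per-capacitor net cycle charge below 1e−6 of
throughput within 30 cycles (the problem size used for that check). A
`zero` init mode exists for step-response verification against the
closed-form R_d·C exponential.

Branch junctions are lumped to the nearest endpoint node of the parent
segment; with the packaged geometry this places both coronary ostia at
the aortic root node, and the negligible aortic Poiseuille resistance
(~0.03 dyn·s/cm⁵ per cm) makes the approximation inconsequential.
Vessel inertance and nonlinear (Young–Tsai-type) stenosis losses are
omitted: at 14% diameter stenosis and coronary Reynolds numbers the
Poiseuille term dominates, and the rigid-wall assumption removes vessel
compliance from the tree itself.

## Waveform-swap ("adjusted") cases

The study's swap is stated as exchanging coronary *inlet flow
waveforms*, so the default implementation replaces the coronary outlet
circuits with prescribed-flow sinks carrying the swapped side shape,
each scaled to the branch's Murray-calibrated mean flow
(f·Q · conductance share). The Fig.-8-style normalized flow change
100·|Q_after − Q_before|/Q_before (baseline = unswapped case) then
measures how far the LPN-emergent baseline means sit from the Murray
targets; branch series resistance makes this distance anatomy-dependent,
and the long anomalous LCX shows the largest change (~2.6% vs ~1.6% for
the healthy LCX) — qualitatively the patient > healthy asymmetry of the
source study, though desk-scale in magnitude. The alternative reading
(exchanging the P_im pair so the outlet circuits themselves produce
swapped shapes) is available via `swap_left_right(lib, swap_pim=True)`.

## Indices

TAWSS integrates |τ|, keeping the signed integral inside OSI — the
printed OSI formula lacks its magnitude bars (it would be identically
zero as printed); the standard definition is implemented and clipped to
[0, 0.5]. Quadrature is trapezoidal with periodic closure, which makes
OSI of a zero-mean sampled sine 0.5 to machine precision. ECAP errors
on zero TAWSS (degenerate location) rather than returning infinity.
The wall-shear surrogate τ = 4μq/(πr³) assumes locally Poiseuille flow;
it cannot represent separation or secondary flow at the plaque
shoulders, so 0D TAWSS/OSI contrasts between cases reflect flow and
calibre changes only. Helicity and Q-criterion use second-order central
differences (one-sided second order at boundaries, `np.gradient`
edge_order=2); both converge at observed order ≥ 1.8 on analytic
fields.

## What the synthetic generator does and does not emulate

Emulated: the anatomical variant structure (LCX origin and added
retroaortic length), the mild focal LAD plaque and its placement, the
4% coronary calibration, the left/right waveform asymmetry, the
12-cycle pulsatile protocol, and the near-unidirectional (OSI < 0.01)
shear regime. Not emulated: true vessel curvature/torsion, lumen
eccentricity, 3D flow features (vortices, helical flow of the real
study's Figs. on velocity fields), wall compliance, and the actual
patient's calibres. Passing tests therefore certify the calibration
closed loop, conservation laws, index formulas and study mechanics —
not patient-specific 3D values, which are explicitly out of scope.

## Numerical choices

* tolerances: periodic convergence 1e−3 (measured ~5e−5 at 12 cycles);
  Murray recombination and ratio splits 1e−9 relative; insert/remove
  round trip 1e−9 cm.
* tie-breaks: `count_peaks` treats equal-sample plateaus as one peak
  and guards with a 10%-of-range threshold; stenosis measurement treats
  relative shortfalls below 1e−9 as zero.
* degenerate inputs: identically zero shear series → OSI 0 with a
  warning; zero-resistance elements, missing outlet BCs,
  period-inconsistent sources and non-finite states raise immediately
  with the offending element or node named.

## Known limitations

Single synthetic anatomy per variant (no population variability); flow
split inside the left tree is set by Murray allocation, not by a
measured LAD/LCX dominance; prescribed-flow swap mode fixes branch
means by construction, so swap-induced *mean* redistribution is a
calibration-distance effect rather than an emergent hemodynamic one;
and all absolute index values are Poiseuille-surrogate quantities, to
be compared between cases, not against 3D CFD magnitudes.
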