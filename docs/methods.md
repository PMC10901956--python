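# Methods

## Scope and model

`osteoadapt` models load-driven cortical bone adaptation in a single 2-D
midshaft cross section of the mouse tibia under the contralateral endpoint
imaging design: the right tibia is loaded axially, the left serves as an
unloaded control, and adaptation is the geometric difference between the
two limbs' cortical surfaces at the end of a 21-day protocol. Three
assumptions underpin the simulation: (i) the tibia behaves as an
Euler–Bernoulli beam, so longitudinal strain is affine over the cross
section and fully determined by the axial force and the two bending
moments; (ii) formation and resorption act along the local surface normal
at a rate set by a mechanostat — a piecewise-linear function of
longitudinal strain with a lazy zone; (iii) the control limb is a valid
proxy for the loaded limb's baseline geometry.

### Surfaces and the P coordinate

Each surface (periosteal and endosteal) is a closed polyline of 500 points
at uniform arc length, oriented clockwise in a y-up frame. The normalised
position P ∈ [0, 1) starts where the contour crosses the negative y axis
and increases clockwise; P — not the point index — carries identity across
time steps. After registration, P ≈ 0 sits on the posterior cortex,
P ≈ 0.46 anterior, and P ≈ 0.27/0.68 near the neutral axis.

### Beam strain

Strain at surface point (x, y) under peak load F (entered as a positive
compressive magnitude):

ε_z = (1/E) [ −0.9F/A + ((M_x I_yy + M_y I_xy)(y − y_c) − (M_y I_xx + M_x I_xy)(x − x_c)) / (I_xx I_yy − I_xy²) ]

with (M_x, M_y) = (−0.9F·e_y, +0.9F·e_x), e = p_F − p_c, the moment of the
compressive force about the section centroid. The signs are fixed by the
classical P/A + Mc/I solution: the surface on the load-offset side is
compressive. Section properties are exact Green's-theorem integrals of the
bounding polygons (outer ring minus inner ring), not pixel sums. A, I are
in μm²/μm⁴, F in N, E in Pa (default 14.8 GPa); stresses convert at
1 N/μm² = 10¹² Pa.

### Mechanostat

Above the lazy zone the stimulus is the normalised strain difference
ε_norm = (|ε| − ε_hom)/ε_hom of the surface's own strain and threshold;
the surface rate is ε_norm·k_C in compression and ε_norm·k_T in tension,
zero inside the lazy zone (boundaries inclusive). The endosteum
additionally loses bone at the constant rate k_SN = 1.398 μm/day on every
day of the protocol, modelling disuse after sciatic neurectomy. Thresholds
default to ε_hom^P = 2785 με and ε_hom^E = 1100 με (M1/M2 share the
1100 με value on both surfaces). Model classes tie the four rates:
M1 one rate, M2 by strain direction, M3 by surface, M4 free.

The stimulus uses |ε| rather than the signed strain: a signed normalised
difference would make super-threshold compression a negative stimulus and
turn formation into resorption in exactly the regions where formation is
observed, so the magnitude reading is the only self-consistent one.

### Time integration

Explicit forward Euler with Δt = 1 day: each day the section properties
are recomputed, strain evaluated at every surface point, the mechanostat
rate applied, and every point moved by M·û·Δt along its formation-direction
normal (outward for the periosteum, marrow-ward for the endosteum; û from
the chord between cyclic neighbours). Both contours are then re-resampled
to uniform arc length with the P-origin convention re-anchored. The default
schedule is 5 disuse days, 14 loading days, 2 disuse days (t_end = 21 d);
daily rates are ≤ ~7 μm/day so the geometry stays simple, and endpoint
simplicity/nesting is verified after the run.

## Measurement pipeline

1. **Binarise** (Otsu) and **fill cavities**: background components other
   than the exterior and the largest interior component (marrow) are set
   to bone.
2. **Extract contours** by marching squares at the 0.5 level (sub-pixel
   polylines); largest loop = periosteal, second = endosteal.
3. **Register**: rotate so the principal axis of minimum second moment of
   area lies along y (I_xy → 0), translate the marrow centroid to the
   origin. The 180° ambiguity is resolved by placing the thickest-cortex
   arc (the ridge proxy for the posterior side) in the y < 0 half-plane.
4. **Mirror** control limbs (x ↦ −x) into the loaded limb's handedness.
5. **Smooth**: cyclic Gaussian over the point index (σ = 2 points)
   suppresses the marching-squares staircase; the radial shrink bias is
   < 0.2 μm, two orders below the 9.56 μm pixel. The same smoothing is
   applied wherever roughness noise enters a contour-level measurement.
6. **Fine-align** the control onto the loaded section: a multi-start robust
   ICP (point-to-plane updates, Tukey weights at 6 μm scale) over rotation
   ±5° about the marrow centroid plus translation ±20 μm. The translation
   term is needed because each limb is registered to its own marrow
   centroid and asymmetric endosteal adaptation moves that centroid by up
   to ~15 μm; the redescending weights anchor the transform on the arcs of
   cortex that did not adapt instead of absorbing genuine formation into
   the alignment. Among starts, the solution matching the most points
   within 1.5 μm wins.
7. **Measure**: Δη^S as the minimum distance from each loaded-surface point
   to the fourfold linearly interpolated control surface, signed by a
   winding-number test (formation-positive on both surfaces, so
   ΔCt.Th ≈ Δη^P + Δη^E on near-parallel cortex); Ct.Th as the smaller of
   the minimum distance to the endosteum and the inward-normal distance to
   the first cortical-edge crossing (points whose ray never crosses fall
   back to the first measure, flagged); group mean, SD, and per-point
   two-sided one-sample t-tests at α = 0.05, uncorrected for multiple
   comparisons (the per-point significance trace is the object of
   interest). Degenerate points (SD = 0) are significant iff the common
   value is nonzero.

## Calibration

Formation rates are fitted against measured Δη fields by full-factorial
search: S0 sweeps each free rate over 0–20 μm/day (M1–M3) or 0–8 μm/day
(M4) at 0.5 μm/day; S1–S3 re-centre on the best candidate with half-widths
0.5/0.05/0.005 and increments 0.1/0.01/0.001 μm/day, clamping negative
candidates away. Candidates are scored by RMS^C over the concatenation of
both 500-point surfaces; ties resolve to the lexicographically smallest
rate vector; a failed simulation yields a non-finite RMS and is skipped.
Thresholds and k_SN stay fixed. The disuse lead-in days are
candidate-independent and are simulated once per calibration. Budget mode
coarsens only S0 (M4: 5⁴ = 625 candidates at 1.0 μm/day over 0–4), leaving
S1–S3 at full resolution; it recovers any truth within 0.5 μm/day of the
coarse grid exactly.

## Synthetic cohorts

The generator emulates the study conditions of an 8-group loading
experiment: n = 6 mice per group, peak loads 0–12 N, pixel size 9.56 μm.
A baseline section is r(θ) = R + Σ aₖcos(kθ+φₖ) per ring plus one Gaussian
ridge bump on the outer ring (defaults: R_out = 600 μm, R_in = 400 μm,
ridge 90 μm at the posteromedial octant, eccentric marrow via a k = 1
harmonic) — values chosen once to give a realistic cortical area
(~0.69 mm²) and thickness (~200 μm); no quantitative shape statistics for
the real midshaft are published, so the shapes claim genericity
(asymmetry, ridge, eccentric marrow), not anatomy. The default load point
p_F = (0, −1250) μm places the neutral axis near P ≈ 0.27/0.72 and makes
the thresholds activate in the physiological order: posterior periosteal
compression from 6 N, anterior periosteal tension from 8 N, endosteal
compression from 4 N, with peak strains ≈ −4900/+3500 με at 10 N.

Per mouse, Fourier amplitudes and base radii are jittered (σ = 20 μm);
the loaded limb is the forward simulation of that mouse's baseline under
the ground-truth mechanostat, the control is the baseline mirrored. Noise
enters the geometry only: point-wise roughness along the normal (σ = 3 μm
default) and a per-limb scan-pose rotation (σ = 2°); rasterisation (pixel
centre in the cortical ring) supplies pixel-level noise itself.
Ground-truth Δη fields are stored before rasterisation. Everything is a
pure function of the cohort spec including its seed.

What passing tests on these cohorts show: the pipeline's geometry,
registration, measurement and calibration logic are correct at realistic
scale and noise. What they do not show: robustness to grayscale artefacts
(beam hardening, metal streaks), 3-D misalignment of the slice plane, or
real anatomical shape variation between animals.

## Numerical choices

* Clockwise orientation is defined by negative shoelace area; the P = 0
  anchor takes the most negative-y crossing of the x = 0 half-line, with a
  warned fallback to the nearest-angle vertex if a contour never crosses it.
* Fourfold interpolation is linear along arc length (each segment split in
  four), preserving original vertices.
* Minimum distances use a k-d tree over the interpolated point set — the
  same quantity as the brute-force all-pairs scan the tests use as oracle.
* The threshold boundary |ε| = ε_hom belongs to the lazy zone.
* Rate grids are rounded to 9 decimals so stage values like 0.1 compose
  exactly across refinements.
* Principal-axis rotation uses the eigenvector of the planar scatter
  tensor; near-degenerate sections (I_xx ≈ I_yy within 0.1 %) warn that
  the rotation is ill-conditioned.

## Known limitations

* **Contralateral frame identifiability.** At 12 N combined with strong
  endosteal sensitivity (e.g. the reference fitted rate k^E_T ≈ 7 μm/day),
  nearly the whole cortex adapts and no rigid alignment can recover the
  true contralateral frame from the surfaces alone; residual bias of ~1–2
  pixels then affects part of the surface. The ground-truth-recovery tests
  therefore cover load groups up to the 10 N calibration load, where the
  group-mean measurement is within one pixel at ≥ 95 % of points. This is
  the same registration limitation that endpoint imaging studies report.
* The disuse rate k_SN is a constant displacement per calendar day; over
  21 days it accumulates 29.36 μm, larger than the ~22 μm mean resorption
  such experiments report for F = 0 — the constant-rate reading is kept
  and the discrepancy noted rather than re-fitted.
* Strain is the peak longitudinal strain of a static load; cycle counts,
  loading frequency and rest insertion are not modelled.
* Woven-bone formation (loads ≥ 14 N) is outside the model's domain.
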