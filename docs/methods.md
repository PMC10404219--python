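# Methods

## Problem

Multi-site multi-phase transcranial alternating current stimulation
(msmp-tACS) drives several cortical regions with sinusoidal currents of
one carrier frequency but *different phases*, so that one region's
stimulation waveform leads another's by a chosen delay (e.g. 90° of an
80 Hz carrier = 3.125 ms).  Designing such a montage means choosing, for
every scalp electrode, a complex injection current x_k = |x_k|∠φ_k such
that the induced cortical electric field approximates a desired phasor
map: amplitude A and phase φ on each region of interest (ROI), zero
elsewhere.  This package implements the complete design chain — head
model, electrostatic forward solver, lead field, complex least-squares
(CLS) optimization, field evaluation, waveform generation — plus the
behavioral indices of the visuospatial working-memory (VWM)
change-detection paradigm used to assess such stimulation, with a
generative simulator so every index is testable without participant
data.

## Head model

The built-in phantom is a nested concentric conductor: scalp / skull /
CSF / brain shells with outer radii 92 / 88 / 83 / 80 mm, approximating
adult head proportions.  Conductivities (S/m, isotropic, quasi-static):
scalp 0.25, skull 0.015, CSF 1.79, grey matter 0.276, white matter
0.126, sponge electrode 5.21.  The phantom brain is a single compartment
at grey-matter conductivity: the optimization only consumes the cortical
surface, while the conductivity table carries all six values for
externally supplied meshes (Gmsh MSH v2.2 ASCII, element type 4, with
physical-group tissue labels).

Meshing strategy: nodes are laid on Fibonacci lattices on every tissue
interface plus interior filling shells and tetrahedralised by a Delaunay
triangulation; tets are labeled by centroid radius.  The interface
shells share one direction lattice so nodes stack into radial columns —
this keeps thin layers (the 3 mm CSF) cleanly resolved with one element
through the thickness even when the tangential node spacing (the
`target_edge_length`, default 8 mm) exceeds the layer thickness.  A
seeded random rotation and a 1e-4 relative radial jitter remove
cospherical degeneracies; generation is bitwise deterministic per seed.
At the default resolution the per-shell volumes match the analytic
shell volumes within ~0.3% and the extracted cortical surface area is
within ~0.2% of 4π·80².

Electrodes are sponge cylinders (disc radius 5 mm, height 25 mm) whose
curved base follows the scalp sphere and which extend radially outward;
61 of them follow a 10-10 layout generated geometrically (midline chain
and outer 10%-ring at 18° steps, lateral electrodes by spherical
interpolation along coronal arcs).  Exact scalp coordinates are
irrelevant on a sphere; what matters is that footprints are disjoint
and the parietal/occipital preset (P3, Pz, P4, PO3, PO4, PO7, Oz, PO8)
exists for the bilateral-parietal protocol.  Because the spreading
resistance of a small electrode concentrates directly beneath it, each
electrode adds local refinement nodes under its footprint; without them
the electrode-to-electrode transfer resistance carries a few percent of
mesh-asymmetry error, with them an antipodal pair reproduces the
half-potential equatorial plane to <0.5%.  Electrode bodies are meshed
together with the head by one Delaunay pass over the combined node
cloud; tets outside the scalp that fall inside an electrode cylinder
are labeled electrode, the rest of the exterior is discarded.  The
distal (outermost) node disc of each electrode is recorded as the
boundary-condition surface.

ROIs are geodesic caps: all cortical elements whose centroid direction
lies within a given angular radius of a centre direction.  Caps must be
non-empty and, within one target, pairwise disjoint.

## Forward problem and lead field

The potential solves ∇·(σ∇V)=0 with linear (P1) tetrahedral finite
elements; the element stiffness is σ·vol·GGᵀ with G the barycentric
gradients.  Coordinates are converted from mm to metres at assembly so
the matrix carries SI units.  For each electrode pair the distal face
of the fixed active electrode (Fpz by default) is set to 1 V and the
return's distal face to ground, the system is solved by sparse LU
(below 2×10⁵ nodes; preconditioned CG at relative tolerance 1e-8
above), and the delivered current is read from the stiffness reaction
forces at the constrained nodes — the variationally consistent flux for
P1 elements, conserving charge to ~1e-10 relative.  Surface integration
of J·n over the distal faces is retained as an independent cross-check
(agrees within discretisation error, ~1%).  The solution is then
rescaled so exactly 1 mA is delivered.

E = −∇V is piecewise constant per tet; each cortical surface triangle
takes its owning tet's E projected on the outward unit normal.  The
lead field stacks these normal components column-by-return (V/m per
1 mA).  It is *real*: each pair solve is electrostatic, and phasors
enter only through complex current weights — consequently the complex
least-squares problem splits exactly into two real problems (an
identity, not an approximation).

Validation: the pair solve on a homogeneous 80 mm sphere matches the
analytic Legendre-series solution for surface point electrodes
(V ∝ Σ (2n+1)/n (r/R)ⁿ Pₙ(cos γ), coded independently of the solver)
to ~1% relative L2 on a ~47k-tet mesh, with monotone convergence under
edge refinement (16 → 11 → 7.5 mm gives 2.5% → 1.2% → 1.0%); the
comparison excludes the electrode neighbourhoods (r < 60 mm) where the
finite discs differ from point sources by construction.

## Montage optimization

The target vector b holds A·e^{jφ} on each ROI's elements (reference
ROI at phase 0; positive φ on another ROI means the reference leads
it), zero elsewhere, with default amplitude A = 0.3 V/m.  The return
currents minimise ‖b − Ax‖₂, solved by LAPACK's rank-revealing gelsd
(never explicit normal equations), real and imaginary parts sharing one
factorisation.  An optional ridge adds Tikhonov damping; at ridge 0 the
solver truncates singular values automatically beyond a condition
number of 1e10, since the textbook closed form (AᴴA)⁻¹Aᴴb presumes an
invertibility the lead field does not guarantee.

The active electrode closes the circuit: its current is minus the sum
of the returns, stored implicitly so Kirchhoff's law holds to the bit
under any scaling.  Safety limits (2 mA per return, 4 mA active) are
enforced by one uniform scale factor s = min(1, limits/maxima) applied
to every current: by linearity this preserves the achieved phase map
and the relative amplitude distribution exactly, which is why post-hoc
scaling was chosen over constrained least squares (left as an extension
point).  Carrier frequency and time are deliberately absent from the
optimization — the system is linear and quasi-static, so they factor
out of the least-squares problem — and the frequency rides along as
montage metadata only.

## Field metrics

The achieved field is the complex superposition Σ x_k·column_k.  Per
ROI: E_max is the peak amplitude; the half-maximum set holds the ROI
elements with amplitude ≥ E_max/2 (thresholded within the ROI only);
the stimulation phase is the *circular median* over that set — the
observed angle minimising the summed absolute circular deviations, ties
broken toward the smallest wrapped angle.  This definition is exact,
robust to wraparound at ±180°, and reduces to the ordinary median
whenever the phase support spans less than a half circle (always the
case for the concentrated ROI phases this pipeline produces).  An
area-weighted variant is exposed as an option.  Amplitude maps default
to the modulus of the normal-component phasor (the optimized quantity);
full-vector magnitudes are available from the pair solutions.

Inter-ROI delays use lead(ref, other) = wrap(φ_other − φ_ref) ∈
(−180°, 180°], positive when the reference leads; wrapping maps −180°
to +180°.  Errors: absolute |wrap(achieved − desired)|; relative =
absolute/|desired|·100 for non-zero desired delays, defined as 0 for a
zero desired delay when the absolute error is below 1° and flagged NaN
otherwise.

## Model interface

`MontageModel(leadfield, target, frequency_hz, ridge)` holds the design
problem; `fit()` returns `MontageResults` with the montage (currents,
amplitudes, phases, scale factor), the achieved phasor field, per-ROI
reports, the delay report, the least-squares residual and a printable
`summary()`.  Waveform simulation (`simulate_waveforms`) and plotting
(`plot_field`) hang off the results object.

## Stimulation protocol

`phase_to_time` converts phase to milliseconds of the carrier cycle.
`render_waveforms` samples env(t)·|x_k|·cos(2πft + φ_k) per channel at
10 kHz by default, with linear 30 s ramps (the protocol fixes the ramp
duration; the ramp *shape* is a package choice, and linear is the
simplest monotone choice).  The plateau duration is a free parameter of
the plan.  The 20 kΩ impedance-abort rule of the stimulation hardware
is recorded as plan metadata only — no device control is attempted.

## Behavioral indices and simulator

Sessions are 120 trials (6 blocks × 20; two blocks per load 4/5/6;
10 left + 10 right hemifield per block, 5 match + 5 mismatch each).
Indices per (load, hemifield) cell:

* K = load × (accuracy − miss rate), with accuracy = (hits + correct
  rejections)/trials and miss rate = misses/trials of the cell.  The
  defining phrase does not pin these denominators down, so both are
  configurable (miss rate over match trials only; Cowan-style
  K = load × (hit rate − FA rate)) and the convention used is recorded
  in the output.  K is not clipped: poor performance may go negative.
* d′ = Φ⁻¹(hit rate) − Φ⁻¹(FA rate), hits being correct "same"
  responses on match trials.  Rates of exactly 0 or 1 are pulled off
  the boundary by the 1/(2N) rule (log-linear alternative available) so
  d′ stays finite.  The weighted d′ is mean over loads of load·d′(load).
* LI = (M_R − M_L)/(M_R + M_L) for K or weighted d′; positive = right-
  hemifield advantage; NaN-flagged (not raised) when the denominator
  vanishes.  Median split sends subjects at or above the median LI to
  the high group.
* Benjamini–Hochberg step-up FDR adjustment for post-hoc p-values.

Omitted responses count as errors and are tallied separately.  Routine
inferential statistics (rmANOVA, t-tests, Friedman, Wilcoxon) are
deliberately out of scope; the module emits tidy per-subject tables for
external statistical software.

The simulator draws "same/different" responses from the equal-variance
Gaussian signal-detection model: P("same"|match) = Φ(d′/2 − c),
P("same"|mismatch) = Φ(−d′/2 − c), with per-hemifield d′, a common
criterion c and a lapse rate (default 0.02, within the range typical of
attentive adult observers) under which the response is a coin flip.
Trial counts match the session design exactly and generation is
deterministic per seed.  The simulator models sensitivity as
load-independent within a session — real observers show declining
per-item capacity with load — and contains no learning, fatigue or
sequential dependencies; passing recovery tests therefore demonstrates
the correctness of the index pipeline, not the realism of human data.

## Problem sizes and numerical choices

The default phantom (8 mm tangential spacing) yields ~107k tets and
~21k nodes with electrodes; a 60-column lead field builds in about two
minutes on one CPU, and the full design pipeline (mesh to delay report)
stays within minutes.  At this resolution the end-to-end recovery of a
90° bilateral-parietal delay lands within ~3° of the target; the ±15°
acceptance band in the tests is deliberately generous for the
phantom's ~8 mm cortical resolution (subject-specific head models at
million-element resolution can be held to much tighter delay errors).  Other fixed choices: solver switch at
2×10⁵ nodes, CG relative tolerance 1e-8, CLS truncation at condition
1e10, waveform sample rate ≥ 20× carrier, zero-desired-delay tolerance
1° for relative-error reporting.

## Known limitations

* The sphere phantom has no gyri; normal-component targets on a smooth
  sphere are easier to hit than on folded cortex, so phantom error
  levels are optimistic relative to realistic head models.
* Electrode placement by re-tetrahedralisation requires the phantom's
  layered geometry; external meshes must arrive with electrodes and
  distal node sets already embedded (MSH sidecar).
* Isotropic conductivity only; no frequency dependence (the quasi-static
  assumption at 80 Hz).
* The complete-electrode model (contact impedance) is not implemented;
  sponges are pure conductors with an equipotential distal face.
* Montage optimization offers least squares with optional ridge only;
  focality- or energy-constrained variants are out of scope.
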