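# Methods

## Scope and model

`ffr0d` treats steady, hyperemic coronary flow as a resistive circuit.
This is the 0D limit of the usual image-based FFR pipeline: no momentum,
no pulsatility, no pressure recovery, no wall shear stress.  What
survives of the physics is exactly what governs FFR at the circuit
level — the division of pressure between a flow-dependent stenosis
resistance and the distal microvascular resistances — and that is the
regime in which side-branch effects can be isolated cleanly.

A vessel tree is a single main vessel (a sampled lumen diameter
profile), zero or more side branches (ostium diameter and a terminal
resistance; the branching angle is stored but hydraulically inert), one
or more stenoses, a fixed inlet pressure, and one distal main outlet.
Outlets discharge to zero reference pressure through their lumped
resistances (`P_out = Q_out · R_out`).

## Components

**Wall friction.**  Healthy-segment resistance is the quadrature of
`128 μ / (π d(s)⁴)` along the centerline (composite trapezoid, default
step 0.05 mm).  The cumulative integral is computed on a grid anchored
at the profile start, which makes interval resistances exactly additive.
The effective viscosity for resistances is the Carreau infinite-shear
plateau μ∞ = 0.0035 Pa·s; the full Carreau law (μ₀ = 0.25 Pa·s,
λ = 25 s, n = 0.25) is available for shear-dependent evaluations.  The
flag `neglect_healthy_resistance` zeroes wall friction, reproducing the
idealized-circuit assumption that healthy segments are lossless; it is
off by default.

**Stenosis.**  The taper of a stenosis is a cosine area profile:
over a lesion of length `L` centred at `c` with minimum/healthy area
ratio `r`, the area is scaled by `1 − (1 − r)·cos²(π(s − c)/L)`.  No
analytic profile is mandated by the geometry alone; the cosine taper is
smooth, symmetric, reaches the minimum at the centre, joins the healthy
lumen with zero area jump, and is configurable at construction.  The
quadratic pressure-drop coefficients default to the classical
decomposition: `C₁` is the viscous resistance of the tapered lumen
(quadrature as above), and `C₂ = K_t ρ/2 (1/A_s − 1/A₀)²` is the
sudden-expansion loss with `K_t = 1.52` (a standard empirical expansion
coefficient; exposed in config) and ρ = 1050 kg/m³.  A two-point
calibration (`calibrate_coefficients`) can replace the geometric
defaults with values fitted to an external characterisation.

**Microvascular bed.**  Each outlet's resistance comes from an
asymmetric fractal structured tree: daughters scaled by α = 0.9 and
β = 0.5, segment length γ·d with γ = 25, termination when d < 50 μm.
Every vessel with d below the cut-off is a leaf contributing only its
own segment resistance; vessels at or above it always spawn both
daughters, and the root segment contributes its own resistance like any
other.  The recursion is memoized on the integer exponent pair (i, j)
of `d_root·αⁱ·βʲ` — distinct states number in the hundreds while the
naive call tree has ~2⁴⁰ nodes for a 3 mm root — and the memoized value
is verified against naive recursion on small roots in the tests.
Hyperemia is a single multiplicative factor 0.24 applied to the total
resistance of every outlet tree, main and branch alike (the adenosine
steady-state value; whether a calibrated distal resistance should also
carry the factor is moot because calibration absorbs any constant).
The viscosity inside the tree is fixed at μ∞ by default: arteriolar
shear rates are high, and a resistance-only tree conventionally uses
the plateau value.

**Network solution.**  Trees are solved by damped Picard iteration:
freeze each `R(q) = C₁ + C₂q` at the current flow, reduce the linear
tree exactly (series/parallel elimination from the distal end), update
flows with damping 0.5, stop when the largest relative flow change is
below 1e-10 (max 200 iterations), then perform one undamped solve so
the reported state conserves flow to machine precision.  Picard was
chosen over Newton because `R(q)` is affine, making the composite map
mildly nonlinear; the damped iteration is derivative-free and its
convergence is certified directly by the residual.  Flow directions are
fixed by the tree orientation; reverse flow is rejected rather than
modelled, as the steady configurations of interest never exhibit it.

**Calibration.**  `calibrate_distal_resistance` finds the main-outlet
resistance reproducing a measured distal FFR by Brent root-finding on
log₁₀R over [1e6, 1e16] Pa·s/m³ (FFR is monotone in R₁), with branch
resistances held fixed — the convention when a pressure-wire measurement
constrains only the main vessel.  The same distal resistance is imposed
on the branchless copy in `compare_with_without`; re-calibrating the
pruned tree would hide precisely the flow-redistribution effect being
measured.

**Virtual pullback.**  FFR(s) is sampled along the main vessel of a
solved tree.  Within a section the pressure falls with the local viscous
gradient; across a stenosis the lumped drop `C₁q + C₂q²` is distributed
in proportion to the local `d(s)⁻⁴` weight, concentrating it at the
throat.  A 0D chain cannot represent post-stenotic pressure recovery (a
3D effect), so the curve is monotone non-increasing by construction and
starts at exactly 1.

**Murray profile.**  `murray_flow_profile` splits flow at each junction
between the branch (ostium diameter cubed) and the main continuation
(healthy main diameter at the junction, cubed).  With no stenosis,
lossless walls and outlet resistances scaling as d⁻³ the resistive
network reproduces this split exactly; the discrepancy measure
`mean((Q_murray − Q_solver)/Q_murray)` quantifies how far a given tree
is from that regime.

## Synthetic data

The idealized fixtures encode the benchmark geometry exactly: 75 mm ×
3 mm main vessel, a 10 mm mid-vessel stenosis with minimum lumen area
20 % of healthy (minimum diameter 3·√0.2 ≈ 1.342 mm), a 2.5 mm branch
at 75° placed 25 mm upstream or downstream of the stenosis centre, and
a 90 mmHg inlet.  The stenosis centre is placed at mid-vessel
(37.5 mm), which keeps both branch positions inside the vessel.

Patient-like trees emulate an intravascular-OCT pullback: lumen samples
every 0.2 mm (36 mm/s pullback at 180 frames/s), a linear proximal→
distal taper (3.4 → 2.6 mm by default), and multiplicative Gaussian
noise on lumen area (default SD 2 %, clipped at ±3 SD, diameter
recomputed) standing in for frame-to-frame segmentation jitter.  Two
layouts mirror the clinically interesting topologies: `patient1_like`
puts the stenosis distal to most branches plus one small (0.9 mm)
distal branch; `patient2_like` puts a focal stenosis proximal to all
branches.  Branches below 0.5 mm are never generated, branch/lesion
overlaps are rejected and re-drawn, and all randomness flows from one
seeded generator so a configuration serializes byte-identically.

What the generator does *not* emulate: real OCT segmentation error
structure (it is not white multiplicative noise), vessel curvature,
eccentric or multi-lobed lumens, diffuse disease outside the tagged
lesions, and true patient microvascular resistances.  Tests passing on
these trees therefore demonstrate the correctness and internal
consistency of the circuit mechanics, not clinical accuracy on any
specific patient.

## Numerical choices and edge cases

* Internal units are strictly SI; mmHg, mm and mL/min exist only at I/O
  boundaries (1 mmHg = 133.322 Pa).
* Tree JSON stores geometry in millimetres via an exact decimal shift
  of each float's shortest representation and pressure/resistance in SI,
  so `read_tree(write_tree(t)) == t` bit-for-bit and equal seeds give
  byte-identical files.
* A stenotic interval may not straddle a junction (refine the tree
  instead); a branch may not attach inside a lesion.
* Degenerate inputs fail loudly: non-positive diameters/resistances,
  area ratio outside (0, 1), reverse flow, unreachable calibration
  targets, singular two-point calibrations.
* Quadrature convergence is checked in the tests by Richardson
  comparison against 1 μm-step references; the cosine taper integrand is
  smooth and symmetric, so the default 0.05 mm step is already accurate
  to ~1e-6 relative on the benchmark lesion.

## Problem sizes

The shipped analyses use the 75 mm fixtures sampled at 0.5 mm
(idealized) or 0.2 mm (patient-like), trees of up to five branches, and
structured trees from 3 mm roots to 50 μm leaves (~10⁴ memoized
states at most).  The full test suite and all analysis scripts run in
well under a minute on one core.

## Known limitations

* No pulsatility, compliance or inertia: purely resistive, steady
  hyperemic flow.
* No pressure recovery distal to a stenosis; 0D FFR is therefore a
  conservative (lower) estimate just distal to the lesion compared with
  3D fields.
* The expansion coefficient `K_t` and the cosine taper are modelling
  conventions, not measured properties of any lesion; quantitative C₁,
  C₂ for a specific patient should come from the two-point calibration.
* Branch conduits are resistanceless (only their terminal beds resist):
  ostium segments are short and wide compared to their microvascular
  load, but very long branches would be misrepresented.
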