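# Methods

This note documents the model implemented by `lobulemech`, the choices made
where the design was genuinely open, and what the synthetic generators do
and do not capture.

## Scope and assumptions

The package computes the bulk (homogenized) complex shear modulus of liver
tissue from an idealized periodic microstructure of the hepatic lobule.
The governing assumptions:

* **Linear viscoelasticity in the frequency domain.** Elastography uses
  small-amplitude waves at 50–300 Hz; flow–deformation coupling and
  material nonlinearity are neglected, so σ(ω) = E(ω)(ε(ω) − ε₀(ω)) with a
  complex modulus tensor. Inertia is neglected inside the cell (the
  wavelength at these frequencies is several lobule diameters), so the cell
  problem is elastostatic with complex coefficients.
* **Perfect periodicity, 2D plane strain.** Real lobule packings are
  disordered and three-dimensional; the model tiles the plane with one
  rectangular two-lobule cell. Homogenized values should be read as
  ensemble means over realizations, not as predictions for a particular
  tissue sample.
* **Near incompressibility** is imposed through ν = 0.4999 in the
  plane-strain constitutive matrix rather than a mixed formulation; only
  the shear response is reported.

Out of scope (deliberately): poroelastic sinusoidal flow, hyperelastic
confinement effects of fat/inflammation, ballooning, 3D lobule packing,
dispersion/scattering at high frequency, and mechanobiological models of
fibrosis progression.

## Geometry

A pointy-top hexagon of vertex-to-vertex diameter d = 1 mm (default) gives
the rectangular periodic cell [0, √3/2·d) × [0, 1.5·d) containing two
lobules: one on the cell corners, one at the center. Portal triads sit on
the four distinct hexagon vertices of the cell. All distance fields
(to veins, triads, hexagon edges, and center-to-vertex radii) are periodic:
minimized over the 3×3 image tiling, which is exact for in-cell points.

Histology does not fix the lumen sizes; defaults are vein radius 0.05 mm
and triad radius 0.04 mm (configurable). Lumens are modeled as very soft
inclusions (10⁻³ × matrix modulus, configurable) rather than holes so the
periodic operator stays nonsingular; this reproduces the observed effect
that the vein region contributes no stiffness and pulls the homogenized
loss modulus slightly below the matrix value (0.476 vs 0.503 kPa at
100 Hz with default radii).

## Phase rheology

| phase | model | default | units |
|---|---|---|---|
| healthy matrix | Kelvin–Voigt G₀ + iωη | G₀ = 2 kPa, η = 0.8 Pa·s | Pa, Pa·s |
| matrix (combined study) | springpot c(iω)ᵃ | c = 800, a = 0.15 | Pa·sᵃ, – |
| fat | Newtonian iωη | η = 0.4 Pa·s | Pa·s |
| collagen | elastic | 60 kPa (sweepable 60–300) | Pa |

ω = 2πf with f in Hz. At 100 Hz these give loss moduli 0.503 kPa (matrix),
0.251 kPa (fat) and 0.491 kPa (springpot). Note one internal inconsistency
in the source constants: a fat loss modulus of "0.5 kPa at 100 Hz" is
sometimes quoted alongside η = 0.4 Pa·s, but iωη gives 0.251 kPa; the
implementation always uses iωη.

### Fat fraction → local modulus

The local effective modulus of fat-laden tissue is the Christensen–Lo
generalized self-consistent (three-phase composite-sphere) estimate for
spherical inclusions, specialized to incompressible phases (ν = ½ for both)
and evaluated with complex moduli via the elastic–viscoelastic
correspondence principle. The scheme's quadratic
A(G_eff/G_m)² + B(G_eff/G_m) + C = 0 is solved with the root continuous
with the φ→0 limit (G_eff → G_m); branch continuity over φ ∈ [0, 0.5] is
verified by a scan. The 50% cap on local fat fraction is the validity
limit of the composite-sphere construction. The implementation is verified
against the dilute incompressible-sphere expansion
G_m (1 + 5φ(G_i − G_m)/(3G_m + 2G_i)) to O(φ²). The conversion sits behind
a single function so an alternative closed form can be swapped in.

## Steatosis generator

On the 80×160 pixel raster, the noiseless profile is
V(ξ) = V_out + √ξ (V_in − V_out), where ξ = d_edge/(d_edge + d_vein) is a
bounded radial coordinate (1 at the lobule center, 0 on the hexagon
boundary). The √ form follows the stated "linear in the square root of the
distance ratio" behavior; a `profile="linear"` switch keeps the
alternative. The naive boundary-to-center distance ratio is ill-posed at
the lobule center (division by zero); ξ is the bounded surrogate with the
same ordering.

Pattern 1 (zone-3 predominant, the common presentation) fixes V_out = 0 and
solves V_in so the parenchyma mean matches the target; if V_in would exceed
the 0.5 cap it is clamped and V_out solved instead. Pattern 2 swaps roles.
Noise is i.i.d. Gaussian with σ = 0.05 in absolute fat-fraction units
(relative noise would vanish at V = 0 and remove the speckle at the lobule
rim), applied **before** clipping to [0, 0.5]; clipping introduces a small
positive bias at low fat, kept within ±0.01 of the target (verified over
seeds). Fat-fraction accounting is over parenchyma pixels; lumens carry no
fat.

Not modeled: droplet-scale geometry, macro- vs microvesicular distinction,
spatially correlated noise.

## Fibrosis generator

Collagen burden is parameterized by CPA = collagen pixels / all cell
pixels (the denominator is configurable to parenchyma-only; the
literature rarely states which is meant). Deposition is staged:

| stage | CPA range | distance field | spread d (mm), linear in CPA |
|---|---|---|---|
| perisinusoidal | first 5 points | nearest central vein | 0.75 @ 1% → 1.40 @ 5% |
| periportal | next 5 points | nearest portal triad | 0.75 @ 5% → 1.75 @ 10% |
| bridging | beyond 10% | hexagon edges (P1) or lobular radii (P2) | 0.50 @ 10% → 1.00 @ 20% |

Per-pixel probability P = 1 − Φ((k·x/d − μ)/σ) with μ = 2, σ = 10 and a
dimensionless sharpness k = 20. Two orientation/scale choices deserve
note. First, the probability law as sometimes printed *increases* with
distance, contradicting the accompanying description ("higher deposition
closer to the portal triad"); the decaying complement is used. Second,
with μ = 2, σ = 10 and k = 1 the probability is nearly flat across the
lobule; k rescales the argument so the patterns localize visibly around
their anatomical features. k, μ, σ are all configuration keys.

Within a stage, undeposited parenchyma pixels are swept with Bernoulli
acceptance until the stage's cumulative pixel quota is met (the last sweep
is truncated by a seeded random subset), making realized CPA exact to one
pixel. Consequences: masks at 5% CPA are subsets of masks at 10% CPA for
the same seed, and Patterns 1 and 2 are bit-identical for CPA ≤ 10%
(bridging never runs). Lumen pixels are excluded even though periportal
collagen histologically surrounds triads.

## Finite elements and homogenization

* Uniform QUAD8 (8-node serendipity) mesh, 40×80 elements on the working
  mesh, 2×2 Gauss quadrature — reduced integration for QUAD8, which also
  prevents volumetric locking at ν = 0.4999. The 40×80 mesh has exactly
  one Gauss point per material pixel; the 80×160 refinement resolves each
  pixel as a full element.
* Material lookup is nearest-pixel at each Gauss point. Collagen pixels
  are binary (collagen modulus or not); no smoothing is applied.
* Periodicity is enforced by tying right→left and top→bottom boundary
  DOFs; one node is pinned to remove rigid translation (the eigenstrain
  load is self-equilibrated, so pinning adds no spurious reaction).
* The unit macroscopic engineering shear γ₁₂ = 1 enters as an eigenstrain
  load f = ∫ Bᵀ D ε₀ dY; the solver returns the periodic fluctuation and
  G*_eff = ⟨σ₁₂⟩. Two independent extraction paths (Gauss-quadrature
  stress averaging and the integrand-average/load-vector identity) agree
  to 10⁻¹⁰ and are both tested.
* All arithmetic is complex; an equivalent real block formulation
  [[E′, −E″], [E″, E′]] (the storage/loss split used by real-only FE
  codes) is implemented for parity testing. A printed variant of this
  block matrix with the opposite off-diagonal signs corresponds to the
  conjugate convention; the standard product convention is used and proven
  equivalent to direct complex arithmetic by the parity test.
* Direct sparse factorization (SuperLU) in symmetric mode with
  diagonal-preference pivoting (threshold 0.01) plus two iterative
  refinement steps; relative residuals are ~10⁻¹². Default partial
  pivoting is pathologically slow on this near-incompressible complex
  matrix and is avoided.

Verification oracles: exact homogeneous patch test for arbitrary complex
moduli; two-strip laminate against the harmonic-mean closed form (<10⁻⁶);
Voigt–Reuss bracketing on random elastic two-phase microstructures;
conjugation symmetry; non-negative dissipation; scale invariance of the
homogenized modulus under geometric rescaling.

## Study conditions and problem sizes

Reference ensemble sizes are 300 realizations for the steatosis sweep and
100 for fibrosis. The package defaults to these in `ExperimentConfig`
only where stated; the test suite and the acceptance script run
scaled-down ensembles chosen so that ensemble scatter is well below the
thresholds being checked: 6 realizations per mesh in the convergence
tests, 20 in the fibrosis-level test, 12 per mesh in the acceptance
script's convergence targets and 100 for its fibrosis ensemble. Per-
realization scatter of the homogenized storage modulus at 10% CPA is
~0.6%, so a 20–25 realization mean is stable to ~0.15%.

## Known limitations and open discrepancies

* **The deposition generators are calibration sketches, not validated
  histology.** They reproduce the qualitative zonal/staged patterns, and
  all directional trends follow: storage modulus falls with fat content
  and rises with CPA; relaxation time rises with fat and falls with CPA;
  the loss modulus moves little at 100 Hz but responds at 300 Hz with the
  springpot matrix.
* **Fibrosis stiffening level.** Independent-pixel Bernoulli deposition
  produces diffuse collagen speckle. At 10% CPA with 60 kPa collagen the
  homogenized modulus computes to ≈2.6 + 0.6i kPa on the 40×80 mesh
  (≈2.45 + 0.59i kPa on 80×160, a ~5.7% mesh difference), and sweeping the
  sharpness k over 20–300 moves the mean only between 2.59 and 2.72 kPa.
  Reported reference values near 4.1 kPa for this condition imply
  connected collagen load paths (septa-like structures) that no parameter
  of the independent-pixel law reproduces; matching them would require a
  different, explicitly structured deposition model (e.g., sampling
  correlated clusters or drawing septa). The package reports its computed
  values as such.
* **Mesh convergence is microstructure-dependent.** Smooth fat fields
  converge fast (0.3% between 40×80 and 80×160 at 20% fat); binary
  collagen speckle converges slowly because the coarse mesh represents
  intra-element heterogeneity only through its Gauss points, which acts as
  an implicit stiffness average. The convergence reports always state
  both means.
* Passing tests show internal consistency and correct composite-mechanics
  limits, not agreement with in vivo elastography; calibration against
  measured histology–stiffness pairs is future work.
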