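# lobulemech

Micromechanical modeling of liver viscoelasticity from synthetic histology.

Elastography (ultrasound shear-wave or MR) measures the bulk complex shear
modulus of liver tissue, G\*(ω) = G′(ω) + iG″(ω), and uses it as a biomarker
for steatosis (fat accumulation) and fibrosis (collagen deposition).
`lobulemech` closes the loop from histology to that measurement in silico:
it generates synthetic microstructures of the hepatic lobule — the ~1 mm
hexagonal functional unit with a central vein at its center and portal
triads at its vertices — and computes the homogenized complex shear modulus
of the bulk tissue by frequency-domain viscoelastic finite-element
homogenization of a periodic unit cell.

It is aimed at researchers in tissue biomechanics and elastography who want
a forward model linking fat fraction, collagen proportionate area (CPA) and
collagen stiffness to the storage modulus, loss modulus and effective
relaxation time τ = G″/(ωG′) in the 100–300 Hz elastography band.

## Model

* **Unit cell.** The hexagonal lobule lattice is represented by a periodic
  rectangle of four half-hexagons (width √3/2 · d, height 1.5 · d; 0.866 ×
  1.5 mm for a d = 1 mm lobule) containing exactly two lobules. Central
  veins and portal triads are soft lumen disks.
* **Phases.** Healthy matrix: Kelvin–Voigt G\* = G₀ + iωη (2 kPa, 0.8 Pa·s)
  or springpot G\* = c(iω)ᵃ (c = 800, a = 0.15); fat: Newtonian fluid
  G\* = iωη (η = 0.4 Pa·s); collagen: purely elastic (60–300 kPa).
* **Steatosis.** A zonal fat-fraction field V = V_out + √ξ (V_in − V_out) on
  an 80×160 raster (ξ a bounded center-to-boundary coordinate), calibrated
  to a target mean, plus σ = 0.05 Gaussian noise, capped at 50%. The local
  fat fraction is converted to a local complex modulus with the
  Christensen–Lo generalized self-consistent composite-sphere scheme for
  incompressible phases, extended to complex moduli by the correspondence
  principle.
* **Fibrosis.** Staged probabilistic collagen deposition (perisinusoidal →
  periportal → bridging as CPA grows), with per-pixel probability
  1 − Φ((k·x/d − μ)/σ) decaying with distance x from the stage's anatomical
  feature, and exact pixel quotas so realized CPA matches the target.
* **Homogenization.** Plane-strain QUAD8 elements (40×80 working mesh, 2×2
  Gauss, ν = 0.4999), complex-valued assembly, periodic boundary conditions,
  unit macroscopic engineering shear imposed as an eigenstrain; the
  homogenized modulus is the volume-averaged shear stress
  G\*_eff = ⟨σ₁₂⟩/γ₁₂.

## Worked example

Homogenize one microstructure with 16% mean fat (Pattern 1, zone-3
predominant) and 5% CPA at 100 Hz:

```bash
lobule-homog homogenize --fat 0.16 --cpa 0.05 --seed 3 --out out/
```

prints

```
G' = 1622.3 Pa, G'' = 519.3 Pa, tau = 0.509 ms at 100 Hz
```

Against the healthy baseline (G\* = 2000 + 503i Pa before lumens are
accounted for), the fat has softened the storage modulus by ~19% while the
5% collagen partially offsets it; the loss modulus barely moves (fat and
matrix have similar loss at 100 Hz), so the relaxation time rises from
0.40 ms to 0.51 ms — the signature by which viscosity-sensitive
elastography separates steatosis from fibrosis. The same computation is
available in Python:

```python
from lobulemech import MaterialSet, build_microstructure, effective_modulus

micro = build_microstructure(fat_target=0.16, cpa_target=0.05, seed=3)
res = effective_modulus(micro, MaterialSet.default(), frequency=100.0)
print(res.G_eff.storage, res.G_eff.loss, res.tau_eff)
```

Parameter sweeps and mesh-convergence reports (`lobule-homog sweep`,
`lobule-homog convergence`) write tidy CSVs, one row per seeded
realization, plus PNG summaries; every row is regenerable from its seed.

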