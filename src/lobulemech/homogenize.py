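"""Effective viscoelastic modulus of the lobule cell (periodic homogenization).

This module glues the synthetic-histology rasters to the periodic FE
solver: it assembles the per-pixel complex shear-modulus raster from
region labels, fat fraction and collagen mask, solves the periodic cell
under unit macroscopic engineering shear, and reports the homogenized
complex shear modulus G*_eff = <sigma_12>/gamma together with the
effective relaxation time tau = G''/(omega G').  Seeded ensembles over
microstructure realizations provide the averaged moduli the random
deposition models call for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import (
    NU_DEFAULT,
    PeriodicCellProblem,
    StructuredMesh,
    build_mesh,
    material_at_gauss,
)
from .fibrosis import CollagenMask, FibrosisPattern, deposit_collagen
from .geometry import (
    DistanceFields,
    RegionLabel,
    UnitCellGeometry,
    classify_region,
    distance_fields,
)
from .rheology import (
    ComplexModulus,
    MaterialSet,
    complex_modulus,
    effective_fat_modulus,
    relaxation_time,
)
from .steatosis import FatField, FatPattern, generate_fat_field

__all__ = [
    "Microstructure",
    "HomogenizationResult",
    "EnsembleSummary",
    "build_microstructure",
    "modulus_raster",
    "effective_modulus",
    "run_ensemble",
    "bounds_check",
]


@dataclass
class Microstructure:
    """One realization of synthetic lobule histology on the raster grid."""

    cell: UnitCellGeometry
    region: np.ndarray  # (ny, nx) RegionLabel values
    fat: FatField | None = None
    collagen: CollagenMask | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.region.shape


def build_microstructure(
    fat_target: float = 0.0,
    cpa_target: float = 0.0,
    seed: int | None = 0,
    cell: UnitCellGeometry | None = None,
    fat_pattern: FatPattern = FatPattern.P1_CENTRAL,
    fibrosis_pattern: FibrosisPattern = FibrosisPattern.P1_PORTAL_PORTAL,
    nx: int = 80,
    ny: int = 160,
    fields: DistanceFields | None = None,
    region: np.ndarray | None = None,
) -> Microstructure:
    """Generate a combined steatosis + fibrosis microstructure.

    Collagen is deposited first; the fat field is then generated on the
    non-collagen parenchyma with its target renormalized by 1/(1 - CPA),
    so the overall fat-per-cell budget matches ``fat_target`` while the
    mean over the remaining tissue is correspondingly higher.  Seeds for
    the two generators are derived from ``seed`` so that fat and
    collagen randomness are independent streams.
    """
    cell = cell or UnitCellGeometry()
    if fields is None:
        fields = distance_fields(cell, nx, ny)
    if region is None:
        region = classify_region(cell, nx=nx, ny=ny)
    collagen = None
    fat = None
    if cpa_target > 0:
        collagen = deposit_collagen(
            cpa_target, fibrosis_pattern, seed=seed, cell=cell,
            nx=nx, ny=ny, fields=fields, region=region,
        )
    if fat_target > 0:
        eligible = region == RegionLabel.PARENCHYMA
        renorm = fat_target
        if collagen is not None:
            eligible = eligible & ~collagen.grid
            renorm = fat_target / (1.0 - collagen.realized_cpa)
        fat_seed = None if seed is None else seed + 1_000_003
        fat = generate_fat_field(
            renorm, fat_pattern, seed=fat_seed, cell=cell, nx=nx, ny=ny,
            fields=fields, region=region, eligible=eligible,
        )
    return Microstructure(cell=cell, region=region, fat=fat, collagen=collagen)


def modulus_raster(
    micro: Microstructure, materials: MaterialSet, frequency: float
) -> np.ndarray:
    """Per-pixel complex shear modulus (Pa) of a microstructure.

    Collagen pixels take the elastic collagen modulus, lumen pixels the
    very soft lumen modulus, and the remaining parenchyma the
    composite-sphere fat-softened matrix modulus.
    """
    Gm = complex_modulus(materials.matrix, frequency).value
    Gi = complex_modulus(materials.fat, frequency).value
    Gc = complex_modulus(materials.collagen, frequency).value
    if micro.fat is not None:
        G = effective_fat_modulus(micro.fat.grid, Gm, Gi)
    else:
        G = np.full(micro.shape, Gm, dtype=complex)
    G[micro.region != RegionLabel.PARENCHYMA] = materials.lumen_factor * Gm
    if micro.collagen is not None:
        G[micro.collagen.grid] = Gc
    return G


@dataclass
class HomogenizationResult:
    """Homogenized complex shear modulus of one realization."""

    G_eff: ComplexModulus  # Pa
    tau_eff: float  # s
    frequency: float  # Hz
    E_column: np.ndarray  # (3,) complex, shear column of the effective tensor
    metadata: dict = field(default_factory=dict)

    @property
    def value(self) -> complex:
        return self.G_eff.value


def effective_modulus(
    micro: Microstructure,
    materials: MaterialSet,
    frequency: float = 100.0,
    mesh: StructuredMesh | tuple[int, int] = (40, 80),
    nu: float = NU_DEFAULT,
    problem: PeriodicCellProblem | None = None,
) -> HomogenizationResult:
    """Homogenize one microstructure at one frequency.

    ``mesh`` may be an (nx, ny) pair or a prebuilt mesh; passing a
    cached ``problem`` skips the mesh/operator setup when sweeping many
    realizations on the same mesh.
    """
    if problem is None:
        if not isinstance(mesh, StructuredMesh):
            mesh = build_mesh(mesh[0], mesh[1], micro.cell)
        problem = PeriodicCellProblem(mesh, nu=nu)
    G_px = modulus_raster(micro, materials, frequency)
    Geg = material_at_gauss(G_px, problem.mesh)
    sol = problem.solve(Geg, mode=(1, 2))
    G_eff = ComplexModulus.from_complex(sol.G_eff, frequency)
    meta = {
        "frequency_Hz": frequency,
        "mesh": (problem.mesh.nx, problem.mesh.ny),
        "nu": nu,
    }
    if micro.fat is not None:
        meta.update(
            fat_pattern=micro.fat.pattern.value,
            fat_target=micro.fat.target_mean,
            fat_realized=micro.fat.realized_mean,
            fat_seed=micro.fat.seed,
        )
    if micro.collagen is not None:
        meta.update(
            fibrosis_pattern=micro.collagen.pattern.value,
            cpa_target=micro.collagen.target_cpa,
            cpa_realized=micro.collagen.realized_cpa,
            fibrosis_seed=micro.collagen.seed,
        )
    return HomogenizationResult(
        G_eff=G_eff,
        tau_eff=relaxation_time(G_eff),
        frequency=frequency,
        E_column=sol.avg_stress.copy(),
        metadata=meta,
    )


@dataclass
class EnsembleSummary:
    """Statistics of homogenized moduli over seeded realizations."""

    n: int
    mean_G: complex  # Pa
    std_Gp: float
    std_Gpp: float
    mean_tau: float
    std_tau: float
    table: pd.DataFrame

    @property
    def mean_modulus(self) -> complex:
        return self.mean_G


def run_ensemble(
    n: int,
    base_seed: int = 0,
    fat_target: float = 0.0,
    cpa_target: float = 0.0,
    materials: MaterialSet | None = None,
    frequency: float = 100.0,
    mesh: tuple[int, int] = (40, 80),
    cell: UnitCellGeometry | None = None,
    fat_pattern: FatPattern = FatPattern.P1_CENTRAL,
    fibrosis_pattern: FibrosisPattern = FibrosisPattern.P1_PORTAL_PORTAL,
    nu: float = NU_DEFAULT,
) -> EnsembleSummary:
    """Homogenize ``n`` realizations with seeds base_seed .. base_seed+n-1."""
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    materials = materials or MaterialSet.default()
    cell = cell or UnitCellGeometry()
    fields = distance_fields(cell)
    region = classify_region(cell)
    m = build_mesh(mesh[0], mesh[1], cell)
    problem = PeriodicCellProblem(m, nu=nu)
    rows = []
    for i in range(n):
        seed = base_seed + i
        micro = build_microstructure(
            fat_target, cpa_target, seed=seed, cell=cell,
            fat_pattern=fat_pattern, fibrosis_pattern=fibrosis_pattern,
            fields=fields, region=region,
        )
        res = effective_modulus(micro, materials, frequency, problem=problem)
        rows.append(
            {
                "seed": seed,
                "fat_target": fat_target,
                "fat_realized": res.metadata.get("fat_realized", 0.0),
                "cpa_target": cpa_target,
                "cpa_realized": res.metadata.get("cpa_realized", 0.0),
                "freq_Hz": frequency,
                "Gp_Pa": res.G_eff.storage,
                "Gpp_Pa": res.G_eff.loss,
                "tau_s": res.tau_eff,
            }
        )
    df = pd.DataFrame(rows)
    return EnsembleSummary(
        n=n,
        mean_G=complex(df.Gp_Pa.mean(), df.Gpp_Pa.mean()),
        std_Gp=float(df.Gp_Pa.std(ddof=1)) if n > 1 else 0.0,
        std_Gpp=float(df.Gpp_Pa.std(ddof=1)) if n > 1 else 0.0,
        mean_tau=float(df.tau_s.mean()),
        std_tau=float(df.tau_s.std(ddof=1)) if n > 1 else 0.0,
        table=df,
    )


def bounds_check(
    G_eff: complex, Geg: np.ndarray
) -> dict:
    """Voigt/Reuss bracketing report for purely elastic microstructures.

    With real phase moduli the homogenized shear modulus must lie
    between the harmonic (Reuss) and arithmetic (Voigt) means of the
    Gauss-point moduli.  Returns the bounds, margins and a pass flag.
    """
    G = np.asarray(Geg)
    if np.abs(G.imag).max() > 1e-12 * np.abs(G.real).max():
        raise ValueError("bounds check requires purely elastic (real) moduli")
    g = G.real.ravel()
    voigt = float(g.mean())
    reuss = float(1.0 / np.mean(1.0 / g))
    val = float(np.real(G_eff))
    return {
        "reuss": reuss,
        "voigt": voigt,
        "value": val,
        "within": bool(reuss - 1e-9 * voigt <= val <= voigt + 1e-9 * voigt),
        "margin_lower": val - reuss,
        "margin_upper": voigt - val,
    }
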