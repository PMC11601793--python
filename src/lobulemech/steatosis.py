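"""Synthetic intralobular fat-fraction fields (steatosis patterns).

Fat accumulates in hepatocytes with a zonal gradient across the lobule.
Two idealized patterns are generated on the 80x160 raster:

* Pattern 1 (``P1_CENTRAL``): fat highest around the central vein
  (zone-3 predominant steatosis, the common presentation).
* Pattern 2 (``P2_BOUNDARY``): fat highest at the lobule boundary.

The noiseless profile is ``V = Vout + sqrt(xi) * (Vin - Vout)`` in the
bounded radial coordinate ``xi = d_edge / (d_edge + d_vein)`` (1 at the
lobule center, 0 on the hexagon boundary).  The endpoint fractions are
calibrated so the parenchyma-average matches a target mean fat content;
i.i.d. Gaussian noise (sigma = 0.05 fat-fraction units) models the
hepatocyte-scale randomness of deposition, after which the field is
clipped to the composite-sphere validity cap [0, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .geometry import (
    DistanceFields,
    RegionLabel,
    UnitCellGeometry,
    classify_region,
    distance_fields,
)
from .rheology import MaterialModel, complex_modulus, effective_fat_modulus

__all__ = [
    "FatPattern",
    "FatField",
    "radial_coordinate",
    "fat_profile",
    "calibrate_endpoints",
    "generate_fat_field",
    "fat_to_modulus_field",
]

FAT_CAP = 0.5  # composite-sphere theory validity limit
NOISE_SIGMA = 0.05  # additive Gaussian noise, absolute fat-fraction units


class FatPattern(str, Enum):
    P1_CENTRAL = "pattern1"
    P2_BOUNDARY = "pattern2"


def radial_coordinate(
    fields: DistanceFields, eps: float = 1e-12
) -> np.ndarray:
    """Bounded radial coordinate xi = d_edge / (d_edge + d_vein).

    xi -> 1 at the lobule center (on the central vein), xi = 0 on the
    hexagon boundary; monotone along every center-to-boundary ray.  The
    form is a bounded surrogate for the boundary-to-center distance ratio,
    well defined everywhere including the lobule center.
    """
    denom = fields.d_edge + fields.d_vein
    return fields.d_edge / np.maximum(denom, eps)


def fat_profile(xi, Vin: float, Vout: float):
    """Noiseless fat fraction: V = Vout + sqrt(xi) * (Vin - Vout)."""
    return Vout + np.sqrt(np.clip(xi, 0.0, 1.0)) * (Vin - Vout)


def _profile_mean(sqrt_xi_mean: float, Vin: float, Vout: float) -> float:
    # the profile is affine in (Vin, Vout); its parenchyma mean only
    # needs the mean of sqrt(xi)
    return Vout + sqrt_xi_mean * (Vin - Vout)


def calibrate_endpoints(
    target_mean: float,
    pattern: FatPattern,
    xi: np.ndarray,
    parenchyma: np.ndarray,
) -> tuple[float, float]:
    """Solve the profile endpoints so the parenchyma-mean hits the target.

    Pattern 1 fixes Vout = 0 and solves Vin (bisection on the mean
    residual); if the required Vin would exceed the 0.5 cap, Vin is
    clamped there and Vout is solved instead.  Pattern 2 swaps the roles.
    Deterministic given the grid.
    """
    if not 0.0 <= target_mean <= 0.4:
        raise ValueError("target mean fat must lie in [0, 0.4]")
    m = float(np.mean(np.sqrt(np.clip(xi[parenchyma], 0.0, 1.0))))

    def solve(lo_val, hi_val, f):
        if abs(f(lo_val)) < 1e-14:
            return lo_val
        return brentq(f, lo_val, hi_val, xtol=1e-12)

    if pattern == FatPattern.P1_CENTRAL:
        # mean = m * Vin for Vout = 0
        if _profile_mean(m, FAT_CAP, 0.0) >= target_mean:
            Vin = solve(0.0, FAT_CAP, lambda v: _profile_mean(m, v, 0.0) - target_mean)
            return float(Vin), 0.0
        Vin = FAT_CAP
        f = lambda v: _profile_mean(m, Vin, v) - target_mean
        if _profile_mean(m, Vin, FAT_CAP) < target_mean:
            raise ValueError("target mean fat unreachable even at the 0.5 cap")
        return Vin, float(solve(0.0, FAT_CAP, f))
    else:
        if _profile_mean(m, 0.0, FAT_CAP) >= target_mean:
            Vout = solve(0.0, FAT_CAP, lambda v: _profile_mean(m, 0.0, v) - target_mean)
            return 0.0, float(Vout)
        Vout = FAT_CAP
        f = lambda v: _profile_mean(m, v, Vout) - target_mean
        if _profile_mean(m, FAT_CAP, Vout) < target_mean:
            raise ValueError("target mean fat unreachable even at the 0.5 cap")
        return float(solve(0.0, FAT_CAP, f)), Vout


@dataclass
class FatField:
    """An 80x160 fat-fraction raster with its generation metadata."""

    grid: np.ndarray  # (ny, nx) fat fraction in [0, 0.5]
    pattern: FatPattern
    target_mean: float
    realized_mean: float
    Vin: float
    Vout: float
    noise_sigma: float
    seed: int | None


def generate_fat_field(
    target_mean: float,
    pattern: FatPattern = FatPattern.P1_CENTRAL,
    seed: int | None = 0,
    cell: UnitCellGeometry | None = None,
    nx: int = 80,
    ny: int = 160,
    noise_sigma: float = NOISE_SIGMA,
    fields: DistanceFields | None = None,
    region: np.ndarray | None = None,
    eligible: np.ndarray | None = None,
    profile: str = "sqrt",
) -> FatField:
    """Generate a seeded fat-fraction raster at a target mean fat content.

    ``eligible`` restricts the pixels that carry fat and enter the mean
    (default: all parenchyma pixels); the combined steatosis + fibrosis
    model passes parenchyma-minus-collagen here.  ``profile="linear"``
    switches the radial profile from sqrt(xi) to xi.
    """
    cell = cell or UnitCellGeometry()
    if fields is None:
        fields = distance_fields(cell, nx, ny)
    if region is None:
        region = classify_region(cell, nx=nx, ny=ny)
    parenchyma = region == RegionLabel.PARENCHYMA
    if eligible is None:
        eligible = parenchyma
    xi = radial_coordinate(fields)
    if profile == "linear":
        xi = xi**2  # sqrt(xi**2) = xi in fat_profile
    elif profile != "sqrt":
        raise ValueError("profile must be 'sqrt' or 'linear'")
    Vin, Vout = calibrate_endpoints(target_mean, pattern, xi, eligible)
    V = fat_profile(xi, Vin, Vout)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        V = V + rng.normal(0.0, noise_sigma, size=V.shape)
    V = np.clip(V, 0.0, FAT_CAP)
    V[~eligible] = 0.0
    realized = float(V[eligible].mean()) if eligible.any() else 0.0
    return FatField(
        grid=V,
        pattern=pattern,
        target_mean=target_mean,
        realized_mean=realized,
        Vin=Vin,
        Vout=Vout,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def fat_to_modulus_field(
    fat: FatField,
    matrix: MaterialModel,
    frequency: float,
    fat_model: MaterialModel | None = None,
    region: np.ndarray | None = None,
    lumen_factor: float = 1e-3,
) -> np.ndarray:
    """Map a fat-fraction raster to a complex shear-modulus raster (Pa).

    Each parenchyma pixel gets the composite-sphere effective modulus at
    its local fat fraction; lumen pixels get the very soft lumen modulus.
    """
    fat_model = fat_model or MaterialModel.viscous(0.4)
    Gm = complex_modulus(matrix, frequency).value
    Gi = complex_modulus(fat_model, frequency).value
    G = effective_fat_modulus(fat.grid, Gm, Gi)
    if region is not None:
        G = np.where(region == RegionLabel.PARENCHYMA, G, lumen_factor * Gm)
    return G
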