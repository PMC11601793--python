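"""Frequency-domain rheology of the tissue phases.

Every phase is described by a complex shear modulus G*(omega) = G' + iG''
(storage + loss, Pa).  Three generators cover the models used here:

* elastic             G* = G0
* Kelvin-Voigt        G* = G0 + i omega eta
* springpot/power law G* = c (i omega)^a,  0 <= a < 1

The local fat fraction is converted to a local effective complex modulus
with the generalized self-consistent (three-phase composite-sphere)
scheme of Christensen & Lo, specialized to incompressible phases and
extended to complex moduli by the elastic-viscoelastic correspondence
principle.  The scheme is the reason fat fraction is capped at 50%: the
composite-sphere construction loses validity beyond that packing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ModelKind",
    "MaterialModel",
    "ComplexModulus",
    "MaterialSet",
    "complex_modulus",
    "effective_fat_modulus",
    "relaxation_time",
]


class ModelKind(str, Enum):
    ELASTIC = "elastic"
    KELVIN_VOIGT = "kelvin_voigt"
    SPRINGPOT = "springpot"


@dataclass(frozen=True)
class MaterialModel:
    """A rheological generator for one phase.

    parameters by kind:
      ELASTIC      {"G0": Pa}
      KELVIN_VOIGT {"G0": Pa, "eta": Pa*s}
      SPRINGPOT    {"c": Pa*s^a, "a": dimensionless in [0, 1)}
    """

    kind: ModelKind
    parameters: dict

    def __post_init__(self):
        p = self.parameters
        if any(v < 0 for v in p.values()):
            raise ValueError("material parameters must be non-negative")
        if self.kind == ModelKind.SPRINGPOT and not 0 <= p["a"] < 1:
            raise ValueError("springpot power must satisfy 0 <= a < 1")

    @staticmethod
    def elastic(G0: float) -> "MaterialModel":
        return MaterialModel(ModelKind.ELASTIC, {"G0": G0})

    @staticmethod
    def kelvin_voigt(G0: float, eta: float) -> "MaterialModel":
        return MaterialModel(ModelKind.KELVIN_VOIGT, {"G0": G0, "eta": eta})

    @staticmethod
    def springpot(c: float, a: float) -> "MaterialModel":
        return MaterialModel(ModelKind.SPRINGPOT, {"c": c, "a": a})

    @staticmethod
    def viscous(eta: float) -> "MaterialModel":
        """Newtonian fluid, G* = i omega eta (Kelvin-Voigt with G0 = 0)."""
        return MaterialModel(ModelKind.KELVIN_VOIGT, {"G0": 0.0, "eta": eta})

    @staticmethod
    def from_dict(obj: dict) -> "MaterialModel":
        return MaterialModel(ModelKind(obj["kind"]), dict(obj["parameters"]))


@dataclass(frozen=True)
class ComplexModulus:
    """Complex shear modulus at one frequency (Pa, Hz)."""

    storage: float
    loss: float
    frequency: float

    def __post_init__(self):
        if not (np.isfinite(self.storage) and np.isfinite(self.loss)):
            raise ValueError("modulus must be finite")

    @property
    def value(self) -> complex:
        return complex(self.storage, self.loss)

    @staticmethod
    def from_complex(G: complex, frequency: float) -> "ComplexModulus":
        return ComplexModulus(float(np.real(G)), float(np.imag(G)), frequency)


def complex_modulus(model: MaterialModel, frequency: float) -> ComplexModulus:
    """Evaluate a phase model at a forcing frequency (Hz)."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * frequency
    p = model.parameters
    if model.kind == ModelKind.ELASTIC:
        G = complex(p["G0"], 0.0)
    elif model.kind == ModelKind.KELVIN_VOIGT:
        G = complex(p["G0"], w * p["eta"])
    elif model.kind == ModelKind.SPRINGPOT:
        a = p["a"]
        G = p["c"] * w**a * complex(np.cos(a * np.pi / 2), np.sin(a * np.pi / 2))
    else:  # pragma: no cover
        raise ValueError(f"unknown model kind {model.kind}")
    return ComplexModulus.from_complex(G, frequency)


def _gscm_coefficients(g, nu_i: float, nu_m: float, phi):
    """Quadratic coefficients of the generalized self-consistent scheme.

    ``g`` is the inclusion/matrix shear-modulus ratio (complex allowed),
    ``phi`` the inclusion volume fraction.  Returns (A, B, C) such that
    A (Geff/Gm)^2 + B (Geff/Gm) + C = 0.
    """
    gm1 = g - 1.0
    eta1 = gm1 * (49.0 - 50.0 * nu_i * nu_m) + 35.0 * g * (nu_i - 2.0 * nu_m) \
        + 35.0 * (2.0 * nu_i - nu_m)
    eta2 = 5.0 * nu_i * (g - 8.0) + 7.0 * (g + 4.0)
    eta3 = g * (8.0 - 10.0 * nu_m) + (7.0 - 5.0 * nu_m)

    p103 = phi ** (10.0 / 3.0)
    p73 = phi ** (7.0 / 3.0)
    p53 = phi ** (5.0 / 3.0)
    mid = 63.0 * gm1 * eta2 + 2.0 * eta1 * eta3

    A = (
        8.0 * gm1 * (4.0 - 5.0 * nu_m) * eta1 * p103
        - 2.0 * mid * p73
        + 252.0 * gm1 * eta2 * p53
        - 50.0 * gm1 * (7.0 - 12.0 * nu_m + 8.0 * nu_m**2) * eta2 * phi
        + 4.0 * (7.0 - 10.0 * nu_m) * eta2 * eta3
    )
    B = (
        -4.0 * gm1 * (1.0 - 5.0 * nu_m) * eta1 * p103
        + 4.0 * mid * p73
        - 504.0 * gm1 * eta2 * p53
        + 150.0 * gm1 * (3.0 - nu_m) * nu_m * eta2 * phi
        + 3.0 * (15.0 * nu_m - 7.0) * eta2 * eta3
    )
    C = (
        4.0 * gm1 * (5.0 * nu_m - 7.0) * eta1 * p103
        - 2.0 * mid * p73
        + 252.0 * gm1 * eta2 * p53
        + 25.0 * gm1 * (nu_m**2 - 7.0) * eta2 * phi
        - (7.0 + 5.0 * nu_m) * eta2 * eta3
    )
    return A, B, C


def effective_fat_modulus(
    phi,
    G_matrix: ComplexModulus | complex,
    G_fat: ComplexModulus | complex,
    nu_inclusion: float = 0.5,
    nu_matrix: float = 0.5,
):
    """Effective complex shear modulus of matrix with spherical fat inclusions.

    Generalized self-consistent (three-phase sphere) estimate for a
    volume fraction ``phi`` of spherical inclusions, both phases
    incompressible by default.  ``phi`` may be a scalar or an array; the
    root of the scheme's quadratic continuous with the phi -> 0 limit
    (effective modulus -> matrix modulus) is returned.

    Scalar ``phi`` with ComplexModulus inputs returns a ComplexModulus;
    array ``phi`` returns a complex ndarray in Pa.
    """
    scalar = np.isscalar(phi)
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr > 0.5):
        raise ValueError("fat fraction must lie in [0, 0.5]")

    wrap = isinstance(G_matrix, ComplexModulus)
    Gm = G_matrix.value if wrap else complex(G_matrix)
    Gi = G_fat.value if isinstance(G_fat, ComplexModulus) else complex(G_fat)
    if Gm == 0:
        raise ValueError("matrix modulus must be nonzero")

    g = Gi / Gm
    A, B, C = _gscm_coefficients(g, nu_inclusion, nu_matrix, phi_arr)
    A = np.asarray(A, dtype=complex)
    B = np.asarray(B, dtype=complex)
    C = np.asarray(C, dtype=complex)
    disc = np.sqrt(B * B - 4.0 * A * C)
    x1 = (-B + disc) / (2.0 * A)
    x2 = (-B - disc) / (2.0 * A)
    # select the physical branch: continuous with x -> 1 as phi -> 0
    x = np.where(np.abs(x1 - 1.0) <= np.abs(x2 - 1.0), x1, x2)
    # degenerate cases (identical phases) give A*1 + B*1 + C = 0 exactly
    if g == 1.0:
        x = np.ones_like(x)
    G_eff = x * Gm
    if scalar:
        G_eff = complex(G_eff)
        if wrap:
            return ComplexModulus.from_complex(G_eff, G_matrix.frequency)
        return G_eff
    return G_eff


def relaxation_time(G: ComplexModulus) -> float:
    """Effective relaxation time tau = G'' / (omega G'), seconds.

    The frequency-normalized viscosity-to-elasticity ratio; for a
    Kelvin-Voigt solid it reduces to eta / G0 at every frequency.
    """
    if G.storage <= 0:
        raise ValueError("relaxation time undefined for non-positive storage modulus")
    return G.loss / (2.0 * np.pi * G.frequency * G.storage)


@dataclass(frozen=True)
class MaterialSet:
    """The phase models of one simulation scenario.

    lumen_factor scales the matrix modulus for the central-vein and
    portal-triad lumen regions: the lumens are kept as very soft
    inclusions (not holes) so the periodic operator stays nonsingular
    while contributing essentially no stiffness.
    """

    matrix: MaterialModel
    fat: MaterialModel
    collagen: MaterialModel
    lumen_factor: float = 1e-3

    @staticmethod
    def default(
        collagen_G: float = 60e3,
        matrix: MaterialModel | None = None,
    ) -> "MaterialSet":
        """Healthy Kelvin-Voigt matrix (2 kPa, 0.8 Pa.s), viscous fat
        (0.4 Pa.s), elastic collagen (default 60 kPa)."""
        return MaterialSet(
            matrix=matrix or MaterialModel.kelvin_voigt(2000.0, 0.8),
            fat=MaterialModel.viscous(0.4),
            collagen=MaterialModel.elastic(collagen_G),
        )

    @staticmethod
    def powerlaw_matrix(collagen_G: float = 60e3) -> "MaterialSet":
        """Springpot matrix (c = 800, a = 0.15) used for the combined
        steatosis + fibrosis study."""
        return MaterialSet.default(
            collagen_G=collagen_G, matrix=MaterialModel.springpot(800.0, 0.15)
        )
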