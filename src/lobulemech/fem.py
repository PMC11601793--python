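"""Frequency-domain viscoelastic finite elements on the periodic cell.

The unit cell is meshed with a uniform grid of 8-node serendipity
quadrilaterals (QUAD8) under plane strain, integrated with 2x2 Gauss
quadrature (reduced for QUAD8, which also avoids volumetric locking at
the near-incompressible Poisson ratio used for soft tissue).  The
constitutive matrix at every Gauss point is ``D = G* M(nu)`` with the
complex shear modulus G* sampled from the nearest pixel of the 80x160
material raster and

    M(nu) = [[2(1-nu)/(1-2nu), 2nu/(1-2nu), 0],
             [2nu/(1-2nu), 2(1-nu)/(1-2nu), 0],
             [0, 0, 1]]

in Voigt order (e11, e22, gamma12).  Homogenization imposes a unit
macroscopic engineering shear as an eigenstrain and solves for the
periodic fluctuation: find periodic v with

    K v = -f,   f = integral BT D eps0 dY,  eps0 = [0, 0, 1]T,

where K is the stiffness reduced onto independent DOFs by tying each
right/top boundary node to its left/bottom partner and pinning one node
to remove rigid translation.  All arithmetic is complex; an equivalent
real 2x2-block formulation (storage/loss split) is provided for parity
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import UnitCellGeometry

__all__ = [
    "StructuredMesh",
    "PeriodicDofMap",
    "CellSolution",
    "build_mesh",
    "material_at_gauss",
    "PeriodicCellProblem",
]

NU_DEFAULT = 0.4999  # near-incompressible plane strain

# SuperLU settings: the stiffness is complex-symmetric with a dominant
# diagonal from the near-incompressible penalty; symmetric-mode minimum
# degree with diagonal-preference pivoting avoids the massive fill that
# default partial pivoting produces here, at no loss of accuracy
# (relative residuals stay ~1e-12).
_SPLU_OPTS = dict(
    permc_spec="MMD_AT_PLUS_A",
    diag_pivot_thresh=0.01,
    options=dict(SymmetricMode=True),
)

# 2x2 Gauss rule on [-1, 1]^2
_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GAUSS_XI, _GAUSS_ETA = [a.ravel() for a in np.meshgrid(_GP, _GP)]
_GAUSS_W = np.ones(4)


def _quad8_dshape(xi: float, eta: float) -> np.ndarray:
    """Parent-coordinate derivatives dN/d(xi, eta), shape (2, 8).

    Node order: corners CCW from (-1,-1), then midsides bottom, right,
    top, left.
    """
    dN = np.empty((2, 8))
    dN[0, 0] = 0.25 * (1 - eta) * (2 * xi + eta)
    dN[1, 0] = 0.25 * (1 - xi) * (xi + 2 * eta)
    dN[0, 1] = 0.25 * (1 - eta) * (2 * xi - eta)
    dN[1, 1] = 0.25 * (1 + xi) * (2 * eta - xi)
    dN[0, 2] = 0.25 * (1 + eta) * (2 * xi + eta)
    dN[1, 2] = 0.25 * (1 + xi) * (2 * eta + xi)
    dN[0, 3] = 0.25 * (1 + eta) * (2 * xi - eta)
    dN[1, 3] = 0.25 * (1 - xi) * (2 * eta - xi)
    dN[0, 4] = -xi * (1 - eta)
    dN[1, 4] = -0.5 * (1 - xi * xi)
    dN[0, 5] = 0.5 * (1 - eta * eta)
    dN[1, 5] = -eta * (1 + xi)
    dN[0, 6] = -xi * (1 + eta)
    dN[1, 6] = 0.5 * (1 - xi * xi)
    dN[0, 7] = -0.5 * (1 - eta * eta)
    dN[1, 7] = -eta * (1 - xi)
    return dN


def constitutive_matrix(nu: float) -> np.ndarray:
    """Plane-strain Voigt matrix M(nu) such that D = G* M(nu)."""
    if not 0 <= nu < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    a = 2.0 * (1.0 - nu) / (1.0 - 2.0 * nu)
    b = 2.0 * nu / (1.0 - 2.0 * nu)
    return np.array([[a, b, 0.0], [b, a, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class StructuredMesh:
    """Uniform QUAD8 mesh of the rectangular cell.

    Nodes live on a (2nx+1) x (2ny+1) lattice with element-center
    positions removed (serendipity elements have no interior node).
    """

    nx: int
    ny: int
    cell: UnitCellGeometry
    nodes: np.ndarray = field(init=False, repr=False)  # (N, 2) mm
    conn: np.ndarray = field(init=False, repr=False)  # (nelem, 8)
    node_id: np.ndarray = field(init=False, repr=False)  # lattice -> id, -1 at holes

    def __post_init__(self):
        nx, ny = self.nx, self.ny
        if nx < 1 or ny < 1:
            raise ValueError("element counts must be positive")
        w, h = self.cell.width, self.cell.height
        li = np.arange(2 * nx + 1)
        lj = np.arange(2 * ny + 1)
        I, J = np.meshgrid(li, lj, indexing="ij")
        hole = (I % 2 == 1) & (J % 2 == 1)
        node_id = -np.ones(I.shape, dtype=np.int64)
        node_id[~hole] = np.arange((~hole).sum())
        x = I[~hole] * w / (2 * nx)
        y = J[~hole] * h / (2 * ny)
        self.nodes = np.column_stack([x, y])
        self.node_id = node_id
        ex, ey = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        ex, ey = ex.ravel(), ey.ravel()
        bi, bj = 2 * ex, 2 * ey
        conn = np.stack(
            [
                node_id[bi, bj],
                node_id[bi + 2, bj],
                node_id[bi + 2, bj + 2],
                node_id[bi, bj + 2],
                node_id[bi + 1, bj],
                node_id[bi + 2, bj + 1],
                node_id[bi + 1, bj + 2],
                node_id[bi, bj + 1],
            ],
            axis=1,
        )
        self.conn = conn
        self.dx = w / nx
        self.dy = h / ny

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.conn)

    def element_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(ex, ey) per element, matching connectivity order."""
        ex, ey = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        return ex.ravel(), ey.ravel()

    def gauss_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical Gauss-point coordinates, shape (nelem, 4) each."""
        ex, ey = self.element_index()
        gx = (ex[:, None] + 0.5 + 0.5 * _GAUSS_XI[None, :]) * self.dx
        gy = (ey[:, None] + 0.5 + 0.5 * _GAUSS_ETA[None, :]) * self.dy
        return gx, gy


def build_mesh(nx: int, ny: int, cell: UnitCellGeometry) -> StructuredMesh:
    """Uniform nx x ny QUAD8 mesh spanning the unit cell."""
    return StructuredMesh(nx, ny, cell)


def material_at_gauss(G_px: np.ndarray, mesh: StructuredMesh) -> np.ndarray:
    """Sample the (ny_px, nx_px) modulus raster at every Gauss point.

    Nearest-grid-point lookup (cell-centered pixels); returns complex
    array of shape (nelem, 4).
    """
    ny_px, nx_px = G_px.shape
    gx, gy = mesh.gauss_coords()
    ix = np.clip((gx / mesh.cell.width * nx_px).astype(int), 0, nx_px - 1)
    iy = np.clip((gy / mesh.cell.height * ny_px).astype(int), 0, ny_px - 1)
    return np.asarray(G_px, dtype=complex)[iy, ix]


@dataclass
class PeriodicDofMap:
    """Reduction of mesh DOFs onto the independent periodic set."""

    master_of: np.ndarray  # (N,) master node of every node
    T: sp.csr_matrix  # (2N, n_red) 0/1 expansion operator
    pinned: int  # node whose displacement is fixed to zero

    @property
    def n_reduced(self) -> int:
        return self.T.shape[1]


def build_dofmap(mesh: StructuredMesh, pin: bool = True) -> PeriodicDofMap:
    """Tie right->left and top->bottom boundary nodes; pin one node."""
    nid = mesh.node_id
    nx2, ny2 = nid.shape[0] - 1, nid.shape[1] - 1
    master_lattice = np.array(nid)
    # right edge -> left edge, top edge -> bottom edge (corner -> origin)
    master_of = np.arange(mesh.n_nodes)
    for i in range(nx2 + 1):
        for j in range(ny2 + 1):
            n = nid[i, j]
            if n < 0:
                continue
            mi = 0 if i == nx2 else i
            mj = 0 if j == ny2 else j
            master_of[n] = nid[mi, mj]
    del master_lattice
    masters = np.unique(master_of)
    pinned = int(nid[0, 0]) if pin else -1
    red_index = -np.ones(mesh.n_nodes, dtype=np.int64)
    k = 0
    for m in masters:
        if m == pinned:
            continue
        red_index[m] = k
        k += 1
    rows, cols = [], []
    for n in range(mesh.n_nodes):
        m = master_of[n]
        if m == pinned:
            continue
        for c in (0, 1):
            rows.append(2 * n + c)
            cols.append(2 * red_index[m] + c)
    T = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(2 * mesh.n_nodes, 2 * k)
    )
    return PeriodicDofMap(master_of=master_of, T=T, pinned=pinned)


@dataclass
class CellSolution:
    """Solution of the periodic cell problem for one macro-strain mode."""

    v: np.ndarray  # (2N,) complex periodic fluctuation displacement
    mode: tuple[int, int]
    avg_stress: np.ndarray  # (3,) complex volume-averaged stress (Pa)
    G_eff: complex  # homogenized shear modulus for mode (1,2) (Pa)


_MODE_EPS0 = {(1, 1): [1.0, 0.0, 0.0], (2, 2): [0.0, 1.0, 0.0], (1, 2): [0.0, 0.0, 1.0]}


class PeriodicCellProblem:
    """Assembled periodic cell ready to solve for any modulus raster.

    Caches everything that depends only on mesh geometry (shape-function
    integrals, periodic reduction operator), so repeated realizations
    only pay for assembly and factorization.
    """

    def __init__(
        self,
        mesh: StructuredMesh,
        nu: float = NU_DEFAULT,
    ):
        self.mesh = mesh
        self.nu = nu
        self.M = constitutive_matrix(nu)
        self.dofmap = build_dofmap(mesh)
        self.detJ = mesh.dx * mesh.dy / 4.0
        # B matrices (3 x 16) at the four Gauss points; uniform elements
        # share one Jacobian
        self.B = np.zeros((4, 3, 16))
        for g, (xi, eta) in enumerate(zip(_GAUSS_XI, _GAUSS_ETA)):
            dN = _quad8_dshape(xi, eta)
            dNdx = dN[0] * 2.0 / mesh.dx
            dNdy = dN[1] * 2.0 / mesh.dy
            self.B[g, 0, 0::2] = dNdx
            self.B[g, 1, 1::2] = dNdy
            self.B[g, 2, 0::2] = dNdy
            self.B[g, 2, 1::2] = dNdx
        # per-gauss element matrices: C_g = w detJ B^T M B  (16 x 16)
        self.Cg = np.einsum(
            "gai,ab,gbj->gij", self.B, self.M, self.B
        ) * self.detJ
        # element DOF indices (nelem, 16)
        conn = mesh.conn
        edofs = np.empty((mesh.n_elements, 16), dtype=np.int64)
        edofs[:, 0::2] = 2 * conn
        edofs[:, 1::2] = 2 * conn + 1
        self.edofs = edofs
        self._rows = np.repeat(edofs, 16, axis=1).ravel()
        self._cols = np.tile(edofs, (1, 16)).ravel()
        self.area = mesh.cell.area

    # -- assembly -------------------------------------------------------
    def assemble(self, Geg: np.ndarray, mode: tuple[int, int] = (1, 2)):
        """Reduced complex stiffness and eigenstrain load for one mode.

        Geg: complex (nelem, 4) shear modulus at Gauss points.
        Returns (K_red csc, f_red, f_full).
        """
        Geg = np.asarray(Geg, dtype=complex)
        Ke = np.einsum("eg,gij->eij", Geg, self.Cg)
        K = sp.coo_matrix(
            (Ke.ravel(), (self._rows, self._cols)),
            shape=(2 * self.mesh.n_nodes,) * 2,
        ).tocsc()
        eps0 = np.array(_MODE_EPS0[mode])
        # b_g = w detJ B^T M eps0
        bg = np.einsum("gai,ab,b->gi", self.B, self.M, eps0) * self.detJ
        fe = np.einsum("eg,gi->ei", Geg, bg)
        f = np.zeros(2 * self.mesh.n_nodes, dtype=complex)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        T = self.dofmap.T
        return (T.T @ K @ T).tocsc(), T.T @ f, f

    # -- solves ---------------------------------------------------------
    def solve(self, Geg: np.ndarray, mode: tuple[int, int] = (1, 2)) -> CellSolution:
        """Direct sparse solve of the periodic fluctuation problem."""
        K_red, f_red, _ = self.assemble(Geg, mode)
        try:
            lu = splu(K_red, **_SPLU_OPTS)
            v_red = lu.solve(-f_red)
            # two steps of iterative refinement: drives the residual of the
            # ill-conditioned near-incompressible system to ~1e-12 relative
            for _ in range(2):
                v_red += lu.solve(-f_red - K_red @ v_red)
        except RuntimeError as err:  # pragma: no cover
            raise RuntimeError(f"periodic cell solve failed: {err}") from err
        v = self.dofmap.T @ v_red
        avg = self.average_stress(Geg, v, mode)
        return CellSolution(v=v, mode=mode, avg_stress=avg, G_eff=avg[2])

    def solve_real_block(self, Geg: np.ndarray, mode: tuple[int, int] = (1, 2)):
        """Equivalent real-arithmetic solve with the storage/loss block
        operator [[K', -K''], [K'', K']]; returns the complex fluctuation.

        Exists to prove the complex formulation equals the split
        real/imaginary formulation used by real-only FE codes.
        """
        Geg = np.asarray(Geg, dtype=complex)
        Kr_red, fr_red, _ = self.assemble(Geg.real.astype(complex), mode)
        Ki_red, fi_red, _ = self.assemble(1j * Geg.imag.astype(complex), mode)
        Kr = Kr_red.real
        Ki = Ki_red.imag
        KB = sp.bmat([[Kr, -Ki], [Ki, Kr]]).tocsc()
        fB = np.concatenate([fr_red.real, fi_red.imag])
        luB = splu(KB, **_SPLU_OPTS)
        vB = luB.solve(-fB)
        for _ in range(2):
            vB += luB.solve(-fB - KB @ vB)
        n = Kr.shape[0]
        v_red = vB[:n] + 1j * vB[n:]
        return self.dofmap.T @ v_red

    # -- postprocessing -------------------------------------------------
    def average_stress(
        self, Geg: np.ndarray, v: np.ndarray, mode: tuple[int, int] = (1, 2)
    ) -> np.ndarray:
        """Volume-averaged complex stress by Gauss quadrature of
        sigma = D (eps0 + B v)."""
        Geg = np.asarray(Geg, dtype=complex)
        eps0 = np.array(_MODE_EPS0[mode])
        ve = v[self.edofs]  # (nelem, 16)
        eps = np.einsum("gai,ei->ega", self.B, ve) + eps0  # (nelem, 4, 3)
        sig = np.einsum("eg,ab,egb->ega", Geg, self.M, eps)
        return sig.sum(axis=(0, 1)) * self.detJ / self.area

    def homogenized_shear_modulus(self, Geg: np.ndarray, v: np.ndarray) -> complex:
        """Homogenized shear modulus by the energy/load-vector identity.

        Independent of :meth:`average_stress`: uses
        <sigma_12> = (integral of D_33 G dY + f . v) / |Y|, the
        integrand-average form of the homogenized tensor entry.
        """
        Geg = np.asarray(Geg, dtype=complex)
        eps0 = np.array(_MODE_EPS0[(1, 2)])
        bg = np.einsum("gai,ab,b->gi", self.B, self.M, eps0) * self.detJ
        fe = np.einsum("eg,gi->ei", Geg, bg)
        f = np.zeros(2 * self.mesh.n_nodes, dtype=complex)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        # D eps0 averaged: component 33 is G * M[2,2] = G
        const = Geg.sum() * self.detJ * self.M[2, 2]
        return (const + f @ v) / self.area

    def periodicity_residual(self, v: np.ndarray) -> float:
        """Max mismatch of the fluctuation across tied boundary pairs
        relative to the field magnitude (zero by construction)."""
        m = self.dofmap.master_of
        pairs = np.flatnonzero(m != np.arange(len(m)))
        if pairs.size == 0:
            return 0.0
        dv = v.reshape(-1, 2)[pairs] - v.reshape(-1, 2)[m[pairs]]
        scale = max(np.abs(v).max(), 1e-300)
        return float(np.abs(dv).max() / scale)
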