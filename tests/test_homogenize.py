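"""Homogenization pipeline: microstructure assembly, bounds, ensembles."""

import numpy as np
import pytest

from lobulemech.fem import PeriodicCellProblem, build_mesh, material_at_gauss
from lobulemech.geometry import RegionLabel, UnitCellGeometry, classify_region, distance_fields
from lobulemech.homogenize import (
    Microstructure,
    bounds_check,
    build_microstructure,
    effective_modulus,
    modulus_raster,
    run_ensemble,
)
from lobulemech.rheology import MaterialModel, MaterialSet, complex_modulus


@pytest.fixture(scope="module")
def materials():
    return MaterialSet.default()


class TestMicrostructure:
    def test_empty_microstructure_is_matrix_with_lumens(self, cell, region, materials):
        micro = build_microstructure(0.0, 0.0, seed=0, cell=cell, region=region)
        G = modulus_raster(micro, materials, 100.0)
        Gm = complex_modulus(materials.matrix, 100.0).value
        paren = region == RegionLabel.PARENCHYMA
        assert np.allclose(G[paren], Gm)
        assert np.allclose(G[~paren], 1e-3 * Gm)

    def test_collagen_pixels_take_collagen_modulus(self, cell, fields, region, materials):
        micro = build_microstructure(
            0.0, 0.10, seed=1, cell=cell, fields=fields, region=region
        )
        G = modulus_raster(micro, materials, 100.0)
        assert np.allclose(G[micro.collagen.grid], 60e3)

    def test_combined_fat_renormalization_accounting(self, cell, fields, region):
        # overall fat budget (fat per cell-parenchyma) matches the
        # unrenormalized target despite collagen displacing tissue
        micro = build_microstructure(
            0.15, 0.10, seed=3, cell=cell, fields=fields, region=region
        )
        paren = region == RegionLabel.PARENCHYMA
        overall = micro.fat.grid[paren].sum() / paren.sum()
        assert overall == pytest.approx(0.15, abs=0.01)
        # and the mean over remaining tissue is higher by 1/(1-CPA)
        assert micro.fat.target_mean == pytest.approx(
            0.15 / (1 - micro.collagen.realized_cpa)
        )

    def test_no_fat_on_collagen(self, cell, fields, region):
        micro = build_microstructure(
            0.2, 0.08, seed=5, cell=cell, fields=fields, region=region
        )
        assert (micro.fat.grid[micro.collagen.grid] == 0).all()


class TestEffectiveModulus:
    def test_homogeneous_patch_without_lumens(self, materials):
        cell = UnitCellGeometry(vein_radius=0.0, triad_radius=0.0)
        micro = build_microstructure(0.0, 0.0, seed=0, cell=cell)
        res = effective_modulus(micro, materials, 100.0, mesh=(10, 20))
        Gm = complex_modulus(materials.matrix, 100.0).value
        assert res.value == pytest.approx(Gm, rel=1e-10)
        assert res.tau_eff == pytest.approx(0.8 / 2000.0, rel=1e-9)

    def test_lumens_reduce_loss_below_matrix(self, cell, materials, working_problem):
        micro = build_microstructure(0.0, 0.0, seed=0, cell=cell)
        res = effective_modulus(micro, materials, 100.0, problem=working_problem)
        Gm = complex_modulus(materials.matrix, 100.0).value
        assert res.G_eff.loss < Gm.imag
        assert res.G_eff.storage < Gm.real

    def test_scale_invariance(self, materials):
        # geometry in mm scaled by 3: same dimensionless cell, same modulus
        r1 = effective_modulus(
            build_microstructure(0.0, 0.0, seed=0, cell=UnitCellGeometry(1.0)),
            materials, 100.0, mesh=(10, 20),
        )
        r3 = effective_modulus(
            build_microstructure(
                0.0, 0.0, seed=0, cell=UnitCellGeometry(3.0, 0.15, 0.12)
            ),
            materials, 100.0, mesh=(10, 20),
        )
        assert r1.value == pytest.approx(r3.value, rel=1e-9)

    def test_phase_interchange_identity(self, cell, fields, region):
        # collagen with matrix properties == no collagen at all
        plain = MaterialSet.default()
        micro0 = build_microstructure(0.0, 0.0, seed=2, cell=cell, region=region)
        base = effective_modulus(micro0, plain, 100.0, mesh=(10, 20))
        fake = MaterialSet(
            matrix=plain.matrix,
            fat=plain.fat,
            collagen=MaterialModel.kelvin_voigt(2000.0, 0.8),
        )
        micro = build_microstructure(
            0.0, 0.10, seed=2, cell=cell, fields=fields, region=region
        )
        res = effective_modulus(micro, fake, 100.0, mesh=(10, 20))
        assert res.value == pytest.approx(base.value, rel=1e-9)


class TestBounds:
    def test_homogeneous_bounds_degenerate(self):
        rep = bounds_check(5000.0 + 0j, np.full((10, 4), 5000.0 + 0j))
        assert rep["reuss"] == pytest.approx(rep["voigt"]) == pytest.approx(5000.0)
        assert rep["within"]

    def test_two_phase_bounds_arithmetic(self):
        g = np.where(np.arange(40).reshape(10, 4) < 4, 60e3, 2e3) + 0j
        rep = bounds_check(3000.0 + 0j, g)
        assert rep["voigt"] == pytest.approx(0.1 * 60e3 + 0.9 * 2e3)
        assert rep["reuss"] == pytest.approx(1 / (0.1 / 60e3 + 0.9 / 2e3))

    def test_random_elastic_microstructures_respect_bounds(self, cell, rng):
        mesh = build_mesh(10, 20, cell)
        prob = PeriodicCellProblem(mesh)
        for _ in range(20):
            frac = rng.uniform(0.05, 0.5)
            G_px = np.where(rng.random((40, 20)) < frac, 60e3, 2e3).astype(complex)
            Geg = material_at_gauss(G_px, mesh)
            sol = prob.solve(Geg)
            rep = bounds_check(sol.G_eff, Geg)
            assert rep["within"], rep

    def test_complex_input_rejected(self):
        with pytest.raises(ValueError):
            bounds_check(1.0, np.full((2, 4), 1.0 + 1.0j))


class TestEnsemble:
    def test_single_realization_matches_direct_call(self, cell, fields, region, materials):
        s = run_ensemble(1, base_seed=11, cpa_target=0.05, materials=materials,
                         mesh=(10, 20))
        micro = build_microstructure(
            0.0, 0.05, seed=11, cell=cell, fields=fields, region=region
        )
        res = effective_modulus(micro, materials, 100.0, mesh=(10, 20))
        assert s.mean_G == pytest.approx(res.value)
        assert s.std_Gp == 0.0

    def test_deterministic_microstructure_zero_std(self, materials):
        s = run_ensemble(3, base_seed=0, materials=materials, mesh=(10, 20))
        assert s.std_Gp == pytest.approx(0.0, abs=1e-9)
        assert s.n == 3 and len(s.table) == 3

    def test_invalid_size(self, materials):
        with pytest.raises(ValueError):
            run_ensemble(0, materials=materials)
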