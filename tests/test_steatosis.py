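"""Fat-field generation: radial profile, calibration, noise, modulus mapping."""

import numpy as np
import pytest

from lobulemech.geometry import RegionLabel
from lobulemech.rheology import MaterialModel, complex_modulus, effective_fat_modulus
from lobulemech.steatosis import (
    FatPattern,
    calibrate_endpoints,
    fat_profile,
    fat_to_modulus_field,
    generate_fat_field,
    radial_coordinate,
)


class TestRadialCoordinate:
    def test_range_and_anchors(self, fields):
        xi = radial_coordinate(fields)
        assert xi.min() >= 0 and xi.max() <= 1
        # near-vein pixels approach 1, near-edge pixels approach 0
        assert xi[fields.d_vein < 0.02].min() > 0.9
        assert xi[fields.d_edge < 0.005].max() < 0.1

    def test_continuity_between_neighbors(self, fields):
        xi = radial_coordinate(fields)
        assert np.abs(np.diff(xi, axis=0)).max() < 0.1
        assert np.abs(np.diff(xi, axis=1)).max() < 0.1


class TestFatProfile:
    def test_endpoint_identities(self):
        assert fat_profile(0.0, 0.4, 0.1) == pytest.approx(0.1)
        assert fat_profile(1.0, 0.4, 0.1) == pytest.approx(0.4)

    def test_constant_when_endpoints_equal(self):
        xi = np.linspace(0, 1, 11)
        assert np.allclose(fat_profile(xi, 0.3, 0.3), 0.3)

    def test_sqrt_shape(self):
        # xi = 0.25 -> sqrt gives half of the span
        assert fat_profile(0.25, 0.4, 0.0) == pytest.approx(0.2)


class TestCalibration:
    def test_zero_target(self, fields, region):
        xi = radial_coordinate(fields)
        paren = region == RegionLabel.PARENCHYMA
        assert calibrate_endpoints(0.0, FatPattern.P1_CENTRAL, xi, paren) == (0.0, 0.0)

    @pytest.mark.parametrize("pattern", list(FatPattern))
    @pytest.mark.parametrize("target", [0.05, 0.2, 0.4])
    def test_noiseless_mean_hits_target(self, fields, region, pattern, target):
        xi = radial_coordinate(fields)
        paren = region == RegionLabel.PARENCHYMA
        Vin, Vout = calibrate_endpoints(target, pattern, xi, paren)
        V = fat_profile(xi, Vin, Vout)
        assert V[paren].mean() == pytest.approx(target, abs=1e-4)
        assert 0 <= min(Vin, Vout) and max(Vin, Vout) <= 0.5

    def test_pattern_orientation(self, fields, region):
        xi = radial_coordinate(fields)
        paren = region == RegionLabel.PARENCHYMA
        Vin1, Vout1 = calibrate_endpoints(0.2, FatPattern.P1_CENTRAL, xi, paren)
        assert Vin1 > Vout1
        Vin2, Vout2 = calibrate_endpoints(0.2, FatPattern.P2_BOUNDARY, xi, paren)
        assert Vout2 > Vin2

    def test_monotone_in_target(self, fields, region):
        xi = radial_coordinate(fields)
        paren = region == RegionLabel.PARENCHYMA
        vins = [
            calibrate_endpoints(t, FatPattern.P1_CENTRAL, xi, paren)[0]
            for t in (0.05, 0.1, 0.2, 0.3)
        ]
        assert np.all(np.diff(vins) > 0)

    def test_out_of_range_target_rejected(self, fields, region):
        xi = radial_coordinate(fields)
        with pytest.raises(ValueError):
            calibrate_endpoints(0.45, FatPattern.P1_CENTRAL, xi, region == 0)


class TestGenerateFatField:
    def test_determinism(self, cell, fields, region):
        a = generate_fat_field(0.2, seed=7, cell=cell, fields=fields, region=region)
        b = generate_fat_field(0.2, seed=7, cell=cell, fields=fields, region=region)
        assert np.array_equal(a.grid, b.grid)

    def test_cap_and_lumen_zeroing(self, cell, fields, region):
        f = generate_fat_field(0.4, seed=3, cell=cell, fields=fields, region=region)
        assert f.grid.max() <= 0.5
        assert f.grid.min() >= 0.0
        assert (f.grid[region != RegionLabel.PARENCHYMA] == 0).all()

    def test_zero_noise_equals_profile(self, cell, fields, region):
        f = generate_fat_field(
            0.2, seed=5, cell=cell, fields=fields, region=region, noise_sigma=0.0
        )
        xi = radial_coordinate(fields)
        expect = fat_profile(xi, f.Vin, f.Vout)
        paren = region == RegionLabel.PARENCHYMA
        assert np.allclose(f.grid[paren], expect[paren])

    def test_realized_mean_near_target_across_seeds(self, cell, fields, region):
        # clipping at 0 and 0.5 biases the mean slightly; stays within 0.01
        means = [
            generate_fat_field(0.2, seed=s, cell=cell, fields=fields, region=region).realized_mean
            for s in range(10)
        ]
        assert abs(np.mean(means) - 0.2) < 0.01
        assert all(abs(m - 0.2) < 0.01 for m in means)

    def test_pattern_contrast(self, cell, fields, region):
        xi = radial_coordinate(fields)
        paren = region == RegionLabel.PARENCHYMA
        inner = paren & (xi > 0.8)
        outer = paren & (xi < 0.2)
        f1 = generate_fat_field(
            0.2, FatPattern.P1_CENTRAL, seed=1, cell=cell, fields=fields, region=region
        )
        assert f1.grid[inner].mean() > f1.grid[outer].mean()
        f2 = generate_fat_field(
            0.2, FatPattern.P2_BOUNDARY, seed=1, cell=cell, fields=fields, region=region
        )
        assert f2.grid[inner].mean() < f2.grid[outer].mean()

    def test_linear_profile_switch(self, cell, fields, region):
        f = generate_fat_field(
            0.2, seed=5, cell=cell, fields=fields, region=region,
            noise_sigma=0.0, profile="linear",
        )
        xi = radial_coordinate(fields)
        paren = region == RegionLabel.PARENCHYMA
        expect = f.Vout + xi * (f.Vin - f.Vout)
        assert np.allclose(f.grid[paren], expect[paren])


class TestFatToModulus:
    def test_zero_fat_gives_uniform_matrix(self, cell, fields, region):
        f = generate_fat_field(0.0, seed=0, cell=cell, fields=fields, region=region,
                               noise_sigma=0.0)
        matrix = MaterialModel.kelvin_voigt(2000.0, 0.8)
        G = fat_to_modulus_field(f, matrix, 100.0, region=region)
        Gm = complex_modulus(matrix, 100.0).value
        paren = region == RegionLabel.PARENCHYMA
        assert np.allclose(G[paren], Gm)
        assert np.allclose(G[~paren], 1e-3 * Gm)

    def test_pixelwise_matches_scalar_oracle(self, cell, fields, region, rng):
        f = generate_fat_field(0.25, seed=2, cell=cell, fields=fields, region=region)
        matrix = MaterialModel.kelvin_voigt(2000.0, 0.8)
        G = fat_to_modulus_field(f, matrix, 100.0)
        Gm = complex_modulus(matrix, 100.0).value
        Gi = complex_modulus(MaterialModel.viscous(0.4), 100.0).value
        iy = rng.integers(0, f.grid.shape[0], 10)
        ix = rng.integers(0, f.grid.shape[1], 10)
        for i, j in zip(iy, ix):
            assert G[i, j] == pytest.approx(
                effective_fat_modulus(f.grid[i, j], Gm, Gi)
            )

    def test_storage_varies_more_than_loss(self, cell, fields, region):
        # at 100 Hz with the Kelvin-Voigt matrix the storage modulus spans a
        # much wider relative range across the lobule than the loss modulus
        f = generate_fat_field(0.16, seed=4, cell=cell, fields=fields, region=region)
        matrix = MaterialModel.kelvin_voigt(2000.0, 0.8)
        G = fat_to_modulus_field(f, matrix, 100.0, region=region)
        paren = region == RegionLabel.PARENCHYMA
        rng_p = np.ptp(G.real[paren]) / np.abs(G.real[paren]).mean()
        rng_pp = np.ptp(G.imag[paren]) / np.abs(G.imag[paren]).mean()
        assert rng_p > 2 * rng_pp
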