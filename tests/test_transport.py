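import numpy as np
import pytest
from scipy.integrate import quad

from kvdose import _kernels
from kvdose.materials import MaterialTable
from kvdose.phantom import (VoxelPhantom, slab_phantom, transmission_pair,
                            water_phantom)
from kvdose.spectrum import BeamSpectrum
from kvdose.synthetic_data import toy_material
from kvdose.transport import (BeamSource, DoseGrid, EnergyConservationError,
                              SimulationConfig, central_axis, in_field_mask,
                              primary_kerma_analytic, read_3ddose,
                              sample_compton, simulate, write_3ddose)

MEC2 = 510.998950


def mono(e_keV):
    return BeamSpectrum(kvp=e_keV + 1.0,
                        bin_edges=np.array([e_keV - 0.1, e_keV + 0.1]),
                        fluence=np.array([1.0]))


def toy_phantom(material, nx=6, ny=6, nz=16, dx=0.5, dy=0.5, dz=1.0):
    mat = np.zeros((nx, ny, nz), np.int8)
    den = np.full((nx, ny, nz), material.density)
    return VoxelPhantom([material], mat, den, dx, dy, dz)


class TestSimulate:
    def test_energy_conservation_and_determinism(self, mono_spectrum):
        ph, _ = transmission_pair()
        src = BeamSource(spectrum=mono_spectrum)
        cfg = SimulationConfig(n_histories=50_000, rng_seed=11)
        a = simulate(src, ph, cfg)
        b = simulate(src, ph, cfg)
        assert a.energy_balance <= 1e-6
        np.testing.assert_array_equal(a.dose, b.dose)
        np.testing.assert_array_equal(a.rel_uncertainty, b.rel_uncertainty)

    def test_different_seeds_differ(self, mono_spectrum):
        ph, _ = transmission_pair()
        src = BeamSource(spectrum=mono_spectrum)
        a = simulate(src, ph, SimulationConfig(n_histories=20_000, rng_seed=1))
        b = simulate(src, ph, SimulationConfig(n_histories=20_000, rng_seed=2))
        assert not np.array_equal(a.dose, b.dose)

    def test_pure_photoelectric_toy_terminates_every_history(self):
        """With a photoelectric-only medium nothing scatters: no energy
        is discarded, the audit closes, and no dose appears outside the
        geometric beam cone."""
        pts = [(5.0, 0.5), (150.0, 0.5)]
        toy = toy_material(pts, [(5.0, 0.4), (150.0, 0.4)],
                           partial_split=(1.0, 0.0, 0.0))
        # shallow grid: the beam cone stays inside the lateral extent
        ph = toy_phantom(toy, nz=8, dz=0.5)
        src = BeamSource(spectrum=mono(60.0))
        g = simulate(src, ph, SimulationConfig(n_histories=30_000, rng_seed=5))
        assert g.discarded_keV == 0.0
        assert g.deposited_keV + g.escaped_keV == pytest.approx(
            g.emitted_keV, rel=1e-9)
        # photons never scatter, so the lateral corner columns (strictly
        # outside the beam cone) must stay at zero dose
        assert np.all(g.dose[0, 0, :] == 0.0)
        assert np.all(g.dose[-1, -1, :] == 0.0)
        assert in_field_mask(src, ph)[3, 3, :].all()

    def test_scatter_only_adds_dose(self, calibrated_beams):
        _, spec = calibrated_beams[100]
        ph, _ = transmission_pair()
        src = BeamSource(spectrum=spec)
        on = simulate(src, ph, SimulationConfig(n_histories=150_000,
                                                rng_seed=21))
        off = simulate(src, ph, SimulationConfig(n_histories=150_000,
                                                 rng_seed=21,
                                                 scatter_enabled=False))
        _, d_on, r_on = central_axis(on)
        _, d_off, _ = central_axis(off)
        assert np.all(d_on >= d_off - 3.0 * r_on * d_on - 1e-12)

    def test_water_pdd_monotone_within_noise(self, calibrated_beams):
        _, spec = calibrated_beams[70]
        ph = slab_phantom(0.0, 0.0, 3.0, 1.28, 0.01)
        src = BeamSource(spectrum=spec)
        g = simulate(src, ph, SimulationConfig(n_histories=200_000,
                                               rng_seed=31))
        _, dose, rel = central_axis(g)
        rises = np.diff(dose)
        sigma = rel * dose
        tol = 3.0 * np.sqrt(sigma[1:] ** 2 + sigma[:-1] ** 2)
        assert np.all(rises <= tol)
        assert dose[0] > dose[-1]

    def test_argument_validation(self, mono_spectrum):
        ph, _ = transmission_pair()
        src = BeamSource(spectrum=mono_spectrum)
        with pytest.raises(ValueError):
            simulate(src, ph, SimulationConfig(n_histories=0, rng_seed=1))
        with pytest.raises(ValueError):
            SimulationConfig(n_histories=5, batches=10)
        with pytest.raises(ValueError):
            SimulationConfig(photon_cutoff_keV=1.0)
        with pytest.raises(ValueError):
            BeamSource(spectrum=mono_spectrum, ssd_cm=-1.0)


class TestPrimaryKermaAnalytic:
    def test_vacuum_limit_is_inverse_square(self):
        pts = [(5.0, 1e-8), (150.0, 1e-8)]
        toy = toy_material(pts, [(5.0, 1e-9), (150.0, 1e-9)],
                           partial_split=(1.0, 0.0, 0.0))
        ph = toy_phantom(toy, nz=16, dz=1.0)
        src = BeamSource(spectrum=mono(60.0), ssd_cm=15.0)
        g = primary_kerma_analytic(src, ph)
        _, dose, _ = central_axis(g)
        z = ph.depths_cm
        expected = (15.0 / (15.0 + z)) ** 2
        np.testing.assert_allclose(dose / dose[0], expected / expected[0],
                                   rtol=1e-6)

    def test_homogeneous_exponential_slope(self, water):
        ph = toy_phantom(water, nz=40, dz=0.25)
        src = BeamSource(spectrum=mono(40.0))
        g = primary_kerma_analytic(src, ph)
        z, dose, _ = central_axis(g)
        y = np.log(dose * (15.0 + z) ** 2)
        slope = np.polyfit(z, y, 1)[0]
        assert slope == pytest.approx(-water.mu(40.0), rel=1e-4)

    def test_interface_jump_equals_muen_ratio(self, water, bone):
        """KERMA jump across the water-bone boundary tracks the ratio of
        mass energy-absorption coefficients at the beam energy."""
        ph = slab_phantom(0.1, 0.1, 3.0, 0.3, dz_cm=0.005)
        src = BeamSource(spectrum=mono(50.0))
        g = primary_kerma_analytic(src, ph)
        _, dose, _ = central_axis(g)
        k0 = 20  # first bone voxel (0.1 cm / 0.005 cm)
        jump = dose[k0] / dose[k0 - 1]
        expected = (bone("energy_absorption", 50.0)
                    / water("energy_absorption", 50.0))
        assert jump == pytest.approx(expected, rel=0.02)

    def test_heterogeneous_lateral_phantom_rejected(self, water):
        ph = toy_phantom(water)
        ph.density[0, 0, 0] *= 2
        with pytest.raises(ValueError, match="layered"):
            primary_kerma_analytic(BeamSource(spectrum=mono(40.0)), ph)


class TestComptonSampler:
    def test_kinematic_bound(self):
        rng = np.random.default_rng(0)
        e = 60.0
        floor = e / (1.0 + 2.0 * e / 511.0)
        for _ in range(2000):
            e_out, cost = sample_compton(e, rng)
            assert e_out >= floor - 1e-12
            assert -1.0 <= cost <= 1.0
            # energy-angle consistency
            assert e_out == pytest.approx(
                e / (1.0 + (e / MEC2) * (1.0 - cost)), rel=1e-12)

    def test_low_energy_thomson_limit(self):
        samples = _kernels.kn_samples(123, 100_000, 1.0)
        mean_loss = 1.0 - samples[:, 0].mean()
        assert mean_loss < 0.005

    def test_mean_scattered_fraction_matches_integral(self):
        """Oracle: numerical integration of the Klein-Nishina
        differential cross section in eps = E'/E."""
        e = 60.0
        a = e / MEC2
        eps0 = 1.0 / (1.0 + 2.0 * a)

        def dsde(eps):
            t = (1.0 - eps) / (a * eps)
            sin2 = max(t * (2.0 - t), 0.0)
            return (1.0 / eps + eps) * (1.0 - eps * sin2 / (1.0 + eps**2))

        norm = quad(dsde, eps0, 1.0)[0]
        expected = quad(lambda x: x * dsde(x), eps0, 1.0)[0] / norm
        n = 1_000_000
        samples = _kernels.kn_samples(99, n, e)
        mean = samples[:, 0].mean()
        se = samples[:, 0].std(ddof=1) / np.sqrt(n)
        assert abs(mean - expected) <= 3.0 * se

    def test_invalid_energy(self):
        with pytest.raises(ValueError):
            sample_compton(0.0, np.random.default_rng(0))


def test_3ddose_round_trip(tmp_path, mono_spectrum):
    ph, _ = transmission_pair()
    src = BeamSource(spectrum=mono_spectrum)
    g = simulate(src, ph, SimulationConfig(n_histories=20_000, rng_seed=4))
    path = tmp_path / "dose.3ddose"
    write_3ddose(g, path)
    back = read_3ddose(path)
    np.testing.assert_allclose(back.dose, g.dose, rtol=2e-6)
    np.testing.assert_allclose(back.rel_uncertainty, g.rel_uncertainty,
                               atol=2e-6)


def test_in_field_mask_geometry(mono_spectrum):
    ph, _ = transmission_pair()
    src = BeamSource(spectrum=mono_spectrum, field_diameter_cm=2.0)
    mask = in_field_mask(src, ph)
    # central voxels are in the field at every depth; corners never are
    assert np.all(mask[2:4, 2:4, :])
    assert not mask[0, 0, :].any()
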