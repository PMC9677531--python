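"""Dose-point-kernel construction, deposits and the convolution dose engine."""

import numpy as np
import pytest

from mbt.dose import (
    ActivityMap,
    brute_force_dose,
    compute_dose,
    deposit_activity,
    deposit_sphere_indices,
    kernel_to_voxel_weights,
)
from mbt.errors import ConfigurationError
from mbt.kernel import DoseKernel, build_default_kernel, load_kernel_csv, save_kernel_csv
from mbt.nuclide import MEV_TO_JOULE, cumulated_activity
from mbt.volume import VoxelVolume


def water_grid(n, spacing=1.0):
    return VoxelVolume(np.zeros((n, n, n)), spacing=(spacing,) * 3)


class TestKernel:
    def test_fractions_normalized_and_nonnegative(self, kernel):
        assert kernel.shell_energy_fraction.sum() == pytest.approx(1.0, abs=1e-6)
        assert (kernel.shell_energy_fraction >= 0).all()

    def test_cumulative_profile_independent_of_shell_width(self):
        coarse = build_default_kernel(shell_width=0.1)
        fine = build_default_kernel(shell_width=0.05)
        radii = np.linspace(0.5, 8.0, 16)
        assert np.allclose(
            coarse.cumulative_fraction(radii), fine.cumulative_fraction(radii), atol=1e-3
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            build_default_kernel(max_range=0.0)
        with pytest.raises(ConfigurationError):
            build_default_kernel(shell_width=-0.1)
        with pytest.raises(ConfigurationError):
            DoseKernel(shell_edges=np.array([0.0, 1.0, 2.0]), shell_energy_fraction=np.array([0.7, 0.2]))

    def test_csv_round_trip(self, kernel, tmp_path):
        path = tmp_path / "kernel.csv"
        save_kernel_csv(kernel, path)
        back = load_kernel_csv(path)
        assert np.allclose(back.shell_edges, kernel.shell_edges)
        assert np.allclose(back.shell_energy_fraction, kernel.shell_energy_fraction)

    def test_voxel_weights_conserve_energy(self, kernel):
        for spacing in [(1.0, 1.0, 1.0), (0.5, 0.5, 2.0)]:
            W = kernel_to_voxel_weights(kernel, spacing)
            assert W.sum() == pytest.approx(1.0, abs=1e-9)
            assert (W >= 0).all()


class TestDeposit:
    def test_total_activity_conserved(self, suspension, nuclide):
        grid = water_grid(21)
        act = deposit_activity([((10.0, 10.0, 10.0), 5.0, 5.5)], grid, suspension, nuclide)
        assert act.total_mbq == pytest.approx(5.5, rel=1e-9)

    def test_8ul_sphere_spans_multiple_fine_voxels(self, suspension, nuclide):
        # equal-volume sphere radius (3·8/4π)^(1/3) ≈ 1.24 mm covers many 0.5 mm voxels
        grid = water_grid(41, spacing=0.5)
        idx = deposit_sphere_indices(grid, np.array([10.0, 10.0, 10.0]), 8.0)
        assert len(idx) > 1

    def test_empty_plan_gives_zero_map(self, suspension, nuclide):
        act = deposit_activity([], water_grid(11), suspension, nuclide)
        assert act.total_mbq == 0.0

    def test_site_outside_grid_names_injection(self, suspension, nuclide):
        with pytest.raises(ConfigurationError, match="injection 1"):
            deposit_activity(
                [((5.0, 5.0, 5.0), 5.0, 1.0), ((99.0, 5.0, 5.0), 5.0, 1.0)],
                water_grid(11),
                suspension,
                nuclide,
            )

    def test_activity_computed_from_suspension_when_absent(self, suspension, nuclide):
        act = deposit_activity([((10.0, 10.0, 10.0), 8.0)], water_grid(21), suspension, nuclide)
        # 8 µl × 0.55 mg/µl × 2.5 MBq/mg = 11 MBq
        assert act.total_mbq == pytest.approx(11.0, rel=1e-9)


class TestComputeDose:
    def test_zero_activity_zero_dose(self, kernel, nuclide):
        act = ActivityMap(volume=water_grid(16))
        dose = compute_dose(act, kernel, nuclide)
        assert np.allclose(dose.volume.data, 0.0)

    def test_linear_in_activity(self, kernel, nuclide, rng):
        data = rng.random((16, 16, 16)) * 0.01
        d1 = compute_dose(ActivityMap(volume=water_grid(16).copy(data=data)), kernel, nuclide)
        d2 = compute_dose(ActivityMap(volume=water_grid(16).copy(data=3 * data)), kernel, nuclide)
        assert np.allclose(d2.volume.data, 3 * d1.volume.data, rtol=1e-9, atol=1e-12)

    def test_energy_conservation_interior_source(self, kernel, nuclide, suspension):
        grid = water_grid(41)
        act = deposit_activity([((20.0, 20.0, 20.0), 5.0, 5.5)], grid, suspension, nuclide)
        dose = compute_dose(act, kernel, nuclide)
        voxel_mass_kg = grid.voxel_volume_mm3 * 1e-6
        deposited = dose.volume.data.sum() * voxel_mass_kg
        emitted = 5.5e6 * cumulated_activity(1.0, nuclide) * nuclide.mean_energy_per_decay * MEV_TO_JOULE
        assert deposited == pytest.approx(emitted, rel=0.01)

    def test_translation_equivariance(self, kernel, nuclide):
        a = np.zeros((40, 40, 40))
        a[14, 20, 20] = 1.0
        b = np.zeros((40, 40, 40))
        b[15, 20, 20] = 1.0
        da = compute_dose(ActivityMap(volume=water_grid(40).copy(data=a)), kernel, nuclide)
        db = compute_dose(ActivityMap(volume=water_grid(40).copy(data=b)), kernel, nuclide)
        # interior region: shifting the source by one voxel shifts the dose field
        assert np.allclose(
            da.volume.data[4:25], db.volume.data[5:26], rtol=1e-9, atol=1e-9
        )

    def test_zero_far_from_activity(self, kernel, nuclide):
        a = np.zeros((40, 40, 40))
        a[20, 20, 20] = 2.0
        dose = compute_dose(ActivityMap(volume=water_grid(40).copy(data=a)), kernel, nuclide)
        # corner voxel is ~34 mm away, far beyond the 8.5 mm kernel range
        assert dose.volume.data[0, 0, 0] < 1e-9 * dose.volume.data.max()


class TestBruteForceOracle:
    def test_fft_matches_brute_force_on_random_map(self, kernel, nuclide):
        rng = np.random.default_rng(7)
        data = np.zeros((16, 16, 16))
        src = rng.random((16, 16, 16)) < 0.05
        data[src] = rng.random(src.sum()) * 0.1
        act = ActivityMap(volume=water_grid(16).copy(data=data))
        fft = compute_dose(act, kernel, nuclide).volume.data
        ref = brute_force_dose(act, kernel, nuclide).volume.data
        sel = ref > 0.01 * ref.max()
        rel = np.abs(fft[sel] - ref[sel]) / ref[sel]
        assert rel.max() < 1e-6

    def test_octahedral_symmetry_of_point_source(self, kernel, nuclide):
        data = np.zeros((17, 17, 17))
        data[8, 8, 8] = 1.0
        dose = brute_force_dose(
            ActivityMap(volume=water_grid(17).copy(data=data)), kernel, nuclide
        ).volume.data
        for axes in [(1, 0, 2), (0, 2, 1), (2, 1, 0)]:
            assert np.allclose(dose, np.transpose(dose, axes), rtol=1e-12, atol=1e-12)
        for axis in range(3):
            assert np.allclose(dose, np.flip(dose, axis=axis), rtol=1e-12, atol=1e-12)

    def test_zero_map_passthrough(self, kernel, nuclide):
        dose = brute_force_dose(ActivityMap(volume=water_grid(8)), kernel, nuclide)
        assert np.all(dose.volume.data == 0.0)

    def test_large_grid_rejected(self, kernel, nuclide):
        with pytest.raises(ConfigurationError):
            brute_force_dose(ActivityMap(volume=water_grid(33)), kernel, nuclide)
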