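"""Phantom geometry, growth law, CT forward model and cohort generation."""

import math

import numpy as np
import pandas as pd
import pytest

from mbt.errors import ConfigurationError, GeometryError
from mbt.metrics import mask_volume
from mbt.synthetic import (
    CohortSpec,
    CTModel,
    GrowthModel,
    Lobe,
    PhantomSpec,
    default_phantom_spec,
    fit_doubling_time,
    grow_volume,
    make_tumor_mask,
    render_ct,
    simulate_cohort,
    sphere_phantom,
)
from mbt.volume import VoxelVolume


class TestTumorMask:
    def test_sphere_volume_matches_analytic(self):
        mask = sphere_phantom(15.0)
        assert mask_volume(mask) == pytest.approx(4 / 3 * math.pi * 7.5**3, rel=0.02)

    def test_disconnected_lobes_rejected(self):
        spec = PhantomSpec(
            lobes=(
                Lobe(center=(10.0, 10.0, 10.0), semi_axes=(3.0, 3.0, 3.0)),
                Lobe(center=(30.0, 30.0, 30.0), semi_axes=(3.0, 3.0, 3.0)),
            ),
            grid_shape=(40, 40, 40),
        )
        with pytest.raises(ConfigurationError, match="disconnected"):
            make_tumor_mask(spec)

    def test_oversized_tumor_rejected(self):
        spec = PhantomSpec(
            lobes=(Lobe(center=(40.0, 40.0, 40.0), semi_axes=(20.0, 20.0, 20.0)),),
            grid_shape=(81, 81, 81),
        )
        with pytest.raises(ConfigurationError, match="equivalent diameter"):
            make_tumor_mask(spec)

    def test_deterministic_for_fixed_spec(self):
        spec = default_phantom_spec(seed=5)
        assert np.array_equal(make_tumor_mask(spec).data, make_tumor_mask(spec).data)

    def test_plurilobed_mask_is_single_component(self):
        from scipy import ndimage

        mask = make_tumor_mask(default_phantom_spec())
        _, n = ndimage.label(mask.data)
        assert n == 1

    def test_voxelization_error_shrinks_with_spacing(self):
        analytic = 4 / 3 * math.pi * 7.5**3
        errors = []
        for spacing in (2.0, 1.0, 0.5):
            mask = sphere_phantom(15.0, spacing_mm=spacing)
            errors.append(abs(mask_volume(mask) - analytic))
        assert errors[0] > errors[1] > errors[2]


class TestGrowthModel:
    def test_one_doubling(self):
        m = GrowthModel(v0=1000.0, doubling_time=3.0, reference_day=14)
        assert grow_volume(m, 17) == pytest.approx(2000.0)

    def test_identity_at_reference(self):
        m = GrowthModel(v0=787.0, doubling_time=3.0, reference_day=14)
        assert grow_volume(m, 14) == pytest.approx(787.0)

    def test_day_before_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            grow_volume(GrowthModel(), 10)

    def test_doubling_time_recovered_from_two_measurements(self):
        # control animal: 787 mm³ at day 14 grows to 2511 mm³ at day 19
        td = fit_doubling_time(787.0, 14, 2511.0, 19)
        assert td == pytest.approx(2.99, abs=0.01)
        m = GrowthModel(v0=787.0, doubling_time=td, reference_day=14)
        assert grow_volume(m, 19) == pytest.approx(2511.0, rel=1e-9)

    def test_invalid_models_rejected(self):
        with pytest.raises(ConfigurationError):
            GrowthModel(v0=-1.0)
        with pytest.raises(ConfigurationError):
            GrowthModel(doubling_time=0.0)


class TestRenderCT:
    def setup_method(self):
        self.mask = sphere_phantom(9.0, margin_mm=4.0)
        self.quiet = CTModel(noise_sd=0.0)

    def test_noiseless_baselines(self):
        hu = render_ct(self.mask, None, self.quiet, seed=0)
        assert np.all(hu.data[self.mask.data] == self.quiet.tumor_hu)
        assert np.all(hu.data[~self.mask.data] == self.quiet.brain_hu)

    def test_linear_ho_term(self):
        conc = self.mask.copy(data=np.zeros(self.mask.shape))
        conc.data[8, 8, 8] = 10.0
        hu = render_ct(self.mask, conc, self.quiet, seed=0)
        base = self.quiet.tumor_hu if self.mask.data[8, 8, 8] else self.quiet.brain_hu
        assert hu.data[8, 8, 8] == pytest.approx(base + self.quiet.ho_slope * 10.0)

    def test_saturation_clipping(self):
        conc = self.mask.copy(data=np.full(self.mask.shape, 1e6))
        hu = render_ct(self.mask, conc, self.quiet, seed=0)
        assert hu.data.max() == self.quiet.saturation_hu

    def test_seed_reproducibility(self):
        noisy = CTModel(noise_sd=5.0)
        a = render_ct(self.mask, None, noisy, seed=3)
        b = render_ct(self.mask, None, noisy, seed=3)
        c = render_ct(self.mask, None, noisy, seed=4)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_geometry_mismatch_rejected(self):
        conc = VoxelVolume(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(GeometryError):
            render_ct(self.mask, conc, self.quiet, seed=0)


class TestCohort:
    def test_deterministic_endpoint_without_jitter(self):
        # 1000 mm³ at treatment, doubling every 3 d, 5000 mm³ endpoint:
        # first integer day with 1000·2^(t/3) > 5000 is t = 7
        spec = CohortSpec(
            n_treated=0,
            n_untreated=3,
            growth=GrowthModel(v0=1000.0, doubling_time=3.0),
            sigma_log_v0=0.0,
            sigma_log_td=0.0,
        )
        df = simulate_cohort(spec, coverage_treated=1.0)
        assert (df["time_days"] == 7).all()
        assert (df["event"] == 1).all()

    def test_full_coverage_treated_all_censored(self):
        df = simulate_cohort(CohortSpec(seed=1), coverage_treated=1.0)
        treated = df[df["arm"] == "treated"]
        assert (treated["event"] == 0).all()
        assert (treated["time_days"] == 66).all()

    def test_under_covered_treated_reach_endpoint(self):
        df = simulate_cohort(CohortSpec(seed=1), coverage_treated=0.5)
        treated = df[df["arm"] == "treated"]
        assert (treated["event"] == 1).all()

    def test_arm_sizes(self):
        df = simulate_cohort(CohortSpec(n_untreated=0, seed=2), coverage_treated=1.0)
        assert len(df) == CohortSpec().n_treated
        assert set(df["arm"]) == {"treated"}

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(sigma_log_v0=-0.1)

    def test_reproducible_for_fixed_seed(self):
        a = simulate_cohort(CohortSpec(seed=11), coverage_treated=0.96)
        b = simulate_cohort(CohortSpec(seed=11), coverage_treated=0.96)
        pd.testing.assert_frame_equal(a, b)

    def test_untreated_event_window_across_seeds(self):
        """Default dispersions keep untreated cohort means inside the observed
        6-9 day post-treatment window over 200 seeds."""
        means = []
        for seed in range(200):
            df = simulate_cohort(CohortSpec(seed=seed), coverage_treated=1.0)
            unt = df[df["arm"] == "untreated"]
            assert (unt["event"] == 1).all()
            means.append(unt["time_days"].mean())
        means = np.asarray(means)
        assert means.min() >= 6.0
        assert means.max() <= 9.0
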