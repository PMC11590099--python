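"""Ground-truth generation, decay rendering and stimulus rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasorph import simulate as sim
from phasorph.phasor import IRFModel, fit_mono_lifetime


class TestProtonatedFraction:
    def test_midpoint_is_half(self):
        assert sim.protonated_fraction(5.7, 5.7) == pytest.approx(0.5)

    def test_one_unit_below_pka(self):
        # 1/(1 + 10^-1) = 10/11
        assert sim.protonated_fraction(4.7, 5.7) == pytest.approx(10 / 11, abs=1e-6)

    def test_physiological_ph(self):
        # 1/(1 + 10^1.7)
        assert sim.protonated_fraction(7.4, 5.7) == pytest.approx(0.01958, abs=2e-4)

    @settings(max_examples=50, deadline=None)
    @given(
        ph=st.floats(3.0, 9.0),
        dph=st.floats(0.01, 2.0),
        pka=st.floats(4.0, 8.0),
    )
    def test_strictly_decreasing_in_ph(self, ph, dph, pka):
        assert sim.protonated_fraction(ph, pka) > sim.protonated_fraction(ph + dph, pka)


class TestSensorAndParams:
    def test_invalid_lifetime_order_rejected(self):
        with pytest.raises(ValueError):
            sim.SensorModel(tau_fret=4.0, tau_donor=2.0)

    def test_out_of_range_pka_rejected(self):
        with pytest.raises(ValueError):
            sim.SensorModel(pka=12.0)

    def test_granule_ph_range_enforced(self):
        with pytest.raises(ValueError):
            sim.GranuleTruth(id=0, centroid=(10, 10), true_ph=9.5)


class TestMakeScene:
    def test_zero_granules_gives_empty_scene(self):
        scene = sim.make_scene([], seed=1, shape=(128, 128))
        assert scene.granules == []

    def test_same_seed_reproduces_identical_scene(self):
        pops = sim.landscape_populations(10, 8)
        a = sim.make_scene(pops, seed=5, shape=(128, 128))
        b = sim.make_scene(pops, seed=5, shape=(128, 128))
        np.testing.assert_array_equal(a.cell_mask, b.cell_mask)
        assert [(g.centroid, g.true_ph, g.brightness) for g in a.granules] == [
            (g.centroid, g.true_ph, g.brightness) for g in b.granules
        ]

    def test_interior_population_quartiles_match_design(self):
        """Interior granule pH quartiles land near the acidic [4.2, 5.0]
        central-50% interval the population was parameterized to."""
        pops = [
            sim.GranulePopulation(
                name="interior", n=150, ph_mean=4.6, ph_sd=0.593,
                ph_range=(3.8, 7.4), depth_range=(0.2, 1.0),
            )
        ]
        scene = sim.make_scene(pops, seed=2, shape=(256, 256), min_separation_px=5)
        q25, q75 = np.percentile([g.true_ph for g in scene.granules], [25, 75])
        assert q25 == pytest.approx(4.2, abs=0.15)
        assert q75 == pytest.approx(5.0, abs=0.15)

    def test_placement_respects_depth_bands(self):
        from scipy import ndimage

        scene = sim.make_scene(sim.landscape_populations(20, 15), seed=3)
        depth = ndimage.distance_transform_edt(scene.cell_mask)
        norm = depth / depth.max()
        for g in scene.granules:
            d = norm[int(round(g.centroid[0])), int(round(g.centroid[1]))]
            if g.population_label == "peripheral":
                assert d <= 0.09
            else:
                assert d >= 0.24

    def test_overfull_spec_rejected(self):
        pops = [sim.GranulePopulation(name="p", n=5000)]
        with pytest.raises(ValueError):
            sim.make_scene(pops, seed=1, shape=(64, 64))


class TestRenderDecayStack:
    def _uniform_scene(self, ph, n=25, seed=4):
        pops = [
            sim.GranulePopulation(
                name="u", n=n, ph_dist="uniform", ph_range=(ph, ph + 1e-9),
                depth_range=(0.1, 0.9),
            )
        ]
        return sim.make_scene(
            pops, seed=seed, shape=(128, 128),
            autofluorescence=(2.5, 0.0), background_counts=0.0,
        )

    def test_fully_protonated_scene_fits_tau_donor(self, sensor, irf):
        # pH 3.6 << pKa: the pooled decay is effectively donor-only
        acq = sim.AcquisitionParams(frame_shape=(128, 128), target_median_counts=30)
        scene = self._uniform_scene(3.6)
        stack = sim.render_decay_stack(scene, sensor, irf, acq, seed=8)
        tau = fit_mono_lifetime(
            stack.summed_decay(), irf, stack.bin_width, stack.rep_rate
        )
        assert tau == pytest.approx(sensor.tau_donor, abs=0.1)

    def test_fully_deprotonated_scene_fits_tau_fret(self, sensor, irf):
        acq = sim.AcquisitionParams(frame_shape=(128, 128), target_median_counts=30)
        scene = self._uniform_scene(8.4)
        stack = sim.render_decay_stack(scene, sensor, irf, acq, seed=9)
        tau = fit_mono_lifetime(
            stack.summed_decay(), irf, stack.bin_width, stack.rep_rate
        )
        assert tau == pytest.approx(sensor.tau_fret, abs=0.06)

    def test_empty_dark_scene_renders_all_zero(self, sensor, irf):
        scene = sim.make_scene(
            [], seed=1, shape=(64, 64),
            autofluorescence=(2.5, 0.0), background_counts=0.0,
        )
        acq = sim.AcquisitionParams(frame_shape=(64, 64))
        stack = sim.render_decay_stack(scene, sensor, irf, acq, seed=1)
        assert stack.counts.sum() == 0

    def test_median_counts_near_target(self, landscape_scene, sensor, irf, acq_live):
        stack = sim.render_decay_stack(landscape_scene, sensor, irf, acq_live, seed=2)
        med = np.median(stack.counts.sum(2)[landscape_scene.cell_mask])
        assert med == pytest.approx(acq_live.target_median_counts, rel=0.1)

    def test_identical_seed_bit_identical_stack(self, landscape_scene, sensor, irf, acq_live):
        a = sim.render_decay_stack(landscape_scene, sensor, irf, acq_live, seed=3)
        b = sim.render_decay_stack(landscape_scene, sensor, irf, acq_live, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_coarse_bins_rejected(self, sensor, irf, landscape_scene):
        acq = sim.AcquisitionParams(n_bins=6, frame_shape=(256, 256))
        with pytest.raises(ValueError):
            sim.render_decay_stack(landscape_scene, sensor, irf, acq, seed=1)


class TestTitration:
    def test_empty_ph_list_gives_empty_output(self, sensor, irf, acq_small):
        assert sim.simulate_titration(sensor, [], acq_small, irf) == []

    def test_endpoint_fractions(self, sensor):
        # pKa 5.7: protonated fraction 0.980 at pH 4.0, 0.012 at pH 7.6
        assert sim.protonated_fraction(4.0, 5.7) == pytest.approx(0.9804, abs=1e-3)
        assert sim.protonated_fraction(7.6, 5.7) == pytest.approx(0.0124, abs=1e-3)

    def test_one_stack_per_ph(self, sensor, irf):
        acq = sim.AcquisitionParams(frame_shape=(16, 16), target_median_counts=100)
        out = sim.simulate_titration(sensor, [4.0, 5.7, 7.6], acq, irf, seed=1)
        assert [ph for ph, _ in out] == [4.0, 5.7, 7.6]
        assert all(st.counts.shape == (16, 16, 64) for _, st in out)


class TestStimulus:
    def _scene(self, seed=6):
        return sim.make_scene(sim.landscape_populations(20, 15), seed=seed)

    def test_none_with_zero_basal_loss_is_identity(self):
        scene = self._scene()
        stim = sim.StimulusModel(
            name="none",
            secretion_rule=lambda ph, d: 0.0,
            acidification_rule=lambda ph, t: 0.0,
            basal_loss=0.0,
        )
        out = sim.apply_stimulus(scene, stim, minutes=10, seed=1)
        assert [g.id for g in out.granules] == [g.id for g in scene.granules]
        assert [g.true_ph for g in out.granules] == [g.true_ph for g in scene.granules]

    def test_ex4_leaves_counts_unchanged_in_first_15_min(self):
        scene = self._scene()
        out = sim.apply_stimulus(scene, sim.standard_stimulus("ex4"), minutes=15, seed=2)
        assert len(out.granules) == len(scene.granules)

    def test_ex4_acidifies(self):
        # the maturation rule shifts less-acidic granules hardest
        # (depletion near pH 5.7, enrichment near 4.5)
        scene = self._scene()
        out = sim.apply_stimulus(scene, sim.standard_stimulus("ex4"), minutes=15, seed=2)
        before = {g.id: g.true_ph for g in scene.granules}
        after = {g.id: g.true_ph for g in out.granules}
        assert np.mean(list(after.values())) < np.mean(list(before.values())) - 0.03
        high = [gid for gid, p in before.items() if p > 5.4]
        assert high, "scene should contain less-acidic granules"
        shifts = [before[g] - after[g] for g in high]
        assert np.mean(shifts) > 0.1

    def test_glucose_spares_alkaline_periphery(self):
        # all peripheral granules at pH >= 6: the pH-selective rule predicts
        # ~2% basal-like removal only
        pops = [
            sim.GranulePopulation(
                name="peripheral", n=40, ph_dist="uniform", ph_range=(6.0, 7.0),
                depth_range=(0.0, 0.08),
            )
        ]
        scene = sim.make_scene(pops, seed=3)
        stim = sim.standard_stimulus("glucose")
        removed = []
        for seed in range(5):
            out = sim.apply_stimulus(scene, stim, minutes=15, seed=seed)
            removed.append(len(scene.granules) - len(out.granules))
        # expected removals ~ n * (secretion 0.06 + basal 0.03) = 3.6
        assert np.mean(removed) < 8

    def test_glucose_removes_acidic_periphery(self):
        pops = [
            sim.GranulePopulation(
                name="peripheral", n=40, ph_dist="uniform", ph_range=(4.2, 5.1),
                depth_range=(0.0, 0.08),
            )
        ]
        scene = sim.make_scene(pops, seed=3)
        out = sim.apply_stimulus(scene, sim.standard_stimulus("glucose"), 15, seed=4)
        # expected survival ~ 1 - (0.45 + 0.03) = 0.52
        assert len(out.granules) < 0.75 * len(scene.granules)

    def test_unknown_stimulus_rejected(self):
        with pytest.raises(ValueError):
            sim.standard_stimulus("caffeine")


def test_poisson_sampling_preserves_expected_mean(sensor, irf):
    """Total counts over repeats match the (scaled) expectation within SE."""
    acq = sim.AcquisitionParams(frame_shape=(64, 64), target_median_counts=40)
    scene = sim.make_scene(
        [], seed=1, shape=(64, 64), autofluorescence=(2.5, 40.0), background_counts=0.0
    )
    totals = [
        sim.render_decay_stack(scene, sensor, irf, acq, seed=s).counts.sum()
        for s in range(5)
    ]
    expected = 40.0 * scene.cell_mask.sum()
    se = np.sqrt(expected)
    assert abs(np.mean(totals) - expected) < 4 * se / np.sqrt(len(totals))
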