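"""Synthetic-eye generator: damage fields, waveforms, whole cohorts."""

import numpy as np
import pytest

from onhcmap import (
    OnhcMap,
    SimParams,
    extract_onhc_amplitude,
    make_damage_field,
    select_reference,
    simulate_cohort,
    simulate_eye,
    simulate_waveform,
)
from onhcmap.simulate import hexagon_integrity, onhc_latency


class TestDamageField:
    def test_control_field_is_unity(self, rng):
        field = make_damage_field(SimParams(), rng, defect_type="none")
        xs = np.linspace(-28, 28, 41)
        gx, gy = np.meshgrid(xs, xs)
        assert np.all(field.integrity(gx, gy) == 1.0)

    def test_deep_arcuate_zone_means(self, noise_free_params, rng):
        field = make_damage_field(noise_free_params, rng,
                                  defect_type="arcuate",
                                  hemifield="superior", depth=0.9)
        xs = np.linspace(-29, 29, 200)
        gx, gy = np.meshgrid(xs, xs)
        integ = field.integrity(gx, gy)
        core = field.core_mask(gx, gy)
        assert core.any()
        assert np.mean(integ[core]) <= 0.1 + 1e-9
        inferior = gy < 0
        assert np.mean(integ[inferior]) >= 0.95

    def test_defect_respects_horizontal_raphe(self, noise_free_params, rng):
        field = make_damage_field(noise_free_params, rng,
                                  defect_type="arcuate",
                                  hemifield="superior", depth=0.9)
        xs = np.linspace(16, 29, 30)
        ys = np.linspace(-10, -0.1, 30)
        gx, gy = np.meshgrid(xs, ys)
        assert np.all(field.integrity(gx, gy) >= 1.0 - 1e-9)

    def test_central_sparing_floor(self, rng):
        params = SimParams(sparing_floor=0.9)
        field = make_damage_field(params, rng, defect_type="arcuate",
                                  hemifield="superior", depth=1.0)
        xs = np.linspace(-7.5, 7.5, 40)
        gx, gy = np.meshgrid(xs, xs)
        central = np.hypot(gx, gy) < params.sparing_radius
        assert np.all(field.integrity(gx, gy)[central] >= 0.9 - 1e-9)

    @pytest.mark.parametrize("defect", ["nasal-step", "paracentral"])
    def test_other_defect_types_confined_to_hemifield(self, defect,
                                                      noise_free_params, rng):
        field = make_damage_field(noise_free_params, rng, defect_type=defect,
                                  hemifield="inferior", depth=0.8)
        xs = np.linspace(-28, 28, 80)
        gx, gy = np.meshgrid(xs, xs)
        integ = field.integrity(gx, gy)
        assert np.any(integ < 0.9)
        assert np.all(integ[gy > 0] >= 1.0 - 1e-9)

    def test_same_generator_state_gives_identical_fields(self, hex_array):
        p = SimParams()
        f1 = make_damage_field(p, np.random.default_rng(7))
        f2 = make_damage_field(p, np.random.default_rng(7))
        xs = np.linspace(-28, 28, 60)
        gx, gy = np.meshgrid(xs, xs)
        np.testing.assert_array_equal(f1.integrity(gx, gy),
                                      f2.integrity(gx, gy))

    def test_invalid_descriptor_rejected(self, rng):
        with pytest.raises(ValueError, match="invalid"):
            make_damage_field(SimParams(), rng, defect_type="ring")
        with pytest.raises(ValueError, match="hemifield"):
            make_damage_field(SimParams(), rng, defect_type="arcuate",
                              hemifield="temporal")


class TestSimulateWaveform:
    def test_full_integrity_recovers_profile_height(self, hex_array, disc,
                                                    noise_free_params):
        for e in hex_array.elements:
            w, planted, _ = simulate_waveform(e, 1.0, disc, noise_free_params)
            got = extract_onhc_amplitude(w, smooth_window=1)
            assert got == pytest.approx(planted, rel=0.01)

    def test_zero_integrity_plants_nothing(self, hex_array, disc,
                                           noise_free_params):
        w, planted, _ = simulate_waveform(hex_array.element(25), 0.0, disc,
                                          noise_free_params)
        assert planted == 0.0
        assert extract_onhc_amplitude(w, smooth_window=1) == 0.0

    def test_latency_is_distance_over_velocity(self, hex_array, disc,
                                               noise_free_params):
        # latency difference between two elements equals their fibre-path
        # distance difference divided by conduction velocity (1 m/s)
        e1, e2 = hex_array.element(3), hex_array.element(50)
        _, _, l1 = simulate_waveform(e1, 1.0, disc, noise_free_params)
        _, _, l2 = simulate_waveform(e2, 1.0, disc, noise_free_params)
        d1 = onhc_latency(e1.center, disc, noise_free_params)
        d2 = onhc_latency(e2.center, disc, noise_free_params)
        assert l2 - l1 == pytest.approx(d2 - d1)

    def test_all_default_latencies_inside_epoch(self, hex_array, disc,
                                                noise_free_params):
        lats = [onhc_latency(e.center, disc, noise_free_params)
                for e in hex_array.elements]
        assert min(lats) > 61.0 and max(lats) < 89.0

    def test_latency_outside_epoch_warns(self, hex_array, disc):
        params = SimParams(noise_sd=0.0, velocity_m_s=0.2)
        with pytest.warns(UserWarning, match="epoch"):
            simulate_waveform(hex_array.element(40), 1.0, disc, params)

    def test_onhc_is_second_positive_epoch_peak(self, hex_array, disc,
                                                noise_free_params, rng):
        # across random integrities the measured peak time must equal the
        # planted conduction latency, not the first IC deflection
        for _ in range(30):
            e = hex_array.element(int(rng.integers(1, 62)))
            integ = float(rng.uniform(0.3, 1.0))
            w, planted, lat = simulate_waveform(e, integ, disc,
                                                noise_free_params)
            amp, t_peak = extract_onhc_amplitude(w, smooth_window=1,
                                                 return_time=True)
            assert amp == pytest.approx(planted, rel=0.02)
            assert t_peak == pytest.approx(lat, abs=0.3)


class TestSimulateEye:
    def test_control_noise_free_is_clean(self, noise_free_params, hex_array,
                                         grid, rng):
        eye = simulate_eye(noise_free_params, rng, label="control",
                           geometry=hex_array, grid=grid)
        assert np.all(eye.td_plot.td_db == 0.0)
        assert np.all(eye.td_plot.prob_category == "none")
        ref = select_reference(eye.truth.planted_amplitude, hex_array)[1]
        ratios = eye.truth.planted_amplitude / ref
        m = OnhcMap.from_recording(eye.recording, hex_array, smooth_window=1,
                                   min_prominence=0.0)
        np.testing.assert_allclose(m.ratio, ratios, atol=0.01)

    def test_closed_loop_ratio_recovery_noise_free(self, noise_free_params,
                                                   hex_array, grid, rng):
        eye = simulate_eye(noise_free_params, rng, label="glaucoma",
                           geometry=hex_array, grid=grid)
        m = OnhcMap.from_recording(eye.recording, hex_array, smooth_window=1,
                                   min_prominence=0.0)
        ref = select_reference(eye.truth.planted_amplitude, hex_array)[1]
        planted_ratio = eye.truth.planted_amplitude / ref
        np.testing.assert_allclose(m.ratio, planted_ratio, atol=0.01)

    def test_deeper_damage_never_increases_amplitude(self, hex_array, grid,
                                                     noise_free_params):
        amps = []
        for depth in (0.3, 0.6, 0.9):
            rng = np.random.default_rng(0)
            damage = make_damage_field(noise_free_params, rng, "arcuate",
                                       "superior", depth)
            eye = simulate_eye(noise_free_params, np.random.default_rng(1),
                               label="glaucoma", geometry=hex_array,
                               grid=grid, damage=damage)
            amps.append(eye.truth.planted_amplitude)
        zone = amps[2] < 0.99 * amps[0]  # hexes inside the defect
        assert zone.any()
        assert np.all(amps[1] <= amps[0] + 1e-12)
        assert np.all(amps[2] <= amps[1] + 1e-12)
        assert np.all(amps[2][zone] < amps[0][zone])

    def test_superior_field_defect_spares_inferior_hexes(
            self, noise_free_params, hex_array, grid, rng):
        damage = make_damage_field(noise_free_params, rng, "arcuate",
                                   "superior", 0.9)
        eye = simulate_eye(noise_free_params, rng, label="glaucoma",
                          geometry=hex_array, grid=grid, damage=damage)
        inferior = hex_array.centers[:, 1] < -1.0
        assert np.all(eye.truth.hex_integrity[inferior] >= 0.95)

    def test_same_seed_reproduces_eye(self, hex_array, grid):
        p = SimParams()
        e1 = simulate_eye(p, np.random.default_rng(42), geometry=hex_array,
                          grid=grid)
        e2 = simulate_eye(p, np.random.default_rng(42), geometry=hex_array,
                          grid=grid)
        np.testing.assert_array_equal(e1.td_plot.td_db, e2.td_plot.td_db)
        np.testing.assert_array_equal(e1.recording.waveforms[30].v,
                                      e2.recording.waveforms[30].v)


class TestSimulateCohort:
    def test_default_sizes_are_39_glaucoma_30_control(self):
        p = SimParams()
        assert p.n_glaucoma == 39 and p.n_control == 30

    def test_cohort_composition_and_reproducibility(self, hex_array, grid):
        p = SimParams(n_control=3, n_glaucoma=4)
        eyes1 = simulate_cohort(p, seed=11, geometry=hex_array, grid=grid)
        eyes2 = simulate_cohort(p, seed=11, geometry=hex_array, grid=grid)
        labels = [e.label for e in eyes1]
        assert labels.count("control") == 3 and labels.count("glaucoma") == 4
        for a, b in zip(eyes1, eyes2):
            np.testing.assert_array_equal(a.td_plot.td_db, b.td_plot.td_db)

    def test_glaucoma_only_cohort_warns(self, hex_array, grid):
        p = SimParams(n_control=0, n_glaucoma=2)
        with pytest.warns(UserWarning, match="no control"):
            eyes = simulate_cohort(p, seed=0, geometry=hex_array, grid=grid)
        assert len(eyes) == 2

    def test_nasotemporal_asymmetry_monotone(self, noise_free_params,
                                             hex_array, grid, disc, rng):
        # implicit time strictly increasing in fibre-path distance
        eye = simulate_eye(noise_free_params, rng, label="control",
                           geometry=hex_array, grid=grid)
        times, dists = [], []
        for e in hex_array.elements:
            _, t_peak = extract_onhc_amplitude(
                eye.recording.waveforms[e.id], smooth_window=1,
                return_time=True)
            times.append(t_peak)
            dists.append(onhc_latency(e.center, disc, noise_free_params))
        order = np.argsort(dists)
        assert np.all(np.diff(np.array(times)[order]) > 0)
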