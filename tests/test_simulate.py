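"""Generator contracts: ground-truth bookkeeping, closed forms, determinism."""

import numpy as np
import pytest

from smquant import polymer, simulate
from smquant.simulate import ParticleSpec, SimConfig


class TestKymographSim:
    def test_static_particle_peaks_at_true_pixel_every_frame(self):
        cfg = SimConfig(seed=0, n_frames=20, n_pixels=32, noise_model="none")
        kymo, _ = simulate.simulate_kymograph(
            cfg, [ParticleSpec(kind="static", x0=1200.0)]
        )
        assert np.all(kymo.intensity.argmax(axis=0) == 12)

    def test_directed_displacement_matches_kinematics(self):
        # 14 nm/s for 300 lines of 0.997 s covers ~4.19 um of DNA
        cfg = SimConfig(seed=0, n_frames=300, n_pixels=64, noise_model="none")
        _, truth = simulate.simulate_kymograph(
            cfg, [ParticleSpec(kind="directed", x0=200.0, v=14.0)]
        )
        path = truth.paths[0]
        disp = np.nanmax(path) - np.nanmin(path)
        assert disp == pytest.approx(14.0 * 300 * 0.997, rel=0.01)

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=7, n_frames=50, n_pixels=32)
        parts = [ParticleSpec(kind="diffusive", x0=1500.0, D=1e4)]
        k1, t1 = simulate.simulate_kymograph(cfg, parts)
        k2, t2 = simulate.simulate_kymograph(cfg, parts)
        np.testing.assert_array_equal(k1.intensity, k2.intensity)
        np.testing.assert_array_equal(t1.paths[0], t2.paths[0])

    def test_particle_leaving_field_contributes_nothing(self):
        cfg = SimConfig(seed=0, n_frames=100, n_pixels=16, noise_model="none")
        # 100 nm/s exits the 1.6 um field within ~12 frames
        kymo, truth = simulate.simulate_kymograph(
            cfg, [ParticleSpec(kind="directed", x0=500.0, v=100.0)]
        )
        gone = np.isnan(truth.paths[0])
        assert gone.any()
        np.testing.assert_allclose(
            kymo.intensity[:, gone], cfg.background, atol=1e-9
        )

    def test_diffusion_reflects_at_dna_ends(self):
        cfg = SimConfig(seed=3, n_frames=2000, n_pixels=8, noise_model="none")
        _, truth = simulate.simulate_kymograph(
            cfg, [ParticleSpec(kind="diffusive", x0=400.0, D=5e4)]
        )
        path = truth.paths[0]
        assert np.nanmin(path) >= 0.0
        assert np.nanmax(path) < 8 * 100.0

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_frames=0),
            dict(n_pixels=-3),
            dict(pixel_size=0.0),
            dict(line_time=-1.0),
            dict(noise_model="salt"),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)

    def test_particle_outside_field_rejected(self):
        cfg = SimConfig(seed=0, n_pixels=16)
        with pytest.raises(ValueError):
            simulate.simulate_kymograph(cfg, [ParticleSpec(kind="static", x0=1600.0)])

    def test_config_json_roundtrip_rejects_unknown_keys(self):
        cfg = SimConfig(seed=5, n_frames=10)
        assert SimConfig.from_json(cfg.to_json()) == cfg
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_json('{"seed": 1, "flux_capacitor": 3}')


class TestDistanceTraceSim:
    def test_single_burst_linear_segment(self):
        trace, truth = simulate.simulate_distance_trace(
            burst_rate_mean=5.0, burst_rate_rel_sd=0.0, burst_dur=100.0,
            pause_dur=1.0, total_dur=100.0, dt=1.0, noise_sigma=0.0, seed=0,
        )
        assert trace.distance[-1] - trace.distance[0] == pytest.approx(
            5.0 * 99.0, rel=1e-9
        )
        assert truth.burst_rates[0] == pytest.approx(5.0)

    def test_zero_rate_trace_constant(self):
        trace, _ = simulate.simulate_distance_trace(
            burst_rate_mean=0.0, noise_sigma=0.0, seed=0
        )
        np.testing.assert_allclose(trace.distance, 0.0, atol=1e-12)

    def test_mean_path_monotone_nondecreasing(self):
        trace, _ = simulate.simulate_distance_trace(noise_sigma=0.0, seed=4)
        assert np.all(np.diff(trace.distance) >= -1e-12)

    def test_drawn_rates_center_on_requested_mean(self):
        # law-of-large-numbers check on the generator itself
        rates = []
        for s in range(10):
            _, truth = simulate.simulate_distance_trace(
                burst_rate_mean=3.3, burst_rate_rel_sd=0.2, seed=s
            )
            rates.extend(truth.burst_rates)
        rates = np.asarray(rates)
        assert rates.size >= 50
        sem = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - 3.3) < 3 * sem

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_distance_trace(burst_rate_mean=-1.0)

    def test_determinism(self):
        a, _ = simulate.simulate_distance_trace(seed=11)
        b, _ = simulate.simulate_distance_trace(seed=11)
        np.testing.assert_array_equal(a.distance, b.distance)


class TestDecaySim:
    def test_zero_rate_constant(self):
        tr = simulate.simulate_decay_trace(k=0.0, A=2.0, C=1.0, noise_sigma=0.0)
        np.testing.assert_allclose(tr.intensity, 3.0)

    def test_closed_form_value(self):
        tr = simulate.simulate_decay_trace(
            k=0.1, A=1.0, C=0.0, total_dur=20.0, dt=0.5, noise_sigma=0.0
        )
        i10 = np.argmin(np.abs(tr.time - 10.0))
        assert tr.intensity[i10] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_determinism(self):
        a = simulate.simulate_decay_trace(noise_sigma=0.05, seed=3)
        b = simulate.simulate_decay_trace(noise_sigma=0.05, seed=3)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_decay_trace(k=-0.1)


class TestFretSim:
    def test_no_release_stays_bound(self):
        trace, truth = simulate.simulate_fret_trace(
            k_bind=1.0, k_release=0.0, n_frames=200, start_state="bound",
            noise_sigma=0.0, seed=0,
        )
        assert np.all(truth.state_path == 0)
        np.testing.assert_allclose(trace.E, 0.2, atol=1e-12)

    def test_noiseless_E_bounded_by_states(self):
        trace, _ = simulate.simulate_fret_trace(
            E_low=0.2, E_high=0.8, k_bind=5.0, k_release=5.0,
            n_frames=500, noise_sigma=0.0, seed=1,
        )
        # exposure averaging keeps E inside [E_low, E_high]
        assert trace.E.min() >= 0.2 - 1e-12
        assert trace.E.max() <= 0.8 + 1e-12

    def test_free_dwell_mean_matches_binding_rate(self):
        k_bind = 2.0
        dwells = []
        for s in range(30):
            _, truth = simulate.simulate_fret_trace(
                k_bind=k_bind, k_release=2.0, n_frames=5000, seed=s
            )
            # interior dwells only: first/last are censored by the window
            for st, dur in list(zip(truth.dwell_states, truth.dwell_durations))[1:-1]:
                if st == "free":
                    dwells.append(dur)
        dwells = np.asarray(dwells)
        assert dwells.size > 1000
        sem = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert abs(dwells.mean() - 1.0 / k_bind) < 3 * sem

    def test_invalid_efficiencies_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_fret_trace(E_low=0.9, E_high=0.3)
        with pytest.raises(ValueError):
            simulate.simulate_fret_trace(E_low=-0.1, E_high=0.8)

    def test_determinism(self):
        a, _ = simulate.simulate_fret_trace(noise_sigma=0.05, seed=9)
        b, _ = simulate.simulate_fret_trace(noise_sigma=0.05, seed=9)
        np.testing.assert_array_equal(a.I_A, b.I_A)


class TestFdSim:
    def test_no_events_single_branch_equals_forward_model(self, dsdna_params):
        curve, truth = simulate.simulate_fd_curve(
            dsdna_params, events=None, noise_sigma=0.0, seed=0
        )
        assert truth.loop_sizes.size == 0
        np.testing.assert_allclose(
            curve.force, polymer.wlc_force(curve.extension, dsdna_params), rtol=1e-9
        )

    def test_event_bookkeeping(self, dsdna_params):
        _, truth = simulate.simulate_fd_curve(
            dsdna_params, events=[(10.0, 500.0)], noise_sigma=0.0, seed=0
        )
        np.testing.assert_allclose(truth.loop_sizes, [500.0])
        assert truth.contour_lengths.tolist() == [16_000.0, 16_500.0]

    def test_invalid_events_rejected(self, dsdna_params):
        with pytest.raises(ValueError):
            simulate.simulate_fd_curve(dsdna_params, events=[(10.0, -5.0)])
        with pytest.raises(ValueError):
            simulate.simulate_fd_curve(dsdna_params, events=[(10.0, 50.0), (8.0, 50.0)])

    def test_determinism(self, dsdna_params):
        a, _ = simulate.simulate_fd_curve(dsdna_params, noise_sigma=0.5, seed=2)
        b, _ = simulate.simulate_fd_curve(dsdna_params, noise_sigma=0.5, seed=2)
        np.testing.assert_array_equal(a.force, b.force)


class TestRepairReadSim:
    def test_all_intact(self, amplicon_reference):
        reads, truth = simulate.simulate_repair_reads(
            amplicon_reference, {"intact": 1.0}, n_reads=20, seed=0
        )
        assert all(seq == amplicon_reference for _, seq in reads)
        assert set(truth.labels) == {"intact"}

    def test_sstr_reads_differ_at_exactly_three_positions(
        self, amplicon_reference, donor_substitutions
    ):
        reads, _ = simulate.simulate_repair_reads(
            amplicon_reference, {"SSTR": 1.0},
            donor_subs=donor_substitutions, n_reads=20, seed=0,
        )
        for _, seq in reads:
            diffs = [i for i, (a, b) in enumerate(zip(amplicon_reference, seq)) if a != b]
            assert diffs == [p for p, _ in donor_substitutions]

    def test_mmej_read_has_long_deletion_with_junction_microhomology(
        self, amplicon_reference
    ):
        reads, truth = simulate.simulate_repair_reads(
            amplicon_reference, {"MMEJ": 1.0}, n_reads=5, seed=7
        )
        # re-examine the first read by hand against the stored deletion
        (s, L) = truth.deletions[0]
        assert L > 5
        assert truth.mh_lengths[0] >= 2
        # the stated microhomology really is present at the junction
        m = truth.mh_lengths[0]
        assert (
            amplicon_reference[s : s + m]
            == amplicon_reference[s + L : s + L + m]
        )
        # and the read equals the reference with that deletion applied
        assert reads[0][1] == amplicon_reference[:s] + amplicon_reference[s + L :]

    def test_nhej_deletions_in_1_to_5(self, amplicon_reference):
        _, truth = simulate.simulate_repair_reads(
            amplicon_reference, {"NHEJ": 1.0}, n_reads=50, seed=3
        )
        lengths = [e - s for (s, e) in
                   [(d[0], d[0] + d[1]) for d in truth.deletions]]
        assert all(1 <= l <= 5 for l in lengths)

    def test_microhomology_site_finder_entries_verified_by_hand(self):
        # GATTACA...GATTACA at distance 10: deleting [0, 10) leaves GATTACA
        # following the junction, so the site (0, 10) has mh >= 7... but mh is
        # evaluated base-by-base: ref[0:m] == ref[10:10+m]
        ref = "GATTACACAT" + "GATTACACAT" + "CCGGAACCGGTTAACCGGAACCTTGGAACC"
        sites = simulate.find_microhomology_sites(ref, min_del=6, max_del=12)
        assert (0, 10, 10) in sites  # full-period repeat: mh capped at L
        for s, L, m in sites:
            assert L > 5 and m >= 2
            assert ref[s : s + m] == ref[s + L : s + L + m]

    def test_determinism(self, amplicon_reference, donor_substitutions):
        a, _ = simulate.simulate_repair_reads(
            amplicon_reference, {"intact": 0.5, "NHEJ": 0.5}, n_reads=30, seed=5
        )
        b, _ = simulate.simulate_repair_reads(
            amplicon_reference, {"intact": 0.5, "NHEJ": 0.5}, n_reads=30, seed=5
        )
        assert a == b
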