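"""Synthetic trace generator: state paths, emission model, pseudo-FRET."""

import dataclasses

import numpy as np
import pytest

from intafret.simulate import (
    PSEUDO_FRET,
    GroundTruth,
    SimConfig,
    emit_intensities,
    inject_pseudo_fret,
    simulate_cohort,
    simulate_state_path,
    simulate_trace,
)


class TestStatePath:
    def test_no_binding_when_k_on_zero(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, k_on=0.0)
        truth = simulate_state_path(cfg)
        assert truth.intervals == [("unbound", 0.0, cfg.duration)]
        assert not truth.stc

    def test_first_binding_absorbs_when_p_stc_one(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, p_stc_per_binding=1.0)
        truth = simulate_state_path(cfg)
        bound = [iv for iv in truth.intervals if iv[0] != "unbound"]
        assert len(bound) == 1
        assert bound[0][0] == "stc"
        assert bound[0][2] == cfg.duration
        assert truth.stc

    def test_bound_dwell_mean_matches_exponential(self):
        """Sample mean of bound dwells within 3 s.e. of 1/k_off."""
        cfg = SimConfig(duration=100000.0, injection_time=0.0, k_on=2.0, k_off=2.0, seed=11)
        dwells = []
        rng = np.random.default_rng(5)
        while len(dwells) < 10000:
            truth = simulate_state_path(cfg, rng)
            dwells += [e - s for lbl, s, e in truth.intervals if lbl == "tcc" and e < cfg.duration]
        dwells = np.array(dwells[:10000])
        se = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert abs(dwells.mean() - 0.5) < 3 * se

    def test_no_events_before_injection(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, k_on=5.0)
        truth = simulate_state_path(cfg)
        first = truth.intervals[0]
        assert first[0] == "unbound" and first[2] >= cfg.injection_time

    def test_intervals_tile_duration(self, quiet_config):
        truth = simulate_state_path(quiet_config)
        assert truth.intervals[0][1] == 0.0
        assert np.isclose(truth.intervals[-1][2], quiet_config.duration)
        for prev, cur in zip(truth.intervals, truth.intervals[1:]):
            assert np.isclose(prev[2], cur[1])

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            SimConfig(duration=-1.0)

    def test_occupancy_matches_two_state_theory(self):
        """Long-run bound fraction converges to k_on/(k_on+k_off)."""
        cfg = SimConfig(
            duration=200000.0, injection_time=0.0, k_on=0.5, k_off=1.5, seed=3
        )
        truth = simulate_state_path(cfg)
        bound_time = sum(e - s for lbl, s, e in truth.intervals if lbl == "tcc")
        frac = bound_time / cfg.duration
        expected = cfg.k_on / (cfg.k_on + cfg.k_off)
        assert abs(frac - expected) < 0.01


class TestEmission:
    def _single_tcc_truth(self, cfg, start, end):
        ivs = []
        if start > 0:
            ivs.append(("unbound", 0.0, start))
        ivs.append(("tcc", start, end))
        if end < cfg.duration:
            ivs.append(("unbound", end, cfg.duration))
        return GroundTruth(ivs, stc=False, bleach_donor=np.inf, bleach_acceptor=np.inf)

    def test_noiseless_partition_is_exact(self, quiet_config):
        cfg = dataclasses.replace(
            quiet_config, fret_states={"unbound": 0.0, "tcc": 0.2, "stc": 0.2, "pseudo": 0.06},
            background=0.0, injection_step=0.0,
        )
        truth = self._single_tcc_truth(cfg, 50.0, 51.0)  # one full frame
        trace = emit_intensities(truth, cfg)
        E = trace.acceptor[50] / (trace.donor[50] + trace.acceptor[50])
        assert E == pytest.approx(0.2, abs=1e-12)

    def test_subframe_change_time_averages(self, quiet_config):
        """A mid-frame switch between emitting states at E=0 and E=0.4
        time-averages to frame FRET 0.2."""
        cfg = dataclasses.replace(
            quiet_config, fret_states={"unbound": 0.0, "tcc": 0.0, "stc": 0.4, "pseudo": 0.06},
            background=0.0, injection_step=0.0,
        )
        truth = GroundTruth(
            [("unbound", 0.0, 50.0), ("tcc", 50.0, 50.5), ("stc", 50.5, cfg.duration)],
            stc=True, bleach_donor=np.inf, bleach_acceptor=np.inf,
        )
        trace = emit_intensities(truth, cfg)
        E = trace.acceptor[50] / (trace.donor[50] + trace.acceptor[50])
        assert E == pytest.approx(0.2, abs=1e-12)

    def test_noisy_fret_mean_recovers_level(self):
        cfg = SimConfig(
            frame_interval=1.0, duration=500.0, injection_time=0.0,
            noise_sd=50.0, background=0.0, injection_step=0.0,
            aggregate_rate=0.0, seed=21,
        )
        truth = GroundTruth(
            [("tcc", 0.0, 500.0)], stc=False, bleach_donor=np.inf, bleach_acceptor=np.inf
        )
        trace = emit_intensities(truth, cfg)
        E = trace.acceptor / (trace.donor + trace.acceptor)
        assert E.std() == pytest.approx(0.05, abs=0.02)
        assert abs(E.mean() - 0.16) < 0.01

    def test_total_intensity_conserved_across_fret_states(self, quiet_config):
        """donor + acceptor equals I_total during bound frames regardless of
        the state's FRET level (energy transfer only moves counts)."""
        for E in (0.05, 0.16, 0.5, 0.9):
            cfg = dataclasses.replace(
                quiet_config, background=0.0, injection_step=0.0,
                fret_states={"unbound": 0.0, "tcc": E, "stc": E, "pseudo": 0.06},
            )
            truth = self._single_tcc_truth(cfg, 50.0, 150.0)
            trace = emit_intensities(truth, cfg)
            assert np.allclose(trace.total[50:150], cfg.total_intensity)

    def test_unbound_frames_sit_at_background(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, k_on=0.0)
        truth = simulate_state_path(cfg)
        trace = emit_intensities(truth, cfg)
        for channel in (trace.donor, trace.acceptor):
            assert np.allclose(channel[: cfg.injection_frame], cfg.background)
            assert np.allclose(
                channel[cfg.injection_frame :], cfg.background + cfg.injection_step
            )


class TestPseudoFret:
    def test_zero_rate_leaves_trace_unchanged(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, aggregate_rate=0.0)
        truth = simulate_state_path(cfg)
        trace = emit_intensities(truth, cfg)
        out, exc = inject_pseudo_fret(trace, cfg)
        assert exc == []
        assert np.array_equal(out.donor, trace.donor)

    def test_excursion_fret_level_is_0_06(self, quiet_config):
        # constructed excursion: corrected FRET during saturation equals 0.06
        cfg = dataclasses.replace(quiet_config, aggregate_rate=0.05, seed=3)
        truth = simulate_state_path(cfg)
        trace = emit_intensities(truth, cfg)
        out, exc = inject_pseudo_fret(trace, cfg)
        assert exc, "expected at least one excursion at this rate"
        bg = cfg.background + cfg.injection_step
        s, e = exc[0]
        f = int(s / cfg.frame_interval) + 1
        d = out.donor[f] - bg
        a = out.acceptor[f] - bg
        assert a / (d + a) == pytest.approx(PSEUDO_FRET, abs=1e-9)

    def test_excursion_counts_are_poisson(self):
        cfg = SimConfig(duration=200.0, injection_time=20.0, aggregate_rate=0.02, seed=0)
        counts = []
        rng = np.random.default_rng(17)
        truth = simulate_state_path(cfg, np.random.default_rng(1))
        trace = emit_intensities(truth, cfg, np.random.default_rng(2))
        for _ in range(1000):
            _, exc = inject_pseudo_fret(trace, cfg, rng)
            counts.append(len(exc))
        counts = np.array(counts)
        expected = cfg.aggregate_rate * (cfg.duration - cfg.injection_time)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3 * se


class TestDeterminism:
    def test_identical_seed_reproduces_bit_identical_trace(self):
        cfg = SimConfig(seed=42, duration=120.0, injection_time=10.0)
        t1, g1 = simulate_trace(cfg)
        t2, g2 = simulate_trace(cfg)
        assert np.array_equal(t1.donor, t2.donor)
        assert np.array_equal(t1.acceptor, t2.acceptor)
        assert g1.intervals == g2.intervals

    def test_different_seeds_give_similar_dwell_distributions(self):
        """KS test between dwell samples from two seeds is rarely significant."""
        from scipy.stats import ks_2samp

        cfg = SimConfig(duration=20000.0, injection_time=0.0, k_on=1.0, k_off=2.0)
        rejections = 0
        for rep in range(20):
            d = []
            for seed in (rep, 1000 + rep):
                truth = simulate_state_path(cfg, np.random.default_rng(seed))
                d.append([e - s for lbl, s, e in truth.intervals if lbl == "tcc"])
            if ks_2samp(d[0], d[1]).pvalue < 0.01:
                rejections += 1
        assert rejections <= 2  # expected rate 1% of 20; allow slack

    def test_cohort_traces_are_independent_and_reproducible(self):
        cfg = SimConfig(seed=5, duration=120.0, injection_time=10.0)
        c1 = simulate_cohort(cfg, 3)
        c2 = simulate_cohort(cfg, 3)
        for (t1, _), (t2, _) in zip(c1, c2):
            assert np.array_equal(t1.donor, t2.donor)
        assert not np.array_equal(c1[0][0].donor, c1[1][0].donor)
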