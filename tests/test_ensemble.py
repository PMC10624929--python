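"""Ensemble statistics: TDP, PSH, FRET histograms, Gaussians, %STC."""

import numpy as np
import pytest

from intafret.ensemble import (
    LabelMix,
    correct_label_mixing,
    fit_gaussians,
    fret_histogram,
    infer_event_count,
    post_synchronized_histogram,
    round_half_up,
    stc_frequency,
    stc_frequency_stderr,
    transition_density,
)
from intafret.traces import FretTrace
from test_kinetics import ideal_from_levels


def fret_from_E(E, dt=1.0):
    E = np.asarray(E, dtype=float)
    return FretTrace(dt, E, E == 0.0)


class TestTransitionDensity:
    def test_alternating_trace_gives_mirrored_peaks(self):
        E = np.array([0.0, 0.2] * 5 + [0.0])
        tdp = transition_density([ideal_from_levels(E)], bin_width=0.02)
        up = tdp.counts[0, 10]     # (0.00-0.02, 0.20-0.22)
        down = tdp.counts[10, 0]
        assert up == 5 and down == 5
        assert tdp.total == 10

    def test_constant_trace_contributes_nothing(self):
        tdp = transition_density([ideal_from_levels([0.2] * 50)])
        assert tdp.total == 0
        assert tdp.counts.sum() == 0

    def test_up_and_down_counts_balance_in_reversible_cohort(self):
        rng = np.random.default_rng(11)
        ideals = []
        for _ in range(30):
            E = np.where(rng.uniform(size=200) < 0.3, 0.2, 0.0)
            ideals.append(ideal_from_levels(E))
        tdp = transition_density(ideals, bin_width=0.02)
        up = tdp.counts[0, 10]
        down = tdp.counts[10, 0]
        assert abs(up - down) <= len(ideals)

    def test_total_matches_per_trace_transition_bookkeeping(self):
        from intafret.kinetics import count_transitions

        rng = np.random.default_rng(12)
        ideals = []
        for _ in range(20):
            E = np.where(rng.uniform(size=150) < 0.4, 0.3, 0.0)
            ideals.append(ideal_from_levels(E))
        tdp = transition_density(ideals)
        up = sum(count_transitions(i) for i in ideals)
        down = sum(
            int(np.sum((i.E_ideal[:-1] > 0.1) & (i.E_ideal[1:] <= 0.1))) for i in ideals
        )
        assert tdp.total == up + down


class TestPostSyncHistogram:
    def test_single_event_counts_conserved_in_fret_bin(self):
        E = np.zeros(50)
        E[10:13] = 0.205  # 3 frames inside the 0.20-0.21 FRET bin
        psh = post_synchronized_histogram([fret_from_E(E)], [0], 1.0)
        assert psh.total == 3
        fret_col = psh.counts.sum(axis=0)
        assert fret_col[20] == 3 and fret_col.sum() == 3

    def test_injection_shift_is_equivariant(self):
        E = np.zeros(80)
        E[40:45] = 0.3
        a = post_synchronized_histogram([fret_from_E(E)], [0], 1.0, time_bin=1.0)
        b = post_synchronized_histogram([fret_from_E(E)], [10], 1.0, time_bin=1.0)
        t_a = np.flatnonzero(a.counts.sum(axis=1))
        t_b = np.flatnonzero(b.counts.sum(axis=1))
        assert (t_a - t_b == 10).all()

    def test_total_counts_equal_nonzero_frames(self):
        rng = np.random.default_rng(13)
        frets = []
        for _ in range(10):
            E = np.where(rng.uniform(size=120) < 0.2, rng.uniform(0.1, 0.4), 0.0)
            frets.append(fret_from_E(E))
        psh = post_synchronized_histogram(frets, [0] * 10, 1.0)
        expected = sum(int((f.E > 0).sum()) for f in frets)
        assert psh.total == expected == psh.counts.sum()

    def test_default_time_bins_follow_frame_rate(self):
        E = np.zeros(200); E[5] = 0.2
        fast = post_synchronized_histogram([fret_from_E(E, 0.1)], [0], 0.1)
        slow = post_synchronized_histogram([fret_from_E(E, 1.0)], [0], 1.0)
        assert np.isclose(np.diff(fast.time_edges)[0], 0.3)
        assert np.isclose(np.diff(slow.time_edges)[0], 0.91)

    def test_mixed_frame_rates_rejected(self):
        with pytest.raises(ValueError, match="frame rates"):
            post_synchronized_histogram(
                [fret_from_E(np.zeros(50), 0.1), fret_from_E(np.zeros(50), 1.0)],
                [0, 0],
                0.1,
            )

    def test_cohort_peak_at_generating_efficiency(self):
        rng = np.random.default_rng(14)
        frets = []
        for _ in range(50):
            bound = rng.uniform(size=300) < 0.3
            E = np.where(bound, np.clip(rng.normal(0.16, 0.05, 300), 0.01, 1), 0.0)
            frets.append(fret_from_E(E))
        psh = post_synchronized_histogram(frets, [0] * 50, 1.0)
        marginal = psh.counts.sum(axis=0)
        centers = 0.5 * (psh.fret_edges[:-1] + psh.fret_edges[1:])
        assert centers[np.argmax(marginal)] == pytest.approx(0.16, abs=0.02)


class TestFretHistogram:
    def test_per_dna_normalization_removes_cohort_size(self):
        E = np.zeros(100)
        E[20:40] = 0.25
        one = fret_histogram([fret_from_E(E)], per_dna=True)
        two = fret_histogram([fret_from_E(E)] * 2, per_dna=True)
        np.testing.assert_allclose(one.counts, two.counts)

    def test_pseudo_only_cohort_renormalizes_to_unit_area(self):
        E = np.zeros(200)
        E[50:150] = 0.06
        hist = fret_histogram([fret_from_E(E)], renormalize_pseudo=True)
        assert hist.area((0.03, 0.09)) == pytest.approx(1.0)

    def test_binding_rate_ratio_preserved_after_renormalization(self):
        """Two conditions with equal aggregate (pseudo-FRET) levels but 5x
        different binding occupancy show a ~5x specific-peak ratio."""
        rng = np.random.default_rng(15)

        def cohort(p_bound):
            frets = []
            for _ in range(40):
                E = np.zeros(300)
                E[rng.uniform(size=300) < 0.05] = 0.06          # aggregates
                bound = rng.uniform(size=300) < p_bound
                E[bound] = np.clip(rng.normal(0.25, 0.04, int(bound.sum())), 0.12, 1)
                frets.append(fret_from_E(E))
            return frets

        lo = fret_histogram(cohort(0.04), renormalize_pseudo=True)
        hi = fret_histogram(cohort(0.20), renormalize_pseudo=True)
        ratio = hi.area((0.12, 0.40)) / lo.area((0.12, 0.40))
        assert ratio == pytest.approx(5.0, rel=0.25)

    def test_empty_pseudo_peak_rejected(self):
        E = np.zeros(100)
        E[10:20] = 0.5
        with pytest.raises(ValueError, match="pseudo"):
            fret_histogram([fret_from_E(E)], renormalize_pseudo=True)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fret_histogram([])


class TestGaussianFits:
    def _hist_from_samples(self, samples, bin_width=0.01):
        frets = [fret_from_E(np.clip(samples, 1e-6, 1.0))]
        return fret_histogram(frets, bin_width=bin_width)

    def test_single_component_recovered(self):
        rng = np.random.default_rng(16)
        hist = self._hist_from_samples(rng.normal(0.16, 0.05, 10000))
        model = fit_gaussians(hist, n=1)
        (c,) = model.components
        assert c.mean == pytest.approx(0.16, abs=0.005)
        assert c.sd == pytest.approx(0.05, abs=0.01)

    def test_two_separated_components_recovered(self):
        rng = np.random.default_rng(17)
        samples = np.concatenate(
            [rng.normal(0.10, 0.04, 6000), rng.normal(0.27, 0.04, 6000)]
        )
        model = fit_gaussians(self._hist_from_samples(samples), n=2)
        means = sorted(c.mean for c in model.components)
        assert means[0] == pytest.approx(0.10, abs=0.01)
        assert means[1] == pytest.approx(0.27, abs=0.01)

    def test_symmetric_histogram_mean_equals_sample_mean(self):
        rng = np.random.default_rng(18)
        samples = rng.normal(0.4, 0.06, 20000)
        hist = self._hist_from_samples(samples)
        model = fit_gaussians(hist, n=1)
        assert model.components[0].mean == pytest.approx(samples.mean(), abs=0.005)

    def test_error_shrinks_with_sample_size(self):
        rng = np.random.default_rng(19)
        errs = []
        for n in (500, 50000):
            hist = self._hist_from_samples(rng.normal(0.2, 0.05, n))
            errs.append(abs(fit_gaussians(hist, n=1).components[0].mean - 0.2))
        assert errs[1] < errs[0]

    def test_invalid_component_count_rejected(self):
        rng = np.random.default_rng(20)
        hist = self._hist_from_samples(rng.normal(0.2, 0.05, 1000))
        with pytest.raises(ValueError, match="n must be"):
            fit_gaussians(hist, n=4)


class TestStcFrequency:
    def test_catalytically_dead_condition_arithmetic(self):
        s = stc_frequency(2, 564)
        assert round_half_up(s.pct, 2) == 0.35
        assert round_half_up(s.pct, 1) == 0.4
        assert round_half_up(s.sigma, 1) == 0.6

    def test_zero_events(self):
        s = stc_frequency(0, 100)
        assert s.pct == 0.0 and s.sigma == 0.0

    def test_reported_sigma_formula_reproduces_printed_uncertainties(self):
        # (n, N, printed sigma at 1 d.p.)
        for n, N, sigma in [(2, 564, 0.6), (125, 614, 4.0), (134, 547, 4.3)]:
            assert round_half_up(stc_frequency(n, N).sigma, 1) == sigma

    def test_sigma_differs_from_binomial_standard_error(self):
        s = stc_frequency(125, 614)
        se = stc_frequency_stderr(125, 614)
        # the reported sigma equals se * sqrt(N)/10, not the standard error
        assert s.sigma == pytest.approx(se * np.sqrt(614) / 10, rel=1e-9)
        assert s.sigma != pytest.approx(se, rel=0.5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            stc_frequency(5, 0)
        with pytest.raises(ValueError):
            stc_frequency(11, 10)


class TestInferEventCount:
    @pytest.mark.parametrize(
        "pct,N,n", [(20.4, 614, 125), (24.5, 547, 134), (0.0, 100, 0)]
    )
    def test_unique_inversion(self, pct, N, n):
        assert infer_event_count(pct, N) == n

    def test_round_trip_with_stc_frequency(self):
        for n, N in [(2, 564), (125, 614), (134, 547), (96, 609)]:
            pct = round_half_up(stc_frequency(n, N).pct, 1)
            try:
                assert infer_event_count(pct, N) == n
            except ValueError as err:
                assert "ambiguous" in str(err)  # several n can print alike

    def test_unreachable_percentage_rejected(self):
        with pytest.raises(ValueError, match="no event count"):
            infer_event_count(50.0, 3)


class TestLabelMixing:
    def test_dual_label_correction_reproduces_totals(self):
        total, undetectable = correct_label_mixing(15.6)
        assert round(total) == 21
        assert round(undetectable) == 5
        assert total == pytest.approx(20.8)
        assert undetectable == pytest.approx(5.2)

    def test_zero_observed_gives_zero(self):
        assert correct_label_mixing(0.0) == (0.0, 0.0)

    def test_all_dual_mix_is_identity(self):
        mix = LabelMix(p_dual=1.0, p_donor_only=0.0, p_acceptor_only=0.0)
        total, undetectable = correct_label_mixing(12.0, mix)
        assert total == 12.0 and undetectable == 0.0

    def test_inconsistent_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LabelMix(p_dual=0.5, p_donor_only=0.5, p_acceptor_only=0.5)
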