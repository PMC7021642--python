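"""Spectral estimation, band powers, the marker, and the scalp models."""

import numpy as np
import pandas as pd
import pytest

from rtmseeg import spectral, stats
from rtmseeg.preprocess import EpochSet
from rtmseeg.spectral import (ALPHA, BETA, LOW_GAMMA, BandDefinition,
                              band_power, compute_marker, dual_channel_r2,
                              epochs_band_power, interhemispheric_balance,
                              iti_dynamics, marker_outcome_map, psd,
                              rest_treatment_correlation,
                              resting_alpha_balance)

SF = 250.0


def _epochs(data, condition="rest", seg=None):
    names = tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(np.asarray(data, float), SF, names, condition,
                    segment_index=seg)


def _tone(freq, n_epochs=6, n_ch=2, amp=1.0, dur=2.0, phase=0.3):
    t = np.arange(int(dur * SF)) / SF
    x = amp * np.sin(2 * np.pi * freq * t + phase)
    return np.tile(x, (n_epochs, n_ch, 1))


class TestPSD:
    def test_pure_alpha_tone_power_in_band(self):
        f, p = psd(_epochs(_tone(10.0)))
        in_band = (f >= 8) & (f <= 14.5)
        assert p[0, in_band].sum() / p[0].sum() >= 0.95

    def test_parseval_on_white_noise(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((20, 1, int(2 * SF)))
        f, p = psd(_epochs(data))
        total = np.trapezoid(p[0], f)
        assert total == pytest.approx(data.var(), rel=0.05)

    def test_zero_signal_zero_psd(self):
        f, p = psd(_epochs(np.zeros((2, 3, 500))))
        assert (p == 0).all()

    def test_seg_len_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            psd(_epochs(np.zeros((1, 1, 100))), seg_len=1.0)


class TestBandPower:
    def test_gamma_tone_lands_in_gamma_band(self):
        f, p = psd(_epochs(_tone(35.0)))
        g = band_power(f, p, LOW_GAMMA)
        a = band_power(f, p, ALPHA)
        total = np.trapezoid(p, f, axis=-1)
        assert g[0] / total[0] > 0.9
        assert a[0] / total[0] < 0.01

    def test_equal_tones_give_equal_band_powers(self):
        data = _tone(10.0) + _tone(35.0, phase=1.1)
        f, p = psd(_epochs(data))
        a = band_power(f, p, ALPHA)[0]
        g = band_power(f, p, LOW_GAMMA)[0]
        assert a == pytest.approx(g, rel=0.1)

    def test_power_is_quadratic_in_amplitude(self):
        f1, p1 = psd(_epochs(_tone(10.0, amp=1.0)))
        f2, p2 = psd(_epochs(_tone(10.0, amp=2.0)))
        np.testing.assert_allclose(band_power(f2, p2, ALPHA),
                                   4 * band_power(f1, p1, ALPHA), rtol=1e-6)

    def test_additive_over_partition_of_spectrum(self):
        rng = np.random.default_rng(1)
        f, p = psd(_epochs(rng.standard_normal((10, 2, 500))))
        edges = [0.5, 8, 14.5, 29.5, 40, 100]
        parts = [band_power(f, p, BandDefinition(f"b{i}", lo, hi))
                 for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))]
        sel = (f >= edges[0]) & (f <= edges[-1])
        total = np.trapezoid(p[:, sel], f[sel], axis=-1)
        # parts share their edge bins, so the sum overshoots slightly
        np.testing.assert_allclose(sum(parts), total, rtol=0.2)

    def test_band_beyond_nyquist_rejected(self):
        f, p = psd(_epochs(_tone(10.0)))
        with pytest.raises(ValueError):
            band_power(f, p, BandDefinition("hf", 100.0, 200.0))


class TestMarker:
    def _tables(self, n=6, m=4, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        cols = [f"ch{i}" for i in range(m)]
        a = pd.DataFrame(rng.uniform(1, 5, (n, m)), index=idx, columns=cols)
        g = pd.DataFrame(rng.uniform(1, 5, (n, m)), index=idx, columns=cols)
        return a, g

    def test_equal_powers_give_unit_marker(self):
        a, _ = self._tables()
        assert (compute_marker(a, a) == 1.0).all().all()

    def test_marker_doubles_with_gamma(self):
        a, g = self._tables()
        m1 = compute_marker(a, g)
        m2 = compute_marker(a, 2 * g)
        np.testing.assert_allclose(m2, 2 * m1)

    def test_zero_alpha_rejected(self):
        a, g = self._tables()
        a.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="alpha"):
            compute_marker(a, g)

    def test_invert_switch(self):
        a, g = self._tables()
        np.testing.assert_allclose(compute_marker(a, g, invert=True),
                                   1.0 / compute_marker(a, g))

    def test_misaligned_tables_rejected(self):
        a, g = self._tables()
        with pytest.raises(ValueError):
            compute_marker(a, g.iloc[::-1])

    def test_marker_rank_orders_with_planted_ratio(self, recovery_cohort,
                                                   recovery_marker):
        """Measured FC4 marker rank-orders with the planted trait ratio."""
        from scipy.stats import spearmanr
        truth = [recovery_cohort.traits_of(s).gamma_resp
                 / recovery_cohort.traits_of(s).alpha_amp
                 for s in recovery_marker.index]
        rho = spearmanr(recovery_marker["FC4"], truth).statistic
        assert rho > 0.9


class TestMarkerOutcomeMap:
    def test_planted_coupling_found_at_fc4(self, recovery_cohort,
                                           recovery_marker, montage):
        clin = recovery_cohort.clinical.set_index("subject")
        imp = clin.loc[recovery_marker.index, "improvement_t"]
        res = marker_outcome_map(recovery_marker, imp, montage,
                                 n_perm=500, seed=0)
        assert "FC4" in res.significant_channels()
        assert res.statistic["FC4"] > 0.6

    def test_constant_improvement_rejected(self, recovery_marker, montage):
        imp = pd.Series(1.0, index=recovery_marker.index)
        with pytest.raises(ValueError):
            marker_outcome_map(recovery_marker, imp, montage, n_perm=10, seed=0)


class TestInterhemisphericBalance:
    def _synthetic(self, montage, n=20, seed=0, couple=0.0):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(rng.standard_normal((n, 64)),
                            index=[f"s{i}" for i in range(n)],
                            columns=montage.channel_names)
        imp = pd.Series(rng.standard_normal(n), index=vals.index)
        imp = imp + couple * vals["FC4"]
        return vals, imp

    def test_orthogonal_control_reduces_to_simple_r(self, montage):
        vals, imp = self._synthetic(montage, couple=0.8)
        out = interhemispheric_balance(vals, imp, montage).set_index("channel")
        r_simple = np.corrcoef(vals["FC4"], imp)[0, 1]
        r_partial = out.loc["FC4", "r_partial"]
        # FC3 is independent noise: partial and simple r nearly coincide
        assert r_partial == pytest.approx(r_simple, abs=0.1)

    def test_matches_residual_regression_oracle(self, montage):
        vals, imp = self._synthetic(montage, seed=1, couple=0.5)
        out = interhemispheric_balance(vals, imp, montage).set_index("channel")
        for ch in ("FC4", "F3", "T8"):
            pair = montage.pairs[ch]
            z = vals[pair].to_numpy()
            rx = vals[ch] - np.polyval(np.polyfit(z, vals[ch], 1), z)
            ry = imp - np.polyval(np.polyfit(z, imp, 1), z)
            assert out.loc[ch, "r_partial"] == pytest.approx(
                np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_antisymmetric_under_left_right_swap(self, montage):
        vals, imp = self._synthetic(montage, seed=2, couple=0.5)
        swapped = vals.copy()
        for left, right in montage.pairs.items():
            swapped[right] = vals[left]
        a = interhemispheric_balance(vals, imp, montage).set_index("channel")
        b = interhemispheric_balance(swapped, imp, montage).set_index("channel")
        for ch in montage.lateral_channels:
            assert b.loc[montage.pairs[ch], "r_partial"] == pytest.approx(
                a.loc[ch, "r_partial"], abs=1e-12)

    def test_covers_all_54_lateral_channels(self, montage):
        vals, imp = self._synthetic(montage, seed=3)
        out = interhemispheric_balance(vals, imp, montage)
        assert len(out) == 54

    def test_too_few_subjects_rejected(self, montage):
        vals, imp = self._synthetic(montage, n=5)
        with pytest.raises(ValueError):
            interhemispheric_balance(vals, imp, montage)

    def test_restriction_consistency_with_resting_alpha_model(self, montage):
        """The 8-channel prefrontal model returns the same partial r as the
        54-channel model restricted to those channels (only q differs)."""
        vals, imp = self._synthetic(montage, seed=4, couple=0.4)
        full = interhemispheric_balance(vals, imp, montage).set_index("channel")
        sub = resting_alpha_balance(vals, imp, montage).set_index("channel")
        for ch in sub.index:
            assert sub.loc[ch, "r_partial"] == pytest.approx(
                full.loc[ch, "r_partial"], abs=1e-12)

    def test_midline_channel_of_interest_rejected(self, montage):
        vals, imp = self._synthetic(montage)
        with pytest.raises(ValueError):
            resting_alpha_balance(vals, imp, montage,
                                  channels_of_interest=("FC4", "Cz"))


class TestRestingAlphaBalance:
    def test_right_negative_coupling_recovered(self, montage):
        """The planted alpha asymmetry coupling drives a negative resting
        alpha partial correlation at FC4 (and FC4 below its FC3 mirror) in
        at least 80% of trial-sized cohorts."""
        from rtmseeg.pipeline import extract_iti_like_rest
        from rtmseeg.simulate import CohortConfig, generate_cohort
        from rtmseeg import preprocess as pre
        ok_fc4 = ok_order = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = CohortConfig(n_per_group=(15, 2, 2), seed=300 + rep,
                               sfreq=250.0, n_trains=2, rest_dur=60.0)
            cohort = generate_cohort(cfg, montage)
            rows = {}
            for t in cohort.traits:
                if t.group != "Real":
                    continue
                rest = pre.apply_average_reference(
                    extract_iti_like_rest(cohort.rest_recording(t.subject)))
                rows[t.subject] = spectral.epochs_band_power(
                    rest, (ALPHA,))["Alpha"]
            tab = pd.DataFrame(rows).T
            tab.columns = montage.channel_names
            imp = cohort.clinical.set_index(
                "subject").loc[tab.index, "improvement_t"]
            bal = resting_alpha_balance(np.log(tab), imp,
                                        montage).set_index("channel")
            ok_fc4 += bal.loc["FC4", "r_partial"] < 0
            ok_order += bal.loc["FC4", "r_partial"] < bal.loc["FC3",
                                                              "r_partial"]
        assert ok_fc4 / n_rep >= 0.8
        assert ok_order / n_rep >= 0.8


class TestDualChannelModel:
    def test_dual_r2_dominates_single_and_factorises(self, montage):
        rng = np.random.default_rng(5)
        n = 40
        vals = pd.DataFrame(rng.standard_normal((n, 64)),
                            index=[f"s{i}" for i in range(n)],
                            columns=montage.channel_names)
        imp = pd.Series(0.7 * vals["FC4"] - 0.5 * vals["FC3"]
                        + rng.standard_normal(n) * 0.5, index=vals.index)
        out = dual_channel_r2(vals, imp, "FC4", montage)
        assert out["r2_dual"] >= out["r2_single"]
        # adding FC4 after FC3: 1 - R2_dual = (1 - r2_FC3)(1 - r2_FC4.FC3)
        r2_pair = np.corrcoef(vals["FC3"], imp)[0, 1] ** 2
        lhs = 1 - out["r2_dual"]
        rhs = (1 - r2_pair) * (1 - out["r_partial"] ** 2)
        assert lhs == pytest.approx(rhs, abs=1e-10)


class TestITIDynamics:
    def _stationary_epochs(self, seed=0, n_seg=5, per_seg=4):
        rng = np.random.default_rng(seed)
        segs = np.repeat(np.arange(1, n_seg + 1), per_seg)
        data = rng.standard_normal((len(segs), 1, int(2 * SF)))
        return EpochSet(data, SF, ("FC4",), "iti", segment_index=segs)

    def test_stationary_signal_gives_unit_ratios(self):
        eps = {f"s{i}": self._stationary_epochs(seed=i) for i in range(8)}
        dyn = iti_dynamics(eps, channel="FC4")
        assert np.allclose(dyn["summary"]["mean"], 1.0, atol=0.4)
        seg1 = dyn["ratios"][dyn["ratios"]["segment"] == 1]["ratio"]
        assert (seg1 == 1.0).all()

    def test_subject_missing_first_segment_dropped(self):
        eps = {f"s{i}": self._stationary_epochs(seed=i) for i in range(6)}
        broken = self._stationary_epochs(seed=99)
        eps["bad"] = broken.select(broken.segment_index > 1)
        with pytest.warns(UserWarning, match="bad"):
            dyn = iti_dynamics(eps, channel="FC4")
        assert "bad" not in dyn["ratios"]["subject"].unique()

    def test_single_segment_input_rejected(self):
        e = self._stationary_epochs()
        only1 = {f"s{i}": e.select(e.segment_index == 1) for i in range(4)}
        with pytest.raises(ValueError):
            iti_dynamics(only1, channel="FC4")


class TestRestTreatmentCorrelation:
    def test_identical_tables_give_unit_r(self, montage):
        rng = np.random.default_rng(6)
        tab = pd.DataFrame(rng.uniform(1, 2, (10, 64)),
                           columns=montage.channel_names)
        r = rest_treatment_correlation(tab, tab)
        np.testing.assert_allclose(r, 1.0)

    def test_independent_tables_give_null_r(self, montage):
        rng = np.random.default_rng(7)
        n = 60
        a = pd.DataFrame(rng.standard_normal((n, 64)),
                         columns=montage.channel_names)
        b = pd.DataFrame(rng.standard_normal((n, 64)),
                         columns=montage.channel_names)
        r = rest_treatment_correlation(a, b)
        assert (np.abs(r) < 3 / np.sqrt(n)).mean() >= 0.95

    def test_too_few_subjects_rejected(self, montage):
        tab = pd.DataFrame(np.ones((3, 64)), columns=montage.channel_names)
        with pytest.raises(ValueError):
            rest_treatment_correlation(tab, tab)
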