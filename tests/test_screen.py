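"""Percent-effect normalization, hit calling, dose-response, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mdscreen as m


class TestPercentEffect:
    def test_control_anchors(self):
        neutral = [100.0, 102.0, 98.0]
        stim = [500.0, 510.0, 490.0]
        assert m.percent_effect(100.0, neutral, stim) == pytest.approx(0.0)
        assert m.percent_effect(500.0, neutral, stim) == pytest.approx(100.0)
        assert m.percent_effect(300.0, neutral, stim) == pytest.approx(50.0)

    def test_equal_control_medians_error(self):
        with pytest.raises(ValueError, match="undefined"):
            m.percent_effect(1.0, [5.0, 5.0], [5.0, 5.0])

    def test_too_few_control_wells_error(self):
        with pytest.raises(ValueError):
            m.percent_effect(1.0, [5.0], [6.0, 7.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        scale=st.floats(min_value=0.01, max_value=100),
        offset=st.floats(min_value=-1000, max_value=1000),
    )
    def test_affine_invariance(self, scale, offset):
        neutral = np.array([10.0, 12.0, 11.0])
        stim = np.array([50.0, 52.0, 49.0])
        raw = 33.0
        base = m.percent_effect(raw, neutral, stim)
        mapped = m.percent_effect(
            raw * scale + offset, neutral * scale + offset,
            stim * scale + offset,
        )
        assert mapped == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestCallHits:
    def test_single_readout_above_threshold_is_hit(self):
        eff = pd.DataFrame(
            {"effect_prolif": [55.0], "effect_ifng": [10.0]}, index=["c"]
        )
        assert m.call_hits(eff)["hit"].iloc[0]

    def test_boundary_is_strict(self):
        eff = pd.DataFrame(
            {"effect_prolif": [49.0, 50.0, 51.0],
             "effect_ifng": [49.0, 50.0, 10.0]},
            index=["a", "b", "c"],
        )
        hits = m.call_hits(eff)
        assert list(hits["hit"]) == [False, False, True]

    def test_missing_readout_is_untestable(self):
        eff = pd.DataFrame(
            {"effect_prolif": [90.0], "effect_ifng": [np.nan]}, index=["c"]
        )
        hits = m.call_hits(eff)
        assert hits["untestable"].iloc[0] and not hits["hit"].iloc[0]

    def test_hit_set_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        eff = pd.DataFrame(
            {"effect_prolif": rng.uniform(-20, 120, 50),
             "effect_ifng": rng.uniform(-20, 120, 50)}
        )
        prev = None
        for thr in (30, 50, 70, 90):
            hits = set(eff.index[m.call_hits(eff, thr)["hit"]])
            if prev is not None:
                assert hits <= prev
            prev = hits


class TestCounterScreen:
    def _hits(self):
        eff = pd.DataFrame(
            {"effect_prolif": [80.0, 70.0, 20.0],
             "effect_ifng": [10.0, 90.0, 10.0]},
            index=["ok", "direct", "nonhit"],
        )
        return m.call_hits(eff)

    def test_inactive_counter_validates(self):
        counter = pd.DataFrame(
            {"effect_prolif": [5.0, 60.0, 1.0],
             "effect_ifng": [3.0, 5.0, 1.0]},
            index=["ok", "direct", "nonhit"],
        )
        out = m.counter_screen_filter(self._hits(), counter)
        assert out.loc["ok", "validated"]
        assert not out.loc["direct", "validated"]
        assert not out.loc["nonhit", "validated"]

    def test_missing_counter_data_excluded(self):
        counter = pd.DataFrame(
            {"effect_prolif": [5.0], "effect_ifng": [3.0]}, index=["direct"]
        )
        out = m.counter_screen_filter(self._hits(), counter)
        assert out.loc["ok", "counter_missing"]
        assert not out.loc["ok", "validated"]


class TestDoseResponse:
    def test_noise_free_self_consistency(self):
        # the 10-point secondary-screen ladder, true EC50 2.6 uM
        conc = np.array([4.0e-5, 1.3e-5, 4.0e-6, 1.3e-6, 4.0e-7, 1.3e-7,
                         4.0e-8, 1.3e-8, 4.0e-9, 1.3e-9])
        true = dict(bottom=0.0, top=100.0, ec50=2.6e-6, slope=1.0)
        resp = true["bottom"] + (true["top"] - true["bottom"]) / (
            1 + (true["ec50"] / conc) ** true["slope"]
        )
        fit = m.fit_dose_response(conc, resp)
        assert fit.converged
        assert fit.ec50 == pytest.approx(true["ec50"], rel=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-4)
        assert fit.top == pytest.approx(100.0, rel=1e-6)

    def test_flat_response_classified_inactive(self):
        conc = np.geomspace(1e-9, 1e-5, 8)
        rng = np.random.default_rng(0)
        resp = rng.normal(0.0, 1.0, 8)
        fit = m.fit_dose_response(conc, resp)
        assert not fit.converged
        assert "inactive" in fit.message

    def test_monotone_decreasing_allows_negative_slope(self):
        conc = np.geomspace(1e-9, 1e-5, 8)
        resp = 100.0 / (1 + (conc / 1e-7) ** 1.0)  # decreasing
        fit = m.fit_dose_response(conc, resp)
        assert fit.converged
        assert fit.ec50 == pytest.approx(1e-7, rel=1e-4)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            m.fit_dose_response([1e-9, 1e-8, 1e-7], [0, 50, 100])


class TestDonorBinning:
    def test_categories(self):
        counts = m.bin_donor_effects([-5.0, 10.0, 45.0])
        assert counts == {"none": 1, "mild": 1, "strong": 1}

    def test_all_zero_is_none(self):
        assert m.bin_donor_effects([0.0, 0.0]) == {
            "none": 2, "mild": 0, "strong": 0
        }

    def test_boundary_forty_is_mild(self):
        assert m.bin_donor_effects([40.0]) == {
            "none": 0, "mild": 1, "strong": 0
        }


def test_noisy_plate_estimator_bias_is_small():
    effects = {f"c{i}": (float(20 + i), float(30 + i)) for i in range(10)}
    biases = []
    for seed in range(10):
        cfg = m.PlateSimConfig(
            true_effects=effects, plate_noise_sd=5.0, seed=seed,
            n_neutral=16, n_stimulator=16,
        )
        plate, truth = m.gen_plate(cfg)
        eff = m.normalize_plate(plate)
        biases.append(
            (eff["effect_prolif"] - truth["true_effect_prolif"]).mean()
        )
    assert abs(np.mean(biases)) < 5.0 / np.sqrt(16)
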