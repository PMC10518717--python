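"""Generator contracts: ground truth, determinism, noise-free limits."""

import numpy as np
import pandas as pd
import pytest

import mdscreen as m


class TestTmtProfile:
    def test_regulated_count_matches_fraction(self):
        _, truth = m.gen_tmt_profile(
            m.ProfileSimConfig(n_proteins=1000, frac_regulated=0.1, seed=1)
        )
        assert truth["regulated"].sum() == 100

    def test_noise_free_fold_changes_exact(self):
        cfg = m.ProfileSimConfig(
            n_proteins=50, noise_sd_log2=0.0, missing_rate=0.0,
            batch_factor_log2=0.0, seed=2,
        )
        mat, truth = m.gen_tmt_profile(cfg)
        lg = mat.log2()
        fc = (
            lg[mat.channels_for("B")].mean(axis=1)
            - lg[mat.channels_for("A")].mean(axis=1)
        )
        np.testing.assert_allclose(fc, truth["true_log2fc"], atol=1e-9)

    def test_seed_reproducibility_bit_for_bit(self):
        cfg = m.ProfileSimConfig(n_proteins=40, missing_rate=0.1, seed=7)
        a, ta = m.gen_tmt_profile(cfg)
        b, tb = m.gen_tmt_profile(cfg)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(ta, tb)

    def test_bridge_channel_present_per_plex(self):
        mat, _ = m.gen_tmt_profile(
            m.ProfileSimConfig(n_proteins=10, n_plexes=3, bridge=True,
                               seed=0)
        )
        per_plex = mat.channels.groupby("plex")["bridge"].sum()
        assert (per_plex == 1).all()

    def test_missing_rate_applied(self):
        mat, _ = m.gen_tmt_profile(
            m.ProfileSimConfig(n_proteins=500, missing_rate=0.2, seed=3)
        )
        frac = mat.intensities.isna().to_numpy().mean()
        assert 0.15 < frac < 0.25

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            m.ProfileSimConfig(n_proteins=0)
        with pytest.raises(ValueError):
            m.ProfileSimConfig(frac_regulated=1.5)
        with pytest.raises(ValueError):
            m.ProfileSimConfig(noise_sd_log2=float("nan"))


class TestPulldownSim:
    def test_residual_binding_half_at_effective_kd(self):
        # Kd 100 nM with cf 0.5 -> Kd_eff 200 nM; binding at 200 nM = 1/2
        ladder = (0.0, 50e-9, 200e-9, 1e-6)
        cfg = m.PulldownSimConfig(
            n_proteins=1, n_targets=1, dose_ladder=ladder,
            true_kd=100e-9, depletion_cf=0.5, noise_cv=0.0, seed=0,
        )
        series, _ = m.gen_pulldown_series(cfg)
        ratios = m.relative_binding(series[0])
        assert ratios[2] == pytest.approx(0.5, abs=1e-12)

    def test_non_target_ratios_unity_noise_free(self):
        cfg = m.PulldownSimConfig(
            n_proteins=3, n_targets=0, noise_cv=0.0, seed=1
        )
        series, _ = m.gen_pulldown_series(cfg)
        for s in series:
            np.testing.assert_allclose(
                m.relative_binding(s), 1.0, atol=1e-12
            )

    def test_pdpd_equals_pd_when_cf_one(self):
        cfg = m.PulldownSimConfig(
            n_proteins=1, n_targets=1, depletion_cf=1.0, noise_cv=0.0,
            seed=2,
        )
        series, _ = m.gen_pulldown_series(cfg)
        assert series[0].pdpd_intensity == pytest.approx(
            series[0].pd_intensity
        )

    def test_default_ladder_matches_assay_design(self):
        cfg = m.PulldownSimConfig()
        np.testing.assert_allclose(
            cfg.dose_ladder,
            (0, 10e-9, 30e-9, 100e-9, 300e-9, 1e-6, 3e-6, 30e-6),
        )

    def test_invalid_cf_rejected(self):
        with pytest.raises(ValueError):
            m.PulldownSimConfig(depletion_cf=0.0)
        with pytest.raises(ValueError):
            m.PulldownSimConfig(depletion_cf=1.5)


class TestSolventProfiles:
    def test_no_shift_means_identical_distributions(self):
        cfg = m.SipSimConfig(
            n_proteins=100, midpoint_shift=0.0, noise_sd_log2=0.0, seed=4
        )
        mat, truth = m.gen_solvent_profiles(cfg)
        active = mat.intensities[mat.channels_for("cmpd2_high")]
        ref = mat.intensities[mat.channels_for("cmpd3_high")]
        np.testing.assert_allclose(active.to_numpy(), ref.to_numpy())

    def test_positive_shift_raises_pooled_intensity(self):
        cfg = m.SipSimConfig(
            n_proteins=50, n_stabilized=10, noise_sd_log2=0.0, seed=5
        )
        mat, truth = m.gen_solvent_profiles(cfg)
        stab = truth.index[truth["stabilized"]]
        active = mat.intensities.loc[stab, mat.channels_for("cmpd2_high")]
        ref = mat.intensities.loc[stab, mat.channels_for("cmpd3_high")]
        assert (active.to_numpy() > ref.to_numpy()).all()

    def test_full_survival_pools_to_baseline(self):
        from mdscreen.sip import pool_soluble_fractions

        baseline = 12345.0
        pooled = pool_soluble_fractions(np.ones(8) * baseline)
        assert pooled == pytest.approx(baseline)

    def test_seed_reproducibility(self):
        cfg = m.SipSimConfig(n_proteins=30, seed=6)
        a, _ = m.gen_solvent_profiles(cfg)
        b, _ = m.gen_solvent_profiles(cfg)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)


class TestPlate:
    def test_noise_free_round_trip(self):
        cfg = m.PlateSimConfig(
            true_effects={"c1": (55.0, 10.0)}, plate_noise_sd=0.0, seed=0
        )
        plate, _ = m.gen_plate(cfg)
        eff = m.normalize_plate(plate)
        assert eff.loc["c1", "effect_prolif"] == pytest.approx(55.0)
        assert eff.loc["c1", "effect_ifng"] == pytest.approx(10.0)

    def test_controls_only_plate_is_valid(self):
        plate, truth = m.gen_plate(m.PlateSimConfig(seed=1))
        assert set(plate["role"]) == {"neutral", "stimulator"}
        assert truth.empty

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            m.PlateSimConfig(n_neutral=1)


class TestPhosphoProfile:
    def test_unregulated_sites_center_on_zero_after_normalization(self):
        cfg = m.ProfileSimConfig(
            n_proteins=200, frac_regulated=0.0, noise_sd_log2=0.1, seed=8
        )
        proteome, _ = m.gen_tmt_profile(cfg)
        _, report = m.total_sum_normalize(proteome)
        site_cfg = m.ProfileSimConfig(
            n_proteins=200, frac_regulated=0.0, noise_sd_log2=0.1, seed=8
        )
        sites, _ = m.gen_phospho_profile(site_cfg, proteome, n_sites=1000)
        normed = m.normalize_phospho_by_proteome(sites, report)
        lg = normed.log2()
        fc = (
            lg[normed.channels_for("B")].mean(axis=1)
            - lg[normed.channels_for("A")].mean(axis=1)
        )
        assert abs(fc.median()) < 0.05

    def test_site_level_effect_on_constant_protein(self):
        cfg = m.ProfileSimConfig(
            n_proteins=20, frac_regulated=0.0, noise_sd_log2=0.0, seed=9
        )
        proteome, _ = m.gen_tmt_profile(cfg)
        site_cfg = m.ProfileSimConfig(
            n_proteins=20, frac_regulated=1.0, effect_log2=2.0,
            effect_sd=0.0, effect_sign_balanced=False,
            noise_sd_log2=0.0, seed=9,
        )
        sites, truth = m.gen_phospho_profile(site_cfg, proteome, n_sites=50)
        lg = sites.log2()
        fc = (
            lg[sites.channels_for("B")].mean(axis=1)
            - lg[sites.channels_for("A")].mean(axis=1)
        )
        np.testing.assert_allclose(fc, truth["true_site_log2fc"], atol=1e-9)

    def test_site_mapped_to_absent_protein_rejected(self):
        proteome, _ = m.gen_tmt_profile(
            m.ProfileSimConfig(n_proteins=5, seed=0)
        )
        with pytest.raises(ValueError, match="absent"):
            m.gen_phospho_profile(
                m.ProfileSimConfig(n_proteins=5, seed=0),
                proteome,
                site_map=["NOTTHERE"],
            )
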