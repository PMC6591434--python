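import numpy as np
import pytest

from hrvkit.simulate import (
    SyntheticConfig,
    drug_effect_transform,
    generate_cohort,
    generate_rr_series,
    genotype_preset,
)


class TestGenerator:
    def test_all_zero_modulation_gives_constant_series(self):
        cfg = SyntheticConfig(mean_rr=100.0, lf_amp=0, hf_amp=0, noise_sd=0,
                              ectopic_rate=0, n_beats=500)
        s = generate_rr_series(cfg)
        np.testing.assert_allclose(s.rr, 100.0)

    def test_same_seed_reproduces_series(self):
        cfg = SyntheticConfig(seed=42, n_beats=1000, ectopic_rate=0.01)
        a, b = generate_rr_series(cfg), generate_rr_series(cfg)
        np.testing.assert_array_equal(a.rr, b.rr)

    def test_different_seeds_differ(self):
        a = generate_rr_series(SyntheticConfig(seed=1, n_beats=1000))
        b = generate_rr_series(SyntheticConfig(seed=2, n_beats=1000))
        assert not np.array_equal(a.rr, b.rr)

    def test_sdrr_matches_closed_form_at_50k(self):
        cfg = SyntheticConfig(seed=7, n_beats=50000, ectopic_rate=0.0)
        s = generate_rr_series(cfg)
        assert s.rr.std(ddof=1) == pytest.approx(cfg.expected_sdrr, rel=0.03)

    def test_trend_slope_adds_linear_drift(self):
        cfg = SyntheticConfig(lf_amp=0, hf_amp=0, noise_sd=0, ectopic_rate=0,
                              trend_slope=0.01, n_beats=1000)
        s = generate_rr_series(cfg)
        np.testing.assert_allclose(np.diff(s.rr), 0.01, atol=1e-12)

    def test_ectopics_scale_affected_beats(self):
        cfg = SyntheticConfig(lf_amp=0, hf_amp=0, noise_sd=0, ectopic_rate=0.05,
                              ectopic_scale=1.6, n_beats=5000, seed=3)
        s = generate_rr_series(cfg)
        hit = s.rr > 150.0
        assert 0.02 < hit.mean() < 0.08
        np.testing.assert_allclose(s.rr[hit], 160.0)

    def test_nonpositive_rr_raises_with_advice(self):
        cfg = SyntheticConfig(mean_rr=5.0, lf_amp=0, hf_amp=0, noise_sd=50.0,
                              n_beats=2000, seed=0)
        with pytest.raises(ValueError, match="reduce"):
            generate_rr_series(cfg)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(mean_rr=0), dict(noise_sd=-1), dict(ectopic_rate=0.2),
         dict(lf_freq=0.4, hf_freq=0.3), dict(hf_freq=0.6)],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown genotype"):
            genotype_preset("KO")

    def test_transgenic_heart_rate_higher(self):
        wt = generate_rr_series(genotype_preset("WT", seed=1, n_beats=20000))
        tg = generate_rr_series(genotype_preset("TGAC8", seed=1, n_beats=20000))
        hr_wt = 60000.0 / wt.rr.mean()  # bpm
        hr_tg = 60000.0 / tg.rr.mean()
        assert hr_tg > hr_wt

    def test_transgenic_sdrr_lower(self):
        wt = generate_rr_series(genotype_preset("WT", seed=2, n_beats=20000,
                                                ectopic_rate=0.0))
        tg = generate_rr_series(genotype_preset("TGAC8", seed=2, n_beats=20000,
                                                ectopic_rate=0.0))
        assert tg.rr.std(ddof=1) < wt.rr.std(ddof=1)

    def test_sdrr_fold_contrast_in_two_to_three_range(self):
        wt = generate_rr_series(genotype_preset("WT", seed=11, n_beats=50000,
                                                ectopic_rate=0.0))
        tg = generate_rr_series(genotype_preset("TGAC8", seed=12, n_beats=50000,
                                                ectopic_rate=0.0))
        ratio = wt.rr.std(ddof=1) / tg.rr.std(ddof=1)
        assert 2.0 <= ratio <= 3.0

    def test_preset_frequencies_map_into_bands(self):
        for name in ("WT", "TGAC8"):
            cfg = genotype_preset(name)
            t = cfg.mean_rr / 1000.0
            assert 0.4 <= cfg.lf_freq / t < 1.5
            assert 1.5 <= cfg.hf_freq / t <= 5.0


class TestDrugTransforms:
    def test_unknown_drug_rejected(self):
        with pytest.raises(ValueError, match="unknown drug"):
            drug_effect_transform(genotype_preset("WT"), "caffeine")

    def test_pure_function_leaves_input_untouched(self):
        cfg = genotype_preset("WT")
        before = vars(cfg).copy()
        drug_effect_transform(cfg, "atropine")
        assert vars(cfg) == before

    def test_atropine_shortens_wt_rr(self):
        cfg = genotype_preset("WT", seed=5, n_beats=20000)
        pre = generate_rr_series(cfg)
        post = generate_rr_series(drug_effect_transform(cfg, "atropine"))
        assert post.rr.mean() < pre.rr.mean()
        assert post.condition == "atropine"

    def test_dual_blockade_shrinks_modulation_amplitudes(self):
        for name in ("WT", "TGAC8"):
            cfg = genotype_preset(name)
            dual = drug_effect_transform(cfg, "dual")
            assert dual.lf_amp < cfg.lf_amp
            assert dual.hf_amp < cfg.hf_amp

    def test_dobutamine_effect_larger_in_wt(self):
        drops = {}
        for name, seed in (("WT", 21), ("TGAC8", 22)):
            cfg = genotype_preset(name, seed=seed, n_beats=20000)
            pre = generate_rr_series(cfg)
            post = generate_rr_series(drug_effect_transform(cfg, "dobutamine"))
            drops[name] = pre.rr.mean() - post.rr.mean()
        assert drops["WT"] > drops["TGAC8"] > 0

    def test_atropine_interaction_direction(self):
        # parasympathetic blockade cuts RR more in WT than in TGAC8
        drops = {}
        for name, seed in (("WT", 31), ("TGAC8", 32)):
            cfg = genotype_preset(name, seed=seed, n_beats=20000)
            pre = generate_rr_series(cfg)
            post = generate_rr_series(drug_effect_transform(cfg, "atropine"))
            drops[name] = (pre.rr.mean() - post.rr.mean()) / pre.rr.mean()
        assert drops["WT"] > drops["TGAC8"]


class TestCohort:
    def test_cohort_shape_and_pairing(self):
        cohort = generate_cohort(n_per_genotype=3, drug="atropine",
                                 n_beats=1000, seed=9)
        assert len(cohort) == 12  # 2 genotypes x 3 animals x (basal, drug)
        basal = [s for s in cohort if s.condition == "basal"]
        post = [s for s in cohort if s.condition == "atropine"]
        assert {s.animal_id for s in basal} == {s.animal_id for s in post}

    def test_cohort_deterministic_by_seed(self):
        a = generate_cohort(n_per_genotype=2, n_beats=500, seed=4)
        b = generate_cohort(n_per_genotype=2, n_beats=500, seed=4)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.rr, y.rr)
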