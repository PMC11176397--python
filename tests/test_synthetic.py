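"""Synthetic-cohort generators: determinism, analytic expectations, and
ground-truth recovery by the downstream quantifiers."""

import numpy as np
import pandas as pd
import pytest

from sahq import stats as st
from sahq.qeeg import (BANDS, band_metrics, band_power, compute_psd,
                       flag_artifacts, segment_epochs)
from sahq.synthetic_cohort import (BehaviorLinkParams, CohortConfig,
                                   EEGProfile, HazardParams, HistoParams,
                                   PhagoParams, VhypoParams, gen_bead_counts,
                                   gen_eeg_cohort, gen_eeg_recording,
                                   gen_histo_image, gen_outcomes, gen_vhypo)


def _mean_metric(rec, attr, window_s=8.0):
    # 8-s windows (0.125 Hz bins) keep band-edge leakage of the spectral
    # estimator well below the generator tolerances being verified
    vals = []
    for ep in segment_epochs(rec):
        flagged, _ = flag_artifacts(ep)
        if not flagged:
            vals.append(getattr(band_metrics(compute_psd(ep, window_s=window_s)),
                                attr))
    return float(np.nanmean(vals))


class TestEEGGenerator:
    def test_flat_gain_profile_reproduces_flat_spectrum_spr(self, fast_profile):
        rec = gen_eeg_recording(fast_profile, "sham-01", "sham", 2, seed=1)
        assert _mean_metric(rec, "spr") == pytest.approx(22 / 7, rel=0.10)
        assert _mean_metric(rec, "adr") == pytest.approx(4 / 3, rel=0.10)

    def test_doubled_delta_gain_lowers_spr(self, fast_profile):
        rec_sham = gen_eeg_recording(fast_profile, "a", "sham", 2, seed=2)
        doubled = EEGProfile(fs_hz=200.0, duration_s=600.0, pink_gain=0.0,
                             artifact_rate=0.0,
                             base_gains={"delta": 2.0, "theta": 1.0,
                                         "alpha": 1.0, "beta": 1.0})
        rec_sah = gen_eeg_recording(doubled, "a", "sham", 2, seed=2)
        assert _mean_metric(rec_sah, "spr") < _mean_metric(rec_sham, "spr")

    def test_same_seed_bit_identical(self, fast_profile):
        r1 = gen_eeg_recording(fast_profile, "x", "SAH", 2, seed=9)
        r2 = gen_eeg_recording(fast_profile, "x", "SAH", 2, seed=9)
        assert np.array_equal(r1.samples, r2.samples)

    def test_analytic_band_power_prediction(self, fast_profile):
        # power_b ~ gain^2 * bandwidth/nyquist * amplitude^2 within 10%
        prof = EEGProfile(fs_hz=200.0, duration_s=600.0, pink_gain=0.0,
                          artifact_rate=0.0,
                          base_gains={"delta": 2.0, "theta": 1.0,
                                      "alpha": 0.5, "beta": 1.0})
        rec = gen_eeg_recording(prof, "s", "sham", 2, seed=4)
        nyq = prof.fs_hz / 2
        powers = {band: [] for band in BANDS}
        for ep in segment_epochs(rec):  # 6 channels x 2 epochs, independent
            flag_artifacts(ep)
            psd = compute_psd(ep, window_s=8.0)
            for band, (lo, hi) in BANDS.items():
                powers[band].append(band_power(psd, lo, hi))
        for band, (lo, hi) in BANDS.items():
            g = prof.base_gains[band]
            expected = g ** 2 * (hi - lo) / nyq * prof.amplitude_uv ** 2
            assert np.mean(powers[band]) == pytest.approx(expected, rel=0.10)

    def test_delta_schedule_monotone_nonincreasing_over_days(self):
        prof = EEGProfile(fs_hz=200.0)
        gains = [prof.band_gain("SAH", "R2", d, "delta") for d in range(0, 30)]
        assert all(a >= b for a, b in zip(gains, gains[1:]))
        assert gains[0] == pytest.approx(prof.sah_delta_factor_focal)

    def test_focal_delta_exceeds_diffuse(self):
        prof = EEGProfile(fs_hz=200.0)
        assert (prof.band_gain("SAH", "R3", 2, "delta")
                > prof.band_gain("SAH", "L1", 2, "delta"))

    def test_artifact_injection_detected_by_rejection_rule(self):
        prof = EEGProfile(fs_hz=200.0, duration_s=600.0, artifact_rate=1.0)
        rec = gen_eeg_recording(prof, "s", "SAH", 2, seed=5)
        assert rec.meta["artifacts"]
        flagged = []
        for ep in segment_epochs(rec):
            f, _ = flag_artifacts(ep)
            flagged.append((ep.channel, ep.t_start_s, f))
        for art in rec.meta["artifacts"]:
            hits = [f for ch, t0, f in flagged
                    if ch == art["channel"] and t0 <= art["t_start_s"] < t0 + 300]
            assert any(hits)

    def test_invalid_group_rejected(self, fast_profile):
        with pytest.raises(ValueError, match="group"):
            gen_eeg_recording(fast_profile, "s", "SAHX", 2, seed=0)

    def test_short_recording_flagged_not_fatal(self):
        prof = EEGProfile(fs_hz=200.0, duration_s=60.0)
        rec = gen_eeg_recording(prof, "s", "sham", 2, seed=0)
        assert rec.meta.get("short_recording")


class TestVhypo:
    def test_nonnegative_for_many_seeds(self):
        params = VhypoParams(mean_sham=0.5, sd_sham=1.4)  # heavy truncation
        for seed in range(5):
            tbl = gen_vhypo(params, 20, 20, seed)
            assert (tbl["v_hypo_mm3"] >= 0).all()

    def test_large_sample_means_recover_configuration(self):
        from scipy import stats as sps

        tbl = gen_vhypo(VhypoParams(), n_sah=100_000, n_sham=100_000, seed=3)
        sah = tbl[tbl["group"] == "SAH"]["v_hypo_mm3"]
        sham = tbl[tbl["group"] == "sham"]["v_hypo_mm3"]
        # oracle: analytic zero-truncated normal means
        def trunc_mean(mu, sd):
            return sps.truncnorm.mean(-mu / sd, np.inf, loc=mu, scale=sd)

        assert sah.mean() == pytest.approx(trunc_mean(7.45, 3.86), rel=0.02)
        assert sham.mean() == pytest.approx(trunc_mean(1.56, 1.40), rel=0.02)
        # ... which sit close to the configured group means themselves
        assert sah.mean() == pytest.approx(7.45, rel=0.05)
        assert sham.mean() == pytest.approx(1.56, rel=0.25)

    def test_observer_average_invariant(self):
        tbl = gen_vhypo(VhypoParams(), 10, 10, seed=1)
        assert np.allclose(tbl["v_hypo_mm3"],
                           0.5 * (tbl["v_obs1_mm3"] + tbl["v_obs2_mm3"]))

    def test_determinism_and_sd_validation(self):
        t1 = gen_vhypo(VhypoParams(), 10, 8, seed=2)
        t2 = gen_vhypo(VhypoParams(), 10, 8, seed=2)
        pd.testing.assert_frame_equal(t1, t2)
        with pytest.raises(ValueError):
            VhypoParams(sd_sah=0.0)


class TestHistoImage:
    def test_zero_density_gives_empty_truth(self):
        params = HistoParams(densities={("sham", 2): 0.0})
        _, mask = gen_histo_image(params, "sham", 2, 1, seed=0)
        assert mask.sum() == 0

    def test_low_density_percent_area_matches_poisson_expectation(self):
        params = HistoParams(image_px=(256, 256))
        expected = params.expected_percent_area("SAH", 2, 1)
        fracs = [gen_histo_image(params, "SAH", 2, 1, seed=s)[1].mean() * 100
                 for s in range(40)]
        assert np.mean(fracs) == pytest.approx(expected, rel=0.15)

    def test_same_seed_identical_image(self):
        i1, m1 = gen_histo_image(HistoParams(), "SAH", 2, 5, seed=8)
        i2, m2 = gen_histo_image(HistoParams(), "SAH", 2, 5, seed=8)
        assert np.array_equal(i1, i2) and np.array_equal(m1, m2)

    def test_oversized_cell_rejected(self):
        params = HistoParams(image_px=(16, 16), cell_radius_um_mean=10.0)
        with pytest.raises(ValueError, match="diameter"):
            gen_histo_image(params, "sham", 2, 1, seed=0)

    def test_missing_density_key_is_error(self):
        with pytest.raises(KeyError):
            gen_histo_image(HistoParams(), "sham", 99, 1, seed=0)


def _fake_metrics(config, rng=None, spread=0.9):
    rows = []
    rng = rng or np.random.default_rng(0)
    for sid, group in config.subjects():
        base = 3.1 if group == "sham" else 1.4
        for day in config.days:
            rows.append({"subject_id": sid, "group": group, "day": day,
                         "spr": base + rng.normal(0, spread)})
    return pd.DataFrame(rows)


class TestOutcomes:
    def test_zero_noise_latent_rank_correlation_is_one(self, tiny_cohort):
        cfg = tiny_cohort
        cfg.behavior = BehaviorLinkParams(noise_sd=0.0, target_rho=None)
        metrics = _fake_metrics(cfg)
        out = gen_outcomes(cfg, metrics)
        r = st.spearman(out["spr"], out["garcia_latent"]).statistic
        assert r == pytest.approx(1.0)

    def test_zero_hazards_censor_everyone_alive(self, tiny_cohort):
        cfg = tiny_cohort
        cfg.survival = HazardParams(hazards={g: (0.0,) * 7
                                             for g in ("sham", "SAH", "SAH-FTY")})
        out = gen_outcomes(cfg, _fake_metrics(cfg))
        assert (~out["died"]).all()
        assert (out["survival_day"] == 7).all()

    def test_target_rank_correlation_recovered(self, fast_profile):
        cfg = CohortConfig(n_per_group=67, days=(2,), seed=21, eeg=fast_profile)
        cfg.behavior = BehaviorLinkParams(target_rho=0.5)
        out = gen_outcomes(cfg, _fake_metrics(cfg, np.random.default_rng(5)))
        assert len(out) > 195
        r = st.spearman(out["spr"], out["garcia"]).statistic
        assert r == pytest.approx(0.5, abs=0.1)

    def test_missing_spr_errors_with_subject_name(self, tiny_cohort):
        metrics = _fake_metrics(tiny_cohort)
        metrics = metrics[metrics["subject_id"] != "SAH-02"]
        with pytest.raises(KeyError, match="SAH-02"):
            gen_outcomes(tiny_cohort, metrics)

    def test_garcia_within_scale(self, tiny_cohort):
        out = gen_outcomes(tiny_cohort, _fake_metrics(tiny_cohort))
        assert out["garcia"].between(3, 21).all()

    def test_determinism(self, tiny_cohort):
        m = _fake_metrics(tiny_cohort)
        pd.testing.assert_frame_equal(gen_outcomes(tiny_cohort, m),
                                      gen_outcomes(tiny_cohort, m))


class TestBeadCounts:
    def test_mean_recovered_at_large_n(self):
        tbl = gen_bead_counts(PhagoParams(), n_cells=10_000, seed=1)
        by = tbl.groupby("condition")["beads"].mean()
        assert by["vehicle"] == pytest.approx(1.12, rel=0.05)
        assert by["hemin"] == pytest.approx(6.55, rel=0.05)

    def test_hemin_sd_matches_negative_binomial_parameterisation(self):
        tbl = gen_bead_counts(PhagoParams(), n_cells=20_000, seed=2)
        sd = tbl[tbl["condition"] == "hemin"]["beads"].std()
        assert sd == pytest.approx(3.91, rel=0.10)

    def test_counts_nonnegative_integers_and_deterministic(self):
        t1 = gen_bead_counts(PhagoParams(), 500, seed=3)
        t2 = gen_bead_counts(PhagoParams(), 500, seed=3)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["beads"] >= 0).all()
        assert t1["beads"].dtype.kind == "i"

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            PhagoParams(dispersions={"vehicle": 0.0, "hemin": 4.9})


class TestCohortLevel:
    def test_cohort_shapes_and_config_validation(self, tiny_cohort):
        recs = gen_eeg_cohort(tiny_cohort)
        assert len(recs) == 3 * 2 * 2  # groups x subjects x days
        with pytest.raises(ValueError):
            CohortConfig(n_per_group=0)
        with pytest.raises(ValueError):
            CohortConfig(days=(7, 2))
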