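"""Synthetic cohort generator: SCR traces, patterns, BOLD, ratings."""

import numpy as np
import pytest
from scipy.stats import norm

from imagcond import design, mvpa, scr, stats, synth
from imagcond.design import Phase


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scr_zero_prob": 1.5},
            {"shared_fraction": -0.1},
            {"roi_n_voxels": 0},
            {"scr_amp_csplus": -1.0},
            {"ar1_coef": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synth.SynthConfig(**kwargs)


class TestSCRTrace:
    def test_no_injected_response_scores_zero(self, imagery_acquisition, quiet_scr_config):
        cfg = synth.SynthConfig(
            **{
                **quiet_scr_config.to_dict(),
                "scr_amp_csplus": 0.0,
                "scr_amp_csminus": 0.0,
                "scr_amp_us": 0.0,
            }
        )
        trace = synth.simulate_scr_trace(imagery_acquisition.runs[0], cfg)
        for s in scr.score_run(trace, imagery_acquisition.runs[0][:-1]):
            assert s.raw_amplitude == 0.0

    def test_injected_amplitude_recovered(self, imagery_acquisition, quiet_scr_config):
        """Scored amplitude ≈ injected kernel peak (0.5 µS) on every trial."""
        trace = synth.simulate_scr_trace(imagery_acquisition.runs[0], quiet_scr_config)
        scores = scr.score_run(trace, imagery_acquisition.runs[0][:-1])
        for s in scores:
            assert s.raw_amplitude == pytest.approx(0.5, rel=0.05)

    def test_seeded_determinism(self, imagery_acquisition):
        cfg = synth.SynthConfig(seed=3)
        a = synth.simulate_scr_trace(imagery_acquisition.runs[1], cfg)
        b = synth.simulate_scr_trace(imagery_acquisition.runs[1], cfg)
        assert np.array_equal(a.values, b.values)

    def test_trace_shape_and_positivity(self, imagery_acquisition):
        cfg = synth.SynthConfig(seed=4)
        trace = synth.simulate_scr_trace(imagery_acquisition.runs[0], cfg)
        assert len(trace.values) == int(cfg.scr_sampling_rate * design.ACQUISITION_RUN_DURATION) + 1
        assert np.isfinite(trace.values).all()
        assert (trace.values > 0).all()

    def test_kernel_peaks_inside_scoring_window(self):
        fs = 500.0
        k = synth.scr_response_kernel(fs)
        peak_t = np.argmax(k) / fs
        assert 1.0 < peak_t < 6.0
        assert k.max() == pytest.approx(1.0)


class TestPatternDataset:
    def _decode(self, cfg, train_sel, test_sel, n_participants=6):
        spec = mvpa.CrossClassSpec(*train_sel, *test_sel)
        cohort = synth.simulate_cohort_patterns(
            cfg, [f"sub-{i:02d}" for i in range(n_participants)]
        )
        accs = [
            mvpa.cross_classify(
                ds.select(phase=spec.train_phase, modality=spec.train_modality),
                ds.select(phase=spec.test_phase, modality=spec.test_modality),
                spec,
            )
            for ds in cohort.values()
        ]
        return float(np.mean(accs))

    def test_zero_effect_gives_chance_decoding(self):
        cfg = synth.SynthConfig(
            roi_n_voxels=40, pattern_effect=0.0, participant_effect_sd=0.0, seed=10
        )
        acc = self._decode(
            cfg,
            ("imagery_acquisition", "imagine"),
            ("visual_acquisition", "view"),
            n_participants=10,
        )
        assert acc == pytest.approx(0.5, abs=0.07)

    def test_orthogonal_modalities_do_not_transfer(self):
        cfg = synth.SynthConfig(
            roi_n_voxels=40,
            pattern_effect=6.0,
            shared_fraction=0.0,
            participant_effect_sd=0.0,
            seed=11,
        )
        cross = self._decode(
            cfg, ("imagery_acquisition", "imagine"), ("visual_acquisition", "view")
        )
        within = self._decode(
            cfg, ("imagery_acquisition", "imagine"), ("visual_acquisition", "imagine")
        )
        assert cross == pytest.approx(0.5, abs=0.08)
        assert within > 0.95

    def test_bayes_accuracy_anchor(self):
        """With separation d and unit noise the optimal within-modality
        accuracy is Φ(d/2); the true-direction classifier attains it."""
        d_eff = 2.0
        correct = 0
        total = 0
        for rep in range(60):
            cfg = synth.SynthConfig(
                roi_n_voxels=40,
                pattern_effect=d_eff,
                participant_effect_sd=0.0,
                seed=50_000 + rep,
            )
            pid = "sub-01"
            basis = synth.participant_basis(cfg, pid)
            sched = design.build_acquisition_schedule(Phase.IMAGERY_ACQUISITION, pid, cfg.seed)
            ds = synth.simulate_pattern_dataset(sched, cfg, basis=basis).select(modality="imagine")
            pred = (ds.X @ basis.u_imagine > 0).astype(int)
            correct += int((pred == ds.y()).sum())
            total += len(pred)
        assert correct / total == pytest.approx(norm.cdf(d_eff / 2), abs=0.03)

    def test_cross_modality_transfer_monotone_in_shared_fraction(self):
        means = []
        for sf in (0.0, 0.5, 1.0):
            accs = []
            for rep in range(8):
                cfg = synth.SynthConfig(
                    n_participants=5,
                    roi_n_voxels=40,
                    pattern_effect=2.0,
                    shared_fraction=sf,
                    participant_effect_sd=0.0,
                    seed=60_000 + rep,
                )
                accs.append(
                    self._decode(
                        cfg,
                        ("imagery_acquisition", "imagine"),
                        ("visual_acquisition", "view"),
                        n_participants=5,
                    )
                )
            means.append(np.mean(accs))
        assert means[0] - 0.03 < means[1] < means[2] + 0.03
        assert means[2] > means[0] + 0.05

    def test_rows_align_with_analysis_trials(self, imagery_acquisition):
        cfg = synth.SynthConfig(roi_n_voxels=10)
        ds = synth.simulate_pattern_dataset(imagery_acquisition, cfg)
        assert ds.n_trials == 48  # 12 CS+ + 12 CS− per modality
        assert not ds.labels["reinforced"].any()
        assert np.isfinite(ds.X).all()

    def test_determinism(self, imagery_acquisition):
        cfg = synth.SynthConfig(roi_n_voxels=10, seed=9)
        a = synth.simulate_pattern_dataset(imagery_acquisition, cfg)
        b = synth.simulate_pattern_dataset(imagery_acquisition, cfg)
        assert np.array_equal(a.X, b.X)


class TestBold:
    def test_zero_betas_zero_noise_is_flat(self, imagery_acquisition):
        cfg = synth.SynthConfig(bold_noise_sd=0.0)
        run = imagery_acquisition.runs[0]
        dm = synth.build_trialwise_design(
            run, cfg.tr, int(design.ACQUISITION_RUN_DURATION / cfg.tr)
        )
        sim = synth.simulate_bold_run(
            run, cfg, n_voxels=3, true_betas=np.zeros((dm.matrix.shape[1], 3))
        )
        assert np.allclose(sim.time_series, 0.0)

    def test_white_noise_has_no_lag1_autocorrelation(self, imagery_acquisition):
        cfg = synth.SynthConfig(ar1_coef=0.0, bold_noise_sd=1.0)
        dm_cols = None
        sims = []
        for salt in range(20):
            run = imagery_acquisition.runs[0]
            sim = synth.simulate_bold_run(run, cfg, n_voxels=10, seed_salt=salt)
            resid = sim.time_series - sim.design.matrix @ sim.true_betas
            x = resid - resid.mean(axis=0)
            r1 = (x[1:] * x[:-1]).sum() / (x**2).sum()
            sims.append(r1)
        assert abs(np.mean(sims)) < 0.05

    def test_ar1_autocorrelation_recovered(self, imagery_acquisition):
        cfg = synth.SynthConfig(ar1_coef=0.5, bold_noise_sd=1.0)
        r1s = []
        for salt in range(20):
            sim = synth.simulate_bold_run(
                imagery_acquisition.runs[0], cfg, n_voxels=10, seed_salt=salt
            )
            resid = sim.time_series - sim.design.matrix @ sim.true_betas
            x = resid - resid.mean(axis=0)
            r1s.append((x[1:] * x[:-1]).sum() / (x**2).sum())
        assert np.mean(r1s) == pytest.approx(0.5, abs=0.06)


class TestRatings:
    def test_bounded_and_complete(self):
        r = synth.simulate_ratings(synth.SynthConfig(n_participants=9, seed=2))
        assert r["rating"].between(1, 7).all()
        assert len(r) == 9 * 8  # 8 condition cells per participant

    def test_degenerate_config_maps_to_midpoint(self):
        cfg = synth.SynthConfig(
            rating_shift=0.0,
            rating_noise_sd=0.0,
            rating_participant_sd=0.0,
            rating_baseline=4.0,
            n_participants=5,
        )
        r = synth.simulate_ratings(cfg)
        assert (r["rating"] == 4).all()

    def test_null_shift_is_calibrated(self):
        """Paired t on CS+ vs CS− cell ratings rejects at ≈5% under no shift."""
        rejections = 0
        n_sim = 150
        for s in range(n_sim):
            cfg = synth.SynthConfig(n_participants=27, rating_shift=0.0, seed=40_000 + s)
            r = synth.simulate_ratings(cfg)
            sel = r[(r.phase == "imagery_acquisition") & (r.modality == "imagine")]
            wide = sel.pivot_table(index="participant_id", columns="cs_type", values="rating")
            try:
                tt = stats.paired_t(
                    wide["CSplus"].to_numpy(float), wide["CSminus"].to_numpy(float)
                )
                rejections += tt.p < 0.05
            except stats.InfiniteTError:
                pass
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_positive_shift_orders_medians(self):
        cfg = synth.SynthConfig(n_participants=27, rating_shift=3.0, seed=1)
        r = synth.simulate_ratings(cfg)
        sel = r[(r.phase == "imagery_acquisition") & (r.modality == "imagine")]
        med = sel.groupby("cs_type")["rating"].median()
        assert med["CSplus"] > med["CSminus"]

    def test_determinism(self):
        cfg = synth.SynthConfig(n_participants=4, seed=8)
        assert synth.simulate_ratings(cfg).equals(synth.simulate_ratings(cfg))
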