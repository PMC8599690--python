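import numpy as np
import pandas as pd
import pytest

from fearsig import (
    build_condition_design,
    build_parametric_design,
    build_single_trial_design,
    canonical_hrf,
    compute_vif,
    estimate_single_trial_betas,
    fit_glm,
)
from fearsig.glm import (
    DesignMatrix,
    convolve_boxcars,
    dct_highpass_basis,
    hrf_values,
    motion_expansion,
)


def make_events(n_trials=8, iti=12.0, duration=4.0, seed=0, jitter=0.0):
    rng = np.random.default_rng(seed)
    onsets = 6.0 + np.arange(n_trials) * iti
    if jitter:
        onsets = onsets + rng.uniform(0, jitter, n_trials)
    ratings = 1 + (np.arange(n_trials) % 5)
    return pd.DataFrame(
        {"onset": onsets, "duration": duration, "rating": ratings}
    )


class TestCanonicalHrf:
    def test_zero_at_origin_and_positive_integral(self):
        h = canonical_hrf(tr=0.5)
        assert h[0] == 0.0
        assert h.sum() > 0

    def test_peak_latency(self):
        t = np.arange(0, 32, 0.1)
        h = hrf_values(t)
        assert 4.5 <= t[np.argmax(h)] <= 5.5
        assert h.max() == pytest.approx(1.0, abs=1e-3)  # unit peak

    def test_invalid_tr(self):
        with pytest.raises(ValueError):
            canonical_hrf(tr=0.0)


class TestDesignBuilders:
    def test_motion_expansion_24_columns(self):
        motion = np.random.default_rng(0).normal(size=(50, 6))
        assert motion_expansion(motion).shape == (50, 24)

    def test_dct_column_count_rule(self):
        # floor(2 * 300 * 2 / 128) = 9 drift columns
        assert dct_highpass_basis(300, 2.0, 128.0).shape == (300, 9)

    def test_one_task_column_per_observed_level(self):
        events = make_events(n_trials=10)
        design = build_condition_design(events, tr=2.0, n_scans=80)
        task = [c for c in design.frame.columns if c.startswith("rating_level")]
        assert len(task) == 5
        # a level with no trials is simply absent
        few = make_events(n_trials=3)  # only levels 1..3 present
        d2 = build_condition_design(few, tr=2.0, n_scans=40)
        t2 = [c for c in d2.frame.columns if c.startswith("rating_level")]
        assert t2 == ["rating_level_1", "rating_level_2", "rating_level_3"]

    def test_full_nuisance_block(self):
        events = make_events(n_trials=6)
        motion = np.random.default_rng(1).normal(size=(60, 6))
        design = build_condition_design(events, 2.0, 60, motion=motion)
        assert len(design.columns_with_role("nuisance")) == 24
        assert len(design.columns_with_role("drift")) == 1  # floor(240/128)
        assert design.columns_with_role("intercept") == ["intercept"]

    def test_constant_ratings_drop_modulator(self):
        events = make_events(n_trials=6)
        events["rating"] = 3
        with pytest.warns(UserWarning, match="constant"):
            design = build_parametric_design(events, 2.0, 60)
        assert "modulation" not in design.frame.columns

    def test_modulator_recovers_rating_slope_noiselessly(self):
        events = make_events(n_trials=10, iti=14.0)
        n_scans = 90
        pic = convolve_boxcars(events.onset, events.duration, 1.0, 2.0, n_scans)
        centered = events.rating - events.rating.mean()
        mod = convolve_boxcars(events.onset, events.duration,
                               centered.to_numpy(), 2.0, n_scans)
        y = 2.0 * pic + 1.5 * mod  # amplitude proportional to rating
        design = build_parametric_design(events, 2.0, n_scans)
        fit = fit_glm(y[:, None], design)
        assert fit.beta("modulation")[0] == pytest.approx(1.5, rel=0.05)
        assert fit.beta("modulation")[0] > 0


class TestFitGlm:
    def test_matches_normal_equations_oracle(self):
        """OLS betas equal (XᵀX)⁻¹XᵀY computed independently."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        frame = pd.DataFrame(X, columns=[f"c{i}" for i in range(4)])
        frame["intercept"] = 1.0
        design = DesignMatrix(
            frame=frame,
            roles={**{f"c{i}": "nuisance" for i in range(4)},
                   "intercept": "intercept"},
            tr=2.0,
        )
        Y = rng.normal(size=(10, 3))
        fit = fit_glm(Y, design)
        Xfull = design.matrix
        oracle = np.linalg.solve(Xfull.T @ Xfull, Xfull.T @ Y)
        assert np.max(np.abs(fit.betas - oracle)) < 1e-10

    def test_rank_deficient_design_named(self):
        frame = pd.DataFrame(
            {"a": np.arange(10.0), "zero": np.zeros(10), "intercept": 1.0}
        )
        design = DesignMatrix(
            frame=frame,
            roles={"a": "nuisance", "zero": "nuisance",
                   "intercept": "intercept"},
            tr=1.0,
        )
        with pytest.raises(np.linalg.LinAlgError, match="zero"):
            fit_glm(np.zeros((10, 2)), design)

    def test_highpass_removes_slow_drift(self):
        """A 256-s cosine loses >=99% of its variance to the DCT block."""
        n_scans, tr = 200, 2.0
        t = np.arange(n_scans) * tr
        drift = np.cos(2 * np.pi * t / 256.0)
        events = make_events(n_trials=5, iti=40.0)
        design = build_condition_design(events, tr, n_scans)
        fit = fit_glm(drift[:, None], design)
        assert fit.residuals[:, 0].var() < 0.01 * drift.var()


class TestVif:
    def _design(self, cols: dict) -> DesignMatrix:
        frame = pd.DataFrame(cols)
        frame["intercept"] = 1.0
        roles = {c: "task" for c in cols}
        roles["intercept"] = "intercept"
        return DesignMatrix(frame=frame, roles=roles, tr=1.0)

    def test_orthogonal_columns_give_unit_vif(self):
        n = 32
        basis = np.cos(
            np.pi * np.outer(2 * np.arange(n) + 1, [1, 2, 3]) / (2 * n)
        )
        design = self._design({f"c{i}": basis[:, i] for i in range(3)})
        vif = compute_vif(design)
        assert np.allclose(vif.to_numpy(), 1.0, atol=1e-10)

    def test_correlated_pair_closed_form(self):
        """corr 0.9 between two columns -> VIF = 1/(1-0.81) ~ 5.263."""
        rng = np.random.default_rng(5)
        n = 20000  # large n so the sample correlation is ~exactly 0.9
        u = rng.normal(size=n)
        v = 0.9 * u + np.sqrt(1 - 0.81) * rng.normal(size=n)
        design = self._design({"u": u, "v": v})
        vif = compute_vif(design)
        assert vif["u"] == pytest.approx(1 / (1 - 0.81), rel=0.05)
        assert (vif > 3).all()  # excluded at the standard threshold

    def test_duplicated_column_infinite(self):
        x = np.arange(12.0)
        design = self._design({"a": x, "b": x})
        assert np.isinf(compute_vif(design)).all()


class TestSingleTrial:
    def test_lsa_lss_agree_in_orthogonal_limit(self, tiny_space,
                                               noiseless_truth):
        """Disjoint trials with equal amplitudes: both estimators exact."""
        from fearsig import generate_timeseries

        events = make_events(n_trials=4, iti=40.0)
        events["rating"] = 3  # equal amplitude maps
        Y, _ = generate_timeseries(
            tiny_space, noiseless_truth, events, 2.0, 110,
            drift_amplitude=0.0, ar_phi=0.0, noise_sd=0.0,
        )
        Y = Y[:, :40]  # a voxel subset is enough
        lsa, qc_a = estimate_single_trial_betas(Y, events, 2.0, mode="LSA")
        lss, _ = estimate_single_trial_betas(Y, events, 2.0, mode="LSS")
        assert np.max(np.abs(lsa.data - lss.data)) < 1e-6
        assert not any(r.excluded for r in qc_a)

    def test_lsa_lss_converge_as_trials_separate(self, tiny_space,
                                                 noiseless_truth):
        """Discrepancy between the two estimators shrinks with trial spacing."""
        from fearsig import generate_timeseries

        gaps = {}
        for iti, n_scans in ((8.0, 40), (36.0, 110)):
            events = make_events(n_trials=4, iti=iti)
            Y, _ = generate_timeseries(
                tiny_space, noiseless_truth, events, 2.0, n_scans,
                drift_amplitude=0.0, ar_phi=0.0, noise_sd=0.0,
            )
            Y = Y[:, :40]
            lsa, _ = estimate_single_trial_betas(Y, events, 2.0, mode="LSA")
            lss, _ = estimate_single_trial_betas(Y, events, 2.0, mode="LSS")
            gaps[iti] = np.max(np.abs(lsa.data - lss.data))
        assert gaps[36.0] < gaps[8.0]

    def test_identical_onsets_flagged_excluded(self):
        events = pd.DataFrame(
            {"onset": [10.0, 10.0, 40.0], "duration": 4.0, "rating": [1, 2, 3]}
        )
        Y = np.random.default_rng(0).normal(size=(40, 5))
        _, qc = estimate_single_trial_betas(Y, events, 2.0, mode="LSA")
        assert qc[0].excluded and qc[1].excluded
        assert np.isinf(qc[0].vif)
        assert not qc[2].excluded

    def test_jittered_design_exclusion_fraction_small(self):
        rng = np.random.default_rng(11)
        n_trials = 20
        onsets = np.cumsum(6.0 + rng.uniform(2.0, 6.0, n_trials))
        events = pd.DataFrame(
            {"onset": onsets, "duration": 4.0,
             "rating": 1 + rng.integers(0, 5, n_trials)}
        )
        n_scans = int(np.ceil((onsets[-1] + 20) / 2.0))
        Y = rng.normal(size=(n_scans, 3))
        _, qc = estimate_single_trial_betas(Y, events, 2.0, mode="LSA")
        excluded = np.mean([r.excluded for r in qc])
        assert excluded < 0.15

    def test_lsa_refuses_more_columns_than_scans(self):
        events = pd.DataFrame(
            {"onset": np.arange(12) * 1.5, "duration": 1.0,
             "rating": 1 + np.arange(12) % 5}
        )
        Y = np.zeros((10, 3))  # 12 trial columns + intercept > 10 scans
        with pytest.raises(ValueError, match="LSS"):
            estimate_single_trial_betas(Y, events, 2.0, mode="LSA")
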