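"""DoG density, shared-center joint fit, profiles, microsaccade handling."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import dblquad

from fovealoc.sfl import (detect_microsaccades, dog_density, dog_ring_radius,
                          filter_microsaccade_trials, fit_sfl_model,
                          quadratic_mean_radius, radial_profile)
from fovealoc.synthetic import SFLTrialSpec, make_sfl_trials


class TestDogDensity:
    SIGMA = np.array([[4.0, 1.0], [1.0, 3.0]])

    def test_zero_at_center(self):
        assert dog_density([[0.5, -1.0]], (0.5, -1.0), self.SIGMA, 1.7)[0] == 0.0

    def test_nonnegative_everywhere(self, rng):
        x = rng.uniform(-20, 20, size=(500, 2))
        assert np.all(dog_density(x, (0, 0), self.SIGMA, 2.3) >= 0)

    def test_integrates_to_one(self):
        val, err = dblquad(
            lambda y, x: dog_density([[x, y]], (0, 0), self.SIGMA, 2.0)[0],
            -40, 40, -40, 40)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_ring_radius_closed_form(self):
        sigma, kappa = 2.0, 1.8
        rs = np.linspace(0.01, 12, 4000)
        dens = dog_density(np.column_stack([rs, np.zeros_like(rs)]),
                           (0, 0), sigma**2 * np.eye(2), kappa)
        assert rs[np.argmax(dens)] == pytest.approx(
            dog_ring_radius(sigma, kappa), abs=0.01)

    def test_kappa_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            dog_density([[1.0, 0.0]], (0, 0), np.eye(2), 1.0)


class TestFitSFLModel:
    def sample_generative(self, rng, c0, n_yes=400, n_maybe=300, n_no=400):
        """Trials drawn from the model's own densities (yes/maybe/no)."""
        S = 6.0 * np.eye(2)
        yes = rng.multivariate_normal(c0, S, n_yes)
        maybe = rng.multivariate_normal(c0, 2 * S, n_maybe)
        no = []
        sig_in, kappa = 9.0 * np.eye(2), 2.0
        dmax = None
        while len(no) < n_no:
            x = rng.uniform(-30, 30, size=(n_no * 4, 2)) + c0
            d = dog_density(x, c0, sig_in, kappa)
            if dmax is None:
                dmax = d.max() * 1.5
            no.extend(x[rng.random(len(x)) < d / dmax])
        no = np.array(no[:n_no])
        r = np.vstack([yes, maybe, no])
        return pd.DataFrame({
            "r_x": r[:, 0], "r_y": r[:, 1],
            "response": ["yes"] * n_yes + ["maybe"] * n_maybe + ["no"] * n_no,
        })

    def test_recovers_center_from_generative_densities(self, rng):
        c0 = np.array([2.0, 1.0])
        trials = self.sample_generative(rng, c0)
        model = fit_sfl_model(trials, n_starts=4, seed=0)
        assert np.linalg.norm(model.center - c0) < 0.5
        assert 1.5 < model.kappa < 2.6

    def test_recovers_center_from_ordinal_generator(self, sfl_trials_1500):
        spec, trials, truth = sfl_trials_1500
        model = fit_sfl_model(trials, n_starts=4, seed=0)
        assert np.linalg.norm(model.center - truth["sfl_true"]) < 0.5

    def test_rotation_equivariance(self, rng):
        c0 = np.array([0.0, 0.0])
        trials = self.sample_generative(rng, c0)
        th = 0.6
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = trials.copy()
        rot[["r_x", "r_y"]] = trials[["r_x", "r_y"]].to_numpy() @ R.T
        m0 = fit_sfl_model(trials, n_starts=4, seed=0)
        m1 = fit_sfl_model(rot, n_starts=4, seed=0)
        assert np.linalg.norm(m1.center - R @ m0.center) < 0.2
        assert np.allclose(m1.sigma_yes, R @ m0.sigma_yes @ R.T, atol=0.8)

    def test_likelihood_at_optimum_beats_generative_params(self, sfl_trials_1500):
        """Optimizer sanity: fitted logL >= logL at a nearby reference point."""
        from fovealoc.sfl import _neg_loglik, _chol_pack

        spec, trials, truth = sfl_trials_1500
        model = fit_sfl_model(trials, n_starts=4, seed=0)
        r = {c: trials.loc[trials["response"] == c, ["r_x", "r_y"]].to_numpy()
             for c in ("yes", "maybe", "no")}
        ref = np.concatenate([
            truth["sfl_true"],
            _chol_pack(np.cov(r["yes"].T, bias=True)),
            _chol_pack(np.cov(r["maybe"].T, bias=True)),
            _chol_pack(np.cov(r["no"].T, bias=True) / 4),
            [np.log(np.e - 1)],
        ])
        assert model.logL >= -_neg_loglik(ref, r["yes"], r["maybe"], r["no"]) - 1e-6

    def test_level_ellipses_bracket_ring(self, rng):
        trials = self.sample_generative(rng, np.array([0.0, 0.0]))
        model = fit_sfl_model(trials, n_starts=4, seed=0)
        inner, _ = model.level_ellipses["inner"]
        outer, _ = model.level_ellipses["outer"]
        assert np.all(inner < outer)

    def test_too_few_trials_per_category_rejected(self):
        trials = pd.DataFrame({
            "r_x": np.zeros(30), "r_y": np.zeros(30),
            "response": ["yes"] * 25 + ["maybe"] * 3 + ["no"] * 2,
        })
        with pytest.raises(ValueError, match="maybe"):
            fit_sfl_model(trials)


class TestRadialProfile:
    def test_generative_shapes(self, sfl_trials_1500):
        """Yes profile decreasing from center; no profile rises off-center."""
        _, trials, _ = sfl_trials_1500
        model = fit_sfl_model(trials, n_starts=4, seed=0)
        prof = radial_profile(trials, model, bin_width=2.0, n_boot=100, seed=0)
        yes = prof["yes"]["profile"]
        no = prof["no"]["profile"]
        assert np.argmax(yes) <= 1  # maximum at/near the center
        assert yes[-3:].mean() < 0.2  # and decays outward
        assert np.argmax(no) >= 2  # ring: "no" density peaks off-center
        assert no[0] < 0.35

    def test_single_radius_single_bin(self):
        th = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        trials = pd.DataFrame({
            "r_x": 5.5 * np.cos(th), "r_y": 5.5 * np.sin(th),
            "response": ["yes"] * 60,
        })
        model_center = np.zeros(2)

        class Dummy:
            center = model_center

        prof = radial_profile(trials, Dummy(), bin_width=1.0, max_radius=10,
                              n_boot=10)
        occupied = np.nonzero(prof["yes"]["profile"])[0]
        assert occupied.tolist() == [5]


class TestMicrosaccades:
    def test_filter_counts(self, sfl_trials_1500):
        _, trials, _ = sfl_trials_1500
        kept = filter_microsaccade_trials(trials)
        assert len(kept) == len(trials) - trials["microsaccade_250ms"].sum()

    def test_filter_no_flags_identity(self, sfl_trials_1500):
        _, trials, _ = sfl_trials_1500
        t2 = trials.copy()
        t2["microsaccade_250ms"] = False
        pd.testing.assert_frame_equal(filter_microsaccade_trials(t2), t2)

    def test_filter_has_small_effect_on_sfl(self, sfl_trials_1500):
        """Microsaccade flags are independent of geometry: refit barely moves."""
        _, trials, _ = sfl_trials_1500
        m_all = fit_sfl_model(trials, n_starts=3, seed=0)
        m_filt = fit_sfl_model(filter_microsaccade_trials(trials), n_starts=3,
                               seed=0)
        assert np.linalg.norm(m_all.center - m_filt.center) < 0.5

    def test_detector_finds_injected_jump(self, rng):
        n = 300
        pos = np.cumsum(rng.normal(0, 0.02, size=(n, 2)), axis=0)
        pos[150:] += [10.0, 0.0]
        events = detect_microsaccades(pos, sample_rate_hz=30.0, lam=6.0)
        assert len(events) == 1
        assert abs(events[0]["onset"] - 150) <= 2
        assert events[0]["amplitude"] > 5.0

    def test_drift_below_threshold_no_events(self, rng):
        pos = np.cumsum(rng.normal(0, 0.02, size=(200, 2)), axis=0)
        assert detect_microsaccades(pos, 30.0, lam=8.0) == []

    def test_lambda_limit_no_events(self, rng):
        pos = rng.normal(size=(100, 2))
        assert detect_microsaccades(pos, 30.0, lam=1e9) == []

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_microsaccades(np.zeros((3, 2)), 30.0)


class TestQuadraticMeanRadius:
    def test_isotropic(self):
        assert quadratic_mean_radius(4.0 * np.eye(2)) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        assert quadratic_mean_radius(np.diag([9.0, 16.0])) == pytest.approx(
            np.sqrt(12.5))

    def test_rotation_invariance(self):
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        S = np.diag([9.0, 16.0])
        assert quadratic_mean_radius(R @ S @ R.T) == pytest.approx(
            quadratic_mean_radius(S))

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            quadratic_mean_radius(np.diag([1.0, -1.0]))
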