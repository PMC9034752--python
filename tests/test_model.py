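import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rotadapt as ra
from rotadapt.model import PosteriorSamples, group_epoch_draws

from conftest import hierarchical_dataset


def _random_point(spec, rng):
    S, E, G = spec.shape
    return dict(beta0=float(rng.normal()), alpha=rng.normal(0, 1, E),
                gamma=rng.normal(0, 1, G), delta=rng.normal(0, 1, (E, G)),
                u=rng.normal(0, 1, S), v=rng.normal(0, 0.5, (S, E)),
                tau=rng.gamma(2.0, 0.1, S), lam=rng.gamma(2.0, 0.5, (E, G)),
                sigma2_delta=1.3, sigma2_u=2.1, sigma2_v=0.7,
                a_tau=1.8, b_tau=9.0, nu=7.5)


def _oracle_log_density(spec, df, point):
    """Term-by-term brute-force joint density using scipy, looping over trials."""
    pc = spec.priors
    sidx = {s: i for i, s in enumerate(spec.subjects)}
    eidx = {e: i for i, e in enumerate(spec.epochs)}
    gidx = {g: i for i, g in enumerate(spec.groups)}
    lp = 0.0
    for _, r in df.iterrows():
        s, e, g = sidx[r.subject_id], eidx[r.epoch], gidx[r.group]
        mu = (point["beta0"] + point["alpha"][e] + point["gamma"][g]
              + point["delta"][e, g] + point["u"][s] + point["v"][s, e])
        lp += stats.norm.logpdf(r.movement_direction_deg, mu,
                                1.0 / math.sqrt(point["tau"][s]))
    lp += stats.norm.logpdf(point["beta0"], 0, pc.fixed_sd)
    lp += stats.norm.logpdf(point["alpha"], 0, pc.fixed_sd).sum()
    lp += stats.norm.logpdf(point["gamma"], 0, pc.fixed_sd).sum()
    lp += stats.norm.logpdf(point["delta"], 0,
                            np.sqrt(point["sigma2_delta"] / point["lam"])).sum()
    lp += stats.gamma.logpdf(point["lam"], point["nu"] / 2, scale=2 / point["nu"]).sum()
    lp += stats.norm.logpdf(point["u"], 0, math.sqrt(point["sigma2_u"])).sum()
    lp += stats.norm.logpdf(point["v"], 0, math.sqrt(point["sigma2_v"])).sum()
    for val, (a, b) in ((point["sigma2_delta"], pc.ig_delta),
                        (point["sigma2_u"], pc.ig_u), (point["sigma2_v"], pc.ig_v)):
        lp += stats.invgamma.logpdf(val, a, scale=b)
    lp += stats.gamma.logpdf(point["tau"], point["a_tau"], scale=1 / point["b_tau"]).sum()
    mu_a, sd_a = pc.tau_shape_lognorm
    lp += stats.lognorm.logpdf(point["a_tau"], sd_a, scale=math.exp(mu_a))
    a, b = pc.tau_rate_gamma
    lp += stats.gamma.logpdf(point["b_tau"], a, scale=1 / b)
    lp += stats.expon.logpdf(point["nu"], loc=2, scale=pc.nu_prior_mean - 2)
    return float(lp)


class TestBuildModel:
    def test_dimension_counting(self, small_epoched):
        spec = ra.build_model(small_epoched)
        S, E, G = spec.shape
        assert (S, E, G) == (18, 35, 3)
        # delta: 35 x 3, u: 18, v: 18 x 35, one sigma per subject
        assert spec.n.shape == (18, 35)
        assert spec.n.sum() == 18 * 400

    def test_degenerate_single_cell_is_normal_means_problem(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"subject_id": "s0", "group": "A", "epoch": "e0",
                           "movement_direction_deg": rng.normal(size=50), "valid": True})
        spec = ra.build_model(df)
        assert spec.shape == (1, 1, 1)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_log_density_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("A", "B"):
            for s in range(3):
                for e in ("e1", "e2", "e3", "e4"):
                    rows.append(pd.DataFrame({
                        "subject_id": f"{g}{s}", "group": g, "epoch": e,
                        "movement_direction_deg": rng.normal(2.0, 3.0, size=5),
                        "valid": True}))
        df = pd.concat(rows, ignore_index=True)
        spec = ra.build_model(df)
        point = _random_point(spec, rng)
        impl = spec.log_density(point)
        oracle = _oracle_log_density(spec, df, point)
        assert impl == pytest.approx(oracle, rel=1e-10)

    def test_invalid_inputs_rejected(self, small_epoched):
        with pytest.raises(ValueError, match="missing columns"):
            ra.build_model(small_epoched.drop(columns=["group"]))
        with pytest.raises(ValueError, match="no valid trials"):
            ra.build_model(small_epoched.assign(valid=False))


class TestSamplePosterior:
    def test_conjugate_toy_matches_analytic_posterior(self):
        """One cell, n=2000, broad priors: posterior mean within 2 MC SEs of ybar."""
        rng = np.random.default_rng(1)
        y = rng.normal(5.0, 3.0, size=2000)
        df = pd.DataFrame({"subject_id": "s0", "group": "A", "epoch": "e1",
                           "movement_direction_deg": y, "valid": True})
        spec = ra.build_model(df)
        ps = ra.sample_posterior(spec, chains=2, burn_in=500, draws=2000, seed=7,
                                 store_subject_means=True)
        mu = ps.posterior["subject_epoch_mean"][:, :, 0, 0].ravel()
        analytic_se = y.std(ddof=1) / math.sqrt(len(y))
        mcse = mu.std() / math.sqrt(150.0)  # conservative ESS estimate
        assert abs(mu.mean() - y.mean()) < 2 * mcse + 0.1 * analytic_se
        assert mu.std() == pytest.approx(analytic_se, rel=0.15)

    def test_identical_groups_give_symmetric_difference(self):
        """Duplicating one group's data under two labels centres the difference on 0."""
        rng = np.random.default_rng(5)
        rows = []
        for s in range(6):
            for e in ("e1", "e2"):
                y = rng.normal(4.0, 5.0, size=10)
                for g in ("A", "B"):
                    rows.append(pd.DataFrame({
                        "subject_id": f"{g}{s}", "group": g, "epoch": e,
                        "movement_direction_deg": y, "valid": True}))
        df = pd.concat(rows, ignore_index=True)
        ps = ra.sample_posterior(ra.build_model(df), chains=2, burn_in=300,
                                 draws=1500, seed=11)
        draws = group_epoch_draws(ps, "e1")
        diff = draws["A"] - draws["B"]
        assert abs(diff.mean()) < 4 * diff.std() / math.sqrt(100.0)

    def test_reproducible_under_seed(self, small_epoched):
        sub = small_epoched[small_epoched.epoch.isin(["early_baseline", "early_aftereffect"])]
        spec = ra.build_model(sub)
        a = ra.sample_posterior(spec, chains=1, burn_in=50, draws=100, seed=3)
        b = ra.sample_posterior(spec, chains=1, burn_in=50, draws=100, seed=3)
        assert np.array_equal(a.posterior["cell_mean"], b.posterior["cell_mean"])

    def test_shrinkage_vanishes_for_large_balanced_data(self):
        """Posterior cell means converge to sample cell means as n grows."""
        rng = np.random.default_rng(9)
        truth = np.array([[0.0], [6.0], [12.0]])
        df = hierarchical_dataset(rng, truth, n_subj=4, trials_per_cell=600,
                                  sigma_u=2.0, sigma_v=0.5, sigma_subj=4.0)
        ps = ra.sample_posterior(ra.build_model(df), chains=2, burn_in=400,
                                 draws=1500, seed=13)
        sample_means = df.groupby("epoch")["movement_direction_deg"].mean()
        for k, e in enumerate(ps.epochs):
            post = ps.posterior["cell_mean"][:, :, k, 0].mean()
            assert abs(post - sample_means[e]) < 0.25

    def test_prior_doubling_leaves_cell_means_unchanged(self, small_epoched):
        """Doubling all prior ranges moves posterior cell means by < 0.1 deg."""
        sub = small_epoched[small_epoched.epoch.isin(
            ["early_baseline", "late_baseline", "early_aftereffect", "late_aftereffect"])]
        base = ra.build_model(sub, priors=ra.PriorConfig())
        wide = ra.build_model(sub, priors=ra.PriorConfig().scaled(2.0))
        ps1 = ra.sample_posterior(base, chains=2, burn_in=500, draws=3000, seed=17)
        ps2 = ra.sample_posterior(wide, chains=2, burn_in=500, draws=3000, seed=18)
        m1 = ps1.posterior["cell_mean"].mean(axis=(0, 1))
        m2 = ps2.posterior["cell_mean"].mean(axis=(0, 1))
        assert np.max(np.abs(m1 - m2)) < 0.1


class TestDiagnose:
    @staticmethod
    def _manual_samples(chain_arrays):
        arr = np.stack(chain_arrays)[:, :, None, None]
        return PosteriorSamples(posterior={"cell_mean": arr}, epochs=["e"],
                                groups=["g"], subjects=[], meta={})

    def test_well_mixed_chains_pass(self):
        rng = np.random.default_rng(0)
        ps = self._manual_samples([rng.normal(size=10000) for _ in range(4)])
        rep = ra.diagnose(ps)
        assert rep.max_rhat < 1.01
        assert rep.passed is True
        # iid draws: ESS close to the number of draws
        ess = rep.table["ess_bulk"].iloc[0]
        assert ess > 0.8 * 40000

    def test_offset_chains_fail(self):
        rng = np.random.default_rng(1)
        ps = self._manual_samples([rng.normal(0, 1, 5000), rng.normal(5, 1, 5000)])
        rep = ra.diagnose(ps)
        assert rep.max_rhat > 1.1
        assert rep.passed is False

    def test_single_chain_reported_as_undefined(self):
        rng = np.random.default_rng(2)
        ps = self._manual_samples([rng.normal(size=2000)])
        rep = ra.diagnose(ps)
        assert rep.passed is None
        assert np.isnan(rep.table["rhat"]).all()


class TestCellMeans:
    def test_single_epoch_identity_and_two_epoch_average(self, small_fit):
        ps = small_fit
        e0 = ps.epochs[0]
        single = ra.cell_means(ps, e0)
        assert np.array_equal(single, ps.posterior["cell_mean"][:, :, 0, :])
        pair = ra.cell_means(ps, [ps.epochs[0], ps.epochs[1]])
        manual = 0.5 * (ps.posterior["cell_mean"][:, :, 0, :]
                        + ps.posterior["cell_mean"][:, :, 1, :])
        assert np.allclose(pair, manual)

    def test_epoch_set_mean_matches_coefficient_recombination(self, small_fit):
        """Recompute the epoch-set mean from the stored sum-to-zero coefficients."""
        ps = small_fit
        epochs = ps.epochs[-2:]
        got = ra.cell_means(ps, epochs)
        post = ps.posterior
        idx = [ps.epochs.index(e) for e in epochs]
        oracle = np.zeros_like(got)
        for g in range(len(ps.groups)):
            acc = 0.0
            for e in idx:
                acc = acc + (post["beta0"] + post["alpha"][:, :, e]
                             + post["gamma"][:, :, g] + post["delta"][:, :, e, g])
            oracle[:, :, g] = acc / len(idx)
        assert np.allclose(got, oracle, atol=1e-10)

    def test_unknown_epoch_rejected(self, small_fit):
        with pytest.raises(KeyError):
            ra.cell_means(small_fit, "adaptation_99")
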